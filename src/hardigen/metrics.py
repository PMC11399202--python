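"""Similarity and overlap metrics, and the paired statistical comparison.

Divergences between ODF sample vectors are natural-log Jensen-Shannon
divergences (nats, bounded by ln 2).  The angular correlation coefficient
(ACC) is the normalized inner product of SH coefficients with the
isotropic l=0 term excluded.  Image fidelity uses 3D Gaussian-window SSIM
and PSNR; bundle overlap uses the Dice similarity coefficient (DSC).
Paired comparisons use the Wilcoxon signed-rank test (effect size
r = |Z|/sqrt(N)) and, for three-arm comparisons, the Friedman test with
Bonferroni-corrected pairwise threshold p < 0.0167.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "kl_divergence",
    "jsd",
    "acc",
    "acc_fields",
    "jsd_fields",
    "ssim_volume",
    "psnr_volume",
    "dice",
    "paired_compare",
    "PairedResult",
]

_EPS = 1e-12


def _as_prob(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    s = p.sum(axis=-1, keepdims=True)
    if np.any(np.abs(s - 1.0) > 1e-6):
        raise ValueError(f"{name} does not sum to 1")
    return p


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float | np.ndarray:
    """Kullback-Leibler divergence sum_i P log(P/Q), natural log.

    0*log(0/q) contributes 0; zero entries of Q under positive P are
    floored at 1e-12 (clamped ODF samples can be exactly zero).
    Supports batches along leading axes.
    """
    P = _as_prob(P, "P")
    Q = _as_prob(Q, "Q")
    if P.shape != Q.shape:
        raise ValueError("P and Q must have equal length")
    Qf = np.maximum(Q, _EPS)
    terms = np.where(P > 0, P * np.log(np.maximum(P, _EPS) / Qf), 0.0)
    return terms.sum(axis=-1)


def jsd(P: np.ndarray, Q: np.ndarray) -> float | np.ndarray:
    """Jensen-Shannon divergence (D_KL(P,M) + D_KL(Q,M)) / 2 with
    M = (P + Q)/2; symmetric, in [0, ln 2], zero iff P == Q."""
    P = _as_prob(P, "P")
    Q = _as_prob(Q, "Q")
    M = 0.5 * (P + Q)
    return 0.5 * (kl_divergence(P, M) + kl_divergence(Q, M))


def acc(u: np.ndarray, v: np.ndarray) -> float:
    """Angular correlation coefficient of two SH coefficient sets.

    ACC = sum_{l>=1,m} u_lm v_lm / (||u||_{l>=1} ||v||_{l>=1}); the l=0
    coefficient (index 0 in this package's ordering) is excluded.  Returns
    NaN when either anisotropic part vanishes (undefined ACC).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("SH coefficient sets must match in shape")
    ua, va = u[1:], v[1:]
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.clip(ua @ va / (nu * nv), -1.0, 1.0))


def acc_fields(sh_u: np.ndarray, sh_v: np.ndarray) -> np.ndarray:
    """Vectorized ACC over (n_voxels, n_coeffs) arrays; NaN where undefined."""
    ua, va = sh_u[:, 1:], sh_v[:, 1:]
    nu = np.linalg.norm(ua, axis=1)
    nv = np.linalg.norm(va, axis=1)
    dot = np.einsum("ij,ij->i", ua, va)
    out = np.full(ua.shape[0], np.nan)
    ok = (nu > 0) & (nv > 0)
    out[ok] = np.clip(dot[ok] / (nu[ok] * nv[ok]), -1.0, 1.0)
    return out


def jsd_fields(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorized JSD over (n_voxels, n_bins) probability arrays."""
    return np.asarray(jsd(P, Q))


def _gaussian_stats(x, sigma, truncate):
    return ndimage.gaussian_filter(x, sigma=sigma, truncate=truncate)


def ssim_volume(
    pred: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray | None = None,
    sigma: float = 1.5,
    truncate: float = 3.5,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
    return_map: bool = False,
):
    """Mean structural similarity of two 3D volumes.

    Gaussian window (sigma 1.5, 11^3 support), dynamic range defaulting to
    the reference maximum over the mask.  The SSIM map is averaged over the
    mask, or over the window-interior region when no mask is given.
    """
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape or pred.ndim != 3:
        raise ValueError("pred and ref must be matching 3D volumes")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
        if mask.shape != ref.shape:
            raise ValueError("mask grid does not match the volumes")
    if data_range is None:
        region = ref[mask] if mask is not None else ref
        data_range = float(region.max())
    if data_range <= 0:
        raise ValueError("nonpositive dynamic range")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_x = _gaussian_stats(pred, sigma, truncate)
    mu_y = _gaussian_stats(ref, sigma, truncate)
    mu_xx = _gaussian_stats(pred * pred, sigma, truncate)
    mu_yy = _gaussian_stats(ref * ref, sigma, truncate)
    mu_xy = _gaussian_stats(pred * ref, sigma, truncate)
    var_x = mu_xx - mu_x**2
    var_y = mu_yy - mu_y**2
    cov = mu_xy - mu_x * mu_y
    smap = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    if mask is not None:
        value = float(smap[mask].mean())
    else:
        pad = int(truncate * sigma + 0.5)
        interior = smap[pad:-pad, pad:-pad, pad:-pad] if pad else smap
        value = float(interior.mean())
    return (value, smap) if return_map else value


def psnr_volume(
    pred: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray | None = None,
    data_range: float | None = None,
) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(MAX^2 / MSE) with MAX the
    reference maximum over the mask.  Identical volumes return +inf."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have matching shapes")
    if mask is None:
        mask = np.ones(ref.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
    if data_range is None:
        data_range = float(ref[mask].max())
    mse = float(np.mean((pred[mask] - ref[mask]) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient 2|x∩y| / (|x| + |y|); NaN if both empty."""
    x = np.asarray(getattr(x, "data", x), dtype=bool)
    y = np.asarray(getattr(y, "data", y), dtype=bool)
    if x.shape != y.shape:
        raise ValueError("bundle masks must share one grid")
    vx, vy = int(x.sum()), int(y.sum())
    if vx + vy == 0:
        return float("nan")
    return 2.0 * int((x & y).sum()) / (vx + vy)


@dataclasses.dataclass
class PairedResult:
    statistic: float
    p_value: float
    effect_size: float
    n: int
    method: str
    degenerate: bool = False
    extra: dict = dataclasses.field(default_factory=dict)


def _wilcoxon_z(diff: np.ndarray) -> float:
    """Normal-approximation Z of the signed-rank statistic (no ties split
    correction beyond midranks; zero differences already removed)."""
    n = diff.size
    ranks = stats.rankdata(np.abs(diff))
    w_plus = ranks[diff > 0].sum()
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    if sigma == 0:
        return 0.0
    return (w_plus - mu) / sigma


def paired_compare(
    values_a,
    values_b,
    method: str = "wilcoxon",
    values_c=None,
    bonferroni_threshold: float = 0.0167,
) -> PairedResult:
    """Paired comparison of per-case metric values.

    ``wilcoxon``: signed-rank test (exact for n <= 12 after dropping zero
    differences, normal approximation otherwise), effect size
    r = |Z|/sqrt(N) with N the retained pair count.  ``friedman_bonferroni``:
    Friedman test across three arms followed by pairwise Wilcoxon tests at
    the Bonferroni-corrected threshold.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if method == "wilcoxon":
        diff = b - a
        nz = diff != 0
        if not nz.any():
            return PairedResult(0.0, 1.0, 0.0, 0, method, degenerate=True)
        d = diff[nz]
        n = d.size
        mode = "exact" if n <= 12 else "approx"
        res = stats.wilcoxon(d, method=mode)
        z = _wilcoxon_z(d)
        r = abs(z) / math.sqrt(n)
        return PairedResult(
            float(res.statistic), float(res.pvalue), float(r), int(n), method,
            extra={"z": float(z), "mode": mode},
        )
    if method == "friedman_bonferroni":
        if values_c is None:
            raise ValueError("friedman_bonferroni needs three arms")
        c = np.asarray(values_c, dtype=float)
        if c.shape != a.shape:
            raise ValueError("paired samples must have equal length")
        if np.allclose(a, b) and np.allclose(b, c):
            return PairedResult(0.0, 1.0, 0.0, int(a.size), method, degenerate=True)
        fr = stats.friedmanchisquare(a, b, c)
        pairs = {}
        for name, (x, y) in {
            "a_vs_b": (a, b),
            "a_vs_c": (a, c),
            "b_vs_c": (b, c),
        }.items():
            sub = paired_compare(x, y, "wilcoxon")
            pairs[name] = {
                "p": sub.p_value,
                "effect_size": sub.effect_size,
                "significant": (not sub.degenerate) and sub.p_value < bonferroni_threshold,
            }
        return PairedResult(
            float(fr.statistic), float(fr.pvalue), float("nan"), int(a.size), method,
            extra={"pairwise": pairs, "threshold": bonferroni_threshold},
        )
    raise ValueError(f"unknown method {method!r}")
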