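"""Diffusion model reconstruction: DTI, analytic Q-ball ODFs, GQI SDFs.

DTI is a weighted log-linear least-squares tensor fit.  Q-ball ODFs use the
analytic Funk-Radon transform: the signal is expanded in even-order real SH
with Laplace-Beltrami regularization, and the transform acts diagonally as
2*pi*P_l(0) on the coefficients.  GQI evaluates the spin distribution
function SDF(u) = sum_i S_i sinc-kernel(sigma, b_i, g_i . u) on the sample
hemisphere and projects it to SH so the same downstream metrics apply.

The SH order per dataset follows the direction count: the largest even l
with (l+1)(l+2)/2 <= n_directions, capped at 8 — a 32-direction half-scheme
reconstructs at lmax 6, the full 64-direction data at lmax 8.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dwi_io import DWIVolume
from .gradients import GradientScheme
from .sphere import (
    SphereSampling,
    default_sphere,
    fine_sphere,
    legendre_p0,
    max_lmax_for,
    n_sh_coeffs,
    real_sh_basis,
    sh_fit_matrix,
    sh_index_list,
)

__all__ = [
    "TensorField",
    "ODFField",
    "PeakField",
    "fit_dti",
    "qbi_odf",
    "gqi_sdf",
    "sample_odf",
    "find_peaks",
    "tensor_peaks",
    "roi_statistics",
]

# 6 * D_water at body temperature (mm^2/s); fixes the GQI q-space scaling
GQI_DIFFUSION_SCALE = 0.01506


@dataclasses.dataclass
class TensorField:
    """Eigen-decomposed diffusion tensors with FA / E1 / color-FA maps."""

    eigenvalues: np.ndarray  # (x, y, z, 3), descending, mm^2/s
    eigenvectors: np.ndarray  # (x, y, z, 3, 3); [..., i] is the i-th eigenvector
    mask: np.ndarray
    clamped: np.ndarray  # voxels whose negative eigenvalues were clamped to 0

    @property
    def fa(self) -> np.ndarray:
        l = self.eigenvalues
        num = np.sqrt(
            (l[..., 0] - l[..., 1]) ** 2
            + (l[..., 1] - l[..., 2]) ** 2
            + (l[..., 0] - l[..., 2]) ** 2
        )
        den = np.sqrt((l**2).sum(axis=-1))
        out = np.zeros(l.shape[:-1])
        ok = den > 0
        out[ok] = np.sqrt(0.5) * num[ok] / den[ok]
        return np.clip(out * self.mask, 0.0, 1.0)

    @property
    def e1(self) -> np.ndarray:
        """Principal diffusivity (largest eigenvalue), mm^2/s."""
        return self.eigenvalues[..., 0] * self.mask

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[..., 0]

    @property
    def color_fa(self) -> np.ndarray:
        return self.fa[..., None] * np.abs(self.principal_direction)


@dataclasses.dataclass
class ODFField:
    """Per-voxel spherical function as even-order real SH coefficients."""

    sh: np.ndarray  # (x, y, z, n_coeffs)
    lmax: int
    mask: np.ndarray
    basis: str = "real-symmetric"
    method: str = ""

    def __post_init__(self):
        if self.sh.shape[-1] != n_sh_coeffs(self.lmax):
            raise ValueError("coefficient count does not match lmax")


@dataclasses.dataclass
class PeakField:
    """Up to ``max_peaks`` unit directions per voxel, amplitude-sorted."""

    peaks: np.ndarray  # (x, y, z, max_peaks, 3)
    counts: np.ndarray  # (x, y, z) uint8
    values: np.ndarray  # (x, y, z, max_peaks) amplitudes


def _masked_view(dwi: DWIVolume, mask: np.ndarray | None):
    if mask is None:
        mask = np.ones(dwi.spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sig = dwi.data[mask]
    return mask, sig


def fit_dti(dwi: DWIVolume, mask: np.ndarray | None = None, weighted: bool = True) -> TensorField:
    """Weighted log-linear least-squares tensor fit per masked voxel.

    Weights are the squared observed signals (the standard WLS correction
    for log-transformed Rician-free noise).  Negative eigenvalues are
    clamped to zero and flagged.  All-zero voxels are excluded and flagged
    out of the mask.
    """
    scheme = dwi.scheme
    g = scheme.directions
    b = scheme.bvalues
    if np.count_nonzero(scheme.dwi_mask) < 6:
        raise ValueError("tensor fit needs at least 6 diffusion directions")
    if not scheme.b0_mask.any():
        raise ValueError("tensor fit needs at least one b0 axis")
    mask, sig = _masked_view(dwi, mask)
    nonzero = (sig > 0).all(axis=1)
    mask_fit = mask.copy()
    idx = np.nonzero(mask)
    mask_fit[idx[0][~nonzero], idx[1][~nonzero], idx[2][~nonzero]] = False
    sig = sig[nonzero]

    # design: ln S = ln S0 - b g^T D g, D packed as xx,yy,zz,xy,xz,yz
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    y = np.log(sig)
    w = sig.astype(float) ** 2 if weighted else np.ones_like(sig, dtype=float)
    A = np.einsum("di,vd,dj->vij", X, w, X)
    rhs = np.einsum("di,vd->vi", X, w * y)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]  # (nvox, 7)

    D = np.zeros((beta.shape[0], 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals, axis=1)[:, ::-1]
    evals = np.take_along_axis(evals, order, axis=1)
    evecs = np.take_along_axis(evecs, order[:, None, :], axis=2)
    clamped_v = evals[:, -1] < 0
    evals = np.clip(evals, 0.0, None)

    shape = dwi.spatial_shape
    out_evals = np.zeros(shape + (3,))
    out_evecs = np.zeros(shape + (3, 3))
    out_clamped = np.zeros(shape, dtype=bool)
    out_evals[mask_fit] = evals
    out_evecs[mask_fit] = evecs
    out_clamped[mask_fit] = clamped_v
    return TensorField(out_evals, out_evecs, mask_fit, out_clamped)


def _normalized_signal(dwi: DWIVolume, mask: np.ndarray):
    """Diffusion-attenuation E = S / S0 on masked voxels."""
    b0 = dwi.b0()[mask]
    sig = dwi.data[mask][:, dwi.scheme.dwi_mask]
    b0 = np.where(b0 > 0, b0, 1.0)
    return np.clip(sig / b0[:, None], 0.0, None)


def _check_single_shell(scheme: GradientScheme) -> None:
    b = scheme.bvalues[scheme.dwi_mask]
    if b.size and (b.max() - b.min()) > 1e-6 * max(b.max(), 1.0):
        raise ValueError("single-shell scheme required")


def resolve_lmax(n_directions: int, lmax: int | None) -> int:
    auto = max_lmax_for(n_directions)
    if lmax is None:
        return auto
    if n_sh_coeffs(lmax) > n_directions:
        raise ValueError(
            f"lmax={lmax} needs {n_sh_coeffs(lmax)} coefficients but only "
            f"{n_directions} directions are available (max lmax {auto})"
        )
    return lmax


def qbi_odf(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    lmax: int | None = None,
    regularization: float = 0.006,
) -> ODFField:
    """Analytic Q-ball ODF: SH fit of E = S/S0, then the Funk-Radon
    transform applied diagonally as 2*pi*P_l(0) per order."""
    _check_single_shell(dwi.scheme)
    mask, _ = _masked_view(dwi, mask)
    dirs = dwi.scheme.dwi_directions()
    lmax = resolve_lmax(dirs.shape[0], lmax)
    E = _normalized_signal(dwi, mask)
    M = sh_fit_matrix(dirs, lmax, lb_lambda=regularization)  # (ncoef, ndirs)
    s_lm = E @ M.T
    odf_lm = (2.0 * np.pi) * legendre_p0(lmax)[None, :] * s_lm
    out = np.zeros(dwi.spatial_shape + (odf_lm.shape[1],))
    out[mask] = odf_lm
    return ODFField(out, lmax, mask, method="qbi")


def gqi_sdf(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    sampling_ratio: float = 1.25,
    sphere: SphereSampling | None = None,
    lmax: int | None = None,
) -> ODFField:
    """Generalized q-sampling SDF, sampled on the hemisphere and projected
    to SH.  ``sampling_ratio`` is the GQI sampling-length ratio sigma."""
    _check_single_shell(dwi.scheme)
    if sampling_ratio <= 0:
        raise ValueError("sampling_ratio must be positive")
    sphere = sphere or default_sphere()
    mask, sig = _masked_view(dwi, mask)
    sig = dwi.data[mask]  # all channels, b0 included (kernel value 1 there)
    scheme = dwi.scheme
    lmax = resolve_lmax(scheme.n_dwi, lmax)
    q = scheme.directions * np.sqrt(GQI_DIFFUSION_SCALE * scheme.bvalues)[:, None]
    z = q @ sphere.vertices.T  # (nchan, 181)
    kernel = np.sinc(sampling_ratio * z / np.pi)
    sdf = sig @ kernel  # (nvox, 181)
    M = sh_fit_matrix(sphere.vertices, lmax)  # exact LS on the sample sphere
    sh = sdf @ M.T
    out = np.zeros(dwi.spatial_shape + (sh.shape[1],))
    out[mask] = sh
    return ODFField(out, lmax, mask, method="gqi")


def sample_odf(
    field: ODFField,
    sphere: SphereSampling | None = None,
    normalize: bool = True,
):
    """Evaluate the SH field on the sphere; clamp negatives; optionally
    normalize each voxel to a probability vector (sum 1).

    Returns (P, degenerate) where ``degenerate`` flags all-zero functions,
    which are replaced by the uniform distribution when normalizing.
    """
    sphere = sphere or default_sphere()
    B = real_sh_basis(sphere.vertices, field.lmax)
    flat = field.sh[field.mask]
    P = np.clip(flat @ B.T, 0.0, None)
    total = P.sum(axis=1)
    degenerate = total <= 0
    if normalize:
        n = len(sphere)
        P = np.where(degenerate[:, None], 1.0 / n, P / np.where(degenerate, 1.0, total)[:, None])
    return P, degenerate


def _local_maxima(amp: np.ndarray, sphere: SphereSampling) -> np.ndarray:
    """Boolean (nvox, npts): strictly greater than every angular neighbor."""
    nbrs = sphere.neighbor_lists()
    out = np.zeros_like(amp, dtype=bool)
    for i, nb in enumerate(nbrs):
        if nb.size == 0:
            out[:, i] = True
        else:
            out[:, i] = amp[:, i] > amp[:, nb].max(axis=1)
    return out


def find_peaks(
    field: ODFField,
    sphere: SphereSampling | None = None,
    min_separation_angle: float = 25.0,
    relative_threshold: float = 0.5,
    max_peaks: int = 3,
    refine: bool = True,
    flat_tolerance: float = 1e-6,
) -> PeakField:
    """Per-voxel ODF peak directions.

    Local maxima on the sample hemisphere (antipodal duplication is already
    folded out), sorted by amplitude, thresholded relative to the voxel
    maximum, and separated by at least ``min_separation_angle``.  With
    ``refine`` the retained directions are sharpened by re-evaluating the
    SH function on a denser hemisphere around each coarse peak.
    """
    sphere = sphere or default_sphere()
    B = real_sh_basis(sphere.vertices, field.lmax)
    flat = field.sh[field.mask]
    amp = np.clip(flat @ B.T, 0.0, None)
    is_max = _local_maxima(amp, sphere)

    fine = fine_sphere() if refine else None
    if refine:
        Bf = real_sh_basis(fine.vertices, field.lmax)
        cos_window = np.cos(np.radians(max(2.5 * sphere.min_angle_deg, 10.0)))

    sep_cos = np.cos(np.radians(min_separation_angle))
    nvox = flat.shape[0]
    peaks = np.zeros((nvox, max_peaks, 3))
    values = np.zeros((nvox, max_peaks))
    counts = np.zeros(nvox, dtype=np.uint8)
    verts = sphere.vertices
    spread = amp.max(axis=1) - amp.min(axis=1)
    is_flat = spread <= flat_tolerance * np.maximum(amp.max(axis=1), 1e-300)
    for v in range(nvox):
        if is_flat[v]:  # isotropic up to numerical ripple: no distinct maximum
            continue
        cand = np.flatnonzero(is_max[v])
        if cand.size == 0:
            continue
        a = amp[v, cand]
        order = np.argsort(a)[::-1]
        cand, a = cand[order], a[order]
        keep = a >= relative_threshold * amp[v].max()
        cand, a = cand[keep], a[keep]
        chosen: list[int] = []
        for c in cand:
            if len(chosen) >= max_peaks:
                break
            if all(abs(verts[c] @ verts[o]) < sep_cos for o in chosen):
                chosen.append(c)
        if not chosen:
            continue
        dirs = verts[list(chosen)]
        vals = amp[v, list(chosen)]
        if refine:
            ampf = np.clip(flat[v] @ Bf.T, 0.0, None)
            for j, d in enumerate(dirs):
                window = np.abs(fine.vertices @ d) > cos_window
                if window.any():
                    sub = np.flatnonzero(window)
                    best = sub[int(np.argmax(ampf[sub]))]
                    newd = fine.vertices[best]
                    dirs[j] = newd if newd @ d >= 0 else -newd
                    vals[j] = ampf[best]
        counts[v] = len(chosen)
        peaks[v, : len(chosen)] = dirs
        values[v, : len(chosen)] = vals

    shape = field.mask.shape
    out_p = np.zeros(shape + (max_peaks, 3))
    out_v = np.zeros(shape + (max_peaks,))
    out_c = np.zeros(shape, dtype=np.uint8)
    out_p[field.mask] = peaks
    out_v[field.mask] = values
    out_c[field.mask] = counts
    return PeakField(out_p, out_c, out_v)


def tensor_peaks(tf: TensorField, fa_threshold: float = 0.15) -> PeakField:
    """Principal eigenvectors as a single-peak field (DTI tractography)."""
    ok = tf.mask & (tf.fa >= fa_threshold)
    shape = tf.mask.shape
    peaks = np.zeros(shape + (1, 3))
    peaks[ok, 0] = tf.principal_direction[ok]
    counts = ok.astype(np.uint8)
    values = tf.fa[..., None] * counts[..., None]
    return PeakField(peaks, counts, values)


def roi_statistics(
    scalar_map: np.ndarray, roi_masks: list[np.ndarray], ddof: int = 0
) -> list[dict]:
    """Mean and SD of a scalar map over each ROI (population SD by default;
    set ddof=1 for the sample convention).  Empty ROIs are flagged."""
    out = []
    for i, roi in enumerate(roi_masks):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != scalar_map.shape:
            raise ValueError(f"ROI {i} grid does not match the map")
        vals = scalar_map[roi]
        if vals.size == 0:
            out.append({"roi": i, "n": 0, "mean": None, "sd": None, "excluded": True})
        else:
            out.append(
                {
                    "roi": i,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0,
                    "excluded": False,
                }
            )
    return out
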