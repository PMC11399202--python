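"""Motion-probing-gradient (MPG) scheme design and I/O.

A diffusion acquisition is described by a set of unit gradient directions
with b-values (s/mm^2).  Direction sets are designed by minimizing the
antipodal electrostatic (Coulomb) energy

    E = sum_{i<j} 1/||d_i - d_j|| + 1/||d_i + d_j||,

which spreads directions evenly over the projective sphere, the standard
criterion for single-shell HARDI gradient tables.  Schemes serialize to the
FSL bvec/bval dialect and to JSON.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "scheme_energy",
    "design_scheme",
    "split_scheme",
    "merge_schemes",
    "read_bvec_bval",
    "write_bvec_bval",
]

_UNIT_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class GradientScheme:
    """An ordered MPG array: unit directions, b-values, and axis labels.

    Entries with bvalue == 0 are b0 axes; their direction is stored as the
    zero vector.  Axis labels are ordinal MPG indices (0 = b0 by default).
    """

    directions: np.ndarray  # (n, 3) float
    bvalues: np.ndarray  # (n,) float, s/mm^2
    labels: tuple[int, ...] | None = None
    meta: dict | None = None

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        b = np.asarray(self.bvalues, dtype=float).ravel()
        if d.shape[0] != b.shape[0]:
            raise ValueError(
                f"directions ({d.shape[0]}) and bvalues ({b.shape[0]}) differ in length"
            )
        if np.any(b < 0):
            raise ValueError("bvalues must be nonnegative")
        norms = np.linalg.norm(d, axis=1)
        dwi = b > 0
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-6):
            raise ValueError("diffusion directions must be unit vectors")
        if np.any(norms[~dwi] > 1e-6):
            raise ValueError("b0 entries must carry the zero direction")
        labels = self.labels
        if labels is None:
            labels = tuple(range(d.shape[0]))
        elif len(labels) != d.shape[0]:
            raise ValueError("labels length mismatch")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "labels", tuple(int(x) for x in labels))

    def __len__(self) -> int:
        return self.directions.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvalues > 0

    @property
    def n_dwi(self) -> int:
        return int(np.count_nonzero(self.dwi_mask))

    def dwi_directions(self) -> np.ndarray:
        return self.directions[self.dwi_mask]

    def to_json(self, path) -> None:
        payload = {
            "directions": self.directions.tolist(),
            "bvalues": self.bvalues.tolist(),
            "labels": list(self.labels),
            "meta": self.meta or {},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GradientScheme":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["directions"]),
            np.asarray(payload["bvalues"]),
            tuple(payload["labels"]),
            payload.get("meta") or None,
        )


def scheme_energy(directions: np.ndarray) -> float:
    """Antipodal electrostatic energy of a direction set.

    Coincident or antipodal pairs make the energy infinite; ``inf`` is
    returned as the documented sentinel rather than raising.
    """
    d = np.asarray(directions, dtype=float).reshape(-1, 3)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 directions")
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("directions must be unit vectors")
    iu = np.triu_indices(d.shape[0], k=1)
    diff = np.linalg.norm(d[iu[0]] - d[iu[1]], axis=1)
    summ = np.linalg.norm(d[iu[0]] + d[iu[1]], axis=1)
    with np.errstate(divide="ignore"):
        e = np.where(diff > 0, 1.0 / np.where(diff > 0, diff, 1.0), np.inf) + np.where(
            summ > 0, 1.0 / np.where(summ > 0, summ, 1.0), np.inf
        )
    return float(np.sum(e))


def _energy_grad(d: np.ndarray) -> np.ndarray:
    """Gradient of the antipodal Coulomb energy w.r.t. each direction."""
    n = d.shape[0]
    g = np.zeros_like(d)
    # pairwise difference / sum terms, vectorized over all pairs
    diff = d[:, None, :] - d[None, :, :]  # (n, n, 3)
    summ = d[:, None, :] + d[None, :, :]
    rd = np.linalg.norm(diff, axis=2)
    rs = np.linalg.norm(summ, axis=2)
    np.fill_diagonal(rd, np.inf)
    np.fill_diagonal(rs, np.inf)
    # d/d d_i (1/||d_i - d_j||) = -(d_i - d_j)/||.||^3 ; antipodal term analogous
    g -= np.einsum("ijk,ij->ik", diff, rd**-3)
    g -= np.einsum("ijk,ij->ik", summ, rs**-3)
    return g


def design_scheme(
    n_directions: int,
    seed: int = 0,
    n_iterations: int = 200,
    n_restarts: int = 100,
    bvalue: float = 3000.0,
    include_b0: bool = True,
) -> GradientScheme:
    """Design an n-direction single-shell scheme by electrostatic repulsion.

    Projected gradient descent on the sphere with step-halving line search,
    restarted from ``n_restarts`` random initializations; the lowest-energy
    solution wins.  Deterministic for a fixed seed.  A single b0 axis is
    stored first when ``include_b0`` (the convention used throughout: MPG
    index 0 is the b0 image).
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    best_e = np.inf
    for _ in range(n_restarts):
        d = rng.normal(size=(n_directions, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        d, e = _descend(d, n_iterations)
        if e < best_e:
            best_e, best = e, d
    best = _canonical_orientation(best)
    if n_directions >= 2:
        energy = scheme_energy(best)
    else:
        energy = 0.0
    meta = {"seed": int(seed), "energy": energy, "method": "electrostatic-repulsion"}
    if include_b0:
        dirs = np.vstack([np.zeros(3), best])
        bvals = np.concatenate([[0.0], np.full(n_directions, float(bvalue))])
    else:
        dirs = best
        bvals = np.full(n_directions, float(bvalue))
    return GradientScheme(dirs, bvals, meta=meta)


def _descend(
    d: np.ndarray, n_iterations: int, history: list | None = None
) -> tuple[np.ndarray, float]:
    if d.shape[0] == 1:
        return d, 0.0
    e = scheme_energy(d)
    if history is not None:
        history.append(e)
    step = 0.1
    for _ in range(n_iterations):
        g = _energy_grad(d)
        # remove the radial component: moves stay tangent to the sphere
        g -= np.sum(g * d, axis=1, keepdims=True) * d
        gnorm = np.max(np.linalg.norm(g, axis=1))
        if gnorm < 1e-12:
            break
        improved = False
        s = step
        for _ in range(30):
            cand = d - s * g / gnorm
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            ce = scheme_energy(cand)
            if ce < e:
                d, e = cand, ce
                step = s * 1.5
                improved = True
                break
            s *= 0.5
        if history is not None:
            history.append(e)
        if not improved:
            break
    return d, e


def _canonical_orientation(d: np.ndarray) -> np.ndarray:
    """Flip directions into the z>=0 hemisphere (ties by y, then x)."""
    d = d.copy()
    for i, v in enumerate(d):
        key = (v[2], v[1], v[0])
        if key < (0.0, 0.0, 0.0):
            d[i] = -v
    return d


def min_folded_angle_deg(directions: np.ndarray) -> float:
    """Smallest pairwise angle after antipodal folding, in degrees."""
    d = np.asarray(directions, dtype=float)
    c = np.abs(d @ d.T)
    np.fill_diagonal(c, -1.0)
    return math.degrees(math.acos(min(1.0, float(np.max(c)))))


def split_scheme(scheme: GradientScheme, k: int) -> tuple[GradientScheme, GradientScheme]:
    """Split the diffusion axes at position k: (b0 + first k, remaining).

    The b0 axes travel with the first part; stored order is preserved so the
    two halves concatenate back to the original scheme.
    """
    n_dwi = scheme.n_dwi
    if not 0 < k < n_dwi:
        raise ValueError(f"k must lie in (0, {n_dwi}); got {k}")
    dwi_idx = np.flatnonzero(scheme.dwi_mask)
    b0_idx = np.flatnonzero(scheme.b0_mask)
    first = np.concatenate([b0_idx, dwi_idx[:k]])
    second = dwi_idx[k:]
    return _take(scheme, first), _take(scheme, second)


def _take(scheme: GradientScheme, idx: np.ndarray) -> GradientScheme:
    return GradientScheme(
        scheme.directions[idx],
        scheme.bvalues[idx],
        tuple(scheme.labels[i] for i in idx),
        scheme.meta,
    )


def merge_schemes(first: GradientScheme, second: GradientScheme) -> GradientScheme:
    """Inverse of split_scheme: interleave halves back into label order."""
    dirs = np.vstack([first.directions, second.directions])
    bvals = np.concatenate([first.bvalues, second.bvalues])
    labels = first.labels + second.labels
    order = np.argsort(labels, kind="stable")
    return GradientScheme(dirs[order], bvals[order], tuple(labels[i] for i in order), first.meta)


def write_bvec_bval(scheme: GradientScheme, path_bvec, path_bval) -> None:
    """Write FSL-dialect gradient tables (bvec: 3 rows; bval: 1 row)."""
    d = scheme.directions
    with open(path_bvec, "w") as f:
        for axis in range(3):
            f.write(" ".join(f"{v:.6f}" for v in d[:, axis]) + "\n")
    with open(path_bval, "w") as f:
        f.write(" ".join(f"{b:g}" for b in scheme.bvalues) + "\n")


def read_bvec_bval(path_bvec, path_bval) -> GradientScheme:
    """Read FSL-dialect bvec/bval files; zero-norm columns become b0 axes."""
    rows = [line.split() for line in Path(path_bvec).read_text().splitlines() if line.strip()]
    if len(rows) != 3:
        raise ValueError(f"{path_bvec}: expected 3 rows, found {len(rows)}")
    ncols = len(rows[0])
    for r, row in enumerate(rows):
        if len(row) != ncols:
            raise ValueError(f"{path_bvec}: row {r} has {len(row)} columns, expected {ncols}")
    bval_rows = [line.split() for line in Path(path_bval).read_text().splitlines() if line.strip()]
    if len(bval_rows) != 1:
        raise ValueError(f"{path_bval}: expected 1 row, found {len(bval_rows)}")
    bvals = np.array([float(x) for x in bval_rows[0]])
    if bvals.shape[0] != ncols:
        raise ValueError(
            f"{path_bval}: {bvals.shape[0]} bvalues but {path_bvec} has {ncols} columns"
        )
    d = np.array(rows, dtype=float).T  # (n, 3)
    norms = np.linalg.norm(d, axis=1)
    zero = norms < 1e-8
    bvals = np.where(zero, 0.0, bvals)
    d = np.where(zero[:, None], 0.0, d)
    nz = ~zero
    d[nz] /= np.linalg.norm(d[nz], axis=1, keepdims=True)
    return GradientScheme(d, bvals)
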