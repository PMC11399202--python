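"""Sphere samplings and real spherical-harmonic (SH) bases.

Diffusion ODFs/SDFs are antipodally symmetric spherical functions, so they
are represented on hemispheres and expanded in even-order real SH.  The
default evaluation sampling is a frequency-6 geodesic icosahedron (362
near-uniform vertices) folded antipodally to exactly 181 hemisphere points
— the sampling density used for the divergence metrics.

The real orthonormal basis is, for each even l and m = -l..l:

    Y_{l,m<0} = sqrt(2) (-1)^m Im(Y_l^{|m|}),
    Y_{l,0}   = Y_l^0,
    Y_{l,m>0} = sqrt(2) (-1)^m Re(Y_l^m),

with coefficients ordered (l, m) lexicographically, l ascending.
"""

from __future__ import annotations

import dataclasses
import functools
import math

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "SphereSampling",
    "default_sphere",
    "fine_sphere",
    "icosphere_vertices",
    "real_sh_basis",
    "sh_index_list",
    "n_sh_coeffs",
    "max_lmax_for",
    "legendre_p0",
]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = [
    (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
    (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
    (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
    (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
]


def icosphere_vertices(frequency: int) -> np.ndarray:
    """Vertices of a geodesic icosahedron (10*f^2 + 2 unit vectors)."""
    if frequency < 1:
        raise ValueError("frequency must be >= 1")
    pts = []
    f = frequency
    for (a, b, c) in _ICO_FACES:
        A, B, C = _ICO_VERTS[a], _ICO_VERTS[b], _ICO_VERTS[c]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                p = (i * A + j * B + (f - i - j) * C) / f
                pts.append(p / np.linalg.norm(p))
    pts = np.asarray(pts)
    # deduplicate shared edges/vertices
    key = np.round(pts * 1e8).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    out = pts[np.sort(idx)]
    assert out.shape[0] == 10 * f * f + 2
    return out


def _fold_hemisphere(pts: np.ndarray) -> np.ndarray:
    """Keep one representative per antipodal pair (z>0 side, canonical ties)."""
    eps = 1e-10
    keep = (pts[:, 2] > eps) | (
        (np.abs(pts[:, 2]) <= eps)
        & ((pts[:, 1] > eps) | ((np.abs(pts[:, 1]) <= eps) & (pts[:, 0] > eps)))
    )
    return pts[keep]


@dataclasses.dataclass(frozen=True)
class SphereSampling:
    """A hemisphere point set with its antipodal pairing implied."""

    vertices: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if np.any(np.abs(np.linalg.norm(v, axis=1) - 1) > 1e-9):
            raise ValueError("sphere vertices must be unit vectors")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    @property
    def min_angle_deg(self) -> float:
        c = np.abs(self.vertices @ self.vertices.T)
        np.fill_diagonal(c, -1.0)
        return math.degrees(math.acos(min(1.0, float(c.max()))))

    def neighbor_lists(self, factor: float = 1.6) -> list[np.ndarray]:
        """Indices of points within ``factor``x the minimum folded angle."""
        thresh = math.cos(math.radians(self.min_angle_deg * factor))
        c = np.abs(self.vertices @ self.vertices.T)
        np.fill_diagonal(c, -1.0)
        return [np.flatnonzero(row > thresh) for row in c]


@functools.lru_cache(maxsize=None)
def default_sphere() -> SphereSampling:
    """The 181-point hemisphere (frequency-6 geodesic icosahedron, folded)."""
    pts = _fold_hemisphere(icosphere_vertices(6))
    assert pts.shape[0] == 181
    return SphereSampling(pts)


@functools.lru_cache(maxsize=None)
def fine_sphere(frequency: int = 16) -> SphereSampling:
    """A denser hemisphere used for peak refinement (default 1281 points)."""
    return SphereSampling(_fold_hemisphere(icosphere_vertices(frequency)))


def sh_index_list(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs for the even-order real basis, in storage order."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def n_sh_coeffs(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def max_lmax_for(n_directions: int, cap: int = 8) -> int:
    """Largest even order whose coefficient count fits the direction count."""
    l = 0
    while l + 2 <= cap and n_sh_coeffs(l + 2) <= n_directions:
        l += 2
    return l


def real_sh_basis(vertices: np.ndarray, lmax: int) -> np.ndarray:
    """Design matrix B with B[i, j] = Y_j(vertex_i), even orders only."""
    v = np.asarray(vertices, dtype=float)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(v[:, 1], v[:, 0])  # azimuth
    cols = []
    for l, m in sh_index_list(lmax):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(math.sqrt(2.0) * (-1) ** m * y.imag)
        elif m == 0:
            cols.append(y.real)
        else:
            cols.append(math.sqrt(2.0) * (-1) ** m * y.real)
    return np.stack(cols, axis=-1)


def legendre_p0(lmax: int) -> np.ndarray:
    """P_l(0) for each (l, m) storage slot (constant across m within l)."""
    return np.array([eval_legendre(l, 0.0) for l, _ in sh_index_list(lmax)])


def sh_fit_matrix(vertices: np.ndarray, lmax: int, lb_lambda: float = 0.0) -> np.ndarray:
    """Pseudo-inverse mapping samples -> SH coefficients, optionally with
    Laplace-Beltrami regularization (penalty lambda * [l(l+1)]^2)."""
    B = real_sh_basis(vertices, lmax)
    L = np.array([l * (l + 1) for l, _ in sh_index_list(lmax)], dtype=float)
    A = B.T @ B + lb_lambda * np.diag(L**2)
    return np.linalg.solve(A, B.T)
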