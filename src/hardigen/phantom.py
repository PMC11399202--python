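"""Synthetic crossing-fiber DWI phantoms with ground truth.

Each phantom is a set of tubular fiber bundles on a voxel grid.  The
noiseless signal follows the multi-tensor model

    S(g, b) = S0 * [ sum_k f_k exp(-b g^T D_k g) + f_bg exp(-b d_iso) ],

with an isotropic background filling the remaining volume fraction, and
magnitude (Rician) noise sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2).

Defaults emulate a 3T white-matter HARDI acquisition at b = 3000 s/mm^2:
bundle eigenvalues (1.7, 0.3, 0.3)e-3 mm^2/s, background diffusivity
0.8e-3 mm^2/s, 2.5 mm isotropic voxels.  Grids default to 32^3 for desk
scale; the clinical 96x96x60 matrix is reachable through configuration.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dwi_io import DWIVolume
from .gradients import GradientScheme
from .tracking import ROISet

__all__ = [
    "FiberBundleSpec",
    "PhantomTruth",
    "PhantomConfig",
    "make_crossing_phantom",
    "simulate_signal",
    "make_roi_set",
    "generate_dataset",
]

WM_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)  # mm^2/s
D_ISO_BACKGROUND = 0.8e-3  # mm^2/s


@dataclasses.dataclass(frozen=True)
class FiberBundleSpec:
    """A tubular bundle: polyline centerline (voxel units), radius,
    axially oriented tensor eigenvalues (descending), volume fraction."""

    centerline: np.ndarray  # (k, 3) voxel coordinates
    radius: float
    eigenvalues: tuple[float, float, float] = WM_EIGENVALUES
    volume_fraction: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if c.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        ev = tuple(float(x) for x in self.eigenvalues)
        if any(x < 0 for x in ev) or list(ev) != sorted(ev, reverse=True):
            raise ValueError("eigenvalues must be nonnegative and sorted descending")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError("volume_fraction must lie in (0, 1]")
        object.__setattr__(self, "centerline", c)
        object.__setattr__(self, "eigenvalues", ev)


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth accompanying a simulated volume."""

    bundle_masks: np.ndarray  # (n_bundles, x, y, z) bool
    fiber_directions: np.ndarray  # (n_bundles, x, y, z, 3); zeros off-bundle
    fractions: np.ndarray  # (n_bundles, x, y, z), per-voxel volume fractions
    tensor_field: np.ndarray  # (x, y, z, 3, 3) fraction-weighted tensor sum
    S0: float
    bundles: list[FiberBundleSpec]
    support_mask: np.ndarray | None = None  # the "head": zero signal outside

    @property
    def object_mask(self) -> np.ndarray:
        return self.bundle_masks.any(axis=0)


def _segment_geometry(centerline: np.ndarray, points: np.ndarray):
    """Distance from each point to the polyline and the local tangent."""
    best_d = np.full(points.shape[0], np.inf)
    best_t = np.zeros_like(points)
    for a, b in zip(centerline[:-1], centerline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(points - proj, axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_t[closer] = ab / np.sqrt(denom)
    return best_d, best_t


def _tensor_from_axis(axis: np.ndarray, eigenvalues) -> np.ndarray:
    """Axially oriented symmetric tensors for an array of unit axes."""
    l1, l2, l3 = eigenvalues
    t = axis
    ref = np.where(np.abs(t[..., [0]]) < 0.9, [1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
    e2 = np.cross(t, ref)
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(t, e2)
    return (
        l1 * t[..., :, None] * t[..., None, :]
        + l2 * e2[..., :, None] * e2[..., None, :]
        + l3 * e3[..., :, None] * e3[..., None, :]
    )


def make_crossing_phantom(
    angle_degrees: float,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    radius: float = 4.0,
    rotation_degrees: float = 0.0,
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
    eigenvalues=WM_EIGENVALUES,
) -> list[FiberBundleSpec]:
    """Two straight tubular bundles crossing at the grid center.

    The bundles lie in the x-y plane at ±angle/2 around an axis that is
    itself rotated by ``rotation_degrees`` in-plane; in the overlap their
    volume fractions resolve to 0.5 each (see simulate_signal).
    """
    if not 0 < angle_degrees < 180:
        raise ValueError("crossing angle must lie strictly between 0 and 180 degrees")
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2 + np.asarray(center_offset, dtype=float)
    half = np.radians(angle_degrees) / 2
    base = np.radians(rotation_degrees)
    L = float(np.linalg.norm(shape))  # long enough to cross the whole grid
    bundles = []
    for sign in (+1, -1):
        a = base + sign * half
        u = np.array([np.cos(a), np.sin(a), 0.0])
        centerline = np.vstack([center - L * u, center + L * u])
        bundles.append(FiberBundleSpec(centerline, radius, eigenvalues))
    return bundles


def simulate_signal(
    bundles: list[FiberBundleSpec],
    scheme: GradientScheme,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    S0: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    d_iso: float = D_ISO_BACKGROUND,
    affine: np.ndarray | None = None,
    voxel_size: float = 2.5,
    support_radius_fraction: float = 0.46,
) -> tuple[DWIVolume, PhantomTruth]:
    """Simulate the multi-tensor signal for every scheme axis.

    The signal lives inside a centered spherical "head" support (radius
    ``support_radius_fraction`` of the smallest grid extent); outside it the
    noiseless signal is zero, mimicking air around the object so that the
    b0 image carries mask contrast.  Where bundle fractions sum above 1
    they are renormalized to sum to 1 (two overlapping unit-fraction
    bundles -> 0.5 each); the remaining in-support fraction is isotropic
    background.  Rician noise is applied per channel, deterministically for
    a fixed seed.
    """
    if len(scheme) == 0:
        raise ValueError("scheme is empty")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if not bundles:
        raise ValueError("need at least one bundle")
    shape = tuple(int(x) for x in grid_shape)
    if any(s <= 0 for s in shape):
        raise ValueError("grid_shape must be positive")

    idx = np.indices(shape).reshape(3, -1).T.astype(float)  # voxel centers
    nvox = idx.shape[0]
    center = (np.asarray(shape, dtype=float) - 1) / 2
    support = (
        np.linalg.norm(idx - center, axis=1) <= support_radius_fraction * min(shape)
    )
    nb = len(bundles)
    masks = np.zeros((nb, nvox), dtype=bool)
    tangents = np.zeros((nb, nvox, 3))
    fracs = np.zeros((nb, nvox))
    for k, b in enumerate(bundles):
        d, t = _segment_geometry(b.centerline, idx)
        inside = (d <= b.radius) & support
        masks[k] = inside
        tangents[k, inside] = t[inside]
        fracs[k, inside] = b.volume_fraction

    total = fracs.sum(axis=0)
    over = total > 1.0
    if over.any():
        fracs[:, over] /= total[over]
        total = fracs.sum(axis=0)
    f_bg = np.where(support, 1.0 - total, 0.0)

    g = scheme.directions  # (nd, 3)
    bvals = scheme.bvalues  # (nd,)
    nd = len(scheme)
    signal = np.zeros((nvox, nd))
    tensor_field = np.zeros((nvox, 3, 3))
    for k in range(nb):
        sel = masks[k]
        if not sel.any():
            continue
        D = _tensor_from_axis(tangents[k, sel], bundles[k].eigenvalues)  # (m, 3, 3)
        tensor_field[sel] += fracs[k, sel, None, None] * D
        gDg = np.einsum("vij,di,dj->vd", D, g, g)
        signal[sel] += fracs[k, sel, None] * np.exp(-bvals[None, :] * gDg)
    signal += f_bg[:, None] * np.exp(-bvals[None, :] * d_iso)
    tensor_field += (f_bg[:, None, None]) * (d_iso * np.eye(3))
    signal *= S0

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        n2 = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    data = signal.reshape(*shape, nd).astype(np.float32)
    if affine is None:
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    volume = DWIVolume(data, affine, scheme)
    truth = PhantomTruth(
        bundle_masks=masks.reshape(nb, *shape),
        fiber_directions=tangents.reshape(nb, *shape, 3),
        fractions=fracs.reshape(nb, *shape),
        tensor_field=tensor_field.reshape(*shape, 3, 3),
        S0=float(S0),
        bundles=list(bundles),
        support_mask=support.reshape(*shape),
    )
    return volume, truth


def make_roi_set(
    truth: PhantomTruth,
    bundle_index: int,
    slab_thickness: int = 2,
    avoid_axis: int | None = None,
) -> ROISet:
    """Seed/target end-slabs of one bundle (phantom analogue of a seed ROI
    at one end of a tract and a target at the other), with an optional
    mid-plane avoidance ROI perpendicular to ``avoid_axis``."""
    if not 0 <= bundle_index < truth.bundle_masks.shape[0]:
        raise ValueError("bundle index out of range")
    mask = truth.bundle_masks[bundle_index]
    if not mask.any():
        raise ValueError("bundle mask is empty")
    b = truth.bundles[bundle_index]
    u = b.centerline[-1] - b.centerline[0]
    axis = int(np.argmax(np.abs(u)))  # dominant axis of the bundle
    coords = np.nonzero(mask)
    lo, hi = coords[axis].min(), coords[axis].max()
    pos = np.indices(mask.shape)[axis]
    seed = mask & (pos <= lo + slab_thickness - 1)
    target = mask & (pos >= hi - slab_thickness + 1)
    if not seed.any() or not target.any() or (seed & target).any():
        raise ValueError("degenerate bundle: seed/target slabs overlap or are empty")
    avoid = np.zeros_like(mask)
    if avoid_axis is not None:
        mid = mask.shape[avoid_axis] // 2
        avoid = np.indices(mask.shape)[avoid_axis] == mid
    return ROISet(seed_mask=seed, target_mask=target, avoid_mask=avoid)


@dataclasses.dataclass
class PhantomConfig:
    """Randomization ranges for dataset generation (angles in degrees)."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    angle_range: tuple[float, float] = (50.0, 90.0)
    rotation_range: tuple[float, float] = (0.0, 180.0)
    offset_range: float = 2.0
    radius_range: tuple[float, float] = (3.0, 4.5)
    S0: float = 100.0
    noise_sigma: float = 0.0
    eigenvalues: tuple[float, float, float] = WM_EIGENVALUES
    d_iso: float = D_ISO_BACKGROUND
    n_train: int = 20
    n_val: int = 2
    n_test: int = 5


@dataclasses.dataclass
class PhantomCase:
    volume: DWIVolume
    truth: PhantomTruth
    params: dict


def generate_dataset(
    scheme: GradientScheme,
    config: PhantomConfig | None = None,
    seed: int = 0,
    n_phantoms: int | None = None,
) -> dict[str, list[PhantomCase]]:
    """Generate a reproducible train/validation/test partition of crossing
    phantoms, varying crossing angle, in-plane rotation, center offset and
    tube radius.  Every phantom contains one crossing region."""
    config = config or PhantomConfig()
    if n_phantoms is not None:
        n_train = n_phantoms
        n_val = n_test = 0
    else:
        n_train, n_val, n_test = config.n_train, config.n_val, config.n_test
    total = n_train + n_val + n_test
    if total < 1:
        raise ValueError("need at least one phantom")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * total) % (2**31)
    rng = np.random.default_rng(child_seeds[0])
    cases = []
    for i in range(total):
        angle = rng.uniform(*config.angle_range)
        rot = rng.uniform(*config.rotation_range)
        off = rng.uniform(-config.offset_range, config.offset_range, size=3)
        off[2] = 0.0  # bundles live in an axial plane
        radius = rng.uniform(*config.radius_range)
        bundles = make_crossing_phantom(
            angle,
            config.grid_shape,
            radius=radius,
            rotation_degrees=rot,
            center_offset=tuple(off),
            eigenvalues=config.eigenvalues,
        )
        noise_seed = int(child_seeds[total + i])
        vol, truth = simulate_signal(
            bundles,
            scheme,
            config.grid_shape,
            S0=config.S0,
            noise_sigma=config.noise_sigma,
            seed=noise_seed,
            d_iso=config.d_iso,
        )
        cases.append(
            PhantomCase(
                vol,
                truth,
                {
                    "angle": float(angle),
                    "rotation": float(rot),
                    "offset": [float(x) for x in off],
                    "radius": float(radius),
                    "noise_sigma": config.noise_sigma,
                    "noise_seed": noise_seed,
                },
            )
        )
    return {
        "train": cases[:n_train],
        "val": cases[n_train : n_train + n_val],
        "test": cases[n_train + n_val :],
    }
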