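"""Deterministic streamline tractography and bundle voxelization.

Tracking integrates per-voxel peak directions (from ODF/SDF fields or a
tensor's principal eigenvector) with fixed-step Euler steps, in voxel
coordinates.  Defaults: step 0.5 voxel, turning-angle limit 45 degrees,
minimum length 4 voxels, one seed per seed voxel placed at the voxel
center.  Streamlines terminate on leaving the stop mask, on finding no
peak, or on exceeding the angle limit; the reason is recorded.

Voxelization marks every voxel a streamline *segment* traverses (3D DDA),
not merely the voxels containing vertices, and yields the binary bundle
mask entering the Dice overlap.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ROISet",
    "StreamlineSet",
    "BundleMask",
    "TrackingParams",
    "track",
    "filter_by_rois",
    "voxelize",
]


@dataclasses.dataclass
class ROISet:
    """Seed / target / avoidance masks on the DWI grid."""

    seed_mask: np.ndarray
    target_mask: np.ndarray
    avoid_mask: np.ndarray

    def __post_init__(self):
        self.seed_mask = np.asarray(self.seed_mask, dtype=bool)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        self.avoid_mask = np.asarray(self.avoid_mask, dtype=bool)
        if not (self.seed_mask.shape == self.target_mask.shape == self.avoid_mask.shape):
            raise ValueError("ROI masks must share one grid")
        if not self.seed_mask.any():
            raise ValueError("seed mask is empty")


@dataclasses.dataclass
class StreamlineSet:
    """Polylines in voxel coordinates with per-streamline provenance."""

    streamlines: list[np.ndarray]  # each (k >= 2, 3)
    provenance: list[dict]
    step_size: float

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
        )


@dataclasses.dataclass
class BundleMask:
    data: np.ndarray
    flags: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def volume(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass(frozen=True)
class TrackingParams:
    step_size: float = 0.5  # voxels
    max_angle: float = 45.0  # degrees per step
    min_length: float = 4.0  # voxels
    seeds_per_voxel: int = 1
    max_steps: int = 2000


def _peak_at(peaks: np.ndarray, counts: np.ndarray, voxel: tuple[int, int, int], direction):
    """Best-aligned peak (after antipodal folding) at a voxel, or None."""
    c = counts[voxel]
    if c == 0:
        return None
    cand = peaks[voxel][:c]  # (c, 3)
    if direction is None:
        return cand[0]
    dots = cand @ direction
    i = int(np.argmax(np.abs(dots)))
    return cand[i] if dots[i] >= 0 else -cand[i]


def _trace(peaks, counts, stop_mask, pos0, d0, params) -> tuple[list, str]:
    shape = stop_mask.shape
    cos_limit = np.cos(np.radians(params.max_angle))
    pts = [pos0.copy()]
    pos = pos0.copy()
    d = d0
    for _ in range(params.max_steps):
        pos = pos + params.step_size * d
        vox = tuple(int(round(x)) for x in pos)
        if any(v < 0 or v >= s for v, s in zip(vox, shape)) or not stop_mask[vox]:
            return pts, "exit"
        pts.append(pos.copy())
        nxt = _peak_at(peaks, counts, vox, d)
        if nxt is None:
            return pts, "no_peak"
        if float(nxt @ d) < cos_limit:
            return pts, "angle"
        d = nxt
    return pts, "max_steps"


def track(
    peaks: np.ndarray,
    counts: np.ndarray,
    stop_mask: np.ndarray,
    seed_mask: np.ndarray,
    params: TrackingParams | None = None,
) -> StreamlineSet:
    """Euler streamline integration from every seed voxel, both directions.

    ``peaks`` is (x, y, z, max_peaks, 3) with ``counts`` valid peaks per
    voxel (see recon.find_peaks).  Deterministic: seeds are voxel centers
    visited in array order.
    """
    params = params or TrackingParams()
    if params.step_size <= 0:
        raise ValueError("step_size must be positive")
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if seed_mask.shape != stop_mask.shape or peaks.shape[:3] != stop_mask.shape:
        raise ValueError("peaks, stop mask and seed mask must share one grid")

    lines: list[np.ndarray] = []
    prov: list[dict] = []
    for voxel in zip(*np.nonzero(seed_mask)):
        d0 = _peak_at(peaks, counts, voxel, None)
        if d0 is None:
            continue
        pos0 = np.array(voxel, dtype=float)
        fwd, r_fwd = _trace(peaks, counts, stop_mask, pos0, d0, params)
        bwd, r_bwd = _trace(peaks, counts, stop_mask, pos0, -d0, params)
        pts = bwd[::-1] + fwd[1:]
        if len(pts) < 2:
            continue
        line = np.asarray(pts)
        length = float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())
        if length < params.min_length:
            continue
        lines.append(line)
        prov.append(
            {"seed_voxel": tuple(int(v) for v in voxel), "termination": (r_bwd, r_fwd)}
        )
    return StreamlineSet(lines, prov, params.step_size)


def filter_by_rois(streamlines: StreamlineSet, rois: ROISet) -> tuple[StreamlineSet, dict]:
    """Keep streamlines reaching the target; drop any touching the avoid ROI.

    Returns the filtered set plus bookkeeping counts; an empty result is
    allowed and flagged as a non-visualized bundle.
    """
    kept, prov = [], []
    n_no_target = n_avoid = 0
    for line, p in zip(streamlines.streamlines, streamlines.provenance):
        vox = np.round(line).astype(int)
        shape = rois.seed_mask.shape
        inb = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        vox = vox[inb]
        if rois.avoid_mask[vox[:, 0], vox[:, 1], vox[:, 2]].any():
            n_avoid += 1
            continue
        if not rois.target_mask[vox[:, 0], vox[:, 1], vox[:, 2]].any():
            n_no_target += 1
            continue
        kept.append(line)
        prov.append(p)
    stats = {
        "n_input": len(streamlines),
        "n_kept": len(kept),
        "n_removed_no_target": n_no_target,
        "n_removed_avoid": n_avoid,
        "visualized": len(kept) > 0,
    }
    return StreamlineSet(kept, prov, streamlines.step_size), stats


def _segment_voxels(p: np.ndarray, q: np.ndarray, shape) -> set:
    """Voxels traversed by segment p->q (voxel centers at integer coords,
    voxel i spans [i-0.5, i+0.5)); Amanatides-Woo traversal."""
    out = set()
    v = q - p
    length = float(np.linalg.norm(v))
    cur = np.array([int(np.floor(x + 0.5)) for x in p])
    end = np.array([int(np.floor(x + 0.5)) for x in q])

    def record(c):
        if all(0 <= c[i] < shape[i] for i in range(3)):
            out.add(tuple(int(x) for x in c))

    record(cur)
    if length == 0:
        return out
    d = v / length
    step = np.sign(d).astype(int)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for i in range(3):
        if d[i] != 0:
            boundary = cur[i] + (0.5 if step[i] > 0 else -0.5)
            t_max[i] = (boundary - p[i]) / d[i]
            t_delta[i] = 1.0 / abs(d[i])
    t = 0.0
    while not np.array_equal(cur, end) and t <= length:
        axis = int(np.argmin(t_max))
        t = t_max[axis]
        if t > length:
            break
        cur[axis] += step[axis]
        t_max[axis] += t_delta[axis]
        record(cur)
    return out


def voxelize(streamlines: StreamlineSet, grid_shape: tuple[int, int, int]) -> BundleMask:
    """Binary mask of all voxels traversed by any streamline segment."""
    mask = np.zeros(grid_shape, dtype=bool)
    for line in streamlines.streamlines:
        for p, q in zip(line[:-1], line[1:]):
            for vox in _segment_voxels(p, q, grid_shape):
                mask[vox] = True
    flags = {"empty_input": len(streamlines) == 0}
    return BundleMask(mask, flags)


def export_trk(streamlines: StreamlineSet, affine: np.ndarray, path) -> None:
    """Write a TrackVis .trk file (streamlines stored in voxel coordinates,
    mapped to rasmm through the affine, which maps voxel centers)."""
    import nibabel.streamlines as nbs

    tractogram = nbs.Tractogram(
        streamlines.streamlines, affine_to_rasmm=np.asarray(affine, dtype=np.float64)
    )
    nbs.save(tractogram, str(path))
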