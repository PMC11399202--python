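"""DWI volume container, NIfTI-1 I/O, b0 masking, intensity normalization.

Conventions used everywhere in the package: voxel coordinates are 0-based,
voxel extents are half-open, and the affine maps voxel *centers* to mm.
Intensities are magnitudes and therefore nonnegative.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .gradients import GradientScheme, read_bvec_bval, write_bvec_bval

__all__ = [
    "DWIVolume",
    "MaskVolume",
    "read_dwi",
    "write_dwi",
    "compute_b0_mask",
    "apply_normalization",
    "invert_normalization",
]


@dataclasses.dataclass
class DWIVolume:
    """A 4D diffusion-weighted volume with its gradient scheme.

    ``data`` is (x, y, z, channel) with one channel per MPG axis, aligned
    with ``scheme`` order.  ``normalization`` records any intensity scaling
    applied so that metrics can be computed on raw intensities.
    """

    data: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme
    normalization: dict | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=np.float32)
        if d.ndim != 4:
            raise ValueError(f"expected 4D data, got {d.ndim}D")
        if d.shape[3] != len(self.scheme):
            raise ValueError(
                f"channel count {d.shape[3]} does not match scheme length {len(self.scheme)}"
            )
        a = np.asarray(self.affine, dtype=float)
        if a.shape != (4, 4) or abs(np.linalg.det(a[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")
        self.data = d
        self.affine = a

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def b0(self) -> np.ndarray:
        """Mean over b0 channels."""
        m = self.scheme.b0_mask
        if not m.any():
            raise ValueError("scheme has no b0 axis")
        return self.data[..., m].mean(axis=-1)

    def dwi_data(self) -> np.ndarray:
        return self.data[..., self.scheme.dwi_mask]


@dataclasses.dataclass
class MaskVolume:
    data: np.ndarray  # bool, (x, y, z)
    provenance: dict

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def read_dwi(path_nifti, path_bvec, path_bval) -> DWIVolume:
    """Load a 4D NIfTI (.nii or .nii.gz) with FSL gradient tables."""
    img = nib.load(str(path_nifti))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path_nifti}: expected 4D image, got {data.ndim}D")
    scheme = read_bvec_bval(path_bvec, path_bval)
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"{path_nifti}: {data.shape[3]} channels but scheme has {len(scheme)} entries"
        )
    norm = None
    sidecar = Path(str(path_nifti).removesuffix(".gz").removesuffix(".nii") + ".json")
    if sidecar.exists():
        norm = json.loads(sidecar.read_text()).get("normalization")
    return DWIVolume(data, img.affine, scheme, norm)


def write_dwi(volume: DWIVolume, path_nifti, path_bvec=None, path_bval=None) -> None:
    """Write NIfTI-1 + bvec/bval + JSON sidecar with the normalization record."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path_nifti))
    stem = str(path_nifti).removesuffix(".gz").removesuffix(".nii")
    if path_bvec is None:
        path_bvec, path_bval = stem + ".bvec", stem + ".bval"
    write_bvec_bval(volume.scheme, path_bvec, path_bval)
    Path(stem + ".json").write_text(
        json.dumps({"normalization": volume.normalization}, sort_keys=True)
    )


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def compute_b0_mask(b0: np.ndarray, method: str = "otsu", fraction: float = 0.1) -> MaskVolume:
    """Analysis mask from the unweighted image.

    ``otsu``: Otsu threshold, keep the largest connected component, close
    with a 1-voxel structuring element.  ``fraction``: threshold at
    fraction * max(b0) (useful for clean phantoms with bimodal histograms
    too sparse for Otsu).
    """
    b0 = np.asarray(b0, dtype=float)
    if np.any(b0 < 0):
        raise ValueError("b0 must be nonnegative")
    if not np.any(b0 > 0):
        raise ValueError("b0 is identically zero; cannot derive a mask")
    if method == "otsu":
        thr = float(threshold_otsu(b0))
        raw = b0 > thr
    elif method == "fraction":
        thr = fraction * float(b0.max())
        raw = b0 > thr
    else:
        raise ValueError(f"unknown mask method {method!r}")
    if not raw.any():
        raise ValueError("mask threshold removed every voxel")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    closed = ndimage.binary_closing(raw, structure=ndimage.generate_binary_structure(3, 1))
    # closing may clip at the array border; keep the union so no voxel is lost
    mask = closed | raw
    return MaskVolume(mask, {"method": method, "threshold": thr})


def apply_normalization(volume: DWIVolume, percentile: float = 99.0) -> DWIVolume:
    """Scale intensities by the robust b0 maximum (a high percentile of the
    b0 image over its foreground); records the scale for exact inversion."""
    if volume.normalization is not None:
        raise ValueError("volume already normalized")
    b0 = volume.b0()
    fg = b0[b0 > 0]
    scale = float(np.percentile(fg, percentile)) if fg.size else 1.0
    if scale <= 0:
        scale = 1.0
    data = volume.data / scale
    return DWIVolume(data, volume.affine, volume.scheme, {"scale": scale, "percentile": percentile})


def invert_normalization(volume: DWIVolume) -> DWIVolume:
    if not volume.normalization or "scale" not in volume.normalization:
        raise ValueError("no normalization record to invert")
    data = volume.data * volume.normalization["scale"]
    return DWIVolume(data, volume.affine, volume.scheme, None)
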