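"""In-memory containers for MR images, tissue maps, motion traces and
diffusion schemes, plus thin NIfTI / plain-text I/O built on nibabel.

These are deliberately small dataclasses: every downstream QC operation
takes one of these and returns plain numbers, so keeping the containers
dumb keeps the feature formulas easy to audit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class InputError(ValueError):
    """Raised when an input violates an operation's precondition."""


@dataclasses.dataclass
class VolumeImage:
    """A 3D scalar image.

    Parameters
    ----------
    data : ndarray, shape (x, y, z)
        Voxel intensities in arbitrary units.
    voxel_size : tuple of 3 floats
        Voxel edge lengths in mm.
    orientation : tuple of 3 str
        Axis codes a la nibabel (e.g. ``('R', 'A', 'S')``); used to find
        the left-right axis for asymmetry features.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InputError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise InputError("volume contains non-finite intensities")
        if any(v <= 0 for v in self.voxel_size):
            raise InputError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def lr_axis(self) -> int:
        """Index of the spatial axis running left-right."""
        for ax, code in enumerate(self.orientation):
            if code.upper() in ("L", "R"):
                return ax
        raise InputError(f"no L/R axis in orientation {self.orientation}")


@dataclasses.dataclass
class SeriesImage:
    """A 4D time series (x, y, z, t)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InputError(f"expected a 4D series, got shape {self.data.shape}")
        if self.tr <= 0:
            raise InputError(f"repetition time must be positive, got {self.tr}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def mean_volume(self) -> np.ndarray:
        return self.data.mean(axis=3)


def default_background_mask(brain_prob: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Air-background mask: voxels with total brain probability below
    `threshold`, eroded by 2 voxels (the erosion also removes a 2-voxel
    rim at the image border, keeping edge/partial-volume voxels out)."""
    candidate = brain_prob < threshold
    return ndimage.binary_erosion(candidate, iterations=2, border_value=0)


@dataclasses.dataclass
class TissueMaps:
    """GM/WM/CSF probability maps aligned to an image, with derived masks.

    `brain_mask` defaults to total brain probability > 0.5 and
    `background_mask` to :func:`default_background_mask`; both can be
    supplied explicitly. Probabilities are validated to lie in [0, 1].
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    brain_mask: np.ndarray | None = None
    background_mask: np.ndarray | None = None
    prob_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise InputError("tissue map grids do not match")
        for name, arr in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if arr.min() < 0 or arr.max() > 1:
                raise InputError(f"{name} probabilities outside [0, 1]")
        if not 0 < self.prob_threshold < 1:
            raise InputError("prob_threshold must be in (0, 1)")
        brain_prob = self.gm + self.wm + self.csf
        if self.brain_mask is None:
            self.brain_mask = brain_prob > 0.5
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.background_mask is None:
            self.background_mask = default_background_mask(brain_prob)
        else:
            self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if np.any(self.brain_mask & self.background_mask):
            raise InputError("brain_mask and background_mask overlap")

    def binary(self, tissue: str) -> np.ndarray:
        """Hard mask for one tissue at ``prob_threshold``."""
        return getattr(self, tissue) > self.prob_threshold


@dataclasses.dataclass
class MotionTrace:
    """Per-volume rigid-body realignment parameters.

    `params` has one row per volume and six columns:
    tx, ty, tz (mm) then rx, ry, rz (radians).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise InputError(
                f"motion trace needs 6 columns (tx ty tz rx ry rz), got {self.params.shape[1]}"
            )
        if not np.all(np.isfinite(self.params)):
            raise InputError("motion trace contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclasses.dataclass
class DiffusionScheme:
    """Diffusion gradient table: per-volume b-values and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, self.bvals.size):
            self.bvecs = self.bvecs.T
        if self.bvecs.shape != (self.bvals.size, 3):
            raise InputError(
                f"bvecs shape {self.bvecs.shape} does not match {self.bvals.size} b-values"
            )
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.any() and np.any(np.abs(norms - 1) > 1e-3):
            raise InputError("non-unit gradient direction for nonzero b-value")

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals == 0)


# ---------------------------------------------------------------------------
# I/O helpers


def load_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(
        data=np.asanyarray(img.dataobj, dtype=float),
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        orientation=tuple(nib.aff2axcodes(img.affine)),
    )


def save_volume(vol: VolumeImage | np.ndarray, path: str | Path,
                voxel_size: tuple[float, float, float] | None = None) -> None:
    if isinstance(vol, VolumeImage):
        data, zooms = vol.data, vol.voxel_size
    else:
        data, zooms = np.asarray(vol, dtype=float), voxel_size or (1.0, 1.0, 1.0)
    affine = np.diag(list(zooms) + [1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def load_series(path: str | Path, tr: float | None = None) -> SeriesImage:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return SeriesImage(
        data=np.asanyarray(img.dataobj, dtype=float),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=tr if tr is not None else (float(zooms[3]) if len(zooms) > 3 else 2.0),
    )


def save_series(series: SeriesImage, path: str | Path) -> None:
    affine = np.diag(list(series.voxel_size) + [1.0])
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr,))
    nib.save(img, str(path))


def load_motion_trace(path: str | Path) -> MotionTrace:
    """Read a whitespace-delimited 6-column motion file; ``#`` lines are
    header comments."""
    return MotionTrace(np.loadtxt(str(path), comments="#", ndmin=2))


def save_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    header = "columns: tx ty tz rx ry rz  (translations mm, rotations rad)"
    np.savetxt(str(path), trace.params, fmt="%.8g", header=header)


def load_scheme(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    """Read FSL-dialect bval/bvec text (one row of b-values, three rows of
    direction components)."""
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    return DiffusionScheme(bvals=bvals, bvecs=bvecs)


def save_scheme(scheme: DiffusionScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.8g")
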