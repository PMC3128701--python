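"""Reading, validating and writing mask and statistic volumes.

All volumes live on a shared standard-space grid (MNI-template space): a
voxel array plus a 4x4 affine mapping 0-based voxel indices to millimetre
coordinates.  Lesion masks are strictly binary; statistical maps carry a
per-voxel p-value where a voxel was tested and a sentinel elsewhere.

Mismatched grids are rejected, never resampled: every mask is expected to
have been normalised to one template beforehand, so a disagreement in shape
or affine indicates an upstream error rather than something to paper over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.affines import apply_affine

from .errors import GridMismatchError, MaskFormatError

#: Value written for voxels that were never tested (covered by fewer than
#: ``min_overlap`` lesions).  Valid p-values lie in (0, 1], so any negative
#: value is unambiguous; the file header's description field documents it.
UNTESTED_SENTINEL = -1.0

_AFFINE_TOL = 1e-4


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a volume: array shape plus index->mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel indices (0-based) -> MNI mm

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if any(d < 1 for d in dims):
            raise ValueError(f"grid dims must all be >= 1, got {dims}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (0-based, any shape (..., 3)) to mm coordinates."""
        return apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return apply_affine(np.linalg.inv(self.affine), np.asarray(xyz, dtype=float))

    def matches(self, other: "VolumeGrid", tol: float = _AFFINE_TOL) -> bool:
        return self.dims == other.dims and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    def require_match(self, other: "VolumeGrid", context: str = "") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch{(' for ' + context) if context else ''}: "
                f"dims {self.dims} vs {other.dims}; affine\n{self.affine}\nvs\n{other.affine}"
            )

    def __eq__(self, other: object) -> bool:  # tolerance-aware equality
        return isinstance(other, VolumeGrid) and self.matches(other)

    def __hash__(self) -> int:
        return hash(self.dims)


def mni_grid(dims: tuple[int, int, int] = (79, 95, 79),
             voxel_mm: float = 2.0) -> VolumeGrid:
    """An MNI-like bounding-box grid (default 79x95x79 at 2 mm).

    The origin is placed so the grid spans roughly x in [-78, 78],
    y in [-112, 76], z in [-50, 106] mm, mirroring the template bounding box.
    """
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = (-78.0, -112.0, -50.0)
    return VolumeGrid(dims=tuple(dims), affine=affine)


@dataclass
class LesionMask:
    """One patient's binary lesion, as a boolean volume on a shared grid."""

    subject_id: str
    grid: VolumeGrid
    data: np.ndarray  # bool, shape == grid.dims

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} != grid dims {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    def voxel_indices(self) -> np.ndarray:
        """(k, 3) array of lesioned voxel indices."""
        return np.argwhere(self.data)


@dataclass
class ScoreWeightedVolume:
    """A lesion mask with every lesioned voxel set to the patient's score.

    Retained as an exchange/visualisation representation; the statistics
    consume raw score lists directly, which is numerically equivalent.
    """

    subject_id: str
    grid: VolumeGrid
    data: np.ndarray  # float volume, score on lesioned voxels, 0 elsewhere
    score: float


@dataclass
class StatMap:
    """Per-voxel p-values (NaN where untested) and a significance volume."""

    grid: VolumeGrid
    p_values: np.ndarray  # float, NaN = untested
    significant: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        if self.p_values.shape != self.grid.dims:
            raise ValueError("p_values shape does not match grid")
        if self.significant.shape != self.grid.dims:
            raise ValueError("significance shape does not match grid")
        if np.any(self.significant & np.isnan(self.p_values)):
            raise ValueError("significant voxels must have been tested")

    @property
    def n_tested(self) -> int:
        return int(np.isfinite(self.p_values).sum())

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _grid_of(img: nib.spatialimages.SpatialImage) -> VolumeGrid:
    return VolumeGrid(dims=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def read_mask(path: str | Path, reference_grid: VolumeGrid | None = None,
              subject_id: str | None = None) -> LesionMask:
    """Read a binary lesion mask from a NIfTI file.

    Values must take at most two distinct levels {0, v>0}; any positive level
    is binarised to 1 (a mask saved as {0, 255} reads the same as {0, 1}).
    If ``reference_grid`` is given the file's grid must match it (dims and
    affine within tolerance); otherwise a :class:`GridMismatchError` names
    both affines.
    """
    path = Path(path)
    img = nib.load(str(path))
    grid = _grid_of(img)
    if reference_grid is not None:
        reference_grid.require_match(grid, context=str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise MaskFormatError(f"{path}: expected a 3D volume, got {data.shape}")
    values = np.unique(data)
    nonzero = values[values != 0]
    if nonzero.size > 1:
        raise MaskFormatError(
            f"{path}: mask has {nonzero.size + 1} distinct values "
            f"(expected binary {{0, v}}); found {values[:5]}..."
        )
    if nonzero.size == 1 and nonzero[0] < 0:
        raise MaskFormatError(f"{path}: mask level must be positive, got {nonzero[0]}")
    if subject_id is None:
        subject_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return LesionMask(subject_id=subject_id, grid=grid, data=data > 0)


def read_masks_dir(directory: str | Path,
                   reference_grid: VolumeGrid | None = None) -> list[LesionMask]:
    """Read every ``<subject_id>.nii[.gz]`` in a directory, sorted by id.

    The first mask's grid becomes the reference for the rest when no
    explicit reference is given.
    """
    directory = Path(directory)
    paths = sorted(
        [p for p in directory.iterdir() if p.name.endswith((".nii", ".nii.gz"))]
    )
    if not paths:
        raise FileNotFoundError(f"no NIfTI masks found in {directory}")
    masks: list[LesionMask] = []
    ref = reference_grid
    for p in paths:
        m = read_mask(p, reference_grid=ref)
        if ref is None:
            ref = m.grid
        masks.append(m)
    return masks


def write_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    img.header["descrip"] = b"binary lesion mask"
    nib.save(img, str(path))


def weight_by_score(mask: LesionMask, score: float) -> ScoreWeightedVolume:
    """Set every lesioned voxel to the patient's score, zero elsewhere."""
    score = float(score)
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    data = np.where(mask.data, score, 0.0)
    return ScoreWeightedVolume(
        subject_id=mask.subject_id, grid=mask.grid, data=data, score=score
    )


def _sig_path(p_path: Path) -> Path:
    name = p_path.name.removesuffix(".gz")
    stem = name.removesuffix(".nii")
    suffix = p_path.name[len(stem):]
    return p_path.with_name(stem + "_sig" + suffix)


def write_stat_map(stat_map: StatMap, path: str | Path,
                   sig_path: str | Path | None = None) -> tuple[Path, Path]:
    """Write a p-value volume plus a companion binary significance volume.

    Untested voxels are encoded as :data:`UNTESTED_SENTINEL` (-1.0); the
    header description field records the convention.  Values round-trip
    bit-exact through :func:`read_stat_map` (float64 storage).
    """
    path = Path(path)
    sig_path = _sig_path(path) if sig_path is None else Path(sig_path)
    p = np.where(np.isfinite(stat_map.p_values), stat_map.p_values,
                 UNTESTED_SENTINEL)
    img = nib.Nifti1Image(p.astype(np.float64), stat_map.grid.affine)
    img.header["descrip"] = f"p-values; untested={UNTESTED_SENTINEL}".encode()
    nib.save(img, str(path))
    sig = nib.Nifti1Image(stat_map.significant.astype(np.uint8),
                          stat_map.grid.affine)
    sig.header["descrip"] = b"1 = significant after Holm correction"
    nib.save(sig, str(sig_path))
    return path, sig_path


def read_stat_map(path: str | Path,
                  sig_path: str | Path | None = None) -> StatMap:
    path = Path(path)
    sig_path = _sig_path(path) if sig_path is None else Path(sig_path)
    img = nib.load(str(path))
    p = np.asanyarray(img.dataobj).astype(np.float64)
    p = np.where(p < 0, np.nan, p)
    sig_img = nib.load(str(sig_path))
    sig = np.asanyarray(sig_img.dataobj) > 0
    grid = _grid_of(img)
    _grid_of(sig_img).require_match(grid, context=str(sig_path))
    return StatMap(grid=grid, p_values=p, significant=sig)
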