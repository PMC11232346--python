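"""Regular-grid mask representation and margin/boolean/overlap operations.

All structures in a case live on one axis-aligned grid with voxel-center
sampling.  Isotropic margins are realized through Euclidean distance
transforms of the mask, thresholded at the margin value measured between
voxel centers; this keeps sub-voxel margins (e.g. 0.5 mm contraction steps
on a 2.5 mm grid) meaningful, because the distance field varies continuously
with the margin even though the voxelized result changes in discrete jumps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "RoiMask",
    "GridMismatchError",
    "Overlap",
    "volume_cc",
    "morph",
    "ring",
    "subtract",
    "intersect",
    "union",
    "overlap",
    "save_structures",
    "load_structures",
]

_EPS = 1e-9


class GridMismatchError(ValueError):
    """Raised when two masks on different grids are combined."""


@dataclass(frozen=True)
class Grid:
    """Axis-aligned regular grid (voxel-center convention, no orientation)."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def coord_grids_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords_mm(i) for i in range(3)), indexing="ij")


@dataclass
class RoiMask:
    """Named boolean voxel set on a shared grid."""

    name: str
    grid: Grid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=bool)
        if vox.shape != self.grid.shape:
            raise ValueError(
                f"mask {self.name!r}: voxel array shape {vox.shape} != grid shape {self.grid.shape}"
            )
        self.voxels = vox

    @property
    def volume_cc(self) -> float:
        return float(np.count_nonzero(self.voxels)) * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def with_voxels(self, voxels: np.ndarray, name: str | None = None) -> "RoiMask":
        return RoiMask(name if name is not None else self.name, self.grid, voxels)


def _check_same_grid(a: RoiMask, b: RoiMask) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(f"masks {a.name!r} and {b.name!r} are on different grids")


def volume_cc(mask: RoiMask) -> float:
    """Volume of a mask in cc (1 cc = 1000 mm^3)."""
    return mask.volume_cc


def distance_outside_mm(mask: RoiMask) -> np.ndarray:
    """Euclidean distance (mm) from each background voxel center to the
    nearest mask voxel center; 0 inside the mask."""
    if mask.is_empty:
        return np.full(mask.grid.shape, np.inf)
    return ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing_mm)


def distance_inside_mm(mask: RoiMask) -> np.ndarray:
    """Euclidean distance (mm) from each mask voxel center to the nearest
    background voxel center; 0 outside the mask."""
    if mask.voxels.all():
        return np.full(mask.grid.shape, np.inf)
    return ndimage.distance_transform_edt(mask.voxels, sampling=mask.grid.spacing_mm)


def expand_from_distance(mask: RoiMask, dist_out: np.ndarray, margin_mm: float,
                         name: str | None = None) -> RoiMask:
    return mask.with_voxels(mask.voxels | (dist_out <= margin_mm + _EPS), name)


def contract_from_distance(mask: RoiMask, dist_in: np.ndarray, margin_mm: float,
                           name: str | None = None) -> RoiMask:
    return mask.with_voxels(mask.voxels & (dist_in > margin_mm + _EPS), name)


def morph(mask: RoiMask, margin_mm: float, name: str | None = None) -> RoiMask:
    """Isotropic Euclidean margin: positive expands, negative contracts,
    0 is the identity.  Expansion is clipped at the grid boundary; contraction
    may legally yield an empty mask."""
    if margin_mm > 0:
        return expand_from_distance(mask, distance_outside_mm(mask), margin_mm, name)
    if margin_mm < 0:
        return contract_from_distance(mask, distance_inside_mm(mask), -margin_mm, name)
    return mask.with_voxels(mask.voxels.copy(), name)


def ring(mask: RoiMask, inner_mm: float, outer_mm: float, name: str | None = None) -> RoiMask:
    """Shell between the inner and outer margins of a mask, disjoint from
    ``morph(mask, inner_mm)`` (and from the mask itself when inner_mm = 0)."""
    if inner_mm < 0:
        raise ValueError(f"inner margin must be >= 0, got {inner_mm}")
    if outer_mm <= inner_mm:
        raise ValueError(f"outer margin ({outer_mm}) must exceed inner margin ({inner_mm})")
    dist_out = distance_outside_mm(mask)
    outer = expand_from_distance(mask, dist_out, outer_mm)
    inner = expand_from_distance(mask, dist_out, inner_mm)
    return mask.with_voxels(outer.voxels & ~inner.voxels, name)


def subtract(a: RoiMask, b: RoiMask, name: str | None = None) -> RoiMask:
    _check_same_grid(a, b)
    return a.with_voxels(a.voxels & ~b.voxels, name)


def intersect(a: RoiMask, b: RoiMask, name: str | None = None) -> RoiMask:
    _check_same_grid(a, b)
    return a.with_voxels(a.voxels & b.voxels, name)


def union(a: RoiMask, b: RoiMask, name: str | None = None) -> RoiMask:
    _check_same_grid(a, b)
    return a.with_voxels(a.voxels | b.voxels, name)


@dataclass(frozen=True)
class Overlap:
    """Overlap of one structure inside another.

    ``fraction_pct`` is None (undefined) when the reference structure is
    empty; ``volume_cc`` is always defined.
    """

    fraction_pct: float | None
    volume_cc: float


def overlap(of: RoiMask, in_: RoiMask) -> Overlap:
    """Overlap of ``of`` inside ``in_``: percentage of ``of``'s volume and
    the absolute intersection volume in cc."""
    _check_same_grid(of, in_)
    n_of = int(np.count_nonzero(of.voxels))
    n_int = int(np.count_nonzero(of.voxels & in_.voxels))
    vol_cc = n_int * of.grid.voxel_volume_cc
    if n_of == 0:
        return Overlap(fraction_pct=None, volume_cc=0.0)
    return Overlap(fraction_pct=100.0 * n_int / n_of, volume_cc=vol_cc)


# ---------------------------------------------------------------------------
# NIfTI I/O: one binary volume per ROI plus a JSON sidecar manifest.
# ---------------------------------------------------------------------------

def _safe_filename(name: str) -> str:
    return "".join(c if (c.isalnum() or c in "._-") else "_" for c in name)


def save_structures(structures: dict[str, RoiMask], out_dir: str | Path,
                    extra_manifest: dict | None = None) -> Path:
    """Write each mask as an uncompressed-header NIfTI (.nii.gz) volume and a
    ``manifest.json`` mapping structure names to files.  Returns the manifest
    path."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, mask in structures.items():
        affine = np.diag(list(mask.grid.spacing_mm) + [1.0])
        affine[:3, 3] = mask.grid.origin_mm
        img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
        fname = _safe_filename(name) + ".nii.gz"
        nib.save(img, out_dir / fname)
        entries[name] = fname
    manifest = {"structures": entries}
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_structures(manifest_path: str | Path) -> tuple[dict[str, RoiMask], dict]:
    """Load a structure set written by :func:`save_structures`.  Grid spacing
    and origin are taken from the NIfTI headers.  Returns (structures, manifest)."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    structures: dict[str, RoiMask] = {}
    grid: Grid | None = None
    for name, fname in manifest["structures"].items():
        img = nib.load(base / fname)
        data = np.asarray(img.dataobj) > 0
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        g = Grid(shape=data.shape, spacing_mm=spacing, origin_mm=origin)
        if grid is None:
            grid = g
        elif g != grid:
            raise GridMismatchError(f"structure {name!r} is on a different grid")
        structures[name] = RoiMask(name, g, data)
    return structures, manifest
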