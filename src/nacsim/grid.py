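"""Structured voxel grids and voxel-registered scalar fields.

The computational domain is a box of breast tissue discretized as a regular
voxel raster. Field values are registered to voxel centers (equivalently,
nodes of a uniform lattice); all integrals downstream use midpoint (voxel-sum)
quadrature.

Raster I/O supports two dialects:

* NIfTI-1 (``.nii`` / ``.nii.gz``) with the voxel spacing (mm) carried in the
  header zooms and the origin in the affine translation;
* a plain ``.npy`` array with a JSON sidecar (``<stem>.json``) holding
  ``shape``, ``spacing_mm`` and ``origin_mm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "ScalarField",
    "make_grid",
    "upsample",
    "read_volume",
    "write_volume",
]


@dataclass(frozen=True)
class Grid:
    """A regular 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis; every entry must be >= 4 so that
        second-order stencils and a healthy-tissue margin fit.
    spacing
        Voxel edge lengths in mm (strictly positive).
    origin
        Physical coordinate (mm) of the first voxel center.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("grid shape and spacing must be length-3")
        if any(int(n) < 4 for n in self.shape):
            raise ValueError(f"all grid shape entries must be >= 4, got {self.shape}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinate arrays (mm), one per axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass
class ScalarField:
    """A real-valued field sampled on a :class:`Grid`."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite everywhere")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


def make_grid(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Grid:
    """Build a :class:`Grid` with the stated shape and spacing, origin at zero
    unless given."""
    return Grid(tuple(shape), tuple(spacing_mm), tuple(origin_mm))


def upsample(f: ScalarField, factor: int) -> ScalarField:
    """Trilinear refinement of a field by an integer factor.

    The refined lattice keeps the original nodes: axis length ``n`` becomes
    ``factor * (n - 1) + 1`` with spacing ``h / factor``, so sampling the
    result at every ``factor``-th node reproduces the input exactly and the
    interpolation never exceeds the original min/max (convexity).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"upsampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return f.copy()
    g = f.grid
    new_shape = tuple(factor * (n - 1) + 1 for n in g.shape)
    coords = np.meshgrid(
        *[np.arange(m) / factor for m in new_shape], indexing="ij"
    )
    vals = ndimage.map_coordinates(f.values, coords, order=1, mode="nearest")
    new_grid = Grid(
        new_shape,
        tuple(s / factor for s in g.spacing),
        g.origin,
    )
    return ScalarField(new_grid, vals)


def write_volume(f: ScalarField, path: str | Path) -> None:
    """Write a field to disk; dialect chosen from the file suffix."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(f.grid.spacing) + [1.0])
        affine[:3, 3] = f.grid.origin
        img = nib.Nifti1Image(f.values, affine)
        img.header.set_zooms(f.grid.spacing)
        nib.save(img, str(path))
    elif path.suffix == ".npy":
        np.save(path, f.values)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "shape": list(f.grid.shape),
                    "spacing_mm": list(f.grid.spacing),
                    "origin_mm": list(f.grid.origin),
                }
            )
        )
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path) -> ScalarField:
    """Read a field written by :func:`write_volume` (lossless round-trip)."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        grid = Grid(data.shape, tuple(float(z) for z in zooms), origin)
        return ScalarField(grid, data)
    if path.suffix == ".npy":
        data = np.load(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"missing JSON sidecar for {path.name}")
        meta = json.loads(sidecar.read_text())
        for key in ("shape", "spacing_mm"):
            if key not in meta:
                raise ValueError(f"sidecar of {path.name} lacks required key '{key}'")
        if tuple(meta["shape"]) != data.shape:
            raise ValueError(
                f"sidecar shape {meta['shape']} does not match array {data.shape}"
            )
        grid = Grid(
            tuple(meta["shape"]),
            tuple(meta["spacing_mm"]),
            tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
        )
        return ScalarField(grid, data)
    raise ValueError(f"unsupported volume format: {path.name}")
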