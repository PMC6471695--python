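"""MRC volume and PDB coordinate I/O.

All volumes are exposed as :class:`DensityMap` objects holding a 3D
``float32`` array in logical ``(x, y, z)`` index order, the per-axis
voxel size in Angstrom, and the Angstrom origin of the grid corner.
Voxel *centers* sit at ``origin + (i + 0.5) * voxel_size``.  MRC files
are written in MRC2014 layout (via gemmi); on read, grids stored with a
permuted axis order are rearranged into the logical order, so no other
module ever sees a transposed volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "AtomicModel",
    "MapFormatError",
    "read_mrc",
    "write_mrc",
    "read_atomic_model",
]


class MapFormatError(ValueError):
    """Raised when an MRC file cannot be interpreted."""


def _as_triple(value, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 sequence")
    return arr


@dataclass
class DensityMap:
    """A 3D scalar grid with physical sampling metadata.

    Parameters
    ----------
    data
        3D array of densities, logical ``(x, y, z)`` order.
    voxel_size
        Sampling rate in Angstrom per voxel; scalar or per-axis triple.
    origin
        Angstrom coordinates of the grid corner (default zero).
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("density grid must be 3D with all dims >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density grid contains non-finite values")
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "DensityMap":
        return DensityMap(self.data.copy(), self.voxel_size.copy(), self.origin.copy())

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Angstrom coordinates of voxel centers along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]


@dataclass
class AtomicModel:
    """Point-atom model: positions in Angstrom plus positive weights."""

    positions: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.weights is None:
            self.weights = np.ones(len(self.positions))
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.weights) != len(self.positions):
            raise ValueError("weights and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")
        if len(self.weights) and np.any(self.weights <= 0):
            raise ValueError("atom weights must be positive")

    def __len__(self) -> int:
        return len(self.positions)


def read_mrc(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 volume into a :class:`DensityMap`.

    The grid is returned in logical ``(x, y, z)`` order regardless of the
    MAPC/MAPR/MAPS permutation stored in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"not a valid MRC file: {path} ({exc})") from exc
    # gemmi normalizes MAPC/MAPR/MAPS into grid (u,v,w) == (x,y,z)
    data = np.array(ccp4.grid, copy=True)
    if data.ndim != 3 or data.size == 0:
        raise MapFormatError(f"MRC header of {path} declares an empty grid (NX/NY/NZ)")
    spacing = np.array(ccp4.grid.spacing, dtype=float)
    if np.any(~np.isfinite(spacing)) or np.any(spacing <= 0):
        raise MapFormatError(f"MRC header of {path} has invalid cell dimensions (CELLA)")
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if not np.all(np.isfinite(data)):
        raise MapFormatError(f"MRC data block of {path} contains non-finite values")
    return DensityMap(data, spacing, origin)


def write_mrc(density_map: DensityMap, path: str | Path) -> None:
    """Write a :class:`DensityMap` as an MRC2014 volume.

    Cell dimensions encode the per-axis voxel size (``CELLA = N *
    voxel_size``); the Angstrom origin goes into the ORIGIN header words.
    """
    path = Path(path)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.data, dtype=np.float32))
    nx, ny, nz = density_map.shape
    vx, vy, vz = density_map.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), density_map.origin):
        ccp4.set_header_float(word, float(value))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write MRC file {path}: {exc}") from exc


def read_atomic_model(path: str | Path, weight_by_element: bool = False) -> AtomicModel:
    """Read ATOM/HETATM coordinates from a PDB file, in file order.

    Parameters
    ----------
    weight_by_element
        When True, atom weights are atomic numbers; otherwise every atom
        gets unit weight.
    """
    path = Path(path)
    structure = gemmi.read_pdb(str(path))
    positions: list[tuple[float, float, float]] = []
    weights: list[float] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    positions.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    if weight_by_element:
                        z = atom.element.atomic_number
                        weights.append(float(z) if z > 0 else 1.0)
                    else:
                        weights.append(1.0)
        break  # first model only; NMR-style multi-model files are not stacked
    if not positions:
        warnings.warn(f"no ATOM/HETATM records found in {path}; returning empty model")
        return AtomicModel(np.empty((0, 3)))
    return AtomicModel(np.array(positions), np.array(weights))
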