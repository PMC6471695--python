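"""Simulation of resolution-labeled density volumes.

Global-resolution maps are rendered from atomic models by the Gaussian
atom model: every atom contributes an isotropic 3D Gaussian whose width
is set by the target resolution R through the half-amplitude contract —
the Fourier amplitude of the atom kernel falls to one half of its
zero-frequency value at spatial frequency ``s = 1/R``.  For a real-space
Gaussian ``exp(-r^2 / 2 sigma^2)`` the transform is
``exp(-2 pi^2 sigma^2 s^2)``, so

    sigma = R * sqrt(ln 2 / 2) / pi  (Angstrom).

Maps are synthesized in Fourier space (Gaussian transfer function times
the exact atomic structure factor) so the *sampled* grid honors the
contract even when sigma is below the voxel size, where direct
real-space rasterization would alias.  Voxels whose amplitude falls
below a small fraction of the map's peak (``zero_tol``, default 3e-4)
are then clamped to exact zero: because the atom kernel decays with
distance, every voxel beyond a structure-dependent support radius is
exactly zero, which keeps empty-volume bookkeeping (empty-cube removal,
mask derivation) well defined while perturbing the spectrum by well
under 1%.  Sub-voxel kernels are band-limited by the grid and carry
small negative side lobes; these are genuine spectral content and are
preserved (only sub-threshold amplitudes are clamped).

Local-resolution phantoms render one shared structure at several
resolutions and stitch axis-aligned regions together, which yields
exact by-construction voxel labels in the ten resolution bins — a
synthetic stand-in for label volumes produced by local-resolution
estimators such as MonoRes or ResMap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AtomicModel, DensityMap
from .preprocess import BACKGROUND, bin_resolution10, split_sizes

__all__ = [
    "SimulationSpec",
    "LocalResolutionPhantomSpec",
    "SimulationError",
    "sigma_for_resolution",
    "simulate_map",
    "make_synthetic_model",
    "make_local_res_phantom",
    "corpus_plan",
]

#: The three training resolutions (Angstrom) for the global classifiers.
TRAINING_RESOLUTIONS = (2.5, 7.5, 12.5)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Target resolution and grid geometry for map simulation."""

    resolution: float
    box: int = 64
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.box < 8:
            raise ValueError("box must be at least 8 voxels")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


def sigma_for_resolution(resolution: float) -> float:
    """Real-space Gaussian sigma (Angstrom) for the half-amplitude contract."""
    return resolution * np.sqrt(np.log(2.0) / 2.0) / np.pi


def _structure_factor(frac_coords: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Exact DFT-grid structure factor of point atoms at fractional voxel coords."""
    freqs = np.fft.fftfreq(n)
    # per-axis phase factors, shape (atoms, n)
    ax = np.exp(-2j * np.pi * np.outer(frac_coords[:, 0], freqs))
    ay = np.exp(-2j * np.pi * np.outer(frac_coords[:, 1], freqs))
    az = np.exp(-2j * np.pi * np.outer(frac_coords[:, 2], freqs))
    ax = ax * weights[:, None]
    out = np.zeros((n, n * n), dtype=np.complex128)
    # chunk over atoms to bound the (atoms, n^2) intermediate
    step = max(1, int(4e7 // (n * n)))
    for i in range(0, len(frac_coords), step):
        yz = (ay[i : i + step, :, None] * az[i : i + step, None, :]).reshape(-1, n * n)
        out += ax[i : i + step].T @ yz
    return out.reshape(n, n, n)


def simulate_map(
    model: AtomicModel,
    spec: SimulationSpec,
    center: bool = True,
    zero_tol: float = 3e-4,
) -> DensityMap:
    """Render an atomic model as a density map at the target resolution.

    Atoms are translated so their centroid sits at the box center
    (unless ``center=False``), each contributes a Gaussian of weight
    proportional to its atom weight, and voxels whose amplitude is
    below ``zero_tol`` times the map peak — in particular all voxels
    far from every atom — are exactly zero.
    """
    n, v = spec.box, spec.voxel_size
    out_map = DensityMap(
        np.zeros((n, n, n), dtype=np.float32), np.full(3, v), np.zeros(3)
    )
    if len(model) == 0:
        return out_map

    positions = model.positions.copy()
    box_edge = n * v
    if center:
        # move the centroid to the box center, but clamp the shift per
        # axis so a structure that fits the box never leaves it
        shift = np.full(3, box_edge / 2.0) - positions.mean(axis=0)
        eps = 1e-6 * box_edge
        low = -positions.min(axis=0)
        high = (box_edge - eps) - positions.max(axis=0)
        positions += np.clip(shift, np.minimum(low, high), np.maximum(low, high))
    outside = np.any((positions < 0) | (positions >= box_edge), axis=1)
    if np.any(outside):
        idx = int(np.argmax(outside))
        raise SimulationError(
            f"atom {idx} at {positions[idx]} falls outside the "
            f"{n}^3 box ({box_edge:.1f} A edge); use a larger box"
        )

    sigma = sigma_for_resolution(spec.resolution)
    if sigma < v:
        warnings.warn(
            f"resolution {spec.resolution} A gives a Gaussian of sigma "
            f"{sigma:.2f} A, narrower than one voxel ({v} A); the rendered "
            "kernel is band-limited by the grid"
        )

    # voxel-center coordinates: voxel i is at (i + 0.5) * v, so the atom's
    # fractional voxel coordinate is p/v - 0.5
    frac = positions / v - 0.5
    sf = _structure_factor(frac, model.weights, n)
    freqs = np.fft.fftfreq(n, d=v)
    s2 = (
        freqs[:, None, None] ** 2 + freqs[None, :, None] ** 2 + freqs[None, None, :] ** 2
    )
    transfer = np.exp(-2.0 * np.pi**2 * sigma**2 * s2)
    density = np.fft.ifftn(transfer * sf).real

    if zero_tol > 0:
        density[np.abs(density) < zero_tol * np.abs(density).max()] = 0.0
    out_map.data = density.astype(np.float32)
    return out_map


def make_synthetic_model(
    n_atoms: int,
    extent: float,
    seed: int,
    persistence: float = 0.92,
    segment_rate: float = 1.0 / 15.0,
) -> AtomicModel:
    """Generate a protein-like atom chain inside ``extent``^3 A.

    The chain is a stiff, self-avoiding random walk: consecutive atoms
    are exactly 1.5 A apart (backbone-bond scale), the direction
    persists within a segment (``persistence``, emulating the local
    rigidity of secondary-structure elements, which renders as rod-like
    motifs the way helices do in real maps) and is redrawn uniformly at
    rate ``segment_rate`` per step (segment length ~15 atoms ~ 22 A).
    A ~1.2 A excluded-volume distance gives the roughly uniform packing
    density of folded proteins; steps that would leave the box or clash
    are resampled, relaxing the clash distance if the walk gets
    trapped.  Deterministic given the seed.
    """
    if n_atoms < 0:
        raise ValueError("n_atoms must be non-negative")
    if extent <= 0:
        raise ValueError("extent must be positive")
    if n_atoms == 0:
        return AtomicModel(np.empty((0, 3)))
    rng = np.random.default_rng(seed)
    step = 1.5
    clash = 1.2
    margin = min(1.0, extent / 4.0)
    lo, hi = margin, extent - margin
    pos = np.empty((n_atoms, 3))
    pos[0] = extent / 2.0
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n_atoms):
        placed = False
        for attempt in range(200):
            # relax the clash distance if the walk gets trapped, keeping
            # the 1.5 A step length exact
            allowed = clash * max(0.0, 1.0 - attempt / 100.0)
            if rng.random() < segment_rate or attempt > 50:
                new_direction = rng.normal(size=3)
            else:
                new_direction = persistence * direction + (
                    1.0 - persistence
                ) * rng.normal(size=3)
            new_direction /= np.linalg.norm(new_direction)
            candidate = pos[i - 1] + step * new_direction
            if not np.all((candidate >= lo) & (candidate <= hi)):
                continue
            if i > 1:
                gaps = np.linalg.norm(pos[: i - 1] - candidate, axis=1)
                if gaps.min() < allowed:
                    continue
            pos[i] = candidate
            direction = new_direction
            placed = True
            break
        if not placed:  # box smaller than one step: stay put rather than escape
            pos[i] = pos[i - 1]
    return AtomicModel(pos)


@dataclass
class LocalResolutionPhantomSpec:
    """Layout and resolutions for a spatially varying resolution phantom.

    ``layout='slabs'`` splits the box into equal slabs along x, one per
    resolution; ``layout='spheres'`` uses concentric shells around the
    box center (innermost region first).
    """

    resolutions: tuple[float, ...]
    layout: str = "slabs"
    box: int = 64
    voxel_size: float = 1.0
    structure: AtomicModel | None = None
    n_atoms: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.resolutions:
            raise ValueError("at least one region resolution is required")
        if any(r <= 0 for r in self.resolutions):
            raise ValueError("region resolutions must be positive")
        if self.layout not in ("slabs", "spheres"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _region_masks(spec: LocalResolutionPhantomSpec) -> list[np.ndarray]:
    n, k = spec.box, len(spec.resolutions)
    idx = np.arange(n)
    if spec.layout == "slabs":
        bounds = np.linspace(0, n, k + 1).round().astype(int)
        masks = []
        for j in range(k):
            m = np.zeros((n, n, n), dtype=bool)
            m[bounds[j] : bounds[j + 1]] = True
            masks.append(m)
        return masks
    # concentric shells, radii splitting the half-edge evenly
    c = (n - 1) / 2.0
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    radii = np.linspace(0, n, k + 1)[1:]
    radii[-1] = np.inf
    masks = []
    inner = np.zeros((n, n, n), dtype=bool)
    for radius in radii:
        shell = (r <= radius) & ~inner
        masks.append(shell)
        inner |= shell
    return masks


def make_local_res_phantom(
    spec: LocalResolutionPhantomSpec,
) -> tuple[DensityMap, np.ndarray]:
    """Build a density map with region-wise resolution plus exact voxel labels.

    One shared structure is rendered at each region's resolution and the
    regions stitched together.  Every voxel inside the structure mask
    (non-zero density) receives the 10-bin class of its region's
    resolution; all other voxels carry the background sentinel.
    """
    structure = spec.structure
    if structure is None:
        extent = 0.7 * spec.box * spec.voxel_size
        structure = make_synthetic_model(spec.n_atoms, extent, spec.seed)
    masks = _region_masks(spec)
    density = np.zeros((spec.box,) * 3, dtype=np.float32)
    labels = np.full((spec.box,) * 3, BACKGROUND, dtype=np.int64)
    for region_mask, resolution in zip(masks, spec.resolutions):
        rendered = simulate_map(
            structure, SimulationSpec(resolution, spec.box, spec.voxel_size)
        )
        inside = region_mask & (rendered.data != 0)
        density[inside] = rendered.data[inside]
        labels[inside] = bin_resolution10(resolution)
    density_map = DensityMap(density, np.full(3, spec.voxel_size), np.zeros(3))
    return density_map, labels


def corpus_plan(
    n_structures: int = 12671,
    resolutions: tuple[float, ...] = TRAINING_RESOLUTIONS,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> dict:
    """Account for the simulated training corpus without materializing it.

    Each structure is simulated once per resolution, so the corpus holds
    ``n_structures * len(resolutions)`` maps; split sizes follow the
    same rounding rule as :func:`cryores.preprocess.split_dataset`.
    """
    total = n_structures * len(resolutions)
    train, val, test = split_sizes(total, ratios)
    return {
        "n_structures": n_structures,
        "per_resolution": {float(r): n_structures for r in resolutions},
        "total_maps": total,
        "split": {"train": train, "validation": val, "test": test},
    }
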