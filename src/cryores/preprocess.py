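"""Data preparation for the resolution classifiers.

Covers the full path from a raw volume to network-ready tensors:
min-max intensity normalization, 3-class and 10-bin resolution
labeling, central crop / trailing zero-pad to a fixed box, masking,
power-of-two padding, 16-cube partitioning with empty-cube removal,
and reproducible dataset splitting.

Two padding protocols coexist deliberately: experimental maps headed
for the global classifiers are padded on the trailing side only
(:func:`central_crop_or_pad`), while map/label pairs headed for the
voxel-wise classifier are padded symmetrically to a power-of-two cube
with the odd leftover voxel placed front or back by a seeded coin flip
(:func:`pad_to_pow2`).

Voxel-wise label volumes are integer arrays with classes ``0..9`` and
the background sentinel :data:`BACKGROUND` (-1) outside the structure
mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .io_formats import DensityMap

__all__ = [
    "BACKGROUND",
    "ResolutionClass3",
    "LabeledVolume",
    "PatchBatch",
    "SplitSpec",
    "minmax_normalize",
    "three_class_label",
    "bin_resolution10",
    "central_crop_or_pad",
    "apply_mask",
    "pad_to_pow2",
    "partition_patches",
    "reassemble_patches",
    "split_dataset",
]

#: Sentinel for voxels outside the structure mask in label volumes.
BACKGROUND = -1

#: Upper edges of the ten resolution bins (Angstrom); bins are [lo, hi),
#: the last bin is [10, inf).
BIN10_EDGES = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])


class ResolutionClass3(IntEnum):
    """Global resolution level; integer codes 0—high, 1—medium, 2—low."""

    HIGH = 0
    MEDIUM = 1
    LOW = 2


@dataclass
class LabeledVolume:
    """A density map paired with its resolution ground truth.

    ``label`` is either a single :class:`ResolutionClass3` (global
    classification) or an integer volume of per-voxel classes 0..9 with
    :data:`BACKGROUND` outside the structure.
    """

    map: DensityMap
    label: ResolutionClass3 | np.ndarray

    def __post_init__(self) -> None:
        if isinstance(self.label, np.ndarray):
            if self.label.shape != self.map.shape:
                raise ValueError("per-voxel label volume must match map dimensions")
            values = np.unique(self.label)
            valid = set(range(10)) | {BACKGROUND}
            if not set(values.tolist()) <= valid:
                raise ValueError(f"label values outside 0..9 / background: {values}")


def minmax_normalize(density_map: DensityMap) -> DensityMap:
    """Linearly rescale intensities into [0, 1].

    A constant map has no dynamic range and maps to all zeros, so that
    downstream empty-cube removal treats it as empty.
    """
    data = density_map.data
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return DensityMap(out, density_map.voxel_size.copy(), density_map.origin.copy())


def three_class_label(resolution: float) -> ResolutionClass3:
    """Map a resolution in Angstrom to high (<5), medium (5-10), low (>10)."""
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if resolution < 5.0:
        return ResolutionClass3.HIGH
    if resolution <= 10.0:
        return ResolutionClass3.MEDIUM
    return ResolutionClass3.LOW


def bin_resolution10(resolution):
    """Bin a resolution (Angstrom) into one of ten classes.

    Bins are half-open ``[lo, hi)``: 0 for [0,2), 1 for [2,3), ... 8 for
    [9,10), and 9 for [10, inf).  Accepts scalars or arrays.
    """
    arr = np.asarray(resolution, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("resolution must be positive")
    bins = np.searchsorted(BIN10_EDGES, arr, side="right")
    if np.isscalar(resolution) or arr.ndim == 0:
        return int(bins)
    return bins.astype(np.int64)


def central_crop_or_pad(density_map: DensityMap, target: int = 64) -> DensityMap:
    """Force a volume to ``target``^3 by central crop and/or trailing zero-pad.

    Axes longer than ``target`` lose their outer parts symmetrically
    (offset ``(dim - target) // 2``); axes shorter than ``target`` keep
    the original data at the low indices and get zeros appended at the
    end.  The origin is advanced by the crop offset so voxel coordinates
    stay physically meaningful.
    """
    data = density_map.data
    origin = density_map.origin.copy()
    for axis in range(3):
        dim = data.shape[axis]
        if dim > target:
            start = (dim - target) // 2
            sl = [slice(None)] * 3
            sl[axis] = slice(start, start + target)
            data = data[tuple(sl)]
            origin[axis] += start * density_map.voxel_size[axis]
        elif dim < target:
            pad = [(0, 0)] * 3
            pad[axis] = (0, target - dim)
            data = np.pad(data, pad)
    return DensityMap(data, density_map.voxel_size.copy(), origin)


def apply_mask(density_map: DensityMap, mask: np.ndarray) -> DensityMap:
    """Zero all voxels where the binary mask is 0."""
    mask = np.asarray(mask)
    if mask.shape != density_map.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match map shape {density_map.shape}"
        )
    values = np.unique(mask)
    if not set(values.tolist()) <= {0, 1}:
        raise ValueError("mask must be binary (values 0/1)")
    out = density_map.data * mask.astype(np.float32)
    return DensityMap(out, density_map.voxel_size.copy(), density_map.origin.copy())


def _pow2_padding(shape: tuple[int, ...], seed: int) -> list[tuple[int, int]]:
    """Front/back pad widths taking ``shape`` to the enclosing power-of-two cube."""
    target = 1
    while target < max(shape):
        target *= 2
    rng = np.random.default_rng(seed)
    pads = []
    for dim in shape:
        total = target - dim
        front = total // 2
        back = total - front
        if total % 2 == 1 and rng.integers(2) == 1:
            front, back = back, front
        pads.append((front, back))
    return pads


def pad_to_pow2(
    density_map: DensityMap,
    seed: int,
    label: np.ndarray | None = None,
    background: int = BACKGROUND,
):
    """Zero-pad a volume to the smallest enclosing power-of-two cube.

    Padding is split evenly between the front and back of each axis;
    when the total is odd, a seeded coin flip decides which side gets
    the extra voxel.  If a per-voxel ``label`` volume is supplied it is
    padded in lockstep (with ``background`` fill) and returned alongside
    the map, preserving voxel-wise correspondence.
    """
    pads = _pow2_padding(density_map.shape, seed)
    data = np.pad(density_map.data, pads)
    origin = density_map.origin - np.array([p[0] for p in pads]) * density_map.voxel_size
    out = DensityMap(data, density_map.voxel_size.copy(), origin)
    if label is None:
        return out
    if label.shape != density_map.shape:
        raise ValueError("label volume must match map dimensions")
    padded_label = np.pad(label, pads, constant_values=background)
    return out, padded_label


@dataclass
class PatchBatch:
    """A stack of cube patches cut from one volume, with parallel labels.

    ``inputs``/``labels`` have shape ``(N, c, c, c)``; ``offsets`` holds
    each cube's corner index in the source volume so predictions can be
    reassembled.
    """

    inputs: np.ndarray
    labels: np.ndarray
    offsets: np.ndarray
    source_shape: tuple[int, int, int]
    cube: int = 16

    def __post_init__(self) -> None:
        if self.inputs.shape != self.labels.shape:
            raise ValueError("inputs and labels must have identical shapes")
        if len(self.offsets) != len(self.inputs):
            raise ValueError("one offset per cube required")

    def __len__(self) -> int:
        return len(self.inputs)


def partition_patches(
    density_map: DensityMap,
    labels: np.ndarray,
    cube: int = 16,
    zero_tol: float = 0.0,
) -> PatchBatch:
    """Tile a volume into non-overlapping cubes, dropping empty ones.

    A cube is empty when every input voxel is (within ``zero_tol`` of)
    zero; its label cube is removed in lockstep.  Dimensions must be
    divisible by ``cube`` — run :func:`pad_to_pow2` first.
    """
    data = density_map.data
    if labels.shape != data.shape:
        raise ValueError("label volume must match map dimensions")
    if any(dim % cube for dim in data.shape):
        raise ValueError(f"dimensions {data.shape} not divisible by cube size {cube}")
    inputs, labs, offsets = [], [], []
    for ix in range(0, data.shape[0], cube):
        for iy in range(0, data.shape[1], cube):
            for iz in range(0, data.shape[2], cube):
                block = data[ix : ix + cube, iy : iy + cube, iz : iz + cube]
                if np.all(np.abs(block) <= zero_tol):
                    continue
                inputs.append(block)
                labs.append(labels[ix : ix + cube, iy : iy + cube, iz : iz + cube])
                offsets.append((ix, iy, iz))
    n = len(inputs)
    shape = (n, cube, cube, cube)
    return PatchBatch(
        inputs=np.array(inputs, dtype=np.float32).reshape(shape),
        labels=np.array(labs).reshape(shape) if n else np.empty(shape, dtype=np.int64),
        offsets=np.array(offsets, dtype=np.int64).reshape(n, 3),
        source_shape=data.shape,
        cube=cube,
    )


def reassemble_patches(
    batch: PatchBatch,
    predictions: np.ndarray,
    background: int = BACKGROUND,
) -> np.ndarray:
    """Place per-cube predictions back onto the source grid.

    Positions of removed (empty) cubes are filled with ``background``.
    """
    predictions = np.asarray(predictions)
    if predictions.shape[:4] != (len(batch), batch.cube, batch.cube, batch.cube):
        raise ValueError(
            f"predictions shape {predictions.shape} incompatible with batch of "
            f"{len(batch)} cubes of edge {batch.cube}"
        )
    out = np.full(batch.source_shape, background, dtype=predictions.dtype)
    seen: set[tuple[int, int, int]] = set()
    c = batch.cube
    for cube_pred, (ix, iy, iz) in zip(predictions, batch.offsets):
        key = (int(ix), int(iy), int(iz))
        if key in seen:
            raise ValueError(f"offset collision at {key}")
        seen.add(key)
        out[ix : ix + c, iy : iy + c, iz : iz + c] = cube_pred
    return out


@dataclass
class SplitSpec:
    """Train/validation/test fractions plus the shuffling seed."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if r.shape != (3,) or np.any(r < 0) or np.any(r > 1):
            raise ValueError("ratios must be three fractions in [0, 1]")
        if abs(r.sum() - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {r.sum()}")


def split_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Subset sizes: validation/test get ``round(ratio * n)``, training the rest."""
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("rounding produced a negative training size")
    return n_train, n_val, n_test


def split_dataset(ids: list, spec: SplitSpec) -> tuple[list, list, list]:
    """Randomly split ids into disjoint train/validation/test lists.

    Deterministic given the seed; subsets are disjoint and cover the input.
    """
    ids = list(ids)
    if not ids:
        return [], [], []
    n_train, n_val, n_test = split_sizes(len(ids), spec.ratios)
    order = np.random.default_rng(spec.seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )
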