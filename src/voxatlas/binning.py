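"""Cubic binning with hemisphere mirroring, and region-mean quantification.

Expression patterns are summarized as mean intensity over 20 µm cubic bins
tiled entirely within the left hemisphere; each bin pools its mirror-image
box on the right hemisphere, and the per-line vector is rescaled to [0, 1]
by its maximum. Region means average 0–1-scaled expression over an integer
label volume of annotated anatomical structures. Because each line is scaled
by its own maximum, values compare bins *within* a line, never across lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .volume import Volume, VoxelGrid, _binary_check

Box = tuple[tuple[int, int, int], tuple[int, int, int]]  # half-open [lo, hi)


@dataclass
class BinSet:
    """Non-overlapping cubic bins inside the left hemisphere, with mirrors."""

    grid: VoxelGrid
    bin_edge_um: float
    boxes: list[Box]
    mirrored: list[Box]
    centers: list[tuple[int, int, int]]
    midline_x: int

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class BinTable:
    """One line's 0–1-scaled mean expression per bin."""

    line_id: str
    values: np.ndarray
    centers: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class RegionMeans:
    """Per-region mean of 0–1-scaled expression, keyed by region label."""

    line_id: str
    means: dict[int, float]


def _edge_voxels(grid: VoxelGrid, edge_um: float) -> tuple[int, int, int]:
    out = []
    for s in grid.spacing_um:
        e = edge_um / s
        if abs(e - round(e)) > 1e-6 or round(e) < 1:
            raise DataError(
                f"bin edge {edge_um} µm is not a positive multiple of the "
                f"voxel spacing {s} µm"
            )
        out.append(int(round(e)))
    return tuple(out)


def define_bins(
    brain_mask: Volume,
    bin_edge_um: float = 20.0,
    midline_x: int | None = None,
) -> BinSet:
    """Tile the left hemisphere with cubic bins fully inside the brain mask.

    Boxes start at the grid origin and step by one edge length; a candidate
    is kept iff every voxel of its box is inside the mask and the box lies
    entirely left of the midline plane. The mirrored box is the reflection
    across the midline plane (between voxel columns at ``midline_x``).
    """
    nx, ny, nz = brain_mask.grid.dims
    if midline_x is None:
        midline_x = nx // 2
    if not 0 < midline_x <= nx:
        raise DataError(f"midline_x {midline_x} outside grid (nx={nx})")
    ex, ey, ez = _edge_voxels(brain_mask.grid, bin_edge_um)
    mask = _binary_check(brain_mask)
    boxes: list[Box] = []
    mirrored: list[Box] = []
    centers: list[tuple[int, int, int]] = []
    for x in range(0, midline_x - ex + 1, ex):
        for y in range(0, ny - ey + 1, ey):
            for z in range(0, nz - ez + 1, ez):
                if mask[x:x + ex, y:y + ey, z:z + ez].all():
                    boxes.append(((x, y, z), (x + ex, y + ey, z + ez)))
                    mirrored.append(
                        (
                            (2 * midline_x - x - ex, y, z),
                            (2 * midline_x - x, y + ey, z + ez),
                        )
                    )
                    centers.append((x + ex // 2, y + ey // 2, z + ez // 2))
    return BinSet(
        grid=brain_mask.grid,
        bin_edge_um=bin_edge_um,
        boxes=boxes,
        mirrored=mirrored,
        centers=centers,
        midline_x=midline_x,
    )


def _box_values(data: np.ndarray, box: Box, dims: tuple[int, int, int]) -> np.ndarray:
    lo = tuple(max(0, l) for l in box[0])
    hi = tuple(min(d, h) for h, d in zip(box[1], dims))
    if any(l >= h for l, h in zip(lo, hi)):
        return np.empty(0)
    return data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].ravel()


def bin_expression(line_volume: Volume, bins: BinSet) -> BinTable:
    """Mean expression per bin (pooling the mirrored box), rescaled to [0, 1].

    Each bin's raw value is the mean intensity over its box together with the
    mirror-image box (clipped to the grid if the mirror falls partially
    outside). The vector is divided by its maximum; an all-zero vector stays
    zero.
    """
    if len(bins) == 0:
        raise DataError("bin_expression: empty BinSet")
    line_volume.grid.require_compatible(bins.grid, context="bin_expression")
    data = np.asarray(line_volume.data, dtype=np.float64)
    dims = bins.grid.dims
    raw = np.empty(len(bins))
    for i, (box, mbox) in enumerate(zip(bins.boxes, bins.mirrored)):
        vals = np.concatenate(
            [_box_values(data, box, dims), _box_values(data, mbox, dims)]
        )
        raw[i] = vals.mean()
    peak = raw.max()
    values = raw / peak if peak > 0 else raw
    return BinTable(line_id=line_volume.channel_label or "", values=values,
                    centers=list(bins.centers))


def region_means(
    line_volume: Volume, labels: Volume, scale_first: bool = True
) -> RegionMeans:
    """Mean 0–1-scaled expression per nonzero region label.

    With ``scale_first`` (default) intensities are divided by the volume
    maximum before averaging, so means reflect relative expression within the
    line. Labels with zero voxels are simply absent from the result (missing,
    not zero).
    """
    line_volume.grid.require_compatible(labels.grid, context="region_means")
    lab = np.asarray(labels.data)
    if not np.issubdtype(lab.dtype, np.integer):
        if not np.allclose(lab, np.round(lab)):
            raise DataError("label volume must be integer-valued")
        lab = np.round(lab).astype(np.int64)
    if (lab < 0).any():
        raise DataError("label volume must be non-negative (0 = background)")
    if not (lab > 0).any():
        raise DataError("region_means: no nonzero labels")
    data = np.asarray(line_volume.data, dtype=np.float64)
    if scale_first:
        peak = data.max()
        if peak > 0:
            data = data / peak
    flat_lab = lab.ravel()
    sums = np.bincount(flat_lab, weights=data.ravel())
    counts = np.bincount(flat_lab)
    means = {
        int(l): float(sums[l] / counts[l])
        for l in range(1, len(counts))
        if counts[l] > 0
    }
    return RegionMeans(line_id=line_volume.channel_label or "", means=means)


def write_bin_table(
    path: str | Path, bins: BinSet, tables: list[BinTable]
) -> Path:
    """Write bin centers plus one column per line.

    The first three columns follow the published supplementary layout:
    Horizontal (dorsal→ventral, the z index), Transverse (anterior→posterior,
    y) and Sagittal (left→right, x) of each bin's center voxel.
    """
    path = Path(path)
    cols = {
        "Horizontal": [c[2] for c in bins.centers],
        "Transverse": [c[1] for c in bins.centers],
        "Sagittal": [c[0] for c in bins.centers],
    }
    for t in tables:
        if len(t.values) != len(bins):
            raise DataError(
                f"bin table for {t.line_id!r} has {len(t.values)} values, "
                f"expected {len(bins)}"
            )
        cols[t.line_id] = t.values
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
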