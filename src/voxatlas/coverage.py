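"""Cell-body volume estimation and per-line / library coverage statistics.

Coverage of a line is the fraction of the brain's cell-body (soma-dominated)
voxels whose normalized expression meets that line's cellular threshold.
Library summaries report how much of the cellular volume any line of a driver
class reaches, and the per-voxel redundancy (lines per voxel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .registry import LineRecord
from .volume import Volume, _binary_check


@dataclass
class CoverageReport:
    line_id: str
    covered_voxels: int
    mask_voxels: int

    @property
    def coverage_fraction(self) -> float:
        return self.covered_voxels / self.mask_voxels


@dataclass
class LibrarySummary:
    driver: str | None
    fraction_covered_ge1: float
    mean_lines_per_voxel: float
    per_line: list[CoverageReport]
    excluded: list[str] = field(default_factory=list)
    median_coverage: float = 0.0
    coverage_range: tuple[float, float] = (0.0, 0.0)
    histogram_counts: np.ndarray | None = None
    histogram_edges: np.ndarray | None = None


def cellbody_mask(
    soma: Volume,
    neuropil: Volume,
    brain_mask: Volume,
    ratio_threshold: float = 0.5,
) -> Volume:
    """Estimate the cell-body volume from soma and neuropil marker channels.

    A brain voxel is cellular iff ``soma / (soma + neuropil) >=
    ratio_threshold``; voxels where both markers are zero are excluded. The
    default 0.5 keeps voxels where the soma marker dominates.
    """
    soma.grid.require_compatible(neuropil.grid, context="cellbody_mask")
    soma.grid.require_compatible(brain_mask.grid, context="cellbody_mask")
    if not 0 < ratio_threshold < 1:
        raise DataError(f"ratio_threshold must be in (0, 1), got {ratio_threshold}")
    brain = _binary_check(brain_mask)
    s = np.asarray(soma.data, dtype=np.float64)
    n = np.asarray(neuropil.data, dtype=np.float64)
    total = s + n
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, s / np.where(total > 0, total, 1.0), 0.0)
    out = (brain & (total > 0) & (ratio >= ratio_threshold)).astype(np.uint8)
    return Volume(soma.grid, out, value_kind="binary", channel_label="cellbody")


def line_coverage(line_volume: Volume, record: LineRecord, mask: Volume) -> CoverageReport:
    """Fraction of mask voxels with super-threshold (>=) signal for one line."""
    line_volume.grid.require_compatible(mask.grid, context="line_coverage")
    sel = _binary_check(mask)
    mask_voxels = int(sel.sum())
    if mask_voxels == 0:
        raise DataError("line_coverage: mask is empty")
    covered = int((np.asarray(line_volume.data)[sel] >= record.cell_threshold).sum())
    return CoverageReport(record.line_id, covered, mask_voxels)


def line_count_map(
    lines: list[tuple[Volume, LineRecord]], mask: Volume
) -> Volume:
    """Per-voxel count of lines that are super-threshold there.

    Lines flagged ``exclude_from_coverage`` are dropped first; counts are
    zero outside the mask.
    """
    kept = [(v, r) for v, r in lines if not r.exclude_from_coverage]
    if not kept:
        raise DataError("line_count_map: no lines remain after exclusion")
    sel = _binary_check(mask)
    counts = np.zeros(mask.grid.dims, dtype=np.int32)
    for vol, rec in kept:
        vol.grid.require_compatible(mask.grid, context=f"line {rec.line_id}")
        counts += (np.asarray(vol.data) >= rec.cell_threshold).astype(np.int32)
    counts[~sel] = 0
    return Volume(mask.grid, counts, value_kind="label", channel_label="line_count")


def library_summary(
    count_map: Volume,
    mask: Volume,
    reports: list[CoverageReport],
    driver: str | None = None,
    excluded: list[str] | None = None,
    n_hist_bins: int = 50,
) -> LibrarySummary:
    """Union coverage, mean redundancy and per-line coverage distribution."""
    count_map.grid.require_compatible(mask.grid, context="library_summary")
    sel = _binary_check(mask)
    n_mask = int(sel.sum())
    if n_mask == 0:
        raise DataError("library_summary: mask is empty")
    counts = np.asarray(count_map.data)[sel]
    fractions = np.array([r.coverage_fraction for r in reports])
    if fractions.size:
        median = float(np.median(fractions))
        rng = (float(fractions.min()), float(fractions.max()))
        hist_hi = max(float(fractions.max()), np.finfo(float).tiny)
        hist_counts, hist_edges = np.histogram(fractions, bins=n_hist_bins,
                                               range=(0.0, hist_hi))
    else:
        median, rng = 0.0, (0.0, 0.0)
        hist_counts = hist_edges = None
    return LibrarySummary(
        driver=driver,
        fraction_covered_ge1=float((counts >= 1).mean()),
        mean_lines_per_voxel=float(counts.mean()),
        per_line=list(reports),
        excluded=list(excluded or []),
        median_coverage=median,
        coverage_range=rng,
        histogram_counts=hist_counts,
        histogram_edges=hist_edges,
    )


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures (half away handled by round)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig_figs - 1))


def neurons_per_line(
    coverage_fraction: float, total_neurons: int = 92000, sig_figs: int = 2
) -> int:
    """Convert a coverage fraction into an approximate neuron count.

    Multiplies the fraction by the brain-wide mature-neuron total (default
    92,000 at 6 dpf) and rounds to ``sig_figs`` significant figures: a median
    coverage of 6% equates to about 5,500 neurons per line.
    """
    if not 0 <= coverage_fraction <= 1:
        raise DataError(f"coverage_fraction {coverage_fraction} outside [0, 1]")
    if total_neurons < 0:
        raise DataError("total_neurons must be >= 0")
    return int(round_sig(coverage_fraction * total_neurons, sig_figs))
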