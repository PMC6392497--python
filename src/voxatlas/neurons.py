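"""Stratified brain-wide neuron-count estimation.

Brain voxels are stratified into neuronal-density bins by the soma:synapse
marker ratio; small cubic sampling volumes are drawn per bin, neurons are
counted in each (counts are *inputs* — manual or external — this module does
no spot detection), and the per-bin mean densities are scaled by the brain
fraction each bin covers to give a total with a propagated standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .volume import Volume, VoxelGrid, _binary_check

Box = tuple[tuple[int, int, int], tuple[int, int, int]]


@dataclass
class DensityBinning:
    """Assignment of every brain voxel to one of ``n_bins`` density strata.

    ``bin_label`` is 0 outside the brain and 1..n_bins inside;
    ``bin_fractions[b-1]`` is the share of brain voxels in bin b (sums to 1).
    """

    grid: VoxelGrid
    bin_label: np.ndarray
    n_bins: int
    bin_fractions: np.ndarray
    edges: np.ndarray

    @property
    def brain_voxels(self) -> int:
        return int((self.bin_label > 0).sum())

    @property
    def brain_volume_um3(self) -> float:
        return self.brain_voxels * self.grid.voxel_volume_um3

    def bin_volume_um3(self, b: int) -> float:
        return int((self.bin_label == b).sum()) * self.grid.voxel_volume_um3


@dataclass
class SamplePlan:
    """Cubic sampling boxes per density bin, plus observed neuron counts."""

    boxes: dict[int, list[Box]]
    edge_um: float
    box_volume_um3: float
    counts: dict[int, np.ndarray] = field(default_factory=dict)

    def with_counts(self, counts: dict[int, np.ndarray]) -> "SamplePlan":
        return SamplePlan(self.boxes, self.edge_um, self.box_volume_um3,
                          {b: np.asarray(c) for b, c in counts.items()})


@dataclass
class TotalEstimate:
    total: float
    se: float
    per_bin_density: dict[int, float]  # neurons per µm³


def density_bins(
    soma: Volume,
    synapse: Volume,
    brain_mask: Volume,
    n_bins: int = 5,
) -> DensityBinning:
    """Stratify brain voxels into equal-population bins of the soma ratio.

    The ratio ``r = soma / (soma + synapse)`` (0 where both markers are zero)
    is cut at its ``k/n_bins`` quantiles (linear interpolation); voxels are
    assigned by counting the edges strictly below their value, so a constant
    field lands entirely in the first bin.
    """
    soma.grid.require_compatible(synapse.grid, context="density_bins")
    soma.grid.require_compatible(brain_mask.grid, context="density_bins")
    if n_bins < 2:
        raise DataError(f"n_bins must be >= 2, got {n_bins}")
    brain = _binary_check(brain_mask)
    if not brain.any():
        raise DataError("density_bins: brain mask is empty")
    s = np.asarray(soma.data, dtype=np.float64)
    p = np.asarray(synapse.data, dtype=np.float64)
    total = s + p
    ratio = np.where(total > 0, s / np.where(total > 0, total, 1.0), 0.0)
    vals = ratio[brain]
    edges = np.quantile(vals, np.arange(1, n_bins) / n_bins)
    assigned = np.searchsorted(edges, vals, side="left") + 1  # 1..n_bins
    label = np.zeros(soma.grid.dims, dtype=np.int32)
    label[brain] = assigned
    fractions = np.bincount(assigned, minlength=n_bins + 1)[1:] / vals.size
    return DensityBinning(soma.grid, label, n_bins, fractions, edges)


def _box_label_counts(bin_label: np.ndarray, n_bins: int,
                      edges: tuple[int, int, int]) -> np.ndarray:
    """Per-anchor label counts over the sliding box, via 3D integral images.

    Returns an array of shape (n_bins + 1, ax, ay, az) where entry
    ``[l, x, y, z]`` is the number of voxels with label l in the box anchored
    at (x, y, z).
    """
    ex, ey, ez = edges
    nx, ny, nz = bin_label.shape
    out = np.empty((n_bins + 1, nx - ex + 1, ny - ey + 1, nz - ez + 1),
                   dtype=np.int64)
    for l in range(n_bins + 1):
        ind = (bin_label == l).astype(np.int64)
        sat = ind.cumsum(0).cumsum(1).cumsum(2)
        sat = np.pad(sat, ((1, 0), (1, 0), (1, 0)))
        out[l] = (
            sat[ex:, ey:, ez:]
            - sat[:-ex, ey:, ez:] - sat[ex:, :-ey, ez:] - sat[ex:, ey:, :-ez]
            + sat[:-ex, :-ey, ez:] + sat[:-ex, ey:, :-ez] + sat[ex:, :-ey, :-ez]
            - sat[:-ex, :-ey, :-ez]
        )
    return out


def plan_samples(
    binning: DensityBinning,
    boxes_per_bin: int = 5,
    edge_um: float = 30.0,
    seed: int = 0,
) -> SamplePlan:
    """Draw non-overlapping cubic sampling boxes per bin, reproducibly.

    For each bin the valid anchors — positions where the box's majority
    (plurality) voxel label equals the target bin — are enumerated, then
    visited in a seeded uniform-random order, keeping the first
    ``boxes_per_bin`` that do not overlap an already accepted box. Bins with
    the fewest valid anchors are placed first so that abundant strata do not
    crowd out scarce ones; if a draw still wedges, the whole placement is
    retried with a derived seed. Deterministic given ``seed``.
    """
    if boxes_per_bin < 1:
        raise DataError("boxes_per_bin must be >= 1")
    edges = []
    for s in binning.grid.spacing_um:
        e = edge_um / s
        if abs(e - round(e)) > 1e-6 or round(e) < 1:
            raise DataError(
                f"sample edge {edge_um} µm not commensurate with spacing {s} µm"
            )
        edges.append(int(round(e)))
    ex, ey, ez = edges
    nx, ny, nz = binning.grid.dims
    if ex > nx or ey > ny or ez > nz:
        raise DataError("sample box larger than the grid")
    counts = _box_label_counts(binning.bin_label, binning.n_bins, (ex, ey, ez))
    majority = counts.argmax(axis=0)  # ties go to the lower label
    anchors = {b: np.argwhere(majority == b)
               for b in range(1, binning.n_bins + 1)}
    order = sorted(anchors, key=lambda b: len(anchors[b]))  # scarcest first
    failed: list[int] = []
    for attempt in range(20):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        chosen: list[Box] = []
        plan: dict[int, list[Box]] = {}
        failed = []
        for b in order:
            got: list[Box] = []
            for i in rng.permutation(len(anchors[b])):
                if len(got) == boxes_per_bin:
                    break
                x, y, z = (int(v) for v in anchors[b][i])
                box: Box = ((x, y, z), (x + ex, y + ey, z + ez))
                if any(_overlap(box, other) for other in chosen):
                    continue
                got.append(box)
                chosen.append(box)
            if len(got) < boxes_per_bin:
                failed.append(b)
            plan[b] = got
        if not failed:
            break
    if failed:
        raise DataError(
            f"could not place {boxes_per_bin} sample box(es) in bin(s) "
            f"{sorted(failed)}; the bin region is too small or fragmented"
        )
    box_vol = ex * ey * ez * binning.grid.voxel_volume_um3
    return SamplePlan(boxes={b: plan[b] for b in sorted(plan)},
                      edge_um=edge_um, box_volume_um3=box_vol)


def _overlap(a: Box, b: Box) -> bool:
    return all(a[0][i] < b[1][i] and b[0][i] < a[1][i] for i in range(3))


def estimate_total(
    plan: SamplePlan,
    binning: DensityBinning,
    brain_volume_um3: float | None = None,
) -> TotalEstimate:
    """Scale per-bin mean densities by bin brain-fractions to a total count.

    total = V · Σ_b f_b · d_b with d_b = mean(counts_b) / box volume and f_b
    the voxel share of bin b. The standard error treats bins as independent:
    se² = V² · Σ_b f_b² · sem_b² / box_volume², where sem_b is the standard
    error of the mean box count in bin b.
    """
    if brain_volume_um3 is None:
        brain_volume_um3 = binning.brain_volume_um3
    densities: dict[int, float] = {}
    var = 0.0
    total = 0.0
    for b in range(1, binning.n_bins + 1):
        if b not in plan.counts:
            raise DataError(f"no observed counts for bin {b}")
        counts = np.asarray(plan.counts[b], dtype=np.float64)
        if counts.size != len(plan.boxes.get(b, [])):
            raise DataError(
                f"bin {b}: {counts.size} counts for {len(plan.boxes.get(b, []))} boxes"
            )
        if (counts < 0).any():
            raise DataError(f"bin {b}: negative counts")
        d = counts.mean() / plan.box_volume_um3
        densities[b] = d
        f = binning.bin_fractions[b - 1]
        total += brain_volume_um3 * f * d
        if counts.size > 1:
            sem = counts.std(ddof=1) / np.sqrt(counts.size)
        else:
            sem = 0.0
        var += (brain_volume_um3 * f * sem / plan.box_volume_um3) ** 2
    return TotalEstimate(total=float(total), se=float(np.sqrt(var)),
                         per_bin_density=densities)


# ---------------------------------------------------------------------------
# Plan / counts TSV round-trip (bin, box corners, count)


def write_plan(plan: SamplePlan, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for b, boxes in sorted(plan.boxes.items()):
        counts = plan.counts.get(b)
        for i, (lo, hi) in enumerate(boxes):
            rows.append({
                "bin": b,
                "x0": lo[0], "y0": lo[1], "z0": lo[2],
                "x1": hi[0], "y1": hi[1], "z1": hi[2],
                "count": "" if counts is None else int(counts[i]),
            })
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_plan(path: str | Path, edge_um: float, voxel_volume_um3: float) -> SamplePlan:
    path = Path(path)
    if not path.exists():
        raise DataError(f"sample plan not found: {path}")
    df = pd.read_csv(path, sep="\t")
    boxes: dict[int, list[Box]] = {}
    counts: dict[int, list[int]] = {}
    have_counts = "count" in df.columns and df["count"].notna().all()
    for _, row in df.iterrows():
        b = int(row["bin"])
        lo = (int(row["x0"]), int(row["y0"]), int(row["z0"]))
        hi = (int(row["x1"]), int(row["y1"]), int(row["z1"]))
        boxes.setdefault(b, []).append((lo, hi))
        if have_counts:
            counts.setdefault(b, []).append(int(row["count"]))
    any_box = next(iter(boxes.values()))[0]
    n_vox = 1
    for l, h in zip(any_box[0], any_box[1]):
        n_vox *= h - l
    plan = SamplePlan(boxes=boxes, edge_um=edge_um,
                      box_volume_um3=n_vox * voxel_volume_um3)
    if have_counts:
        plan = plan.with_counts({b: np.asarray(c) for b, c in counts.items()})
    return plan
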