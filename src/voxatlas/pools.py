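"""Combinatorial pool design and integration-site deconvolution.

Enhancer-trap lines are sequenced in pools arranged so that every line
occupies a unique *pair* of pools. A genomic site that is strongly enriched
in exactly one line's pair — and at background level in every other pool —
deconvolves to that line. Sites present in all pools are treated as
off-target capture and removed first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

Site = tuple[str, int]  # (chromosome, 0-based position)


@dataclass
class PoolDesign:
    """Assignment of each line to an unordered pair of pool indices."""

    n_pools: int
    assignment: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        pairs = list(self.assignment.values())
        for lid, pair in self.assignment.items():
            if len(pair) != 2 or not all(0 <= p < self.n_pools for p in pair):
                raise DataError(f"line {lid}: invalid pool pair {set(pair)}")
        if len(set(pairs)) != len(pairs):
            raise DataError("pool pairs are not distinct across lines")

    @property
    def pool_sizes(self) -> np.ndarray:
        sizes = np.zeros(self.n_pools, dtype=int)
        for pair in self.assignment.values():
            for p in pair:
                sizes[p] += 1
        return sizes

    def to_json_dict(self) -> dict:
        return {
            "n_pools": self.n_pools,
            "assignment": {lid: sorted(pair) for lid, pair in self.assignment.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PoolDesign":
        return cls(
            n_pools=int(d["n_pools"]),
            assignment={lid: frozenset(p) for lid, p in d["assignment"].items()},
        )


@dataclass
class SiteTable:
    """Genomic sites × pools read-count matrix."""

    sites: list[Site]
    counts: np.ndarray  # shape (n_sites, n_pools), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.sites):
            raise DataError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sites)} sites"
            )
        if (self.counts < 0).any():
            raise DataError("site counts must be non-negative")
        if any(pos < 0 for _, pos in self.sites):
            raise DataError("site positions must be non-negative")

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]


@dataclass
class SiteAssignment:
    """Deconvolution result: candidate sites per line, plus rejects."""

    assigned: dict[str, list[Site]]
    unassigned: list[tuple[Site, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Design


def design_pools(line_ids: list[str], n_pools: int, seed: int = 0) -> PoolDesign:
    """Assign each line a distinct pool pair, balancing pool sizes.

    Greedy: each line takes the unused pair with the least-loaded pools
    (smallest load sum, then smallest max load), ties broken by a seeded
    shuffle — deterministic given ``seed``.
    """
    capacity = n_pools * (n_pools - 1) // 2
    if len(line_ids) > capacity:
        raise DataError(
            f"{len(line_ids)} lines exceed capacity C({n_pools},2) = {capacity}"
        )
    if len(set(line_ids)) != len(line_ids):
        raise DataError("duplicate line ids")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(n_pools), 2))
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]  # seeded tie-break order
    loads = np.zeros(n_pools, dtype=int)
    used: set[frozenset[int]] = set()
    assignment: dict[str, frozenset[int]] = {}
    for lid in line_ids:
        best = None
        best_key = None
        for a, b in pairs:
            pair = frozenset((a, b))
            if pair in used:
                continue
            key = (loads[a] + loads[b], max(loads[a], loads[b]))
            if best_key is None or key < best_key:
                best, best_key = pair, key
        assert best is not None  # guaranteed by capacity check
        used.add(best)
        assignment[lid] = best
        for p in best:
            loads[p] += 1
    return PoolDesign(n_pools=n_pools, assignment=assignment)


# ---------------------------------------------------------------------------
# Filtering and assignment


def filter_offtarget(
    table: SiteTable, presence_min: int = 1
) -> tuple[SiteTable, list[Site]]:
    """Drop sites present (count >= ``presence_min``) in ALL pools.

    Sequences recovered from every pool cannot be line-specific and are
    assumed to be off-target capture. Returns the filtered table and the
    removed sites. Idempotent.
    """
    if presence_min < 1:
        raise DataError("presence_min must be >= 1")
    if not table.sites:
        raise DataError("filter_offtarget: empty site table")
    present = table.counts >= presence_min
    everywhere = present.all(axis=1)
    keep = ~everywhere
    removed = [s for s, r in zip(table.sites, everywhere) if r]
    filtered = SiteTable(
        sites=[s for s, k in zip(table.sites, keep) if k],
        counts=table.counts[keep],
    )
    return filtered, removed


def merge_nearby_sites(table: SiteTable, window_bp: int = 100) -> SiteTable:
    """Merge sites on the same chromosome within ``window_bp`` of each other.

    Alignment scatter spreads one integration over neighbouring coordinates;
    chains of sites with consecutive gaps <= window are summed and reported
    at the first (smallest) position.
    """
    if window_bp < 0:
        raise DataError("window_bp must be >= 0")
    order = sorted(range(len(table.sites)), key=lambda i: table.sites[i])
    merged_sites: list[Site] = []
    merged_counts: list[np.ndarray] = []
    last_chrom: str | None = None
    last_pos = 0
    for i in order:
        chrom, pos = table.sites[i]
        if merged_sites and chrom == last_chrom and pos - last_pos <= window_bp:
            merged_counts[-1] = merged_counts[-1] + table.counts[i]
        else:
            merged_sites.append((chrom, pos))
            merged_counts.append(table.counts[i].copy())
        last_chrom, last_pos = chrom, pos
    return SiteTable(sites=merged_sites, counts=np.array(merged_counts))


def assign_sites(
    table: SiteTable,
    design: PoolDesign,
    min_reads: int = 10,
    max_bg_reads: int = 2,
    merge_window_bp: int = 100,
) -> SiteAssignment:
    """Assign each site to the line whose pool pair it is enriched in.

    A site belongs to line L iff its count is >= ``min_reads`` in BOTH pools
    of L's pair and <= ``max_bg_reads`` in every other pool ("high and
    specific"). Sites whose above-background pools match no pair are rejected
    as ``no_matching_signature``; sites compatible with some pair's
    background profile but failing the enrichment bar in it are
    ``below_enrichment``. The table should already be off-target filtered;
    nearby sites are merged first (``merge_window_bp``; 0 disables).
    """
    if not min_reads > max_bg_reads >= 0:
        raise DataError(
            f"need min_reads > max_bg_reads >= 0, got ({min_reads}, {max_bg_reads})"
        )
    if table.n_pools != design.n_pools:
        raise DataError(
            f"table has {table.n_pools} pools but design has {design.n_pools}"
        )
    if merge_window_bp > 0:
        table = merge_nearby_sites(table, merge_window_bp)
    assigned: dict[str, list[Site]] = {lid: [] for lid in design.assignment}
    unassigned: list[tuple[Site, str]] = []
    all_pools = np.arange(design.n_pools)
    for site, row in zip(table.sites, table.counts):
        hit = None
        partial = False
        for lid, pair in design.assignment.items():
            idx = sorted(pair)
            others = np.setdiff1d(all_pools, idx)
            if (row[others] <= max_bg_reads).all():
                if (row[idx] >= min_reads).all():
                    hit = lid
                    break
                partial = True
        if hit is not None:
            assigned[hit].append(site)
        elif partial:
            unassigned.append((site, "below_enrichment"))
        else:
            unassigned.append((site, "no_matching_signature"))
    return SiteAssignment(assigned=assigned, unassigned=unassigned)


# ---------------------------------------------------------------------------
# Simulation harness


def simulate_pool_experiment(
    design: PoolDesign,
    planted: dict[str, Site],
    signal_reads: int = 50,
    noise_rate: float = 0.1,
    n_offtarget: int = 0,
    seed: int = 0,
) -> tuple[SiteTable, dict[str, Site]]:
    """Generate a pooled-sequencing count table with known ground truth.

    Each planted site receives ~Poisson(``signal_reads``) reads in its line's
    two pools; every cell additionally gets Poisson(``noise_rate``)
    background; ``n_offtarget`` extra sites are present in all pools.
    Deterministic given ``seed``.
    """
    if signal_reads < 0 or noise_rate < 0 or n_offtarget < 0:
        raise DataError("simulation parameters must be non-negative")
    unknown = [lid for lid in planted if lid not in design.assignment]
    if unknown:
        raise DataError(f"planted lines not in design: {unknown}")
    rng = np.random.default_rng(seed)
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    for lid, site in planted.items():
        row = np.zeros(design.n_pools, dtype=np.int64)
        for p in design.assignment[lid]:
            row[p] = rng.poisson(signal_reads)
        sites.append(site)
        rows.append(row)
    for k in range(n_offtarget):
        # off-target capture shows up everywhere; clip to >= 1 so it is
        # "present in all pools" by construction
        row = np.maximum(1, rng.poisson(signal_reads, size=design.n_pools))
        sites.append(("chrOT", 1_000_000 + 1000 * k))
        rows.append(row.astype(np.int64))
    counts = np.array(rows) if rows else np.zeros((0, design.n_pools), dtype=np.int64)
    if noise_rate > 0 and counts.size:
        counts = counts + rng.poisson(noise_rate, size=counts.shape)
    return SiteTable(sites=sites, counts=counts), dict(planted)


# ---------------------------------------------------------------------------
# I/O


def write_site_table(table: SiteTable, path: str | Path) -> Path:
    path = Path(path)
    cols = {"chrom": [s[0] for s in table.sites],
            "pos": [s[1] for s in table.sites]}
    for p in range(table.n_pools):
        cols[f"pool_{p}"] = table.counts[:, p]
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    return path


def read_site_table(path: str | Path) -> SiteTable:
    path = Path(path)
    if not path.exists():
        raise DataError(f"site table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    pool_cols = sorted(
        (c for c in df.columns if c.startswith("pool_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not pool_cols or "chrom" not in df.columns or "pos" not in df.columns:
        raise DataError(f"{path}: expected columns chrom, pos, pool_0..")
    sites = [(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])]
    return SiteTable(sites=sites, counts=df[pool_cols].to_numpy())


def write_assignments(
    assignment: SiteAssignment, path: str | Path, bed_path: str | Path | None = None
) -> Path:
    """Write assignments as TSV; optionally also BED (0-based half-open)."""
    path = Path(path)
    rows = []
    for lid, sites in assignment.assigned.items():
        for chrom, pos in sites:
            rows.append({"line_id": lid, "chrom": chrom, "pos": pos,
                         "status": "assigned"})
    for (chrom, pos), reason in assignment.unassigned:
        rows.append({"line_id": "", "chrom": chrom, "pos": pos, "status": reason})
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["line_id", "chrom", "pos", "status"]).to_csv(
        path, sep="\t", index=False
    )
    if bed_path is not None:
        bed_path = Path(bed_path)
        with bed_path.open("w") as fh:
            for lid, sites in assignment.assigned.items():
                for chrom, pos in sites:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{lid}\n")
    return path
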