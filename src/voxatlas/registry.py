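"""Line metadata: per-line records, the atlas registry, and the line census.

The registry's line order is stable and defines the slot order of the packed
spatial-search index, so it is preserved through TSV round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataError
from .volume import VoxelGrid, Volume

DRIVERS = ("Gal4", "Cre", "FP")
CONSTRUCTIONS = ("enhancer_trap", "promoter_transgenic", "BAC")

REGISTRY_COLUMNS = [
    "line_id",
    "driver",
    "construction",
    "cell_threshold",
    "n_averaged",
    "exclude_from_coverage",
    "mapped_chrom",
    "mapped_pos",
    "zfin_id",
]


@dataclass
class LineRecord:
    """Metadata for one transgenic line.

    ``cell_threshold`` is the manually chosen intensity (on the normalized
    0–255 scale) that best separates cellular expression from neuropil and
    background for this line. ``exclude_from_coverage`` flags lines with
    extremely broad (near pan-neuronal) expression that would dominate
    library-wide coverage statistics.
    """

    line_id: str
    driver: str
    construction: str = "enhancer_trap"
    cell_threshold: float = 1.0
    n_averaged: int = 3
    exclude_from_coverage: bool = False
    mapped_chrom: str | None = None
    mapped_pos: int | None = None
    zfin_id: str | None = None

    def __post_init__(self) -> None:
        if self.driver not in DRIVERS:
            raise DataError(f"line {self.line_id}: unknown driver {self.driver!r}")
        if self.construction not in CONSTRUCTIONS:
            raise DataError(
                f"line {self.line_id}: unknown construction {self.construction!r}"
            )
        if not 0 <= self.cell_threshold <= 255:
            raise DataError(
                f"line {self.line_id}: cell_threshold {self.cell_threshold} "
                "outside the normalized range [0, 255]"
            )
        if self.n_averaged < 1:
            raise DataError(f"line {self.line_id}: n_averaged must be >= 1")
        if self.n_averaged < 3:
            warnings.warn(
                f"line {self.line_id}: averaged from only {self.n_averaged} "
                "scan(s); the atlas policy is >= 3",
                stacklevel=2,
            )

    @property
    def mapped(self) -> bool:
        return self.mapped_chrom is not None and self.mapped_pos is not None


@dataclass
class AtlasRegistry:
    """Ordered collection of lines sharing one atlas grid.

    The order of ``lines`` defines index line order everywhere downstream.
    """

    grid: VoxelGrid
    lines: list[LineRecord]
    brain_mask: Volume | None = None
    volume_paths: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.line_id for r in self.lines]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate line_ids in registry: {dupes}")
        if self.brain_mask is not None:
            self.grid.require_compatible(self.brain_mask.grid, context="brain_mask")

    @property
    def line_order(self) -> list[str]:
        return [r.line_id for r in self.lines]

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)

    def get(self, line_id: str) -> LineRecord:
        for r in self.lines:
            if r.line_id == line_id:
                return r
        raise DataError(f"line {line_id!r} not in registry")

    def select(self, driver: str | None = None) -> list[LineRecord]:
        return [r for r in self.lines if driver is None or r.driver == driver]


def read_registry(
    path: str | Path,
    grid: VoxelGrid,
    brain_mask: Volume | None = None,
    volume_dir: str | Path | None = None,
) -> AtlasRegistry:
    """Load a registry TSV (columns per :data:`REGISTRY_COLUMNS`)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"registry file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"line_id": str})
    missing = [c for c in REGISTRY_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: registry missing columns {missing}")
    lines = []
    for _, row in df.iterrows():
        chrom = row.get("mapped_chrom")
        pos = row.get("mapped_pos")
        zfin = row.get("zfin_id")
        lines.append(
            LineRecord(
                line_id=str(row["line_id"]),
                driver=str(row["driver"]),
                construction=str(row["construction"]),
                cell_threshold=float(row["cell_threshold"]),
                n_averaged=int(row["n_averaged"]),
                exclude_from_coverage=bool(row["exclude_from_coverage"]),
                mapped_chrom=None if pd.isna(chrom) else str(chrom),
                mapped_pos=None if pd.isna(pos) else int(pos),
                zfin_id=None if pd.isna(zfin) else str(zfin),
            )
        )
    volume_paths = {}
    if volume_dir is not None:
        volume_dir = Path(volume_dir)
        for rec in lines:
            p = volume_dir / f"{rec.line_id}.nii.gz"
            if p.exists():
                volume_paths[rec.line_id] = p
    return AtlasRegistry(grid, lines, brain_mask=brain_mask, volume_paths=volume_paths)


def write_registry(registry: AtlasRegistry, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in registry.lines:
        rows.append(
            {
                "line_id": r.line_id,
                "driver": r.driver,
                "construction": r.construction,
                "cell_threshold": r.cell_threshold,
                "n_averaged": r.n_averaged,
                "exclude_from_coverage": r.exclude_from_coverage,
                "mapped_chrom": r.mapped_chrom,
                "mapped_pos": r.mapped_pos,
                "zfin_id": r.zfin_id,
            }
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Published line census (printed per-category counts of the 264-line atlas)


def load_line_census() -> pd.DataFrame:
    """Per-category line counts of the published atlas collection.

    Columns: ``category`` (enhancer_trap / transgenic), ``driver``
    (Gal4 / Cre / FP), ``n_lines`` and ``n_mapped`` (lines with a known locus,
    inherent for promoter/BAC transgenics, from integration-site mapping for
    enhancer traps).
    """
    with resources.files("voxatlas.data").joinpath("line_census.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def census_totals(census: pd.DataFrame | None = None) -> dict:
    """Aggregate census counts: grand totals and per-driver totals."""
    df = load_line_census() if census is None else census
    per_driver = df.groupby("driver")[["n_lines", "n_mapped"]].sum()
    return {
        "total_lines": int(df["n_lines"].sum()),
        "mapped_lines": int(df["n_mapped"].sum()),
        "lines_by_driver": {d: int(n) for d, n in per_driver["n_lines"].items()},
        "mapped_by_driver": {d: int(n) for d, n in per_driver["n_mapped"].items()},
    }
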