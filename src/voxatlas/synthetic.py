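"""Phantom brains, line volumes, registries and ground-truth counts.

Every generator is a pure function of its spec and seed, so fixtures are
reproducible and carry exact ground truth. The phantom emulates the marker
geometry the pipeline assumes — an ellipsoidal brain with a soma-dominated
shell and neuropil-dominated core, optionally exactly left-right symmetric —
not the appearance of real confocal data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DataError
from .neurons import DensityBinning, SamplePlan
from .registry import AtlasRegistry, LineRecord
from .volume import Volume, VoxelGrid


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions for one synthetic brain.

    Defaults (128×64×64 voxels at 2 µm isotropic) keep whole-pipeline tests
    at seconds scale while leaving 20 µm bins, 30 µm sample boxes and 8×8×8
    index blocks non-degenerate.
    """

    dims: tuple[int, int, int] = (128, 64, 64)
    spacing_um: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0
    n_lines: int = 6
    clusters_per_line: int = 3
    cluster_radius_um: float = 12.0
    symmetric: bool = True

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.dims, self.spacing_um)


def make_phantom_brain(spec: PhantomSpec) -> tuple[Volume, Volume, Volume]:
    """Ellipsoidal brain mask plus complementary soma / neuropil channels.

    The soma marker peaks in an outer shell and the neuropil marker in the
    core (their normalized radial profiles are complementary), with smooth
    seeded perturbations so ratio-based masks and density strata have
    non-trivial shapes. Both channels are strictly positive inside the mask.
    With ``symmetric`` the three volumes equal their own x-mirror exactly.
    """
    nx, ny, nz = spec.dims
    if min(spec.dims) < 8:
        raise DataError(f"phantom dims {spec.dims} too small")
    grid = spec.grid
    centre = [(n - 1) / 2.0 for n in spec.dims]
    semi = [0.45 * n for n in spec.dims]
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    rho2 = (
        ((x - centre[0]) / semi[0]) ** 2
        + ((y - centre[1]) / semi[1]) ** 2
        + ((z - centre[2]) / semi[2]) ** 2
    )
    mask = rho2 <= 1.0
    rho = np.sqrt(np.clip(rho2, 0, 1))

    rng = np.random.default_rng(spec.seed)
    # regional texture: smooth random fields give blobby density strata (as
    # in real tissue) on top of the radial shell/core trend, so every
    # quantile stratum is thick enough to host cubic sampling volumes
    sigma = max(3.0, min(spec.dims) / 8)
    bump_s = gaussian_filter(rng.standard_normal(spec.dims), sigma=sigma)
    bump_n = gaussian_filter(rng.standard_normal(spec.dims), sigma=sigma)
    for b in (bump_s, bump_n):
        b /= max(np.abs(b).max(), 1e-12)
    if spec.symmetric:
        bump_s = 0.5 * (bump_s + bump_s[::-1])
        bump_n = 0.5 * (bump_n + bump_n[::-1])

    trend = 0.35 + 0.3 * rho  # soma-ward in the shell, neuropil-ward in the core
    soma_f = np.clip(trend + 0.45 * bump_s, 0.05, 1.0)
    neuropil_f = np.clip(1.0 - trend + 0.45 * bump_n, 0.05, 1.0)
    soma = np.where(mask, np.rint(255 * soma_f), 0).astype(np.uint8)
    neuropil = np.where(mask, np.rint(255 * neuropil_f), 0).astype(np.uint8)

    return (
        Volume(grid, mask.astype(np.uint8), value_kind="binary",
               channel_label="brain_mask"),
        Volume(grid, soma, value_kind="normalized8", channel_label="soma"),
        Volume(grid, neuropil, value_kind="normalized8", channel_label="neuropil"),
    )


def make_line_volume(
    mask: Volume,
    n_clusters: int,
    radius_um: float = 12.0,
    seed: int = 0,
    channel_label: str = "",
) -> tuple[Volume, np.ndarray]:
    """Gaussian expression blobs at uniform in-mask centers, clipped to mask.

    Returns the normalized8 volume and the planted cluster centers (voxel
    coordinates, one row each).
    """
    if n_clusters < 0:
        raise DataError("n_clusters must be >= 0")
    sel = np.asarray(mask.data).astype(bool)
    grid = mask.grid
    if n_clusters == 0:
        data = np.zeros(grid.dims, dtype=np.uint8)
        return (
            Volume(grid, data, value_kind="normalized8", channel_label=channel_label),
            np.empty((0, 3), dtype=int),
        )
    rng = np.random.default_rng(seed)
    coords = np.argwhere(sel)
    centers = coords[rng.integers(0, len(coords), size=n_clusters)]
    nx, ny, nz = grid.dims
    sx, sy, sz = grid.spacing_um
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    field = np.zeros(grid.dims, dtype=np.float64)
    for cx, cy, cz in centers:
        d2 = (
            ((x - cx) * sx) ** 2 + ((y - cy) * sy) ** 2 + ((z - cz) * sz) ** 2
        )
        field += np.exp(-d2 / (2.0 * radius_um**2))
    field[~sel] = 0.0
    peak = field.max()
    data = (
        np.rint(255 * field / peak).astype(np.uint8)
        if peak > 0
        else np.zeros(grid.dims, dtype=np.uint8)
    )
    return (
        Volume(grid, data, value_kind="normalized8", channel_label=channel_label),
        centers,
    )


def make_registry(
    k_cre: int,
    k_gal4: int,
    k_fp: int,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    cell_threshold: float = 40.0,
) -> tuple[AtlasRegistry, dict[str, Volume], dict[str, int]]:
    """A phantom line library mimicking a mixed-driver collection.

    Emits ``k_cre`` Cre, then ``k_gal4`` Gal4, then ``k_fp`` FP lines in
    stable id order. When any Cre line exists, the first is a broad
    near-pan-neuronal line flagged ``exclude_from_coverage`` (the analogue of
    an extremely broad Cre driver that would swamp library statistics).
    Returns the registry, the line volumes, and per-line ground-truth
    super-threshold voxel counts inside the brain mask.
    """
    if min(k_cre, k_gal4, k_fp) < 0:
        raise DataError("line counts must be >= 0")
    spec = spec or PhantomSpec(seed=seed)
    brain_mask, _, _ = make_phantom_brain(spec)
    sel = np.asarray(brain_mask.data).astype(bool)

    records: list[LineRecord] = []
    volumes: dict[str, Volume] = {}
    truth_covered: dict[str, int] = {}
    plan = [("Cre", k_cre), ("Gal4", k_gal4), ("FP", k_fp)]
    idx = 0
    for driver, k in plan:
        for j in range(k):
            line_id = f"y{100 + idx}"
            idx += 1
            broad = driver == "Cre" and j == 0
            if broad:
                data = np.where(sel, 200, 0).astype(np.uint8)
                vol = Volume(spec.grid, data, value_kind="normalized8",
                             channel_label=line_id)
            else:
                vol, _ = make_line_volume(
                    brain_mask,
                    spec.clusters_per_line,
                    spec.cluster_radius_um,
                    seed=spec.seed * 100_003 + idx,
                    channel_label=line_id,
                )
            records.append(
                LineRecord(
                    line_id=line_id,
                    driver=driver,
                    construction="enhancer_trap" if driver != "FP" else "promoter_transgenic",
                    cell_threshold=cell_threshold,
                    n_averaged=3,
                    exclude_from_coverage=broad,
                )
            )
            volumes[line_id] = vol
            truth_covered[line_id] = int(
                (np.asarray(vol.data)[sel] >= cell_threshold).sum()
            )
    registry = AtlasRegistry(spec.grid, records, brain_mask=brain_mask)
    return registry, volumes, truth_covered


def make_nuclei_counts(
    binning: DensityBinning,
    densities: dict[int, float],
    plan: SamplePlan,
    seed: int = 0,
) -> tuple[dict[int, np.ndarray], float]:
    """Poisson neuron counts per sample box from planted per-bin densities.

    Each box in bin b draws Poisson(density_b × box volume); the returned
    ``true_total`` is Σ_b density_b × (brain volume of bin b) — the quantity
    the stratified estimator targets.
    """
    for b, d in densities.items():
        if d < 0:
            raise DataError(f"bin {b}: negative density")
    rng = np.random.default_rng(seed)
    counts: dict[int, np.ndarray] = {}
    for b in range(1, binning.n_bins + 1):
        d = densities.get(b, 0.0)
        n_boxes = len(plan.boxes.get(b, []))
        counts[b] = rng.poisson(d * plan.box_volume_um3, size=n_boxes)
    true_total = sum(
        densities.get(b, 0.0) * binning.bin_volume_um3(b)
        for b in range(1, binning.n_bins + 1)
    )
    return counts, float(true_total)
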