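"""Volume data model, NIfTI I/O, averaging, normalization, masking, montages.

All volumes live on a shared atlas voxel grid. Arrays are indexed ``[x, y, z]``
with the atlas convention x = left→right, y = anterior→posterior,
z = dorsal→ventral. NIfTI orientation matrices are not interpreted beyond the
voxel spacing: inputs are assumed co-registered onto a common grid
(registration itself is outside this package), and an affine with rotational
components only triggers a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize

from .errors import DataError, GridMismatchError

VALUE_KINDS = ("raw", "normalized8", "binary", "label")


@dataclass(frozen=True)
class VoxelGrid:
    """Dimensions and physical spacing of the shared atlas voxel lattice.

    Parameters
    ----------
    dims
        Voxel counts ``(nx, ny, nz)``; each ≥ 1.
    spacing_um
        Physical edge length of one voxel per axis, in µm; each > 0.
    """

    dims: tuple[int, int, int]
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_um", tuple(float(s) for s in self.spacing_um))
        if len(self.dims) != 3 or len(self.spacing_um) != 3:
            raise DataError("VoxelGrid requires 3 dims and 3 spacings")
        if any(d < 1 for d in self.dims):
            raise DataError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing_um):
            raise DataError(f"all spacings must be > 0, got {self.spacing_um}")

    @property
    def voxel_volume_um3(self) -> float:
        return math.prod(self.spacing_um)

    def compatible(self, other: "VoxelGrid") -> bool:
        """Two grids are compatible iff dims and spacing are equal."""
        return self.dims == other.dims and np.allclose(
            self.spacing_um, other.spacing_um
        )

    def require_compatible(self, other: "VoxelGrid", context: str = "") -> None:
        if not self.compatible(other):
            where = f" ({context})" if context else ""
            raise GridMismatchError(
                f"grid mismatch{where}: dims {self.dims} @ {self.spacing_um} µm "
                f"vs dims {other.dims} @ {other.spacing_um} µm"
            )


@dataclass
class Volume:
    """A 3D scalar field on a :class:`VoxelGrid`.

    ``value_kind`` declares the interpretation of the voxel values:
    ``raw`` (acquisition intensities, any dtype), ``normalized8`` (0–255),
    ``binary`` (0/1 occupancy) or ``label`` (integer region / count labels).
    """

    grid: VoxelGrid
    data: np.ndarray
    value_kind: str = "raw"
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.dims:
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        if self.value_kind not in VALUE_KINDS:
            raise DataError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "normalized8":
            if self.data.min() < 0 or self.data.max() > 255:
                raise DataError("normalized8 volume has values outside [0, 255]")
        elif self.value_kind == "binary":
            if not np.isin(self.data, (0, 1)).all():
                raise DataError("binary volume has values outside {0, 1}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.grid.dims


def _binary_check(mask: Volume) -> np.ndarray:
    if mask.value_kind != "binary" and not np.isin(mask.data, (0, 1)).all():
        raise DataError("mask must be binary (values in {0, 1})")
    return mask.data.astype(bool)


# ---------------------------------------------------------------------------
# I/O


def read_volume(
    path: str | Path,
    expect_grid: VoxelGrid | None = None,
    value_kind: str = "raw",
    channel_label: str = "",
) -> Volume:
    """Read a 3D single-channel NIfTI volume.

    Spacing is taken from the header zooms; the orientation part of the affine
    is ignored (a warning is emitted if it is not axis-aligned). When
    ``expect_grid`` is given the file's grid must be compatible with it.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate a trailing singleton (time/channel) dimension
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DataError(f"{path}: expected 3D single-channel data, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    rot = np.asarray(img.affine)[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
        warnings.warn(
            f"{path}: affine has off-diagonal terms; orientation is ignored "
            "(volumes are assumed co-registered on a common grid)",
            stacklevel=2,
        )
    grid = VoxelGrid(data.shape, spacing)
    if expect_grid is not None:
        expect_grid.require_compatible(grid, context=str(path))
    return Volume(grid, data, value_kind=value_kind, channel_label=channel_label)


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine built from spacing."""
    path = Path(path)
    data = volume.data
    if volume.value_kind in ("normalized8", "binary"):
        data = data.astype(np.uint8)
    elif volume.value_kind == "label":
        data = data.astype(np.int32)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)
    affine = np.diag(list(volume.grid.spacing_um) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.grid.spacing_um)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Processing


def average_scans(volumes: list[Volume]) -> Volume:
    """Voxel-wise arithmetic mean of registered scans of the same line.

    Representative line images are built by averaging registered scans from
    several larvae; a warning (not an error) is emitted when fewer than three
    scans are supplied, since fewer inputs give a noisy representative image.
    """
    if not volumes:
        raise DataError("average_scans requires at least one volume")
    grid = volumes[0].grid
    for v in volumes[1:]:
        grid.require_compatible(v.grid, context="average_scans")
    if len(volumes) < 3:
        warnings.warn(
            f"averaging only {len(volumes)} scan(s); at least 3 are recommended "
            "for a representative image",
            stacklevel=2,
        )
    acc = np.zeros(grid.dims, dtype=np.float64)
    for v in volumes:
        acc += v.data
    acc /= len(volumes)
    return Volume(grid, acc, value_kind="raw", channel_label=volumes[0].channel_label)


def normalize_to_8bit(
    volume: Volume,
    saturation_fraction: float = 1e-4,
    domain: str = "all_voxels",
    mask: Volume | None = None,
) -> Volume:
    """Rescale intensities to 8-bit, saturating the brightest voxels.

    The reference intensity is the ``1 - saturation_fraction`` quantile
    (linear interpolation) of either all voxels or, with ``domain="mask"``,
    the voxels inside ``mask``. Values are clipped at the quantile, scaled to
    255 and rounded half-to-even. The default fraction 1e-4 saturates the top
    0.01% of voxels. An all-zero input (quantile 0) maps to all zeros.
    """
    if not 0 <= saturation_fraction < 0.5:
        raise DataError(
            f"saturation_fraction must be in [0, 0.5), got {saturation_fraction}"
        )
    data = np.asarray(volume.data, dtype=np.float64)
    if data.min() < 0:
        raise DataError("normalize_to_8bit requires non-negative intensities")
    if domain == "all_voxels":
        ref = data
    elif domain == "mask":
        if mask is None:
            raise DataError("domain='mask' requires a mask volume")
        volume.grid.require_compatible(mask.grid, context="normalize_to_8bit mask")
        sel = _binary_check(mask)
        if not sel.any():
            raise DataError("mask domain is empty")
        ref = data[sel]
    else:
        raise DataError(f"unknown domain {domain!r}")
    q = float(np.quantile(ref, 1.0 - saturation_fraction))
    if q <= 0:
        out = np.zeros(volume.grid.dims, dtype=np.uint8)
    else:
        scaled = np.rint(255.0 * np.minimum(data, q) / q)
        out = np.clip(scaled, 0, 255).astype(np.uint8)
    return Volume(
        volume.grid, out, value_kind="normalized8", channel_label=volume.channel_label
    )


def apply_mask(volume: Volume, mask: Volume) -> Volume:
    """Zero every voxel outside the mask; voxels inside are unchanged."""
    volume.grid.require_compatible(mask.grid, context="apply_mask")
    sel = _binary_check(mask)
    out = np.where(sel, volume.data, 0)
    return Volume(
        volume.grid,
        out.astype(volume.data.dtype, copy=False),
        value_kind=volume.value_kind,
        channel_label=volume.channel_label,
    )


# ---------------------------------------------------------------------------
# Texture-atlas montage export


def export_texture_atlas(
    volume: Volume,
    z_step: int = 4,
    grid_cols: int = 10,
    grid_rows: int = 10,
    scale: float = 1.0,
) -> tuple[np.ndarray, int]:
    """Tile every ``z_step``-th plane into a 2D montage for volume rendering.

    Planes z = 0, z_step, 2·z_step, … are rescaled in-plane by ``scale`` and
    placed row-major (top-left first) into a ``grid_cols × grid_rows`` tile
    grid; unused tiles stay zero. Each tile is the transposed plane so image
    rows run along the y (anterior→posterior) axis. Returns the montage and
    the number of slices placed. The browser-facing configuration uses 100
    slices over a 10 × 10 grid, taking every 4th plane.
    """
    if z_step < 1:
        raise DataError(f"z_step must be >= 1, got {z_step}")
    if not 0 < scale <= 1:
        raise DataError(f"scale must be in (0, 1], got {scale}")
    nx, ny, nz = volume.grid.dims
    z_indices = range(0, nz, z_step)
    n_slices = len(z_indices)
    if n_slices > grid_cols * grid_rows:
        raise DataError(
            f"{n_slices} slices do not fit a {grid_cols}x{grid_rows} grid"
        )
    out_h = max(1, round(ny * scale))
    out_w = max(1, round(nx * scale))
    montage = np.zeros((grid_rows * out_h, grid_cols * out_w), dtype=np.float64)
    for k, z in enumerate(z_indices):
        plane = volume.data[:, :, z].T.astype(np.float64)  # (ny, nx) image
        if (out_h, out_w) != plane.shape:
            plane = resize(
                plane, (out_h, out_w), order=1, preserve_range=True,
                anti_aliasing=scale < 1.0,
            )
        r, c = divmod(k, grid_cols)
        montage[r * out_h:(r + 1) * out_h, c * out_w:(c + 1) * out_w] = plane
    if volume.data.dtype == np.uint8:
        montage = np.clip(np.rint(montage), 0, 255).astype(np.uint8)
    return montage, n_slices
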