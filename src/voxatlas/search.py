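"""Bit-packed, block-fragmented occupancy index and 3D spatial search.

Each line's expression is binarized at its cellular threshold, max-pool
downsampled (default 4×), and cut into 8×8×8 blocks packed to 64 bytes each
(one bit per cell — an exact 8× reduction over byte-per-voxel storage). For
every block coordinate the per-line payloads are concatenated in registry
order into a single *fragment*, so a search touches only the fragments
overlapping the query box. With 264 lines a fragment is 16,896 bytes (~17 kb).

Packing layout (pinned so fragment files are bit-exact across
implementations): cells are linearized x-fastest, then y, then z; bit ``i``
of byte ``j`` holds linear cell ``8j + i``, least-significant bit first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import block_reduce

from .errors import DataError, GridMismatchError
from .registry import AtlasRegistry
from .volume import VoxelGrid, Volume

BLOCK_EDGE = 8
BLOCK_BYTES = 64  # 8*8*8 bits / 8


# ---------------------------------------------------------------------------
# Types


@dataclass
class BinaryMask:
    """A line's binarized occupancy on the downsampled search grid."""

    grid: VoxelGrid
    data: np.ndarray
    source_line: str = ""
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.dims:
            raise GridMismatchError(
                f"mask shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        if not np.isin(self.data, (0, 1)).all():
            raise DataError("BinaryMask values must be in {0, 1}")


@dataclass(frozen=True)
class SearchBox:
    """Half-open voxel box ``[lo, hi)`` at full atlas resolution."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if any(l > h for l, h in zip(self.lo, self.hi)):
            raise DataError(f"box lo {self.lo} exceeds hi {self.hi}")

    def to_downsampled(
        self, factor: int, down_dims: tuple[int, int, int]
    ) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Outward-rounded (cover) conversion to downsampled coordinates.

        Covering the full-resolution box guarantees no false negatives: any
        set full-resolution voxel inside the box maps into the converted box.
        """
        lo = tuple(max(0, l // factor) for l in self.lo)
        hi = tuple(
            min(d, -(-h // factor)) for h, d in zip(self.hi, down_dims)
        )
        if any(l >= h for l, h in zip(lo, hi)):
            raise DataError(
                f"box {self.lo}..{self.hi} is empty after downsampling by {factor}"
            )
        return lo, hi


# ---------------------------------------------------------------------------
# Binarize / downsample


def binarize(volume: Volume, threshold: float) -> Volume:
    """Set a voxel iff its normalized intensity is >= the line threshold."""
    if not 0 <= threshold <= 255:
        raise DataError(f"threshold {threshold} outside [0, 255]")
    if volume.value_kind != "normalized8":
        raise DataError("binarize expects a normalized8 volume")
    out = (np.asarray(volume.data) >= threshold).astype(np.uint8)
    return Volume(volume.grid, out, value_kind="binary",
                  channel_label=volume.channel_label)


def downsample_mask(mask: Volume, factor: int = 4, source_line: str = "") -> BinaryMask:
    """Max-pool a full-resolution binary volume by ``factor`` per axis.

    An output cell is set iff ANY constituent voxel is set; edge cells pool
    over the truncated remainder. Max-pooling (rather than majority) keeps
    the no-false-negative search guarantee.
    """
    if factor < 1:
        raise DataError(f"downsample factor must be >= 1, got {factor}")
    data = _as_binary_array(mask)
    pooled = block_reduce(data, (factor, factor, factor), np.max)
    spacing = tuple(s * factor for s in mask.grid.spacing_um)
    grid = VoxelGrid(pooled.shape, spacing)
    return BinaryMask(grid, pooled.astype(np.uint8), source_line=source_line,
                      downsample_factor=factor)


def _as_binary_array(mask: Volume) -> np.ndarray:
    data = np.asarray(mask.data)
    if not np.isin(data, (0, 1)).all():
        raise DataError("expected a binary volume")
    return data.astype(np.uint8)


# ---------------------------------------------------------------------------
# Bit packing


def pack_block(bits: np.ndarray) -> bytes:
    """Pack an 8×8×8 binary array into 64 bytes (layout in module docstring)."""
    bits = np.asarray(bits)
    if bits.shape != (BLOCK_EDGE,) * 3:
        raise DataError(f"pack_block expects shape (8, 8, 8), got {bits.shape}")
    if not np.isin(bits, (0, 1)).all():
        raise DataError("pack_block expects binary values")
    flat = bits.astype(np.uint8).ravel(order="F")  # x fastest, then y, then z
    return np.packbits(flat, bitorder="little").tobytes()


def unpack_block(payload: bytes) -> np.ndarray:
    """Exact inverse of :func:`pack_block`."""
    if len(payload) != BLOCK_BYTES:
        raise DataError(f"payload must be {BLOCK_BYTES} bytes, got {len(payload)}")
    flat = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), bitorder="little")
    return flat.reshape((BLOCK_EDGE,) * 3, order="F")


# ---------------------------------------------------------------------------
# Fragment store


@dataclass
class FragmentStore:
    """Per-block concatenation of every line's 64-byte packed payload."""

    block_dims: tuple[int, int, int]
    line_order: list[str]
    downsample_factor: int
    down_dims: tuple[int, int, int]
    fragments: dict[tuple[int, int, int], bytes] = field(default_factory=dict)

    @property
    def fragment_nbytes(self) -> int:
        return BLOCK_BYTES * len(self.line_order)

    @property
    def total_nbytes(self) -> int:
        return sum(len(v) for v in self.fragments.values())

    def line_block(self, coord: tuple[int, int, int], line_index: int) -> np.ndarray:
        frag = self.fragments[coord]
        return unpack_block(frag[line_index * BLOCK_BYTES:(line_index + 1) * BLOCK_BYTES])

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "line_order": self.line_order,
            "downsample_factor": self.downsample_factor,
            "down_dims": list(self.down_dims),
            "block_dims": list(self.block_dims),
            "block_edge": BLOCK_EDGE,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for (bx, by, bz), payload in self.fragments.items():
            (directory / f"frag_{bx}_{by}_{bz}.bin").write_bytes(payload)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "FragmentStore":
        directory = Path(directory)
        mpath = directory / "manifest.json"
        if not mpath.exists():
            raise DataError(f"index manifest not found: {mpath}")
        manifest = json.loads(mpath.read_text())
        store = cls(
            block_dims=tuple(manifest["block_dims"]),
            line_order=list(manifest["line_order"]),
            downsample_factor=int(manifest["downsample_factor"]),
            down_dims=tuple(manifest["down_dims"]),
        )
        expect = store.fragment_nbytes
        for bx in range(store.block_dims[0]):
            for by in range(store.block_dims[1]):
                for bz in range(store.block_dims[2]):
                    p = directory / f"frag_{bx}_{by}_{bz}.bin"
                    if not p.exists():
                        raise DataError(f"missing fragment file: {p}")
                    payload = p.read_bytes()
                    if len(payload) != expect:
                        raise DataError(
                            f"{p}: fragment is {len(payload)} bytes, expected {expect}"
                        )
                    store.fragments[(bx, by, bz)] = payload
        return store


def build_fragments(
    registry: AtlasRegistry, masks: dict[str, BinaryMask]
) -> FragmentStore:
    """Pack every line's downsampled mask into per-block fragments.

    The downsampled grid is zero-padded to multiples of the block edge; for
    every block coordinate the 64-byte payloads are concatenated in registry
    order, so fragment size is 64 × n_lines bytes.
    """
    order = registry.line_order
    missing = [lid for lid in order if lid not in masks]
    if missing:
        raise DataError(f"masks missing for registry lines: {missing}")
    first = masks[order[0]]
    down_dims = first.grid.dims
    factor = first.downsample_factor
    for lid in order:
        m = masks[lid]
        if m.grid.dims != down_dims or m.downsample_factor != factor:
            raise GridMismatchError(
                f"mask for {lid} on grid {m.grid.dims} (factor {m.downsample_factor}) "
                f"!= expected {down_dims} (factor {factor})"
            )
    block_dims = tuple(-(-d // BLOCK_EDGE) for d in down_dims)
    padded_dims = tuple(b * BLOCK_EDGE for b in block_dims)
    padded = {}
    for lid in order:
        pad = [(0, p - d) for p, d in zip(padded_dims, down_dims)]
        padded[lid] = np.pad(masks[lid].data, pad)
    store = FragmentStore(
        block_dims=block_dims,
        line_order=list(order),
        downsample_factor=factor,
        down_dims=tuple(down_dims),
    )
    for bx in range(block_dims[0]):
        for by in range(block_dims[1]):
            for bz in range(block_dims[2]):
                parts = []
                sl = (
                    slice(bx * BLOCK_EDGE, (bx + 1) * BLOCK_EDGE),
                    slice(by * BLOCK_EDGE, (by + 1) * BLOCK_EDGE),
                    slice(bz * BLOCK_EDGE, (bz + 1) * BLOCK_EDGE),
                )
                for lid in order:
                    parts.append(pack_block(padded[lid][sl]))
                store.fragments[(bx, by, bz)] = b"".join(parts)
    return store


# ---------------------------------------------------------------------------
# Search


def spatial_search(
    store: FragmentStore, box: SearchBox, min_cells: int = 1
) -> list[str]:
    """Lines with at least ``min_cells`` set cells inside the box.

    The box is converted to downsampled coordinates with cover semantics and
    only fragments overlapping it are unpacked. Results follow registry
    (index) order.
    """
    if min_cells < 1:
        raise DataError(f"min_cells must be >= 1, got {min_cells}")
    lo, hi = box.to_downsampled(store.downsample_factor, store.down_dims)
    n_lines = len(store.line_order)
    counts = np.zeros(n_lines, dtype=np.int64)
    for bx in range(lo[0] // BLOCK_EDGE, (hi[0] - 1) // BLOCK_EDGE + 1):
        for by in range(lo[1] // BLOCK_EDGE, (hi[1] - 1) // BLOCK_EDGE + 1):
            for bz in range(lo[2] // BLOCK_EDGE, (hi[2] - 1) // BLOCK_EDGE + 1):
                frag = store.fragments[(bx, by, bz)]
                bits = np.unpackbits(
                    np.frombuffer(frag, dtype=np.uint8), bitorder="little"
                )
                # per line: linear order x-fastest -> [line, z, y, x] in C order
                blocks = bits.reshape(n_lines, BLOCK_EDGE, BLOCK_EDGE, BLOCK_EDGE)
                blocks = blocks.transpose(0, 3, 2, 1)  # -> [line, x, y, z]
                base = (bx * BLOCK_EDGE, by * BLOCK_EDGE, bz * BLOCK_EDGE)
                sl = tuple(
                    slice(max(l - b, 0), min(h - b, BLOCK_EDGE))
                    for l, h, b in zip(lo, hi, base)
                )
                counts += blocks[(slice(None),) + sl].sum(axis=(1, 2, 3), dtype=np.int64)
    return [lid for lid, c in zip(store.line_order, counts) if c >= min_cells]


def brute_force_search(
    masks: dict[str, BinaryMask], box: SearchBox, min_cells: int = 1
) -> list[str]:
    """Oracle search: direct per-voxel loop over the converted box.

    Deliberately naive (explicit triple loop) and independent of the packed
    index; same return contract as :func:`spatial_search`.
    """
    if min_cells < 1:
        raise DataError(f"min_cells must be >= 1, got {min_cells}")
    result = []
    for line_id, mask in masks.items():
        lo, hi = box.to_downsampled(mask.downsample_factor, mask.grid.dims)
        count = 0
        for x in range(lo[0], hi[0]):
            for y in range(lo[1], hi[1]):
                for z in range(lo[2], hi[2]):
                    if mask.data[x, y, z]:
                        count += 1
        if count >= min_cells:
            result.append(line_id)
    return result
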