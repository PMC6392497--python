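"""Defaults shared by the library and the command line.

Every default is overridable per call; the CLI records the effective config
(and any seeds) in a provenance header on its text outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import DataError


@dataclass(frozen=True)
class Config:
    saturation_fraction: float = 1e-4   # top 0.01% of voxels saturate
    downsample_factor: int = 4          # search-grid downsampling per axis
    block_edge: int = 8                 # index block edge (cells)
    bin_edge_um: float = 20.0           # expression-binning cube edge
    n_density_bins: int = 5             # neuron-density strata
    boxes_per_bin: int = 5              # sampling volumes per stratum
    sample_edge_um: float = 30.0        # sampling-volume cube edge
    total_neurons: int = 92000          # brain-wide mature-neuron total, 6 dpf
    ratio_threshold: float = 0.5        # soma/(soma+neuropil) cellular cut
    min_reads: int = 10                 # pool enrichment floor
    max_bg_reads: int = 2               # pool background ceiling
    merge_window_bp: int = 100          # site merge window
    log_level: str = "INFO"

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Config from an optional YAML file; keyword overrides win."""
    values: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise DataError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise DataError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(Config.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    return Config(**values)


def provenance_header(config: Config, seed: int | None = None, **extra) -> str:
    from . import __version__

    parts = [f"voxatlas {__version__}", f"config={config.hash()}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts += [f"{k}={v}" for k, v in extra.items()]
    return "# " + " ".join(parts)
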