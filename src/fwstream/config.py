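"""Run configuration: defaults and a minimal TOML loader.

A config file can override any processing default, e.g.::

    carve_depth = 22.0
    stream_threshold = 100
    chunk_size = 10000
    lake_connectivity = 4
    workers = 1
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    carve_depth: float = 22.0
    stream_threshold: int = 100
    chunk_size: int = 10_000
    lake_connectivity: int = 4
    lake_min_cells: int = 1
    qc_max_iter: int = 50
    workers: int = 1
    diagonal_sqrt2: bool = False

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        cfg = cls()
        if path is None:
            return cfg
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in data.items():
            setattr(cfg, key, val)
        return cfg
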