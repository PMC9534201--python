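"""Pipeline configuration: a flat, YAML-serializable parameter set.

Every knob of the five pipeline stages lives here so a run is fully
described by (config, seed, inputs). ``config_hash`` is stable under key
reordering of the YAML file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # supercell stage
    d_max: float = 20.0                 # px; hard edge-length cut of the local graph
    k_nn: int = 10                      # candidate neighbors per cell before the cut
    min_supercell_size: int = 5         # smaller components are discarded
    local_graph_mode: str = "agnostic"  # "agnostic" | "stratified"
    # phenotyping stage
    k_cell_range: tuple[int, int] = (2, 6)   # candidate phenotype counts (inclusive)
    # community stage
    n_communities: int | str = "auto"   # explicit count or eigengap selection
    # global-graph stage
    delaunay_prune_percentile: float = 95.0
    n_laplacian_eigenvalues: int = 8    # spectrum block length of the feature vector
    # classification stage
    cv_folds: int = 5
    cv_repeats: int = 20
    # shared
    random_seed: int = 0
    feature_columns: list[str] | None = None  # None = auto-detect from CSV

    def __post_init__(self) -> None:
        self.k_cell_range = tuple(int(v) for v in self.k_cell_range)  # type: ignore[assignment]
        if self.d_max <= 0:
            raise ConfigError("d_max must be > 0")
        if self.k_nn < 1:
            raise ConfigError("k_nn must be >= 1")
        if self.min_supercell_size < 1:
            raise ConfigError("min_supercell_size must be >= 1")
        lo, hi = self.k_cell_range
        if not (2 <= lo <= hi <= 50):
            raise ConfigError("k_cell_range must lie within [2, 50] with lo <= hi")
        if self.local_graph_mode not in ("agnostic", "stratified"):
            raise ConfigError(f"unknown local_graph_mode {self.local_graph_mode!r}")
        if not (0 < self.delaunay_prune_percentile <= 100):
            raise ConfigError("delaunay_prune_percentile must be in (0, 100]")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ConfigError("cv_repeats must be >= 1")
        if self.n_communities != "auto":
            if int(self.n_communities) < 2:
                raise ConfigError("n_communities must be >= 2 or 'auto'")
            self.n_communities = int(self.n_communities)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_cell_range"] = list(self.k_cell_range)
        return d

    def config_hash(self) -> str:
        """sha256 over a canonical (sorted-key) JSON rendering."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = cls.__dataclass_fields__.keys()
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
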