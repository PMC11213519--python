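"""Run configuration for the cESFW workflow.

Defaults encode the reference analysis parameters: activity
percentile p = 97.5, EP gate at one null standard deviation, UMAP with
n_neighbors = 50 / min_dist = 0.1 on correlation distances,
agglomerative clustering into 30 sample clusters, and a 20-neighbour
label-transfer classifier.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    percentile_p: float = 97.5
    percentile_on_positive: bool = True
    min_cells_expressing: int = 1
    ep_z: float = 1.0
    overlap_operator: str = "product"  # or "minimum"
    batch_ess_threshold: float = 0.5
    top_k: int = 4000
    penalty: str = "log2"  # edge-count penalty: log2 | linear | none
    umap_neighbors: int = 50
    umap_min_dist: float = 0.1
    knn_k: int = 20
    n_sample_clusters: int = 30
    n_gene_clusters: int = 2
    hub_centrality_factor: float = 1.5
    chunk_size: int = 512
    memory_cap_gb: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.percentile_p <= 100:
            raise ValueError("percentile_p must lie in (0, 100]")
        if self.min_cells_expressing < 1:
            raise ValueError("min_cells_expressing must be >= 1")
        if self.ep_z <= 0:
            raise ValueError("ep_z must be positive")
        if not 0 < self.batch_ess_threshold <= 1:
            raise ValueError("batch_ess_threshold must lie in (0, 1]")
        if self.overlap_operator not in ("product", "minimum"):
            raise ValueError("overlap_operator must be 'product' or 'minimum'")
        if self.penalty not in ("log2", "linear", "none"):
            raise ValueError("penalty must be one of log2/linear/none")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a ``key = value`` config file (INI sections are ignored)."""
        parser = configparser.ConfigParser()
        parser.read(Path(path))
        merged: dict = {}
        for section in parser.sections():
            merged.update(parser.items(section))
        merged.update(parser.defaults())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in merged:
                continue
            raw = merged[f.name]
            if f.type in ("bool", bool):
                kwargs[f.name] = raw.strip().lower() in ("1", "true", "yes", "on")
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw.strip()
        return cls(**kwargs)

    def to_file(self, path) -> None:
        parser = configparser.ConfigParser()
        parser["cesfw"] = {
            f.name: str(getattr(self, f.name)) for f in dataclasses.fields(self)
        }
        with open(path, "w") as fh:
            parser.write(fh)
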