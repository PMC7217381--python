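"""Run configuration with strict validation.

All stage parameters carry the pipeline defaults (UMI > 1000, genes >
500, mito < 15%, scale 10,000, HVG mean/dispersion cutoffs 0.05, 20
PCs, 30 neighbors, AUC gate 0.4, marker filters |log2FC| >= 0.5 /
q < 0.05 / fraction > 0.3 / top 50, running-average window 5,000,
GSEA FDR q < 0.25) plus one global seed.  Unknown keys in a config file
are rejected; every parameter is validated at load time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # paths
    input_dir: str | None = None       # MTX triplet directory; None -> simulate
    cell_meta: str | None = None
    geneset_file: str | None = None
    out_dir: str = "results/run"
    # QC / normalization
    min_umi: int = 1000
    min_genes: int = 500
    max_mito: float = 0.15
    min_cells_per_gene: int = 10
    scale_factor: float = 10000.0
    # HVG
    mean_min: float = 0.05
    disp_min: float = 0.05
    # clustering
    n_pcs: int = 20
    n_pcs_max: int = 50
    neighbors: int = 30
    resolution: float = 1.0
    contaminant_threshold: float | None = None  # None -> control-quantile rule
    # scoring / gating
    auc_gate: float = 0.4
    auc_top_frac: float = 0.05
    lineage_quantile: float = 0.9
    # markers
    lfc_min: float = 0.5
    q_max: float = 0.05
    frac_min: float = 0.3
    top_n: int = 50
    # trajectory
    n_avg: int = 5000
    traj_k: int = 30
    # enrichment
    fdr_q: float = 0.25
    n_perm: int = 1000
    min_set_size: int = 15
    max_set_size: int = 500
    # embeddings (visualization only; slow, optional)
    embed: bool = True
    # simulation fallback (used when input_dir is None)
    sim_cells_per_donor: int = 200
    sim_n_genes: int = 800
    # global seed
    seed: int = 0

    def validate(self) -> None:
        if self.min_umi < 0 or self.min_genes < 0:
            raise ConfigError("QC minima must be non-negative")
        if not 0.0 <= self.max_mito <= 1.0:
            raise ConfigError("max_mito must be in [0, 1]")
        for name in ("auc_gate", "auc_top_frac", "lineage_quantile",
                     "q_max", "frac_min", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_pcs", "neighbors", "top_n", "n_avg", "n_perm", "traj_k"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_pcs > self.n_pcs_max:
            raise ConfigError("n_pcs exceeds n_pcs_max")
        if self.n_perm < 10:
            raise ConfigError("n_perm must be at least 10")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def param_dict(self) -> dict:
        """Analysis parameters only (paths excluded) — the config-hash basis."""
        d = dataclasses.asdict(self)
        for key in ("input_dir", "cell_meta", "geneset_file", "out_dir"):
            d.pop(key, None)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys, and validate it."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
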