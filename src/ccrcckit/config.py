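"""Pipeline configuration and logging setup.

A flat TOML file mirrors the CLI flags; on conflict the CLI wins.  Every run
writes a manifest recording the effective configuration and seed.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig", "load_config", "setup_logging"]

log = logging.getLogger("ccrcckit")


@dataclass
class PipelineConfig:
    """Tunables surfaced by the pipeline stages."""

    seed: int = 0
    # subtyping
    n_variable_genes: int = 3000
    rank_min: int = 2
    rank_max: int = 8
    nmf_runs: int = 50
    signature_size: int = 300
    gene_method: str = "mad"  # or "max"
    transfer_linkage: str = "average"  # or "complete"
    # filtering
    median_convention: str = "lower"
    # phenotyping / deconvolution
    n_phenotype_groups: int = 4
    etmb_correlation: str = "pearson"
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Read a TOML config file and apply CLI overrides (CLI wins)."""
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extras"}
    cfg = PipelineConfig(**{k: v for k, v in values.items() if k in known})
    cfg.extras = {k: v for k, v in values.items() if k not in known}
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def stage_banner(name: str, **counts) -> None:
    log.info("=== %s === %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))
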