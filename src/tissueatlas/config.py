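"""Run configuration: thresholds, tissue panel, seeds and bootstrap sizes.

A single YAML key-value file configures the whole pipeline; every CLI flag
overrides the corresponding config entry. All stochastic operations take
an explicit seed (default 1729, logged on every run).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields

import yaml

DEFAULT_SEED = 1729

logger = logging.getLogger("tissueatlas")


@dataclass
class PipelineConfig:
    tissues: tuple = (
        "head",
        "midgut",
        "salivary_gland",
        "malpighian_tubules",
        "carcass",
        "gonad",
        "accessory_gland",
    )
    # detection
    tau_det: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06
    min_present: int = 3
    # differential expression
    fold_threshold_log2: float = 1.0
    q_threshold: float = 0.05
    m_threshold: float = 2.0  # gonad-vs-carcass log2 enrichment cut
    detection_filter: bool = True
    # tissue specificity
    tau_low: float = 0.15
    tau_high: float = 0.85
    tau_detection_filter: bool = False
    # A/S estimation
    bootstrap_B: int = 10000
    # cross-species
    min_similarity: float = 0.8
    min_cluster_size: int = 50
    ra_scale: str = "linear"
    dendrogram_B: int = 10000
    # misc
    seed: int = DEFAULT_SEED

    @classmethod
    def load(cls, path=None, **overrides) -> "PipelineConfig":
        values = {}
        if path is not None:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        if isinstance(cfg.tissues, list):
            cfg.tissues = tuple(cfg.tissues)
        logger.info("configuration: seed=%d", cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        return d
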