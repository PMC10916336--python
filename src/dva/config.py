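"""Run configuration: defaults, YAML loading, fingerprinting.

Config files are flat YAML mappings using dotted keys, e.g.::

    embed.dim: 64
    model.n_trees: 500
    cv.folds: 10

Unknown keys are rejected so typos fail loudly.  Every pipeline run
writes its fully resolved config (and the derived fingerprint) next to
its outputs.
"""

from __future__ import annotations

import hashlib
import json

import yaml

from .exceptions import ParameterError

DEFAULTS = {
    # curation
    "curation.af_threshold": 0.01,
    # annotation / imputation
    "impute.strategy": "median",
    "impute.seed": 0,
    "impute.knn_k": 5,
    # PPI embedding
    "ppi.score_threshold": 700,
    "embed.p": 1.0,
    "embed.q": 1.0,
    "embed.walk_length": 80,
    "embed.walks_per_node": 10,
    "embed.dim": 64,
    "embed.window": 5,
    "embed.epochs": 5,
    "embed.negative": 5,
    "embed.seed": 0,
    # model / CV
    "model.n_trees": 500,
    "model.seed": 0,
    "cv.folds": 10,
    "cv.seed": 0,
    "cv.stratified": True,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a run config from defaults, an optional YAML file, overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ParameterError(f"config file {path} must be a flat mapping")
        unknown = [k for k in user if k not in DEFAULTS]
        if unknown:
            raise ParameterError(f"unknown config key(s): {unknown}")
        cfg.update(user)
    if overrides:
        unknown = [k for k in overrides if k not in DEFAULTS]
        if unknown:
            raise ParameterError(f"unknown config key(s): {unknown}")
        cfg.update(overrides)
    return cfg


def fingerprint(cfg: dict) -> str:
    """Short stable hash of a resolved config."""
    payload = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_resolved(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(sorted(cfg.items())), fh, default_flow_style=False)
        fh.write(f"# fingerprint: {fingerprint(cfg)}\n")
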