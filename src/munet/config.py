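"""Declarative YAML configuration for experiments.

The schema is the field set of :class:`munet.train_eval.ExperimentConfig`
(see its docstring for units and defaults); unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .train_eval import ExperimentConfig

__all__ = ["load_config", "dump_config"]

_TUPLE_FIELDS = {"shape", "voxel_size_mm", "ps_grid", "nlm_exp_grid",
                 "mlem_checkpoints"}


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k in _TUPLE_FIELDS & set(raw):
        raw[k] = tuple(raw[k])
    return ExperimentConfig(**raw)


def dump_config(cfg: ExperimentConfig, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
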