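"""Config and tabular-text input/output."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .bout_analytics import validate_annotations
from .model_core import ModelParams
from .simulator import RenewalParams

__all__ = [
    "load_config",
    "load_model_params",
    "load_renewal_params",
    "read_annotations",
    "write_annotations",
]


def _from_mapping(cls, mapping: dict, what: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}; "
                         f"valid keys: {sorted(fields)}")
    return cls(**mapping)


def load_config(path) -> tuple[ModelParams, RenewalParams]:
    """Read a YAML config with optional ``model:`` and ``renewal:`` sections.

    A flat file is treated as model parameters only. Missing keys take the
    defaults; unknown keys raise ``ValueError``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a key: value mapping")
    if "model" in raw or "renewal" in raw:
        unknown = set(raw) - {"model", "renewal"}
        if unknown:
            raise ValueError(f"unknown top-level config sections: {sorted(unknown)}")
        model = _from_mapping(ModelParams, raw.get("model") or {}, "model")
        renewal = _from_mapping(RenewalParams, raw.get("renewal") or {}, "renewal")
    else:
        model = _from_mapping(ModelParams, raw, "model")
        renewal = RenewalParams()
    return model, renewal


def load_model_params(path) -> ModelParams:
    return load_config(path)[0]


def load_renewal_params(path) -> RenewalParams:
    return load_config(path)[1]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_annotations(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited annotation table (header required)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_annotations(df)


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep=_sep_for(path), index=False)
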