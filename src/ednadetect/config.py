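"""YAML run configuration: priors and covariate standardization.

Recognized keys::

    priors:
      fixed_sd: 10.0
      fixed_family: normal
      random_sd_family: uniform
      random_sd_params: [0.0, 10.0]
    standardize:
      density: {source: data-distinct-values}           # or mean/sd explicit
      temperature: {source: explicit, mean: 29.6, sd: 1.02}

Command-line flags override file values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from .data import SampleTable
from .models import PriorSpec, Standardization, study_standardization

__all__ = ["load_config", "priors_from_config", "standardization_from_config"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config file {path} must hold a mapping")
    return dict(cfg)


def priors_from_config(cfg: Mapping) -> PriorSpec:
    section = dict(cfg.get("priors", {}))
    kwargs = {}
    for key in ("fixed_sd", "fixed_family", "random_sd_family"):
        if key in section:
            kwargs[key] = section[key]
    if "random_sd_params" in section:
        kwargs["random_sd_params"] = tuple(section["random_sd_params"])
    return PriorSpec(**kwargs)


def standardization_from_config(
    cfg: Mapping, table: SampleTable
) -> dict[str, Standardization]:
    """Resolve per-covariate standardization, defaulting to the study scale."""
    std = study_standardization(table)
    section = dict(cfg.get("standardize", {}))
    columns = {"density": "density_fish_per_m3", "temperature": "temperature_c"}
    for name, opts in section.items():
        if name not in columns:
            raise ValueError(f"unknown covariate {name!r} in standardize config")
        source = opts.get("source", "explicit")
        values = table.df[columns[name]]
        if source == "data-distinct-values":
            std[name] = Standardization.from_distinct(values)
        elif source == "data-all-rows":
            std[name] = Standardization.from_values(values)
        elif source == "explicit":
            std[name] = Standardization(float(opts["mean"]), float(opts["sd"]))
        else:
            raise ValueError(f"unknown standardization source {source!r}")
    return std
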