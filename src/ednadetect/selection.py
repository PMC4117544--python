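"""DIC model selection: effective parameters, weights, confidence sets.

DIC = Dbar + pD, where Dbar is the posterior mean deviance and
pD = Dbar - D(theta_bar) is the effective number of parameters, with
theta_bar plugging in the posterior means of every sampled quantity
(fixed effects and, when present, random intercepts). Smaller DIC is
better; DIC weights exp(-dDIC/2) / sum exp(-dDIC/2) express relative
plausibility over a model set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import SampleTable
from .mcmc import MCMCConfig, PosteriorFit, fit as _fit, log_likelihood
from .models import ModelSpec, PriorSpec, Standardization, round_half_up

__all__ = [
    "DICResult",
    "ModelComparison",
    "dic",
    "dic_weights",
    "rank_models",
    "compare_models",
    "select_structure",
    "confidence_set",
    "plausibility_ratios",
]

#: Comparison-table column layout.
COMPARISON_COLUMNS = ["Model", "Deviance", "pd", "DIC", "dDIC", "weight"]


@dataclass(frozen=True)
class DICResult:
    deviance_bar: float
    p_d: float
    dic: float


def dic(fit: PosteriorFit) -> DICResult:
    """Posterior mean deviance, effective parameters and DIC for one fit."""
    dbar = float(fit.deviance.mean())
    theta_bar = fit.flat.mean(axis=0)
    d_hat = -2.0 * log_likelihood(theta_bar, fit.dm)
    p_d = dbar - d_hat
    return DICResult(deviance_bar=dbar, p_d=p_d, dic=dbar + p_d)


def dic_weights(dics: Sequence[float]) -> np.ndarray:
    """exp(-dDIC/2) normalized over the supplied set, order preserved.

    Invariant under adding a constant to every DIC.
    """
    dics = np.asarray(list(dics), dtype=float)
    if dics.size == 0:
        raise ValueError("need at least one DIC value")
    if not np.all(np.isfinite(dics)):
        raise ValueError("DIC values must be finite")
    rel = np.exp(-0.5 * (dics - dics.min()))
    return rel / rel.sum()


@dataclass
class ModelComparison:
    """Ranked comparison table plus the fitted models behind it."""

    table: pd.DataFrame
    fits: dict[str, PosteriorFit]

    def __len__(self) -> int:
        return len(self.table)


def rank_models(results: Mapping[str, DICResult]) -> pd.DataFrame:
    """Rank models by ascending DIC and attach dDIC and DIC weights.

    Ties in DIC preserve the supplied (enumeration) order, which
    ``dict`` insertion order encodes.
    """
    labels = list(results)
    dics = [results[m].dic for m in labels]
    order = sorted(range(len(labels)), key=lambda i: (dics[i], i))
    w = dic_weights([dics[i] for i in order])
    best = min(dics)
    frame = pd.DataFrame(
        {
            "Model": [labels[i] for i in order],
            "Deviance": [results[labels[i]].deviance_bar for i in order],
            "pd": [results[labels[i]].p_d for i in order],
            "DIC": [dics[i] for i in order],
            "dDIC": [dics[i] - best for i in order],
            "weight": w,
        }
    )
    return frame.reset_index(drop=True)


def compare_models(
    table: SampleTable,
    specs: Sequence[ModelSpec],
    std: Mapping[str, Standardization] | None = None,
    cfg: MCMCConfig | None = None,
) -> ModelComparison:
    """Fit every candidate and return the ranked DIC comparison.

    Each model gets a distinct reproducible sub-seed derived from
    ``cfg.seed`` and its position in ``specs``.
    """
    cfg = cfg or MCMCConfig()
    fits: dict[str, PosteriorFit] = {}
    results: dict[str, DICResult] = {}
    for i, spec in enumerate(specs):
        model_cfg = replace(cfg, seed=int(cfg.seed) + 1000 * i)
        f = _fit(table, spec, std, model_cfg)
        fits[spec.label] = f
        results[spec.label] = dic(f)
    return ModelComparison(table=rank_models(results), fits=fits)


def select_structure(
    table: SampleTable,
    predictors: Sequence[str],
    std: Mapping[str, Standardization] | None = None,
    cfg: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
) -> ModelComparison:
    """Compare the four random-intercept structures using the global model.

    The structure is chosen once, on the model containing all predictors,
    before the all-subsets comparison of fixed effects is run with the
    winning structure.
    """
    from .models import variance_structures

    priors = priors or PriorSpec()
    specs = [
        ModelSpec(fixed_terms=tuple(predictors), random_structure=rs, priors=priors)
        for rs in variance_structures()
    ]
    return compare_models(table, specs, std, cfg)


def confidence_set(comparison: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Models whose weight is at least ``fraction`` of the best weight.

    Adds ``weight_renormalized`` (weights renormalized within the retained
    set); idempotent apart from that recomputation. Accepts the comparison
    frame or a :class:`ModelComparison`.
    """
    frame = comparison.table if isinstance(comparison, ModelComparison) else comparison
    keep = frame[frame["weight"] >= fraction * frame["weight"].max()].copy()
    keep["weight_renormalized"] = keep["weight"] / keep["weight"].sum()
    return keep.reset_index(drop=True)


def plausibility_ratios(comparison, rounded: bool = True) -> np.ndarray:
    """Ratio of the best model's DIC weight to each other model's weight.

    With ``rounded=True`` (the reporting convention) each weight is first
    rounded half-up to 2 decimals and the ratio is rounded likewise. The
    unrounded variant equals exp(dDIC/2) exactly.
    """
    if isinstance(comparison, ModelComparison):
        weights = comparison.table["weight"].to_numpy()
    elif isinstance(comparison, pd.DataFrame):
        weights = comparison["weight"].to_numpy()
    else:
        weights = np.asarray(list(comparison), dtype=float)
    if len(weights) < 2:
        raise ValueError("need at least two models to form plausibility ratios")
    weights = weights[np.argsort(-weights, kind="stable")]
    if rounded:
        w = np.array([round_half_up(x, 2) for x in weights])
        return np.array([round_half_up(w[0] / wi, 2) for wi in w[1:]])
    return weights[0] / weights[1:]
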