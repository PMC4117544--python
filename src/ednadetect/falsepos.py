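"""False-positive rate estimation from control (fishless) pond samples.

With no fish present every detection is a false positive, so an
intercept-only Bernoulli logistic model on the control samples estimates
the per-sample false-positive probability. When the control data contain
zero detections the likelihood alone cannot bound that probability away
from zero and the posterior is dominated by the (proper) prior; the module
therefore also produces a mandatory prior-sensitivity table in that case,
and projects the expected number of false positives hiding in a stocked-
pond sample set of a given size.

The per-sample probability is the posterior mean of inverse-logit(b0)
(averaging the probability over draws), not inverse-logit of the posterior
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import SampleTable
from .mcmc import MCMCConfig, PosteriorFit, fit as _fit
from .models import ModelSpec, PriorSpec

__all__ = [
    "FalsePositiveEstimate",
    "fit_false_positive",
    "expected_false_positives",
    "prior_sensitivity",
]


@dataclass(frozen=True)
class FalsePositiveEstimate:
    """Per-sample false-positive probability and its projection to N samples."""

    intercept_mean: float
    intercept_sd: float
    intercept_ci: tuple[float, float]
    per_sample_p: float
    n_projected: int
    expected_count: float
    predictive_interval: tuple[int, int]
    predictive_min_max: tuple[int, int]
    level: float


def _expit(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def fit_false_positive(
    control: SampleTable,
    priors: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
) -> PosteriorFit:
    """Intercept-only Bernoulli fit to control-pond detection data.

    A proper prior is mandatory: with zero detections the likelihood is
    monotone in the intercept and an improper or absent prior would leave
    the posterior improper.
    """
    if len(control) == 0:
        raise ValueError("control table is empty")
    if priors is None:
        raise ValueError(
            "a proper fixed-effect prior is required: with zero control "
            "detections the intercept posterior exists only through the prior"
        )
    spec = ModelSpec(fixed_terms=(), random_structure="none", priors=priors)
    return _fit(control, spec, std=None, cfg=cfg or MCMCConfig())


def expected_false_positives(
    est: PosteriorFit | np.ndarray | float,
    n: int,
    level: float = 0.95,
    seed: int = 0,
) -> FalsePositiveEstimate:
    """Project a false-positive posterior to an N-sample survey.

    ``est`` may be the intercept-only :class:`PosteriorFit`, an array of
    posterior draws of the per-sample probability p, or a single fixed p
    (treated as a point mass). The expected count is N times the posterior
    mean of p; the predictive distribution of the count is Binomial(N, p)
    with p drawn from the posterior, summarized both by the central
    ``level`` interval and by the min-max of the simulated counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(est, PosteriorFit):
        b0 = est.param("intercept")
        p_draws = _expit(b0)
        b_mean, b_sd = float(b0.mean()), float(b0.std(ddof=1))
        b_ci = tuple(float(q) for q in np.percentile(b0, [2.5, 97.5]))
    else:
        p_draws = np.atleast_1d(np.asarray(est, dtype=float))
        if np.any((p_draws < 0) | (p_draws > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        with np.errstate(divide="ignore", invalid="ignore"):
            b0 = np.log(p_draws / (1.0 - p_draws))
            b_mean = float(np.mean(b0))
            b_sd = float(np.std(b0, ddof=1)) if len(b0) > 1 else 0.0
            if np.all(np.isfinite(b0)):
                b_ci = tuple(float(q) for q in np.percentile(b0, [2.5, 97.5]))
            else:  # point mass at p = 0 or 1 has an infinite logit
                b_ci = (float(np.min(b0)), float(np.max(b0)))
    rng = np.random.default_rng(seed)
    reps = p_draws if len(p_draws) >= 2000 else np.tile(p_draws, int(np.ceil(2000 / len(p_draws))))
    counts = rng.binomial(n, reps)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(counts, [100 * alpha, 100 * (1 - alpha)])
    return FalsePositiveEstimate(
        intercept_mean=b_mean,
        intercept_sd=b_sd,
        intercept_ci=b_ci,
        per_sample_p=float(np.mean(p_draws)),
        n_projected=int(n),
        expected_count=float(n * np.mean(p_draws)),
        predictive_interval=(int(lo), int(hi)),
        predictive_min_max=(int(counts.min()), int(counts.max())),
        level=level,
    )


def prior_sensitivity(
    control: SampleTable,
    prior_sds: tuple[float, ...] = (2.5, 5.0, 10.0),
    cfg: MCMCConfig | None = None,
    n: int = 243,
    base_priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """Per-sample false-positive probability under several prior SDs.

    Mandatory companion output whenever the control data contain zero
    detections: the posterior is prior-dominated there, so a single number
    without this table would overstate what the data say. One row per prior
    SD with the intercept summary, posterior-mean p and the expected count
    among ``n`` stocked-pond samples.
    """
    base = base_priors or PriorSpec()
    rows = []
    for i, sd in enumerate(prior_sds):
        run_cfg = replace(cfg or MCMCConfig(), seed=(cfg.seed if cfg else 0) + 100 * i)
        f = fit_false_positive(control, replace(base, fixed_sd=float(sd)), run_cfg)
        est = expected_false_positives(f, n=n, seed=run_cfg.seed)
        rows.append(
            {
                "prior_sd": float(sd),
                "intercept_mean": est.intercept_mean,
                "intercept_sd": est.intercept_sd,
                "per_sample_p": est.per_sample_p,
                "expected_count": est.expected_count,
            }
        )
    return pd.DataFrame(rows)
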