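"""Survey design: per-sample detection probabilities and sample numbers.

Turns fitted coefficients into the quantities a survey planner needs: the
probability that one 1-L water sample detects the species at given fish
density, water temperature and sampling position; the cumulative detection
probability 1 - (1 - p)^n of at least one detection in n independent
samples; and the smallest n achieving a target certainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mcmc import PosteriorFit
from .models import Standardization, standardize

__all__ = [
    "DetectionDesign",
    "per_sample_probability",
    "posterior_mean_probability",
    "cumulative_detection",
    "samples_required",
    "detection_curve",
]


@dataclass(frozen=True)
class DetectionDesign:
    """Per-sample probability, cumulative curve and samples required."""

    per_sample_p: float
    density: float
    temperature: float
    position: str
    curve: tuple[tuple[int, float], ...]
    n_required: int | None
    target: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density": self.density,
                "temperature": self.temperature,
                "position": self.position,
                "n": [n for n, _ in self.curve],
                "cumulative_probability": [c for _, c in self.curve],
            }
        )


def _linear_predictor(
    coefs: Mapping[str, float],
    std: Mapping[str, Standardization],
    density: float,
    temperature: float,
    position: str,
    day: float | None,
) -> float:
    eta = float(coefs.get("intercept", 0.0))
    if "density" in coefs:
        eta += coefs["density"] * float(standardize([density], std["density"])[0])
    if "temperature" in coefs:
        eta += coefs["temperature"] * float(
            standardize([temperature], std["temperature"])[0]
        )
    if "day" in coefs:
        if day is None:
            raise ValueError("model includes a day term; supply day=")
        eta += coefs["day"] * float(day)
    # position offsets absent from the model contribute zero
    if position == "middle":
        eta += float(coefs.get("middle", 0.0))
    elif position == "bottom":
        eta += float(coefs.get("bottom", 0.0))
    return eta


def per_sample_probability(
    coefs: Mapping[str, float],
    std: Mapping[str, Standardization],
    density: float,
    temperature: float,
    position: str = "surface",
    day: float | None = None,
) -> float:
    """Plug-in detection probability of one 1-L sample.

    inverse-logit of the linear predictor evaluated at the supplied
    coefficient values (typically posterior means) and covariate setting.
    """
    eta = _linear_predictor(coefs, std, density, temperature, position, day)
    if eta >= 0:
        return float(1.0 / (1.0 + math.exp(-eta)))
    return float(math.exp(eta) / (1.0 + math.exp(eta)))


def posterior_mean_probability(
    fit: PosteriorFit,
    std: Mapping[str, Standardization],
    density: float,
    temperature: float,
    position: str = "surface",
    day: float | None = None,
) -> float:
    """Posterior-averaged detection probability, mean over draws of
    inverse-logit(eta).

    Differs from the plug-in value because inverse-logit is nonlinear; in
    the probability tails the averaged value is the larger of the two.
    """
    etas = np.array(
        [
            _linear_predictor(
                dict(zip(fit.names, draw)), std, density, temperature, position, day
            )
            for draw in fit.flat
        ]
    )
    with np.errstate(over="ignore"):
        return float(np.mean(1.0 / (1.0 + np.exp(-etas))))


def cumulative_detection(p: float, n: int) -> float:
    """Probability of at least one detection in n independent samples."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(1.0 - (1.0 - p) ** n)


def samples_required(p: float, target: float = 0.95) -> int:
    """Smallest n with cumulative detection probability >= target.

    Closed form ceil(log(1 - target) / log(1 - p)), with the boundary
    checked explicitly so floating-point rounding cannot shift n by one.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target must lie strictly between 0 and 1")
    if not (0.0 < p < 1.0):
        raise ValueError(
            "per-sample probability must lie strictly between 0 and 1 "
            "(a target certainty is unreachable at p = 0)"
        )
    n = max(1, math.ceil(math.log1p(-target) / math.log1p(-p)))
    while n > 1 and cumulative_detection(p, n - 1) >= target:
        n -= 1
    while cumulative_detection(p, n) < target:
        n += 1
    return n


def detection_curve(
    coefs: Mapping[str, float],
    std: Mapping[str, Standardization],
    densities: Sequence[float],
    temperature: float = 28.0,
    position: str = "surface",
    max_n: int = 100,
    target: float = 0.95,
) -> list[DetectionDesign]:
    """Cumulative detection curves over a density grid at one temperature.

    One :class:`DetectionDesign` per density level, each with the per-sample
    probability, the curve for n = 1..max_n and the samples required to hit
    ``target`` (None when the target is not reached by ``max_n`` and the
    closed form exceeds it).
    """
    if len(densities) == 0:
        raise ValueError("density grid must be non-empty")
    out = []
    for d in densities:
        p = per_sample_probability(coefs, std, d, temperature, position)
        curve = tuple((n, cumulative_detection(p, n)) for n in range(1, max_n + 1))
        n_req = samples_required(p, target) if 0.0 < p < 1.0 else None
        out.append(
            DetectionDesign(
                per_sample_p=p,
                density=float(d),
                temperature=float(temperature),
                position=position,
                curve=curve,
                n_required=n_req,
                target=target,
            )
        )
    return out
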