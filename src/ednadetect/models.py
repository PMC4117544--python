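"""Candidate model specification: standardization, design matrices, priors.

The regression models considered here are Bernoulli logistic regressions of
per-sample eDNA detection on pond-level covariates (fish density, water
temperature, study day) and a sample-level covariate (water-column position,
with surface as baseline), optionally with normally distributed random
intercepts for pond sections and/or transects:

    logit p = b0 + b_h x_h + b_k x_k + u_section + u_transect

Continuous covariates enter standardized ((x - mean) / sd); the mean/sd
constants are explicit :class:`Standardization` objects so that simulation,
fitting and survey-design prediction all share one covariate scale.
"""

from __future__ import annotations

import decimal
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import POSITIONS, SampleTable, subset

__all__ = [
    "FIXED_TERMS",
    "RANDOM_STRUCTURES",
    "Standardization",
    "PriorSpec",
    "ModelSpec",
    "DesignMatrix",
    "standardize",
    "build_design_matrix",
    "enumerate_candidates",
    "variance_structures",
    "study_standardization",
    "round_half_up",
]

#: Supported fixed-effect terms, in canonical column order.
FIXED_TERMS = ("density", "temperature", "day", "middle", "bottom")

#: The four random-intercept structures compared during structure selection.
RANDOM_STRUCTURES = ("none", "section", "transect", "section+transect")

_TERM_SOURCE = {
    "density": "density_fish_per_m3",
    "temperature": "temperature_c",
    "day": "day",
}

#: Water-temperature SD (deg C) used by the original pond study to
#: standardize temperature. It derives from per-stratum thermometer readings
#: that were never published (pond-day means alone give 1.09), so it is kept
#: as an explicit constant rather than recomputed from the bundled table.
STUDY_TEMPERATURE_SD = 1.02


def round_half_up(x, ndigits: int = 2):
    """Round half away from zero (the convention of the reported tables).

    Plain ``round`` rounds half to even; reported values such as DIC weights
    and odds ratios are rounded half-up instead.
    """
    if np.ndim(x) > 0:
        return np.array([round_half_up(v, ndigits) for v in np.asarray(x).ravel()]).reshape(
            np.shape(x)
        )
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class Standardization:
    """Mean/SD pair used to put a covariate on the z-scale.

    ``source`` records how the constants were obtained: from the distinct
    covariate values (``"data-distinct-values"``, e.g. the three stocked pond
    densities), from all rows (``"data-all-rows"``), or supplied verbatim
    (``"explicit"``). SDs use the n-1 denominator.
    """

    mean: float
    sd: float
    source: str = "explicit"

    def __post_init__(self):
        if not (self.sd > 0 and np.isfinite(self.sd) and np.isfinite(self.mean)):
            raise ValueError(f"standardization requires finite mean and sd > 0, got {self}")

    @classmethod
    def from_distinct(cls, values: Iterable[float]) -> "Standardization":
        vals = np.unique(np.asarray(list(values), dtype=float))
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            raise ValueError("cannot standardize: fewer than two distinct values")
        return cls(float(vals.mean()), float(vals.std(ddof=1)), "data-distinct-values")

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "Standardization":
        vals = np.asarray(list(values), dtype=float)
        sd = float(vals.std(ddof=1))
        if not sd > 0:
            raise ValueError("cannot standardize: values have zero variance")
        return cls(float(vals.mean()), sd, "data-all-rows")

    def apply(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


def standardize(values, how: Standardization) -> np.ndarray:
    """Return ``(values - how.mean) / how.sd`` as a float array."""
    return how.apply(values)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for fixed effects and random-intercept SDs.

    Fixed effects get independent zero-mean priors on the logit scale:
    ``"normal"`` with SD ``fixed_sd`` (default a diffuse Normal(0, 10)), or
    ``"logistic"`` with scale ``fixed_sd`` (a Logistic(0, 1) intercept prior
    makes inverse-logit(b0) uniform on (0, 1), handy for conjugate checks).
    Random-intercept SDs get ``"uniform"`` on ``random_sd_params = (lo, hi)``
    or ``"halfnormal"`` with ``random_sd_params = (sd,)``.
    """

    fixed_sd: float = 10.0
    fixed_family: str = "normal"
    random_sd_family: str = "uniform"
    random_sd_params: tuple[float, ...] = (0.0, 10.0)

    def __post_init__(self):
        if not (np.isfinite(self.fixed_sd) and self.fixed_sd > 0):
            raise ValueError(f"fixed-effect prior scale must be finite and positive, got {self.fixed_sd}")
        if self.fixed_family not in ("normal", "logistic"):
            raise ValueError(f"unknown fixed-effect prior family {self.fixed_family!r}")
        if self.random_sd_family not in ("uniform", "halfnormal"):
            raise ValueError(f"unknown random-SD prior family {self.random_sd_family!r}")
        params = tuple(float(p) for p in self.random_sd_params)
        if not all(np.isfinite(p) for p in params):
            raise ValueError("random-SD prior hyperparameters must be finite")
        if self.random_sd_family == "uniform" and not (0 <= params[0] < params[1]):
            raise ValueError(f"uniform random-SD prior needs 0 <= lo < hi, got {params}")
        if self.random_sd_family == "halfnormal" and not params[0] > 0:
            raise ValueError(f"half-normal random-SD prior needs sd > 0, got {params}")
        object.__setattr__(self, "random_sd_params", params)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: fixed terms, random structure and priors.

    The intercept is always included and is not listed in ``fixed_terms``.
    Position indicators (``middle``, ``bottom``) are 0/1 with surface as the
    baseline; ``day`` enters unstandardized (its effect is per study day).
    """

    fixed_terms: tuple[str, ...] = ()
    random_structure: str = "none"
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        terms = tuple(t for t in FIXED_TERMS if t in self.fixed_terms)
        unknown = set(self.fixed_terms) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed term(s) {sorted(unknown)}; known: {FIXED_TERMS}")
        if len(set(self.fixed_terms)) != len(tuple(self.fixed_terms)):
            raise ValueError("duplicate fixed terms")
        object.__setattr__(self, "fixed_terms", terms)
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(
                f"unknown random structure {self.random_structure!r}; "
                f"one of {RANDOM_STRUCTURES}"
            )

    @property
    def has_section(self) -> bool:
        return "section" in self.random_structure

    @property
    def has_transect(self) -> bool:
        return "transect" in self.random_structure

    @property
    def label(self) -> str:
        parts = ("Intercept",) + self.fixed_terms
        lab = ", ".join(parts)
        if self.random_structure != "none":
            lab += f" | {self.random_structure}"
        return lab


@dataclass
class DesignMatrix:
    """Response, fixed-effect columns and random-effect grouping indices.

    ``X`` carries a leading all-ones intercept column; ``columns`` names the
    columns (``("intercept", ...)``). ``section_index`` / ``transect_index``
    map each row to a 0-based group (groups are (pond, section) respectively
    (pond, transect) pairs, so physical locations are not shared across
    ponds); they are ``None`` when the model has no such random intercepts.
    """

    y: np.ndarray
    X: np.ndarray
    columns: tuple[str, ...]
    section_index: np.ndarray | None = None
    transect_index: np.ndarray | None = None
    section_labels: tuple = ()
    transect_labels: tuple = ()
    #: pond-day-position cell of each row, for cell-grouped discrepancies
    cell_index: np.ndarray | None = None
    cell_labels: tuple = ()

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_sections(self) -> int:
        return len(self.section_labels)

    @property
    def n_transects(self) -> int:
        return len(self.transect_labels)


def _group_index(df, cols):
    labels = sorted(set(map(tuple, df[list(cols)].itertuples(index=False))))
    lookup = {lab: i for i, lab in enumerate(labels)}
    idx = np.array([lookup[tuple(row)] for row in df[list(cols)].itertuples(index=False)])
    return idx, tuple(labels)


def build_design_matrix(
    table: SampleTable,
    spec: ModelSpec,
    std: Mapping[str, Standardization] | None = None,
) -> DesignMatrix:
    """Assemble the response vector and covariate columns for one model.

    ``std`` must supply a :class:`Standardization` for every continuous term
    in the model (``density``, ``temperature``); ``day`` enters on its raw
    scale and position terms as 0/1 indicators.
    """
    if len(table) == 0:
        raise ValueError("cannot build a design matrix from an empty table")
    std = dict(std or {})
    df = table.df
    y = df["detection"].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in spec.fixed_terms:
        if term in ("middle", "bottom"):
            col = (df["position"] == term).to_numpy(dtype=float)
        elif term == "day":
            col = df["day"].to_numpy(dtype=float)
        else:
            if term not in std:
                raise ValueError(f"no standardization supplied for continuous term {term!r}")
            col = standardize(df[_TERM_SOURCE[term]], std[term])
        cols.append(col)
        names.append(term)
    dm = DesignMatrix(y=y, X=np.column_stack(cols), columns=tuple(names))
    dm.cell_index, dm.cell_labels = _group_index(df, ("pond_id", "day", "position"))
    if spec.has_section:
        dm.section_index, dm.section_labels = _group_index(df, ("pond_id", "section"))
    if spec.has_transect:
        dm.transect_index, dm.transect_labels = _group_index(df, ("pond_id", "transect"))
    return dm


def enumerate_candidates(
    predictors: Sequence[str],
    priors: PriorSpec | None = None,
    random_structure: str = "none",
) -> list[ModelSpec]:
    """All-subsets candidate set over ``predictors`` (2^k models).

    Includes the intercept-only model (empty subset); an empty predictor set
    yields just that one model. Deterministic order: by subset size, then
    lexicographically by term names.
    """
    priors = priors or PriorSpec()
    preds = list(dict.fromkeys(predictors))
    specs = []
    for size in range(len(preds) + 1):
        for combo in sorted(map(tuple, itertools.combinations(sorted(preds), size))):
            specs.append(
                ModelSpec(fixed_terms=combo, random_structure=random_structure, priors=priors)
            )
    return specs


def variance_structures() -> list[str]:
    """The four random-intercept structures, in the order they are compared."""
    return list(RANDOM_STRUCTURES)


def study_standardization(table: SampleTable | None = None) -> dict[str, Standardization]:
    """Covariate standardization used for the bundled pond study.

    Density uses the distinct stocked-pond densities (SD 2.53 fish/m3 with
    the n-1 denominator); temperature uses the mean of the stocked pond-day
    temperatures together with the study's published SD constant
    :data:`STUDY_TEMPERATURE_SD` (1.02 C), which came from per-stratum
    readings that are not part of the bundled table.
    """
    if table is None:
        from .data import builtin_pond_study

        table = builtin_pond_study()
    stocked = subset(table, predicate=lambda d: d["density_fish_per_m3"] > 0)
    densities = sorted(stocked.df["density_fish_per_m3"].unique())
    pond_day_temps = stocked.df.groupby(["pond_id", "day"])["temperature_c"].first()
    return {
        "density": Standardization.from_distinct(densities),
        "temperature": Standardization(
            float(pond_day_temps.mean()), STUDY_TEMPERATURE_SD, "explicit"
        ),
    }
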