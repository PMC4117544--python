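"""Bayesian fitting of the detection models by adaptive Metropolis MCMC.

The posterior is the Bernoulli likelihood of the detection outcomes at
inverse-logit(linear predictor + random intercepts), times the priors on
fixed effects, random-intercept SDs and the random intercepts themselves.
Sampling is componentwise random-walk Metropolis with per-coordinate step
sizes adapted during burn-in (Roberts-Rosenthal batch adaptation targeting
an acceptance rate of 0.44) and frozen afterwards. Random-effect SDs are
sampled on the log scale with the Jacobian correction; draws are stored on
the natural scale. Chains start from over-dispersed initial values so that
the Gelman-Rubin diagnostic is meaningful.

The per-draw deviance D = -2 * Bernoulli log-likelihood (priors excluded,
random intercepts conditioned on) is stored with every retained draw; it is
the ingredient for DIC-based model selection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import SampleTable
from .models import (
    DesignMatrix,
    ModelSpec,
    PriorSpec,
    Standardization,
    build_design_matrix,
    round_half_up,
)

__all__ = [
    "MCMCConfig",
    "TEST_PROFILE",
    "PosteriorFit",
    "log_posterior",
    "log_likelihood",
    "fit",
    "gelman_rubin",
    "summarize",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MCMCConfig:
    """Chain lengths and seeding. Defaults reproduce the full study profile."""

    iterations: int = 200_000
    burn_in: int = 50_000
    chains: int = 3
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError(
                f"burn_in must satisfy 0 <= burn_in < iterations, got "
                f"{self.burn_in} / {self.iterations}"
            )
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


#: Reduced profile for desk-scale runs and the test suite.
TEST_PROFILE = MCMCConfig(iterations=20_000, burn_in=5_000)


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Layout:
    """Maps the flat parameter vector onto betas, SDs and random intercepts."""

    n_beta: int
    n_sections: int = 0
    n_transects: int = 0

    @property
    def n_params(self) -> int:
        n = self.n_beta
        if self.n_sections:
            n += 1 + self.n_sections
        if self.n_transects:
            n += 1 + self.n_transects
        return n

    @property
    def sl_sigma_section(self) -> int | None:
        return self.n_beta if self.n_sections else None

    @property
    def sl_u_section(self) -> slice | None:
        if not self.n_sections:
            return None
        return slice(self.n_beta + 1, self.n_beta + 1 + self.n_sections)

    @property
    def sl_sigma_transect(self) -> int | None:
        if not self.n_transects:
            return None
        off = self.n_beta + (1 + self.n_sections if self.n_sections else 0)
        return off

    @property
    def sl_u_transect(self) -> slice | None:
        if not self.n_transects:
            return None
        off = self.sl_sigma_transect
        return slice(off + 1, off + 1 + self.n_transects)

    def names(self, dm: DesignMatrix) -> tuple[str, ...]:
        names = list(dm.columns)
        if self.n_sections:
            names.append("sigma_section")
            names += [f"u_section[p{p}s{s}]" for p, s in dm.section_labels]
        if self.n_transects:
            names.append("sigma_transect")
            names += [f"u_transect[p{p}t{t}]" for p, t in dm.transect_labels]
        return tuple(names)


def _layout_for(dm: DesignMatrix) -> _Layout:
    return _Layout(
        n_beta=dm.X.shape[1],
        n_sections=dm.n_sections if dm.section_index is not None else 0,
        n_transects=dm.n_transects if dm.transect_index is not None else 0,
    )


# ---------------------------------------------------------------------------
# Density pieces
# ---------------------------------------------------------------------------


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log p(y | eta) = y*eta - log(1 + exp(eta)), overflow-safe via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _eta(theta: np.ndarray, dm: DesignMatrix, layout: _Layout) -> np.ndarray:
    eta = dm.X @ theta[: layout.n_beta]
    if layout.n_sections:
        eta = eta + theta[layout.sl_u_section][dm.section_index]
    if layout.n_transects:
        eta = eta + theta[layout.sl_u_transect][dm.transect_index]
    return eta


def _beta_logprior(beta: np.ndarray, priors: PriorSpec) -> float:
    s = priors.fixed_sd
    if priors.fixed_family == "normal":
        return float(-0.5 * np.sum((beta / s) ** 2) - len(beta) * (np.log(s) + 0.5 * _LOG2PI))
    # logistic(0, s): -|b|/s - 2 log(1 + exp(-|b|/s)) - log s   (symmetric form)
    a = np.abs(beta) / s
    return float(np.sum(-a - 2.0 * np.log1p(np.exp(-a)) - np.log(s)))


def _sigma_logprior(sigma: float, priors: PriorSpec) -> float:
    if priors.random_sd_family == "uniform":
        lo, hi = priors.random_sd_params
        if not (lo < sigma < hi):
            return -np.inf
        return -float(np.log(hi - lo))
    (s,) = priors.random_sd_params
    if sigma <= 0:
        return -np.inf
    return float(-0.5 * (sigma / s) ** 2 + 0.5 * np.log(2.0 / np.pi) - np.log(s))


def _u_logprior(u: np.ndarray, sigma: float) -> float:
    if sigma <= 0:
        return -np.inf
    return float(-0.5 * np.sum((u / sigma) ** 2) - len(u) * (np.log(sigma) + 0.5 * _LOG2PI))


def _logprior_t(theta_t: np.ndarray, priors: PriorSpec, layout: _Layout) -> float:
    """Log prior in the transformed space (log-sigma), incl. Jacobian."""
    lp = _beta_logprior(theta_t[: layout.n_beta], priors)
    if layout.n_sections:
        ls = theta_t[layout.sl_sigma_section]
        sigma = np.exp(ls)
        lp += _sigma_logprior(sigma, priors) + ls  # + log sigma Jacobian
        lp += _u_logprior(theta_t[layout.sl_u_section], sigma)
    if layout.n_transects:
        ls = theta_t[layout.sl_sigma_transect]
        sigma = np.exp(ls)
        lp += _sigma_logprior(sigma, priors) + ls
        lp += _u_logprior(theta_t[layout.sl_u_transect], sigma)
    return lp


def log_likelihood(theta: np.ndarray, dm: DesignMatrix) -> float:
    """Bernoulli log-likelihood at a natural-scale parameter vector."""
    layout = _layout_for(dm)
    theta = np.asarray(theta, dtype=float)
    if len(theta) != layout.n_params:
        raise ValueError(f"expected {layout.n_params} parameters, got {len(theta)}")
    return _bernoulli_loglik(_eta(theta, dm, layout), dm.y)


def log_posterior(theta: np.ndarray, dm: DesignMatrix, priors: PriorSpec) -> float:
    """Unnormalized log posterior at a natural-scale parameter vector.

    ``theta`` follows the layout [betas, sigma_section, u_section...,
    sigma_transect, u_transect...] with random-effect SDs on their natural
    scale. Returns -inf only for out-of-support values (e.g. an SD outside
    its uniform prior range).
    """
    layout = _layout_for(dm)
    theta = np.asarray(theta, dtype=float)
    if len(theta) != layout.n_params:
        raise ValueError(f"expected {layout.n_params} parameters, got {len(theta)}")
    lp = _beta_logprior(theta[: layout.n_beta], priors)
    for sl_sig, sl_u in (
        (layout.sl_sigma_section, layout.sl_u_section),
        (layout.sl_sigma_transect, layout.sl_u_transect),
    ):
        if sl_sig is not None:
            sigma = theta[sl_sig]
            lp += _sigma_logprior(sigma, priors)
            lp += _u_logprior(theta[sl_u], sigma)
    if not np.isfinite(lp):
        return -np.inf
    return lp + _bernoulli_loglik(_eta(theta, dm, layout), dm.y)


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """Post-burn-in draws (chains x draws x params) plus chain metadata.

    ``draws`` are on the natural scale (random-effect SDs exponentiated);
    ``deviance`` holds -2 * log-likelihood per retained draw. The design
    matrix is kept so that model selection and posterior-predictive checks
    can recompute likelihood quantities without re-reading data.
    """

    draws: np.ndarray
    names: tuple[str, ...]
    deviance: np.ndarray
    spec: ModelSpec
    config: MCMCConfig
    dm: DesignMatrix
    std: dict = field(default_factory=dict)
    data_fingerprint: str = ""
    accept_rates: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def param(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]

    @property
    def fixed_names(self) -> tuple[str, ...]:
        return tuple(self.dm.columns)

    def to_frame(self) -> pd.DataFrame:
        """Draws as a tidy frame with chain and iteration columns."""
        n_ch, n_dr, _ = self.draws.shape
        frame = pd.DataFrame(self.flat, columns=list(self.names))
        frame.insert(0, "iteration", np.tile(np.arange(n_dr), n_ch))
        frame.insert(0, "chain", np.repeat(np.arange(n_ch), n_dr))
        return frame


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def _init_state(rng, layout: _Layout, priors: PriorSpec) -> np.ndarray:
    theta = np.empty(layout.n_params)
    theta[: layout.n_beta] = rng.normal(0.0, 2.0, layout.n_beta)
    for sl_sig, sl_u, n in (
        (layout.sl_sigma_section, layout.sl_u_section, layout.n_sections),
        (layout.sl_sigma_transect, layout.sl_u_transect, layout.n_transects),
    ):
        if sl_sig is not None:
            if priors.random_sd_family == "uniform":
                lo, hi = priors.random_sd_params
                sigma = rng.uniform(max(lo, 1e-3), min(hi, 2.0))
            else:
                sigma = abs(rng.normal(0.0, 1.0)) + 1e-3
            theta[sl_sig] = np.log(sigma)
            theta[sl_u] = rng.normal(0.0, 0.5, n)
    return theta


def _run_chain(rng, dm, priors, layout, cfg):
    d = layout.n_params
    y = dm.y
    # row indices per random-effect group, for incremental eta updates
    groups: dict[int, np.ndarray] = {}
    if layout.n_sections:
        for g in range(layout.n_sections):
            groups[layout.sl_u_section.start + g] = np.flatnonzero(dm.section_index == g)
    if layout.n_transects:
        for g in range(layout.n_transects):
            groups[layout.sl_u_transect.start + g] = np.flatnonzero(dm.transect_index == g)
    sigma_coords = {layout.sl_sigma_section, layout.sl_sigma_transect} - {None}

    theta = _init_state(rng, layout, priors)
    eta = _eta_t(theta, dm, layout)
    cur_ll = _bernoulli_loglik(eta, y)
    cur_lprior = _logprior_t(theta, priors, layout)

    n_keep = (cfg.iterations - cfg.burn_in) // cfg.thin
    kept = np.empty((n_keep, d))
    kept_dev = np.empty(n_keep)
    log_scales = np.full(d, np.log(0.5))
    batch = 50
    batch_accepts = np.zeros(d)
    accepts = np.zeros(d)
    k = 0
    normals = None
    for it in range(cfg.iterations):
        # draw per-iteration innovations in one call; cheaper than d calls
        normals = rng.standard_normal(d)
        unifs = rng.random(d)
        for j in range(d):
            old = theta[j]
            prop = old + np.exp(log_scales[j]) * normals[j]
            if j in sigma_coords:
                eta_prop, ll_prop = eta, cur_ll
            elif j in groups:
                rows = groups[j]
                eta_prop = eta.copy()
                eta_prop[rows] += prop - old
                ll_prop = cur_ll + float(
                    np.sum(y[rows] * (eta_prop[rows] - eta[rows]))
                    - np.sum(np.logaddexp(0.0, eta_prop[rows]) - np.logaddexp(0.0, eta[rows]))
                )
            else:
                eta_prop = eta + dm.X[:, j] * (prop - old)
                ll_prop = _bernoulli_loglik(eta_prop, y)
            theta[j] = prop
            lprior_prop = _logprior_t(theta, priors, layout)
            if np.log(unifs[j]) < ll_prop + lprior_prop - cur_ll - cur_lprior:
                eta, cur_ll, cur_lprior = eta_prop, ll_prop, lprior_prop
                batch_accepts[j] += 1
                accepts[j] += 1
            else:
                theta[j] = old
        if it < cfg.burn_in and (it + 1) % batch == 0:
            delta = min(0.1, ((it + 1) / batch) ** -0.5)
            rates = batch_accepts / batch
            log_scales += np.where(rates > 0.44, delta, -delta)
            batch_accepts[:] = 0.0
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < n_keep:
            kept[k] = theta
            kept_dev[k] = -2.0 * cur_ll
            k += 1
    # natural scale for stored SDs
    for sl in (layout.sl_sigma_section, layout.sl_sigma_transect):
        if sl is not None:
            kept[:, sl] = np.exp(kept[:, sl])
    return kept, kept_dev, accepts / cfg.iterations


def _eta_t(theta_t, dm, layout):
    # transformed-space state has log-sigmas, but eta ignores sigmas entirely
    return _eta(theta_t, dm, layout)


def fit(
    table: SampleTable,
    spec: ModelSpec,
    std: Mapping[str, Standardization] | None = None,
    cfg: MCMCConfig | None = None,
) -> PosteriorFit:
    """Fit one candidate model to a sample table by MCMC.

    Runs ``cfg.chains`` independent chains from over-dispersed starts
    (fixed effects drawn Normal(0, 2) per chain, chain-specific sub-seeds of
    ``cfg.seed``) and stores post-burn-in draws with per-draw deviance.
    Zero-detection tables are fittable because the priors are proper.
    """
    cfg = cfg or MCMCConfig()
    dm = build_design_matrix(table, spec, std)
    layout = _layout_for(dm)
    chains, devs, rates = [], [], []
    for c in range(cfg.chains):
        rng = np.random.default_rng((int(cfg.seed), c))
        kept, kept_dev, rate = _run_chain(rng, dm, spec.priors, layout, cfg)
        chains.append(kept)
        devs.append(kept_dev)
        rates.append(rate)
    fingerprint = hashlib.sha256(
        table.df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]
    return PosteriorFit(
        draws=np.stack(chains),
        names=layout.names(dm),
        deviance=np.stack(devs),
        spec=spec,
        config=cfg,
        dm=dm,
        std=dict(std or {}),
        data_fingerprint=fingerprint,
        accept_rates=np.stack(rates),
    )


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------


def gelman_rubin(fit: PosteriorFit) -> pd.Series:
    """Potential scale reduction factor (PSRF) per parameter.

    Classic between/within-chain variance form: with m chains of n draws,
    W = mean within-chain variance, B/n = variance of chain means, and
    PSRF = sqrt(((n-1)/n * W + B/n) / W). Values above 1.1 indicate
    non-convergence; see :func:`unconverged`.
    """
    if fit.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic needs chains >= 2; rerun with more chains")
    m, n, _ = fit.draws.shape
    out = {}
    for i, name in enumerate(fit.names):
        x = fit.draws[:, :, i]
        w = float(np.mean(np.var(x, axis=1, ddof=1)))
        b_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
        if w == 0.0:
            out[name] = 1.0 if b_over_n == 0.0 else np.inf
            continue
        out[name] = float(np.sqrt((n - 1) / n + b_over_n / w))
    return pd.Series(out, name="psrf")


def unconverged(psrf: pd.Series, threshold: float = 1.1) -> list[str]:
    """Names of parameters whose PSRF exceeds ``threshold``."""
    return list(psrf.index[psrf > threshold])


def summarize(fit: PosteriorFit, round_to: int | None = None) -> pd.DataFrame:
    """Posterior mean, SD, central 95% interval and odds ratios.

    Credible bounds are the 2.5/97.5 percentiles of the pooled draws. The
    odds ratio exp(posterior mean) is reported for fixed effects only (it is
    the multiplicative change in detection odds per unit -- here per SD --
    change of the predictor). ``round_to`` applies half-up rounding, the
    convention used for reported tables.
    """
    flat = fit.flat
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    orr = np.full(len(fit.names), np.nan)
    for i, name in enumerate(fit.names):
        if name in fit.fixed_names:
            orr[i] = np.exp(mean[i])
    table = pd.DataFrame(
        {"Mean": mean, "SD": sd, "Lower95": lo, "Upper95": hi, "OR": orr},
        index=list(fit.names),
    )
    if round_to is not None:
        table = table.map(lambda v: np.nan if np.isnan(v) else round_half_up(v, round_to))
    return table
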