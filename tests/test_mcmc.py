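"""Posterior density, sampler behaviour, diagnostics and summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import ednadetect as ed
from ednadetect.models import DesignMatrix
from ednadetect.mcmc import PosteriorFit


def _dm(y, x=None):
    y = np.asarray(y, dtype=float)
    cols = [np.ones(len(y))]
    names = ["intercept"]
    if x is not None:
        cols.append(np.asarray(x, dtype=float))
        names.append("density")
    return DesignMatrix(y=y, X=np.column_stack(cols), columns=tuple(names))


def _table_from(y_x_pairs):
    records = []
    for i, (y, x) in enumerate(y_x_pairs):
        records.append(
            ed.SampleRecord(
                pond_id=1,
                day=1,
                section=(i % 9) // 3 + 1,
                transect=i % 9 + 1,
                position="surface",
                density_fish_per_m3=float(x),
                temperature_c=29.0,
                detection=int(y),
            )
        )
    return ed.SampleTable.from_records(records)


class TestLogPosterior:
    def test_single_observation_closed_form(self):
        dm = _dm([1.0])
        priors = ed.PriorSpec()
        lp = ed.log_posterior(np.array([0.0]), dm, priors)
        prior_part = stats.norm.logpdf(0.0, scale=priors.fixed_sd)
        assert lp - prior_part == pytest.approx(np.log(0.5), abs=1e-12)

    def test_three_row_hand_computation(self):
        # independently coded arithmetic: y=(1,0,1), z=(-1, 0, 2), beta=(0.3, -0.7)
        dm = _dm([1, 0, 1], x=[-1.0, 0.0, 2.0])
        beta = np.array([0.3, -0.7])
        eta = [0.3 + 0.7, 0.3, 0.3 - 1.4]
        expected_ll = sum(
            y * e - np.log(1.0 + np.exp(e)) for y, e in zip([1, 0, 1], eta)
        )
        assert ed.log_likelihood(beta, dm) == pytest.approx(expected_ll, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="parameters"):
            ed.log_posterior(np.zeros(3), _dm([1, 0]), ed.PriorSpec())

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.sampled_from([0.0, 1.0, 2.0])),
            min_size=4,
            max_size=16,
        ),
        st.floats(-2, 2),
        st.floats(-1.5, 1.5),
    )
    def test_bernoulli_equals_binomial_up_to_constant(self, pairs, b0, b1):
        """The record-level likelihood matches the per-covariate-pattern
        binomial likelihood up to a parameter-free additive constant."""
        y = np.array([p[0] for p in pairs], dtype=float)
        x = np.array([p[1] for p in pairs])
        dm = _dm(y, x=x)

        def binom_ll(beta):
            total = 0.0
            for val in np.unique(x):
                mask = x == val
                n, k = int(mask.sum()), int(y[mask].sum())
                p = 1.0 / (1.0 + np.exp(-(beta[0] + beta[1] * val)))
                total += stats.binom.logpmf(k, n, p)
            return total

        t1, t2 = np.array([b0, b1]), np.array([b0 - 0.5, b1 + 0.3])
        diff1 = ed.log_likelihood(t1, dm) - binom_ll(t1)
        diff2 = ed.log_likelihood(t2, dm) - binom_ll(t2)
        assert diff1 == pytest.approx(diff2, abs=1e-9)

    def test_extreme_intercept_is_finite(self):
        dm = _dm([0, 0, 0, 0])
        lp = ed.log_posterior(np.array([-50.0]), dm, ed.PriorSpec())
        assert np.isfinite(lp)


class TestFit:
    def test_balanced_data_intercept_near_zero(self, fast_cfg):
        table = _table_from([(i % 2, 1.0) for i in range(40)])
        fit = ed.fit(table, ed.ModelSpec(), cfg=fast_cfg)
        draws = fit.param("intercept")
        mcse = draws.std(ddof=1) / np.sqrt(len(draws) / 20)  # conservative ESS
        assert abs(draws.mean()) < 3 * max(mcse, 0.05)

    def test_reproducible_given_seed(self, fast_cfg):
        table = _table_from([(i % 3 == 0, 1.0) for i in range(30)])
        f1 = ed.fit(table, ed.ModelSpec(), cfg=fast_cfg)
        f2 = ed.fit(table, ed.ModelSpec(), cfg=fast_cfg)
        assert np.array_equal(f1.draws, f2.draws)
        assert np.array_equal(f1.deviance, f2.deviance)

    def test_draw_count_and_finite_deviance(self, best_fit):
        cfg = best_fit.config
        expected = (cfg.iterations - cfg.burn_in) // cfg.thin
        assert best_fit.draws.shape == (cfg.chains, expected, 4)
        assert np.all(np.isfinite(best_fit.deviance))
        assert np.all(best_fit.deviance >= 0)

    def test_density_posterior_responds_to_added_detections(
        self, stocked, std, fast_cfg
    ):
        """Turning high-density non-detections into detections shifts the
        density coefficient posterior upward."""
        spec = ed.ModelSpec(fixed_terms=("density", "temperature", "middle"))
        base = ed.fit(stocked, spec, std, fast_cfg)
        df = stocked.df.copy()
        rows = df.query("pond_id == 4 and detection == 0").index[:10]
        df.loc[rows, "detection"] = 1
        more = ed.fit(ed.SampleTable(df), spec, std, fast_cfg)
        assert more.param("density").mean() > base.param("density").mean()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ed.MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ed.MCMCConfig(chains=0)

    def test_zero_detection_table_fits(self, control, fast_cfg):
        fit = ed.fit(control, ed.ModelSpec(), cfg=fast_cfg)
        assert np.isfinite(fit.param("intercept").mean())


class TestGelmanRubin:
    def _fit_with_draws(self, draws):
        dm = _dm([1.0])
        n_params = draws.shape[-1]
        return PosteriorFit(
            draws=draws,
            names=tuple(["intercept"] + [f"p{i}" for i in range(1, n_params)]),
            deviance=np.zeros(draws.shape[:2]),
            spec=ed.ModelSpec(),
            config=ed.MCMCConfig(iterations=2, burn_in=1),
            dm=dm,
        )

    def test_identical_chains_give_unity(self):
        chain = np.random.default_rng(0).normal(size=(1, 500, 1))
        fit = self._fit_with_draws(np.concatenate([chain, chain]))
        psrf = ed.gelman_rubin(fit)
        # two identical chains: B = 0, so PSRF = sqrt((n-1)/n)
        assert psrf["intercept"] == pytest.approx(np.sqrt(499 / 500), abs=1e-9)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = np.stack([rng.normal(0, 1, (400, 1)), rng.normal(10, 1, (400, 1))])
        fit = self._fit_with_draws(draws)
        psrf = ed.gelman_rubin(fit)
        assert psrf["intercept"] > 3.0
        from ednadetect.mcmc import unconverged

        assert unconverged(psrf) == ["intercept"]

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(3, 200, 2))
        fit = self._fit_with_draws(draws)
        psrf = ed.gelman_rubin(fit)
        m, n, _ = draws.shape
        for i, name in enumerate(fit.names):
            chains = draws[:, :, i]
            means = chains.mean(axis=1)
            b = n * means.var(ddof=1)
            w = chains.var(axis=1, ddof=1).mean()
            expected = np.sqrt(((n - 1) / n * w + b / n) / w)
            assert psrf[name] == pytest.approx(expected, abs=1e-10)

    def test_single_chain_rejected(self):
        fit = self._fit_with_draws(np.zeros((1, 10, 1)))
        with pytest.raises(ValueError, match="chains >= 2"):
            ed.gelman_rubin(fit)


class TestSummarize:
    def _point_fit(self, means):
        rng = np.random.default_rng(3)
        draws = means + 1e-9 * rng.normal(size=(2, 400, len(means)))
        dm = DesignMatrix(
            y=np.array([1.0]),
            X=np.ones((1, len(means))),
            columns=tuple(["intercept", "temperature", "middle"][: len(means)]),
        )
        return PosteriorFit(
            draws=draws,
            names=dm.columns,
            deviance=np.zeros((2, 400)),
            spec=ed.ModelSpec(),
            config=ed.MCMCConfig(iterations=2, burn_in=1),
            dm=dm,
        )

    def test_odds_ratios_from_reported_coefficients(self):
        fit = self._point_fit(np.array([0.0, -0.51, -0.81]))
        table = ed.summarize(fit, round_to=2)
        assert table.loc["temperature", "OR"] == 0.60
        assert table.loc["middle", "OR"] == 0.44
        assert table.loc["intercept", "OR"] == 1.0

    def test_interval_ordering(self, best_fit):
        table = ed.summarize(best_fit)
        assert (table["Lower95"] <= table["Mean"]).all()
        assert (table["Mean"] <= table["Upper95"]).all()
        assert (table["OR"].dropna() > 0).all()

    def test_draw_export_shape(self, best_fit):
        frame = best_fit.to_frame()
        assert {"chain", "iteration"} <= set(frame.columns)
        assert len(frame) == best_fit.flat.shape[0]
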