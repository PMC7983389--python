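import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from conftest import make_regions
from ddikit.errors import DegenerateFitError, InsufficientDataError
from ddikit.incidence import (
    expected_counts,
    fit_all_groups,
    fit_poisson_offset,
    sir_table,
)


def counts_df(rows):
    return pd.DataFrame(rows, columns=["region_id", "group_label", "observed"])


def direct_ml(y, t, pop):
    """Independent maximization of the Poisson log-likelihood."""
    def nll(beta):
        eta = beta[0] + beta[1] * t + np.log(pop)
        return float(np.sum(np.exp(eta) - y * eta))

    res = minimize(nll, x0=np.array([np.log(max(y.mean(), 0.5) / pop.mean()), 0.0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x


class TestExpectedCounts:
    def test_equal_populations_split_evenly(self):
        obs = counts_df([("r1", "g1", 4), ("r2", "g1", 6)])
        regions = make_regions([("r1", 100, 5.0), ("r2", 100, 50.0)])
        out = expected_counts(obs, regions)
        assert list(out["expected"]) == [5.0, 5.0]

    def test_standardization_identity(self, rng):
        regions = make_regions([(f"r{i}", int(rng.integers(50, 500)), float(i))
                                for i in range(20)])
        obs = counts_df([
            (f"r{i}", g, int(rng.poisson(3)))
            for i in range(20) for g in ("g1", "g2")
        ])
        out = expected_counts(obs, regions)
        for g, sub in out.groupby("group_label"):
            assert sub["observed"].sum() == pytest.approx(
                sub["expected"].sum(), abs=1e-9
            )

    def test_zero_total_group_skipped(self):
        obs = counts_df([("r1", "g1", 0), ("r2", "g1", 0), ("r1", "g2", 3),
                         ("r2", "g2", 1)])
        regions = make_regions([("r1", 100, 5.0), ("r2", 100, 50.0)])
        out = expected_counts(obs, regions)
        assert set(out["group_label"]) == {"g2"}

    def test_homogeneous_simulation_gives_mean_sir_near_1(self):
        rng = np.random.default_rng(7)
        pop = rng.integers(500, 5000, 200)
        regions = make_regions([(f"r{i}", int(p), float(i)) for i, p in enumerate(pop)])
        lam = 0.01
        obs = counts_df([(f"r{i}", "g1", int(rng.poisson(p * lam)))
                         for i, p in enumerate(pop)])
        out = expected_counts(obs, regions)
        w = out["expected"] / out["expected"].sum()
        assert float((w * out["sir"]).sum()) == pytest.approx(1.0, abs=1e-12)
        assert out["sir"].mean() == pytest.approx(1.0, abs=0.05)

    def test_sir_table_has_all_block(self):
        obs = counts_df([("r1", "g1", 4), ("r2", "g1", 6), ("r1", "g2", 1),
                         ("r2", "g2", 1)])
        regions = make_regions([("r1", 100, 5.0), ("r2", 100, 50.0)])
        st = sir_table(obs, regions)
        allb = st[st["group_label"] == "ALL"]
        assert allb["observed"].sum() == 12


class TestPoissonOffsetFit:
    def test_noise_free_link_inversion(self):
        """Counts equal to pop*exp(a + b t) exactly recover (a, b)."""
        a, b = -6.0, -0.01
        t = np.linspace(0, 120, 40)
        pop = np.linspace(1000, 8000, 40)
        y = pop * np.exp(a + b * t)  # non-integer working response
        fit = fit_poisson_offset(y, t, pop)
        assert fit.beta0 == pytest.approx(a, abs=1e-8)
        assert fit.beta1 == pytest.approx(b, abs=1e-8)

    def test_doubling_population_shifts_intercept_by_ln2(self, rng):
        t = rng.uniform(0, 120, 100)
        pop = rng.integers(500, 5000, 100).astype(float)
        y = rng.poisson(pop * 0.002 * np.exp(-0.005 * t)).astype(float)
        y[y.sum() == 0] = 1
        f1 = fit_poisson_offset(y, t, pop)
        f2 = fit_poisson_offset(y, t, 2 * pop)
        assert f2.beta0 - f1.beta0 == pytest.approx(-np.log(2), abs=1e-8)
        assert f2.beta1 == pytest.approx(f1.beta1, abs=1e-8)

    def test_irls_agrees_with_direct_likelihood_maximization(self):
        """100 random small instances, agreement to 1e-6."""
        for trial in range(100):
            r = np.random.default_rng(trial)
            n = int(r.integers(5, 20))
            t = r.uniform(0, 120, n)
            pop = r.integers(100, 2000, n).astype(float)
            y = r.poisson(pop * 0.005 * np.exp(-0.008 * t)).astype(float)
            if y.sum() == 0:
                continue
            fit = fit_poisson_offset(y, t, pop)
            ref = direct_ml(y, t, pop)
            assert fit.beta0 == pytest.approx(ref[0], abs=1e-6)
            assert fit.beta1 == pytest.approx(ref[1], abs=1e-6)

    def test_all_zero_counts_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_poisson_offset(np.zeros(10), np.arange(10.0),
                               np.full(10, 100.0))

    def test_too_few_regions(self):
        with pytest.raises(InsufficientDataError):
            fit_poisson_offset(np.array([1.0, 2.0]), np.array([0.0, 1.0]),
                               np.array([10.0, 10.0]))

    def test_rate_ratio_per_10min(self):
        t = np.linspace(0, 120, 30)
        pop = np.full(30, 1000.0)
        y = pop * np.exp(-5 - 0.02 * t)
        fit = fit_poisson_offset(y, t, pop)
        assert fit.rate_ratio_per_10min == pytest.approx(np.exp(-0.2), rel=1e-6)


class TestFitAllGroups:
    def _table(self, rng, betas, lam=30.0, n_regions=300):
        pop = rng.integers(1000, 8000, n_regions).astype(float)
        t = rng.uniform(0, 120, n_regions)
        rows = []
        for g, beta in enumerate(betas):
            mu = pop / 1e4 * lam * np.exp(beta * t)
            y = rng.poisson(mu)
            for i in range(n_regions):
                rows.append((f"r{i}", f"g{g}", int(y[i]), pop[i], t[i]))
        return pd.DataFrame(rows, columns=["region_id", "group_label",
                                           "observed", "population",
                                           "travel_time_min"])

    def test_strong_negative_slope_is_significant(self, rng):
        tab = self._table(rng, [-0.015])
        regions = make_regions(
            tab.drop_duplicates("region_id")[
                ["region_id", "population", "travel_time_min"]
            ].itertuples(index=False)
        )
        fits, summary = fit_all_groups(tab, regions)
        assert summary["n_significant"] == 1
        assert fits[0].significant
        assert fits[0].rate_ratio_per_10min < 1
        assert fits[0].p_adjusted >= fits[0].p_value

    def test_alpha_zero_flags_nothing(self, rng):
        tab = self._table(rng, [-0.015, -0.01])
        regions = make_regions(
            tab.drop_duplicates("region_id")[
                ["region_id", "population", "travel_time_min"]
            ].itertuples(index=False)
        )
        _, summary = fit_all_groups(tab, regions, alpha=0.0)
        assert summary["n_significant"] == 0

    def test_failed_group_recorded_not_fatal(self, rng):
        tab = self._table(rng, [-0.01])
        zero = tab.copy()
        zero["group_label"] = "gz"
        zero["observed"] = 0
        tab = pd.concat([tab, zero], ignore_index=True)
        regions = make_regions(
            tab.drop_duplicates("region_id")[
                ["region_id", "population", "travel_time_min"]
            ].itertuples(index=False)
        )
        fits, summary = fit_all_groups(tab, regions)
        assert summary["n_fitted"] == 1
        assert summary["failures"][0]["group_label"] == "gz"
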