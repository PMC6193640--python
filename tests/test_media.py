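"""Media-contagion analyses: rank correlations, ridge, Poisson interval model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gvtrends.media import (
    MediaContagionModel,
    interval_zscore,
    poisson_interval_fit,
    ridge_fit,
    spearman_matrix,
)
from tests.conftest import media_interval_records


def _avg_rank(values):
    """Average ranks computed by explicit enumeration (tie-aware oracle)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestSpearman:
    def test_perfect_inverse(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [10, 8, 6, 4, 2]})
        rho, _ = spearman_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_six_point_tie_matches_rank_oracle(self):
        x = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]
        y = [2.0, 6.0, 1.0, 3.0, 5.0, 1.5]
        rho, _ = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        rx, ry = _avg_rank(x), _avg_rank(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(want, rel=1e-12)

    def test_generator_roundtrip_hits_target(self):
        recs = media_interval_records(n=80, rho=-0.70, seed=3)
        df = pd.DataFrame(
            {
                "interval_days": [r.interval_days for r in recs],
                "media_density": [r.media_density for r in recs],
            }
        )
        rho, _ = spearman_matrix(df)
        assert -0.85 < rho.loc["media_density", "interval_days"] < -0.55

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [7, 7, 7, 7]})
        with pytest.raises(ValueError, match="constant"):
            spearman_matrix(df)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1, 2], "y": [2, 1]}))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base, _ = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        trans, _ = spearman_matrix(pd.DataFrame({"x": np.exp(x), "y": y**3}))
        assert trans.loc["x", "y"] == pytest.approx(base.loc["x", "y"], abs=1e-12)


class TestRidge:
    def _xy(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)}
        )
        y = 1.0 + 0.5 * x["a"] - 0.3 * x["b"] + rng.normal(0, 0.4, n)
        return y.to_numpy(), x

    def test_zero_penalty_equals_ols(self):
        y, x = self._xy()
        fit = ridge_fit(y, x, penalty=0.0)
        z = (x - x.mean()) / x.std(ddof=0)
        ols = np.linalg.lstsq(z.to_numpy(), y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ols, atol=1e-8)

    def test_shrinkage_monotone_in_penalty(self):
        y, x = self._xy(seed=4)
        norms = [
            np.linalg.norm(ridge_fit(y, x, penalty=lam).coefficients)
            for lam in [0.0, 0.1, 1.0, 10.0, 100.0, 1e4]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2

    def test_collinear_design_stabilised(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=50)
        x = pd.DataFrame({"a": a, "b": a + rng.normal(0, 1e-4, 50)})
        y = a + rng.normal(0, 0.1, 50)
        ols_cov = np.linalg.inv((x - x.mean()).T @ (x - x.mean()))
        assert np.abs(ols_cov).max() > 1e4  # OLS variance explodes
        fit = ridge_fit(y, x, penalty=5.0)
        assert np.all(np.isfinite(fit.coefficients))
        assert np.abs(fit.coefficients).max() < 2.0

    def test_negative_penalty_rejected(self):
        y, x = self._xy()
        with pytest.raises(ValueError):
            ridge_fit(y, x, penalty=-1.0)

    def test_gcv_selects_positive_penalty(self):
        y, x = self._xy(seed=5)
        fit = ridge_fit(y, x)
        assert fit.penalty > 0 and fit.gcv is not None


class TestPoissonIntervalModel:
    def _frame(self, recs):
        return pd.DataFrame(
            {
                "interval_days": [r.interval_days for r in recs],
                "media_density": [r.media_density for r in recs],
                "temporal_order": np.concatenate(
                    [[0.0], np.cumsum([r.interval_days for r in recs])[:-1]]
                ),
            }
        )

    def test_null_coupling_covers_zero(self):
        covered = 0
        n_rep = 100
        for s in range(n_rep):
            recs = media_interval_records(n=60, rho=0.0, seed=s, days_seed=100 + s)
            df = self._frame(recs)
            fit = poisson_interval_fit(df, np.full(60, 8.0), np.full(60, 12.0))
            coef = fit.loc["log_media_density"]
            lo = coef["coef"] - 1.96 * coef["se"]
            hi = coef["coef"] + 1.96 * coef["se"]
            covered += lo <= 0.0 <= hi
        assert covered >= 80  # nominal 95%, overdispersion makes Wald slightly liberal

    def test_contagion_coupling_negative_coefficient(self):
        neg = 0
        for s in range(40):
            recs = media_interval_records(n=60, rho=-0.70, seed=s, days_seed=200 + s)
            df = self._frame(recs)
            fit = poisson_interval_fit(df, np.full(60, 8.0), np.full(60, 12.0))
            neg += fit.loc["log_media_density", "coef"] < 0
        assert neg >= 36

    def test_degenerate_constant_response(self):
        # all intervals equal: the density slope vanishes and the intercept
        # is the log of the common interval
        df = pd.DataFrame(
            {
                "interval_days": [30.0] * 10,
                "media_density": np.linspace(1.0, 5.0, 10),
                "temporal_order": 30.0 * np.arange(10),
            }
        )
        fit = poisson_interval_fit(df, np.zeros(10), np.zeros(10), offset="none")
        assert fit.loc["log_media_density", "coef"] == pytest.approx(0.0, abs=1e-6)
        assert fit.loc["const", "coef"] == pytest.approx(math.log(30.0), abs=1e-6)

    def test_zero_interval_rejected(self):
        df = pd.DataFrame(
            {"interval_days": [0.0, 5.0, 5.0, 5.0], "media_density": [1.0] * 4,
             "temporal_order": [0.0, 5.0, 10.0, 15.0]}
        )
        with pytest.raises(ValueError):
            poisson_interval_fit(df, np.full(4, 4.0), np.zeros(4))


class TestIntervalZscore:
    def test_geometric_mean_is_zero(self):
        vals = [10.0, 100.0, 1000.0]
        gm = math.exp(np.mean(np.log(vals)))
        assert interval_zscore(gm, vals) == pytest.approx(0.0, abs=1e-12)

    def test_sd_conventions(self):
        # log values 1,2,3: sample SD 1 -> z=-1; population SD sqrt(2/3) -> -sqrt(3/2)
        vals = [math.e, math.e**2, math.e**3]
        assert interval_zscore(math.e, vals, ddof=1) == pytest.approx(-1.0, rel=1e-12)
        assert interval_zscore(math.e, vals, ddof=0) == pytest.approx(
            -math.sqrt(1.5), rel=1e-12)

    def test_monotone_above_all(self):
        vals = [10.0, 20.0, 30.0]
        assert interval_zscore(100.0, vals) > 0


class TestModelAndSensitivity:
    def test_full_fit_reports_negative_association(self):
        recs = media_interval_records(n=80, rho=-0.70, seed=12)
        res = MediaContagionModel(recs).fit()
        assert res.density_interval_rho < 0
        assert res.ridge.coefficients["log_media_density"] < 0
        assert res.poisson.loc["log_media_density", "coef"] < 0
        assert "Spearman" in res.summary()

    def test_excluding_nothing_is_identity(self):
        recs = media_interval_records(n=30, rho=-0.70, seed=13)
        model = MediaContagionModel(recs)
        rep = model.fit().sensitivity_remove([])
        assert rep.loc["full", "spearman_rho"] == pytest.approx(
            rep.loc["reduced", "spearman_rho"])
        assert rep.loc["full", "ridge_coef"] == pytest.approx(
            rep.loc["reduced", "ridge_coef"])

    def test_outlier_removal_keeps_negative_association(self):
        recs = media_interval_records(n=80, rho=-0.70, seed=14)
        model = MediaContagionModel(recs)
        res = model.fit()
        top = res.model.frame.nlargest(3, "media_density")
        excl = [model.records[i].start_event for i in top.index]
        rep = res.sensitivity_remove(excl)
        assert rep.loc["reduced", "spearman_rho"] < 0
        assert rep.loc["reduced", "n"] < rep.loc["full", "n"]

    def test_excluding_almost_everything_rejected(self):
        recs = media_interval_records(n=10, rho=-0.70, seed=15)
        model = MediaContagionModel(recs)
        excl = [r.start_event for r in recs[:-2]] + [r.end_event for r in recs]
        with pytest.raises(ValueError, match="too few"):
            model.fit().sensitivity_remove(excl)
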