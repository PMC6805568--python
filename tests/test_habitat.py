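"""Habitat GAMM tests: bases, fitting, selection, prediction.

Cross-checks: a de Boor recursion oracle for the B-spline basis, a
factors-only GLM limit for infinite smoothing, and mgcv (R) on a shared
small dataset for the penalized-spline fit itself.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.special import expit

from pengmove.habitat import (
    SmoothBasis,
    aic_dredge,
    build_smooth_basis,
    fit_binomial_gamm,
    sample_env,
    season_of,
)

COARSE = dict(
    lambda_grid=tuple(10.0 ** np.arange(-1.0, 4.1, 1.0)),
    re_grid=tuple(10.0 ** np.arange(-1.0, 3.1, 0.5)),
    sweeps=1,
)


def wind_sim(n=2000, n_ind=15, re_sd=1.0, seed=0, extra=()):
    """Foraging probability decreasing in wind, increasing in SST."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "wind": rng.uniform(0, 20, n),
            "sst": rng.uniform(-1, 10, n),
            "id": rng.integers(0, n_ind, n).astype(str),
        }
    )
    for name in extra:
        df[name] = rng.uniform(0, 1, n)
    b = rng.normal(size=n_ind)
    if re_sd > 0:
        # normalize so the planted between-individual SD is exactly re_sd
        b = (b - b.mean()) / b.std(ddof=1) * re_sd
    else:
        b = np.zeros(n_ind)
    eta = 0.5 - 0.15 * df.wind + 0.25 * df.sst + b[df.id.astype(int)]
    df["y"] = (rng.random(n) < expit(eta)).astype(float)
    return df


class TestSampleEnv:
    @pytest.fixture(scope="class")
    def grid(self):
        lon = np.arange(0.0, 10.1, 1.0)
        lat = np.arange(-50.0, -39.9, 1.0)
        time = pd.date_range("2014-01-01", periods=4, freq="3D")
        # linear analytic field: v = 2*lon - 3*lat + t_index
        v = (
            2.0 * lon[None, None, :]
            - 3.0 * lat[None, :, None]
            + np.arange(4)[:, None, None]
        )
        return xr.Dataset(
            {"sst": (("time", "lat", "lon"), v)},
            coords={"time": time, "lat": lat, "lon": lon},
        )

    def test_grid_node_exact(self, grid):
        v = sample_env(grid, [3.0], [-45.0], [pd.Timestamp("2014-01-01")], "sst")
        assert v[0] == pytest.approx(2 * 3 - 3 * -45 + 0)

    def test_linear_field_recovered_anywhere(self, grid, rng):
        lon = rng.uniform(0, 10, 50)
        lat = rng.uniform(-50, -40, 50)
        t = [pd.Timestamp("2014-01-04 01:00")] * 50  # nearest slice index 1
        v = sample_env(grid, lon, lat, t, "sst")
        assert np.allclose(v, 2 * lon - 3 * lat + 1, atol=1e-10)

    def test_outside_bbox_is_nan(self, grid):
        v = sample_env(grid, [-5.0, 3.0], [-45.0, -45.0], [pd.Timestamp("2014-01-01")] * 2, "sst")
        assert np.isnan(v[0]) and np.isfinite(v[1])


class TestSmoothBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(0, 10, 200)
        B, S, _ = build_smooth_basis(x, n_basis=10)
        assert B.shape == (200, 10)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_de_boor_recursion_oracle(self, rng):
        x = rng.uniform(0, 10, 40)
        sb = SmoothBasis.from_data(x, n_basis=8)
        B = sb.design(x)

        def de_boor_basis(xv, t, k):
            # Cox-de Boor recursion, written independently of scipy
            n = len(t) - k - 1
            N = np.zeros((len(t) - 1,))
            out = np.zeros(n)
            for i in range(len(t) - 1):
                N[i] = 1.0 if t[i] <= xv < t[i + 1] else 0.0
            if xv >= t[-1]:
                N[:] = 0.0
            for d in range(1, k + 1):
                for i in range(len(t) - d - 1):
                    a = 0.0 if t[i + d] == t[i] else (xv - t[i]) / (t[i + d] - t[i]) * N[i]
                    b = (
                        0.0
                        if t[i + d + 1] == t[i + 1]
                        else (t[i + d + 1] - xv) / (t[i + d + 1] - t[i + 1]) * N[i + 1]
                    )
                    N[i] = a + b
            out[:] = N[:n]
            return out

        for j in rng.choice(len(x), size=10, replace=False):
            xv = float(np.minimum(x[j], np.nextafter(sb.knots[-1], -np.inf)))
            oracle = de_boor_basis(xv, sb.knots, sb.degree)
            assert np.allclose(B[j], oracle, atol=1e-10)

    def test_reduced_basis_for_few_distinct_values(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 10)
        with pytest.warns(UserWarning):
            sb = SmoothBasis.from_data(x, n_basis=10)
        assert sb.n_basis == 5

    def test_penalty_shrinks_to_zero_function(self):
        # heavy penalty on a shrinkage basis collapses the smooth entirely
        rng = np.random.default_rng(1)
        df = wind_sim(n=800, n_ind=5, re_sd=0.0, seed=3)
        fit = fit_binomial_gamm(
            df, smooths=("wind",), fixed_lambda={"wind": 1e9}, **COARSE
        )
        grid = pd.DataFrame({"wind": np.linspace(1, 19, 20)})
        eff = fit.term_effect(grid, "wind")
        assert np.max(np.abs(eff)) < 1e-3
        assert fit.edf_by_term["wind"] < 0.1


class TestFitting:
    def test_intercept_only_balanced(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": np.r_[np.ones(300), np.zeros(300)]})
        fit = fit_binomial_gamm(df, smooths=(), factors=())
        p, _ = fit.predict(df.iloc[:5])
        assert np.allclose(p, 0.5, atol=1e-8)

    def test_wind_smooth_monotone_decreasing(self):
        df = wind_sim(n=3000, n_ind=15, seed=4)
        fit = fit_binomial_gamm(df, smooths=("wind", "sst"), random="id", **COARSE)
        lo, hi = np.quantile(df.wind, [0.05, 0.95])
        grid = pd.DataFrame({"wind": np.linspace(lo, hi, 40), "sst": 5.0, "id": "0"})
        eff = fit.term_effect(grid, "wind")
        assert np.all(np.diff(eff) < 1e-8)

    def test_random_intercept_sd_recovered(self):
        df = wind_sim(n=4000, n_ind=20, re_sd=1.0, seed=8)
        fit = fit_binomial_gamm(df, smooths=("wind", "sst"), random="id")
        assert 0.6 <= fit.random_intercept_sd <= 1.4

    def test_infinite_penalty_equals_factors_only_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        df = wind_sim(n=1000, n_ind=5, re_sd=0.0, seed=5)
        df["season"] = rng.choice(["summer", "winter"], len(df))
        fit = fit_binomial_gamm(
            df,
            smooths=("wind",),
            factors=("season",),
            fixed_lambda={"wind": 1e10},
            **COARSE,
        )
        Xg = sm.add_constant((df["season"] == "winter").astype(float))
        glm = sm.GLM(df["y"], Xg, family=sm.families.Binomial()).fit()
        assert fit.loglik == pytest.approx(glm.llf, abs=0.02)

    def test_season_sign_recovery(self):
        rng = np.random.default_rng(9)
        n = 3000
        df = pd.DataFrame(
            {
                "season": rng.choice(["summer", "winter"], n),
                "id": rng.integers(0, 10, n).astype(str),
            }
        )
        eta = -0.5 + 1.0 * (df.season == "winter")
        df["y"] = (rng.random(n) < expit(eta)).astype(float)
        fit = fit_binomial_gamm(df, factors=("season",), random="id", **COARSE)
        i = fit.param_names.index("season[winter]")
        assert fit.coef[i] > 0

    def test_separation_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 400)
        df = pd.DataFrame({"x": x, "y": (x > 0.5).astype(float)})
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_binomial_gamm(df, smooths=("x",), fixed_lambda={"x": 1e-8}, **COARSE)
        assert fit.separation_flag

    def test_validation_errors(self):
        df = wind_sim(n=300, n_ind=1)
        with pytest.raises(ValueError):
            fit_binomial_gamm(df.iloc[:50], smooths=("wind",))
        with pytest.raises(ValueError):
            fit_binomial_gamm(df, smooths=("wind",), random="id")

    def test_matches_mgcv_on_shared_data(self, tmp_path):
        df = wind_sim(n=600, n_ind=4, re_sd=0.0, seed=21)
        path = tmp_path / "gam.csv"
        df[["y", "wind"]].to_csv(path, index=False)
        fit = fit_binomial_gamm(df, smooths=("wind",))
        p_ours, _ = fit.predict(df)
        rscript = textwrap.dedent(
            f"""
            d <- read.csv("{path}")
            suppressMessages(library(mgcv))
            m <- gam(y ~ s(wind, bs="cs", k=10), data=d, family=binomial, method="REML")
            write.csv(data.frame(p=fitted(m)), "{tmp_path}/mgcv.csv", row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        p_mgcv = pd.read_csv(tmp_path / "mgcv.csv")["p"].to_numpy()
        assert np.corrcoef(p_ours, p_mgcv)[0, 1] > 0.97
        assert np.mean(np.abs(p_ours - p_mgcv)) < 0.03


class TestPrediction:
    @pytest.fixture(scope="class")
    def fit_and_data(self):
        df = wind_sim(n=1500, n_ind=8, seed=6)
        fit = fit_binomial_gamm(df, smooths=("wind", "sst"), random="id", **COARSE)
        return fit, df

    def test_probabilities_in_unit_interval(self, fit_and_data):
        fit, df = fit_and_data
        p, _ = fit.predict(df)
        assert (p > 0).all() and (p < 1).all()

    def test_extrapolation_flagged(self, fit_and_data):
        fit, df = fit_and_data
        new = df.iloc[:2].copy()
        new.loc[new.index[0], "wind"] = df.wind.max() + 10.0
        _, flags = fit.predict(new)
        assert flags[0] and not flags[1]

    def test_low_wind_probability_exceeds_high_wind(self, fit_and_data):
        fit, df = fit_and_data
        lo = pd.DataFrame({"wind": [2.0], "sst": [5.0], "id": ["0"]})
        hi = pd.DataFrame({"wind": [18.0], "sst": [5.0], "id": ["0"]})
        assert fit.predict(lo)[0][0] > fit.predict(hi)[0][0]


class TestDredge:
    def test_nested_loglik_monotone(self):
        df = wind_sim(n=1200, n_ind=6, seed=7)
        lam = {"wind": 10.0, "sst": 10.0, "id": 10.0}
        small = fit_binomial_gamm(df, smooths=("wind",), random="id",
                                  fixed_lambda=lam, **COARSE)
        large = fit_binomial_gamm(df, smooths=("wind", "sst"), random="id",
                                  fixed_lambda=lam, **COARSE)
        assert large.loglik >= small.loglik - 1e-6

    def test_true_terms_selected(self):
        df = wind_sim(n=2500, n_ind=10, seed=10, extra=("noise1",))
        table, best = aic_dredge(df, ("wind", "sst", "noise1"), random="id", **COARSE)
        assert table.delta_aic.iloc[0] == 0.0
        chosen = set(table.terms.iloc[0].split("+"))
        assert {"wind", "sst"} <= chosen

    def test_spatial_candidate_supported(self):
        df = wind_sim(n=900, n_ind=5, seed=11)
        rng = np.random.default_rng(0)
        df["x_km"] = rng.uniform(-500, 500, len(df))
        df["y_km"] = rng.uniform(-500, 500, len(df))
        table, best = aic_dredge(df, ("wind",), include_spatial=True, random="id", **COARSE)
        assert len(table) == 4  # {}, {wind}, {spatial}, {wind, spatial}


def test_season_mapping():
    s = season_of(pd.to_datetime(["2014-01-15", "2014-04-15", "2014-07-15", "2014-10-15"]))
    assert list(s) == ["summer", "autumn", "winter", "spring"]
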