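"""Orientation classification, proportion tables and mixed-model tests.

The adaptive Gauss-Hermite marginal likelihood is cross-checked against a
high-accuracy 1-D quadrature oracle and against lme4 on a shared dataset.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from pengmove.orientation import (
    _agh_loglik,
    build_orientation_records,
    classify_direction,
    compare_proportions,
    fit_chla_orientation,
    fit_mixed_logit,
    proportion_table,
)
from pengmove.simulate import SimConfig, simulate_env, simulate_track


class TestClassify:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (0.0, "similar"),
            (45.0, "similar"),
            (315.0, "similar"),
            (359.9, "similar"),
            (135.0, "against"),
            (180.0, "against"),
            (225.0, "against"),
            (90.0, "cross"),
            (270.0, "cross"),
            (46.0, "cross"),
            (134.9, "cross"),
        ],
    )
    def test_bins(self, delta, expected):
        assert classify_direction(delta) == expected

    def test_exhaustive_and_exclusive(self):
        d = np.arange(0.0, 360.0, 0.1)
        k = classify_direction(d)
        assert set(np.unique(k)) == {"similar", "against", "cross"}
        # bin measure: 90 / 90 / 180 degrees (boundaries are measure zero)
        frac = pd.Series(k).value_counts(normalize=True)
        assert frac["similar"] == pytest.approx(0.25, abs=0.01)
        assert frac["against"] == pytest.approx(0.25, abs=0.01)
        assert frac["cross"] == pytest.approx(0.50, abs=0.01)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify_direction(360.0)


class TestBuildRecords:
    @pytest.fixture(scope="class")
    def track_env(self):
        cfg = SimConfig(seed=13, outlier_rate=0.0)
        tr = simulate_track(cfg, "A", rng=np.random.default_rng(13))
        bbox = (
            float(np.floor(tr.lon.min() - 3)),
            float(np.ceil(tr.lon.max() + 3)),
            float(np.floor(tr.lat.min() - 3)),
            float(np.ceil(tr.lat.max() + 3)),
        )
        env = simulate_env(cfg, bbox, tr.timestamp, rng=np.random.default_rng(14))
        return tr, env

    def test_flow_direction_convention(self, track_env):
        tr, env = track_env
        env = env.copy()
        env["u10"].values[:] = 5.0
        env["v10"].values[:] = 0.0
        rec = build_orientation_records(tr, env, medium="wind")
        assert np.allclose(rec.flow_toward, 90.0)

    def test_from_convention_rotates_180(self, track_env):
        tr, env = track_env
        env = env.copy()
        env["u10"].values[:] = 5.0
        env["v10"].values[:] = 0.0
        rec = build_orientation_records(tr, env, medium="wind", uv_convention="from")
        assert np.allclose(rec.flow_toward, 270.0)

    def test_bird_east_in_east_wind_is_similar(self):
        cfg = SimConfig(seed=1)
        t0 = pd.Timestamp("2014-01-01")
        tr = pd.DataFrame(
            {
                "id": "A",
                "stage": "juvenile",
                "timestamp": [t0 + pd.Timedelta(hours=12 * i) for i in range(5)],
                "lon": 30.0 + 0.5 * np.arange(5),
                "lat": -50.0,
            }
        )
        env = simulate_env(cfg, (25.0, 35.0, -55.0, -45.0), tr.timestamp)
        env["u10"].values[:] = 8.0
        env["v10"].values[:] = 0.0
        rec = build_orientation_records(tr, env, medium="wind")
        assert (rec.klass == "similar").all()

    def test_isotropic_headings_quarter_quarter_half(self):
        # analytic bin measure: 25% similar, 25% against, 50% cross
        rng = np.random.default_rng(7)
        n = 20000
        delta = (rng.uniform(0, 360, n) - 90.0) % 360.0
        k = pd.Series(classify_direction(delta)).value_counts(normalize=True)
        se3 = 3 * np.sqrt(0.25 * 0.75 / n)
        assert abs(k["similar"] - 0.25) < se3
        assert abs(k["against"] - 0.25) < se3
        assert abs(k["cross"] - 0.50) < 3 * np.sqrt(0.5 * 0.5 / n)

    def test_record_counts_conserved(self, track_env):
        tr, env = track_env
        rec = build_orientation_records(tr, env, medium="current")
        cells = rec.groupby(["stage", "season"]).size()
        assert cells.sum() == len(rec)


class TestProportionTable:
    def _records(self, klasses, ind="A", stage="juvenile", season="winter"):
        return pd.DataFrame(
            {
                "id": ind,
                "stage": stage,
                "season": season,
                "medium": "wind",
                "klass": klasses,
            }
        )

    def test_single_individual_all_cross(self):
        tab = proportion_table(self._records(["cross"] * 10))
        row = tab.iloc[0]
        assert row.cross_mean == 1.0 and np.isnan(row.cross_sd)
        assert tab.attrs["flagged_cells"]

    def test_rows_sum_to_one(self, rng):
        recs = pd.concat(
            [
                self._records(list(rng.choice(["similar", "against", "cross"], 50)), ind=i)
                for i in "ABC"
            ],
            ignore_index=True,
        )
        tab = proportion_table(recs)
        total = tab.against_mean + tab.similar_mean + tab.cross_mean
        assert np.allclose(total, 1.0)

    def test_planted_probabilities_recovered(self, rng):
        n = 400
        recs = pd.concat(
            [
                self._records(
                    list(rng.choice(["similar", "against", "cross"], n, p=[0.6, 0.2, 0.2])),
                    ind=i,
                )
                for i in "ABCDE"
            ],
            ignore_index=True,
        )
        tab = proportion_table(recs).iloc[0]
        se3 = 3 * np.sqrt(0.6 * 0.4 / (5 * n))
        assert abs(tab.similar_mean - 0.6) < se3
        assert abs(tab.against_mean - 0.2) < 3 * np.sqrt(0.2 * 0.8 / (5 * n))


class TestMixedLogit:
    def _sim(self, seed=0, n=600, G=12, beta=(-0.3, 0.9), sd=0.8):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, G, n)
        x = rng.normal(size=n)
        b = rng.normal(0, sd, G)
        eta = beta[0] + beta[1] * x + b[g]
        y = (rng.random(n) < expit(eta)).astype(float)
        return np.column_stack([np.ones(n), x]), y, g

    def test_agh_matches_quadrature_oracle(self):
        X, y, g = self._sim()
        G = g.max() + 1
        theta = np.array([-0.2, 0.7, np.log(0.6)])
        nodes, weights = hermgauss(15)
        ll = _agh_loglik(theta, X, y, g, G, nodes, weights)
        beta, sigma = theta[:2], np.exp(theta[2])
        eta0 = X @ beta
        oracle = 0.0
        for i in range(G):
            m = g == i

            def f(b):
                e = eta0[m] + b
                return np.exp(np.sum(y[m] * e - np.logaddexp(0, e))) * norm.pdf(b, scale=sigma)

            v, _ = quad(f, -8 * sigma, 8 * sigma, limit=200)
            oracle += np.log(v)
        assert ll == pytest.approx(oracle, abs=1e-4)

    def test_matches_lme4_on_shared_data(self, tmp_path):
        X, y, g = self._sim(seed=3)
        df = pd.DataFrame({"y": y, "x": X[:, 1], "g": g})
        path = tmp_path / "glmm.csv"
        df.to_csv(path, index=False)
        fit = fit_mixed_logit(X, y, g, names=["(Intercept)", "x"], n_nodes=15)
        rscript = textwrap.dedent(
            f"""
            d <- read.csv("{path}")
            suppressMessages(library(lme4))
            m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15)
            v <- sqrt(diag(vcov(m)))
            cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), v, sep=",")
            """
        )
        r = subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True, text=True)
        b0, b1, sd, ll, se0, se1 = map(float, r.stdout.strip().split(","))
        assert fit.beta[0] == pytest.approx(b0, abs=2e-3)
        assert fit.beta[1] == pytest.approx(b1, abs=2e-3)
        assert fit.sigma == pytest.approx(sd, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)
        assert np.sqrt(fit.vcov[0, 0]) == pytest.approx(se0, rel=0.05)
        assert np.sqrt(fit.vcov[1, 1]) == pytest.approx(se1, rel=0.05)


def glmm_records(rng, p_by_cell, n_per_cell=300, n_ind=16, re_sd=0.5):
    """Upstream/downstream records with planted cell probabilities."""
    rows = []
    inds = [f"I{i}" for i in range(n_ind)]
    b = dict(zip(inds, rng.normal(0, re_sd, n_ind)))
    for (stage, season), p in p_by_cell.items():
        base = np.log(p / (1 - p))
        for _ in range(n_per_cell):
            ind = inds[rng.integers(0, n_ind)]
            pr = expit(base + b[ind])
            klass = "against" if rng.random() < pr else "similar"
            rows.append((ind, stage, season, "wind", klass))
    return pd.DataFrame(rows, columns=["id", "stage", "season", "medium", "klass"])


class TestCompareProportions:
    def test_bonferroni_definition_and_letters(self, rng):
        recs = glmm_records(
            rng,
            {("juv", "summer"): 0.3, ("juv", "winter"): 0.3, ("nb", "winter"): 0.7},
            n_per_cell=250,
        )
        res = compare_proportions(recs)
        con = res["contrasts"]
        n_con = len(con)
        ok = con[con.estimable]
        assert np.allclose(ok.p_adj, np.minimum(1.0, ok.p_raw * n_con))
        # the two identical cells share a letter
        la = res["letters"]["juv:summer"]
        lb = res["letters"]["juv:winter"]
        assert set(la) & set(lb)

    def test_planted_difference_detected(self, rng):
        recs = glmm_records(
            rng, {("juv", "a"): 0.25, ("juv", "b"): 0.75}, n_per_cell=400, re_sd=0.3
        )
        res = compare_proportions(recs)
        con = res["contrasts"].iloc[0]
        assert con.p_adj < 0.01
        assert set(res["letters"]["juv:a"]).isdisjoint(res["letters"]["juv:b"])

    def test_cross_excluded(self, rng):
        recs = glmm_records(rng, {("j", "a"): 0.4, ("j", "b"): 0.4}, n_per_cell=150)
        recs.loc[:10, "klass"] = "cross"
        res = compare_proportions(recs)
        assert res["fit"].n_obs == (recs.klass != "cross").sum()


class TestChlaOrientation:
    def test_increasing_chla_t1_effect_recovered(self, rng):
        n, n_ind = 3000, 12
        chla_t = rng.uniform(0.05, 2.0, n)
        chla_t1 = rng.uniform(0.05, 2.0, n)
        ids = rng.integers(0, n_ind, n)
        b = rng.normal(0, 0.4, n_ind)
        eta = -1.0 + 1.5 * chla_t1 + b[ids]
        klass = np.where(rng.random(n) < expit(eta), "against", "similar")
        recs = pd.DataFrame(
            {
                "id": [f"I{i}" for i in ids],
                "stage": "juvenile",
                "season": "winter",
                "klass": klass,
                "chla_t": chla_t,
                "chla_t1": chla_t1,
            }
        )
        fit = fit_chla_orientation(
            recs,
            lambda_grid=tuple(10.0 ** np.arange(-1.0, 4.1, 1.0)),
            re_grid=tuple(10.0 ** np.arange(-1.0, 3.1, 0.5)),
            sweeps=1,
        )
        lo, hi = np.quantile(chla_t1, [0.05, 0.95])
        grid = pd.DataFrame(
            {"chla_t1": np.linspace(lo, hi, 30), "chla_t": 1.0, "id": "I0"}
        )
        eff = fit.term_effect(grid, "chla_t1")
        assert np.all(np.diff(eff) > -1e-8)
        p, _ = fit.predict(grid)
        assert (p > 0).all() and (p < 1).all()

    def test_null_chla_shrinks_flat(self, rng):
        n, n_ind = 2000, 10
        recs = pd.DataFrame(
            {
                "id": [f"I{i}" for i in rng.integers(0, n_ind, n)],
                "stage": "juvenile",
                "season": "winter",
                "klass": rng.choice(["against", "similar"], n),
                "chla_t": rng.uniform(0.05, 2.0, n),
                "chla_t1": rng.uniform(0.05, 2.0, n),
            }
        )
        fit = fit_chla_orientation(
            recs,
            lambda_grid=tuple(10.0 ** np.arange(-1.0, 6.1, 1.0)),
            re_grid=tuple(10.0 ** np.arange(-1.0, 3.1, 0.5)),
            sweeps=1,
        )
        # shrinkage keeps the null terms far below the ~9 df available ...
        assert fit.edf_by_term["chla_t"] < 2.5
        assert fit.edf_by_term["chla_t1"] < 2.5
        # ... and the fitted effects stay weak on the logit scale (the
        # planted-effect case above spans ~2.7 logits over the same range)
        for term in ("chla_t", "chla_t1"):
            grid = pd.DataFrame(
                {"chla_t1": 1.0, "chla_t": 1.0, term: np.linspace(0.1, 1.9, 20), "id": "I0"}
            )
            assert np.ptp(fit.term_effect(grid, term)) < 0.5
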