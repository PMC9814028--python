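"""Poisson GLMM sampler: correctness, determinism, summaries."""

import numpy as np
import pytest

from carfield import gmrf
from carfield.glmm import (
    DiseaseMapData,
    GLMMConfig,
    PosteriorDraws,
    fit,
    summarize,
)
from carfield.simulate import Scenario, generate

FIVE_PRIORS = [
    gmrf.CARSpec(model="icar", sigma=0.3),
    gmrf.CARSpec(model="pcar", c=0.5, sigma=0.3),
    gmrf.CARSpec(model="lcar", c=0.5, sigma=0.3),
    gmrf.CARSpec(model="bym", sigma_s=0.3, sigma_h=0.3),
    gmrf.CARSpec(model="mbym", c=0.5, sigma=0.3),
]


def _draws_from_chain(values, n_areas=1):
    """Wrap a raw chain into a PosteriorDraws for summary tests."""
    arr = np.asarray(values, dtype=float)[None, :]  # one chain
    T = arr.shape[1]
    psi = np.zeros((1, T, n_areas))
    gamma = np.exp(arr[:, :, None] + psi)
    return PosteriorDraws(
        model="lcar", mu=arr, psi=psi, gamma=gamma, E=np.ones(n_areas)
    )


class TestValidation:
    def test_data_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            DiseaseMapData(y=[1, -2], E=[1.0, 1.0])
        with pytest.raises(ValueError):
            DiseaseMapData(y=[1, 2], E=[1.0, 0.0])
        with pytest.raises(ValueError):
            DiseaseMapData(y=[1.5, 2], E=[1.0, 1.0])
        with pytest.raises(ValueError):
            DiseaseMapData(y=[1, 2, 3], E=[1.0, 1.0])

    def test_config_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            GLMMConfig(iters=100, burnin=100)
        with pytest.raises(ValueError):
            GLMMConfig(prior_c=(0.0, 1.0))
        with pytest.raises(ValueError):
            GLMMConfig(prior_sigma=("gamma", 1.0))

    def test_fit_requires_matching_sizes(self, grid33):
        data = DiseaseMapData(y=np.ones(4), E=np.ones(4))
        with pytest.raises(ValueError, match="areas"):
            fit(grid33, data, FIVE_PRIORS[2], GLMMConfig(iters=20, burnin=10))


class TestDeterminismAndIdentities:
    def test_same_seed_identical_chains(self, grid33):
        data = DiseaseMapData(y=np.arange(9), E=np.full(9, 5.0))
        cfg = GLMMConfig(iters=300, burnin=100, chains=2, seed=42)
        spec = gmrf.CARSpec(model="mbym", c=0.5, sigma=0.3)
        a = fit(grid33, data, spec, cfg)
        b = fit(grid33, data, spec, cfg)
        for name in ("mu", "psi", "gamma", "c", "sigma"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_stored_draws_respect_link_and_decomposition(self, grid33):
        data = DiseaseMapData(y=np.arange(9), E=np.full(9, 5.0))
        cfg = GLMMConfig(iters=300, burnin=100, chains=1, seed=1)
        d = fit(grid33, data, gmrf.CARSpec(model="mbym", c=0.5, sigma=0.3), cfg)
        # log lambda = log E + mu + psi exactly, and psi = psi_s + psi_h
        assert np.allclose(
            np.log(d.lambda_), np.log(data.E) + d.mu[:, :, None] + d.psi
        )
        assert np.allclose(d.psi, d.psi_s + d.psi_h)


class TestPosteriorConcentration:
    @pytest.mark.parametrize("spec", [FIVE_PRIORS[2], FIVE_PRIORS[3]], ids=["lcar", "bym"])
    def test_huge_counts_pin_relative_risks_at_one(self, grid33, spec):
        """y = E with enormous E: every relative risk concentrates at 1."""
        E = np.full(9, 1e5)
        data = DiseaseMapData(y=E.copy(), E=E)
        cfg = GLMMConfig(iters=2500, burnin=1000, chains=2, seed=3)
        d = fit(grid33, data, spec, cfg)
        med = np.median(d.flat("gamma"), axis=0)
        assert np.all((med > 0.99) & (med < 1.01))


class TestPriorRecovery:
    def test_disabled_likelihood_recovers_field_prior(self, grid44):
        """With y treated as missing the chains must sample the prior:
        psi moments match exact draws from sample_field."""
        spec = gmrf.CARSpec(model="lcar", c=0.8, sigma=0.5)
        data = DiseaseMapData(y=np.zeros(16), E=np.ones(16))
        cfg = GLMMConfig(
            iters=22000, burnin=2000, chains=2, seed=3,
            prior_only=True, fixed=("c", "sigma"),
        )
        d = fit(grid44, data, spec, cfg)
        psi = d.flat("psi")
        exact = gmrf.sample_field(grid44, spec, 100_000, seed=9)
        assert np.max(np.abs(psi.var(axis=0) - exact.var(axis=0))) < 0.05
        assert np.abs(np.cov(psi[:, 0], psi[:, 1])[0, 1]
                      - np.cov(exact[:, 0], exact[:, 1])[0, 1]) < 0.05

    def test_beta_prior_on_c_recovered(self, grid33):
        data = DiseaseMapData(y=np.zeros(9), E=np.ones(9))
        cfg = GLMMConfig(
            iters=22000, burnin=2000, chains=2, seed=5,
            prior_only=True, fixed=("sigma",),
        )
        d = fit(grid33, data, gmrf.CARSpec(model="lcar", c=0.5, sigma=0.5), cfg)
        c = d.flat("c")
        assert c.mean() == pytest.approx(0.5, abs=0.05)
        assert c.var() == pytest.approx(1.0 / 12.0, abs=0.02)


class TestShrinkage:
    def test_risk_estimates_contract_toward_pooled_rate(self, grid44):
        """Borrowing information: posterior-median log risks lie between the
        pooled rate and the saturated per-area estimate (up to smoothing
        slack) and are strictly less dispersed than the saturated ones."""
        sc = Scenario(
            graph=grid44,
            true_spec=gmrf.CARSpec(model="lcar", c=0.8, sigma=0.5),
            E=5.0, replicates=1, seed=0,
        )
        data, _ = generate(sc, 0)
        glob = np.log(data.y.sum() / data.E.sum())
        cfg = GLMMConfig(iters=3000, burnin=1000, chains=2, seed=5)
        for spec in FIVE_PRIORS:
            d = fit(grid44, data, spec, cfg)
            logrr = np.log(np.median(d.flat("gamma"), axis=0))
            pos = data.y > 0
            sat = np.log(data.y[pos] / data.E[pos])
            lo = np.minimum(glob, sat) - 0.05
            hi = np.maximum(glob, sat) + 0.05
            assert np.all((lo <= logrr[pos]) & (logrr[pos] <= hi)), spec.model
            assert np.sum((logrr[pos] - glob) ** 2) < np.sum((sat - glob) ** 2)


class TestPriorSensitivity:
    def test_informative_c_prior_pulls_posterior_toward_prior_mean(self, grid44):
        """On weak data, Beta(8,3) moves the c posterior toward 8/11."""
        sc = Scenario(
            graph=grid44,
            true_spec=gmrf.CARSpec(model="lcar", c=0.4, sigma=0.3),
            E=2.0, replicates=1, seed=3,
        )
        data, _ = generate(sc, 0)
        meds = {}
        for prior in [(1.0, 1.0), (8.0, 3.0)]:
            cfg = GLMMConfig(iters=6000, burnin=2000, chains=2, seed=5, prior_c=prior)
            d = fit(grid44, data, gmrf.CARSpec(model="lcar", c=0.5, sigma=0.3), cfg)
            meds[prior] = float(np.median(d.flat("c")))
        prior_mean = 8.0 / 11.0
        assert abs(meds[(8.0, 3.0)] - prior_mean) < abs(meds[(1.0, 1.0)] - prior_mean)


class TestBymMbymEquivalence:
    def test_matched_fixed_covariances_agree(self, grid44):
        """BYM(sigma*sqrt(c), sigma*sqrt(1-c)) and MBYM(c, sigma), with c and
        the scales held fixed, give the same posterior risk summaries."""
        c, s = 0.6, 0.4
        sc = Scenario(
            graph=grid44,
            true_spec=gmrf.CARSpec(model="mbym", c=c, sigma=s),
            E=50.0, replicates=1, seed=2,
        )
        data, _ = generate(sc, 0)
        db = fit(
            grid44, data,
            gmrf.CARSpec(model="bym", sigma_s=s * np.sqrt(c), sigma_h=s * np.sqrt(1 - c)),
            GLMMConfig(iters=8000, burnin=2000, chains=2, seed=9,
                       fixed=("sigma_s", "sigma_h")),
        )
        dm = fit(
            grid44, data, gmrf.CARSpec(model="mbym", c=c, sigma=s),
            GLMMConfig(iters=8000, burnin=2000, chains=2, seed=10, fixed=("c", "sigma")),
        )
        gb = np.median(db.flat("gamma"), axis=0)
        gm = np.median(dm.flat("gamma"), axis=0)
        assert np.max(np.abs(gb - gm)) < 0.05


class TestSummarize:
    def test_constant_chain_degenerate(self):
        d = _draws_from_chain(np.full(100, 2.5))
        s = summarize(d, quantities=["mu"], diagnostics=False)
        row = s.iloc[0]
        assert row["sd"] == 0.0
        assert row["q2.5"] == row["q97.5"] == row["median"] == 2.5

    def test_running_chain_median(self):
        d = _draws_from_chain(np.arange(1, 101))
        s = summarize(d, quantities=["mu"], diagnostics=False)
        assert s.iloc[0]["median"] == pytest.approx(50.5)

    def test_normal_chain_interval_endpoints(self, rng):
        d = _draws_from_chain(rng.standard_normal(100_000))
        s = summarize(d, quantities=["mu"], diagnostics=False)
        assert s.iloc[0]["q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert s.iloc[0]["q97.5"] == pytest.approx(1.96, abs=0.05)
        assert s.iloc[0]["q2.5"] <= s.iloc[0]["median"] <= s.iloc[0]["q97.5"]

    def test_too_few_draws_rejected(self):
        d = _draws_from_chain([1.0])
        with pytest.raises(ValueError):
            summarize(d)

    def test_full_summary_has_diagnostics(self, grid33):
        data = DiseaseMapData(y=np.arange(9), E=np.full(9, 5.0))
        cfg = GLMMConfig(iters=400, burnin=200, chains=2, seed=0)
        d = fit(grid33, data, gmrf.CARSpec(model="lcar", c=0.5, sigma=0.3), cfg)
        s = summarize(d)
        assert {"quantity", "median", "sd", "q2.5", "q97.5", "ess", "rhat"} <= set(s.columns)
        assert (s[s["quantity"] == "gamma"].shape[0]) == 9
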