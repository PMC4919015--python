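"""Decomposition-model contracts: censoring, likelihood, Gibbs vs closed form."""

import math

import numpy as np
import pandas as pd
import pytest

from seagrass_metals import (
    SimulationConfig,
    fit_decomposition,
    simulate_decomposition,
    substitute_detection_limits,
)
from seagrass_metals.decomposition import (
    DECOMP_SCHEDULE,
    conjugate_posterior,
    decomp_loglik,
    fit_decomposition_arrays,
)
from seagrass_metals.mixing import MCMCConfig

from ._oracles import (
    effective_sample_size,
    ig_excess_kurtosis,
    mc_standard_error,
    sd_standard_error,
    t_excess_kurtosis,
)


def _obs_frame(cd=(0.005, 0.0005, 0.02), censored=(False, True, False)):
    return pd.DataFrame(
        {
            "experiment": ["EX1"] * len(cd),
            "c_content": [30.0, 25.0, 20.0],
            "cd": cd,
            "cd_censored": censored,
        }
    )


class TestDetectionLimits:
    def test_identity_without_censoring(self):
        df = _obs_frame(censored=(False, False, False))
        out = substitute_detection_limits(df, {"cd": 0.001})
        pd.testing.assert_frame_equal(out, df)

    def test_substitution_by_definition(self):
        out = substitute_detection_limits(_obs_frame(), {"cd": 0.001})
        assert out["cd"].tolist() == [0.005, 0.001, 0.02]
        assert out["cd_censored"].tolist() == [False, True, False]

    def test_idempotence(self):
        once = substitute_detection_limits(_obs_frame(), {"cd": 0.001})
        twice = substitute_detection_limits(once, {"cd": 0.001})
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_limit_rejected(self):
        with pytest.raises(ValueError, match="no detection limit"):
            substitute_detection_limits(_obs_frame(), {})


class TestDecompLoglik:
    def test_single_point_on_line_closed_form(self):
        # residual zero, sigma2 = 1: logpdf = -log(sqrt(2*pi))
        ll = decomp_loglik(1.0, -0.1, 1.0, np.array([20.0]), np.array([math.exp(-1.0)]))
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_per_observation_sum(self, rng):
        from scipy import stats as sps

        c = rng.uniform(11, 35, 20)
        y = np.exp(4.0 - 0.1 * c + 0.3 * rng.standard_normal(20))
        b1, b2, s2 = 3.8, -0.12, 0.09
        naive = sum(
            sps.norm.logpdf(math.log(yi), b1 + b2 * ci, math.sqrt(s2))
            for ci, yi in zip(c, y)
        )
        assert decomp_loglik(b1, b2, s2, c, y) == pytest.approx(naive, rel=1e-12)

    def test_penalizes_wrong_slope_on_noiseless_data(self):
        c = np.linspace(11, 35, 10)
        y = np.exp(4.0 - 0.1 * c)
        lls = [decomp_loglik(4.0, b2, 0.05, c, y) for b2 in (-0.1, -0.12, -0.2)]
        assert lls[0] > lls[1] > lls[2]

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            decomp_loglik(0.0, 0.0, 1.0, np.array([20.0]), np.array([0.0]))


class TestGibbsSampler:
    def test_matches_conjugate_oracle_on_random_small_datasets(self, rng):
        """Posterior means/SDs agree with the closed-form NIG posterior."""
        # n >= 20 keeps the sigma2 posterior's fourth moment well-behaved,
        # so the SD comparison has a meaningful Monte-Carlo standard error
        mcmc = MCMCConfig(iterations=9_000, burn_in=1_000, thinning=3, chains=3, seed=5)
        z_scores = []
        for rep in range(3):
            n = int(rng.integers(20, 40))
            c = rng.uniform(11, 35, n)
            logy = rng.normal(2.0, 1.0) + rng.normal(0, 0.2) * c
            logy += 0.4 * rng.standard_normal(n)
            fit = fit_decomposition_arrays(c, logy, mcmc=mcmc)
            cp = conjugate_posterior(c, logy)
            df_t = 2 * cp.a_n
            exact = {
                "beta1": (cp.beta_mean[0], math.sqrt(cp.beta_cov[0, 0]),
                          t_excess_kurtosis(df_t)),
                "beta2": (cp.beta_mean[1], math.sqrt(cp.beta_cov[1, 1]),
                          t_excess_kurtosis(df_t)),
                "sigma2": (cp.sigma2_mean, cp.sigma2_sd, ig_excess_kurtosis(cp.a_n)),
            }
            for k, p in enumerate(("beta1", "beta2", "sigma2")):
                mean_exact, sd_exact, kurt = exact[p]
                se = mc_standard_error(fit.draws[:, k])
                z_scores.append(abs(fit.summaries[p]["mean"] - mean_exact) / se)
                se_sd = sd_standard_error(fit.draws[:, k], sd_exact**2, kurt)
                z_scores.append(abs(fit.summaries[p]["sd"] - sd_exact) / se_sd)
        # 18 simultaneous 3-SE checks: budget a single mild excursion
        z = np.array(z_scores)
        assert (z >= 3.0).sum() <= 1, z[z >= 3.0]
        assert z.max() < 5.0, z.max()

    def test_noiseless_line_concentrates_on_ols(self):
        c = np.linspace(11, 35, 30)
        logy = 4.0 - 0.1 * c
        fit = fit_decomposition_arrays(
            c,
            logy,
            mcmc=MCMCConfig(iterations=6_000, burn_in=1_000, thinning=3, chains=3, seed=2),
        )
        assert fit.summaries["beta1"]["mean"] == pytest.approx(4.0, abs=1e-2)
        assert fit.summaries["beta2"]["mean"] == pytest.approx(-0.1, abs=5e-4)
        assert fit.summaries["sigma2"]["mean"] < 1e-3

    def test_retained_draws_default_schedule(self, rng):
        c = rng.uniform(11, 35, 40)
        logy = 4.0 - 0.1 * c + 0.3 * rng.standard_normal(40)
        fit = fit_decomposition_arrays(c, logy, mcmc=DECOMP_SCHEDULE)
        assert fit.n_retained == 10_000
        counts = np.bincount(fit.chain_id)
        assert counts.max() - counts.min() <= 1  # pooled thinning near-balanced
        assert np.all(fit.draws[:, 2] > 0)

    def test_shift_invariance_of_slope_and_variance(self, rng, fast_decomp_schedule):
        c = rng.uniform(11, 35, 50)
        logy = 4.0 - 0.12 * c + 0.25 * rng.standard_normal(50)
        shift = 10.0
        a = fit_decomposition_arrays(c, logy, mcmc=fast_decomp_schedule)
        b = fit_decomposition_arrays(c + shift, logy, mcmc=fast_decomp_schedule)
        se2 = math.hypot(
            mc_standard_error(a.draws[:, 1]), mc_standard_error(b.draws[:, 1])
        )
        assert abs(a.summaries["beta2"]["mean"] - b.summaries["beta2"]["mean"]) < 3 * se2
        se1 = math.hypot(
            mc_standard_error(a.draws[:, 0]), mc_standard_error(b.draws[:, 0])
        )
        expected_b1 = a.summaries["beta1"]["mean"] - shift * a.summaries["beta2"]["mean"]
        assert abs(b.summaries["beta1"]["mean"] - expected_b1) < 3 * se1 + 0.01

    def test_sign_recovery_against_reference_truth(self, fast_decomp_schedule):
        """95% CIs for beta2 exclude zero with the generative sign."""
        import dataclasses

        hits = 0
        runs = 0
        for rep in range(5):
            cfg = SimulationConfig(seed=100 + rep, n_obs=30)
            obs = simulate_decomposition(cfg, metals=("cu", "cd"))
            for metal, exp in (("cu", "EX1"), ("cd", "EX2")):
                mc = dataclasses.replace(fast_decomp_schedule, seed=rep)
                fit = fit_decomposition(obs, metal, exp, mc)
                truth_sign = np.sign(cfg.decomp_truth[(metal, exp)][1])
                s = fit.summaries["beta2"]
                runs += 1
                if np.sign(s["ci_low"]) == np.sign(s["ci_high"]) == truth_sign:
                    hits += 1
        assert hits >= runs - 1

    def test_all_censored_refused(self):
        df = _obs_frame(censored=(True, True, True))
        df = pd.concat([df, df], ignore_index=True)
        with pytest.raises(ValueError, match="censored"):
            fit_decomposition(df, "cd", "EX1")

    def test_too_few_observations_refused(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_decomposition(_obs_frame(), "cd", "EX1")
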