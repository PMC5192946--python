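"""Priors, rejection step, posterior summaries and scaling conversions."""

import math

import numpy as np
import pandas as pd
import pytest

from popdemog.abcinfer import (
    Prior,
    StudyDesign,
    TimeScale,
    build_reference_table,
    coalescent_units,
    default_priors,
    demography_from_params,
    fit_im2,
    hpd_interval,
    mutation_scaled_time,
    observed_summaries,
    population_migration_rate,
    posterior_mode,
    posterior_predictive_check,
    rejection_sample,
    sample_prior,
    theta_trajectory,
    years_from_scaled,
)
from popdemog.coalsim import Demography, simulate_dataset
from popdemog.errors import ConfigError, EstimationError
from popdemog.sumstats import harmonic_number

DESIGN = StudyDesign(n=8, loci=[("a", 400), ("b", 400), ("c", 300), ("d", 500)])


class TestPriors:
    def test_uniform_mean(self, rng):
        p = Prior("uniform", 0.0, 1.0)
        x = p.sample(10_000, rng)
        assert abs(x.mean() - 0.5) < 3 * x.std() / 100
        assert (x >= 0).all() and (x <= 1).all()

    def test_log_uniform_median(self, rng):
        x = Prior("log-uniform", 0.1, 10.0).sample(20_000, rng)
        assert np.median(x) == pytest.approx(1.0, rel=0.1)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigError):
            Prior("uniform", 1.0, 1.0)
        with pytest.raises(ConfigError):
            Prior("log-uniform", 0.0, 1.0)
        with pytest.raises(ConfigError):
            Prior("gamma", 0.0, 1.0)

    def test_sample_prior_reproducible(self):
        pr = default_priors("BOT")
        a = sample_prior(pr, 50, np.random.default_rng(3))
        b = sample_prior(pr, 50, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)


class TestReferenceTable:
    def test_shape_and_determinism(self):
        tab1 = build_reference_table(
            "SNM", default_priors("SNM"), DESIGN, 50, np.random.default_rng(7)
        )
        tab2 = build_reference_table(
            "SNM", default_priors("SNM"), DESIGN, 50, np.random.default_rng(7)
        )
        assert tab1.n_sims == 50
        pd.testing.assert_frame_equal(tab1.summaries, tab2.summaries)
        assert np.isfinite(tab1.summaries.to_numpy()).all()

    def test_snm_summary_means_match_analytics(self, rng):
        # fixed theta via a degenerate prior: E[S] = theta_locus * a_n per locus
        prior = {"theta_site": Prior("uniform", 0.0039999, 0.0040001)}
        tab = build_reference_table("SNM", prior, DESIGN, 800, rng)
        mean_L = DESIGN.mean_L
        expected_S = np.mean(
            [0.004 * L / mean_L * mean_L * harmonic_number(8) for _, L in DESIGN.loci]
        )
        got = tab.summaries["S_mean"].mean()
        assert got == pytest.approx(expected_S, rel=0.05)
        assert tab.summaries["pi_mean"].mean() == pytest.approx(
            np.mean([0.004 * L for _, L in DESIGN.loci]), rel=0.05
        )


@pytest.fixture(scope="module")
def tables():
    rng = np.random.default_rng(11)
    return [
        build_reference_table(mid, default_priors(mid), DESIGN, 400, rng)
        for mid in ("SNM", "EXP")
    ]


class TestRejection:
    def test_tolerance_one_returns_prior_shares(self, tables, rng):
        d = Demography("SNM", theta0=0.004 * DESIGN.mean_L)
        obs = observed_summaries(simulate_dataset(d, 8, DESIGN.sim_loci(), rng))
        res = rejection_sample(obs, tables, 1.0)
        assert res.model_posteriors == {"SNM": 0.5, "EXP": 0.5}
        assert sum(res.model_posteriors.values()) == pytest.approx(1.0, abs=1e-12)
        # accepted-draw posterior at tolerance 1 is the prior itself
        prior_mean = np.exp((math.log(5e-4) + math.log(2e-2)) / 2)
        acc = res.accepted["SNM"]["theta_site"]
        assert np.median(acc) == pytest.approx(prior_mean, rel=0.3)

    def test_exact_row_accepted_at_minimal_tolerance(self, tables):
        obs = tables[0].summaries.iloc[17]
        res = rejection_sample(obs, tables, 1.0 / 800)
        assert res.n_accepted == 1
        assert res.model_posteriors["SNM"] == 1.0
        assert res.accepted["SNM"].iloc[0].equals(tables[0].params.iloc[17])


class TestPosteriorSummaries:
    def test_mode_of_constant_sample(self):
        assert posterior_mode(np.full(80, 2.5)) == 2.5

    def test_mode_of_triangular_peak(self, rng):
        x = rng.triangular(0.0, 1.0, 2.0, size=20_000)
        assert posterior_mode(x) == pytest.approx(1.0, abs=0.05)

    def test_mode_needs_enough_samples(self):
        with pytest.raises(EstimationError):
            posterior_mode(np.arange(10.0))

    def test_hpd_uniform_spacing(self):
        lo, hi = hpd_interval(np.arange(1.0, 101.0))
        assert hi - lo == 94.0

    def test_hpd_point_mass(self):
        lo, hi = hpd_interval(np.full(60, 7.0))
        assert lo == hi == 7.0

    def test_hpd_never_wider_than_central_interval(self, rng):
        for _ in range(60):
            x = rng.gamma(2.0, 2.0, size=300)
            lo, hi = hpd_interval(x)
            clo, chi = np.quantile(x, [0.025, 0.975])
            assert hi - lo <= chi - clo + 1e-12

    def test_hpd_matches_brute_force(self, rng):
        for _ in range(80):
            x = np.sort(rng.normal(size=int(rng.integers(50, 200))))
            k = math.ceil(0.95 * x.size)
            widths = [(x[i + k - 1] - x[i], x[i], x[i + k - 1])
                      for i in range(x.size - k + 1)]
            _, blo, bhi = min(widths)
            assert hpd_interval(x) == (blo, bhi)


class TestPredictiveCheck:
    def test_quantiles_cover_observed_under_truth(self, rng):
        tab = build_reference_table(
            "SNM", default_priors("SNM"), DESIGN, 600, np.random.default_rng(21)
        )
        d = Demography("SNM", theta0=0.004 * DESIGN.mean_L)
        obs = observed_summaries(simulate_dataset(d, 8, DESIGN.sim_loci(), rng))
        res = rejection_sample(obs, [tab], 0.1)
        q = posterior_predictive_check(res, "SNM", DESIGN, 100, rng)
        vals = [v for k, v in q.items() if k != "n_mono"]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert np.mean([(0.01 < v < 0.99) for v in vals]) >= 0.8

    def test_zero_replicates_rejected(self, rng):
        tab = build_reference_table(
            "SNM", default_priors("SNM"), DESIGN, 60, np.random.default_rng(2)
        )
        obs = tab.summaries.iloc[0]
        res = rejection_sample(obs, [tab], 1.0)
        with pytest.raises(EstimationError):
            posterior_predictive_check(res, "SNM", DESIGN, 0, rng)


class TestIm2Fit:
    def test_recovers_split_time_order_of_magnitude(self):
        rng = np.random.default_rng(31)
        truth = Demography(
            "IM2", theta0=1.6, theta1=1.6, theta2=1.6, thetaA=1.6, t_split=0.5
        )
        loci = [(f"l{i}", 1.0, 400) for i in range(6)]
        mats = simulate_dataset(truth, (8, 8), loci, rng)
        rowsA = [np.arange(8)] * 6
        rowsB = [np.arange(8, 16)] * 6
        priors = {
            "theta1_site": Prior("log-uniform", 1e-3, 1e-2),
            "theta2_site": Prior("log-uniform", 1e-3, 1e-2),
            "thetaA_site": Prior("log-uniform", 1e-3, 1e-2),
            "t_split": Prior("uniform", 0.0, 2.0),
            "m12": Prior("uniform", 0.0, 2.0),
            "m21": Prior("uniform", 0.0, 2.0),
        }
        res = fit_im2(mats, rowsA, rowsB, priors, n_sims=1500, tolerance=0.05, rng=rng)
        lo, hi = res.hpd95["IM2"]["t_split"]
        assert lo <= 0.5 <= hi
        acc = res.accepted["IM2"]
        assert (acc["two_NM_12"] == acc["m12"] / 2.0).all()
        assert "t_mut" in acc


class TestScalingIdentities:
    def test_population_migration_rate_formula(self):
        assert population_migration_rate(1.0, 2.0) == 1.0
        assert population_migration_rate(0.136, 3.0) == pytest.approx(0.204)

    def test_years_from_scaled(self):
        ts = TimeScale(mu_per_locus_year=1e-6, theta_ref=1.0)
        assert years_from_scaled(0.01, ts) == 10_000.0

    def test_published_style_pairing(self):
        # a mutation-scaled split time of 0.043 with mu = 6.23e-7 per locus
        # and year corresponds to roughly 69 thousand years
        ts = TimeScale(mu_per_locus_year=6.23e-7)
        assert years_from_scaled(0.043, ts) == pytest.approx(69_000, rel=0.01)

    def test_coalescent_units(self):
        ts = TimeScale(mu_per_locus_year=1e-6, theta_ref=1.0)
        assert coalescent_units(0.05, ts) == 0.05
        assert mutation_scaled_time(0.05, 2.0) == 0.1

    def test_invalid_timescale(self):
        with pytest.raises(ConfigError):
            TimeScale(mu_per_locus_year=0.0)


class TestThetaTrajectory:
    def test_bot_trajectory_steps_at_t_b(self):
        acc = pd.DataFrame(
            {"theta_site": np.full(100, 0.004), "t_b": np.full(100, 0.5),
             "severity": np.full(100, 0.1)}
        )
        out = theta_trajectory("BOT", acc, np.array([0.0, 0.4, 0.6]))
        assert out["q0.5"].tolist() == pytest.approx([0.004, 0.004, 0.04])

    def test_demography_builder_rejects_unknown_model(self):
        with pytest.raises(ConfigError):
            demography_from_params("XXX", {}, 400.0)
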