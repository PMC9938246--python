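"""Estimator arithmetic, oracles, and invariances for the MR suite."""

import numpy as np
import pytest
import statsmodels.api as sm

from ferromr import mr
from ferromr.summary import harmonise, select_instruments
from tests.conftest import make_instruments


class TestWaldRatio:
    def test_arithmetic(self):
        inst = make_instruments([0.10], [0.02], Gamma_se=0.01)[0]
        res = mr.wald_ratio(inst)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)

    def test_joint_sign_flip_invariance(self):
        a = mr.wald_ratio(make_instruments([0.10], [0.02])[0])
        b = mr.wald_ratio(make_instruments([-0.10], [-0.02])[0])
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mr.wald_ratio(make_instruments([0.0], [0.02])[0])

    def test_single_strong_snp_recovers_theta(self, medium_dataset):
        params, (exp_stats, out_stats, truth) = medium_dataset
        insts = [h for h in harmonise(exp_stats, out_stats) if h.usable]
        strongest = max(insts, key=lambda h: abs(h.exposure_beta / h.exposure_se))
        res = mr.wald_ratio(strongest)
        assert abs(res.beta - params.causal_effect_theta) < 2 * res.se


class TestIvwFixed:
    def test_single_snp_reduces_to_wald(self):
        insts = make_instruments([0.1], [0.02], Gamma_se=0.01)
        w, i = mr.wald_ratio(insts[0]), mr.ivw_fixed(insts)
        assert i.beta == pytest.approx(w.beta, rel=1e-12)
        assert i.se == pytest.approx(w.se, rel=1e-12)

    def test_matches_brute_force_weighted_mean_oracle(self):
        rng = np.random.default_rng(1)
        gamma = rng.uniform(0.05, 0.3, 12) * rng.choice([-1, 1], 12)
        Gamma = 0.2 * gamma + rng.normal(0, 0.01, 12)
        Gse = rng.uniform(0.01, 0.05, 12)
        insts = make_instruments(gamma, Gamma, Gamma_se=Gse)
        res = mr.ivw_fixed(insts)
        num = den = 0.0
        for g, G, s in zip(gamma, Gamma, Gse):
            w = g * g / (s * s)
            num += w * (G / g)
            den += w
        assert res.beta == pytest.approx(num / den, rel=1e-12)
        assert res.se == pytest.approx(den**-0.5, rel=1e-12)

    def test_equals_zero_intercept_wls_slope(self):
        rng = np.random.default_rng(2)
        gamma = rng.uniform(0.05, 0.3, 10)
        Gamma = 0.15 * gamma + rng.normal(0, 0.01, 10)
        Gse = rng.uniform(0.01, 0.05, 10)
        insts = make_instruments(gamma, Gamma, Gamma_se=Gse)
        wls = sm.WLS(Gamma, gamma[:, None], weights=1.0 / Gse**2).fit()
        assert mr.ivw_fixed(insts).beta == pytest.approx(wls.params[0], rel=1e-12)

    def test_identical_ratios_give_zero_q(self):
        gamma = np.array([0.1, 0.2, 0.3])
        insts = make_instruments(gamma, 0.25 * gamma)
        res = mr.ivw_fixed(insts)
        assert res.beta == pytest.approx(0.25, rel=1e-12)
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_q_nonnegative_and_zero_iff_ratios_equal(self):
        rng = np.random.default_rng(3)
        gamma = rng.uniform(0.05, 0.3, 8)
        insts = make_instruments(gamma, 0.2 * gamma + rng.normal(0, 0.05, 8))
        assert mr.ivw_fixed(insts).q_stat > 0

    def test_empty_set_fails(self):
        with pytest.raises(ValueError):
            mr.ivw_fixed([])


class TestEgger:
    def test_exact_line_recovered(self):
        gamma = np.linspace(0.05, 0.4, 8)
        Gamma = 0.01 + 0.2 * gamma
        res = mr.egger(make_instruments(gamma, Gamma))
        assert res.beta == pytest.approx(0.2, abs=1e-10)
        assert res.intercept == pytest.approx(0.01, abs=1e-10)
        assert res.q_stat == pytest.approx(0.0, abs=1e-16)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match=">= 3"):
            mr.egger(make_instruments([0.1, 0.2], [0.02, 0.04]))

    def test_zero_gamma_spread_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mr.egger(make_instruments([0.1, 0.1, 0.1], [0.01, 0.02, 0.03]))

    def test_orientation_invariance(self):
        gamma = np.array([0.1, -0.2, 0.3, -0.15])
        Gamma = 0.02 + 0.2 * np.abs(gamma)
        Gamma = Gamma * np.sign(gamma)
        # flipping any pair jointly must not change the fit
        a = mr.egger(make_instruments(gamma, Gamma))
        b = mr.egger(make_instruments(-gamma, -Gamma))
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        gamma = np.ones(3)
        insts = make_instruments(gamma, [0.1, 0.2, 0.3])
        res = mr.weighted_median(insts, n_boot=200, seed=0)
        assert res.beta == pytest.approx(0.2)

    def test_seeded_bootstrap_is_deterministic(self):
        gamma = np.linspace(0.1, 0.3, 5)
        insts = make_instruments(gamma, 0.2 * gamma + 0.01)
        a = mr.weighted_median(insts, n_boot=300, seed=7)
        b = mr.weighted_median(insts, n_boot=300, seed=7)
        assert a.se == b.se

    def test_needs_two_instruments_and_enough_boots(self):
        insts = make_instruments([0.1], [0.02])
        with pytest.raises(ValueError):
            mr.weighted_median(insts)
        with pytest.raises(ValueError, match="n_boot"):
            mr.weighted_median(make_instruments([0.1, 0.2], [0.02, 0.04]), n_boot=10)


class TestLeaveOneOut:
    def test_two_snp_reduction_to_walds(self):
        insts = make_instruments([0.1, 0.2], [0.02, 0.05])
        loo = mr.leave_one_out(insts)
        assert loo[0].label == "s0"
        assert loo[0].beta == pytest.approx(mr.wald_ratio(insts[1]).beta)
        assert loo[1].beta == pytest.approx(mr.wald_ratio(insts[0]).beta)

    def test_homogeneous_set_is_stable(self):
        rng = np.random.default_rng(4)
        gamma = rng.uniform(0.1, 0.3, 10)
        insts = make_instruments(gamma, 0.2 * gamma + rng.normal(0, 0.005, 10),
                                 Gamma_se=0.005)
        full = mr.ivw_fixed(insts)
        worst = max(abs(r.beta - full.beta) for r in mr.leave_one_out(insts))
        assert worst < full.se

    def test_excluding_planted_outlier_moves_estimate_toward_truth(self):
        gamma = np.full(6, 0.2)
        Gamma = 0.15 * gamma
        Gamma[0] += 0.1  # planted pleiotropic outlier
        insts = make_instruments(gamma, Gamma, Gamma_se=0.005)
        full = mr.ivw_fixed(insts)
        loo = {r.label: r for r in mr.leave_one_out(insts)}
        assert abs(loo["s0"].beta - 0.15) < abs(full.beta - 0.15)


class TestPresso:
    def planted(self):
        rng = np.random.default_rng(5)
        gamma = rng.uniform(0.1, 0.3, 10)
        Gamma = 0.15 * gamma + rng.normal(0, 0.004, 10)
        Gamma[3] += 0.08
        return make_instruments(gamma, Gamma, gamma_se=0.004, Gamma_se=0.004)

    def test_flags_planted_outlier_and_corrects(self):
        rep = mr.mr_presso(self.planted(), n_sim=1000, seed=0)
        assert rep.global_p < 0.05
        assert rep.outlier_ids == ("s3",)
        assert rep.corrected is not None
        raw = mr.ivw_fixed(self.planted())
        assert abs(rep.corrected.beta - 0.15) < abs(raw.beta - 0.15)

    def test_clean_set_not_flagged(self):
        rng = np.random.default_rng(6)
        gamma = rng.uniform(0.1, 0.3, 10)
        Gamma = 0.15 * gamma + rng.normal(0, 0.004, 10)
        rep = mr.mr_presso(make_instruments(gamma, Gamma, Gamma_se=0.004),
                           n_sim=1000, seed=1)
        assert rep.global_p > 0.05 and rep.outlier_ids == ()

    def test_deterministic_given_seed(self):
        a = mr.mr_presso(self.planted(), n_sim=500, seed=3)
        b = mr.mr_presso(self.planted(), n_sim=500, seed=3)
        assert a.global_p == b.global_p and a.per_snp_p == b.per_snp_p

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">= 4"):
            mr.mr_presso(make_instruments([0.1, 0.2, 0.3], [0.02, 0.04, 0.06]))
        with pytest.raises(ValueError, match="n_sim"):
            mr.mr_presso(self.planted(), n_sim=100)

    def test_global_p_respects_simulation_floor(self):
        rep = mr.mr_presso(self.planted(), n_sim=500, seed=2)
        assert rep.global_p >= 1 / 501


@pytest.mark.parametrize("estimator", [
    mr.ivw_fixed,
    lambda s: mr.weighted_median(s, n_boot=200, seed=0),
    mr.egger,
])
def test_sign_flip_invariance_of_all_estimators(estimator):
    rng = np.random.default_rng(8)
    gamma = rng.uniform(0.05, 0.3, 8)
    Gamma = 0.2 * gamma + rng.normal(0, 0.01, 8)
    insts = make_instruments(gamma, Gamma)
    flip = rng.choice([-1.0, 1.0], 8)
    flipped = make_instruments(gamma * flip, Gamma * flip)
    assert estimator(flipped).beta == pytest.approx(estimator(insts).beta, rel=1e-9)


def test_two_sample_recovery_through_full_path(medium_dataset):
    """End-to-end: simulate -> select -> harmonise -> IVW recovers theta within 2 SE."""
    params, (exp_stats, out_stats, _) = medium_dataset
    sel = select_instruments(exp_stats)
    insts = [h for h in harmonise(sel.snps, out_stats) if h.usable]
    res = mr.ivw_fixed(insts)
    assert abs(res.beta - params.causal_effect_theta) < 2 * res.se


def test_run_mr_suite_contains_all_methods(medium_dataset):
    _, (exp_stats, out_stats, _) = medium_dataset
    insts = [h for h in harmonise(exp_stats, out_stats) if h.usable]
    suite = mr.run_mr_suite(insts, seed=0, n_boot=200, presso_n_sim=500)
    assert set(suite) == {"ivw", "weighted_median", "leave_one_out", "egger", "presso"}
    assert len(suite["leave_one_out"]) == suite["ivw"].nsnp


class TestPleiotropyRegimes:
    """Egger and IVW agree under balanced pleiotropy; Egger is less biased
    under directional pleiotropy (paired over seeds)."""

    @staticmethod
    def _paired_estimates(mode, scale, n_seeds=30):
        from dataclasses import replace
        from ferromr.simulate import SimulationParams, make_two_sample_dataset
        base = SimulationParams(n_exposure_sample=25_000, n_outcome_sample=25_000,
                                n_snps=20, pleiotropy_mode=mode, pleiotropy_scale=scale)
        eggers, ivws = [], []
        for seed in range(n_seeds):
            exp_stats, out_stats, _ = make_two_sample_dataset(replace(base, seed=seed))
            insts = [h for h in harmonise(exp_stats, out_stats) if h.usable]
            eggers.append(mr.egger(insts).beta)
            ivws.append(mr.ivw_fixed(insts).beta)
        return np.mean(eggers), np.mean(ivws)

    def test_balanced_pleiotropy_egger_and_ivw_agree(self):
        e, i = self._paired_estimates("balanced", 0.03)
        assert abs(e - i) < 0.1

    def test_directional_pleiotropy_biases_ivw_more_than_egger(self):
        theta = 0.15
        e, i = self._paired_estimates("directional", 0.03)
        assert abs(e - theta) < abs(i - theta)
        assert abs(i - theta) > 0.05  # IVW is genuinely displaced
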