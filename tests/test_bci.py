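"""Tests for the two-level causal inference model."""

import math

import numpy as np
import pytest
from scipy.special import expit

from trisense.bci import (
    CONDITION_KEYS,
    CausalPriors,
    ConditionSpec,
    ModalityNoise,
    SelfMotionCoeffs,
    combine_ownership,
    default_conditions,
    infer_trial,
    make_stimulus_stream,
    pair_evidence,
    posterior_common_cause,
    predict_conditions,
    predict_self_motion,
    update_priors,
)


class TestStimulusStream:
    def test_event_counts_match_rates(self):
        """A 3-minute trial yields 90 stroke and 25 vestibular pulse events."""
        cond = ConditionSpec(duration=180.0, stroke_rate=0.5, gvs_period=7.0)
        stream = make_stimulus_stream(cond, ModalityNoise(), seed=0)
        assert len(stream.vt_disparities) == 90
        assert len(stream.vv_disparities) == 25

    def test_noiseless_synchronous_disparities_are_zero(self):
        tiny = ModalityNoise(sigma_v=1e-12, sigma_t=1e-12, sigma_vest=1e-12)
        stream = make_stimulus_stream(ConditionSpec(), tiny, seed=3)
        assert np.allclose(stream.vt_disparities, 0.0, atol=1e-10)
        assert np.allclose(stream.vv_disparities, 0.0, atol=1e-10)

    def test_deterministic_given_seed(self):
        cond = ConditionSpec(vt_sync=False)
        a = make_stimulus_stream(cond, ModalityNoise(), seed=42)
        b = make_stimulus_stream(cond, ModalityNoise(), seed=42)
        assert np.array_equal(a.vt_disparities, b.vt_disparities)
        assert np.array_equal(a.vv_disparities, b.vv_disparities)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            ConditionSpec(duration=-1.0)


class TestPosteriorCommonCause:
    def test_degenerate_prior(self):
        assert posterior_common_cause(5.0, 0.1, 0.1, 1.0, 1.0) == 1.0
        assert posterior_common_cause(0.0, 0.1, 0.1, 1.0, 0.0) == 0.0

    def test_zero_disparity_value(self):
        """Closed form: densities 2.8209 vs 0.2807 at zero -> posterior 0.9095."""
        p = posterior_common_cause(0.0, 0.1, 0.1, 1.0, 0.5)
        assert p == pytest.approx(0.9095, abs=1e-4)

    @pytest.mark.parametrize("x", [0.1, 0.5, 2.0, 10.0])
    def test_even_in_disparity(self, x):
        a = posterior_common_cause(x, 0.2, 0.3, 1.0, 0.4)
        b = posterior_common_cause(-x, 0.2, 0.3, 1.0, 0.4)
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_nonincreasing_in_abs_disparity(self):
        grid = np.linspace(0.0, 5.0, 101)
        vals = [posterior_common_cause(d, 0.1, 0.3, 1.0, 0.5) for d in grid]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            posterior_common_cause(0.0, 0.0, 0.1, 1.0, 0.5)


class TestPairEvidence:
    def test_single_event_equals_posterior(self):
        d, _ = pair_evidence([0.3], 0.1, 0.2, 1.0, 0.5)
        assert d == pytest.approx(posterior_common_cause(0.3, 0.1, 0.2, 1.0, 0.5), rel=1e-12)

    def test_reliability_linear_in_event_count(self):
        _, w1 = pair_evidence([0.0] * 10, 0.1, 0.2, 1.0, 0.5)
        _, w2 = pair_evidence([0.0] * 20, 0.1, 0.2, 1.0, 0.5)
        assert w2 == pytest.approx(2.0 * w1, rel=1e-12)

    def test_ninety_zero_disparity_events(self):
        d, w = pair_evidence([0.0] * 90, 0.1, 0.1, 1.0, 0.5)
        assert d == pytest.approx(0.9095, abs=1e-4)
        assert w == pytest.approx(90 / 0.02, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pair_evidence([], 0.1, 0.1, 1.0, 0.5)


class TestCombineOwnership:
    def test_degenerate_weight(self):
        assert combine_ownership(0.7, 3.0, 0.1, 0.0) == pytest.approx(0.7)

    def test_equal_weights_mean(self):
        assert combine_ownership(0.9, 2.0, 0.1, 2.0) == pytest.approx(0.5)

    def test_weighted_mean_example(self):
        assert combine_ownership(0.9, 4500.0, 0.1, 500.0) == pytest.approx(0.82)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            combine_ownership(0.5, 0.0, 0.5, 0.0)


class TestUpdatePriors:
    def test_zero_gain_no_change(self):
        priors = CausalPriors(gamma=0.0)
        updated = update_priors(priors, 1.0)
        assert updated.p_vt == priors.p_vt0 and updated.p_vv == priors.p_vv0

    def test_neutral_ownership_no_change(self):
        priors = CausalPriors(gamma=2.0)
        updated = update_priors(priors, 0.5)
        assert updated.p_vt == pytest.approx(priors.p_vt0)

    def test_full_ownership_logistic_shift(self):
        priors = CausalPriors(p_vt0=0.5, w_prior_vt=1.0, gamma=2.0)
        updated = update_priors(priors, 1.0)
        assert updated.p_vt == pytest.approx(expit(2.0), abs=1e-4)

    def test_clipping_bounds(self):
        priors = CausalPriors(p_vt0=0.9, w_prior_vt=1.0, gamma=50.0)
        assert update_priors(priors, 1.0).p_vt == 0.99
        assert update_priors(priors, 0.0).p_vt == 0.01


class TestInferTrial:
    def test_zero_gain_matches_single_pass(self):
        noise, priors = ModalityNoise(), CausalPriors(gamma=0.0)
        cond = ConditionSpec()
        est = infer_trial(cond, noise, priors, analytic=True)
        d_vt, w_vt = pair_evidence([0.0] * 90, noise.sigma_v, noise.sigma_t, noise.sigma_indep, 0.5)
        d_vv, w_vv = pair_evidence([0.0] * 25, noise.sigma_v, noise.sigma_vest, noise.sigma_indep, 0.5)
        assert est.d_own == pytest.approx(combine_ownership(d_vt, w_vt, d_vv, w_vv), rel=1e-9)

    def test_synchrony_raises_ownership(self):
        noise, priors = ModalityNoise(), CausalPriors()
        sync = infer_trial(ConditionSpec(), noise, priors, analytic=True)
        asyn = infer_trial(ConditionSpec(vt_sync=False, vv_sync=False), noise, priors, analytic=True)
        assert sync.d_own > asyn.d_own

    def test_tactile_dominance_in_default_regime(self):
        """With vestibular noise >> tactile noise, losing vestibular synchrony
        costs less ownership than losing tactile synchrony."""
        ests = predict_conditions()
        assert ests["AVV_SVT"].d_own - ests["SVV_AVT"].d_own > 0

    def test_ownership_bracketed_by_pairwise_estimates(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            noise = ModalityNoise(
                sigma_v=rng.uniform(0.02, 0.2),
                sigma_t=rng.uniform(0.03, 0.3),
                sigma_vest=rng.uniform(0.1, 1.0),
                sigma_indep=rng.uniform(0.5, 2.0),
            )
            priors = CausalPriors(gamma=rng.uniform(0.0, 2.0))
            for key, cond in default_conditions().items():
                est = infer_trial(cond, noise, priors, analytic=True)
                lo, hi = sorted((est.d_vt, est.d_vv))
                assert lo - 1e-9 <= est.d_own <= hi + 1e-9

    def test_fixed_point_converges_and_is_damping_independent(self):
        """The feedback fixed point converges for gamma in [0, 2] and does not
        depend on the damping factor."""
        import trisense.bci as bci_mod

        rng = np.random.default_rng(17)
        src = bci_mod.infer_trial

        def run_with_damping(cond, noise, priors, damping):
            # re-run the fixed-point loop with a different damping factor
            vt = np.full(cond.n_vt_events, cond.lag_vt)
            vv = np.full(cond.n_vv_events, cond.lag_vv)
            cur, d_own = priors, None
            for _ in range(400):
                d_vt, w_vt = pair_evidence(vt, noise.sigma_v, noise.sigma_t, noise.sigma_indep, cur.p_vt)
                d_vv, w_vv = pair_evidence(vv, noise.sigma_v, noise.sigma_vest, noise.sigma_indep, cur.p_vv)
                target = combine_ownership(d_vt, w_vt, d_vv, w_vv)
                new = target if d_own is None else d_own + damping * (target - d_own)
                if d_own is not None and abs(new - d_own) < 1e-9:
                    return new
                d_own = new
                cur = update_priors(priors, d_own)
            return d_own

        for _ in range(20):
            noise = ModalityNoise(
                sigma_v=rng.uniform(0.02, 0.15),
                sigma_t=rng.uniform(0.03, 0.3),
                sigma_vest=rng.uniform(0.1, 0.9),
            )
            priors = CausalPriors(
                p_vt0=rng.uniform(0.2, 0.8), p_vv0=rng.uniform(0.2, 0.8),
                gamma=rng.uniform(0.0, 2.0),
            )
            cond = ConditionSpec(vt_sync=bool(rng.integers(2)), vv_sync=bool(rng.integers(2)))
            est = src(cond, noise, priors, analytic=True)
            assert est.converged
            fps = [run_with_damping(cond, noise, priors, d) for d in (0.25, 0.5, 0.75)]
            assert max(fps) - min(fps) < 1e-5

    def test_vestibular_degeneracy(self):
        """As vestibular noise grows unbounded, ownership follows the
        visuo-tactile estimate and the vestibular main effect vanishes."""
        noise = ModalityNoise(sigma_vest=500.0)
        ests = predict_conditions(noise, CausalPriors())
        assert ests["SVV_SVT"].d_own == pytest.approx(ests["SVV_SVT"].d_vt, abs=1e-3)
        assert abs(ests["SVV_SVT"].d_own - ests["AVV_SVT"].d_own) < 1e-3
        assert abs(ests["SVV_AVT"].d_own - ests["AVV_AVT"].d_own) < 1e-3


class TestSelfMotion:
    def test_constant_when_gains_zero(self):
        coeffs = SelfMotionCoeffs(b0=1.2, b_vv=0.0, b_vis=0.0)
        for cond in default_conditions().values():
            est = infer_trial(cond, ModalityNoise(), CausalPriors(), analytic=True)
            assert predict_self_motion(est, cond, coeffs) == pytest.approx(1.2)

    def test_increasing_in_ownership(self):
        cond = ConditionSpec()
        coeffs = SelfMotionCoeffs(b_vis=1.0)
        ests = predict_conditions()
        low, high = ests["AVV_AVT"], ests["SVV_SVT"]
        m_low = coeffs.b0 + coeffs.b_vis * low.d_own
        m_high = coeffs.b0 + coeffs.b_vis * high.d_own
        assert m_high > m_low

    def test_mixed_conditions_near_equal(self):
        """Default coefficients make the two mixed conditions' predicted
        self-motion agree within 10%."""
        ests = predict_conditions()
        conds = default_conditions()
        m_avs = predict_self_motion(ests["AVV_SVT"], conds["AVV_SVT"])
        m_sva = predict_self_motion(ests["SVV_AVT"], conds["SVV_AVT"])
        assert abs(m_avs - m_sva) / max(m_avs, m_sva) < 0.10


class TestPredictConditions:
    def test_default_condition_ordering(self):
        ests = predict_conditions()
        d = {k: ests[k].d_own for k in CONDITION_KEYS}
        assert d["SVV_SVT"] >= d["AVV_SVT"] > d["SVV_AVT"] > d["AVV_AVT"]

    def test_pathway_symmetry_with_matched_noise_and_counts(self):
        """Equal sensory noise, equal lags and equal event counts make the
        two mixed conditions exactly interchangeable."""
        noise = ModalityNoise(sigma_t=0.2, sigma_vest=0.2)
        priors = CausalPriors()
        kw = dict(stroke_rate=0.5, gvs_period=2.0, duration=180.0)  # 90 events each
        a = infer_trial(
            ConditionSpec(vt_sync=True, vv_sync=False, lag_vv=1.0, **kw),
            noise, priors, analytic=True,
        )
        b = infer_trial(
            ConditionSpec(vt_sync=False, vv_sync=True, lag_vt=1.0, **kw),
            noise, priors, analytic=True,
        )
        assert a.d_own == pytest.approx(b.d_own, abs=1e-12)

    def test_population_correlation_signs(self):
        """Across a heterogeneous population the model-implied S1 latents show
        a negative dominance-vs-congruence correlation and a positive
        correlation between the two synchronous-vestibular conditions."""
        from trisense.stats import spearman
        from trisense.synth import draw_profiles

        profiles = draw_profiles(200, seed=23)
        lat = {k: [] for k in CONDITION_KEYS}
        for prof in profiles:
            ests = predict_conditions(prof.noise, prof.priors)
            for k in CONDITION_KEYS:
                d = min(max(ests[k].d_own, 1e-12), 1 - 1e-12)
                lat[k].append(
                    prof.latent_intercept + prof.random_intercept
                    + prof.latent_slope * math.log(d / (1 - d))
                )
        lat = {k: np.asarray(v) for k, v in lat.items()}
        r_neg = spearman(lat["SVV_SVT"] - lat["AVV_SVT"], lat["AVV_SVT"] - lat["SVV_AVT"])
        r_pos = spearman(lat["SVV_AVT"], lat["SVV_SVT"])
        assert r_neg.statistic < 0
        assert r_pos.statistic > 0
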