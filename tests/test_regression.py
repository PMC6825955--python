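"""Stimulus–response fits and standardized cue-weight regressions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monaural_adapt.listener import proximal_level, simulate_session
from monaural_adapt.regression import (
    CollinearityError,
    CollinearityWarning,
    fit_azimuth_cues,
    fit_elevation_cues,
    fit_stimulus_response,
    zscore,
)
from monaural_adapt.trials import (
    Condition,
    DoublePolarDirection,
    Phase,
    StimulusType,
    TrialRecord,
)


def make_cue_trials(t_az, t_el, levels, r_az=None, r_el=None):
    """Assemble TrialRecords from parallel arrays (responses default 0)."""
    n = len(t_az)
    r_az = np.zeros(n) if r_az is None else r_az
    r_el = np.zeros(n) if r_el is None else r_el
    return [
        TrialRecord(
            i + 1, Phase.PRE, Condition.PLUGGED, StimulusType.HP,
            float(levels[i]),
            DoublePolarDirection(float(t_az[i]), float(t_el[i])),
            DoublePolarDirection(float(r_az[i]), float(r_el[i])), None,
        )
        for i in range(n)
    ]


def random_cue_geometry(rng, n):
    t_az = rng.uniform(-60, 60, n)
    t_el = rng.uniform(-30, 30, n)
    levels = rng.choice([50.0, 60.0, 70.0], n)
    return t_az, t_el, levels


class TestZscore:
    def test_integer_triplet_is_exact(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            zscore([5, 5, 5])

    def test_output_standardized(self):
        x = np.random.default_rng(0).normal(3, 7, 1000)
        z = zscore(x)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10


class TestFitStimulusResponse:
    def test_identity_localizer(self):
        t = np.linspace(-60, 60, 20)
        fit = fit_stimulus_response(t, t)
        assert fit.gain == pytest.approx(1.0)
        assert fit.bias_deg == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.mae_deg == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_prior_captured_limit(self):
        t = np.array([-60.0, -30.0, 0.0, 30.0, 60.0])
        r = np.full_like(t, -35.0)
        fit = fit_stimulus_response(t, r)
        assert fit.gain == pytest.approx(0.0, abs=1e-12)
        assert fit.bias_deg == pytest.approx(-35.0)
        assert fit.mae_deg == pytest.approx(np.mean(np.abs(-35.0 - t)))

    def test_five_point_hand_computation(self):
        t = [-60, -30, 0, 30, 60]
        r = [-50, -40, -30, -20, -10]
        fit = fit_stimulus_response(t, r)
        assert fit.gain == pytest.approx(1 / 3)
        assert fit.bias_deg == pytest.approx(-30.0)

    def test_mae_uses_raw_error_not_residuals(self):
        # perfectly linear but biased: residual SD 0, MAE > 0
        t = np.linspace(-60, 60, 10)
        fit = fit_stimulus_response(t, t + 10.0)
        assert fit.residual_sd_deg == pytest.approx(0.0, abs=1e-10)
        assert fit.mae_deg == pytest.approx(10.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_stimulus_response([0, 1], [0, 1])
        with pytest.raises(ValueError, match="target variance"):
            fit_stimulus_response([5, 5, 5, 5], [1, 2, 3, 4])

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 30))
    def test_matches_normal_equations_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        t = rng.uniform(-60, 60, n)
        if np.std(t) == 0:
            return
        r = rng.normal(0, 20, n)
        fit = fit_stimulus_response(t, r)
        X = np.column_stack([np.ones(n), t])
        beta = np.linalg.solve(X.T @ X, X.T @ r)
        assert fit.bias_deg == pytest.approx(beta[0], abs=1e-8)
        assert fit.gain == pytest.approx(beta[1], abs=1e-8)


class TestAzimuthCues:
    def test_noiseless_linear_generative_self_consistency(self):
        """Exact OLS identity: the fitted weights are the generative weights
        divided by the sample SD of the constructed response (the response is
        itself z-scored by the model)."""
        rng = np.random.default_rng(1)
        t_az, t_el, levels = random_cue_geometry(rng, 300)
        iprox = np.array(
            [proximal_level(a, l) for a, l in zip(t_az, levels)]
        )
        r = 0.85 * zscore(t_az) - 0.42 * zscore(iprox)
        scale = np.std(r, ddof=1)
        trials = make_cue_trials(t_az, t_el, levels, r_az=r)
        cw = fit_azimuth_cues(trials)
        assert cw.p == pytest.approx(-0.42 / scale, abs=1e-6)
        assert cw.q == pytest.approx(0.85 / scale, abs=1e-6)
        assert cw.r2 == pytest.approx(1.0, abs=1e-10)

    def test_veridical_localizer_contract(self):
        """Responses equal to targets give p = 0, q = 1 exactly."""
        rng = np.random.default_rng(2)
        t_az, t_el, levels = random_cue_geometry(rng, 200)
        trials = make_cue_trials(t_az, t_el, levels, r_az=t_az)
        cw = fit_azimuth_cues(trials)
        assert cw.p == pytest.approx(0.0, abs=1e-6)
        assert cw.q == pytest.approx(1.0, abs=1e-6)

    def test_plugged_pre_session_signatures(self, pre_session):
        """Level weight negative, azimuth weight strictly inside (0, 1)."""
        cw = fit_azimuth_cues(pre_session)
        assert cw.p < 0
        assert 0 < cw.q < 1

    def test_single_level_refused_as_collinear(self):
        rng = np.random.default_rng(3)
        t_az, t_el, _ = random_cue_geometry(rng, 50)
        trials = make_cue_trials(t_az, t_el, np.full(50, 60.0), r_az=t_az)
        with pytest.raises(CollinearityError, match="distinct sound levels"):
            fit_azimuth_cues(trials)

    def test_near_collinear_design_warns_and_flags(self):
        rng = np.random.default_rng(4)
        # narrow azimuth range: sin(az) is numerically linear in az, and with
        # a nearly-constant level the proximal level tracks target azimuth
        t_az = rng.uniform(-5, 5, 50)
        levels = np.full(50, 60.0)
        levels[0] += 1e-7  # technically two levels, numerically one
        trials = make_cue_trials(t_az, np.zeros(50), levels, r_az=t_az)
        with pytest.warns(CollinearityWarning):
            cw = fit_azimuth_cues(trials)
        assert cw.warning is not None

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(5)
        t_az, t_el, levels = random_cue_geometry(rng, 5)
        with pytest.raises(ValueError, match="at least 10"):
            fit_azimuth_cues(make_cue_trials(t_az, t_el, levels))

    def test_orthogonalized_predictors_equal_simple_correlations(self):
        """With exactly orthogonal standardized predictors, each fitted
        weight equals the Pearson correlation with the response."""
        rng = np.random.default_rng(6)
        n = 400
        t_az = rng.uniform(-60, 60, n)
        levels = rng.choice([50.0, 60.0, 70.0], n)
        iprox = np.array([proximal_level(a, l) for a, l in zip(t_az, levels)])
        zi, zt = zscore(iprox), zscore(t_az)
        # orthogonalize the level regressor against azimuth, then rebuild a
        # level sequence whose proximal level reproduces it exactly
        zi_orth = zi - (zi @ zt) / (zt @ zt) * zt
        iprox_new = zi_orth  # any affine image works: z-scoring removes it
        levels_new = iprox_new - 10.0 * np.sin(np.radians(t_az)) + 60.0
        r = 0.3 * zt + 0.5 * zscore(iprox_new) + rng.normal(0, 0.4, n)
        trials = make_cue_trials(t_az, np.zeros(n), levels_new, r_az=r)
        cw = fit_azimuth_cues(trials)
        zr = zscore(r)
        zi2 = zscore([proximal_level(a, l) for a, l in zip(t_az, levels_new)])
        corr_p = float(np.corrcoef(zi2, zr)[0, 1])
        corr_q = float(np.corrcoef(zt, zr)[0, 1])
        assert cw.p == pytest.approx(corr_p, abs=1e-9)
        assert cw.q == pytest.approx(corr_q, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        t_az, t_el, levels = random_cue_geometry(rng, n)
        if np.unique(levels).size < 2:
            return
        r = rng.normal(0, 10, n)
        trials = make_cue_trials(t_az, t_el, levels, r_az=r)
        cw = fit_azimuth_cues(trials)
        iprox = np.array([proximal_level(a, l) for a, l in zip(t_az, levels)])
        X = np.column_stack([zscore(iprox), zscore(t_az)])
        beta = np.linalg.solve(X.T @ X, X.T @ zscore(r))
        assert cw.p == pytest.approx(beta[0], abs=1e-8)
        assert cw.q == pytest.approx(beta[1], abs=1e-8)


class TestElevationCues:
    def test_veridical_contract(self):
        """Noiseless veridical elevation responses give [p, q, s] = [0, 0, 1]."""
        rng = np.random.default_rng(7)
        t_az, t_el, levels = random_cue_geometry(rng, 200)
        trials = make_cue_trials(t_az, t_el, levels, r_el=t_el)
        cw = fit_elevation_cues(trials)
        assert cw.p == pytest.approx(0.0, abs=1e-6)
        assert cw.q == pytest.approx(0.0, abs=1e-6)
        assert cw.s == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_linear_generative_self_consistency(self):
        rng = np.random.default_rng(8)
        t_az, t_el, levels = random_cue_geometry(rng, 300)
        r = 0.5 * zscore(t_el) - 0.3 * zscore(t_az)
        scale = np.std(r, ddof=1)
        trials = make_cue_trials(t_az, t_el, levels, r_el=r)
        cw = fit_elevation_cues(trials)
        assert cw.s == pytest.approx(0.5 / scale, abs=1e-6)
        assert cw.q == pytest.approx(-0.3 / scale, abs=1e-6)
        assert cw.p == pytest.approx(0.0, abs=1e-6)

    def test_hemifield_split_excludes_midline(self):
        rng = np.random.default_rng(9)
        t_az = np.concatenate([rng.uniform(-60, -1, 30), np.zeros(10),
                               rng.uniform(1, 60, 30)])
        t_el = rng.uniform(-30, 30, 70)
        levels = np.tile([50.0, 60.0, 70.0], 24)[:70]
        trials = make_cue_trials(t_az, t_el, levels, r_el=t_el)
        left = fit_elevation_cues(trials, hemifield="left")
        right = fit_elevation_cues(trials, hemifield="right")
        assert left.n == 30 and right.n == 30

    def test_underfilled_hemifield_error_names_side(self):
        rng = np.random.default_rng(10)
        t_az = rng.uniform(1, 60, 30)  # right side only
        t_el = rng.uniform(-30, 30, 30)
        levels = np.tile([50.0, 60.0, 70.0], 10)
        trials = make_cue_trials(t_az, t_el, levels, r_el=t_el)
        with pytest.raises(ValueError, match="left"):
            fit_elevation_cues(trials, hemifield="left")

    def test_plugged_pre_spectral_weight_higher_on_hearing_side(self, pre_session):
        s_left = fit_elevation_cues(pre_session, hemifield="left").s
        s_right = fit_elevation_cues(pre_session, hemifield="right").s
        assert s_left > s_right


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_standardized_weights_recovered_within_3_se(self, seed):
        """Linear-generative sessions with unit-variance responses recover
        (p*, q*, s*) within 3 standard errors at n = 2000."""
        p_true, q_true, s_true = -0.30, 0.55, 0.60
        rng = np.random.default_rng(seed)
        n = 2000
        t_az, t_el, levels = random_cue_geometry(rng, n)
        iprox = np.array([proximal_level(a, l) for a, l in zip(t_az, levels)])
        zi, zt, ze = zscore(iprox), zscore(t_az), zscore(t_el)

        def response(weights, preds):
            signal = sum(w * z for w, z in zip(weights, preds))
            noise_var = 1.0 - np.var(signal, ddof=1)
            assert noise_var > 0.05
            return signal + rng.normal(0, np.sqrt(noise_var), n)

        r_az = response((p_true, q_true), (zi, zt))
        r_el = response((p_true, q_true, s_true), (zi, zt, ze))
        trials = make_cue_trials(t_az, t_el, levels, r_az=r_az, r_el=r_el)

        def se(X, y, coefs):
            resid = y - X @ coefs
            s2 = resid @ resid / (len(y) - X.shape[1])
            return np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))

        cw2 = fit_azimuth_cues(trials)
        X2 = np.column_stack([zi, zt])
        se2 = se(X2, zscore(r_az), np.array([cw2.p, cw2.q]))
        assert abs(cw2.p - p_true) < 3 * se2[0]
        assert abs(cw2.q - q_true) < 3 * se2[1]

        cw4 = fit_elevation_cues(trials)
        X4 = np.column_stack([zi, zt, ze])
        se4 = se(X4, zscore(r_el), np.array([cw4.p, cw4.q, cw4.s]))
        assert abs(cw4.p - p_true) < 3 * se4[0]
        assert abs(cw4.q - q_true) < 3 * se4[1]
        assert abs(cw4.s - s_true) < 3 * se4[2]


def test_generative_listener_weights_recovered(pre_model):
    """A simulated plugged session analyzed end-to-end recovers the response
    gain implied by the generative prior/likelihood widths."""
    trials = simulate_session(pre_model, "pre_test", 21, n_trials=1998)
    fit = fit_stimulus_response(
        [t.target.azimuth_deg for t in trials],
        [t.response.azimuth_deg for t in trials],
    )
    sp = pre_model.azimuth_prior.sd_deg
    ss = pre_model.azimuth_sensory_sd_deg
    g_expected = sp**2 / (sp**2 + ss**2)
    # three approximate SEs of the windowed slope at this n and noise level
    assert fit.gain == pytest.approx(g_expected, abs=0.05)
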