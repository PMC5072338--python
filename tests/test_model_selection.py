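import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import circaflux as cf
from circaflux.model_selection import (
    SCHEMES,
    aic,
    akaike_weights,
    attach_drivers,
    delta_aic,
    fit_spec,
    run_scheme,
    validation_r2,
)
from circaflux.stomatal_models import OscillatorParams, spec_from_key


@pytest.fixture(scope="module")
def merged_noiseless(env):
    truth = cf.TrueParams(
        noise_sd_leaf=0.0, noise_sd_gs=0.0, noise_sd_canopy=0.0, noise_sd_e=0.0,
        g0=0.01, amp_a=0.0, osc=OscillatorParams(g1m=4.0, g1a=0.0),
    )
    leaf, _ = cf.simulate_fluxes(env, truth)
    return attach_drivers(leaf, env)


class TestInformationCriterion:
    def test_aic_direct(self):
        assert aic(0.0, 2) == 4.0

    def test_single_model_weight_is_one(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_two_model_weights_hand_value(self):
        w = akaike_weights([10.0, 12.0])
        assert w == pytest.approx([0.73106, 0.26894], abs=1e-5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            delta_aic([])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=10))
    def test_weights_match_brute_force_normalization(self, aics):
        w = akaike_weights(aics)
        rel = [np.exp(-0.5 * (a - min(aics))) for a in aics]
        expected = [r / sum(rel) for r in rel]
        assert np.allclose(w, expected, atol=1e-12)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
        d = delta_aic(aics)
        assert d.min() == 0.0 and np.all(d >= 0.0)


class TestValidationR2:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.5, 4.0])
        assert validation_r2(obs, obs) == pytest.approx(1.0)

    def test_affine_transform_invariance(self):
        obs = np.array([1.0, 2.0, 3.5, 4.0, 7.0])
        assert validation_r2(obs, 2 * obs + 3) == pytest.approx(1.0)

    def test_constant_prediction_is_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(validation_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))


class TestFitSpec:
    def test_noiseless_medlyn_recovery(self, merged_noiseless):
        fit = fit_spec(spec_from_key("Med+g0"), merged_noiseless)
        assert fit.estimates["g0"] == pytest.approx(0.01, abs=1e-6)
        assert fit.estimates["g1"] == pytest.approx(4.0, abs=1e-6)

    def test_oscillator_noiseless_recovery(self, env):
        truth = cf.TrueParams(
            noise_sd_leaf=0.0, noise_sd_gs=0.0, noise_sd_canopy=0.0, noise_sd_e=0.0,
            g0=0.01, amp_a=0.0, osc=OscillatorParams(g1m=4.0, g1a=1.0, g1p=1.75 * np.pi),
        )
        leaf, _ = cf.simulate_fluxes(env, truth)
        merged = attach_drivers(leaf, env)
        merged = merged[merged["t_h"] >= 108.0]
        base = fit_spec(spec_from_key("Med+g0"), merged)
        osc = fit_spec(spec_from_key("Med+g0+Osc"), merged, g1m_source=base)
        assert osc.estimates["g1a"] == pytest.approx(1.0, rel=0.05)
        assert osc.estimates["g1p"] == pytest.approx(1.75 * np.pi, abs=0.05)

    def test_null_amplitude_within_two_se(self, env):
        """Data generated without a g1 oscillation: the estimated amplitude
        stays within 2 SE of zero in at least 90 % of noise replicates.

        White noise here: the reported SEs assume independent errors, so
        their calibration is checked under that assumption."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            truth = cf.TrueParams(
                seed=4000 + rep, amp_a=0.0, ar1_rho=0.0, osc=OscillatorParams(g1m=4.0, g1a=0.0)
            )
            leaf, _ = cf.simulate_fluxes(env, truth)
            merged = attach_drivers(leaf, env)
            merged = merged[merged["t_h"] >= 108.0]
            base = fit_spec(spec_from_key("Med+g0"), merged)
            osc = fit_spec(spec_from_key("Med+g0+Osc"), merged, g1m_source=base)
            hits += osc.estimates["g1a"] <= 2.0 * osc.standard_errors["g1a"]
        assert hits / n_rep >= 0.9

    def test_refit_is_deterministic(self, dataset):
        leaf = attach_drivers(dataset["leaf"], dataset["env"])
        leaf = leaf[(leaf["species"] == "bean") & (leaf["t_h"] >= 108.0)]
        base = fit_spec(spec_from_key("Med+g0"), leaf)
        f1 = fit_spec(spec_from_key("Med+g0+Osc"), leaf, g1m_source=base)
        f2 = fit_spec(spec_from_key("Med+g0+Osc"), leaf, g1m_source=base)
        assert f1.estimates == f2.estimates
        assert f1.aic == f2.aic

    def test_oscillator_nests_plain_model(self, dataset):
        """Inherited-g1m oscillator fits can always reach the plain model's
        likelihood by setting g1a to zero."""
        leaf = attach_drivers(dataset["leaf"], dataset["env"])
        leaf = leaf[(leaf["species"] == "cotton") & (leaf["t_h"] >= 108.0)]
        for key in ("Med", "Leu", "Bal", "Med+g0", "Leu+g0", "Bal+g0"):
            base = fit_spec(spec_from_key(key), leaf)
            osc = fit_spec(spec_from_key(key + "+Osc"), leaf, g1m_source=base)
            assert osc.loglik >= base.loglik - 1e-8
            assert osc.converged

    def test_too_few_points_rejected(self, merged_noiseless):
        with pytest.raises(ValueError):
            fit_spec(spec_from_key("Med+g0"), merged_noiseless.iloc[:3])


class TestSchemes:
    def test_three_legal_schemes(self):
        assert set(SCHEMES) == {"All->All", "Cha->Con", "Con->Cha"}

    def test_scheme_report_shape_and_weights(self, dataset):
        leaf = dataset["leaf"]
        tab = run_scheme(SCHEMES["Cha->Con"], leaf[leaf["t_h"] >= 108.0], dataset["env"])
        assert len(tab) == 12
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        d = tab["delta_aic"].to_numpy()
        assert (d >= 0).all() and (d == 0).sum() >= 1

    def test_empty_window_raises(self, dataset):
        leaf = dataset["leaf"]
        entrain_only = leaf[leaf["t_h"] < 100.0]
        with pytest.raises(ValueError, match="Cha->Con"):
            run_scheme(SCHEMES["Cha->Con"], entrain_only, dataset["env"])

    def test_noiseless_null_truth_gives_no_oscillator_advantage(self, env):
        """Without a true oscillation the oscillator spec cannot beat its
        nested parent by more than the parameter penalty on noiseless data."""
        truth = cf.TrueParams(
            noise_sd_leaf=0.0, noise_sd_gs=0.0, noise_sd_canopy=0.0, noise_sd_e=0.0,
            amp_a=0.0, osc=OscillatorParams(g1m=4.0, g1a=0.0),
        )
        leaf, _ = cf.simulate_fluxes(env, truth)
        leaf = leaf[leaf["t_h"] >= 108.0]
        tab = run_scheme(SCHEMES["All->All"], leaf, env)
        for family in ("Medlyn", "Leuning", "BallBerry"):
            for g0 in (False, True):
                pair = tab[(tab["family"] == family) & (tab["g0"] == g0)]
                plain = pair[~pair["oscillator"]]["aic"].iloc[0]
                osc = pair[pair["oscillator"]]["aic"].iloc[0]
                assert plain <= osc + 2.0 + 1e-6
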