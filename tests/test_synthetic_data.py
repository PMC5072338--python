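from dataclasses import replace

import numpy as np
import pytest

import circaflux as cf
from circaflux.stomatal_models import OscillatorParams


class TestEnvironment:
    def test_constant_onset_holds_solar_noon_values(self, env, protocol):
        onset = env[env["phase"] == "constant"].iloc[0]
        assert onset["t_h"] == protocol.constant_start_h
        assert onset["par"] == 500.0
        assert onset["tair_c"] == pytest.approx(28.0)
        assert onset["vpd_kpa"] == pytest.approx(1.7)

    def test_constant_phase_drivers_are_frozen(self, env):
        const = env[env["phase"] == "constant"]
        for col in ("par", "tair_c", "vpd_kpa"):
            assert const[col].nunique() == 1

    def test_zero_constant_hours_gives_pure_entrainment(self):
        env = cf.generate_environment(cf.ProtocolConfig(constant_hours=0.0))
        assert (env["phase"] == "entrainment").all()

    def test_entrainment_respects_printed_extremes(self, env):
        ent = env[env["phase"] == "entrainment"]
        assert set(np.unique(ent["par"])) == {0.0, 500.0}
        assert ent["tair_c"].min() >= 19.0 and ent["tair_c"].max() <= 28.0
        assert ent["vpd_kpa"].min() >= 0.5 and ent["vpd_kpa"].max() <= 1.7
        # 12 h photoperiod: half of each full entrainment day is lit
        day1 = ent[ent["t_h"] < 24.0]
        assert (day1["par"] > 0).mean() == pytest.approx(0.5, abs=0.01)

    def test_subjective_day_matches_lit_window(self, env, protocol):
        hod = np.mod(env["t_h"].to_numpy(), 24.0)
        expected = (hod >= protocol.lights_on_h) & (hod < protocol.lights_on_h + 12.0)
        assert np.array_equal(env["subjective_day"].to_numpy(), expected)

    @pytest.mark.parametrize("bad", [dict(step_h=0.0), dict(entrainment_days=0), dict(constant_hours=-1.0)])
    def test_invalid_protocol_rejected(self, bad):
        with pytest.raises(ValueError):
            cf.ProtocolConfig(**bad)


class TestFluxes:
    def test_noiseless_no_oscillation_is_constant(self, env, noiseless_truth):
        truth = replace(noiseless_truth, amp_a=0.0, osc=OscillatorParams(g1m=4.0, g1a=0.0))
        leaf, canopy = cf.simulate_fluxes(env, truth)
        const = leaf[leaf["t_h"] >= 132.0]
        assert const["gs"].nunique() == 1
        assert const["a_leaf"].nunique() == 1
        cc = canopy[canopy["t_h"] >= 132.0]
        assert np.ptp(cc["a_canopy"].to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_gs_is_24h_periodic_under_constant_conditions(self, env, noiseless_truth):
        leaf, _ = cf.simulate_fluxes(env, noiseless_truth)
        const = leaf[(leaf["t_h"] >= 132.0) & (leaf["macrocosm_id"] == 1)]
        for t in const["t_h"]:
            if t + 24.0 <= const["t_h"].max():
                g1 = const.loc[const["t_h"] == t, "gs"].iloc[0]
                g2 = const.loc[const["t_h"] == t + 24.0, "gs"].iloc[0]
                assert g1 == pytest.approx(g2, abs=1e-12)

    def test_canopy_range_is_diluted_leaf_range(self, env, noiseless_truth):
        truth = replace(noiseless_truth, amp_a=0.3, dilution=0.5, osc=OscillatorParams(g1m=4.0, g1a=0.0))
        leaf, canopy = cf.simulate_fluxes(env, truth)
        rng_leaf = np.ptp(leaf.loc[leaf["t_h"] >= 132.0, "a_leaf"].to_numpy())
        rng_can = np.ptp(canopy.loc[canopy["t_h"] >= 132.0, "a_canopy"].to_numpy())
        assert rng_can / rng_leaf == pytest.approx(0.5, rel=1e-9)

    def test_no_assimilation_in_the_dark(self, env):
        leaf, _ = cf.simulate_fluxes(env, cf.TrueParams(seed=3))
        merged = leaf.merge(env[["t_h", "par"]], on="t_h")
        assert (merged.loc[merged["par"] == 0.0, "a_leaf"] == 0.0).all()

    def test_gs_nonnegative(self, dataset):
        assert (dataset["leaf"]["gs"] >= 0.0).all()

    def test_dilution_monotonicity(self, env, noiseless_truth):
        ranges = []
        for dil in (0.2, 0.5, 0.8, 1.0):
            truth = replace(noiseless_truth, dilution=dil)
            _, canopy = cf.simulate_fluxes(env, truth)
            ranges.append(np.ptp(canopy.loc[canopy["t_h"] >= 132.0, "a_canopy"].to_numpy()))
        assert all(a <= b + 1e-12 for a, b in zip(ranges, ranges[1:]))

    def test_ground_truth_amplitude_recoverable_by_harmonic_regression(self, env):
        """Constant-phase gs regressed on sin/cos(2*pi*t/24) recovers the
        oscillator-driven amplitude within 3 sigma over Monte Carlo replicates."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            truth = cf.TrueParams(seed=9000 + rep, amp_a=0.0)
            leaf, _ = cf.simulate_fluxes(env, truth)
            const = leaf[leaf["t_h"] >= 132.0]
            t = const["t_h"].to_numpy()
            y = const["gs"].to_numpy()
            x = np.column_stack([np.ones_like(t), np.sin(2 * np.pi * t / 24), np.cos(2 * np.pi * t / 24)])
            beta, res, *_ = np.linalg.lstsq(x, y, rcond=None)
            amp_hat = float(np.hypot(beta[1], beta[2]))
            sigma2 = float(res[0]) / (len(y) - 3)
            cov = sigma2 * np.linalg.inv(x.T @ x)
            se_amp = float(np.sqrt((beta[1] ** 2 * cov[1, 1] + beta[2] ** 2 * cov[2, 2]) / amp_hat**2))
            # expected gs amplitude implied by the g1 oscillation
            const_env = env[env["phase"] == "constant"].iloc[0]
            a_const = const["a_leaf"].mean()
            amp_true = 1.6 * a_const / (const_env["ca_umol_mol"] * np.sqrt(const_env["vpd_kpa"])) * truth.osc.g1a
            hits += abs(amp_hat - amp_true) <= 3 * se_amp
        assert hits / n_rep >= 0.9


class TestLysimeter:
    def test_zero_flux_keeps_mass_constant(self):
        t = np.arange(0, 10.5, 0.5)
        mass = cf.simulate_lysimeter(np.zeros_like(t), t, initial_mass=1000.0)
        assert np.allclose(mass, 1000.0)

    def test_constant_flux_exact_integral(self):
        t = np.arange(0, 10.01, 0.2)
        mass = cf.simulate_lysimeter(np.full_like(t, 0.4), t, initial_mass=1000.0)
        assert mass[0] - mass[-1] == pytest.approx(4.0)

    def test_same_seed_reproduces(self):
        t = np.arange(0, 10.01, 0.2)
        e = np.full_like(t, 0.3)
        m1 = cf.simulate_lysimeter(e, t, noise_sd=0.05, seed=5)
        m2 = cf.simulate_lysimeter(e, t, noise_sd=0.05, seed=5)
        assert np.array_equal(m1, m2)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            cf.simulate_lysimeter(np.zeros(5), np.arange(5.0), noise_sd=-1.0)


class TestReproducibility:
    def test_identical_seed_gives_byte_identical_csv(self, tmp_path):
        paths = []
        for i in (1, 2):
            data = cf.generate_dataset(seed=42)
            p = tmp_path / f"leaf{i}.csv"
            data["leaf"].to_csv(p, index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            cf.TrueParams(amp_a=1.5)
        with pytest.raises(ValueError):
            cf.TrueParams(dilution=0.0)
        with pytest.raises(ValueError):
            cf.TrueParams(noise_sd_leaf=-0.1)
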