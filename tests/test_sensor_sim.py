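"""Simulator unit and property tests: kinetics, determinism, labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nosecam.sensor_sim import (
    ADSORPTION_END_S,
    CATEGORIES,
    CONCENTRATIONS,
    N_CHANNELS,
    N_RAW_POINTS,
    SAMPLING_HZ,
    AffinityModel,
    KineticParams,
    MoleculeSpec,
    default_affinity_model,
    generate_dataset,
    noiseless_trace,
    simulate_trace,
)


def hydrocarbon(solvent_id="hexane_like"):
    return MoleculeSpec(solvent_id, "aliphatic hydrocarbons", 0, False, False)


class TestMoleculeSpec:
    def test_oxygen_consistency_enforced(self):
        with pytest.raises(ValueError, match="has_oxygen"):
            MoleculeSpec("x", "esters", 2, False, False)
        with pytest.raises(ValueError, match="implies has_oxygen"):
            MoleculeSpec("x", "alcohols", 0, False, False)

    def test_aromatics_imply_ring(self):
        with pytest.raises(ValueError, match="implies has_ring"):
            MoleculeSpec("x", "aromatic hydrocarbons", 0, False, False)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            MoleculeSpec("x", "noble gases", 0, False, False)


class TestKineticParams:
    @given(
        amp=st.floats(-2, 2),
        tau_a=st.floats(-1, 20),
        tau_d=st.floats(-1, 50),
        r=st.floats(-0.5, 1.5),
    )
    @settings(max_examples=60, deadline=None)
    def test_validation_matches_invariants(self, amp, tau_a, tau_d, r):
        valid = amp >= 0 and tau_a > 0 and tau_d > 0 and 0 <= r <= 1
        if valid:
            KineticParams(amp, tau_a, tau_d, r)
        else:
            with pytest.raises(ValueError):
                KineticParams(amp, tau_a, tau_d, r)


class TestKineticsClosedForm:
    """Noiseless traces follow the piecewise exponential exactly."""

    def test_end_of_adsorption_value(self):
        # A_eff=1, tau_ads=10 -> S(30) = 1 - e^-3
        p = KineticParams(1.0, 10.0, 20.0, 0.0)
        s = noiseless_trace(p, gain=1.0)
        i30 = int(ADSORPTION_END_S * SAMPLING_HZ)
        assert s[i30] == pytest.approx(1 - np.exp(-3), abs=1e-12)
        assert s[i30] == pytest.approx(0.95021, abs=1e-5)

    def test_full_grid_matches_formula(self, noiseless_model):
        mol = hydrocarbon()
        tr = simulate_trace(mol, 5, 20, noiseless_model, rng_seed=0)
        p = noiseless_model.params_for(mol, 5)
        a = p.amplitude * noiseless_model.concentration_gain[20]
        t = tr.time_s
        ads = t <= ADSORPTION_END_S
        expect = np.where(
            ads,
            a * (1 - np.exp(-t / p.tau_ads)),
            a * (1 - np.exp(-ADSORPTION_END_S / p.tau_ads))
            * (p.residual_frac + (1 - p.residual_frac) * np.exp(-(t - ADSORPTION_END_S) / p.tau_des)),
        )
        np.testing.assert_allclose(tr.signal, expect, atol=1e-12)

    def test_continuity_at_phase_boundary(self):
        # adsorption value at t=30 equals the desorption start value exactly
        p = KineticParams(1.3, 7.0, 25.0, 0.4)
        s = noiseless_trace(p, gain=1.0)
        i30 = int(ADSORPTION_END_S * SAMPLING_HZ)
        ads_value = p.amplitude * (1 - np.exp(-ADSORPTION_END_S / p.tau_ads))
        assert s[i30] == ads_value  # t=30 belongs to the adsorption branch
        # one step later the desorption branch starts from exactly S(30)
        des_next = ads_value * (p.residual_frac + (1 - p.residual_frac) * np.exp(-0.05 / p.tau_des))
        assert s[i30 + 1] == pytest.approx(des_next, abs=1e-15)

    def test_full_residual_keeps_purge_constant(self):
        p = KineticParams(1.0, 10.0, 20.0, 1.0)
        s = noiseless_trace(p, gain=1.0)
        i30 = int(ADSORPTION_END_S * SAMPLING_HZ)
        assert s[-1] == pytest.approx(s[i30], abs=1e-15)

    def test_zero_amplitude_gives_zero_trace(self):
        s = noiseless_trace(KineticParams(0.0, 10.0, 20.0, 0.3), gain=1.0)
        assert np.all(s == 0)

    def test_phase_monotonicity(self, noiseless_model):
        tr = simulate_trace(hydrocarbon(), 3, 10, noiseless_model, rng_seed=0)
        i30 = int(ADSORPTION_END_S * SAMPLING_HZ)
        assert np.all(np.diff(tr.signal[: i30 + 1]) >= 0)
        assert np.all(np.diff(tr.signal[i30:]) <= 0)

    def test_strictly_increasing_in_concentration(self, noiseless_model):
        mol = hydrocarbon()
        traces = [simulate_trace(mol, 2, c, noiseless_model, 0).signal for c in CONCENTRATIONS]
        for lo, hi in zip(traces, traces[1:]):
            pos = lo > 0
            assert np.all(hi[pos] > lo[pos])


class TestSimulateTraceContracts:
    def test_rejects_unknown_channel_and_concentration(self, default_model):
        with pytest.raises(ValueError, match="channel"):
            simulate_trace(hydrocarbon(), 15, 20, default_model, 0)
        with pytest.raises(ValueError, match="concentration"):
            simulate_trace(hydrocarbon(), 1, 15, default_model, 0)

    def test_negative_noise_rejected(self, default_model):
        with pytest.raises(ValueError, match="noise_sigma"):
            default_affinity_model(noise_sigma=-0.1)

    def test_noise_reproducible_given_seed(self, default_model):
        a = simulate_trace(hydrocarbon(), 1, 20, default_model, 123).signal
        b = simulate_trace(hydrocarbon(), 1, 20, default_model, 123).signal
        c = simulate_trace(hydrocarbon(), 1, 20, default_model, 124).signal
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_grid_is_20hz_over_120s(self, default_model):
        tr = simulate_trace(hydrocarbon(), 1, 5, default_model, 0)
        assert tr.time_s[0] == 0.0
        assert tr.time_s[-1] == 120.0
        assert len(tr.time_s) == N_RAW_POINTS
        np.testing.assert_allclose(np.diff(tr.time_s), 0.05)


class TestGenerateDataset:
    def test_counts_and_structure(self, dataset42):
        samples, manifest = dataset42
        assert len(samples) == 45
        assert all(len(s.traces) == 42 for s in samples)
        assert manifest["n_samples"] == 45
        assert set(manifest["affinity_model"]["planted_channels"]) >= set(CATEGORIES)

    def test_determinism_bitwise(self):
        a, _ = generate_dataset(2, seed=42)
        b, _ = generate_dataset(2, seed=42)
        for sa, sb in zip(a, b):
            assert sa.molecule == sb.molecule
            for key in sa.traces:
                np.testing.assert_array_equal(sa.traces[key].signal, sb.traces[key].signal)

    def test_different_seeds_differ(self):
        a, _ = generate_dataset(1, seed=1)
        b, _ = generate_dataset(1, seed=2)
        assert any(
            not np.array_equal(a[i].traces[k].signal, b[i].traces[k].signal)
            for i in range(len(a)) for k in a[i].traces
        )

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(0, seed=1)

    def test_esters_dominate_channel3_adsorption_peak(self):
        """Planted affinity: esters' raw end-of-adsorption signal on channel 3
        is on average strictly larger than every other category's (oracle:
        direct noiseless simulation of the generated molecules)."""
        model = default_affinity_model(noise_sigma=0.0)
        samples, _ = generate_dataset(5, model=model, seed=1)
        i30 = int(ADSORPTION_END_S * SAMPLING_HZ)
        means = {}
        for cat in CATEGORIES:
            vals = [
                s.traces[(3, 20)].signal[i30]
                for s in samples if s.molecule.category == cat
            ]
            means[cat] = np.mean(vals)
        best = max(means, key=means.get)
        assert best == "esters"
        for cat in CATEGORIES:
            if cat != "esters":
                assert means["esters"] > means[cat]

    def test_manifest_roundtrips_model(self, dataset42):
        _, manifest = dataset42
        model = AffinityModel.from_dict(manifest["affinity_model"])
        assert model.planted_channels["esters"] == 3
        assert model.base_params[(3, "esters")].amplitude > 0


def test_channels_8_and_9_share_kinetics(default_model):
    for cat in CATEGORIES:
        p8 = default_model.base_params[(8, cat)]
        p9 = default_model.base_params[(9, cat)]
        assert p9.amplitude == pytest.approx(p8.amplitude + 0.05)
        assert (p9.tau_ads, p9.tau_des, p9.residual_frac) == (
            p8.tau_ads, p8.tau_des, p8.residual_frac)
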