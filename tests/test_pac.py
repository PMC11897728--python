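"""Phase-amplitude coupling: extraction, MVL, surrogates, comodulograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emopac import pac

SR = 256.0


def trials_of(signal_fn, n_trials=8, seconds=10.0, rng=None):
    n = int(seconds * SR)
    t = np.arange(n) / SR
    rows = []
    for k in range(n_trials):
        rows.append(signal_fn(t, k, rng))
    return np.stack(rows)


class TestExtraction:
    def test_phase_advances_at_tone_frequency(self):
        t = np.arange(int(10 * SR)) / SR
        sig = np.cos(2 * np.pi * 5.0 * t)[None, :]
        phase = pac.extract_phase(sig, (3.0, 7.0), SR)
        unwrapped = np.unwrap(phase[0])
        sl = slice(256, -256)
        rate = np.polyfit(t[sl], unwrapped[sl], 1)[0]
        assert rate == pytest.approx(2 * np.pi * 5.0, rel=0.01)

    def test_cosine_phase_zero_at_peak(self):
        t = np.arange(int(10 * SR)) / SR
        sig = np.cos(2 * np.pi * 5.0 * t)[None, :]
        phase = pac.extract_phase(sig, (3.0, 7.0), SR)
        peak = int(round(5 * SR / 5.0))  # a peak well inside the window
        assert abs(phase[0, peak]) < 0.05

    def test_uniform_phase_coverage_of_pure_tone(self):
        t = np.arange(int(20 * SR)) / SR
        sig = np.cos(2 * np.pi * 5.0 * t)[None, :]
        phase = pac.extract_phase(sig, (3.0, 7.0), SR)[0, 256:-256]
        resultant = np.abs(np.mean(np.exp(1j * phase)))
        assert resultant < 0.05

    def test_envelope_of_pure_tone(self):
        t = np.arange(int(10 * SR)) / SR
        sig = 3.0 * np.sin(2 * np.pi * 40.0 * t)[None, :]
        env = pac.extract_amplitude(sig, (30.0, 50.0), SR)[0, 256:-256]
        assert env.mean() == pytest.approx(3.0, rel=0.02)

    def test_zero_signal_zero_envelope(self):
        env = pac.extract_amplitude(np.zeros((2, 512)), (30.0, 50.0), SR)
        assert np.allclose(env, 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            pac.extract_phase(np.zeros((1, 512)), (50.0, 200.0), SR)


class TestMvl:
    def test_uniform_phase_constant_amplitude_near_zero(self):
        phi = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        assert pac.mvl(phi, np.ones_like(phi)) < 1e-3

    @pytest.mark.parametrize("m", [0.2, 0.4, 0.6, 0.8])
    def test_closed_form_m_over_two(self, m):
        phi = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        value = pac.mvl(phi, 1.0 + m * np.cos(phi))
        assert value == pytest.approx(m / 2, rel=0.01)

    def test_single_sample_returns_amplitude(self):
        assert pac.mvl(np.array([0.7]), np.array([2.5])) == pytest.approx(2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pac.mvl(np.array([]), np.array([]))

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(0.1, 20.0), st.integers(0, 2 ** 16 - 1))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-np.pi, np.pi, 500)
        a = rng.gamma(2.0, size=500)
        assert pac.mvl(phi, c * a) == pytest.approx(c * pac.mvl(phi, a), rel=1e-9)


class TestSurrogateNormalize:
    def coupled_trials(self, m, n_trials=12, rng=None):
        rng = rng or np.random.default_rng(0)
        n = int(10 * SR)
        t = np.arange(n) / SR
        phases, amps = [], []
        for _ in range(n_trials):
            theta = rng.uniform(0, 2 * np.pi)
            phi = 2 * np.pi * 5.0 * t + theta
            phases.append(np.angle(np.exp(1j * phi)))
            amps.append(1.0 + m * np.cos(phi) + 0.05 * rng.standard_normal(n))
        return np.stack(phases), np.stack(amps)

    def test_seeded_determinism(self):
        phase, amp = self.coupled_trials(0.5)
        a = pac.surrogate_normalize(phase, amp, seed=4)
        b = pac.surrogate_normalize(phase, amp, seed=4)
        assert a == b

    def test_strong_coupling_exceeds_normal_criterion(self):
        phase, amp = self.coupled_trials(0.8, n_trials=30)
        out = pac.surrogate_normalize(phase, amp, seed=1)
        assert out["value"] > 3.29

    def test_normalized_value_invariant_to_amplitude_scale(self):
        phase, amp = self.coupled_trials(0.5)
        a = pac.surrogate_normalize(phase, amp, seed=2)
        b = pac.surrogate_normalize(phase, amp * 12.0, seed=2)
        assert b["value"] == pytest.approx(a["value"], rel=1e-9)
        assert b["raw"] == pytest.approx(12.0 * a["raw"], rel=1e-9)

    def test_uncoupled_noise_is_roughly_standard_normal(self):
        rng = np.random.default_rng(7)
        values = []
        for _ in range(60):
            phase = rng.uniform(-np.pi, np.pi, (8, 400))
            amp = rng.gamma(2.0, size=(8, 400))
            values.append(pac.surrogate_normalize(
                phase, amp, n_surrogates=150,
                seed=int(rng.integers(2 ** 31)))["value"])
        values = np.asarray(values)
        assert abs(values.mean()) < 0.35
        assert 0.7 < values.std() < 1.45

    def test_relative_mode(self):
        phase, amp = self.coupled_trials(0.5)
        out = pac.surrogate_normalize(phase, amp, seed=3, mode="relative")
        assert out["value"] == pytest.approx(
            (out["raw"] - out["surrogate_mean"]) / out["surrogate_mean"])

    def test_too_few_trials_rejected(self):
        phase, amp = self.coupled_trials(0.5, n_trials=3)
        with pytest.raises(ValueError):
            pac.surrogate_normalize(phase, amp)


class TestComodulogram:
    def test_injected_path_and_band_dominate(self, coupled_dataset):
        lflp = pac.comodulogram(coupled_dataset, "LF-LP", "neutral", seed=1)
        rfrp = pac.comodulogram(coupled_dataset, "RF-RP", "neutral", seed=2)
        assert pac.band_feature(lflp, "theta", "low_gamma") > 3.29
        assert (pac.band_feature(lflp, "theta", "low_gamma")
                > pac.band_feature(lflp, "alpha", "high_gamma"))
        assert pac.zscore_mask(lflp, cluster_k=12).any()
        assert not pac.zscore_mask(rfrp, cluster_k=12).any()

    def test_grand_average_of_opposite_matrices_is_zero(self):
        grid = pac.BandGrid()
        values = np.random.default_rng(0).standard_normal(
            (len(grid.phase_centers), len(grid.amp_centers)))
        m = pac.PACMatrix(values=values, phase_freqs=grid.phase_centers,
                          amp_freqs=grid.amp_centers, path="LF-LP",
                          condition="happy")
        neg = pac.PACMatrix(values=-values, phase_freqs=grid.phase_centers,
                            amp_freqs=grid.amp_centers, path="LF-LP",
                            condition="happy")
        grand = pac.grand_average_pac([m, neg])
        assert np.allclose(grand.values, 0.0)
        assert grand.level == "grand_average"

    def test_missing_cluster_channels_rejected(self, coupled_dataset):
        import dataclasses

        broken = dataclasses.replace(
            coupled_dataset,
            data=coupled_dataset.data[:, :6, :],
            channel_names=coupled_dataset.channel_names[:6],
            channel_positions=None)
        with pytest.raises(KeyError):
            pac.comodulogram(broken, "LF-LP", "neutral")


class TestBandFeature:
    def constant_matrix(self, c=2.0):
        grid = pac.BandGrid()
        return pac.PACMatrix(
            values=np.full((len(grid.phase_centers), len(grid.amp_centers)), c),
            phase_freqs=grid.phase_centers, amp_freqs=grid.amp_centers)

    def test_constant_matrix_gives_constant(self):
        assert pac.band_feature(self.constant_matrix(2.5), "theta",
                                "low_gamma") == pytest.approx(2.5)

    def test_partition_additivity(self):
        rng = np.random.default_rng(2)
        m = self.constant_matrix()
        m.values = rng.standard_normal(m.values.shape)
        total, weight = 0.0, 0
        for pband, (plo, phi) in pac.PHASE_BANDS.items():
            for aband, (alo, ahi) in pac.AMP_BANDS.items():
                rows = ((m.phase_freqs >= plo) & (m.phase_freqs < phi)).sum()
                cols = ((m.amp_freqs >= alo) & (m.amp_freqs < ahi)).sum()
                total += pac.band_feature(m, pband, aband) * rows * cols
                weight += rows * cols
        assert total / weight == pytest.approx(m.values.mean())

    def test_unknown_band_rejected(self):
        with pytest.raises(KeyError):
            pac.band_feature(self.constant_matrix(), "beta", "low_gamma")

    def test_feature_labels(self):
        assert pac.feature_label("happy", "theta", "high_gamma") == "Happy-T-HG"
        assert pac.feature_label("neutral", "delta", "low_gamma") == "Neutral-D-LG"


def test_coupling_path_roles():
    cp = pac.CouplingPath("RF-LP")
    assert cp.phase_cluster == "RF"
    assert cp.amp_cluster == "LP"
    with pytest.raises(ValueError):
        pac.CouplingPath("LP-LF")
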