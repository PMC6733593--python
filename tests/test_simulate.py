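"""Simulator contracts: kernel shape, presence balance, SNR bound,
orthogonality of the two spatial patterns, and determinism."""


import numpy as np
import pytest

from dualdecode.epochs import EpochsSet
from dualdecode.simulate import (ChannelSplit, SimulationConfig,
                                 default_channel_split, draw_presence,
                                 generate_cohort, generate_dataset,
                                 make_erp_kernel)


def phi_coefficient(a, b):
    """Correlation of two boolean vectors (test-local oracle)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


# ----------------------------------------------------------------------
class TestErpKernel:
    times = np.arange(0.0, 701.0)  # 1 ms grid so stated instants are exact

    @pytest.mark.parametrize("t_ms, expected", [
        (400.0, 1.0),                      # midpoint: sin(pi/2)
        (300.0, np.sin(np.pi / 4.0)),      # quarter point
        (200.0, 0.0),                      # onset
        (600.0, 0.0),                      # offset
        (100.0, 0.0),                      # before onset
        (650.0, 0.0),                      # after offset
    ])
    def test_half_sine_values(self, t_ms, expected):
        k = make_erp_kernel(1.0, 200.0, 600.0, 1000.0, self.times)
        idx = int(np.flatnonzero(self.times == t_ms)[0])
        assert k.waveform[idx] == pytest.approx(expected, abs=1e-12)

    def test_zero_amplitude_is_all_zero(self):
        k = make_erp_kernel(0.0, 200.0, 600.0, 1000.0, self.times)
        assert np.all(k.waveform == 0.0)

    def test_single_interior_maximum_at_midpoint(self):
        k = make_erp_kernel(2.5, 200.0, 600.0, 1000.0, self.times)
        assert np.max(k.waveform) == pytest.approx(2.5, rel=1e-9)
        assert self.times[int(np.argmax(k.waveform))] == 400.0
        inside = (self.times > 200.0) & (self.times < 600.0)
        assert np.all(k.waveform[inside] > 0.0)
        assert np.all(np.abs(k.waveform[~inside]) < 1e-12)

    def test_window_outside_grid_raises(self):
        with pytest.raises(ValueError):
            make_erp_kernel(1.0, -50.0, 600.0, 1000.0, self.times)
        with pytest.raises(ValueError):
            make_erp_kernel(1.0, 200.0, 100.0, 1000.0, self.times)


# ----------------------------------------------------------------------
class TestDrawPresence:
    def test_positive_mode_exact_counts_and_phi(self, rng):
        h, v = draw_presence("positive", 512, rng)
        assert np.array_equal(h, v)
        assert h.sum() == 256
        assert phi_coefficient(h, v) == pytest.approx(1.0)

    def test_negative_mode_never_both(self, rng):
        h, v = draw_presence("negative", 512, rng)
        assert np.sum(h & v) == 0
        assert h.sum() == 256 and v.sum() == 256
        assert phi_coefficient(h, v) == pytest.approx(-1.0)

    def test_null_mode_independent(self, rng):
        h, v = draw_presence("null", 100_000, rng)
        assert abs(phi_coefficient(h, v)) < 0.02

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ValueError):
            draw_presence("sideways", 64, rng)

    def test_odd_trial_count_raises(self, rng):
        with pytest.raises(ValueError):
            draw_presence("positive", 63, rng)


# ----------------------------------------------------------------------
class TestChannelSplit:
    def test_default_split_is_orthogonal(self):
        s = default_channel_split()
        assert len(s.signal_channels) == 8
        ph = s.pattern("horizontal", 64)
        pv = s.pattern("vertical", 64)
        assert ph @ pv == 0.0
        assert np.sum(ph != 0) == 8 and np.sum(pv != 0) == 8

    def test_uneven_intersection_rejected(self):
        with pytest.raises(ValueError):
            ChannelSplit((0, 1, 2, 3), (4, 5, 6, 7),
                         (0, 1, 2, 4), (3, 5, 6, 7))


# ----------------------------------------------------------------------
class TestGenerateDataset:
    def test_noise_bound_is_bit_exact(self):
        cfg = SimulationConfig(n_trials=64, snr=4.0, amplitude=1.0, seed=0)
        ep = generate_dataset(cfg)
        quiet = [i for i in range(64)
                 if i not in default_channel_split().signal_channels]
        assert np.max(np.abs(ep.data[:, quiet, :])) <= 0.25

    def test_class_mean_difference_near_two_kernels(self):
        cfg = SimulationConfig(n_trials=512, snr=4.0, seed=1,
                               correlation_mode="positive")
        ep = generate_dataset(cfg)
        split = default_channel_split()
        present = ep.trials["erp_present_h"].to_numpy()
        left = present & (ep.trials["h_class"] == "left").to_numpy()
        right = present & (ep.trials["h_class"] == "right").to_numpy()
        contra = list(split.h_contra)
        diff = (ep.data[left][:, contra, :].mean(axis=(0, 1))
                - ep.data[right][:, contra, :].mean(axis=(0, 1)))
        assert diff.max() == pytest.approx(2.0, abs=0.15)

    def test_noise_free_limit_reproduces_kernel_exactly(self):
        cfg = SimulationConfig(n_trials=32, snr=4.0, noise_amplitude=0.0,
                               correlation_mode="positive", seed=2)
        ep = generate_dataset(cfg)
        split = default_channel_split()
        from dualdecode.simulate import make_erp_kernel as mk
        kern = mk(1.0, 200.0, 600.0, 512.0, ep.times_ms).waveform
        present = ep.trials["erp_present_h"].to_numpy()
        left = present & (ep.trials["h_class"] == "left").to_numpy()
        trial = int(np.flatnonzero(left)[0])
        contra = ep.data[trial, list(split.h_contra), :].mean(axis=0)
        ipsi = ep.data[trial, list(split.h_ipsi), :].mean(axis=0)
        # vertical injection cancels between the two horizontal halves
        assert np.allclose(contra - ipsi, 2.0 * kern, atol=1e-12)

    def test_negative_mode_never_energizes_both_patterns(self):
        cfg = SimulationConfig(n_trials=64, noise_amplitude=0.0,
                               correlation_mode="negative", seed=3)
        ep = generate_dataset(cfg)
        split = default_channel_split()
        ph = split.pattern("horizontal", 64)
        pv = split.pattern("vertical", 64)
        eh = np.abs(np.einsum("c,ncs->ns", ph, ep.data)).sum(axis=1)
        ev = np.abs(np.einsum("c,ncs->ns", pv, ep.data)).sum(axis=1)
        assert not np.any((eh > 1e-9) & (ev > 1e-9))
        assert np.all((eh > 1e-9) | (ev > 1e-9))

    def test_regeneration_is_bit_identical(self):
        cfg = SimulationConfig(n_trials=32, seed=4)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert np.array_equal(a.data, b.data)
        assert a.trials.equals(b.trials)

    def test_class_labels_counterbalanced(self):
        ep = generate_dataset(SimulationConfig(n_trials=128, seed=5))
        counts = ep.trials.groupby(["h_class", "v_class"]).size()
        assert set(counts) == {32}

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            SimulationConfig(snr=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_trials=65)
        with pytest.raises(ValueError):
            SimulationConfig(correlation_mode="bogus")

    def test_gaussian_noise_flag(self):
        ep = generate_dataset(SimulationConfig(n_trials=32, noise="gaussian",
                                               snr=1.0, seed=6))
        quiet = ep.data[:, 40, :]  # a non-signal channel
        assert quiet.std() == pytest.approx(1.0 / 3.0, rel=0.05)


class TestCohort:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_trials=16, seed=1)
        a = generate_cohort(cfg, 3, seed=1)
        b = generate_cohort(cfg, 3, seed=1)
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)

    def test_subjects_and_seeds_differ(self):
        cfg = SimulationConfig(n_trials=16, seed=1)
        cohort = generate_cohort(cfg, 3, seed=1)
        other = generate_cohort(cfg, 3, seed=2)
        assert not np.array_equal(cohort[0].data, cohort[1].data)
        assert not np.array_equal(cohort[0].data, other[0].data)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SimulationConfig(n_trials=16), 1)


# ----------------------------------------------------------------------
class TestEpochsIO:
    def test_h5_round_trip_bit_exact(self, tmp_path):
        ep = generate_dataset(SimulationConfig(n_trials=16, seed=9))
        path = tmp_path / "ep.h5"
        ep.save_h5(path)
        back = EpochsSet.load_h5(path)
        assert np.array_equal(ep.data, back.data)
        assert np.array_equal(ep.times_ms, back.times_ms)
        assert ep.channel_names == back.channel_names
        assert ep.trials.equals(back.trials)

    def test_mne_round_trip(self):
        ep = generate_dataset(SimulationConfig(n_trials=8, seed=9))
        back = EpochsSet.from_mne(ep.to_mne())
        assert np.allclose(ep.data, back.data, atol=1e-9)
        assert back.trials["h_class"].equals(ep.trials["h_class"])

    def test_times_grid_uniform_at_sample_rate(self):
        ep = generate_dataset(SimulationConfig(n_trials=8, seed=9))
        dt = np.diff(ep.times_ms)
        assert np.allclose(dt, 1000.0 / 512.0)
        assert ep.times_ms[0] <= -300.0 + 1000.0 / 512.0
        assert ep.times_ms[-1] >= 800.0 - 1000.0 / 512.0
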