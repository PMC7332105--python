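"""Replicate averaging, smoothing, trough-to-peak and stability screening."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import conespect as cs
from conespect.preprocess import (
    PreprocessConfig,
    average_replicates,
    build_amplitude_dataset,
    smooth_running_mean,
    stability_index,
    trough_to_peak,
)


class TestAverageReplicates:
    def test_identical_traces_unchanged(self):
        t = np.sin(np.linspace(0, 1, 100))
        out = average_replicates(np.tile(t, (4, 1)))
        assert np.allclose(out, t)

    def test_symmetric_constants_cancel(self):
        traces = np.array([[1.0] * 50, [-1.0] * 50, [3.0] * 50, [-3.0] * 50])
        assert np.allclose(average_replicates(traces), 0.0)

    def test_warns_on_unexpected_count(self):
        with pytest.warns(UserWarning, match="replicates"):
            out = average_replicates(np.ones((3, 20)))
        assert np.allclose(out, 1.0)

    def test_noise_variance_halves(self, rng):
        # averaging 4 replicates reduces the noise sd by a factor of 2
        sigma = 1.0
        traces = rng.normal(0, sigma, (4, 20000))
        assert average_replicates(traces).std() == pytest.approx(sigma / 2, rel=0.05)


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        assert np.allclose(smooth_running_mean(np.full(200, 7.0)), 7.0)

    def test_impulse_spreads_to_kernel_mass(self):
        x = np.zeros(201)
        x[100] = 1.0
        out = smooth_running_mean(x, 33)
        assert out[100] == pytest.approx(1 / 33)
        assert out[100 - 16] == pytest.approx(1 / 33)
        assert out[100 - 17] == 0.0

    def test_length_preserved_and_edges_shrink(self):
        x = np.arange(100, dtype=float)
        out = smooth_running_mean(x, 33)
        assert out.size == x.size
        assert out[0] == x[0]  # half-width 0 at the edge
        assert out[1] == pytest.approx(x[:3].mean())

    @pytest.mark.parametrize("window", [2, 0, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth_running_mean(np.zeros(100), window)

    def test_white_noise_reduction(self, rng):
        x = rng.normal(0, 1.0, 60000)
        out = smooth_running_mean(x, 33)
        assert out[5000:-5000].std() == pytest.approx(1 / np.sqrt(33), rel=0.05)


class TestTroughToPeak:
    def _time(self, fs=2000.0, dur=1.2):
        return np.arange(int(dur * fs)) / fs - 0.1

    def test_flat_trace_is_zero(self):
        t = self._time()
        assert trough_to_peak(t, np.zeros_like(t), 0.0, 0.3) == 0.0

    def test_constructed_piii_waveform(self):
        # -10 μV plateau during the flash, +3 μV rebound after offset
        t = self._time()
        v = np.zeros_like(t)
        v[(t >= 0) & (t < 0.3)] = -10.0
        v[(t >= 0.35) & (t < 0.45)] = 3.0
        assert trough_to_peak(t, v, 0.0, 0.3) == pytest.approx(13.0)

    def test_never_negative(self):
        # the trough and peak windows overlap at [offset, offset+trough_pad],
        # so the measure is structurally non-negative even for a ramp
        t = self._time()
        assert trough_to_peak(t, -t, 0.0, 0.3) >= 0.0
        assert trough_to_peak(t, 5 * t, 0.0, 0.3) >= 0.0

    def test_window_outside_trace_rejected(self):
        t = self._time(dur=0.3)
        with pytest.raises(ValueError):
            trough_to_peak(t, np.zeros_like(t), 0.0, 0.3)
        with pytest.raises(ValueError):
            trough_to_peak(t, np.zeros_like(t), 0.3, 0.0)


class TestStability:
    def _frame(self, first_max, second_max):
        rows = []
        for block, mx in [(0, first_max), (5, second_max)]:
            for step in range(1, 8):
                rows.append({"block_index": block, "wavelength_nm": 650,
                             "step_index": step, "log_irradiance": 4.2 + 0.5 * (step - 1),
                             "amplitude": mx * step / 7})
        return pd.DataFrame(rows)

    def test_identical_blocks_included(self):
        ratio, excluded = stability_index(self._frame(10.0, 10.0))
        assert ratio == pytest.approx(1.0)
        assert not excluded

    def test_halved_second_block_excluded(self):
        ratio, excluded = stability_index(self._frame(10.0, 5.0))
        assert ratio == pytest.approx(0.5)
        assert excluded

    def test_zero_first_block_is_undefined_and_excluded(self):
        ratio, excluded = stability_index(self._frame(0.0, 5.0))
        assert np.isnan(ratio)
        assert excluded

    def test_single_block_rejected(self):
        frame = self._frame(1.0, 1.0)
        with pytest.raises(ValueError):
            stability_index(frame[frame.block_index == 0])

    def test_stable_noisy_datasets_rarely_excluded(self, protocol, wt_larva):
        # amplitude-level noise at the generator default; fixed seed batch
        included = 0
        n = 400
        for i in range(n):
            ds = cs.simulate_amplitude_dataset(wt_larva, protocol, seed=10_000 + i)
            included += not ds.excluded
        assert included / n >= 0.95


@pytest.fixture(scope="module")
def small_protocol():
    # two 650-nm blocks + one mid-spectrum block: enough structure for
    # the stability index at a fraction of the full schedule's cost
    return cs.SpectralProtocol(blocks=(650, 490, 650))


class TestBuildAmplitudeDataset:
    def test_zero_voltage_sweeps_give_zero_amplitudes_and_exclusion(self, small_protocol):
        sw = cs.simulate_sweepset(
            cs.preset("wt_larva"), small_protocol,
            cs.NoiseModel(trace_sigma_uv=0.0, gain_uv=0.0), seed=1,
        )
        ds = build_amplitude_dataset(sw, small_protocol)
        assert (ds.frame["amplitude"] == 0).all()
        assert ds.excluded and np.isnan(ds.stability_ratio)

    def test_row_count_and_completeness(self, small_protocol, wt_larva):
        sw = cs.simulate_sweepset(wt_larva, small_protocol, cs.NoiseModel(), seed=2)
        ds = build_amplitude_dataset(sw, small_protocol)
        assert ds.n_rows == 21
        assert ds.complete

    def test_missing_stimuli_reported(self, small_protocol, wt_larva):
        sw = cs.simulate_sweepset(wt_larva, small_protocol, cs.NoiseModel(), seed=2)
        for idx in list(sw.traces)[:4]:  # drop the first combo's replicates
            del sw.traces[idx]
        ds = build_amplitude_dataset(sw, small_protocol)
        assert not ds.complete
        assert (0, 650, 1) in ds.missing_combos

    def test_duplicated_650_combos_share_block_averages(self, small_protocol, wt_larva):
        sw = cs.simulate_sweepset(wt_larva, small_protocol, cs.NoiseModel(), seed=3)
        ds = build_amplitude_dataset(sw, small_protocol)
        f = ds.frame
        first = f[(f.wavelength_nm == 650) & (f.block_index == 0)].set_index("step_index")
        second = f[(f.wavelength_nm == 650) & (f.block_index == 2)].set_index("step_index")
        assert np.allclose(first["amplitude"], second["amplitude"])

    def test_dc_offset_invariance(self, small_protocol, wt_larva):
        sw = cs.simulate_sweepset(wt_larva, small_protocol, cs.NoiseModel(), seed=4)
        ds1 = build_amplitude_dataset(sw, small_protocol)
        shifted = {k: v + 55.0 for k, v in sw.traces.items()}
        sw2 = cs.SweepSet(sw.sample_rate_hz, sw.time_s, shifted,
                          genotype_label=sw.genotype_label)
        ds2 = build_amplitude_dataset(sw2, small_protocol)
        assert np.allclose(ds1.frame["amplitude"], ds2.frame["amplitude"])

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_homogeneity_under_voltage_scaling(self, scale):
        proto = cs.SpectralProtocol(blocks=(650, 490, 650))
        sw = cs.simulate_sweepset(cs.preset("wt_larva"), proto, cs.NoiseModel(), seed=5)
        base = build_amplitude_dataset(sw, proto).frame["amplitude"].to_numpy()
        scaled = {k: v * scale for k, v in sw.traces.items()}
        sw2 = cs.SweepSet(sw.sample_rate_hz, sw.time_s, scaled)
        out = build_amplitude_dataset(sw2, proto).frame["amplitude"].to_numpy()
        assert np.allclose(out, base * scale, rtol=1e-9)

    def test_pipeline_is_deterministic(self, small_protocol, wt_larva):
        sw = cs.simulate_sweepset(wt_larva, small_protocol, cs.NoiseModel(), seed=6)
        a = build_amplitude_dataset(sw, small_protocol).frame
        b = build_amplitude_dataset(sw, small_protocol).frame
        pd.testing.assert_frame_equal(a, b)


class TestSweepSetIO:
    def test_csv_round_trip(self, tmp_path, wt_larva):
        proto = cs.SpectralProtocol(blocks=(650, 650))
        sw = cs.simulate_sweepset(wt_larva, proto, cs.NoiseModel(), seed=7)
        path = tmp_path / "sweeps.csv"
        sw.to_csv(path)
        back = cs.SweepSet.from_csv(path)
        assert set(back.traces) == set(sw.traces)
        idx = next(iter(sw.traces))
        assert np.allclose(back.traces[idx], sw.traces[idx], atol=1e-4)

    def test_amplitude_dataset_csv_round_trip(self, tmp_path, protocol, wt_larva):
        ds = cs.simulate_amplitude_dataset(wt_larva, protocol, seed=8, dataset_id="x1")
        path = tmp_path / "amps.csv"
        ds.to_csv(path)
        back = cs.AmplitudeDataset.from_csv(path)
        assert back.dataset_id == "x1"
        assert back.stability_ratio == pytest.approx(ds.stability_ratio, rel=1e-5)
        assert np.allclose(back.frame["amplitude"], ds.frame["amplitude"], rtol=1e-5)
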