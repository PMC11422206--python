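import math

import numpy as np
import pytest

from nirsvot.preprocess import (
    FormatError,
    compute_delta_hb,
    compute_tsi,
    lowpass_zero_phase,
    normalize_to_baseline,
    read_nirs_csv,
    write_nirs_csv,
)
from nirsvot.recording import NIRSRecording
from nirsvot.simulate import SimulationParams, simulate_session


def _make_rec(n=12000, fs=10.0, fill=0.0):
    t = np.arange(n) / fs
    z = np.full(n, fill, dtype=float)
    return NIRSRecording(time=t, o2hb=z.copy(), hhb=z.copy(), tsi=z.copy(),
                         sampling_rate=fs)


class TestReadWrite:
    def test_well_formed_csv(self, tmp_path):
        p = tmp_path / "rec.csv"
        p.write_text("time_s,o2hb,hhb,tsi\n0.0,1,2,33\n0.1,1,2,33\n0.2,1,2,33\n")
        rec = read_nirs_csv(p)
        assert len(rec) == 3
        assert rec.o2hb[0] == 1

    def test_missing_channel_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,o2hb,tsi\n0.0,1,33\n0.1,1,33\n")
        with pytest.raises(FormatError, match="hhb"):
            read_nirs_csv(p)

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,o2hb,hhb,tsi\n0.0,1,2,33\n0.1,oops,2,33\n")
        with pytest.raises(FormatError, match="o2hb"):
            read_nirs_csv(p)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_nirs_csv(p)

    def test_simulated_recording_roundtrips_bitwise(self, tmp_path):
        rec, _ = simulate_session(SimulationParams(seed=4))
        path = tmp_path / "sim.csv"
        write_nirs_csv(rec, path, {"seed": 4})
        back = read_nirs_csv(path)
        assert np.array_equal(back.o2hb, rec.o2hb)
        assert np.array_equal(back.hhb, rec.hhb)
        assert np.array_equal(back.tsi, rec.tsi)

    def test_missing_tsi_column_is_derived(self, tmp_path):
        p = tmp_path / "rec.csv"
        p.write_text("time_s,o2hb,hhb\n0.0,30,10\n0.1,30,10\n0.2,30,10\n")
        rec = read_nirs_csv(p)
        assert rec.meta["tsi_derived"]
        np.testing.assert_allclose(rec.tsi, 75.0)

    def test_nonuniform_grid_resampled_with_warning(self, tmp_path):
        p = tmp_path / "rec.csv"
        rows = ["time_s,o2hb,hhb,tsi"]
        t = [0.0, 0.1, 0.25, 0.3, 0.4]  # one late sample
        for ti in t:
            rows.append(f"{ti},1,1,50")
        p.write_text("\n".join(rows) + "\n")
        with pytest.warns(UserWarning, match="resampling"):
            rec = read_nirs_csv(p)
        assert np.allclose(np.diff(rec.time), 0.1)


class TestLowpassZeroPhase:
    def test_dc_gain_is_unity(self):
        rec = _make_rec(fill=7.5)
        out = lowpass_zero_phase(rec)
        np.testing.assert_allclose(out.o2hb, 7.5, atol=1e-9)

    def test_passband_sinusoid_preserved_with_zero_lag(self):
        # two passes of the order-10 Butterworth: |H(f)|^2 = 1/(1+(f/fc)^20),
        # essentially unity at 0.05 Hz
        rec = _make_rec(n=12000)
        f0 = 0.05
        sig = np.sin(2 * np.pi * f0 * rec.time)
        rec = rec.copy_with(tsi=sig.copy(), o2hb=sig.copy(), hhb=sig.copy())
        out = lowpass_zero_phase(rec)
        core = slice(2000, 10000)
        amp_ratio = np.std(out.tsi[core]) / np.std(sig[core])
        assert abs(amp_ratio - 1) < 0.01
        xc = np.correlate(out.tsi[core] - out.tsi[core].mean(),
                          sig[core] - sig[core].mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(xc) // 2)
        assert lag == 0

    def test_stopband_sinusoid_attenuated_60_db(self):
        rec = _make_rec(n=12000)
        sig = np.sin(2 * np.pi * 2.0 * rec.time)
        rec = rec.copy_with(tsi=sig.copy(), o2hb=sig.copy(), hhb=sig.copy())
        out = lowpass_zero_phase(rec)
        core = slice(2000, 10000)
        atten_db = -20 * np.log10(np.std(out.tsi[core]) / np.std(sig[core]))
        assert atten_db >= 60

    def test_filter_is_linear(self):
        rng = np.random.default_rng(0)
        rec = _make_rec(n=4000)
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        fx = lowpass_zero_phase(rec.copy_with(tsi=x)).tsi
        fy = lowpass_zero_phase(rec.copy_with(tsi=y)).tsi
        fxy = lowpass_zero_phase(rec.copy_with(tsi=2 * x + 3 * y)).tsi
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, atol=1e-9)

    def test_short_record_rejected(self):
        rec = _make_rec(n=20)  # shorter than the 3x filter-length padding
        with pytest.raises(ValueError, match="too short"):
            lowpass_zero_phase(rec)

    def test_cutoff_above_nyquist_rejected(self):
        rec = _make_rec()
        with pytest.raises(ValueError):
            lowpass_zero_phase(rec, cutoff_hz=6.0)


class TestNormalizeToBaseline:
    def test_constant_channel_becomes_zero(self):
        rec = _make_rec(fill=7.0)
        out = normalize_to_baseline(rec)
        np.testing.assert_allclose(out.o2hb, 0.0, atol=1e-12)
        assert out.normalized
        assert out.baseline_window == (150.0, 750.0)

    def test_ramp_loses_its_window_mean(self):
        rec = _make_rec()
        rec = rec.copy_with(tsi=rec.time.copy())
        out = normalize_to_baseline(rec)
        # mean of t over [150, 750) on the 10 Hz grid
        expected_mean = np.mean(np.arange(1500, 7500) / 10.0)
        np.testing.assert_allclose(out.tsi, rec.time - expected_mean, atol=1e-9)

    def test_window_mean_of_result_is_zero(self):
        rec, _ = simulate_session(SimulationParams(seed=5))
        out = normalize_to_baseline(rec)
        sl = out.window_slice(150.0, 750.0)
        for _, chan in out.channels():
            assert abs(chan[sl].mean()) < 1e-9

    def test_double_normalization_rejected(self):
        rec = _make_rec()
        out = normalize_to_baseline(rec)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_to_baseline(out)

    def test_window_outside_recording_rejected(self):
        rec = _make_rec(n=1000)  # 100 s record
        with pytest.raises(ValueError, match="outside"):
            normalize_to_baseline(rec, (150.0, 750.0))

    def test_normalization_preserves_differences_exactly(self):
        rng = np.random.default_rng(3)
        rec = _make_rec()
        x = rng.normal(size=len(rec))
        rec = rec.copy_with(tsi=x)
        out = normalize_to_baseline(rec)
        np.testing.assert_allclose(np.diff(out.tsi), np.diff(x), atol=1e-12)


class TestDerivedChannels:
    @pytest.mark.parametrize(
        "o2hb,hhb,expected",
        [(10.0, 10.0, 50.0), (30.0, 10.0, 75.0), (0.0, 5.0, 0.0)],
    )
    def test_tsi_formula(self, o2hb, hhb, expected):
        assert compute_tsi(np.array([o2hb]), np.array([hhb]))[0] == expected

    def test_tsi_zero_denominator_flagged_not_raised(self):
        out = compute_tsi(np.array([0.0, 30.0]), np.array([0.0, 10.0]))
        assert math.isnan(out[0])
        assert out[1] == 75.0

    @pytest.mark.parametrize("o2hb,hhb,expected", [(5, 5, 0), (10, 4, 6)])
    def test_delta_hb(self, o2hb, hhb, expected):
        assert compute_delta_hb(np.array([o2hb]), np.array([hhb]))[0] == expected

    def test_delta_hb_commutes_with_normalization(self):
        rec, _ = simulate_session(SimulationParams(seed=6))
        norm = normalize_to_baseline(rec)
        # linear operator: difference of normalized channels equals the
        # normalized difference
        direct = norm.o2hb - norm.hhb
        raw_dhb = rec.o2hb - rec.hhb
        sl = rec.window_slice(150.0, 750.0)
        np.testing.assert_allclose(direct, raw_dhb - raw_dhb[sl].mean(), atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_delta_hb(np.zeros(3), np.zeros(4))
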