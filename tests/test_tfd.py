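"""Choi-Williams distribution: oracle equivalence, marginals, truncation."""

import numpy as np
import pytest
from scipy.signal import hilbert

from cwdetect import (
    ContractError,
    ParameterError,
    ValidationError,
    cwd,
    cwd_reference,
    marginal_freq,
    marginal_time,
    total_power,
    truncate_positive,
)

FS = 250.0
SMALL = dict(sigma=1.0, n_freq=64, lag_window=15)


def _tone(freq, n=512, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


def _battery(n=64, seeds=(0, 1, 2)):
    t = np.arange(n) / FS
    sigs = {
        "tone": np.sin(2 * np.pi * 20 * t),
        "chirp": np.sin(2 * np.pi * (5 + 40 * t) * t),
        "impulse": np.eye(1, n, n // 2)[0],
        "two-tone": np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 16 * t),
    }
    for s in seeds:
        sigs[f"noise-{s}"] = np.random.default_rng(s).normal(size=n)
    return sigs


class TestOracleEquivalence:
    @pytest.mark.parametrize("name,signal", sorted(_battery().items()))
    def test_fast_path_matches_literal_double_sum(self, name, signal):
        fast = cwd(signal, FS, **SMALL)
        ref = cwd_reference(signal, FS, **SMALL)
        num = np.linalg.norm(fast.values - ref.values)
        den = np.linalg.norm(ref.values)
        assert num <= 1e-8 * den, f"{name}: rel Frobenius err {num / den:.2e}"

    def test_zero_signal_gives_zero_matrix(self):
        # the distribution is bilinear in the signal
        assert not cwd(np.zeros(128), FS, **SMALL).values.any()
        assert not cwd_reference(np.zeros(64), FS, **SMALL).values.any()

    def test_impulse_concentrates_in_time_flat_in_frequency(self):
        # complex delta keeps the check free of Hilbert edge effects
        n, n0 = 64, 32
        x = np.zeros(n, dtype=complex)
        x[n0] = 1.0
        ref = cwd_reference(x, FS, **SMALL)
        energy_per_slice = np.abs(ref.values).sum(axis=1)
        assert np.argmax(energy_per_slice) == n0
        row = ref.values[n0]
        assert row.std() < 1e-9 * abs(row.mean())  # flat over frequency

    def test_oracle_refuses_large_signals(self):
        with pytest.raises(ParameterError):
            cwd_reference(np.zeros(512), FS, **SMALL)


class TestParameterValidation:
    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            cwd(_tone(10), FS, sigma=0.0)

    def test_nonpower_of_two_bins_rejected(self):
        with pytest.raises(ParameterError):
            cwd(_tone(10), FS, n_freq=100)

    def test_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            cwd(np.zeros(100), FS, lag_window=127)


class TestToneLocalization:
    def test_time_averaged_peak_at_tone_frequency(self):
        m = cwd(_tone(10.0), FS, sigma=1.0)
        avg = m.values.mean(axis=0)
        peak = m.freq_axis[np.argmax(avg)]
        assert abs(peak - 10.0) <= m.df

    def test_time_shift_covariance(self):
        # shifting the input shifts the time axis; compare interior slices
        rng = np.random.default_rng(7)
        x = rng.normal(size=200) + 1j * rng.normal(size=200)
        shift = 16
        a = cwd(x, FS, **SMALL)
        b = cwd(np.concatenate([np.zeros(shift, complex), x[:-shift]]), FS, **SMALL)
        interior = slice(70, 130)
        shifted = slice(70 + shift, 130 + shift)
        assert np.allclose(b.values[shifted], a.values[interior], atol=1e-10)


class TestMarginals:
    def test_time_marginal_is_instantaneous_power(self):
        x = _tone(10.0, n=512)
        m = cwd(x, FS, sigma=1.0)
        mt = marginal_time(m)
        inst = np.abs(hilbert(x)) ** 2
        c = slice(128, 384)  # central half
        rms = np.sqrt(np.mean((mt[c] - inst[c]) ** 2)) / np.mean(inst[c])
        assert rms < 0.02

    def test_time_marginal_tracks_am_envelope(self):
        n = 512
        t = np.arange(n) / FS
        envelope = 0.5 + 0.5 * np.sin(2 * np.pi * 1.5 * t) ** 2
        x = envelope * np.exp(2j * np.pi * 20 * t)  # analytic AM tone
        mt = marginal_time(cwd(x, FS, sigma=1.0))
        c = slice(128, 384)
        corr = np.corrcoef(mt[c], envelope[c] ** 2)[0, 1]
        assert corr > 0.99

    def test_frequency_marginal_peak(self):
        m = cwd(_tone(10.0), FS, sigma=1.0)
        mf = marginal_freq(m)
        assert abs(m.freq_axis[np.argmax(mf)] - 10.0) <= m.df

    def test_two_tone_masses_comparable(self):
        x = _tone(8.0) + _tone(16.0)
        m = cwd(x, FS, sigma=1.0)
        mf = marginal_freq(m)
        mass_a = mf[(m.freq_axis >= 6) & (m.freq_axis <= 10)].sum()
        mass_b = mf[(m.freq_axis >= 14) & (m.freq_axis <= 18)].sum()
        assert 0.8 <= mass_a / mass_b <= 1.25

    def test_total_power_equals_signal_energy(self):
        x = _tone(10.0, n=512)  # ~2 s at 250 Hz
        m = cwd(x, FS, sigma=1.0)
        energy = np.sum(np.abs(hilbert(x)) ** 2) / FS
        assert total_power(m) == pytest.approx(energy, rel=0.01)

    def test_quadratic_amplitude_scaling(self):
        a = total_power(cwd(_tone(10.0, amp=1.0), FS, sigma=1.0))
        b = total_power(cwd(_tone(10.0, amp=2.0), FS, sigma=1.0))
        assert b == pytest.approx(4.0 * a, rel=1e-6)

    def test_marginals_refuse_truncated_matrix(self):
        m = truncate_positive(cwd(_tone(10.0), FS, sigma=1.0))
        for op in (marginal_time, marginal_freq, total_power):
            with pytest.raises(ContractError):
                op(m)


class TestTruncation:
    def test_definition_on_small_matrix(self):
        m = cwd(_tone(10.0, n=128), FS, **SMALL)
        m.values = np.array([[1.0, -2.0], [0.0, 3.0]])
        out = truncate_positive(m)
        assert np.array_equal(out.values, [[1.0, 0.0], [0.0, 3.0]])
        assert out.truncated

    def test_all_positive_matrix_unchanged(self):
        m = cwd(_tone(10.0, n=128), FS, **SMALL)
        m.values = np.abs(m.values) + 0.1
        assert np.array_equal(truncate_positive(m).values, m.values)

    def test_double_truncation_rejected(self):
        m = truncate_positive(cwd(_tone(10.0, n=128), FS, **SMALL))
        with pytest.raises(ContractError):
            truncate_positive(m)

    def test_truncation_never_decreases_total(self):
        # cross-terms of a two-tone signal oscillate negative
        x = _tone(8.0) + _tone(16.0)
        m = cwd(x, FS, sigma=1.0)
        assert (m.values < 0).any()
        tr = truncate_positive(m)
        assert (tr.values >= 0).all()
        assert tr.values.sum() >= m.values.sum()


def test_cross_term_suppression_monotone_in_sigma():
    # midband (11.5-12.5 Hz) interference between 8 and 16 Hz tones shrinks
    # monotonically as the kernel parameter decreases
    x = _tone(8.0) + _tone(16.0)
    levels = []
    for sigma in (10.0, 1.0, 0.1, 0.01):
        m = cwd(x, FS, sigma=sigma)
        sel = (m.freq_axis >= 11.5) & (m.freq_axis <= 12.5)
        levels.append(np.abs(m.values[:, sel]).mean())
    assert all(a > b for a, b in zip(levels, levels[1:])), levels


def test_decimated_grid_subsamples_full_grid():
    x = _tone(10.0)
    full = cwd(x, FS, sigma=1.0, time_decimation=1)
    dec = cwd(x, FS, sigma=1.0, time_decimation=4)
    assert np.allclose(dec.values, full.values[::4], atol=1e-12)
    assert np.allclose(dec.time_axis, full.time_axis[::4])
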