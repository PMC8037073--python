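"""Discrete Choi-Williams time-frequency distribution (CWD).

The CWD is the Cohen's-class bilinear distribution with exponential kernel

    CWD(t, w) = Int e^{-i w tau} Int sqrt(sigma / (4 pi tau^2))
                e^{-sigma (mu - t)^2 / (4 tau^2)}
                x(mu + tau/2) x*(mu - tau/2) dmu dtau,

whose kernel parameter ``sigma`` trades frequency resolution against
suppression of the oscillatory cross-terms every bilinear distribution puts
between genuine signal components. The discrete form evaluated here is, for
sample index n and lag k,

    CWD(n, w) = 2 sum_k e^{-2 i w k} sum_m sqrt(sigma / (4 pi k^2))
                e^{-sigma (m - n)^2 / (4 k^2)} x(m + k) x*(m - k),

with the k = 0 time-smoothing window taken as a Kronecker delta (the
Gaussian's k -> 0 limit). Conventions shared by the fast path and the
brute-force oracle:

* the input is converted to its analytic form (Hilbert transform) first, so
  a real tone concentrates at its own frequency without negative-frequency
  interference;
* the lag sum runs over a finite odd window (default 127 samples) under a
  Hamming taper;
* the Gaussian time-smoothing window at lag k is truncated where its value
  falls below 1e-4 of the peak, i.e. at |m - n| > 2|k| sqrt(ln 1e4 / sigma);
* samples outside the record are treated as zero (edge windows shrink); time
  slices within one lag window of either edge are flagged via ``edge_mask``;
* values are scaled by 1/fs so the Riemann-sum marginals hold: summing over
  frequency (x df) returns the instantaneous power |s(n)|^2, summing that
  over time (x dt) returns the analytic signal's energy.

The frequency axis carries ``n_freq + 1`` bins spanning [0, fs/2] inclusive;
the discrete distribution is fs/2-periodic in frequency, so the endpoint bin
duplicates bin 0 (negligible for band-limited ECG content).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ContractError, ParameterError, ValidationError

# Gaussian support cut: exp(-sigma d^2 / 4k^2) < 1e-4  <=>  |d| > _SUPPORT * |k| / sqrt(sigma)
_SUPPORT = 2.0 * np.sqrt(np.log(1e4))


@dataclass
class CWDMatrix:
    """Time x frequency energy density for one signal.

    ``values[i, j]`` is the density at ``time_axis[i]`` seconds and
    ``freq_axis[j]`` Hz; units are mV^2/Hz for an mV input so that Riemann
    sums reproduce instantaneous power and total energy.
    """

    values: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    sigma: float
    fs: float
    lag_window: int
    time_decimation: int
    n_samples: int = 0
    truncated: bool = False

    @property
    def df(self) -> float:
        return float(self.freq_axis[1] - self.freq_axis[0])

    @property
    def dt(self) -> float:
        """Effective time step between analyzed slices (s)."""
        return self.time_decimation / self.fs

    @property
    def edge_mask(self) -> np.ndarray:
        """True for time slices within one lag window of either record edge."""
        idx = np.round(self.time_axis * self.fs).astype(int)
        return (idx < self.lag_window) | (idx >= self.n_samples - self.lag_window)


def _validate_cwd_params(n: int, sigma: float, n_freq: int, lag_window: int,
                         time_decimation: int) -> None:
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if n_freq < 2 or (n_freq & (n_freq - 1)) != 0:
        raise ParameterError(f"n_freq must be a power of two, got {n_freq}")
    if lag_window < 3 or lag_window % 2 == 0:
        raise ParameterError(f"lag_window must be odd and >= 3, got {lag_window}")
    if time_decimation < 1:
        raise ParameterError("time_decimation must be >= 1")
    if n < 2 * lag_window:
        raise ValidationError(
            f"signal of {n} samples is shorter than twice the lag window ({lag_window})"
        )


def _analytic(signal: np.ndarray) -> np.ndarray:
    signal = np.asarray(signal)
    if np.iscomplexobj(signal):
        return signal.astype(complex)
    return sps.hilbert(signal.astype(float))


def _smoothing_window(k: int, sigma: float) -> np.ndarray:
    """Choi-Williams Gaussian weights over m - n for lag k (not renormalized)."""
    d_max = int(np.ceil(_SUPPORT * abs(k) / np.sqrt(sigma)))
    d = np.arange(-d_max, d_max + 1)
    return np.sqrt(sigma / (4.0 * np.pi * k * k)) * np.exp(-sigma * d * d / (4.0 * k * k))


def _lag_products(x: np.ndarray, k: int) -> np.ndarray:
    """p_k(m) = x(m+k) x*(m-k), zero where m +/- k leaves the record."""
    n = x.size
    p = np.zeros(n, dtype=complex)
    if k == 0:
        return x * np.conj(x)
    p[k : n - k] = x[2 * k :] * np.conj(x[: n - 2 * k])
    return p


def cwd(
    signal: np.ndarray,
    fs: float,
    sigma: float = 1.0,
    n_freq: int = 256,
    lag_window: int = 127,
    time_decimation: int = 1,
) -> CWDMatrix:
    """Discrete Choi-Williams distribution of a (real) signal.

    Parameters
    ----------
    signal : array
        Samples (mV); converted to analytic form internally.
    fs : float
        Sampling rate, Hz.
    sigma : float
        Kernel parameter; smaller values suppress cross-terms harder at the
        cost of time-frequency resolution.
    n_freq : int
        Power of two; output has ``n_freq + 1`` frequency bins on [0, fs/2].
    lag_window : int
        Odd length of the lag window (Hamming tapered).
    time_decimation : int
        Analyze every ``time_decimation``-th sample instant.
    """
    x = _analytic(signal)
    n = x.size
    _validate_cwd_params(n, sigma, n_freq, lag_window, time_decimation)
    half = lag_window // 2
    taper = sps.windows.hamming(lag_window, sym=True)
    times = np.arange(0, n, time_decimation)

    # conjugate-symmetric lag spectrum A[t, k mod n_freq]; FFT over lags then
    # yields a purely real distribution
    a = np.zeros((times.size, n_freq), dtype=complex)
    for k in range(0, half + 1):
        p = _lag_products(x, k)
        if k == 0:
            r = p[times]
        else:
            w = _smoothing_window(k, sigma)
            r = sps.fftconvolve(p, w, mode="same")[times]
        r = taper[half + k] * r
        a[:, k % n_freq] += r
        if k > 0:
            a[:, (-k) % n_freq] += np.conj(r)

    spec = np.fft.fft(a, axis=1)
    values = (2.0 / fs) * spec.real
    values = np.concatenate([values, values[:, :1]], axis=1)
    freq_axis = np.arange(n_freq + 1) * fs / (2.0 * n_freq)
    return CWDMatrix(
        values=values,
        time_axis=times / fs,
        freq_axis=freq_axis,
        sigma=sigma,
        fs=fs,
        lag_window=lag_window,
        time_decimation=time_decimation,
        n_samples=n,
    )


def cwd_reference(
    signal: np.ndarray,
    fs: float,
    sigma: float = 1.0,
    n_freq: int = 256,
    lag_window: int = 127,
) -> CWDMatrix:
    """Brute-force transcription of the discrete CWD double sum (test oracle).

    Evaluates, for every time instant, the kernel-weighted lag products by
    direct summation and transforms over lag with an explicit DFT matrix.
    Deliberately independent of the fast convolution/FFT path; refuses
    signals longer than 256 samples.
    """
    x = _analytic(signal)
    n = x.size
    if n > 256:
        raise ParameterError(f"reference oracle is limited to 256 samples, got {n}")
    _validate_cwd_params(n, sigma, n_freq, lag_window, 1)
    half = lag_window // 2
    taper = sps.windows.hamming(lag_window, sym=True)

    r = np.zeros((n, 2 * half + 1), dtype=complex)  # lags -half..half
    for t in range(n):
        for k in range(-half, half + 1):
            if k == 0:
                acc = x[t] * np.conj(x[t])
            else:
                w = _smoothing_window(k, sigma)
                d_max = w.size // 2
                acc = 0.0 + 0.0j
                for d in range(-d_max, d_max + 1):
                    m = t + d
                    if 0 <= m + k < n and 0 <= m - k < n:
                        acc += w[d + d_max] * x[m + k] * np.conj(x[m - k])
            r[t, k + half] = taper[half + k] * acc

    ks = np.arange(-half, half + 1)
    js = np.arange(n_freq + 1)
    dft = np.exp(-2j * np.pi * np.outer(js, ks) / n_freq)  # e^{-2 i w_j k}
    values = (2.0 / fs) * (r @ dft.T).real
    freq_axis = js * fs / (2.0 * n_freq)
    return CWDMatrix(
        values=values,
        time_axis=np.arange(n) / fs,
        freq_axis=freq_axis,
        sigma=sigma,
        fs=fs,
        lag_window=lag_window,
        time_decimation=1,
        n_samples=n,
    )


def truncate_positive(m: CWDMatrix) -> CWDMatrix:
    """Zero the negative part of the distribution (cross-term residue).

    Follows the convention that the information-bearing content of a
    Cohen's-class matrix lives in its positive part; elements <= 0 map to 0.
    """
    if m.truncated:
        raise ContractError("matrix is already truncated")
    return replace(m, values=np.where(m.values > 0, m.values, 0.0), truncated=True)


def _require_full(m: CWDMatrix, op: str) -> None:
    if m.truncated:
        raise ContractError(f"{op} is defined for the full (untruncated) distribution")


def marginal_time(m: CWDMatrix) -> np.ndarray:
    """Frequency integral per time slice: the instantaneous power |s(t)|^2."""
    _require_full(m, "marginal_time")
    return m.values[:, :-1].sum(axis=1) * m.df


def marginal_freq(m: CWDMatrix) -> np.ndarray:
    """Time integral per frequency bin: the energy spectral density |S(w)|^2."""
    _require_full(m, "marginal_freq")
    return m.values.sum(axis=0) * m.dt


def total_power(m: CWDMatrix) -> float:
    """Double Riemann sum: the analytic signal's total energy."""
    _require_full(m, "total_power")
    return float(marginal_time(m).sum() * m.dt)
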