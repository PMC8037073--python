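"""Synthetic multi-lead ECG with controllable ischemic morphology.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative to
the R peak, plus explicit piecewise-constant level offsets on the ST segment
(between S end and T start) and the PR segment (between P end and Q onset).
This gives direct, auditable control over exactly the quantities the
downstream spectral features respond to: an ischemic ST shift is literally a
level step of known height in mV.

Conditions map to morphology presets:

======================  =======================================
``normal``              no segment offsets
``ischemia_st_elev``    ST offset +0.15 mV
``ischemia_st_dep``     ST offset −0.15 mV
``ischemia_pr_elev``    PR offset +0.10 mV (reference-level drift)
``infarction``          ST offset +0.30 mV and inverted T wave
======================  =======================================

Noise is additive and mirrors the classes the preprocessing filters target:
a low-frequency baseline-wander sinusoid, 50 Hz mains pickup, and
band-limited (20–100 Hz) Gaussian muscle noise.

Everything is deterministic under a seed: identical parameters and seed give
bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, ValidationError
from .records import ECGRecord

_WAVES = ("p", "q", "r", "s", "t")

#: lead labels assigned in order when synthesizing multi-lead records
DEFAULT_LEAD_ORDER = ["I", "II", "III", "V1", "V2", "V3", "V4", "V5", "V6", "aVR", "aVL", "aVF"]


@dataclass
class BeatTemplateParams:
    """Gaussian-bump beat morphology.

    ``amplitudes`` are mV, ``centers`` are seconds relative to the R peak
    (negative = earlier), ``widths`` are Gaussian standard deviations in
    seconds. ``st_offset``/``pr_offset`` are level shifts in mV applied as
    piecewise-constant plateaus on the ST / PR segments.
    """

    amplitudes: dict[str, float] = field(
        default_factory=lambda: {"p": 0.12, "q": -0.10, "r": 1.00, "s": -0.15, "t": 0.30}
    )
    centers: dict[str, float] = field(
        default_factory=lambda: {"p": -0.20, "q": -0.045, "r": 0.0, "s": 0.040, "t": 0.30}
    )
    widths: dict[str, float] = field(
        default_factory=lambda: {"p": 0.025, "q": 0.010, "r": 0.012, "s": 0.010, "t": 0.050}
    )
    st_offset: float = 0.0
    pr_offset: float = 0.0

    def __post_init__(self) -> None:
        for w in _WAVES:
            if w not in self.amplitudes or w not in self.centers or w not in self.widths:
                raise ValidationError(f"missing wave {w!r} in beat template")
            if self.widths[w] <= 0:
                raise ValidationError(f"width of wave {w!r} must be positive")
        if self.amplitudes["r"] <= 0:
            raise ValidationError("R amplitude must be positive")
        order = [self.centers[w] for w in _WAVES]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValidationError(f"wave centers must be ordered P<Q<R<S<T, got {order}")

    # fiducial windows for the level plateaus, seconds relative to R
    def st_window(self) -> tuple[float, float]:
        """[S center + 40 ms, T center − 50 ms]."""
        return self.centers["s"] + 0.04, self.centers["t"] - 0.05

    def pr_window(self) -> tuple[float, float]:
        """[P center + 30 ms, Q center − 20 ms]."""
        return self.centers["p"] + 0.03, self.centers["q"] - 0.02


@dataclass
class NoiseParams:
    """Additive noise mixture amplitudes (mV); all must be non-negative."""

    baseline_amp: float = 0.10
    baseline_freq: float = 0.25
    mains_amp: float = 0.02
    muscle_noise_sd: float = 0.03
    mains_freq: float = 50.0

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.mains_amp, self.muscle_noise_sd) < 0:
            raise ValidationError("noise amplitudes must be non-negative")
        if self.baseline_freq <= 0 or self.mains_freq <= 0:
            raise ValidationError("noise frequencies must be positive")


CONDITION_PRESETS: dict[str, dict] = {
    "normal": {},
    "ischemia_st_elev": {"st_offset": 0.15},
    "ischemia_st_dep": {"st_offset": -0.15},
    "ischemia_pr_elev": {"pr_offset": 0.10},
    "infarction": {"st_offset": 0.30, "t_amplitude": -0.30},
}

CONDITION_LABELS: dict[str, str] = {
    "normal": "normal",
    "ischemia_st_elev": "ischemia",
    "ischemia_st_dep": "ischemia",
    "ischemia_pr_elev": "ischemia",
    "infarction": "infarction",
}


def beat_template_for(condition: str) -> BeatTemplateParams:
    """Morphology preset for a named condition."""
    if condition not in CONDITION_PRESETS:
        raise ParameterError(
            f"unknown condition {condition!r}; choose from {sorted(CONDITION_PRESETS)}"
        )
    preset = CONDITION_PRESETS[condition]
    params = BeatTemplateParams(
        st_offset=preset.get("st_offset", 0.0), pr_offset=preset.get("pr_offset", 0.0)
    )
    if "t_amplitude" in preset:
        params.amplitudes = dict(params.amplitudes, t=preset["t_amplitude"])
    return params


def _compression(rr: float) -> float:
    # beats shorter than 0.8 s squeeze the wave layout proportionally so the
    # template still fits inside one RR interval
    return min(1.0, rr / 0.8)


def generate_beat(params: BeatTemplateParams, fs: float, rr: float) -> np.ndarray:
    """One beat of ``round(rr*fs)`` samples; R peak at 0.35·rr into the beat."""
    if fs < 100:
        raise ParameterError(f"fs must be >= 100 Hz, got {fs}")
    if not 0.4 <= rr <= 2.0:
        raise ParameterError(f"rr must lie in [0.4, 2.0] s, got {rr}")
    n = int(round(rr * fs))
    t = np.arange(n) / fs
    c = _compression(rr)
    t_r = round(0.35 * rr * fs) / fs  # R peak lands on the sample grid
    beat = np.zeros(n)
    for w in _WAVES:
        center = t_r + c * params.centers[w]
        width = c * params.widths[w]
        beat += params.amplitudes[w] * np.exp(-0.5 * ((t - center) / width) ** 2)
    for (lo, hi), level in ((params.st_window(), params.st_offset),
                            (params.pr_window(), params.pr_offset)):
        if level != 0.0:
            mask = (t >= t_r + c * lo) & (t <= t_r + c * hi)
            beat[mask] += level
    return beat


def generate_record(
    condition: str,
    minutes: int = 2,
    n_leads: int = 2,
    fs: float = 250.0,
    hr_mean: float = 60.0,
    seed: int = 0,
    record_id: str | None = None,
    noise: NoiseParams | None = None,
) -> ECGRecord:
    """Synthesize a labeled multi-lead record of exactly ``minutes*60*fs`` samples.

    Per-beat RR intervals jitter around ``60/hr_mean`` s (Gaussian, sd = 3% of
    the mean, truncated to ±10%); each lead carries the same beat train with a
    lead-specific gain in [0.7, 1.3] to mimic lead diversity. If ``noise`` is
    given it is added via :func:`add_noise` with a seed derived from ``seed``.
    """
    if minutes < 1:
        raise ParameterError("minutes must be >= 1")
    if not 1 <= n_leads <= 12:
        raise ParameterError("n_leads must lie in [1, 12]")
    template = beat_template_for(condition)
    rng = np.random.default_rng(seed)
    rr_mean = 60.0 / hr_mean
    n_target = int(round(minutes * 60 * fs))

    chunks, total = [], 0
    while total < n_target:
        rr = rr_mean + np.clip(rng.normal(0.0, 0.03 * rr_mean), -0.1 * rr_mean, 0.1 * rr_mean)
        rr = float(np.clip(rr, 0.4, 2.0))
        beat = generate_beat(template, fs, rr)
        chunks.append(beat)
        total += beat.size
    train = np.concatenate(chunks)[:n_target]

    gains = rng.uniform(0.7, 1.3, size=n_leads)
    signals = gains[:, None] * train[None, :]
    rec = ECGRecord(
        signals=signals,
        fs=fs,
        lead_names=DEFAULT_LEAD_ORDER[:n_leads],
        label=CONDITION_LABELS[condition],
        record_id=record_id or f"{condition}-{seed}",
    )
    if noise is not None:
        rec = add_noise(rec, noise, seed=int(rng.integers(0, 2**31 - 1)))
    return rec


def add_noise(record: ECGRecord, noise: NoiseParams, seed: int = 0) -> ECGRecord:
    """Additive baseline wander + mains + band-limited muscle noise, per lead."""
    rng = np.random.default_rng(seed)
    t = np.arange(record.n_samples) / record.fs
    out = record.signals.copy()
    for i in range(record.n_leads):
        if noise.baseline_amp > 0:
            out[i] += noise.baseline_amp * np.sin(
                2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.mains_amp > 0:
            out[i] += noise.mains_amp * np.sin(
                2 * np.pi * noise.mains_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.muscle_noise_sd > 0:
            white = rng.normal(0.0, noise.muscle_noise_sd, size=record.n_samples)
            out[i] += _bandlimit(white, record.fs, 20.0, 100.0)
    return record.with_signals(out)


def _bandlimit(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    taps = sps.firwin(201, [lo, hi], pass_zero=False, fs=fs)
    return sps.filtfilt(taps, [1.0], x)


def generate_corpus(
    conditions: dict[str, int],
    minutes: int = 3,
    n_leads: int = 2,
    fs: float = 250.0,
    seed: int = 0,
    noise: NoiseParams | None = None,
    hr_mean: float = 60.0,
) -> list[ECGRecord]:
    """Labeled record collection, e.g. ``{"normal": 20, "ischemia_st_elev": 20}``.

    ``noise`` defaults to :class:`NoiseParams` defaults (pass an all-zero
    instance for clean records). Record seeds derive deterministically from
    ``seed``.
    """
    if noise is None:
        noise = NoiseParams()
    rng = np.random.default_rng(seed)
    records = []
    for condition in sorted(conditions):
        for j in range(conditions[condition]):
            records.append(
                generate_record(
                    condition,
                    minutes=minutes,
                    n_leads=n_leads,
                    fs=fs,
                    hr_mean=hr_mean,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    record_id=f"{condition}-{j:03d}",
                    noise=noise,
                )
            )
    return records
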