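"""ST-band and PR-band mean-power features from 1-minute segments.

Myocardial ischemia shifts the ST segment relative to the PR reference
level; in the Choi-Williams plane of a long ECG interval this expresses
itself in fixed frequency bands — 11–14 Hz for ST-related content and
5–8.5 Hz for PR-related content. The feature pair per (record, minute, lead)
is the mean positive-part CWD density over each band, normalized by the mean
over the full post-filter support (0–35 Hz) and expressed as a percentage:

    p_band = 100 * mean(CWD+ over band bins, all time slices)
                 / mean(CWD+ over 0-35 Hz bins, all time slices)

Truncation of the negative part precedes any band averaging. A frequency bin
belongs to a band when its center lies in the closed interval. Because the
preprocessing chain z-scores each lead and the features are ratios, the
features are invariant to any positive gain applied to the raw record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .preprocess import MinuteSegment, segment_minutes
from .records import ECGRecord, FeatureTable
from .tfd import CWDMatrix, cwd, truncate_positive

logger = logging.getLogger(__name__)

ST_BAND = (11.0, 14.0)
PR_BAND = (5.0, 8.5)
FULL_BAND = (0.0, 35.0)


@dataclass
class TFDConfig:
    """Choi-Williams analysis settings used for feature extraction."""

    sigma: float = 1.0
    n_freq: int = 256
    lag_window: int = 127
    time_decimation: int = 4
    st_band: tuple[float, float] = ST_BAND
    pr_band: tuple[float, float] = PR_BAND
    full_band: tuple[float, float] = FULL_BAND


@dataclass
class STPRFeature:
    """Normalized (p_st, p_pr) power percentages for one segment of one lead."""

    p_st: float
    p_pr: float
    record_id: str = "record"
    segment_index: int = 0
    lead_name: str = "lead0"
    label: str | None = None


def band_mean_power(m: CWDMatrix, f_lo: float, f_hi: float) -> float:
    """Mean truncated-CWD density over all time slices and band bins.

    Requires the positive-part (truncated) matrix; bins are selected by
    center inclusion in the closed interval ``[f_lo, f_hi]``.
    """
    if not m.truncated:
        raise ContractError("band_mean_power requires the positive-part (truncated) matrix")
    nyq = m.freq_axis[-1]
    if not 0 <= f_lo < f_hi <= nyq:
        raise ParameterError(f"band ({f_lo}, {f_hi}) outside [0, {nyq}] or empty")
    sel = (m.freq_axis >= f_lo) & (m.freq_axis <= f_hi)
    if not sel.any():
        raise ParameterError(f"no frequency bins fall inside [{f_lo}, {f_hi}] Hz")
    return float(m.values[:, sel].mean())


def extract_st_pr(segment: MinuteSegment, config: TFDConfig | None = None) -> STPRFeature:
    """CWD -> positive-part truncation -> normalized ST/PR band percentages."""
    config = config or TFDConfig()
    meta = dict(
        record_id=segment.record_id,
        segment_index=segment.segment_index,
        lead_name=segment.lead_name,
        label=segment.label,
    )
    if not np.any(segment.samples):
        warnings.warn(
            f"all-zero segment {segment.record_id}/{segment.segment_index}/"
            f"{segment.lead_name}; features set to (0, 0)",
            stacklevel=2,
        )
        return STPRFeature(p_st=0.0, p_pr=0.0, **meta)
    matrix = truncate_positive(
        cwd(
            segment.samples,
            segment.fs,
            sigma=config.sigma,
            n_freq=config.n_freq,
            lag_window=config.lag_window,
            time_decimation=config.time_decimation,
        )
    )
    denom = band_mean_power(matrix, *config.full_band)
    if denom == 0.0:
        warnings.warn("zero full-band power; features set to (0, 0)", stacklevel=2)
        return STPRFeature(p_st=0.0, p_pr=0.0, **meta)
    p_st = 100.0 * band_mean_power(matrix, *config.st_band) / denom
    p_pr = 100.0 * band_mean_power(matrix, *config.pr_band) / denom
    return STPRFeature(p_st=p_st, p_pr=p_pr, **meta)


def extract_dataset(
    records: list[ECGRecord] | list[MinuteSegment],
    config: TFDConfig | None = None,
) -> FeatureTable:
    """One feature row per (record, segment, lead) over preprocessed records.

    Accepts whole records (segmented here) or ready-made minute segments.
    Per-segment failures are logged and skipped rather than aborting the run.
    """
    config = config or TFDConfig()
    segments: list[MinuteSegment] = []
    for item in records:
        if isinstance(item, MinuteSegment):
            segments.append(item)
        else:
            segments.extend(segment_minutes(item))

    rows = []
    for seg in segments:
        try:
            feat = extract_st_pr(seg, config)
        except Exception as exc:
            logger.warning(
                "skipping segment %s/%s/%s: %s",
                seg.record_id, seg.segment_index, seg.lead_name, exc,
            )
            continue
        rows.append(
            {
                "record_id": feat.record_id,
                "segment_index": feat.segment_index,
                "lead_name": feat.lead_name,
                "p_st": feat.p_st,
                "p_pr": feat.p_pr,
                "label": feat.label,
            }
        )
    return FeatureTable(
        pd.DataFrame(
            rows,
            columns=["record_id", "segment_index", "lead_name", "p_st", "p_pr", "label"],
        )
    )
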