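"""ECG record and feature-table data model with file round-tripping.

Two on-disk record formats are supported:

* CSV + JSON sidecar — the package's plain-text fixture format: one column per
  lead (header row = lead names), one row per sample, values in mV; the
  sidecar ``<stem>.json`` declares ``fs`` (Hz), ``record_id`` and an optional
  ``label``.
* WFDB signal/header pairs (``.hea`` + ``.dat``, format 16, interleaved
  little-endian int16) for interoperability with Physionet-style data. Only
  the single-segment format-16 subset is handled; ADC gain and baseline are
  applied on read so in-memory amplitudes are always mV.

Class labels are stored as strings (``normal`` / ``ischemia`` /
``infarction``) so artifacts stay self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

VALID_LABELS = ("normal", "ischemia", "infarction")

#: columns of a feature table, in canonical order
FEATURE_COLUMNS = ["record_id", "segment_index", "lead_name", "p_st", "p_pr", "label"]


@dataclass
class ECGRecord:
    """A multi-lead ECG record.

    Parameters
    ----------
    signals : ndarray, shape (n_leads, n_samples)
        Sample values in mV.
    fs : float
        Sampling rate in Hz.
    lead_names : list of str
        Unique lead identifiers, e.g. ``["I", "III", "V1"]``.
    label : str or None
        Ground-truth class, one of ``normal``/``ischemia``/``infarction``.
    record_id : str
        Identifier used to key derived artifacts.
    """

    signals: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=list)
    label: str | None = None
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.signals.ndim != 2 or self.signals.shape[1] == 0:
            raise ValidationError("signals must be a non-empty (n_leads, n_samples) matrix")
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(self.signals.shape[0])]
        if len(self.lead_names) != self.signals.shape[0]:
            raise ValidationError(
                f"{len(self.lead_names)} lead names for {self.signals.shape[0]} signal rows"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValidationError(f"lead names not unique: {self.lead_names}")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValidationError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def with_signals(self, signals: np.ndarray, fs: float | None = None) -> "ECGRecord":
        """Copy of this record with new sample data (same leads/label/id)."""
        return replace(self, signals=signals, fs=self.fs if fs is None else fs)


def read_record(path: str | Path, format: str | None = None) -> ECGRecord:
    """Read an ECG record from ``csv`` (+ JSON sidecar) or ``wfdb`` files.

    ``format`` may be omitted, in which case it is inferred from the file
    suffix (``.csv`` vs ``.hea``/``.dat``/bare record name).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb"
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ParameterError(f"unknown record format {format!r}")


def write_record(record: ECGRecord, path: str | Path, format: str | None = None) -> None:
    """Write a record so that :func:`read_record` round-trips it."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb"
    if format == "csv":
        _write_csv(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ParameterError(f"unknown record format {format!r}")


# ---------------------------------------------------------------------------
# CSV + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_csv(path: Path) -> ECGRecord:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar} declaring fs")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise FormatError(f"sidecar {sidecar} does not declare 'fs'")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if frame.isna().any().any():
        raise ValidationError(f"{path}: ragged or non-numeric lead columns")
    return ECGRecord(
        signals=frame.to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        lead_names=list(frame.columns),
        label=meta.get("label"),
        record_id=meta.get("record_id", path.stem),
    )


def _write_csv(record: ECGRecord, path: Path) -> None:
    frame = pd.DataFrame(record.signals.T, columns=record.lead_names)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.9g")
    meta = {"fs": record.fs, "record_id": record.record_id, "label": record.label}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Minimal WFDB (single-segment, format 16)

_WFDB_FMT = "16"
_WFDB_GAIN = 2000.0  # ADC units per mV: 16-bit range maps +/-16 mV, ample for ECG


def _read_wfdb(path: Path) -> ECGRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"no such header: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if not ln.startswith("#")]
    head = body[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: header line must carry record n_sig fs n_samples")
    record_id, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    sig_lines = body[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise FormatError(f"{hea}: expected {n_sig} signal lines")

    gains, baselines, names, dat_names = [], [], [], []
    for i, ln in enumerate(sig_lines):
        tok = ln.split()
        if len(tok) < 2 or tok[1].split("x")[0] != _WFDB_FMT:
            raise FormatError(f"{hea}: only format {_WFDB_FMT} is supported, got {ln!r}")
        dat_names.append(tok[0])
        gspec = tok[2] if len(tok) > 2 else "200"
        gpart = gspec.split("/")[0]
        if "(" in gpart:
            g, b = gpart[:-1].split("(")
        else:
            g, b = gpart, "0"
        gain = float(g) if float(g) != 0 else 200.0
        gains.append(gain)
        baselines.append(int(b))
        names.append(tok[8] if len(tok) > 8 else f"lead{i}")

    if len(set(dat_names)) != 1:
        raise FormatError(f"{hea}: multi-file signal layout not supported")
    dat = hea.with_name(dat_names[0])
    if not dat.exists():
        raise FormatError(f"no such signal file: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samples:
        raise ValidationError(
            f"{dat}: {raw.size} samples do not factor as {n_sig} leads x {n_samples}"
        )
    adc = raw.reshape(n_samples, n_sig).T.astype(float)
    signals = (adc - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]

    label = None
    for c in comments:
        if c.lower().startswith("label:"):
            label = c.split(":", 1)[1].strip() or None
    return ECGRecord(signals=signals, fs=fs, lead_names=names, label=label, record_id=record_id)


def _write_wfdb(record: ECGRecord, path: Path) -> None:
    base = path.with_suffix("") if path.suffix in {".hea", ".dat"} else path
    base.parent.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.signals * _WFDB_GAIN)
    if np.abs(adc).max(initial=0) > 32767:
        raise ValidationError("amplitudes exceed the 16-bit WFDB range at gain 2000/mV")
    adc16 = adc.astype("<i2")
    adc16.T.reshape(-1).tofile(base.with_suffix(".dat"))

    fs_str = f"{record.fs:g}"
    lines = [f"{record.record_id} {record.n_leads} {fs_str} {record.n_samples}"]
    for i, name in enumerate(record.lead_names):
        first = int(adc16[i, 0])
        checksum = int(np.sum(adc16[i].astype(np.int64)) % 65536)
        lines.append(
            f"{base.name}.dat {_WFDB_FMT} {_WFDB_GAIN:g}(0)/mV 16 0 {first} {checksum} 0 {name}"
        )
    if record.label is not None:
        lines.append(f"# label: {record.label}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Feature tables


@dataclass
class FeatureTable:
    """Per-(record, segment, lead) ST/PR band-power features.

    Thin validated wrapper around a :class:`pandas.DataFrame` with columns
    ``record_id, segment_index, lead_name, p_st, p_pr, label``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        frame = pd.DataFrame(self.data)
        missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"feature table missing columns {missing}")
        frame = frame[FEATURE_COLUMNS].copy()
        frame["segment_index"] = frame["segment_index"].astype(int)
        for col in ("p_st", "p_pr"):
            frame[col] = frame[col].astype(float)
            if (frame[col] < 0).any():
                raise ValidationError(f"{col} must be non-negative (post-truncation power)")
        bad = frame["label"].dropna()
        bad = bad[~bad.isin(VALID_LABELS)]
        if len(bad):
            raise ValidationError(f"unknown labels {sorted(set(bad))}")
        keys = frame[["record_id", "segment_index", "lead_name"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate feature key {tuple(dup)}")
        self.data = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        a = self.data.sort_values(["record_id", "segment_index", "lead_name"]).reset_index(drop=True)
        b = other.data.sort_values(["record_id", "segment_index", "lead_name"]).reset_index(drop=True)
        return a.equals(b)

    @property
    def leads(self) -> list[str]:
        return sorted(self.data["lead_name"].unique())


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype={"record_id": str, "lead_name": str})
    if "label" in frame.columns:
        frame["label"] = frame["label"].where(frame["label"].notna(), None)
    return FeatureTable(frame)
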