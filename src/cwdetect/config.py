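"""Pipeline configuration: one flat, validated bundle of every tunable.

Loadable from YAML (`PipelineConfig.from_yaml`); CLI flags override file
values. Validation happens up front, before any stage runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import ParameterError
from .features import FULL_BAND, PR_BAND, ST_BAND, TFDConfig
from .preprocess import BP_TAPS, HP_TAPS


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline with their defaults."""

    # preprocessing
    target_fs: float = 250.0
    hp_cutoff: float = 0.5
    hp_taps: int = HP_TAPS
    bp_low: float = 2.0
    bp_high: float = 35.0
    bp_taps: int = BP_TAPS
    # Choi-Williams analysis
    sigma: float = 1.0
    n_freq: int = 256
    lag_window: int = 127
    time_decimation: int = 4
    st_low: float = ST_BAND[0]
    st_high: float = ST_BAND[1]
    pr_low: float = PR_BAND[0]
    pr_high: float = PR_BAND[1]
    full_low: float = FULL_BAND[0]
    full_high: float = FULL_BAND[1]
    # classifier
    sigma_rbf: float = 0.1
    gamma_cost: float = 10.0
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.target_fs > 0, "target_fs must be positive"),
            (0 < self.hp_cutoff < self.target_fs / 2, "hp_cutoff outside (0, Nyquist)"),
            (0 < self.bp_low < self.bp_high < self.target_fs / 2, "band-pass edges invalid"),
            (self.hp_taps % 2 == 1 and self.bp_taps % 2 == 1, "filter taps must be odd"),
            (self.sigma > 0, "CWD sigma must be positive"),
            (self.n_freq >= 2 and (self.n_freq & (self.n_freq - 1)) == 0,
             "n_freq must be a power of two"),
            (self.lag_window >= 3 and self.lag_window % 2 == 1,
             "lag_window must be odd and >= 3"),
            (self.time_decimation >= 1, "time_decimation must be >= 1"),
            (0 <= self.st_low < self.st_high <= self.target_fs / 2, "ST band invalid"),
            (0 <= self.pr_low < self.pr_high <= self.target_fs / 2, "PR band invalid"),
            (0 <= self.full_low < self.full_high <= self.target_fs / 2, "full band invalid"),
            (self.sigma_rbf > 0, "sigma_rbf must be positive"),
            (self.gamma_cost > 0, "gamma_cost must be positive"),
            (self.k_folds >= 2, "k_folds must be >= 2"),
            (0 <= self.seed < 2**31, "seed must fit in a signed 32-bit integer"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(msg)

    @property
    def tfd(self) -> TFDConfig:
        return TFDConfig(
            sigma=self.sigma,
            n_freq=self.n_freq,
            lag_window=self.lag_window,
            time_decimation=self.time_decimation,
            st_band=(self.st_low, self.st_high),
            pr_band=(self.pr_low, self.pr_high),
            full_band=(self.full_low, self.full_high),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
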