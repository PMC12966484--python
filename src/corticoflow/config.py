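"""Run configuration shared by all pipeline stages.

Every numeric analysis constant (windows, surrogate counts, thresholds) lives
here so that a run's parameters can be echoed verbatim into output metadata.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    Times are in milliseconds unless a ``_s``/``_hz`` suffix says otherwise;
    distances in millimeters; stimulation intensities in milliamperes.
    """

    seed: int = 0
    #: samples after stimulus onset replaced by linear interpolation
    artifact_window_ms: float = 12.0
    #: width of the line-length integration window
    ll_window_ms: float = 250.0
    #: post-stimulus epoch analysed for a response
    post_window_ms: float = 500.0
    #: pre-stimulus epoch used for surrogates and baseline statistics
    pre_window_ms: float = 600.0
    #: cross-correlation lag range for trial-vs-centroid matching
    max_lag_ms: float = 10.0
    #: surrogate counts: single-trial null / per-centroid null / excitability null
    n_trial_surrogates: int = 400
    n_centroid_surrogates: int = 200
    n_exi_surrogates: int = 200
    #: connection-class thresholds
    distance_threshold_mm: float = 25.0
    latency_threshold_ms: float = 65.0
    #: one-sided surrogate percentile for significance
    percentile: float = 95.0
    fdr_alpha: float = 0.05
    #: minimum trials for a stable magnitude / complete intensity level
    min_trials: int = 5
    #: sampling rate after preprocessing
    target_rate_hz: float = 500.0
    #: trials with line length above this multiple of the connection median
    #: are flagged (automated stand-in for visual artifact review)
    outlier_ll_factor: float = 4.0
    #: whether flagged outliers are excluded from probability denominators
    #: as well as magnitude averages ("both") or kept ("flag_only")
    outlier_mode: str = "both"

    def __post_init__(self) -> None:
        for name in (
            "artifact_window_ms",
            "ll_window_ms",
            "post_window_ms",
            "pre_window_ms",
            "target_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 50.0 < self.percentile < 100.0:
            raise ValueError(f"percentile must be in (50, 100), got {self.percentile}")
        if self.outlier_mode not in ("both", "flag_only"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")

    # -- derived sample counts -------------------------------------------------
    def n_pre_samples(self, fs: float | None = None) -> int:
        fs = self.target_rate_hz if fs is None else fs
        return int(round(self.pre_window_ms * fs / 1000.0))

    def n_post_samples(self, fs: float | None = None) -> int:
        fs = self.target_rate_hz if fs is None else fs
        return int(round(self.post_window_ms * fs / 1000.0))

    def n_ll_samples(self, fs: float | None = None) -> int:
        fs = self.target_rate_hz if fs is None else fs
        return int(round(self.ll_window_ms * fs / 1000.0))

    def artifact_offset_samples(self, fs: float | None = None) -> int:
        fs = self.target_rate_hz if fs is None else fs
        return int(round(self.artifact_window_ms * fs / 1000.0))

    def max_lag_samples(self, fs: float | None = None) -> int:
        fs = self.target_rate_hz if fs is None else fs
        return int(round(self.max_lag_ms * fs / 1000.0))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
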