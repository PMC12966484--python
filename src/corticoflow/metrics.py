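"""Connection-level quantities derived from single-trial decisions.

Signaling probability P (significant responses out of delivered
stimulations), the directionality index DI = (P_AB − P_BA)/max(P_AB, P_BA),
connection classes by distance and latency, response magnitude (line length
of the average significant response), and the excitability index ExI (area
under the normalized stimulation–response curve).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import RunConfig
from .detection import line_length, _sample_epochs

__all__ = [
    "ConnectionMetrics",
    "StimResponseCurve",
    "signaling_probability",
    "directionality_index",
    "classify_connection",
    "response_magnitude",
    "build_sr_curve",
    "excitability_index",
    "excitability_significance",
]

#: Intensity normalization anchors: 0 at 0.2 mA, 1 at 12 mA.
INTENSITY_MIN_MA = 0.2
INTENSITY_MAX_MA = 12.0


@dataclass
class ConnectionMetrics:
    """Summary of one directed connection in one vigilance state."""

    connection: tuple[str, str]
    n_stims: int
    n_significant: int
    probability: float
    latency_ms: float = float("nan")
    magnitude: float = float("nan")
    distance_mm: float = float("nan")
    connection_class: str = "unclassified"
    state: str = "pooled"


def signaling_probability(trial_decisions: Sequence[bool]) -> tuple[float, int, int]:
    """P = significant single-trial responses / delivered stimulations.

    Returns (P, n_significant, n_stims); raises on zero stimulations since an
    unprobed connection has no probability (not P = 0).
    """
    decisions = np.asarray(trial_decisions, bool)
    if decisions.size == 0:
        raise ValueError("signaling probability undefined for zero stimulations")
    n_sig = int(decisions.sum())
    return n_sig / decisions.size, n_sig, decisions.size


def directionality_index(p_ab: float, p_ba: float) -> float:
    """DI_AB = (P_AB − P_BA) / max(P_AB, P_BA).

    DI → 0 for bidirectional signaling, +1 for a pure efference, −1 for a
    pure afference; |DI| = 0.5 already means a doubling of signaling in one
    direction.  When both probabilities are zero the index is undefined and
    NaN is returned (distinct from 0, which would assert bidirectionality).
    """
    for p in (p_ab, p_ba):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    denom = max(p_ab, p_ba)
    if denom == 0.0:
        return float("nan")
    return (p_ab - p_ba) / denom


def classify_connection(
    distance_mm: float,
    latency_ms: float,
    same_region: bool,
    same_hemisphere: bool = True,
    config: RunConfig | None = None,
) -> str:
    """Three connection classes by distance and signaling latency.

    local: within 25 mm, same hemisphere and brain region; long-range
    otherwise, split at 65 ms into short- and long-latency.  Long-range
    connections without a measurable latency are 'unclassified'.
    """
    config = config or RunConfig()
    if distance_mm <= config.distance_threshold_mm and same_region and same_hemisphere:
        return "local"
    if np.isnan(latency_ms):
        return "unclassified"
    if latency_ms <= config.latency_threshold_ms:
        return "long_short"
    return "long_long"


def response_magnitude(
    significant_windows: np.ndarray,
    sampling_rate: float,
    min_trials: int = 5,
) -> float:
    """Line length of the pointwise average of ≥ 5 significant trials.

    NaN (undefined) when fewer significant trials are available — a
    magnitude from a sparser average would not be stable.
    """
    W = np.atleast_2d(np.asarray(significant_windows, float))
    if W.shape[0] < min_trials or W.size == 0:
        return float("nan")
    return line_length(W.mean(axis=0), sampling_rate)


# ---------------------------------------------------------------------------
# stimulation-response curve / excitability
# ---------------------------------------------------------------------------

@dataclass
class StimResponseCurve:
    """Response magnitude vs stimulation intensity for one connection/state."""

    intensities_ma: np.ndarray
    magnitudes: np.ndarray
    n_trials: np.ndarray
    state: str = "W"
    wake_max: float = float("nan")  # normalization anchor (max LL in wake)
    min_trials: int = 5

    def __post_init__(self) -> None:
        self.intensities_ma = np.asarray(self.intensities_ma, float)
        self.magnitudes = np.asarray(self.magnitudes, float)
        self.n_trials = np.asarray(self.n_trials, int)
        order = np.argsort(self.intensities_ma)
        self.intensities_ma = self.intensities_ma[order]
        self.magnitudes = self.magnitudes[order]
        self.n_trials = self.n_trials[order]

    @property
    def complete(self) -> np.ndarray:
        """Levels with at least ``min_trials`` trials and a finite magnitude."""
        return (self.n_trials >= self.min_trials) & np.isfinite(self.magnitudes)

    @property
    def normalized_intensity(self) -> np.ndarray:
        return (self.intensities_ma - INTENSITY_MIN_MA) / (INTENSITY_MAX_MA - INTENSITY_MIN_MA)

    @property
    def normalized_magnitude(self) -> np.ndarray:
        anchor = self.wake_max
        if not np.isfinite(anchor) or anchor <= 0:
            finite = self.magnitudes[self.complete]
            anchor = finite.max() if finite.size else float("nan")
        return np.clip(self.magnitudes / anchor, 0.0, 1.0)


def build_sr_curve(
    intensities_ma: Sequence[float],
    magnitudes: Sequence[float],
    n_trials: Sequence[int],
    state: str = "W",
    wake_max: float = float("nan"),
    min_trials: int = 5,
) -> StimResponseCurve:
    return StimResponseCurve(
        np.asarray(intensities_ma), np.asarray(magnitudes), np.asarray(n_trials), state, wake_max, min_trials
    )


def excitability_index(curve: StimResponseCurve) -> float:
    """ExI: trapezoidal area under the normalized stimulation–response curve.

    Magnitude is normalized to the connection's maximal wake LL and intensity
    to [0, 1] over 0.2–12 mA; incomplete levels (< 5 trials) are excluded and
    the trapezoid runs over the available levels without interpolation.
    ExI → 1 is maximal sensitivity at minimal intensity, ≈ 0.5 a linear
    increase over the full range, → 0 non-excitable.  NaN when fewer than two
    complete levels remain.
    """
    keep = curve.complete
    if keep.sum() < 2:
        return float("nan")
    x = curve.normalized_intensity[keep]
    y = curve.normalized_magnitude[keep]
    return float(np.clip(np.trapezoid(y, x), 0.0, 1.0))


def excitability_significance(
    curve: StimResponseCurve,
    baseline: np.ndarray,
    sampling_rate: float,
    seed: int | np.random.Generator = 0,
    config: RunConfig | None = None,
) -> tuple[bool, float]:
    """Test an ExI against 200 surrogate stimulation–response curves.

    Each surrogate curve replaces every complete level's average response by
    an average of the same number of baseline epochs (same channel, same
    line-length window) and recomputes the area with the same normalization
    anchor.  Returns (significant, surrogate 95th percentile).
    """
    config = config or RunConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = curve.complete
    if keep.sum() < 2:
        return False, float("nan")
    m = config.n_ll_samples(sampling_rate)
    counts = curve.n_trials[keep]
    anchor = curve.wake_max
    if not np.isfinite(anchor) or anchor <= 0:
        anchor = curve.magnitudes[keep].max()
    x = curve.normalized_intensity[keep]
    surrogate_exi = np.empty(config.n_exi_surrogates)
    for s in range(config.n_exi_surrogates):
        mags = np.empty(counts.size)
        for j, count in enumerate(counts):
            epochs = _sample_epochs(np.asarray(baseline, float), int(count), m, rng)
            mags[j] = line_length(epochs.mean(axis=0), sampling_rate)
        y = np.clip(mags / anchor, 0.0, 1.0)
        surrogate_exi[s] = np.clip(np.trapezoid(y, x), 0.0, 1.0)
    observed = excitability_index(curve)
    threshold = float(np.percentile(surrogate_exi, config.percentile))
    return bool(observed > threshold), threshold
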