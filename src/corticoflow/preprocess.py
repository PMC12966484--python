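"""Raw recording → clean epoched trials.

Stages, in order: stimulation-artifact removal by linear interpolation
(10–15 ms after each pulse), zero-phase bandpass (0.5–200 Hz) and notch
(50 Hz + harmonics) filtering, polyphase downsampling to 500 Hz, robust
per-channel rescaling, and epoch extraction around each stimulation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .config import RunConfig
from .synthetic_data import BipolarRecording, StimEvent, VigilanceTrack

__all__ = [
    "Trial",
    "interpolate_artifact",
    "filter_resample",
    "rescale_channels",
    "epoch_trials",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)


@dataclass
class Trial:
    """One peri-stimulation epoch on one recording channel.

    ``pre`` covers [T0 − pre_window, T0), ``post`` covers
    [T0, T0 + post_window); the two are contiguous at T0.
    """

    stim_pair: str
    channel: str
    onset_s: float
    intensity_ma: float
    state: str
    pre: np.ndarray
    post: np.ndarray
    sampling_rate: float
    event_idx: int = -1
    block_kind: str = "mapping"

    @property
    def connection(self) -> tuple[str, str]:
        return (self.stim_pair, self.channel)


def interpolate_artifact(
    signal: np.ndarray,
    onsets_s: Sequence[float],
    sampling_rate: float,
    window_ms: float = 12.0,
) -> tuple[np.ndarray, int]:
    """Replace the artifact span after each stimulation with a straight line.

    Samples in [T0, T0 + window_ms] are replaced by the line joining the
    bracketing samples; everything else is returned bit-identical.  Events
    lacking a bracketing sample at either edge are dropped (counted, logged).
    """
    if not 10.0 <= window_ms <= 15.0:
        raise ValueError(f"window_ms must be in [10, 15], got {window_ms}")
    sig = np.array(signal, float, copy=True)
    one_d = sig.ndim == 1
    if one_d:
        sig = sig[None, :]
    n = sig.shape[1]
    span = int(round(window_ms / 1000.0 * sampling_rate))
    dropped = 0
    for t0 in onsets_s:
        i0 = int(round(t0 * sampling_rate))
        i1 = i0 + span  # inclusive end of the replaced range
        if i0 - 1 < 0 or i1 + 1 >= n:
            dropped += 1
            logger.warning("event at %.3f s lacks bracketing samples; dropped", t0)
            continue
        left = sig[:, i0 - 1]
        right = sig[:, i1 + 1]
        frac = np.arange(1, span + 2) / (span + 2)
        sig[:, i0 : i1 + 1] = left[:, None] + (right - left)[:, None] * frac[None, :]
    return (sig[0] if one_d else sig), dropped


def _design_filters(fs: float, band=(0.5, 200.0), notches=(50.0, 100.0, 150.0, 200.0), q=30.0):
    nyq = fs / 2.0
    high = min(band[1], 0.95 * nyq)
    sos = sps.butter(4, [band[0] / nyq, high / nyq], btype="bandpass", output="sos")
    notch_ba = [sps.iirnotch(f0, q, fs=fs) for f0 in notches if f0 < nyq]
    return sos, notch_ba


def filter_resample(
    signal: np.ndarray,
    sampling_rate: float,
    target_rate: float = 500.0,
    band: tuple[float, float] = (0.5, 200.0),
    notches: Sequence[float] = (50.0, 100.0, 150.0, 200.0),
) -> np.ndarray:
    """Zero-phase bandpass + notch filtering, then resample to 500 Hz.

    4th-order Butterworth bandpass and 2nd-order notches, both applied
    forward-backward so latencies are preserved; polyphase rational
    resampling handles the non-integer 1024→500 Hz ratio.
    """
    if sampling_rate < target_rate:
        raise ValueError(
            f"input rate {sampling_rate} Hz below target {target_rate} Hz; cannot downsample"
        )
    sig = np.atleast_2d(np.asarray(signal, float))
    sos, notch_ba = _design_filters(sampling_rate, band, tuple(notches))
    out = sps.sosfiltfilt(sos, sig, axis=1)
    for b, a in notch_ba:
        out = sps.filtfilt(b, a, out, axis=1)
    if sampling_rate != target_rate:
        frac = Fraction(target_rate / sampling_rate).limit_denominator(1000)
        out = sps.resample_poly(out, frac.numerator, frac.denominator, axis=1)
    return out[0] if np.asarray(signal).ndim == 1 else out


def rescale_channels(
    signal: np.ndarray,
    sampling_rate: float,
    baseline_windows_s: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Bring channels to a shared robust scale.

    Each channel is divided by 1.4826 × the median absolute deviation of its
    non-stimulated baseline segments (a robust SD, insensitive to evoked
    outliers).  Returns the rescaled signal and the per-channel factors.
    """
    sig = np.atleast_2d(np.asarray(signal, float))
    idx = []
    n = sig.shape[1]
    for start, end in baseline_windows_s:
        i0, i1 = int(round(start * sampling_rate)), int(round(end * sampling_rate))
        idx.append(np.arange(max(i0, 0), min(i1, n)))
    if not idx:
        raise ValueError("no baseline windows supplied")
    cols = np.concatenate(idx)
    base = sig[:, cols]
    mad = np.median(np.abs(base - np.median(base, axis=1, keepdims=True)), axis=1)
    factors = 1.4826 * mad
    factors[factors == 0] = 1.0
    out = sig / factors[:, None]
    return (out[0] if np.asarray(signal).ndim == 1 else out), factors


def preprocess_recording(
    recording: BipolarRecording,
    events: Sequence[StimEvent],
    baseline_windows_s: Sequence[tuple[float, float]],
    config: RunConfig | None = None,
) -> tuple[BipolarRecording, dict]:
    """Full preprocessing chain on a raw recording.

    Artifact interpolation at the native rate, filtering, resampling to the
    target rate, then robust rescaling against the baseline windows.
    """
    config = config or RunConfig()
    sig, dropped = interpolate_artifact(
        recording.signal,
        [e.onset_s for e in events],
        recording.sampling_rate,
        config.artifact_window_ms,
    )
    sig = filter_resample(sig, recording.sampling_rate, config.target_rate_hz)
    sig, factors = rescale_channels(sig, config.target_rate_hz, baseline_windows_s)
    out = BipolarRecording(
        sig, config.target_rate_hz, recording.channel_table.copy(), recording.start_time
    )
    info = {
        "dropped_edge_events": dropped,
        "rescale_factors": factors.tolist(),
        "artifact_window_ms": config.artifact_window_ms,
        "target_rate_hz": config.target_rate_hz,
    }
    return out, info


def epoch_trials(
    recording: BipolarRecording,
    events: Sequence[StimEvent],
    vigilance: VigilanceTrack | None = None,
    config: RunConfig | None = None,
) -> tuple[list[Trial], int]:
    """Cut one trial per (event, non-stimulated channel).

    Trials whose pre/post windows overlap a recording edge are dropped and
    counted.  Each trial is tagged with the vigilance state containing its
    onset ('unknown' when unscored — such trials are excluded from
    state contrasts only).
    """
    config = config or RunConfig()
    fs = recording.sampling_rate
    n_pre = config.n_pre_samples(fs)
    n_post = config.n_post_samples(fs)
    n = recording.signal.shape[1]
    trials: list[Trial] = []
    dropped = 0
    for ev_idx, ev in enumerate(events):
        i0 = int(round(ev.onset_s * fs))
        if i0 - n_pre < 0 or i0 + n_post > n:
            dropped += 1
            continue
        state = vigilance.state_at(ev.onset_s) if vigilance is not None else "unknown"
        for ci, ch in enumerate(recording.channel_names):
            if ch == ev.stim_pair:
                continue
            trials.append(
                Trial(
                    stim_pair=ev.stim_pair,
                    channel=ch,
                    onset_s=ev.onset_s,
                    intensity_ma=ev.intensity_ma,
                    state=state,
                    pre=recording.signal[ci, i0 - n_pre : i0].copy(),
                    post=recording.signal[ci, i0 : i0 + n_post].copy(),
                    sampling_rate=fs,
                    event_idx=ev_idx,
                    block_kind=ev.block_kind,
                )
            )
    return trials, dropped
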