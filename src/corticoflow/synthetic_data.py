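"""Synthetic stimulation sessions with known ground truth.

This module generates everything the analysis consumes: a directed
ground-truth network between bipolar iEEG electrodes, an hourly-block
stimulation schedule, a vigilance (sleep-stage) track, and the multichannel
signal itself — 1/f background noise with 50 Hz line contamination, brief
stimulation artifacts, and stereotyped biphasic evoked responses injected
with per-connection probability, latency, amplitude, and state-dependent
modulation.  Every draw is controlled by an explicit seed and the generator
emits an exact per-trial injection table so recovery tests can compare
against truth.

Two levels of realism are offered:

* :func:`simulate_session` renders a full continuous recording that must be
  preprocessed (artifact interpolation, filtering, resampling) before
  analysis — this exercises the whole pipeline.
* :func:`simulate_connection_trials` renders already-epoched trials of one
  directed connection (band-limited 1/f noise, no line or artifact, i.e. the
  statistical equivalent of preprocessed data), which is what calibration
  and parameter-recovery studies use.
"""
from __future__ import annotations


from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SR_INTENSITIES_MA",
    "MAPPING_INTENSITY_MA",
    "VIGILANCE_STATES",
    "ConnectionParams",
    "GroundTruthNetwork",
    "StimEvent",
    "VigilanceTrack",
    "BipolarRecording",
    "ScheduleInfeasibleError",
    "evoked_waveform",
    "pink_noise",
    "intensity_scale",
    "build_schedule",
    "baseline_windows",
    "simulate_session",
    "simulate_baseline",
    "simulate_connection_trials",
    "ConnectionTrials",
    "make_incidence_matrix",
    "demo_network",
]

#: The 14 single-pulse intensities (mA) of the stimulation-response protocol,
#: spanning the 0.2–12 mA range delivered in randomized triplicates.
SR_INTENSITIES_MA: tuple[float, ...] = (
    0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 11.0, 12.0,
)

#: Fixed intensity (mA) used for the hourly full-map blocks.
MAPPING_INTENSITY_MA: float = 3.0

VIGILANCE_STATES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: Map from scored stage to the coarse state class used for gains/contrasts.
STATE_CLASS: dict[str, str] = {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "R": "REM"}


class ScheduleInfeasibleError(ValueError):
    """Requested session too short to host one full stimulation block."""


class SchemaError(ValueError):
    """An event or table references an unknown electrode/field."""


# ---------------------------------------------------------------------------
# ground-truth network
# ---------------------------------------------------------------------------

@dataclass
class ConnectionParams:
    """Generative parameters of one directed connection A→B.

    ``true_probability`` is the chance a 3 mA mapping pulse evokes a response
    in wakefulness; it may be a per-state-class mapping ({'W','NREM','REM'})
    when probability itself is state dependent.  ``state_gain`` multiplies
    the evoked *amplitude* per state class (sleep modulation of response
    magnitude).  Intensity dependence is a logistic in mA with the given
    midpoint and slope, scaling both response probability and amplitude.
    """

    true_probability: float | Mapping[str, float] = 0.8
    latency_ms: float = 40.0
    amplitude: float = 50.0
    sigmoid_midpoint_ma: float = 1.0
    sigmoid_slope: float = 3.0
    state_gain: Mapping[str, float] = field(
        default_factory=lambda: {"W": 1.0, "NREM": 1.0, "REM": 1.0}
    )
    amp_jitter_sigma: float = 0.3
    latency_jitter_ms: float = 5.0

    def probability(self, state_class: str) -> float:
        if isinstance(self.true_probability, Mapping):
            return float(self.true_probability.get(state_class, 0.0))
        return float(self.true_probability)

    def validate(self) -> None:
        probs = (
            list(self.true_probability.values())
            if isinstance(self.true_probability, Mapping)
            else [self.true_probability]
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"true_probability {p} outside [0, 1]")
        if not (np.isfinite(self.latency_ms) and self.latency_ms > 0):
            raise ValueError(f"latency_ms must be positive/finite, got {self.latency_ms}")


@dataclass
class GroundTruthNetwork:
    """Electrode table plus directed connection parameters.

    ``electrodes`` columns: name, region, hemisphere, x_mm, y_mm, z_mm.
    ``connections`` maps ordered (stim, response) electrode-name pairs to
    :class:`ConnectionParams`; absent pairs are unconnected.
    """

    electrodes: pd.DataFrame
    connections: dict[tuple[str, str], ConnectionParams]

    def __post_init__(self) -> None:
        required = {"name", "region", "hemisphere", "x_mm", "y_mm", "z_mm"}
        missing = required - set(self.electrodes.columns)
        if missing:
            raise SchemaError(f"electrode table missing columns {sorted(missing)}")
        names = set(self.electrodes["name"])
        for (a, b), params in self.connections.items():
            if a == b:
                raise ValueError(f"self-connection {a}→{b} not allowed")
            if a not in names or b not in names:
                raise SchemaError(f"connection {a}→{b} references unknown electrode")
            params.validate()

    @property
    def names(self) -> list[str]:
        return list(self.electrodes["name"])

    def coords(self) -> np.ndarray:
        return self.electrodes[["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    def distance_mm(self, a: str, b: str) -> float:
        tab = self.electrodes.set_index("name")
        pa = tab.loc[a, ["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        pb = tab.loc[b, ["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        return float(np.linalg.norm(pa - pb))

    def distance_matrix(self) -> pd.DataFrame:
        xyz = self.coords()
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        return pd.DataFrame(d, index=self.names, columns=self.names)


# ---------------------------------------------------------------------------
# events, vigilance, recording containers
# ---------------------------------------------------------------------------

@dataclass
class StimEvent:
    """One delivered single pulse."""

    onset_s: float
    stim_pair: str
    intensity_ma: float
    pulse_width_ms: float = 1.0
    block_id: int = 0
    block_kind: str = "mapping"  # baseline | mapping | sr_curve


@dataclass
class VigilanceTrack:
    """Ordered, non-overlapping scored segments (start_s, end_s, state)."""

    segments: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, state in self.segments:
            if state not in VIGILANCE_STATES:
                raise ValueError(f"unknown vigilance state {state!r}")
            if end <= start or start < prev_end:
                raise ValueError("vigilance segments must be ordered and non-overlapping")
            prev_end = end

    @classmethod
    def constant(cls, duration_s: float, state: str = "W") -> "VigilanceTrack":
        return cls([(0.0, float(duration_s), state)])

    def state_at(self, t: float) -> str:
        for start, end, state in self.segments:
            if start <= t < end:
                return state
        return "unknown"

    @property
    def end_s(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0


@dataclass
class BipolarRecording:
    """Multichannel bipolar signal matrix with channel metadata."""

    signal: np.ndarray  # channels x samples, microvolt scale
    sampling_rate: float
    channel_table: pd.DataFrame  # name, region, hemisphere, x_mm, y_mm, z_mm
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(self.channel_table) != self.signal.shape[0]:
            raise SchemaError("channel table length does not match signal rows")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return list(self.channel_table["name"])


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def intensity_scale(intensity_ma, midpoint_ma: float, slope: float):
    """Logistic intensity dependence in (0, 1), ≈1 well above the midpoint."""
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(intensity_ma, float) - midpoint_ma)))


def evoked_waveform(
    n_samples: int,
    fs: float,
    latency_ms: float,
    amplitude: float = 1.0,
    second_peak_factor: float = 2.5,
    amp_ratio: float = 0.6,
    width1_ms: float | None = None,
    width2_ms: float | None = None,
) -> np.ndarray:
    """Stereotyped biphasic evoked response.

    Sum of two Gaussian-windowed deflections of opposite polarity: an early
    sharp negativity peaking at ``latency_ms`` and a later broad positivity
    near ``second_peak_factor * latency_ms`` — the two peaks a 250 ms
    integration window is meant to capture.  ``amplitude`` is the magnitude
    of the first peak in signal units.
    """
    t = np.arange(n_samples) / fs * 1000.0
    w1 = width1_ms if width1_ms is not None else max(4.0, 0.2 * latency_ms)
    w2 = width2_ms if width2_ms is not None else max(10.0, 0.5 * latency_ms)
    wave = -np.exp(-0.5 * ((t - latency_ms) / w1) ** 2)
    wave += amp_ratio * np.exp(-0.5 * ((t - second_peak_factor * latency_ms) / w2) ** 2)
    return amplitude * wave


def pink_noise(
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    sd: float = 1.0,
    f_min: float | None = None,
) -> np.ndarray:
    """1/f-power background noise, normalized to the requested SD.

    With ``f_min`` set, the spectrum flattens below that frequency —
    the band-limited shape of recordings after a high-pass filter; without
    it the spectrum is pure 1/f down to the resolution of the stream.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.zeros_like(f)
    nz = f > 0
    floor = f_min if f_min is not None else 0.0
    scale[nz] = 1.0 / np.sqrt(np.maximum(f[nz], floor))  # power ∝ 1/f above f_min
    x = np.fft.irfft(spec * scale, n_samples)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def baseline_windows(
    duration_h: float, baseline_s: float = 300.0, block_interval_s: float = 3600.0
) -> list[tuple[float, float]]:
    """Stimulation-free window at the start of each block (hourly by default)."""
    n_blocks = int(np.floor(duration_h * 3600.0 / block_interval_s))
    return [(b * block_interval_s, b * block_interval_s + baseline_s) for b in range(max(n_blocks, 1))]


def _draw_isi(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    isi = rng.normal(mean, sd)
    while isi < floor:
        isi = rng.normal(mean, sd)
    return isi


def build_schedule(
    duration_h: float,
    electrodes: Sequence[str],
    *,
    mapping_reps: int = 3,
    sr_electrodes: Sequence[str] = (),
    mapping_intensity_ma: float = MAPPING_INTENSITY_MA,
    sr_reps: int = 3,
    isi_mean_s: float = 4.5,
    isi_sd_s: float = 0.2,
    isi_min_s: float = 3.0,
    baseline_s: float = 300.0,
    block_interval_s: float = 3600.0,
    seed: int | np.random.Generator = 0,
) -> list[StimEvent]:
    """Hourly-block stimulation schedule.

    Each block holds (1) a ``baseline_s`` stimulation-free window, (2) a
    mapping block probing every electrode ``mapping_reps`` times at the fixed
    mapping intensity in randomized order, and (3) for ``sr_electrodes`` a
    stimulation-response block of the 14 protocol intensities × ``sr_reps``
    in randomized order.  Inter-stimulus intervals are Gaussian
    (``isi_mean_s`` ± ``isi_sd_s``) truncated at ``isi_min_s``.  Blocks
    repeat every ``block_interval_s`` (hourly in the clinical protocol;
    smaller intervals pack a denser session into less signal).
    """
    if len(electrodes) < 2:
        raise ValueError("need at least 2 electrodes")
    if not 3 <= mapping_reps <= 5:
        raise ValueError("mapping_reps must be in 3..5")
    unknown = set(sr_electrodes) - set(electrodes)
    if unknown:
        raise SchemaError(f"sr_electrodes not in electrode list: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration_s = duration_h * 3600.0
    n_map = len(electrodes) * mapping_reps
    n_sr = len(sr_electrodes) * len(SR_INTENSITIES_MA) * sr_reps
    required_s = baseline_s + (n_map + n_sr) * isi_mean_s
    if duration_s < required_s or block_interval_s < required_s:
        raise ScheduleInfeasibleError(
            f"duration {duration_s:.0f} s / block interval {block_interval_s:.0f} s "
            f"cannot fit one block (baseline {baseline_s:.0f} s + {n_map + n_sr} "
            f"stimulations ≈ {required_s:.0f} s)"
        )

    events: list[StimEvent] = []
    n_blocks = max(int(np.floor(duration_s / block_interval_s)), 1)
    for hour in range(n_blocks):
        t = hour * block_interval_s + baseline_s
        # mapping block: randomized electrode order, reps interleaved
        stim_order = list(np.repeat(electrodes, mapping_reps))
        rng.shuffle(stim_order)
        for name in stim_order:
            t += _draw_isi(rng, isi_mean_s, isi_sd_s, isi_min_s)
            if t >= duration_s:
                break
            events.append(
                StimEvent(t, str(name), mapping_intensity_ma, block_id=hour, block_kind="mapping")
            )
        # stimulation-response block
        sr_items = [
            (name, inten)
            for name in sr_electrodes
            for inten in SR_INTENSITIES_MA
            for _ in range(sr_reps)
        ]
        order = rng.permutation(len(sr_items))
        for k in order:
            name, inten = sr_items[k]
            t += _draw_isi(rng, isi_mean_s, isi_sd_s, isi_min_s)
            if t >= duration_s:
                break
            events.append(StimEvent(t, str(name), float(inten), block_id=hour, block_kind="sr_curve"))
    events.sort(key=lambda e: e.onset_s)
    return events


# ---------------------------------------------------------------------------
# full-session synthesis
# ---------------------------------------------------------------------------

def simulate_session(
    network: GroundTruthNetwork,
    schedule: Sequence[StimEvent],
    vigilance: VigilanceTrack,
    seed: int,
    *,
    sampling_rate: float = 1024.0,
    noise_sd: float = 10.0,
    line_amplitude: float = 3.0,
    line_freq_hz: float = 50.0,
    artifact_ms: float = 8.0,
    artifact_gain: float = 20.0,
    artifact_space_mm: float = 20.0,
    duration_s: float | None = None,
) -> tuple[BipolarRecording, pd.DataFrame]:
    """Render a continuous multichannel recording for a stimulation schedule.

    Background per channel is 1/f noise of SD ``noise_sd`` plus a
    ``line_amplitude`` 50 Hz sinusoid with a random channel phase.  At each
    stimulation, every connected recording channel independently receives a
    biphasic evoked waveform with probability
    ``true_probability(state) × logistic(intensity)``, scaled by
    ``amplitude × state_gain(state) × logistic(intensity)`` with
    multiplicative lognormal trial jitter; the stimulated channel carries a
    brief square artifact (``artifact_gain`` × noise SD) that decays over
    ``artifact_space_mm`` on other channels.

    Returns the recording and an exact injection table (one row per
    event × channel) for ground-truth comparisons.  Identical arguments and
    seed produce bit-identical output.
    """
    rng = np.random.default_rng(seed)
    names = network.names
    n_ch = len(names)
    if duration_s is None:
        last = max((e.onset_s for e in schedule), default=0.0)
        duration_s = max(last + 2.0, vigilance.end_s)
    n = int(round(duration_s * sampling_rate))
    for e in schedule:
        if e.stim_pair not in names:
            raise SchemaError(f"event references unknown electrode {e.stim_pair!r}")
        if not 0 <= e.onset_s < duration_s:
            raise ValueError(f"event at {e.onset_s} s outside recording extent")

    sig = np.empty((n_ch, n))
    t = np.arange(n) / sampling_rate
    for c in range(n_ch):
        sig[c] = pink_noise(n, sampling_rate, rng, sd=noise_sd)
        phase = rng.uniform(0, 2 * np.pi)
        sig[c] += line_amplitude * np.sin(2 * np.pi * line_freq_hz * t + phase)

    dist = network.distance_matrix().to_numpy()
    name_idx = {name: i for i, name in enumerate(names)}
    n_art = int(round(artifact_ms / 1000.0 * sampling_rate))
    wave_samples = int(round(0.5 * sampling_rate))  # responses fit in 500 ms

    rows = []
    for ev_idx, ev in enumerate(schedule):
        i0 = int(round(ev.onset_s * sampling_rate))
        state = vigilance.state_at(ev.onset_s)
        state_class = STATE_CLASS.get(state, "W")
        si = name_idx[ev.stim_pair]
        # stimulation + switch-matrix artifact, spatially attenuated
        art = artifact_gain * noise_sd * np.exp(-dist[si] / artifact_space_mm)
        stop = min(i0 + n_art, n)
        sig[:, i0:stop] += art[:, None]
        for ci, ch in enumerate(names):
            if ch == ev.stim_pair:
                continue
            params = network.connections.get((ev.stim_pair, ch))
            injected = False
            inj_amp = 0.0
            inj_lat = np.nan
            if params is not None:
                scale = float(
                    intensity_scale(ev.intensity_ma, params.sigmoid_midpoint_ma, params.sigmoid_slope)
                )
                p_hit = params.probability(state_class) * scale
                if rng.random() < p_hit:
                    injected = True
                    gain = float(params.state_gain.get(state_class, 1.0))
                    jitter = float(np.exp(rng.normal(0.0, params.amp_jitter_sigma)))
                    inj_amp = params.amplitude * gain * scale * jitter
                    inj_lat = params.latency_ms + rng.uniform(
                        -params.latency_jitter_ms, params.latency_jitter_ms
                    )
                    m = min(wave_samples, n - i0)
                    sig[ci, i0 : i0 + m] += evoked_waveform(m, sampling_rate, inj_lat, inj_amp)
            rows.append(
                {
                    "event_idx": ev_idx,
                    "onset_s": ev.onset_s,
                    "stim_pair": ev.stim_pair,
                    "channel": ch,
                    "intensity_ma": ev.intensity_ma,
                    "block_kind": ev.block_kind,
                    "state": state,
                    "injected": injected,
                    "injected_amplitude": inj_amp,
                    "injected_latency_ms": inj_lat,
                }
            )
    recording = BipolarRecording(sig, sampling_rate, network.electrodes.copy())
    truth = pd.DataFrame(rows)
    return recording, truth


# ---------------------------------------------------------------------------
# epoch-level synthesis (preprocessed-equivalent trials)
# ---------------------------------------------------------------------------

def simulate_baseline(
    duration_s: float,
    fs: float = 500.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    f_min: float = 0.5,
) -> np.ndarray:
    """Non-stimulated baseline signal for surrogate sampling.

    Band-limited 1/f noise — the statistical equivalent of a preprocessed
    (0.5 Hz high-passed) recording channel at rest.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return pink_noise(int(round(duration_s * fs)), fs, rng, sd=noise_sd, f_min=f_min)


@dataclass
class ConnectionTrials:
    """Epoched trials of one directed connection with exact injection truth.

    ``baseline`` is a non-stimulated stretch of the *same* synthetic channel
    (the surrogate-null substrate, as the method requires).
    """

    pre: np.ndarray  # n_trials x n_pre
    post: np.ndarray  # n_trials x n_post
    injected: np.ndarray  # bool per trial
    amplitudes: np.ndarray  # injected amplitude (0 when not injected)
    latencies_ms: np.ndarray  # injected latency (nan when not injected)
    states: np.ndarray  # state class per trial
    intensities_ma: np.ndarray
    sampling_rate: float
    baseline: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_trials(self) -> int:
        return self.post.shape[0]


def simulate_connection_trials(
    n_trials: int,
    params: ConnectionParams,
    *,
    fs: float = 500.0,
    noise_sd: float = 1.0,
    pre_ms: float = 600.0,
    post_ms: float = 500.0,
    states: Sequence[str] | str = "W",
    intensities_ma: Sequence[float] | float = MAPPING_INTENSITY_MA,
    baseline_s: float = 300.0,
    f_min: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> ConnectionTrials:
    """Draw already-epoched trials of one directed connection.

    Equivalent to extracting epochs from a preprocessed session: one
    continuous band-limited 1/f noise stream of SD ``noise_sd`` is cut into
    a ``baseline_s`` non-stimulated stretch followed by consecutive trial
    epochs, and an evoked waveform is injected at each epoch onset with
    probability ``true_probability(state) × logistic(I)`` and amplitude
    ``amplitude × state_gain(state) × logistic(I) × jitter``.  Trials and
    baseline share one noise process, exactly as surrogate testing against
    the same recording channel assumes.  ``states``/``intensities_ma`` may
    be scalars or per-trial sequences.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pre = int(round(pre_ms / 1000.0 * fs))
    n_post = int(round(post_ms / 1000.0 * fs))
    if isinstance(states, str):
        states = [states] * n_trials
    if np.isscalar(intensities_ma):
        intensities_ma = [float(intensities_ma)] * n_trials
    states = np.asarray(states)
    intensities = np.asarray(intensities_ma, float)
    if len(states) != n_trials or len(intensities) != n_trials:
        raise ValueError("states/intensities length must match n_trials")

    n_epoch = n_pre + n_post
    n_base = int(round(baseline_s * fs))
    stream = pink_noise(n_base + n_trials * n_epoch, fs, rng, sd=noise_sd, f_min=f_min)
    baseline = stream[:n_base]
    pre = np.empty((n_trials, n_pre))
    post = np.empty((n_trials, n_post))
    injected = np.zeros(n_trials, bool)
    amps = np.zeros(n_trials)
    lats = np.full(n_trials, np.nan)
    for i in range(n_trials):
        epoch = stream[n_base + i * n_epoch : n_base + (i + 1) * n_epoch].copy()
        state_class = STATE_CLASS.get(str(states[i]), str(states[i]))
        scale = float(
            intensity_scale(intensities[i], params.sigmoid_midpoint_ma, params.sigmoid_slope)
        )
        if rng.random() < params.probability(state_class) * scale:
            injected[i] = True
            gain = float(params.state_gain.get(state_class, 1.0))
            jitter = float(np.exp(rng.normal(0.0, params.amp_jitter_sigma)))
            amps[i] = params.amplitude * gain * scale * jitter
            lats[i] = params.latency_ms + rng.uniform(
                -params.latency_jitter_ms, params.latency_jitter_ms
            )
            epoch[n_pre:] += evoked_waveform(n_post, fs, lats[i], amps[i])
        pre[i] = epoch[:n_pre]
        post[i] = epoch[n_pre:]
    return ConnectionTrials(pre, post, injected, amps, lats, states, intensities, fs, baseline)


# ---------------------------------------------------------------------------
# incidence matrix with planted communities
# ---------------------------------------------------------------------------

def make_incidence_matrix(
    partition_truth: Mapping[str, int] | Sequence[int],
    p_within: float,
    p_between: float,
    seed: int | np.random.Generator = 0,
    *,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Planted-partition connection-incidence matrix (areas × areas, percent).

    Each off-diagonal entry is Bernoulli(p_within or p_between) times a
    uniform incidence in [40, 100] percent; the matrix is symmetric with a
    zero diagonal so expected within-community incidence exceeds
    between-community incidence whenever ``p_within > p_between``.
    """
    for p in (p_within, p_between):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    if p_within <= p_between:
        raise ValueError("p_within must exceed p_between")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(partition_truth, Mapping):
        areas = list(partition_truth)
        comm = np.asarray([partition_truth[a] for a in areas])
    else:
        comm = np.asarray(list(partition_truth))
        areas = list(labels) if labels is not None else [f"area{i:02d}" for i in range(len(comm))]
    k = len(areas)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = p_within if comm[i] == comm[j] else p_between
            if rng.random() < p:
                mat[i, j] = mat[j, i] = rng.uniform(40.0, 100.0)
    return pd.DataFrame(mat, index=areas, columns=areas)


# ---------------------------------------------------------------------------
# demo scenario
# ---------------------------------------------------------------------------

def demo_network(seed: int = 0, *, amplitude: float = 60.0, noise_ref_sd: float = 10.0) -> GroundTruthNetwork:
    """Small two-region network used by the demo pipeline and examples.

    Six electrodes in two regions of one hemisphere; a strong local pair, a
    long-range asymmetric pair (efference twice as probable as the reverse),
    and one unconnected pair to exercise the null path.
    """
    del noise_ref_sd  # amplitudes quoted directly in signal units
    rng = np.random.default_rng(seed)
    regions = ["hippocampus"] * 3 + ["dorsofrontal"] * 3
    base = np.array([[0.0, 0.0, 0.0], [8.0, 3.0, 2.0], [14.0, 6.0, 1.0],
                     [60.0, 40.0, 20.0], [66.0, 44.0, 23.0], [73.0, 47.0, 21.0]])
    electrodes = pd.DataFrame(
        {
            "name": [f"e{i}" for i in range(6)],
            "region": regions,
            "hemisphere": ["L"] * 6,
            "x_mm": base[:, 0] + rng.normal(0, 0.1, 6),
            "y_mm": base[:, 1] + rng.normal(0, 0.1, 6),
            "z_mm": base[:, 2] + rng.normal(0, 0.1, 6),
        }
    )
    conns = {
        ("e0", "e1"): ConnectionParams(true_probability=0.95, latency_ms=25.0, amplitude=amplitude),
        ("e1", "e0"): ConnectionParams(true_probability=0.95, latency_ms=25.0, amplitude=amplitude),
        ("e0", "e3"): ConnectionParams(true_probability=0.8, latency_ms=45.0, amplitude=amplitude),
        ("e3", "e0"): ConnectionParams(true_probability=0.4, latency_ms=45.0, amplitude=amplitude),
        ("e4", "e5"): ConnectionParams(true_probability=0.9, latency_ms=20.0, amplitude=amplitude),
    }
    return GroundTruthNetwork(electrodes, conns)
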