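"""Single-trial evoked-response detection against surrogate nulls.

For each directed electrode pair (connection) the post-stimulation epochs
are summarized by line length (LL), clustered into two centroid waveforms
(K-means of rank two under a Pearson-correlation distance), and tested:

* connection level — a connection is *effective* when the LL of at least one
  centroid reaches the 95th percentile of a 2 × 200 surrogate null built
  from non-stimulated baseline epochs of the same channel;
* trial level — each single trial is scored by the compound metric
  ±ρ²·LL (LL weighted by its maximal squared correlation with the centroids
  within ±10 ms lag, sign preserved) and compared against a 400-surrogate
  null of identically scored baseline epochs.

Signaling latency is the first prominent peak of the average response inside
the LL-elevated span; trials with LL above four times the connection median
are flagged as putative artifacts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import RunConfig

__all__ = [
    "CentroidSet",
    "NullDistribution",
    "ConnectionResult",
    "line_length",
    "sliding_line_length",
    "extract_centroids",
    "score_trials",
    "build_null",
    "test_effective_connection",
    "test_single_trial",
    "detect_latency",
    "flag_outliers",
    "analyze_connection",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# line length
# ---------------------------------------------------------------------------

def line_length(x: np.ndarray, sampling_rate: float) -> float:
    """Line length of a signal window.

    LL = (Σ_i |x_i − x_{i−1}| / N) · (sf / 1000), where N is the number of
    datapoints in the window and sf the sampling frequency; zero iff the
    window is constant.
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("line_length needs a 1-D window of at least 2 samples")
    return float(np.abs(np.diff(x)).sum() / x.size * sampling_rate / 1000.0)


def _ll_rows(windows: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Row-wise line length of an (n, m) matrix of windows."""
    w = np.atleast_2d(np.asarray(windows, float))
    return np.abs(np.diff(w, axis=1)).sum(axis=1) / w.shape[1] * sampling_rate / 1000.0


def sliding_line_length(x: np.ndarray, sampling_rate: float, window_ms: float = 250.0) -> np.ndarray:
    """LL over a causal sliding window; entry i covers samples [i, i+W)."""
    x = np.asarray(x, float)
    w = int(round(window_ms / 1000.0 * sampling_rate))
    if x.size < w:
        raise ValueError("signal shorter than the sliding window")
    absdiff = np.abs(np.diff(x))
    kernel = np.ones(w - 1)
    sums = np.convolve(absdiff, kernel, mode="valid")
    return sums / w * sampling_rate / 1000.0


# ---------------------------------------------------------------------------
# centroids (rank-2 K-means under correlation distance)
# ---------------------------------------------------------------------------

@dataclass
class CentroidSet:
    """Two average waveforms summarizing a connection's trial repertoire."""

    centroid_1: np.ndarray
    centroid_2: np.ndarray
    labels: np.ndarray  # cluster index per trial (0/1)
    member_counts: tuple[int, int]
    degenerate: bool = False
    connection: tuple[str, str] | None = None

    @property
    def centroids(self) -> list[np.ndarray]:
        return [self.centroid_1, self.centroid_2]


def _rows_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with vector y (0 for flat rows)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum())
    denom = xs * ys
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    return r


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm (flat rows become zero rows)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    return Xc / norms


def extract_centroids(
    windows: np.ndarray,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> CentroidSet:
    """Partition trials into two clusters minimizing 1 − ρ to cluster means.

    Lloyd iterations with Pearson-correlation distance: trials are assigned
    to the centroid they correlate best with, and centroids are plain
    averages of their member trials.  Ten seeded restarts; the lowest-inertia
    solution is kept, so the result is deterministic under a fixed seed.
    Fewer than two trials yields a single duplicated centroid, flagged.
    """
    W = np.atleast_2d(np.asarray(windows, float))
    n = W.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 2:
        c = W[0] if n == 1 else np.zeros(W.shape[1])
        return CentroidSet(c.copy(), c.copy(), np.zeros(n, int), (n, 0), degenerate=True)

    Z = _standardize_rows(W)  # unit-norm rows: pearson = plain dot product
    best = None
    for _ in range(n_restarts):
        init = rng.choice(n, size=2, replace=False)
        cents = np.stack([W[init[0]], W[init[1]]])
        labels = np.zeros(n, int)
        for _ in range(max_iter):
            r = Z @ _standardize_rows(cents).T  # n x 2 correlations
            new_labels = np.argmax(r, axis=1)
            for k in (0, 1):
                members = W[new_labels == k]
                if len(members):
                    cents[k] = members.mean(axis=0)
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        r = Z @ _standardize_rows(cents).T
        inertia = float((1.0 - r[np.arange(n), labels]).sum())
        if best is None or inertia < best[0] - 1e-12:
            best = (inertia, labels.copy(), cents.copy())
    _, labels, cents = best
    counts = (int((labels == 0).sum()), int((labels == 1).sum()))
    degenerate = 0 in counts
    if degenerate:
        # one empty cluster: duplicate the populated centroid
        keep = 0 if counts[0] else 1
        cents = [cents[keep].copy(), cents[keep].copy()]
    return CentroidSet(cents[0], cents[1], labels, counts, degenerate=degenerate)


# ---------------------------------------------------------------------------
# trial scoring (±ρ²·LL)
# ---------------------------------------------------------------------------

def _lagged_correlations(W: np.ndarray, centroid: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Best signed ρ (by ρ²) per row over integer lags in [−max_lag, +max_lag]."""
    n, m = W.shape
    best_r = np.zeros(n)
    best_lag = np.zeros(n, int)
    best_r2 = np.full(n, -1.0)
    for lag in range(-max_lag, max_lag + 1):
        a, b = max(0, lag), m + min(0, lag)
        if b - a < 3:
            continue
        r = _rows_pearson(W[:, a:b], centroid[a - lag : b - lag])
        r2 = r * r
        upd = r2 > best_r2
        best_r[upd] = r[upd]
        best_lag[upd] = lag
        best_r2[upd] = r2[upd]
    return best_r, best_lag


def score_trials(
    windows: np.ndarray,
    centroids: CentroidSet,
    sampling_rate: float,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Compound single-trial score ±ρ²·LL against the connection centroids.

    For each trial, the Pearson correlation with each centroid is maximized
    in ρ² over lags within ±10 ms; the score is sign(ρ)·ρ²·LL so that a
    trial resembling either centroid (or its inverse, negatively) registers.
    Zero-variance trials score 0.  Columns: ll, rho, lag_ms, score.
    """
    config = config or RunConfig()
    W = np.atleast_2d(np.asarray(windows, float))
    max_lag = config.max_lag_samples(sampling_rate)
    ll = _ll_rows(W, sampling_rate)
    best_r = np.zeros(W.shape[0])
    best_lag = np.zeros(W.shape[0], int)
    best_r2 = np.full(W.shape[0], -1.0)
    cents = [centroids.centroid_1] + ([] if centroids.degenerate else [centroids.centroid_2])
    for c in cents:
        if np.allclose(c, c[0]):
            continue
        r, lag = _lagged_correlations(W, c, max_lag)
        upd = r * r > best_r2
        best_r[upd] = r[upd]
        best_lag[upd] = lag[upd]
        best_r2[upd] = (r * r)[upd]
    best_r2 = np.maximum(best_r2, 0.0)
    score = np.sign(best_r) * best_r2 * ll
    return pd.DataFrame(
        {
            "ll": ll,
            "rho": best_r,
            "lag_ms": best_lag / sampling_rate * 1000.0,
            "score": score,
        }
    )


# ---------------------------------------------------------------------------
# surrogate nulls
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Sorted surrogate statistic values of one kind."""

    values: np.ndarray
    statistic_kind: str  # 'centroid_ll' | 'trial_score'

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null distribution contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


class InsufficientBaselineError(ValueError):
    """Baseline too short to host the requested surrogate epochs."""


def _sample_epochs(
    baseline: np.ndarray, n_epochs: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    if baseline.size < n_samples:
        need = n_samples
        raise InsufficientBaselineError(
            f"baseline of {baseline.size} samples cannot host {n_samples}-sample "
            f"surrogate epochs (need ≥ {need})"
        )
    onsets = rng.integers(0, baseline.size - n_samples + 1, size=n_epochs)
    return baseline[onsets[:, None] + np.arange(n_samples)[None, :]]


def build_null(
    baseline: np.ndarray,
    statistic_kind: str,
    sampling_rate: float,
    seed: int | np.random.Generator = 0,
    config: RunConfig | None = None,
    centroids: CentroidSet | None = None,
    n_trials: int | None = None,
) -> NullDistribution:
    """Surrogate null from random non-stimulated baseline epochs.

    ``centroid_ll``: 200 surrogate re-computations of the centroid pipeline —
    each draws as many baseline epochs as the connection has trials, runs the
    rank-2 correlation K-means, and records both centroid line lengths
    (2 × 200 pooled values), so the surrogate statistic carries the same
    cluster-selection effect as the observed one.  ``trial_score``: 400
    single baseline epochs scored with exactly the trial pipeline (±ρ²·LL
    against the real centroids).  Surrogate onsets are drawn with
    replacement — a 5-min baseline cannot host 400 disjoint epochs.
    """
    config = config or RunConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = np.asarray(baseline, float)
    m = config.n_ll_samples(sampling_rate)
    if statistic_kind == "centroid_ll":
        count = max(int(n_trials or 2), 2)
        values = np.empty(2 * config.n_centroid_surrogates)
        for s in range(config.n_centroid_surrogates):
            epochs = _sample_epochs(baseline, count, m, rng)
            surr = extract_centroids(epochs, rng)
            values[2 * s] = line_length(surr.centroid_1, sampling_rate)
            values[2 * s + 1] = line_length(surr.centroid_2, sampling_rate)
        return NullDistribution(values, "centroid_ll")
    if statistic_kind == "trial_score":
        if centroids is None:
            raise ValueError("trial_score null requires the connection centroids")
        epochs = _sample_epochs(baseline, config.n_trial_surrogates, m, rng)
        scores = score_trials(epochs, centroids, sampling_rate, config)["score"].to_numpy()
        return NullDistribution(scores, "trial_score")
    raise ValueError(f"unknown statistic_kind {statistic_kind!r}")


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------

def test_effective_connection(
    centroids: CentroidSet,
    null: NullDistribution,
    sampling_rate: float,
    config: RunConfig | None = None,
) -> tuple[bool, float]:
    """Connection-level test: max centroid LL vs the surrogate 95th percentile.

    The p-value uses the add-one surrogate estimator (1 + #{null ≥ obs}) /
    (1 + n) so it can never be exactly zero.
    """
    config = config or RunConfig()
    if null.statistic_kind != "centroid_ll":
        raise ValueError(f"expected centroid_ll null, got {null.statistic_kind}")
    observed = max(line_length(c, sampling_rate) for c in centroids.centroids)
    p = (1 + int((null.values >= observed).sum())) / (1 + null.n)
    significant = observed >= null.percentile(config.percentile)
    return bool(significant), float(p)


def test_single_trial(score: float, null: NullDistribution, config: RunConfig | None = None) -> bool:
    """One-sided single-trial test: ±ρ²·LL at or above the null 95th percentile."""
    config = config or RunConfig()
    if null.statistic_kind != "trial_score":
        raise ValueError(f"expected trial_score null, got {null.statistic_kind}")
    return bool(score >= null.percentile(config.percentile))


# ---------------------------------------------------------------------------
# latency & outliers
# ---------------------------------------------------------------------------

def detect_latency(
    avg_post: np.ndarray,
    sampling_rate: float,
    baseline_sd: float,
    config: RunConfig | None = None,
    avg_pre: np.ndarray | None = None,
    ll_elevation_factor: float = 1.25,
) -> tuple[float, str]:
    """Signaling latency: first prominent peak of the average response.

    Responses are sought within the post-stimulation window (≤ 500 ms) as an
    increase in line length over a 250 ms window; the latency is the first
    local extremum (prominence ≥ 2 × the baseline SD of the average trace)
    after the interpolated artifact span.  Returns (latency_ms, reason);
    latency is NaN when no LL elevation or no prominent peak is found.
    """
    config = config or RunConfig()
    x = np.asarray(avg_post, float)
    if np.allclose(x, x[0]):
        return float("nan"), "flat"
    offset = config.artifact_offset_samples(sampling_rate)
    m = config.n_ll_samples(sampling_rate)
    if avg_pre is not None and avg_pre.size >= m:
        ll_base = line_length(np.asarray(avg_pre, float)[-m:], sampling_rate)
        span = x[offset : offset + m]
        if span.size >= 2 and line_length(span, sampling_rate) <= ll_elevation_factor * ll_base:
            return float("nan"), "no_ll_elevation"
    threshold = 2.0 * baseline_sd if baseline_sd > 0 else 0.1 * np.ptp(x)
    level = float(np.mean(avg_pre)) if avg_pre is not None else float(np.median(x))
    pos, _ = find_peaks(x, prominence=threshold)
    neg, _ = find_peaks(-x, prominence=threshold)
    peaks = np.sort(np.concatenate([pos, neg]))
    # a response peak must also deviate from the pre-stimulation level, not
    # just be a locally prominent ripple on a flank
    peaks = peaks[(peaks >= offset) & (np.abs(x[peaks] - level) >= threshold)]
    if peaks.size == 0:
        return float("nan"), "no_peak"
    return float(peaks[0] / sampling_rate * 1000.0), "ok"


def flag_outliers(lls: np.ndarray, factor: float = 4.0) -> np.ndarray:
    """Trials with LL above ``factor`` × the connection median (automated
    stand-in for visual artifact/epileptic-discharge review)."""
    lls = np.asarray(lls, float)
    if lls.size < 5:
        return np.zeros(lls.size, bool)
    return lls > factor * np.median(lls)


# ---------------------------------------------------------------------------
# per-connection driver
# ---------------------------------------------------------------------------

@dataclass
class ConnectionResult:
    """All detection outputs of one directed connection."""

    effective: bool
    p_value: float
    centroids: CentroidSet
    scores: pd.DataFrame  # ll, rho, lag_ms, score, significant, outlier
    latency_ms: float
    latency_reason: str
    n_trials: int
    trial_threshold: float
    connection: tuple[str, str] | None = None

    @property
    def decisions(self) -> np.ndarray:
        """Per-trial response decisions after outlier handling."""
        return self.scores["response"].to_numpy()


def analyze_connection(
    post: np.ndarray,
    baseline: np.ndarray,
    sampling_rate: float,
    seed: int | np.random.Generator = 0,
    config: RunConfig | None = None,
    pre: np.ndarray | None = None,
    connection: tuple[str, str] | None = None,
    test_effective: bool = True,
) -> ConnectionResult:
    """Run the full detection chain on one connection's epoched trials.

    ``post`` is (n_trials, n_post_samples) from T0; ``baseline`` a 1-D
    non-stimulated signal of the same (preprocessed) channel; ``pre``
    optionally the matching pre-stimulation epochs, used for the latency
    gate and baseline SD.  ``test_effective=False`` skips the (costly)
    connection-level surrogate test when only trial decisions are needed.
    """
    config = config or RunConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    post = np.atleast_2d(np.asarray(post, float))
    offset = config.artifact_offset_samples(sampling_rate)
    m = config.n_ll_samples(sampling_rate)
    windows = post[:, offset : offset + m]

    centroids = extract_centroids(windows, rng)
    if test_effective:
        centroid_null = build_null(
            baseline, "centroid_ll", sampling_rate, rng, config, n_trials=post.shape[0]
        )
        effective, p_value = test_effective_connection(
            centroids, centroid_null, sampling_rate, config
        )
    else:
        effective, p_value = False, float("nan")

    scores = score_trials(windows, centroids, sampling_rate, config)
    trial_null = build_null(baseline, "trial_score", sampling_rate, rng, config, centroids=centroids)
    threshold = trial_null.percentile(config.percentile)
    scores["significant"] = scores["score"].to_numpy() >= threshold
    scores["outlier"] = flag_outliers(scores["ll"].to_numpy(), config.outlier_ll_factor)
    if config.outlier_mode == "flag_only":
        decisions = scores["significant"].to_numpy()
    else:
        decisions = scores["significant"].to_numpy() & ~scores["outlier"].to_numpy()
    scores["response"] = decisions

    # latency from the average of significant (non-outlier) trials
    use = decisions if decisions.sum() >= config.min_trials else np.ones(post.shape[0], bool)
    avg_post = post[use].mean(axis=0)
    if pre is not None:
        pre_arr = np.atleast_2d(np.asarray(pre, float))
        avg_pre = pre_arr[use].mean(axis=0)
        baseline_sd = float(avg_pre.std())
    else:
        avg_pre = None
        baseline_sd = float(np.std(baseline)) / max(np.sqrt(use.sum()), 1.0)
    latency_ms, reason = detect_latency(
        avg_post, sampling_rate, baseline_sd, config, avg_pre=avg_pre
    )
    return ConnectionResult(
        effective=effective,
        p_value=p_value,
        centroids=centroids,
        scores=scores,
        latency_ms=latency_ms,
        latency_reason=reason,
        n_trials=post.shape[0],
        trial_threshold=float(threshold),
        connection=connection,
    )
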