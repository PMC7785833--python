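"""Phase-locking-value (PLV) connectivity from event-locked HbO2 epochs.

Pipeline:

1. ``analytic_signal`` -- instantaneous phase per trial/channel via the
   discrete Hilbert transform over the full 20-s epoch (margins included to
   absorb edge effects, discarded later).
2. ``plv`` -- for each unordered channel pair and time sample, the magnitude
   of the trial-averaged unit phasor of the phase difference (in [0, 1]).
3. ``normalize_plv`` -- z-score each pair against its own pre-stimulus
   baseline ([-4, -1) s), cancelling stationary task-unrelated synchrony.
4. ``tplv_matrix`` -- average the normalized PLV over the post-stimulus
   window ([0, 12) s; M = round(12 * fs) samples) into a symmetric adjacency
   matrix with zero diagonal.
5. ``gplv`` -- the subject-level mean over all channel pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochSet, EpochWindow

logger = logging.getLogger(__name__)

#: Baseline interval in seconds relative to stimulus onset, [start, stop).
BASELINE_WINDOW = (-4.0, -1.0)
#: Post-stimulus averaging interval in seconds, [start, stop).
POST_WINDOW = (0.0, 12.0)


def channel_pairs(n_channels: int) -> np.ndarray:
    """All unordered channel pairs {k, l}, k < l, as an (n_pairs, 2) array."""
    iu = np.triu_indices(n_channels, k=1)
    return np.column_stack(iu)


@dataclass
class PhaseEpochs:
    """Instantaneous phases in radians, wrapped to (-pi, pi].

    ``phases[trial, channel, sample]``; trials flagged degenerate (all-zero
    signal in any channel) are already removed.
    """

    phases: np.ndarray
    fs: float
    channel_labels: list[str]
    window: EpochWindow = field(default_factory=EpochWindow)
    dropped_trials: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 3:
            raise ValueError("phases must be 3-D (trial x channel x sample)")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phases.shape[1]

    @property
    def t_start(self) -> float:
        return self.window.t_start


@dataclass
class PLVTimeSeries:
    """Per-pair, per-sample phase-locking values.

    ``values[pair, sample]`` with ``pairs[i] = (k, l), k < l`` covering all
    unordered channel pairs.  ``kind`` is ``"plv"`` (raw, in [0, 1]) or
    ``"zplv"`` (baseline-normalized, unbounded).  After normalization the
    per-pair baseline mean and standard deviation are stored.
    """

    values: np.ndarray
    kind: str
    fs: float
    channel_labels: list[str]
    n_trials: int
    window: EpochWindow = field(default_factory=EpochWindow)
    pairs: np.ndarray | None = None
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("plv", "zplv"):
            raise ValueError("kind must be 'plv' or 'zplv'")
        if self.pairs is None:
            self.pairs = channel_pairs(len(self.channel_labels))
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.values.shape[0] != self.pairs.shape[0]:
            raise ValueError("values row count does not match pair count")
        if self.kind == "plv":
            if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
                raise ValueError("raw PLV values must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, t: float) -> int:
        return int(np.floor((t - self.window.t_start) * self.fs))


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of post-stimulus-averaged normalized PLV (tPLV).

    Dimensionless z-units; diagonal fixed at zero (self-connections are not
    part of the analysis).  ``m_samples`` records how many post-stimulus
    samples were averaged.
    """

    matrix: np.ndarray
    channel_labels: list[str]
    m_samples: int = 0
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.channel_labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be square with one row per channel")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("connectivity matrix diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def analytic_signal(epochs: EpochSet) -> PhaseEpochs:
    """Instantaneous phase of each trial/channel via the Hilbert transform.

    The analytic signal ``x_a[n] = x[n] + j x_h[n]`` is computed over the
    full epoch (margins included, to keep the filter edge effects away from
    the analysis windows); the phase is the quadrant-correct angle
    ``atan2(x_h, x)``, wrapped to (-pi, pi].

    Trials containing an all-zero channel have undefined phase; such trials
    are dropped for every channel pair consistently, with a warning.
    """
    data = epochs.data
    flat = np.ptp(data, axis=2) == 0  # (trial, channel): constant signal
    zero = flat & (data[:, :, 0] == 0)
    bad_trials = np.where(zero.any(axis=1))[0]
    if bad_trials.size:
        logger.warning(
            "dropping %d trial(s) with all-zero channels: %s",
            bad_trials.size, bad_trials.tolist(),
        )
        data = np.delete(data, bad_trials, axis=0)
    if data.shape[0] == 0:
        raise ValueError("no trials with defined phase remain")
    xa = hilbert(data, axis=2)
    phases = np.arctan2(xa.imag, xa.real)
    # np.arctan2 returns [-pi, pi]; fold -pi onto +pi to match (-pi, pi].
    phases[phases == -np.pi] = np.pi
    return PhaseEpochs(
        phases=phases, fs=epochs.fs, channel_labels=list(epochs.channel_labels),
        window=epochs.window, dropped_trials=tuple(int(i) for i in bad_trials),
    )


def plv(phases: PhaseEpochs) -> PLVTimeSeries:
    """Trial-averaged phase-locking value per channel pair and sample.

    ``PLV_kl[n] = | (1/N) sum_p exp(j (phi_k[p, n] - phi_l[p, n])) |``
    over the N trials; values lie in [0, 1].  At least two trials are
    required (a single trial makes PLV identically 1).
    """
    if phases.n_trials < 2:
        raise ValueError("PLV requires >= 2 trials (degenerate at 1 otherwise)")
    z = np.exp(1j * phases.phases)  # (trial, channel, sample)
    pairs = channel_pairs(phases.n_channels)
    k, l = pairs[:, 0], pairs[:, 1]
    # mean over trials of the pairwise phase-difference phasor
    cross = np.mean(z[:, k, :] * np.conj(z[:, l, :]), axis=0)  # (pair, sample)
    values = np.abs(cross)
    np.clip(values, 0.0, 1.0, out=values)
    return PLVTimeSeries(
        values=values, kind="plv", fs=phases.fs,
        channel_labels=list(phases.channel_labels), n_trials=phases.n_trials,
        window=phases.window, pairs=pairs,
    )


def normalize_plv(
    series: PLVTimeSeries, baseline: tuple[float, float] = BASELINE_WINDOW
) -> PLVTimeSeries:
    """Baseline-z-score the PLV of each pair against its own baseline.

    ``zPLV_kl[n] = (PLV_kl[n] - mu_kl) / sigma_kl`` with the mean and the
    population standard deviation taken over the baseline samples ([-4, -1) s
    by default, floor sample mapping).  A pair with a constant baseline
    (sigma = 0) gets zPLV = 0 everywhere, with a warning.
    """
    if series.kind != "plv":
        raise ValueError("normalize_plv expects raw PLV input")
    i0, i1 = series.sample_index(baseline[0]), series.sample_index(baseline[1])
    if i1 - i0 < 2:
        raise ValueError("baseline window maps to fewer than 2 samples")
    base = series.values[:, i0:i1]
    mu = base.mean(axis=1)
    sigma = base.std(axis=1)  # population SD (ddof=0)
    degenerate = sigma == 0
    if degenerate.any():
        logger.warning(
            "degenerate baseline (sigma = 0) for %d pair(s); zPLV set to 0",
            int(degenerate.sum()),
        )
    safe_sigma = np.where(degenerate, 1.0, sigma)
    zvalues = (series.values - mu[:, None]) / safe_sigma[:, None]
    zvalues[degenerate, :] = 0.0
    return PLVTimeSeries(
        values=zvalues, kind="zplv", fs=series.fs,
        channel_labels=list(series.channel_labels), n_trials=series.n_trials,
        window=series.window, pairs=series.pairs,
        baseline_mean=mu, baseline_sd=sigma,
    )


def tplv_matrix(
    zplv: PLVTimeSeries, post: tuple[float, float] = POST_WINDOW
) -> ConnectivityMatrix:
    """Average zPLV over the post-stimulus window into an adjacency matrix.

    The window is [0, 12) s by default with ``M = round(12 * fs)`` samples
    (M = 94 at fs = 7.81 Hz), starting at the floor-mapped onset sample.
    """
    if zplv.kind != "zplv":
        raise ValueError("tplv_matrix expects baseline-normalized (zplv) input")
    start = zplv.sample_index(post[0])
    m = int(round((post[1] - post[0]) * zplv.fs))
    if m < 1:
        raise ValueError("post-stimulus window is empty")
    if start < 0 or start + m > zplv.n_samples:
        raise ValueError("post-stimulus window exceeds the epoch")
    tplv = zplv.values[:, start : start + m].mean(axis=1)
    n = len(zplv.channel_labels)
    matrix = np.zeros((n, n))
    k, l = zplv.pairs[:, 0], zplv.pairs[:, 1]
    matrix[k, l] = tplv
    matrix[l, k] = tplv
    return ConnectivityMatrix(
        matrix=matrix, channel_labels=list(zplv.channel_labels),
        m_samples=m, n_trials=zplv.n_trials,
    )


def gplv(conn: ConnectivityMatrix) -> float:
    """Global PLV: mean tPLV over all unordered channel pairs.

    For 14 channels this is the mean of the 91 strictly-upper-triangular
    entries of the adjacency matrix.
    """
    iu = np.triu_indices(conn.n_nodes, k=1)
    return float(conn.matrix[iu].mean())


def connectivity_matrix(
    epochs: EpochSet,
    baseline: tuple[float, float] = BASELINE_WINDOW,
    post: tuple[float, float] = POST_WINDOW,
) -> ConnectivityMatrix:
    """Convenience chain: epochs -> phases -> PLV -> zPLV -> tPLV matrix."""
    return tplv_matrix(
        normalize_plv(plv(analytic_signal(epochs)), baseline=baseline), post=post
    )
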