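"""Continuous-recording preprocessing: Beer-Lambert conversion, band-pass
filtering, and event-locked epoching.

The analysis operates on oxygenated-hemoglobin (HbO2) concentration changes.
Recordings may enter the pipeline either as raw optical-density changes at two
near-infrared wavelengths (converted here via the modified Beer-Lambert law)
or directly as exported HbO2 time series, which is the usual starting point.

Epoch geometry is fixed by the experimental design: each target stimulus
yields a 20-s epoch spanning [-6, 14] s around the onset, decomposed as
2 s margin + 4 s pre-stimulus + 12 s post-stimulus + 2 s margin.  The margins
exist only to absorb edge effects of the analytic-signal (Hilbert) step and
are discarded before any averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Default differential pathlength factor, applied to both wavelengths.
DEFAULT_DPF = 6.0

#: Molar extinction coefficients [1/(cm*M)] for (HbO2, HbR) at the two
#: acquisition wavelengths.  Values are the commonly tabulated ones used by
#: fNIRS processing toolboxes; they are configurable because acquisition
#: software vendors ship slightly different tables.
DEFAULT_EXTINCTION = {
    760.0: (1486.59, 3843.71),
    850.0: (2526.39, 1798.64),
}


@dataclass(frozen=True)
class EpochWindow:
    """Epoch geometry in seconds: ``margin | pre | post | margin``.

    ``t = 0`` is the stimulus onset; the epoch spans
    ``[-(margin + pre), post + margin)``.
    """

    margin: float = 2.0
    pre: float = 4.0
    post: float = 12.0

    @property
    def total(self) -> float:
        return 2.0 * self.margin + self.pre + self.post

    @property
    def t_start(self) -> float:
        return -(self.margin + self.pre)

    def n_samples(self, fs: float) -> int:
        return int(round(self.total * fs))


@dataclass
class ContinuousRecording:
    """A continuous multi-channel recording with stimulus onsets.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        HbO2 concentration change per channel (arbitrary uM-scale units).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One opaque label per channel (e.g. emitter-detector pairs).
    onsets : ndarray
        Target-stimulus times in seconds, strictly increasing.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x channel)")
        if self.samples.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels length does not match samples")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs


@dataclass
class EpochSet:
    """Event-locked epochs: ``data[trial, channel, sample]``.

    Sample 0 corresponds to ``window.t_start`` (-6 s by default) relative to
    the stimulus onset; the sample count is ``round(window.total * fs)`` and
    is identical across trials.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    window: EpochWindow = field(default_factory=EpochWindow)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trial x channel x sample)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels length does not match data")
        expected = self.window.n_samples(self.fs)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != round(total*fs) = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def t_start(self) -> float:
        return self.window.t_start

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t_start + np.arange(self.n_samples) / self.fs

    def sample_index(self, t: float) -> int:
        """Map an epoch-relative time to a sample index (floor convention)."""
        return int(math.floor((t - self.t_start) * self.fs))

    def window_slice(self, start: float, stop: float) -> slice:
        """Half-open sample slice for epoch-relative times ``[start, stop)``."""
        return slice(self.sample_index(start), self.sample_index(stop))


def beer_lambert(
    od_changes: np.ndarray,
    dpf: float | tuple[float, float] = DEFAULT_DPF,
    distances: float | np.ndarray = 3.0,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    extinction: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Convert optical-density changes to HbO2 concentration changes.

    Solves the 2x2 modified Beer-Lambert system per channel and sample::

        dOD(lambda) = eps_HbO2(lambda) * dHbO2 * d * DPF
                    + eps_HbR(lambda)  * dHbR  * d * DPF

    and returns the HbO2 component only, since the downstream connectivity
    analysis uses HbO2 exclusively.

    Parameters
    ----------
    od_changes : ndarray, shape (n_samples, n_channels, 2)
        Optical-density change per wavelength.
    dpf : float or pair of floats
        Differential pathlength factor per wavelength.
    distances : float or ndarray of shape (n_channels,)
        Source-detector separation per channel in cm.
    wavelengths : pair of floats
        The two acquisition wavelengths in nm; must be distinct and present
        in the extinction table.
    extinction : mapping wavelength -> (eps_HbO2, eps_HbR), optional

    Returns
    -------
    ndarray, shape (n_samples, n_channels)
        HbO2 concentration change.
    """
    od = np.asarray(od_changes, dtype=float)
    if od.ndim != 3 or od.shape[2] != 2:
        raise ValueError("od_changes must have shape (time, channel, 2 wavelengths)")
    if wavelengths[0] == wavelengths[1]:
        raise ValueError("wavelengths must be distinct (singular extinction system)")
    table = extinction if extinction is not None else DEFAULT_EXTINCTION
    try:
        rows = [table[float(w)] for w in wavelengths]
    except KeyError as exc:
        raise ValueError(f"no extinction coefficients for wavelength {exc}") from None
    E = np.asarray(rows, dtype=float)  # (2 wavelengths, 2 chromophores)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")

    dpf_arr = np.broadcast_to(np.asarray(dpf, dtype=float), (2,))
    if np.any(dpf_arr <= 0):
        raise ValueError("DPF must be positive")
    dist = np.broadcast_to(np.asarray(distances, dtype=float), (od.shape[1],))
    if np.any(dist <= 0):
        raise ValueError("source-detector distances must be positive")

    # dOD / (d * DPF) = E @ [dHbO2, dHbR]  ->  invert once, apply everywhere.
    Einv = np.linalg.inv(E)
    scaled = od / (dist[None, :, None] * dpf_arr[None, None, :])
    conc = np.einsum("cw,tkw->tkc", Einv, scaled)  # (..., [HbO2, HbR])
    return conc[:, :, 0]


def _bandpass_sos(low: float, high: float, fs: float, order: int):
    nyq = fs / 2.0
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    x: np.ndarray, fs: float, low: float = 0.01, high: float = 0.15, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the first axis."""
    sos = _bandpass_sos(low, high, fs, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def bandpass(
    recording: ContinuousRecording,
    low: float = 0.01,
    high: float = 0.15,
    order: int = 4,
) -> ContinuousRecording:
    """Band-pass a recording to the hemodynamic band (default 0.01-0.15 Hz).

    A 4th-order Butterworth applied forward-backward (zero phase) so the
    instantaneous phase extracted later is not biased by filter delay.  The
    band excludes respiratory (~0.2-0.3 Hz) and cardiac (~0.8-2 Hz) rhythms.
    """
    filtered = bandpass_array(recording.samples, recording.fs, low, high, order)
    return replace(recording, samples=filtered)


def epoch(
    recording: ContinuousRecording,
    window: EpochWindow | None = None,
    min_trials: int = 2,
) -> EpochSet:
    """Segment a recording into stimulus-locked epochs.

    One epoch per onset, covering ``[onset + window.t_start, onset +
    window.t_start + window.total)``.  Onsets whose window would fall outside
    the recording are dropped with a warning; fewer than ``min_trials``
    surviving trials is an error.
    """
    win = window or EpochWindow()
    n_samp = win.n_samples(recording.fs)
    n_total = recording.samples.shape[0]
    trials = []
    for onset in np.atleast_1d(recording.onsets):
        start = int(math.floor((onset + win.t_start) * recording.fs))
        if start < 0 or start + n_samp > n_total:
            logger.warning(
                "dropping trial at onset %.3f s: window [%d, %d) outside recording",
                onset, start, start + n_samp,
            )
            continue
        trials.append(recording.samples[start : start + n_samp, :].T)
    if len(trials) < min_trials:
        raise ValueError(
            f"only {len(trials)} trial(s) survive epoching; need >= {min_trials}"
        )
    data = np.stack(trials, axis=0)
    return EpochSet(data=data, fs=recording.fs,
                    channel_labels=list(recording.channel_labels), window=win)
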