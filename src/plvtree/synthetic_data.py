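"""Synthetic multi-trial fNIRS-like cohorts with a planted coupling topology.

Real recordings behind this kind of study are restricted, so the pipeline is
exercised on generated data whose ground truth is known.  The generator
emulates the experimental geometry -- 14 channels sampled at 7.81 Hz, 28
target trials per subject, 20-s epochs spanning [-6, 14] s around the
stimulus with 2-s edge margins and a [-4, -1] s baseline -- and plants an
inter-channel phase-coupling structure during the post-stimulus window.

Signal model (per trial, per channel): a carrier inside the hemodynamic
pass band (default 0.05 Hz) whose phase offset is a tree-coupled anchor plus
a variance-modulated random walk, with an additive white Gaussian noise
floor.  The anchors follow the planted spanning tree: walking the tree from
its root, each channel's anchor is its parent's anchor plus a von Mises
jitter with concentration ``coupling_kappa`` (kappa = 0 is uniform jitter,
i.e. no coupling; larger kappa means tighter phase locking, decaying with
hop distance along the tree).  The random walk is anchored to zero at the
stimulus onset and its step size tapers from ``baseline_drift_sd`` (large:
channels decohere from each other within a few seconds pre-stimulus) to
``post_drift_sd`` (small: the planted coupling is expressed cleanly) over
the final second before onset.  The phase trajectory is therefore continuous
-- there is no onset phase step, whose broadband transient would otherwise
corrupt the Hilbert phase across much of a 20-s epoch at a 0.05 Hz carrier.

Subjects are reproducible streams: subject i uses seed ``seed + i``.  Each
subject's realized coupling strength is drawn around the configured kappa,
and synthetic clinical scores are deterministic monotone functions of that
realized strength, so score-vs-metric correlations are recoverable ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .group_stats import CONTROL, PATIENT, SubjectRecord
from .mst import TreeGraph, line_edges, star_edges
from .preprocess import EpochSet, EpochWindow


def default_alsfrs_link(kappa: float) -> float:
    """Strictly decreasing map from coupling strength to an ALSFRS-R-like score.

    Stronger planted coupling plays the role of more severe disease, so the
    functional score (48 = normal, 0 = complete loss) decays with kappa.
    """
    return 48.0 / (1.0 + kappa)


def default_duration_link(kappa: float) -> float:
    """Strictly increasing map from coupling strength to disease years."""
    return float(kappa)


@dataclass
class SyntheticConfig:
    """Stated-world parameters of the synthetic cohort generator.

    Defaults follow the emulated acquisition (28 trials, 14 channels,
    7.81 Hz, 2/4/12/2-s epoch geometry).  ``coupling_template`` may be
    ``"star"``, ``"line"`` or an explicit edge list and must be a spanning
    tree over the channels.  ``kappa_spread`` is the half-width of the
    uniform multiplicative per-subject variation of the realized kappa.
    """

    n_subjects_per_group: int = 10
    n_trials: int = 28
    n_channels: int = 14
    fs: float = 7.81
    window: EpochWindow = field(default_factory=EpochWindow)
    carrier_freq: float = 0.05
    coupling_template: str | Sequence[tuple[int, int]] = "star"
    coupling_kappa: float = 2.0
    kappa_spread: float = 0.5
    noise_sd: float = 0.3
    baseline_drift_sd: float = 0.9
    post_drift_sd: float = 0.02
    amplitude: float = 1.0
    clinical_link: Callable[[float], float] = default_alsfrs_link
    duration_link: Callable[[float], float] = default_duration_link
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_trials < 1 or self.n_channels < 2:
            raise ValueError("subject, trial and channel counts must be positive")
        if not 0.01 < self.carrier_freq < 0.15:
            raise ValueError(
                f"carrier_freq {self.carrier_freq} Hz must lie strictly inside "
                "the (0.01, 0.15) Hz pass band"
            )
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")
        if not 0 <= self.kappa_spread < 1:
            raise ValueError("kappa_spread must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_drift_sd < 0 or self.post_drift_sd < 0:
            raise ValueError("phase drift step sizes must be >= 0")
        # Resolving the template also validates the spanning-tree invariant.
        self.template_tree()

    def template_tree(self) -> TreeGraph:
        """The planted topology as a validated spanning tree."""
        if isinstance(self.coupling_template, str):
            if self.coupling_template == "star":
                edges = star_edges(self.n_channels)
            elif self.coupling_template == "line":
                edges = line_edges(self.n_channels)
            else:
                raise ValueError(
                    f"unknown template '{self.coupling_template}' "
                    "(expected 'star', 'line' or an edge list)"
                )
        else:
            edges = tuple(tuple(e) for e in self.coupling_template)
            if len(edges) != self.n_channels - 1:
                raise ValueError(
                    f"coupling_template must be a spanning tree: expected "
                    f"{self.n_channels - 1} edges, got {len(edges)}"
                )
        try:
            return TreeGraph(n_nodes=self.n_channels, edges=edges,
                             channel_labels=self.channel_labels())
        except ValueError as exc:
            raise ValueError(f"coupling_template is not a spanning tree: {exc}")

    def channel_labels(self) -> list[str]:
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]

    def geometry(self) -> tuple[float, float, float, float, int]:
        return (self.fs, self.window.margin, self.window.pre, self.window.post,
                self.n_channels)


def _bfs_order(tree: TreeGraph) -> list[tuple[int, int]]:
    """(parent, child) pairs in breadth-first order from node 0."""
    adjacency: dict[int, list[int]] = {i: [] for i in range(tree.n_nodes)}
    for a, b in tree.edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    order, seen, queue = [], {0}, [0]
    while queue:
        node = queue.pop(0)
        for nb in sorted(adjacency[node]):
            if nb not in seen:
                seen.add(nb)
                order.append((node, nb))
                queue.append(nb)
    return order


def subject_rng(config: SyntheticConfig, subject_index: int) -> np.random.Generator:
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    return np.random.default_rng(config.seed + subject_index)


def realized_kappa(config: SyntheticConfig, subject_index: int) -> float:
    """Per-subject coupling strength: the first draw of the subject stream."""
    rng = subject_rng(config, subject_index)
    lo, hi = 1.0 - config.kappa_spread, 1.0 + config.kappa_spread
    return float(config.coupling_kappa * rng.uniform(lo, hi))


def generate_subject(config: SyntheticConfig, subject_index: int) -> EpochSet:
    """Generate one subject's trial x channel x sample HbO2-like epochs.

    Deterministic given ``(config.seed, subject_index)``.  See the module
    docstring for the signal and coupling model.
    """
    rng = subject_rng(config, subject_index)
    lo, hi = 1.0 - config.kappa_spread, 1.0 + config.kappa_spread
    kappa = config.coupling_kappa * rng.uniform(lo, hi)

    tree = config.template_tree()
    bfs = _bfs_order(tree)
    n_trials, n_ch = config.n_trials, config.n_channels
    n_samples = config.window.n_samples(config.fs)
    t = config.window.t_start + np.arange(n_samples) / config.fs

    # Tree-coupled phase anchors: propagate a trial-specific root phase down
    # the template with von Mises jitter per edge (kappa = 0 reduces to
    # uniform jitter, i.e. fully independent channels).
    anchor = np.empty((n_trials, n_ch))
    anchor[:, 0] = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    for parent, child in bfs:
        jitter = rng.vonmises(0.0, kappa, size=n_trials)
        anchor[:, child] = anchor[:, parent] + jitter

    # Per-channel phase random walk, anchored at zero at the stimulus onset,
    # with step size tapering from baseline_drift_sd to post_drift_sd over
    # the final second before onset.  Pre-stimulus, the walk decoheres the
    # channels from their coupled anchors (independent baseline phases);
    # post-stimulus, the residual wander is small and the planted coupling
    # shows.  Keeping the phase continuous avoids an onset step, whose
    # broadband transient would bias the Hilbert phase deep into the epoch.
    taper = np.clip((t + 1.0) / 1.0, 0.0, 1.0)
    taper = 0.5 * (1.0 - np.cos(np.pi * taper))  # smoothstep over [-1, 0)
    step_sd = config.baseline_drift_sd * (1.0 - taper) + config.post_drift_sd * taper
    walk = np.cumsum(
        rng.normal(0.0, 1.0, size=(n_trials, n_ch, n_samples)) * step_sd[None, None, :],
        axis=2,
    )
    onset_idx = int(np.floor((0.0 - config.window.t_start) * config.fs))
    walk -= walk[:, :, onset_idx : onset_idx + 1]
    offset = anchor[:, :, None] + walk

    carrier = 2.0 * np.pi * config.carrier_freq * t
    data = config.amplitude * np.cos(carrier[None, None, :] + offset)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    if not np.all(np.isfinite(data)):  # pragma: no cover - defensive
        raise RuntimeError("generated data contain non-finite values")
    return EpochSet(data=data, fs=config.fs,
                    channel_labels=config.channel_labels(), window=config.window)


def generate_cohort(
    config_hc: SyntheticConfig, config_patient: SyntheticConfig
) -> list[tuple[EpochSet, SubjectRecord]]:
    """Generate a labelled two-group cohort (controls first, then patients).

    Both configs must share the acquisition geometry (fs, window, channel
    count).  Each record carries the subject's realized coupling strength
    and the deterministic clinical scores derived from it.
    """
    if config_hc.geometry() != config_patient.geometry():
        raise ValueError("group configs must share fs, window and n_channels")
    cohort: list[tuple[EpochSet, SubjectRecord]] = []
    for group, cfg in ((CONTROL, config_hc), (PATIENT, config_patient)):
        prefix = "HC" if group == CONTROL else "PT"
        for i in range(cfg.n_subjects_per_group):
            epochs = generate_subject(cfg, i)
            kappa = realized_kappa(cfg, i)
            score = float(cfg.clinical_link(kappa))
            record = SubjectRecord(
                subject_id=f"{prefix}{i + 1:02d}",
                group=group,
                disease_duration=float(cfg.duration_link(kappa)),
                alsfrs_r=int(np.clip(round(score), 0, 48)),
                clinical_score=score,
                coupling_kappa=kappa,
            )
            cohort.append((epochs, record))
    return cohort
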