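"""Instantaneous phase, PLV, baseline normalization, tPLV and gPLV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from plvtree.connectivity import (
    ConnectivityMatrix,
    PhaseEpochs,
    PLVTimeSeries,
    analytic_signal,
    channel_pairs,
    gplv,
    normalize_plv,
    plv,
    tplv_matrix,
)
from plvtree.preprocess import EpochWindow

from conftest import FS, epochs_from_signal


def phase_series(values, kind="plv", fs=FS, n_channels=3, n_trials=4):
    labels = [f"CH{c + 1:02d}" for c in range(n_channels)]
    return PLVTimeSeries(values=values, kind=kind, fs=fs, channel_labels=labels,
                         n_trials=n_trials)


class TestAnalyticSignal:
    def test_cosine_phase_matches_closed_form(self, cosine_epochs):
        """phi[n] of cos(2 pi f t) is 2 pi f t mod 2 pi away from the edges."""
        epochs, freq = cosine_epochs
        ph = analytic_signal(epochs)
        t = epochs.times()
        expected = np.angle(np.exp(1j * 2 * np.pi * freq * t))
        central = epochs.window_slice(-4.0, 12.0)  # central 16 s
        err = np.angle(np.exp(1j * (ph.phases[0, 0] - expected)))
        assert np.abs(err[central]).max() < 0.05

    def test_quadrature_pair_offset_by_half_pi(self):
        freq = 2 * FS / 156

        def build(p, c, t):
            return np.cos(2 * np.pi * freq * t) if c == 0 else np.sin(2 * np.pi * freq * t)

        epochs = epochs_from_signal(build, n_channels=2)
        ph = analytic_signal(epochs)
        central = epochs.window_slice(-4.0, 12.0)
        diff = np.angle(np.exp(1j * (ph.phases[0, 0] - ph.phases[0, 1])))
        assert np.allclose(diff[central], np.pi / 2, atol=0.05)

    def test_phase_invariant_to_amplitude(self, cosine_epochs):
        epochs, _ = cosine_epochs
        scaled = epochs_from_signal(lambda p, c, t: 3.0 * epochs.data[p, c])
        assert np.allclose(analytic_signal(epochs).phases,
                           analytic_signal(scaled).phases)

    def test_all_zero_trial_dropped(self, cosine_epochs):
        epochs, _ = cosine_epochs
        epochs.data[1, :, :] = 0.0
        ph = analytic_signal(epochs)
        assert ph.dropped_trials == (1,)
        assert ph.n_trials == epochs.n_trials - 1

    def test_phases_wrapped(self, cosine_epochs):
        epochs, _ = cosine_epochs
        ph = analytic_signal(epochs)
        assert np.all(ph.phases > -np.pi) and np.all(ph.phases <= np.pi)


class TestPLV:
    def test_identical_phases_give_one(self, rng):
        phases = np.tile(rng.uniform(-np.pi, np.pi, size=(1, 3, 156)), (5, 1, 1))
        ph = PhaseEpochs(phases=phases, fs=FS, channel_labels=["a", "b", "c"])
        out = plv(ph)
        assert np.allclose(out.values, 1.0)

    def test_antipodal_pair_cancels(self):
        phases = np.zeros((2, 2, 156))
        phases[1, 0, 10] = np.pi  # phase difference 0 vs pi at sample 10
        ph = PhaseEpochs(phases=phases, fs=FS, channel_labels=["a", "b"])
        out = plv(ph)
        assert out.values[0, 10] < 1e-12
        assert np.allclose(np.delete(out.values[0], 10), 1.0)

    def test_single_trial_rejected(self):
        ph = PhaseEpochs(phases=np.zeros((1, 2, 156)), fs=FS, channel_labels=["a", "b"])
        with pytest.raises(ValueError, match="2 trials"):
            plv(ph)

    def test_uniform_random_phases_match_rayleigh_mean(self, rng):
        """E|mean of N unit phasors| ~ sqrt(pi/(4 N)) for i.i.d. phases."""
        n_trials, n_ch = 28, 21  # 210 pairs
        phases = rng.uniform(-np.pi, np.pi, size=(n_trials, n_ch, 156))
        ph = PhaseEpochs(phases=phases, fs=FS,
                         channel_labels=[f"c{i}" for i in range(n_ch)])
        out = plv(ph)
        expected = np.sqrt(np.pi / (4 * n_trials))  # ~ 0.1675
        assert abs(out.values.mean() - expected) < 0.01

    def test_common_phase_shift_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(6, 3, 156))
        shifts = rng.uniform(-np.pi, np.pi, size=(6, 1, 1))  # per-trial, both channels
        ph1 = PhaseEpochs(phases=phases, fs=FS, channel_labels=["a", "b", "c"])
        shifted = np.angle(np.exp(1j * (phases + shifts)))
        ph2 = PhaseEpochs(phases=shifted, fs=FS, channel_labels=["a", "b", "c"])
        assert np.allclose(plv(ph1).values, plv(ph2).values, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(2, 6), st.integers(2, 4), st.just(156)),
            elements=st.floats(-3.14, 3.14),
        )
    )
    def test_plv_bounded(self, phases):
        ph = PhaseEpochs(
            phases=phases, fs=FS,
            channel_labels=[f"c{i}" for i in range(phases.shape[1])],
        )
        out = plv(ph)
        assert np.all(out.values >= 0.0) and np.all(out.values <= 1.0)


class TestNormalize:
    def test_direct_arithmetic(self):
        """mu=0.5, sigma=0.1, PLV=0.7 -> zPLV=2."""
        values = np.full((3, 156), 0.7)
        i0 = int(np.floor(2 * FS))
        i1 = int(np.floor(5 * FS))
        base = np.linspace(0.4, 0.6, i1 - i0)  # mean 0.5
        values[:, i0:i1] = base
        series = phase_series(values)
        out = normalize_plv(series)
        sigma = base.std()
        assert np.allclose(out.baseline_mean, 0.5)
        post = out.values[:, int(np.floor(6 * FS)) :]
        assert np.allclose(post, (0.7 - 0.5) / sigma)
        # reference arithmetic: sigma = 0.1 would give exactly 2.0
        assert np.allclose((0.7 - 0.5) / 0.1, 2.0)

    def test_location_invariance(self, rng):
        values = np.clip(rng.uniform(0.1, 0.7, size=(3, 156)), 0, 1)
        shifted = values + 0.2
        z1 = normalize_plv(phase_series(values)).values
        z2 = normalize_plv(phase_series(np.clip(shifted, 0, 1))).values
        assert np.allclose(z1, z2, atol=1e-10)

    def test_constant_baseline_guarded_to_zero(self):
        values = np.full((3, 156), 0.5)
        out = normalize_plv(phase_series(values))
        assert np.all(out.values == 0.0)

    def test_requires_raw_kind(self, rng):
        z = phase_series(rng.normal(size=(3, 156)), kind="zplv")
        with pytest.raises(ValueError, match="raw"):
            normalize_plv(z)


class TestTPLV:
    def test_constant_zplv_mean(self):
        values = np.full((3, 156), 1.5)
        out = tplv_matrix(phase_series(values, kind="zplv"))
        iu = np.triu_indices(3, 1)
        assert np.allclose(out.matrix[iu], 1.5)
        assert np.all(np.diag(out.matrix) == 0)

    def test_m_is_94_at_paper_rate(self, rng):
        out = tplv_matrix(phase_series(rng.normal(size=(3, 156)), kind="zplv"))
        assert out.m_samples == 94  # round(12 s x 7.81 Hz)

    def test_matches_naive_summation_oracle(self, rng):
        values = rng.normal(size=(3, 156))
        series = phase_series(values, kind="zplv")
        out = tplv_matrix(series)
        start = int(np.floor(6 * FS))
        for idx, (k, l) in enumerate(channel_pairs(3)):
            acc = 0.0
            for p in range(94):
                acc += values[idx, start + p]
            assert abs(out.matrix[k, l] - acc / 94) < 1e-12

    def test_requires_zplv(self, rng):
        raw = phase_series(np.clip(rng.uniform(size=(3, 156)), 0, 1))
        with pytest.raises(ValueError, match="zplv"):
            tplv_matrix(raw)


class TestGPLV:
    def test_constant_matrix(self):
        m = np.ones((14, 14)) - np.eye(14)
        conn = ConnectivityMatrix(matrix=m, channel_labels=[f"c{i}" for i in range(14)])
        assert gplv(conn) == 1.0

    def test_arithmetic_series_oracle(self):
        """Upper-triangle entries 1..91 -> mean (1+91)/2 = 46."""
        m = np.zeros((14, 14))
        iu = np.triu_indices(14, 1)
        m[iu] = np.arange(1, 92)
        m = m + m.T
        conn = ConnectivityMatrix(matrix=m, channel_labels=[f"c{i}" for i in range(14)])
        assert gplv(conn) == 46.0

    def test_permutation_invariance(self, rng):
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        perm = rng.permutation(6)
        conn = ConnectivityMatrix(matrix=m, channel_labels=[f"c{i}" for i in range(6)])
        permuted = ConnectivityMatrix(matrix=m[np.ix_(perm, perm)],
                                      channel_labels=[f"c{i}" for i in perm])
        assert np.isclose(gplv(conn), gplv(permuted))


def test_margins_absorb_edge_effects(rng):
    """PLV with vs without margins differs more at the window edges."""
    from plvtree.synthetic_data import SyntheticConfig, generate_subject

    cfg = SyntheticConfig(coupling_kappa=2.0, seed=7, n_channels=6)
    epochs = generate_subject(cfg, 0)
    full = plv(analytic_signal(epochs))

    # strip the 2-s margins before the Hilbert step
    inner = EpochWindow(margin=0.0, pre=4.0, post=12.0)
    keep = epochs.window_slice(-4.0, 12.0)
    from plvtree.preprocess import EpochSet

    stripped = EpochSet(data=epochs.data[:, :, keep], fs=epochs.fs,
                        channel_labels=epochs.channel_labels, window=inner)
    part = plv(analytic_signal(stripped))

    aligned = full.values[:, keep]
    diff = np.abs(aligned - part.values)
    edge = np.concatenate([diff[:, :5].ravel(), diff[:, -5:].ravel()])
    center_idx = diff.shape[1] // 2
    center = diff[:, center_idx - 5 : center_idx + 5].ravel()
    assert edge.mean() > center.mean()
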