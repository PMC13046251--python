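"""Chimera statistics: spectral communities, order parameters, contrast
labeling, windowed series and three-phase segmentation."""

import numpy as np
import pytest
from scipy.special import iv
from sklearn.metrics import adjusted_rand_score

from chimerapred.chimera import (chimera_index_series, chimera_label,
                                 order_parameter, segment_three_phases,
                                 spectral_clusters)
from chimerapred.core import PhaseTrajectory, WindowLabels, WindowPlan
from chimerapred.kuramoto import KuramotoParams, simulate_kuramoto


def block_plv(n_a=5, n_b=5, within=0.9, between=0.05, noise=0.0, seed=0):
    c = n_a + n_b
    m = np.full((c, c), between)
    m[:n_a, :n_a] = within
    m[n_a:, n_a:] = within
    if noise:
        rng = np.random.default_rng(seed)
        e = rng.normal(0, noise, (c, c))
        m = m + (e + e.T) / 2
    m = np.clip(m, 0, 1)
    np.fill_diagonal(m, 1.0)
    return m


class TestSpectralClusters:
    def test_exact_block_recovery(self):
        assign = spectral_clusters(block_plv(), k=2, seed=0)
        labels = assign.labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_noisy_blocks_recovered_with_high_ari(self):
        truth = np.array([0] * 5 + [1] * 5)
        good = 0
        for trial in range(50):
            m = block_plv(noise=0.05, seed=trial)
            assign = spectral_clusters(m, k=2, seed=0)
            if adjusted_rand_score(truth, assign.labels) > 0.9:
                good += 1
        assert good >= 48  # >= 95 % of trials

    def test_k_equal_to_channel_count_rejected(self):
        with pytest.raises(ValueError):
            spectral_clusters(block_plv(), k=10)

    def test_eigengaps_reported(self):
        assign = spectral_clusters(block_plv(), k=2, seed=0)
        assert assign.eigengaps is not None and assign.eigengaps.size == 9


class TestOrderParameter:
    def test_aligned_phases_give_unity(self):
        assert order_parameter(np.full(7, 1.3)) == pytest.approx(1.0, abs=1e-15)

    def test_balanced_phases_cancel(self):
        assert order_parameter(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_von_mises_matches_bessel_ratio(self):
        """Monte-Carlo resultant of von Mises(kappa=2) draws matches the
        population mean resultant length I1(k)/I0(k)."""
        rng = np.random.default_rng(0)
        draws = rng.vonmises(0.0, 2.0, size=100_000)
        population = iv(1, 2.0) / iv(0, 2.0)
        assert order_parameter(draws) == pytest.approx(population, abs=0.01)

    def test_invariances(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(-np.pi, np.pi, 50)
        r = order_parameter(phases)
        assert abs(order_parameter(phases + 2.1) - r) < 1e-12
        assert abs(order_parameter(rng.permutation(phases)) - r) < 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([]))


class TestChimeraLabel:
    @pytest.mark.parametrize("cluster_r, contrast, label", [
        ((0.95, 0.40), 0.55, 1),
        ((0.60, 0.35), 0.25, 0),
        ((0.65, 0.35), 0.30, 0),  # strict threshold
    ])
    def test_contrast_rule(self, cluster_r, contrast, label):
        c, y = chimera_label(np.array(cluster_r))
        assert c == pytest.approx(contrast)
        assert y == label

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            chimera_label(np.array([0.8]))

    def test_contrast_invariant_to_cluster_relabeling(self):
        a, _ = chimera_label(np.array([0.9, 0.2, 0.5]))
        b, _ = chimera_label(np.array([0.5, 0.9, 0.2]))
        assert a == b


def synthetic_series(contrasts, min_rs=None):
    out = []
    for i, c in enumerate(contrasts):
        lo = 0.3 if min_rs is None else min_rs[i]
        out.append(WindowLabels(window=(2.5 * i, 2.5 * i + 5.0),
                                cluster_R=np.array([lo + c, lo]),
                                contrast=float(c), ychimera=int(c > 0.3)))
    return out


class TestChimeraIndexSeries:
    def test_global_synchrony_has_low_contrast(self):
        params = KuramotoParams(12, omega=np.full(12, 8.0), coupling_K=1.2,
                                phase_lag_alpha=0.0)
        traj = simulate_kuramoto(params, 30.0, 1 / 256, seed=0)
        series = chimera_index_series(traj)
        assert all(w.contrast < 0.1 for w in series[4:])

    def test_incoherent_network_has_low_contrast(self):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            # spaced frequencies avoid accidental within-window locking
            omega = np.linspace(5, 100, 16) + rng.uniform(-1, 1, 16)
            params = KuramotoParams(16, omega=omega,
                                    coupling_K=0.0, phase_lag_alpha=0.0)
            traj = simulate_kuramoto(params, 30.0, 1 / 256, seed=seed)
            series = chimera_index_series(traj, seed=seed)
            hits.extend([w.contrast < 0.15 for w in series])
        assert np.mean(hits) >= 0.9

    def test_episode_series_matches_generator_truth(self, desk_episode):
        """Pipeline-derived chimera flags agree with ground-truth labels
        evaluated at the same (guard-shifted) window boundaries."""
        from chimerapred.episodes import ground_truth_labels
        from chimerapred.phase import analytic_phase

        traj = analytic_phase(desk_episode.signal)
        series = chimera_index_series(traj)
        truth = ground_truth_labels(desk_episode, [w.window for w in series])
        assert len(series) > 50
        acc = np.mean([w.ychimera == t for w, t in zip(series, truth[:, 0])])
        assert acc > 0.85


class TestSegmentation:
    def test_detects_three_phases_in_canonical_profile(self):
        contrasts = np.concatenate([
            np.zeros(20),                 # baseline
            np.linspace(0, 0.6, 20),      # emergence ramp
            np.full(30, 0.6),             # stabilization plateau
            np.linspace(0.6, 0.05, 10),   # transition to global sync
        ])
        min_rs = np.concatenate([np.full(70, 0.2), np.linspace(0.2, 0.95, 10)])
        seg = segment_three_phases(synthetic_series(contrasts, min_rs))
        assert seg.detected
        assert seg.emergence_onset is not None
        assert seg.stabilization_onset is not None and \
            seg.stabilization_onset > seg.emergence_onset
        assert seg.transition_onset is not None and \
            seg.transition_onset > seg.stabilization_onset

    def test_monotone_ramp_without_plateau(self):
        contrasts = np.concatenate([np.zeros(10), np.linspace(0, 0.9, 40)])
        seg = segment_three_phases(synthetic_series(contrasts),
                                   slope_tolerance=0.001)
        assert seg.detected and seg.emergence_onset is not None
        assert seg.stabilization_onset is None

    def test_flat_baseline_reports_no_phases(self):
        seg = segment_three_phases(synthetic_series(np.full(40, 0.05)))
        assert not seg.detected
        assert seg.emergence_onset is None

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            segment_three_phases(synthetic_series(np.zeros(5)))

    def test_detection_close_to_truth_on_generated_episodes(self):
        """Segmentation on the pipeline-derived series lands within 2
        windows of the segmentation of the ground-truth series in >= 80 %
        of seeds."""
        from chimerapred.episodes import EpisodeSpec, generate_episode
        from chimerapred.phase import analytic_phase

        hop = 2.5
        hits = []
        for seed in range(1, 11):
            ep = generate_episode(EpisodeSpec.desk(seed=seed))
            truth_seg = segment_three_phases(ep.window_labels)
            series = chimera_index_series(analytic_phase(ep.signal))
            pipe_seg = segment_three_phases(series)
            ok = (truth_seg.detected and pipe_seg.detected and
                  abs(pipe_seg.emergence_onset - truth_seg.emergence_onset)
                  <= 2 * hop + 0.5)
            hits.append(ok)
        assert np.mean(hits) >= 0.8
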