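"""DTAK, the segment-clustering objective, ACA/HACA, and the baselines."""

import numpy as np
import pytest

from surgseg import (
    ACAConfig,
    ClusterState,
    FeatureFrames,
    Segmentation,
    ValidationError,
    aca,
    aca_objective,
    dtak,
    gmm_segment,
    haca,
    run_with_restarts,
    segment_cluster_distance,
    spectral_segment,
)
from surgseg.tclust import _cluster_distances, _objective_from_tau
from surgseg import _dtak
from conftest import block_kernel, dtak_bruteforce, random_kernel, random_segmentation, trace_objective


def _ff(X):
    return FeatureFrames(X=np.asarray(X, float), feature_set="ssc", rate_hz_effective=1.0)


class TestDtak:
    def test_single_frame_pair_returns_kernel_entry(self, rng):
        F = random_kernel(rng, 6)
        assert dtak(F, (2, 3), (4, 5)) == pytest.approx(F[2, 4])

    def test_saturated_kernel_gives_one(self):
        F = np.ones((12, 12))
        assert dtak(F, (0, 5), (5, 12)) == pytest.approx(1.0)
        assert dtak(F, (0, 4), (4, 8)) == pytest.approx(1.0)

    def test_matches_bruteforce_path_enumeration(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            F = random_kernel(rng, 9)
            for na in range(1, 5):
                for nb in range(1, 5):
                    a0 = int(rng.integers(0, 9 - na))
                    b0 = int(rng.integers(0, 9 - nb))
                    got = dtak(F, (a0, a0 + na), (b0, b0 + nb))
                    want = dtak_bruteforce(F, a0, a0 + na, b0, b0 + nb)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry_and_range(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            F = random_kernel(rng, 20)
            a = sorted(rng.integers(0, 21, 2))
            b = sorted(rng.integers(0, 21, 2))
            if a[0] == a[1] or b[0] == b[1]:
                continue
            t1 = dtak(F, a, b)
            assert t1 == pytest.approx(dtak(F, b, a), abs=1e-12)
            assert 0.0 < t1 <= 1.0 + 1e-12

    def test_empty_range_rejected(self, rng):
        F = random_kernel(rng, 5)
        with pytest.raises(ValidationError):
            dtak(F, (2, 2), (0, 3))


class TestSegmentClusterDistance:
    def test_singleton_cluster_containing_itself_is_zero(self, rng):
        F = random_kernel(rng, 12)
        seg = random_segmentation(rng, 12, 3, l_min=2, l_max=5)
        state = ClusterState(membership=seg.labels, K=3)
        m = 0
        rng_seg = (seg.boundaries[m], seg.boundaries[m + 1])
        # make segment 0 the only member of its cluster
        state.membership[1:][state.membership[1:] == state.membership[0]] = (
            (state.membership[0] + 1) % 3
        )
        d = segment_cluster_distance(F, rng_seg, state, seg, int(state.membership[0]))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_two_point_form(self, rng):
        F = random_kernel(rng, 10)
        seg = Segmentation(boundaries=[0, 4, 10], labels=[0, 1], K=2, N=10)
        state = ClusterState(membership=seg.labels, K=2)
        d = segment_cluster_distance(F, (0, 4), state, seg, 1)
        expected = dtak(F, (0, 4), (0, 4)) - 2 * dtak(F, (0, 4), (4, 10)) + dtak(F, (4, 10), (4, 10))
        assert d == pytest.approx(expected, abs=1e-12)

    def test_matches_literal_triple_sum(self, rng):
        F = random_kernel(rng, 25)
        seg = random_segmentation(rng, 25, 2, l_min=3, l_max=8)
        state = ClusterState(membership=seg.labels, K=2)
        b = seg.boundaries
        for k in range(2):
            members = np.flatnonzero(seg.labels == k)
            mk = members.size
            for m in range(seg.M):
                q = (b[m], b[m + 1])
                tau = lambda i, j: dtak(F, i, j)  # noqa: E731
                lit = (
                    tau(q, q)
                    - 2 / mk * sum(tau(q, (b[j], b[j + 1])) for j in members)
                    + 1 / mk**2 * sum(
                        tau((b[i], b[i + 1]), (b[j], b[j + 1]))
                        for i in members for j in members
                    )
                )
                got = segment_cluster_distance(F, q, state, seg, k)
                assert got == pytest.approx(lit, abs=1e-10)

    def test_fast_matrix_path_agrees_with_reference(self, rng):
        F = random_kernel(rng, 30)
        seg = random_segmentation(rng, 30, 3, l_min=2, l_max=7)
        state = ClusterState(membership=seg.labels, K=3)
        b = seg.boundaries
        T = _dtak.dtak_matrix(F, b[:-1], b[1:])
        D2 = _cluster_distances(T, seg.labels, 3)
        for m in range(seg.M):
            for k in range(3):
                if (seg.labels == k).any():
                    ref = segment_cluster_distance(F, (b[m], b[m + 1]), state, seg, k)
                    assert D2[m, k] == pytest.approx(ref, abs=1e-10)


class TestObjective:
    def test_singleton_clusters_give_zero(self, rng):
        F = random_kernel(rng, 12)
        seg = Segmentation(boundaries=[0, 4, 8, 12], labels=[0, 1, 2], K=3, N=12)
        assert aca_objective(F, seg) == pytest.approx(0.0, abs=1e-12)

    def test_identical_segments_one_cluster_give_zero(self):
        F = np.ones((10, 10))
        seg = Segmentation(boundaries=[0, 5, 10], labels=[0, 0], K=1, N=10)
        assert aca_objective(F, seg) == pytest.approx(0.0, abs=1e-12)

    def test_sum_form_equals_trace_form(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            N = int(rng.integers(15, 40))
            K = int(rng.integers(2, 5))
            seg = random_segmentation(rng, N, K, l_min=2, l_max=max(4, N // 6))
            if seg.M > 12 or np.bincount(seg.labels, minlength=K).min() == 0:
                continue
            F = random_kernel(rng, N)
            b = seg.boundaries
            T = _dtak.dtak_matrix(F, b[:-1], b[1:])
            assert aca_objective(F, seg) == pytest.approx(
                trace_objective(T, seg.labels, K), abs=1e-8
            )


class TestACA:
    def test_objective_monotone_and_lengths_bounded(self):
        cfg = ACAConfig(K=4, l_min=3, l_max=12, seed=0)
        for seed in range(6):
            rng = np.random.default_rng(seed)
            F = random_kernel(rng, 120, sigma=1.5)
            seg = aca(F, cfg, seed=seed)
            h = np.asarray(seg.meta["history"])
            assert np.all(np.diff(h) <= 1e-9)
            assert seg.segment_lengths.min() >= 3
            assert seg.segment_lengths.max() <= 12
            assert seg.energy == pytest.approx(h[-1])

    def test_recovers_planted_blocks(self):
        F = block_kernel([10, 10, 10])
        cfg = ACAConfig(K=3, l_min=2, l_max=10)
        seg = aca(F, cfg, seed=0)
        planted = Segmentation(boundaries=[0, 10, 20, 30], labels=[0, 1, 2], K=3, N=30)
        # boundary positions at 10 and 20; the three blocks get distinct labels
        assert {10, 20} <= set(seg.boundaries.tolist())
        fl = seg.frame_labels()
        assert len({fl[0], fl[15], fl[25]}) == 3
        assert seg.energy <= aca_objective(F, planted) + 1e-9

    def test_k1_gives_single_label(self, rng):
        F = random_kernel(rng, 30)
        seg = aca(F, ACAConfig(K=1, l_min=2, l_max=8), seed=0)
        assert set(seg.labels.tolist()) == {0}

    def test_too_short_series_rejected(self, rng):
        F = random_kernel(rng, 10)
        with pytest.raises(ValidationError):
            aca(F, ACAConfig(K=4, l_min=3, l_max=5), seed=0)


class TestHACA:
    def test_recovers_planted_blocks_like_aca(self):
        F = block_kernel([10, 10, 10])
        cfg = ACAConfig(K=3, l_min=2, l_max=10)
        seg = haca(F, cfg, l_max_1=5, l_max_2=10, seed=0)
        planted = Segmentation(boundaries=[0, 10, 20, 30], labels=[0, 1, 2], K=3, N=30)
        assert {10, 20} <= set(seg.boundaries.tolist())
        fl = seg.frame_labels()
        assert len({fl[0], fl[15], fl[25]}) == 3
        assert seg.energy <= aca_objective(F, planted) + 1e-9

    def test_matched_configuration_close_to_plain_aca(self):
        F = block_kernel([12, 12, 12])
        cfg = ACAConfig(K=3, l_min=2, l_max=12)
        s_aca = aca(F, cfg, seed=1)
        s_haca = haca(F, cfg, level1_K=3, l_max_1=12, l_max_2=12, seed=1)
        assert abs(s_haca.energy - s_aca.energy) <= 1e-6

    def test_level1_K_below_K_rejected(self, rng):
        F = random_kernel(rng, 40)
        with pytest.raises(ValidationError):
            haca(F, ACAConfig(K=4, l_min=2, l_max=8), level1_K=2, seed=0)


class TestFrameBaselines:
    def test_gmm_separable_two_block_recovery(self, rng):
        X = np.concatenate(
            [rng.standard_normal((2, 40)), 10 + rng.standard_normal((2, 40))], axis=1
        )
        seg = gmm_segment(_ff(X), K=2, seed=0)
        assert seg.M == 2 and set(seg.boundaries.tolist()) == {0, 40, 80}

    def test_gmm_k1_single_segment(self, rng):
        seg = gmm_segment(_ff(rng.standard_normal((2, 30))), K=1, seed=0)
        assert seg.M == 1 and seg.boundaries.tolist() == [0, 30]

    def test_run_length_encoding(self):
        seg = Segmentation.from_frame_labels([0, 0, 1, 1, 0], K=2)
        assert seg.boundaries.tolist() == [0, 2, 4, 5]
        assert seg.labels.tolist() == [0, 1, 0]

    def test_spectral_two_cloud_blocks(self, rng):
        X = np.concatenate(
            [rng.standard_normal((2, 30)), 30 + rng.standard_normal((2, 30))], axis=1
        )
        seg = spectral_segment(_ff(X), K=2, seed=0)
        fl = seg.frame_labels()
        assert len(set(fl[:30])) == 1 and len(set(fl[30:])) == 1 and fl[0] != fl[-1]

    def test_spectral_k_equal_n_rejected(self, rng):
        X = _ff(rng.standard_normal((2, 10)))
        with pytest.raises(ValidationError):
            spectral_segment(X, K=10, seed=0)

    def test_label_permutation_equivalent_under_evaluation(self, rng):
        from surgseg import cluster_accuracy, confusion_matrix

        X = np.concatenate(
            [rng.standard_normal((2, 30)), 30 + rng.standard_normal((2, 30))], axis=1
        )
        truth = Segmentation(boundaries=[0, 30, 60], labels=[0, 1], K=2, N=60)
        accs = {
            cluster_accuracy(confusion_matrix(spectral_segment(_ff(X), K=2, seed=s), truth))
            for s in range(3)
        }
        assert accs == {1.0}


class TestRestarts:
    def _algo(self, F, cfg):
        return lambda seed: aca(F, cfg, seed=seed)

    def test_single_restart_equals_plain_run(self, rng):
        F = random_kernel(rng, 60)
        cfg = ACAConfig(K=3, l_min=2, l_max=10)
        best = run_with_restarts(self._algo(F, cfg), {}, n_init=1, base_seed=7)
        assert best == aca(F, cfg, seed=7)

    def test_returns_minimum_energy_run(self, rng):
        F = random_kernel(rng, 60)
        cfg = ACAConfig(K=3, l_min=2, l_max=10)
        best = run_with_restarts(self._algo(F, cfg), {}, n_init=4, base_seed=0)
        assert best.energy == min(best.meta["energies"])

    def test_deterministic_selection(self, rng):
        F = random_kernel(rng, 60)
        cfg = ACAConfig(K=3, l_min=2, l_max=10)
        a = run_with_restarts(self._algo(F, cfg), {}, n_init=3, base_seed=5)
        b = run_with_restarts(self._algo(F, cfg), {}, n_init=3, base_seed=5)
        assert a == b and a.meta["energies"] == b.meta["energies"]
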