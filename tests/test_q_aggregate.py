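import itertools

import numpy as np
import pytest

from panstruct import q_aggregate, simdata
from panstruct.core_io import QMatrix, ValidationError
from panstruct.q_aggregate import (RunEnsemble, aggregate_modes, align_columns,
                                   cluster_runs, ladder_match, run_distance)


def _random_q(rng, n, k):
    return QMatrix([f"s{i}" for i in range(n)], rng.dirichlet(np.ones(k), size=n))


@pytest.fixture(scope="module")
def true_q():
    m = simdata.PopModel(K_true=4, n_snps=50, pure_sizes=[12] * 4,
                         admixed_specs=[(6, [0.4, 0.3, 0.2, 0.1])])
    return simdata.simulate_genotypes(m, seed=21)[1]


class TestAlignColumns:
    def test_identity(self, true_q):
        perm, aligned = align_columns(true_q, true_q)
        assert perm.tolist() == [0, 1, 2, 3]
        np.testing.assert_array_equal(aligned.proportions, true_q.proportions)

    def test_reversed_columns(self, true_q):
        rev = QMatrix(true_q.sample_ids, true_q.proportions[:, ::-1])
        perm, aligned = align_columns(true_q, rev)
        assert perm.tolist() == [3, 2, 1, 0]
        np.testing.assert_allclose(aligned.proportions, true_q.proportions)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_matches_brute_force_over_permutations(self, k):
        rng = np.random.default_rng(k)
        a, b = _random_q(rng, 15, k), _random_q(rng, 15, k)
        _, aligned = align_columns(a, b)
        best = min(
            ((a.proportions - b.proportions[:, list(p)]) ** 2).sum()
            for p in itertools.permutations(range(k))
        )
        got = ((a.proportions - aligned.proportions) ** 2).sum()
        assert got == pytest.approx(best, abs=1e-12)

    def test_k_mismatch(self, true_q):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError, match="K mismatch"):
            align_columns(true_q, _random_q(rng, true_q.n_samples, 3))


class TestRunDistance:
    def test_identical_zero(self, true_q):
        assert run_distance(true_q, true_q) == 0.0

    def test_permuted_copy_zero(self, true_q):
        rng = np.random.default_rng(1)
        perm = rng.permutation(4)
        other = QMatrix(true_q.sample_ids, true_q.proportions[:, perm])
        assert run_distance(true_q, other) < 1e-12

    def test_metric_properties(self):
        rng = np.random.default_rng(2)
        qs = [_random_q(rng, 10, 3) for _ in range(4)]
        for a, b in itertools.combinations(qs, 2):
            dab, dba = run_distance(a, b), run_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-9)
            assert 0 <= dab <= 1
        for q in qs:
            assert run_distance(q, q) == 0.0


class TestClusterRuns:
    def test_identical_runs_one_cluster(self, true_q):
        ens = simdata.simulate_run_ensemble(true_q, 5, noise_sd=0.0,
                                            permute=True, seed=3)
        assert cluster_runs(ens, 0.1) == [[0, 1, 2, 3, 4]]

    def test_planted_two_mode_partition(self, true_q):
        ens = simdata.simulate_run_ensemble(true_q, 10, noise_sd=0.02, modes=2,
                                            seed=4, mode2_fraction=0.4)
        clusters = cluster_runs(ens, 0.1)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2, 3, 4, 5], [6, 7, 8, 9]]

    def test_zero_cut_all_singletons(self, true_q):
        ens = simdata.simulate_run_ensemble(true_q, 4, noise_sd=0.05,
                                            permute=True, seed=5)
        assert cluster_runs(ens, 0.0) == [[0], [1], [2], [3]]


class TestAggregateModes:
    def test_identical_cluster_average_equals_member(self, true_q):
        ens = simdata.simulate_run_ensemble(true_q, 4, noise_sd=0.0,
                                            permute=True, seed=6)
        [mode] = aggregate_modes(ens, 0.1)
        assert mode.mode_label == "4"
        d = run_distance(mode.averaged, true_q)
        assert d < 1e-9

    def test_noise_reduction_by_averaging(self, true_q):
        noise_sd, n_runs = 0.03, 16
        ens = simdata.simulate_run_ensemble(true_q, n_runs, noise_sd=noise_sd,
                                            permute=True, seed=7)
        [mode] = aggregate_modes(ens, 0.2)
        _, aligned = align_columns(true_q, mode.averaged)
        err = np.abs(aligned.proportions - true_q.proportions).mean()
        single = np.abs(
            align_columns(true_q, ens.replicates[0])[1].proportions
            - true_q.proportions).mean()
        assert err < single  # averaging reduces per-cell error
        assert err < 3 * noise_sd / np.sqrt(n_runs)

    def test_singleton_outlier_discarded(self, true_q):
        rng = np.random.default_rng(8)
        ens = simdata.simulate_run_ensemble(true_q, 9, noise_sd=0.01,
                                            permute=True, seed=9)
        outlier = QMatrix(true_q.sample_ids,
                          rng.dirichlet(np.ones(4), size=true_q.n_samples))
        ens10 = RunEnsemble(4, ens.replicates + [outlier])
        modes = aggregate_modes(ens10, 0.1)
        assert len(modes) == 1
        assert modes[0].discarded_runs == [9]
        assert sorted(modes[0].member_runs) == list(range(9))

    def test_all_singletons_error(self):
        rng = np.random.default_rng(10)
        reps = [_random_q(np.random.default_rng(s), 12, 3) for s in range(3)]
        ens = RunEnsemble(3, reps)
        with pytest.raises(ValidationError, match="no stable mode"):
            aggregate_modes(ens, 0.01)

    def test_rows_stay_on_simplex(self, true_q):
        ens = simdata.simulate_run_ensemble(true_q, 6, noise_sd=0.02,
                                            permute=True, seed=11)
        [mode] = aggregate_modes(ens, 0.2)
        np.testing.assert_allclose(mode.averaged.proportions.sum(axis=1), 1.0,
                                   atol=1e-9)


class TestLadderMatch:
    def _mode(self, K, q):
        from panstruct.q_aggregate import ModeSummary
        return ModeSummary(K, str(K), q, [0, 1], [])

    def test_planted_split_single_edge(self):
        rng = np.random.default_rng(12)
        n = 60
        # K=2: two groups; K=3: group 2 splits into two
        q2 = np.zeros((n, 2))
        q2[:30, 0] = 1
        q2[30:, 1] = 1
        q3 = np.zeros((n, 3))
        q3[:30, 0] = 1
        q3[30:45, 1] = 1
        q3[45:, 2] = 1
        ids = [f"s{i}" for i in range(n)]
        ladder = ladder_match([self._mode(2, QMatrix(ids, q2)),
                               self._mode(3, QMatrix(ids, q3))],
                              base_names=["XI", "GJ"])
        assert ladder.names[2] == ["XI", "GJ"]
        assert sorted(ladder.names[3]) == ["GJ1", "GJ2", "XI"]
        assert ladder.splits(3) == [1]

    def test_missing_level_rejected(self):
        rng = np.random.default_rng(13)
        ids = [f"s{i}" for i in range(10)]
        m2 = self._mode(2, _random_q(rng, 10, 2))
        m4 = self._mode(4, _random_q(rng, 10, 4))
        with pytest.raises(ValidationError, match="missing K"):
            ladder_match([m2, m4])

    def test_planted_hierarchy_recovery(self):
        # 4 leaf groups merging pairwise at K=2: the ladder recovers both splits
        n = 80
        ids = [f"s{i}" for i in range(n)]
        blocks = [range(0, 20), range(20, 40), range(40, 60), range(60, 80)]
        q4 = np.zeros((n, 4))
        for k, b in enumerate(blocks):
            q4[list(b), k] = 1
        q2 = np.zeros((n, 2))
        q2[:40, 0] = 1
        q2[40:, 1] = 1
        q3 = np.zeros((n, 3))
        q3[:40, 0] = 1
        q3[40:60, 1] = 1
        q3[60:, 2] = 1
        ladder = ladder_match([self._mode(2, QMatrix(ids, q2)),
                               self._mode(3, QMatrix(ids, q3)),
                               self._mode(4, QMatrix(ids, q4))])
        assert ladder.splits(3) == [1]   # G2 splits first
        assert ladder.splits(4) == [0]   # then G1
        assert sorted(ladder.names[4]) == sorted(["G11", "G12", "G21", "G22"])


class TestInvariance:
    def test_aggregation_invariant_to_per_run_permutations(self, true_q):
        rng = np.random.default_rng(14)
        ens = simdata.simulate_run_ensemble(true_q, 6, noise_sd=0.02,
                                            permute=False, seed=15)
        permuted = RunEnsemble(4, [
            QMatrix(r.sample_ids, r.proportions[:, rng.permutation(4)])
            for r in ens.replicates])
        [m1] = aggregate_modes(ens, 0.2)
        [m2] = aggregate_modes(permuted, 0.2)
        assert run_distance(m1.averaged, m2.averaged) < 1e-9
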