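import itertools

import numpy as np
import pytest

from oracles import nested_ss_from_vectors, oneway_permanova_f
from potmorph.dissimilarity import DissimilarityMatrix
from potmorph.distance_stats import (alt_gower, dispersion_analysis,
                                     distance_matrix, nested_permanova,
                                     potter_aggregate, upgma)
from potmorph.errors import DesignError, DomainError, ValidationError


class TestAltGower:
    @pytest.mark.parametrize("x,y,expected", [
        ((0, 2, 4), (1, 2, 0), 5 / 3),       # all columns counted
        ((0, 3), (0, 5), 2.0),               # double zero excluded
        ((1, 2, 3), (1, 2, 3), 0.0),         # identity
        ((0, 0), (0, 0), 0.0),               # all double zeros
    ])
    def test_hand_examples(self, x, y, expected):
        assert alt_gower(x, y) == pytest.approx(expected, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            alt_gower([1, 2], [1, 2, 3])

    def test_matrix_matches_pairwise_brute_force(self, rng):
        X = rng.normal(size=(10, 7))
        X[rng.random(size=X.shape) < 0.2] = 0.0  # some double zeros
        D = distance_matrix(X, metric="altGower")
        for i in range(10):
            for j in range(10):
                assert D.values[i, j] == pytest.approx(
                    alt_gower(X[i], X[j]), abs=1e-14)


class TestDistanceMatrix:
    def test_unit_basis_euclidean(self):
        X = np.eye(3)
        D = distance_matrix(X, metric="euclidean")
        off = D.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, np.sqrt(2.0))
        assert np.allclose(np.diag(D.values), 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            distance_matrix([[1.0, np.nan], [0.0, 1.0]])

    def test_unknown_metric_rejected(self):
        with pytest.raises(DomainError):
            distance_matrix(np.eye(3), metric="manhattan")


def nested_fixture(rng, n_comm=2, n_pot=2, n_trial=2, comm_effect=0.0,
                   pot_effect=0.0, d=5):
    """Observation vectors with optional community / potter mean shifts."""
    X, comm, pott = [], [], []
    for c in range(n_comm):
        c_shift = rng.normal(size=d) * comm_effect
        for p in range(n_pot):
            p_shift = rng.normal(size=d) * pot_effect
            for _ in range(n_trial):
                X.append(c_shift + p_shift + rng.normal(size=d))
                comm.append(f"C{c}")
                pott.append(f"C{c}P{p}")
    return np.vstack(X), np.array(comm), np.array(pott)


class TestNestedPermanova:
    def test_ss_partition_matches_vector_space(self, rng):
        # Euclidean distances: the distance-matrix partition must equal the
        # classical nested MANOVA sums of squares computed from group means
        X, comm, pott = nested_fixture(rng, n_comm=3, n_pot=3, n_trial=4,
                                       comm_effect=0.5, pot_effect=0.5)
        D = distance_matrix(X, metric="euclidean")
        res = nested_permanova(D, comm, pott, n_perm=9, seed=0)
        sst, ssc, ssp, ssr = nested_ss_from_vectors(X, comm, pott)
        assert res.ss["total"] == pytest.approx(sst, rel=1e-8)
        assert res.ss["community"] == pytest.approx(ssc, rel=1e-8)
        assert res.ss["potter"] == pytest.approx(ssp, rel=1e-8)
        assert res.ss["residual"] == pytest.approx(ssr, rel=1e-8)

    def test_ss_conservation(self, rng):
        X, comm, pott = nested_fixture(rng, n_comm=3, n_pot=2, n_trial=3)
        D = distance_matrix(X, metric="altGower")
        res = nested_permanova(D, comm, pott, n_perm=9, seed=0)
        total = res.ss["community"] + res.ss["potter"] + res.ss["residual"]
        assert total == pytest.approx(res.ss["total"], rel=1e-8)

    def test_flat_design_equals_oneway_permanova(self, rng):
        # a single community: the individual test reduces to a one-way
        # PERMANOVA over potters, cross-checked by the trace-identity oracle
        X = rng.normal(size=(9, 4))
        pott = np.repeat(["a", "b", "c"], 3)
        comm = np.repeat("only", 9)
        D = distance_matrix(X, metric="euclidean")
        res = nested_permanova(D, comm, pott, n_perm=9, seed=0)
        assert res.community is None
        f_oracle = oneway_permanova_f(D.values, pott)
        assert res.individual.F == pytest.approx(f_oracle, rel=1e-10)
        assert res.individual.df == 2

    def test_degrees_of_freedom(self, rng):
        X, comm, pott = nested_fixture(rng, n_comm=3, n_pot=3, n_trial=2)
        D = distance_matrix(X, metric="euclidean")
        res = nested_permanova(D, comm, pott, n_perm=9, seed=0)
        assert res.community.df == 2          # communities - 1
        assert res.individual.df == 9 - 3     # potters - communities

    def test_exhaustive_enumeration_toy_design(self, rng):
        # 2 communities x 2 potters x 2 trials; the community null has
        # C(4, 2) = 6 equally likely potter-to-community assignments, so the
        # sampled permutation p must converge to the enumerated fraction
        X, comm, pott = nested_fixture(rng, comm_effect=3.0, pot_effect=0.3)
        D = distance_matrix(X, metric="euclidean")
        res = nested_permanova(D, comm, pott, n_perm=4999, seed=1)

        # enumerate all assignments preserving community sizes
        potters = sorted(set(pott))
        obs_of = {p: np.flatnonzero(pott == p) for p in potters}
        G = D.values**2
        N = len(X)
        ss_total = G.sum() / (2 * N)
        ss_resid = sum(G[np.ix_(m, m)].sum() / (2 * len(m))
                       for m in obs_of.values())
        fs = []
        for group_a in itertools.combinations(potters, 2):
            members_a = np.concatenate([obs_of[p] for p in group_a])
            members_b = np.concatenate([obs_of[p] for p in potters
                                        if p not in group_a])
            ss_comm = ss_total - sum(
                G[np.ix_(m, m)].sum() / (2 * len(m))
                for m in (members_a, members_b))
            ss_pot = ss_total - ss_comm - ss_resid
            fs.append((ss_comm / 1) / (ss_pot / 2))
        fs = np.array(fs)
        # the observed assignment is {C0P0, C0P1} vs rest
        obs_assignment = tuple(p for p in potters if p.startswith("C0"))
        f_obs = [f for g, f in zip(itertools.combinations(potters, 2), fs)
                 if g == obs_assignment][0]
        assert res.community.F == pytest.approx(f_obs, rel=1e-10)
        p_exhaustive = np.mean(fs >= f_obs - 1e-12)
        assert abs(res.community.p - p_exhaustive) < 0.03

    def test_observed_f_in_null_with_plus_one_rule(self, rng):
        X, comm, pott = nested_fixture(rng, n_comm=3, n_pot=2, n_trial=3)
        D = distance_matrix(X, metric="euclidean")
        res = nested_permanova(D, comm, pott, n_perm=99, seed=0)
        for pr in (res.community, res.individual):
            assert 1 / 100 <= pr.p <= 1.0

    def test_design_errors(self, rng):
        X = rng.normal(size=(6, 3))
        D = distance_matrix(X, metric="euclidean")
        with pytest.raises(DesignError, match="single observation"):
            nested_permanova(D, ["A"] * 3 + ["B"] * 3,
                             ["p1", "p1", "p2", "p3", "p3", "p3"],
                             n_perm=9, seed=0)
        with pytest.raises(DesignError, match="more than one community"):
            nested_permanova(D, ["A", "A", "A", "B", "B", "B"],
                             ["p1"] * 6, n_perm=9, seed=0)

    def test_singleton_potter_community_skips_community_test(self, rng, caplog):
        X, comm, pott = nested_fixture(rng, n_comm=2, n_pot=2, n_trial=2)
        # merge community C1's potters into one
        pott = np.where(comm == "C1", "C1P0", pott)
        D = distance_matrix(X, metric="euclidean")
        res = nested_permanova(D, comm, pott, n_perm=9, seed=0)
        assert res.community is None
        assert res.individual is not None


class TestDispersion:
    def test_pcoa_distance_equals_direct_distance_to_mean(self, rng):
        X = rng.normal(size=(20, 6))
        groups = np.repeat(["a", "b"], 10)
        res = dispersion_analysis(X, groups, metric="euclidean", n_perm=9,
                                  seed=0)
        for g in ("a", "b"):
            m = groups == g
            direct = np.linalg.norm(X[m] - X[m].mean(axis=0), axis=1)
            assert np.allclose(np.sort(res.distances[m]), np.sort(direct),
                               atol=1e-8)

    def test_scaling_one_group_doubles_its_dispersion(self, rng):
        X = rng.normal(size=(16, 5))
        groups = np.repeat(["a", "b"], 8)
        X2 = X.copy()
        m = groups == "b"
        X2[m] = X2[m].mean(axis=0) + 2.0 * (X2[m] - X2[m].mean(axis=0))
        r1 = dispersion_analysis(X, groups, metric="euclidean", n_perm=9, seed=0)
        r2 = dispersion_analysis(X2, groups, metric="euclidean", n_perm=9, seed=0)
        assert r2.group_means["b"] == pytest.approx(2 * r1.group_means["b"],
                                                    rel=1e-10)
        assert r2.group_means["a"] == pytest.approx(r1.group_means["a"],
                                                    rel=1e-10)

    def test_translated_clouds_have_equal_dispersion(self, rng):
        X = rng.normal(size=(12, 4))
        Y = X + 5.0  # translated copy
        data = np.vstack([X, Y])
        groups = np.repeat(["a", "b"], 12)
        res = dispersion_analysis(data, groups, metric="euclidean", n_perm=99,
                                  seed=0)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"],
                                                     rel=1e-10)

    def test_null_rarely_rejects(self, rng):
        rejections = 0
        for i in range(40):
            r = np.random.default_rng(i)
            X = r.normal(size=(24, 5))
            groups = np.repeat(["a", "b", "c"], 8)
            res = dispersion_analysis(X, groups, metric="altGower",
                                      n_perm=99, seed=i)
            rejections += res.p <= 0.05
        assert rejections <= 6  # about alpha-level behaviour

    def test_design_errors(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(DesignError):
            dispersion_analysis(X, ["a"] * 5, metric="euclidean")
        with pytest.raises(DesignError):
            dispersion_analysis(X, ["a", "a", "b", "b", "c"],
                                metric="euclidean")


class TestPotterAggregate:
    def test_hand_computed_mean(self):
        # 2 potters x 2 trials with cross-pair distances {1, 2, 3, 4}
        D = np.array([
            [0, 9, 1, 2],
            [9, 0, 3, 4],
            [1, 3, 0, 9],
            [2, 4, 9, 0],
        ], dtype=float)
        mat = DissimilarityMatrix(labels=["a1", "a2", "b1", "b2"], values=D)
        out = potter_aggregate(mat, ["A", "A", "B", "B"])
        assert out.values[0, 1] == pytest.approx(2.5)
        assert out.values[0, 0] == 0.0

    def test_identical_trial_sets_give_zero(self, rng):
        X = rng.normal(size=(4, 6))
        Xall = np.vstack([X, X])
        D = distance_matrix(Xall, metric="euclidean")
        out = potter_aggregate(D, ["A"] * 4 + ["B"] * 4)
        # each of A's trials has a zero-distance twin in B, but the mean
        # cross-pair includes non-twin pairs; the exact check is symmetry
        assert np.allclose(out.values, out.values.T)
        assert np.allclose(np.diag(out.values), 0.0)


class TestUpgma:
    def test_three_leaf_hand_case(self):
        D = DissimilarityMatrix(labels=["A", "B", "C"],
                                values=np.array([[0, 1, 4],
                                                 [1, 0, 4],
                                                 [4, 4, 0.0]]))
        dend = upgma(D)
        assert dend.heights[0] == pytest.approx(0.5)
        assert dend.heights[1] == pytest.approx(2.0)
        first = {int(dend.merges[0, 0]), int(dend.merges[0, 1])}
        assert first == {0, 1}  # A and B merge first

    def test_two_leaves(self):
        D = DissimilarityMatrix(labels=["A", "B"],
                                values=np.array([[0, 3.0], [3.0, 0]]))
        dend = upgma(D)
        assert dend.heights[0] == pytest.approx(1.5)

    def test_four_leaf_hand_case(self):
        vals = np.array([
            [0, 2, 6, 10],
            [2, 0, 6, 10],
            [6, 6, 0, 10],
            [10, 10, 10, 0.0],
        ])
        dend = upgma(DissimilarityMatrix(labels=list("ABCD"), values=vals))
        assert np.allclose(dend.heights, [1.0, 3.0, 5.0])

    def test_cophenetic_is_ultrametric(self, rng):
        for _ in range(5):
            X = rng.normal(size=(8, 5))
            D = distance_matrix(X, metric="euclidean")
            C = upgma(D).cophenetic()
            for i, j, k in itertools.combinations(range(8), 3):
                assert C[i, j] <= max(C[i, k], C[j, k]) + 1e-10

    def test_newick_round_trip(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        vals = np.array([
            [0, 2, 6, 10],
            [2, 0, 6, 10],
            [6, 6, 0, 10],
            [10, 10, 10, 0.0],
        ])
        dend = upgma(DissimilarityMatrix(labels=list("ABCD"), values=vals))
        tree = Phylo.read(StringIO(dend.to_newick()), "newick")
        depths = tree.depths()
        leaf_depth = {cl.name: d for cl, d in depths.items() if cl.name}
        # ultrametric: every leaf sits at the root height
        assert np.allclose(list(leaf_depth.values()), dend.heights[-1])
        # cophenetic distance between A and D through the tree
        assert tree.distance("A", "D") == pytest.approx(2 * dend.heights[-1])
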