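"""Discretization, mutual information, and the greedy mRMR ranking."""

from __future__ import annotations

import numpy as np
import pytest

from cpgsig.io import BetaMatrix, ClassLabels
from cpgsig.mrmr import (
    DiscretizedMatrix,
    discretize,
    mrmr_rank,
    mutual_information,
    redundancy,
    relevance,
)
from conftest import mi_bruteforce


def _matrix(rows, probes=None, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    probes = probes or tuple(f"cg{i}" for i in range(rows.shape[0]))
    samples = samples or tuple(f"s{j}" for j in range(rows.shape[1]))
    return BetaMatrix(tuple(probes), tuple(samples), rows)


class TestDiscretize:
    def test_constant_site_all_zero(self):
        d = discretize(_matrix([[0.5, 0.5, 0.5, 0.5]]), t=1.0)
        assert (d.states == 0).all()

    def test_mean_sd_thresholds(self):
        # m = 0.5, sample sd (ddof=1) = 0.408248; t=0.5 thresholds ~ (0.296, 0.704)
        site = np.array([0.1, 0.2, 0.8, 0.9])
        assert np.isclose(site.std(ddof=1), 0.408248290463863)
        d = discretize(_matrix([site]), t=0.5)
        np.testing.assert_array_equal(d.states[0], [-1, -1, 1, 1])

    def test_huge_t_yields_all_zero(self):
        d = discretize(_matrix([[0.1, 0.9, 0.4, 0.6]]), t=1000.0)
        assert (d.states == 0).all()

    def test_default_width_splits_tails_only(self):
        site = np.array([0.05, 0.45, 0.5, 0.55, 0.95])
        d = discretize(_matrix([site]), t=1.0)
        np.testing.assert_array_equal(d.states[0], [-1, 0, 0, 0, 1])

    def test_nonpositive_t_rejected(self):
        with pytest.raises(ValueError):
            discretize(_matrix([[0.1, 0.9]]), t=0.0)


class TestMutualInformation:
    def test_perfect_dependence_is_one_bit(self):
        assert mutual_information((1, 1, 2, 2), (1, 1, 2, 2)) == pytest.approx(1.0)

    def test_empirical_independence_is_zero(self):
        assert mutual_information((1, 1, 2, 2), (1, 2, 1, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_partial_dependence_value(self):
        got = mutual_information((1, 1, 1, 2, 2, 2), (1, 1, 2, 2, 2, 2))
        assert got == pytest.approx(0.4591479170272448, abs=1e-12)

    def test_natural_log_base(self):
        bits = mutual_information((1, 1, 2, 2), (1, 1, 2, 2), base=2)
        nats = mutual_information((1, 1, 2, 2), (1, 1, 2, 2), base=np.e)
        assert nats == pytest.approx(bits * np.log(2.0))

    @pytest.mark.parametrize("a,b", [((1, 2), (1,)), ((1,), (1,))])
    def test_bad_inputs_rejected(self, a, b):
        with pytest.raises(ValueError):
            mutual_information(a, b)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 51)
            ka, kb = rng.integers(2, 5, size=2)
            a = rng.integers(0, ka, size=n)
            b = rng.integers(0, kb, size=n)
            assert mutual_information(a, b) == pytest.approx(
                mi_bruteforce(a, b), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 40)
            a = rng.integers(-1, 2, size=n)
            b = rng.integers(-1, 2, size=n)
            assert mutual_information(a, b) == pytest.approx(
                mutual_information(b, a), abs=1e-12
            )


class TestRelevanceRedundancy:
    def test_binary_relabelled_site_is_one_bit(self):
        assert relevance((1, 1, -1, -1), ("A", "A", "B", "B")) == pytest.approx(1.0)

    def test_constant_site_is_zero(self):
        assert relevance((0, 0, 0, 0), ("A", "A", "B", "B")) == pytest.approx(0.0)

    def test_planted_site_beats_null(self, recovery_dataset):
        d = recovery_dataset
        dm = discretize(d.matrix)
        y = d.labels.for_samples(dm.sample_ids)
        idx = {p: i for i, p in enumerate(dm.probe_ids)}
        inf = relevance(dm.states[idx["inf_0"]], y)
        null = relevance(dm.states[idx["null_0"]], y)
        assert inf > null

    def test_empty_selection_is_zero(self):
        assert redundancy((1, 0, -1, 0), []) == 0.0

    def test_self_copy_equals_entropy(self):
        site = (1, 1, -1, -1)
        ent = mutual_information(site, site)  # I(X, X) = H(X)
        assert redundancy(site, [site]) == pytest.approx(ent)

    def test_mean_of_copy_and_independent(self):
        site = (1, 1, -1, -1)
        indep = (1, -1, 1, -1)
        ent = mutual_information(site, site)
        assert redundancy(site, [site, indep]) == pytest.approx(ent / 2)


def _labelled_states(states_rows, labels_seq, probes=None):
    rows = np.asarray(states_rows, dtype=np.int8)
    probes = probes or tuple(f"g{i}" for i in range(rows.shape[0]))
    samples = tuple(f"s{j}" for j in range(rows.shape[1]))
    dmatrix = DiscretizedMatrix(tuple(probes), samples, rows)
    labels = ClassLabels(dict(zip(samples, labels_seq)))
    return dmatrix, labels


class TestMRMRRank:
    def test_single_candidate_scores_its_relevance(self):
        dmatrix, labels = _labelled_states([[1, 1, -1, -1]], "AABB")
        ranking = mrmr_rank(dmatrix, labels, 1)
        assert ranking.entries == (("g0", pytest.approx(1.0)),)

    def test_zero_selection_is_empty(self):
        dmatrix, labels = _labelled_states([[1, 1, -1, -1]], "AABB")
        assert mrmr_rank(dmatrix, labels, 0).entries == ()

    def test_overlong_selection_rejected(self):
        dmatrix, labels = _labelled_states([[1, 1, -1, -1]], "AABB")
        with pytest.raises(ValueError):
            mrmr_rank(dmatrix, labels, 2)

    def test_duplicate_suppressed_behind_independent_site(self):
        # four balanced classes (n=8); A = half indicator (relevance 1 bit),
        # A_copy an exact duplicate, B carries 0.5 bit about the labels while
        # being empirically independent of A.  Step 2 must prefer B (objective
        # 0.5) over the duplicate (objective 1 - 1 = 0).
        labels_seq = ["c0", "c0", "c1", "c1", "c2", "c2", "c3", "c3"]
        A = [0, 0, 0, 0, 1, 1, 1, 1]
        B = [0, 0, 1, 1, 0, 1, 0, 1]
        dmatrix, labels = _labelled_states(
            [A, A, B], labels_seq, probes=("A", "A_copy", "B")
        )
        ranking = mrmr_rank(dmatrix, labels, 3)
        assert ranking.probe_ids == ("A", "B", "A_copy")
        scores = dict(ranking.entries)
        assert scores["A"] == pytest.approx(1.0)
        assert scores["B"] == pytest.approx(0.5)
        # the duplicate's step-2 objective (1 - I(A_copy, A)) is 0, which is
        # why it falls behind B; by the time it is selected at step 3 its
        # recorded score is 1 - mean(I(.,A)=1, I(.,B)=0) = 0.5
        y = labels.for_samples(dmatrix.sample_ids)
        assert mutual_information(A, y) - mutual_information(A, A) == pytest.approx(
            0.0, abs=1e-12
        )
        assert scores["A_copy"] == pytest.approx(0.5, abs=1e-12)

    def test_first_pick_maximizes_relevance(self, recovery_dataset):
        d = recovery_dataset
        dm = discretize(d.matrix)
        y = d.labels.encode(dm.sample_ids)
        rels = [mutual_information(dm.states[i], y) for i in range(dm.states.shape[0])]
        best = max(rels)
        winners = sorted(
            dm.probe_ids[i] for i, r in enumerate(rels) if r == best
        )
        ranking = mrmr_rank(dm, d.labels, 1)
        assert ranking.entries[0] == (winners[0], pytest.approx(best))

    def test_tie_break_is_lexicographic(self):
        # two identical sites tie at every step
        dmatrix, labels = _labelled_states(
            [[1, 1, -1, -1], [1, 1, -1, -1]], "AABB", probes=("zz", "aa")
        )
        ranking = mrmr_rank(dmatrix, labels, 2)
        assert ranking.probe_ids == ("aa", "zz")

    def test_every_step_maximizes_objective_under_rescan(self, mi_oracle):
        # independent oracle: full brute-force MI matrix + explicit per-step
        # re-scan of Eq-style objective over all remaining candidates
        rng = np.random.default_rng(13)
        n_sites, n = 40, 24
        states = rng.integers(-1, 2, size=(n_sites, n)).astype(np.int8)
        labels_seq = [("A", "B", "C")[k % 3] for k in range(n)]
        dmatrix, labels = _labelled_states(states, labels_seq)
        y = labels.for_samples(dmatrix.sample_ids)

        rel = np.array([mi_oracle(states[i], y) for i in range(n_sites)])
        mi_mat = np.zeros((n_sites, n_sites))
        for i in range(n_sites):
            for j in range(i, n_sites):
                mi_mat[i, j] = mi_mat[j, i] = mi_oracle(states[i], states[j])

        ranking = mrmr_rank(dmatrix, labels, n_sites)
        probes = list(dmatrix.probe_ids)
        selected: list[int] = []
        for probe, score in ranking.entries:
            remaining = [i for i in range(n_sites) if i not in selected]
            if selected:
                obj = {
                    i: rel[i] - mi_mat[i, selected].mean() for i in remaining
                }
            else:
                obj = {i: rel[i] for i in remaining}
            best_val = max(obj.values())
            tied = sorted(probes[i] for i, v in obj.items() if np.isclose(v, best_val, atol=1e-12))
            assert probe == tied[0]
            assert score == pytest.approx(best_val, abs=1e-10)
            selected.append(probes.index(probe))
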