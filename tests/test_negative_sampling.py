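import math

import numpy as np
import pytest

from lgfc.io_data import SequenceRecord
from lgfc.negative_sampling import (
    AlignmentScoring,
    NegativeSamplingConfig,
    SimilarityMatrix,
    build_negatives,
    protein_similarity_matrix,
    rank_candidates,
)
from lgfc.synthetic_fixtures import worked_toy


def _prot(pid, seq):
    return SequenceRecord(id=pid, seq=seq, kind="protein")


@pytest.fixture
def toy_sim():
    """Hand-built similarity matrix: p2 similar to p1, p3 dissimilar."""
    ids = ["p1", "p2", "p3"]
    scores = np.array(
        [
            [10.0, 8.0, 1.0],
            [8.0, 10.0, 1.5],
            [1.0, 1.5, 10.0],
        ]
    )
    return SimilarityMatrix(ids=ids, scores=scores)


class TestSimilarityMatrix:
    def test_identical_sequences_score_equals_self_alignment(self):
        prots = [_prot("a", "MKV"), _prot("b", "MKV")]
        sim = protein_similarity_matrix(prots)
        assert sim.score("a", "b") == sim.score("a", "a") == 3.0

    def test_symmetry(self):
        prots = [_prot("a", "MKVLAT"), _prot("b", "MKV"), _prot("c", "WYHRK")]
        sim = protein_similarity_matrix(prots)
        np.testing.assert_array_equal(sim.scores, sim.scores.T)

    def test_diagonal_is_row_maximum(self):
        prots = [_prot("a", "MKVLAT"), _prot("b", "MKVWYH"), _prot("c", "AAAA")]
        sim = protein_similarity_matrix(prots)
        for i in range(3):
            assert sim.scores[i, i] == sim.scores[i].max()

    def test_mkv_self_score_under_unit_match(self):
        sim = protein_similarity_matrix([_prot("a", "MKV"), _prot("b", "MKV")])
        assert sim.score("a", "a") == 3.0

    def test_blosum_scoring_differs(self):
        prots = [_prot("a", "MKVLAT"), _prot("b", "MKILAT")]
        simple = protein_similarity_matrix(prots)
        blosum = protein_similarity_matrix(
            prots, AlignmentScoring(matrix="BLOSUM62", open_gap=10, extend_gap=0.5)
        )
        assert simple.score("a", "b") != blosum.score("a", "b")

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            protein_similarity_matrix([_prot("a", "MKV")])

    def test_tsv_round_trip(self, tmp_path, toy_sim):
        path = tmp_path / "sim.tsv"
        toy_sim.to_tsv(path)
        back = SimilarityMatrix.from_tsv(path)
        assert back.ids == toy_sim.ids
        np.testing.assert_allclose(back.scores, toy_sim.scores)


class TestRankCandidates:
    def test_dissimilar_candidate_ranks_first(self, toy_sim):
        order = rank_candidates("l1", [("l1", "p1")], toy_sim)
        assert order == ["p3", "p2"]

    def test_ties_break_by_id(self):
        ids = ["pa", "pb", "pc"]
        sim = SimilarityMatrix(ids=ids, scores=np.full((3, 3), 5.0))
        assert rank_candidates("l1", [("l1", "pc")], sim) == ["pa", "pb"]

    def test_partners_excluded(self, toy_sim):
        order = rank_candidates("l1", [("l1", "p1"), ("l1", "p2")], toy_sim)
        assert set(order) == {"p3"}

    def test_no_partner_errors(self, toy_sim):
        with pytest.raises(ValueError, match="no known positive partner"):
            rank_candidates("l9", [("l1", "p1")], toy_sim)


def _toy_setup():
    toy = worked_toy()
    prots = [r for r in toy.registry.values() if r.kind == "protein"]
    positives = [(l, p) for l, p, _ in toy.positives]
    sim = protein_similarity_matrix(sorted(prots, key=lambda r: r.id))
    return toy, positives, sim


class TestBuildNegatives:
    def test_counts_and_disjointness(self):
        _, positives, sim = _toy_setup()
        negatives = build_negatives(positives, sim, NegativeSamplingConfig(seed=7))
        assert len(negatives) == len(positives) == 6
        assert not set(negatives) & set(positives)
        assert len(set(negatives)) == len(negatives)

    def test_deterministic_for_seed(self):
        _, positives, sim = _toy_setup()
        cfg = NegativeSamplingConfig(seed=42)
        assert build_negatives(positives, sim, cfg) == build_negatives(positives, sim, cfg)

    def test_different_seeds_differ(self):
        _, positives, sim = _toy_setup()
        draws = {
            tuple(build_negatives(positives, sim, NegativeSamplingConfig(seed=s)))
            for s in range(20)
        }
        assert len(draws) > 1

    def test_low_fraction_membership_ten_candidates(self):
        """With 10 candidates, half-1 draws come only from the 2 lowest-ranked
        and half-2 draws from the remaining 8, over 100 seeded draws."""
        ids = ["partner"] + [f"p{i:02d}" for i in range(10)]
        rng0 = np.random.default_rng(99)
        scores = rng0.uniform(1, 9, size=(11, 11))
        scores = (scores + scores.T) / 2
        np.fill_diagonal(scores, 10.0)
        sim = SimilarityMatrix(ids=ids, scores=scores)
        positives = [("lA", "partner"), ("lB", "partner")]
        for seed in range(100):
            cfg = NegativeSamplingConfig(low_fraction=0.20, seed=seed)
            half_rng = np.random.default_rng(seed)
            lncs = sorted({l for l, _ in positives})
            perm = half_rng.permutation(len(lncs))
            half1 = {lncs[i] for i in perm[: math.ceil(len(lncs) / 2)]}
            for lnc, prot in build_negatives(positives, sim, cfg, strict=True):
                ranking = rank_candidates(lnc, positives, sim)
                n_low = math.ceil(0.20 * len(ranking))
                assert n_low == 2
                if lnc in half1:
                    assert prot in ranking[:n_low]
                else:
                    assert prot in ranking[n_low:]

    def test_extensions_only_when_pool_structurally_too_small(self):
        """On the toy, draws leave the designated pool only when that lncRNA
        demands more distinct proteins than the pool holds."""
        _, positives, sim = _toy_setup()
        demand = {}
        for lnc, _ in positives:
            demand[lnc] = demand.get(lnc, 0) + 1
        for seed in range(100):
            cfg = NegativeSamplingConfig(low_fraction=0.20, seed=seed)
            half_rng = np.random.default_rng(seed)
            lncs = sorted({l for l, _ in positives})
            perm = half_rng.permutation(len(lncs))
            half1 = {lncs[i] for i in perm[: math.ceil(len(lncs) / 2)]}
            negatives = build_negatives(positives, sim, cfg)
            out_of_pool = {lnc: 0 for lnc in lncs}
            pool_size = {}
            for lnc in lncs:
                ranking = rank_candidates(lnc, positives, sim)
                n_low = math.ceil(0.20 * len(ranking))
                pool = ranking[:n_low] if lnc in half1 else ranking[n_low:]
                pool_size[lnc] = len(pool)
                for l2, prot in negatives:
                    if l2 == lnc and prot not in pool:
                        out_of_pool[lnc] += 1
            for lnc in lncs:
                assert out_of_pool[lnc] == max(0, demand[lnc] - pool_size[lnc])

    def test_empty_positives_rejected(self):
        _, _, sim = _toy_setup()
        with pytest.raises(ValueError):
            build_negatives([], sim)

    def test_pool_exhaustion_errors(self):
        # single candidate protein in the low pool; three positives for one lncRNA
        ids = [f"p{i}" for i in range(5)]
        sim = SimilarityMatrix(ids=ids, scores=np.eye(5) * 10)
        positives = [("l1", "p0"), ("l1", "p1"), ("l1", "p2"), ("l1", "p3")]
        # ranking has 1 candidate; low pool size 1; half-1 lnc needs 4 draws
        with pytest.raises(RuntimeError, match="exhausted"):
            build_negatives(positives, sim, NegativeSamplingConfig(seed=0))

    def test_low_fraction_validation(self):
        with pytest.raises(ValueError):
            NegativeSamplingConfig(low_fraction=0.0)
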