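import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from lgfc.evaluation import (
    ConfusionCounts,
    confusion,
    evaluate_scores,
    metrics,
    rank_feature_combinations,
    roc_pr,
)
from lgfc.io_data import InteractionDataset, SequenceRecord


class TestConfusion:
    def test_basic(self):
        c = confusion([1, 0], [0.9, 0.1])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_all_scores_one(self):
        c = confusion([1, 1, 0, 0], [1.0, 1.0, 1.0, 1.0])
        assert c.fp == 2  # every negative predicted positive

    def test_zero_threshold_predicts_all_positive(self):
        c = confusion([1, 0, 0], [0.1, 0.2, 0.0], threshold=0.0)
        assert c.tn == 0 and c.fn == 0 and c.tp + c.fp == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5])

    def test_nonbinary_labels(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [0.5, 0.5])


class TestMetrics:
    def test_perfect_classifier(self):
        r = metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert r.acc == 1.0 and r.mcc == 1.0 and r.f1 == 1.0

    def test_acc_hand_computed(self):
        r = metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert r.acc == pytest.approx(17 / 20)

    def test_mcc_hand_computed(self):
        r = metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert r.mcc == pytest.approx(70 / math.sqrt(9900))
        assert r.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_sn_sp_ppv_hand_computed(self):
        r = metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert r.sn == pytest.approx(9 / 11)
        assert r.sp == pytest.approx(8 / 9)
        assert r.ppv == pytest.approx(9 / 10)
        assert r.f1 == pytest.approx(18 / 21)

    def test_mcc_zero_denominator_convention(self):
        r = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert r.mcc == 0.0 and "mcc-zero-denominator" in r.flags

    def test_single_class_flagged(self):
        r = metrics(ConfusionCounts(tp=3, fp=0, tn=0, fn=1))
        assert "single-class" in r.flags

    @given(k=st.integers(1, 50))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        base = ConfusionCounts(tp=9, fp=1, tn=8, fn=2)
        scaled = ConfusionCounts(tp=9 * k, fp=1 * k, tn=8 * k, fn=2 * k)
        rb, rs = metrics(base), metrics(scaled)
        for attr in ("acc", "mcc", "f1", "sn", "sp", "ppv"):
            assert getattr(rb, attr) == pytest.approx(getattr(rs, attr))

    @given(tp=st.integers(1, 40), fp=st.integers(1, 40),
           tn=st.integers(1, 40), fn=st.integers(1, 40))
    @settings(max_examples=50, deadline=None)
    def test_f1_is_harmonic_mean_of_ppv_and_sn(self, tp, fp, tn, fn):
        r = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        harmonic = 2 * r.ppv * r.sn / (r.ppv + r.sn)
        assert r.f1 == pytest.approx(harmonic)

    @given(tp=st.integers(0, 20), fp=st.integers(0, 20),
           tn=st.integers(0, 20), fn=st.integers(0, 20))
    @settings(max_examples=60, deadline=None)
    def test_ranges(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        r = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        for attr in ("acc", "f1", "sn", "sp", "ppv"):
            assert 0.0 <= getattr(r, attr) <= 1.0
        assert -1.0 <= r.mcc <= 1.0


class TestRocPr:
    def test_perfect_separation(self):
        auroc, auprc, _ = roc_pr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auroc == 1.0 and auprc == 1.0

    def test_score_negation_symmetry(self, rng):
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        a1, _, _ = roc_pr(labels, scores)
        a2, _, _ = roc_pr(labels, -scores)
        assert a1 + a2 == pytest.approx(1.0)

    def test_permuted_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=10000)
        scores = rng.random(10000)
        auroc, _, _ = roc_pr(labels, scores)
        assert auroc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr([1, 1], [0.3, 0.4])

    @given(n=st.integers(4, 200), seed=st.integers(0, 500))
    @settings(max_examples=60, deadline=None)
    def test_auroc_equals_mann_whitney_u(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.normal(size=n) + labels  # informative with ties unlikely
        auroc, _, _ = roc_pr(labels, scores)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auroc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-9)

    def test_curves_returned(self):
        _, _, curves = roc_pr([0, 1, 0, 1], [0.2, 0.7, 0.4, 0.9])
        assert {"fpr", "tpr", "precision", "recall"} <= set(curves)


class TestEvaluateScores:
    def test_combines_threshold_and_curve_metrics(self):
        r = evaluate_scores([0, 0, 1, 1], [0.1, 0.4, 0.6, 0.9])
        assert r.acc == 1.0 and r.auroc == 1.0

    def test_single_class_graceful(self):
        r = evaluate_scores([1, 1], [0.9, 0.8])
        assert r.auroc is None and "curves-undefined" in r.flags


def _rf_dataset(n_pairs=60, seed=0):
    """Labels follow lncRNA GC-richness -> only GC-sensitive encoders help."""
    rng = np.random.default_rng(seed)
    registry, pairs = {}, []
    for i in range(n_pairs):
        gc_rich = i % 2 == 0
        probs = [0.15, 0.35, 0.35, 0.15] if gc_rich else [0.35, 0.15, 0.15, 0.35]
        rna = "".join(rng.choice(list("ACGU"), size=60, p=probs))
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        registry[f"r{i}"] = SequenceRecord(id=f"r{i}", seq=rna, kind="rna")
        registry[f"p{i}"] = SequenceRecord(id=f"p{i}", seq=prot, kind="protein")
        pairs.append((f"r{i}", f"p{i}", int(gc_rich)))
    return InteractionDataset(pairs=pairs, registry=registry)


class TestRankFeatureCombinations:
    def test_single_encoder_gives_1x1_matrix(self):
        ds = _rf_dataset()
        rk = rank_feature_combinations(
            ds,
            {"gc": lambda s: np.array([s.count("G") + s.count("C")])},
            {"len": lambda s: np.array([float(len(s))])},
            rf_params={"n_estimators": 30},
            cv=3,
        )
        assert rk.matrix.shape == (1, 1)
        assert 0.0 <= rk.matrix.iloc[0, 0] <= 1.0

    def test_matrix_shape(self):
        ds = _rf_dataset()
        rk = rank_feature_combinations(
            ds,
            {"gc": lambda s: np.array([s.count("G") + s.count("C")]),
             "len": lambda s: np.array([float(len(s))])},
            {"len": lambda s: np.array([float(len(s))]),
             "a": lambda s: np.array([s.count("A")]),
             "w": lambda s: np.array([s.count("W")])},
            rf_params={"n_estimators": 30},
            cv=3,
        )
        assert rk.matrix.shape == (2, 3)

    def test_failing_encoder_marks_cells_missing(self):
        def broken(_):
            raise RuntimeError("boom")

        ds = _rf_dataset()
        rk = rank_feature_combinations(
            ds,
            {"gc": lambda s: np.array([s.count("G") + s.count("C")]), "bad": broken},
            {"len": lambda s: np.array([float(len(s))])},
            rf_params={"n_estimators": 30},
            cv=3,
        )
        assert np.isnan(rk.matrix.loc["bad", "len"])
        assert np.isfinite(rk.matrix.loc["gc", "len"])

    def test_signal_encoder_tops_its_side(self):
        ds = _rf_dataset(n_pairs=80, seed=3)
        rng = np.random.default_rng(5)
        rk = rank_feature_combinations(
            ds,
            {"gc": lambda s: np.array([(s.count("G") + s.count("C")) / len(s)]),
             "noise": lambda s: rng.normal(size=2)},
            {"len": lambda s: np.array([float(len(s))])},
            rf_params={"n_estimators": 60},
            cv=3,
            seed=1,
        )
        assert rk.top("lnc", 1) == ["gc"]
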