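"""Similarity-ranked construction of the reliable negative pair set D-.

Rationale: an lncRNA is likely to interact with proteins similar to its
known partners, and unlikely to interact with dissimilar ones.  Candidate
proteins are therefore ranked per lncRNA by their best global-alignment
similarity to any known partner, lncRNAs are split into two halves, and
negatives are drawn from the bottom ``low_fraction`` of the ranking for
half 1 and from the remaining candidates for half 2, one negative per
positive pair, giving |D-| = |D+| exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from lgfc.io_data import SequenceRecord


@dataclass(frozen=True)
class AlignmentScoring:
    """Global pairwise alignment parameters.

    The default (match 1, mismatch 0, no gap penalties) is the simplest
    global-similarity dialect; ``matrix='BLOSUM62'`` with affine gaps is the
    conventional protein alternative.
    """

    match: float = 1.0
    mismatch: float = 0.0
    open_gap: float = 0.0
    extend_gap: float = 0.0
    matrix: str | None = None  # e.g. "BLOSUM62"

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        if self.matrix:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -abs(self.open_gap)
        aligner.extend_gap_score = -abs(self.extend_gap)
        return aligner


@dataclass
class SimilarityMatrix:
    """All-vs-all symmetric protein similarity scores."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.scores.shape != (n, n):
            raise ValueError("scores shape must match ids")
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.ids, columns=self.ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.index), scores=df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class NegativeSamplingConfig:
    low_fraction: float = 0.20
    seed: int = 0
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def __post_init__(self) -> None:
        if not 0 < self.low_fraction < 1:
            raise ValueError("low_fraction must lie in (0, 1)")


def protein_similarity_matrix(
    proteins: Sequence[SequenceRecord], scoring: AlignmentScoring | None = None
) -> SimilarityMatrix:
    """Global-alignment score between every protein pair (symmetric)."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    for rec in proteins:
        if not rec.seq:
            raise ValueError(f"empty sequence for {rec.id}")
    scoring = scoring or AlignmentScoring()
    aligner = scoring.make_aligner()
    ids = [rec.id for rec in proteins]
    n = len(proteins)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = float(aligner.score(proteins[i].seq, proteins[j].seq))
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(ids=ids, scores=scores)


def _partners_of(positives: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    partners: dict[str, set[str]] = {}
    for lnc, prot in positives:
        partners.setdefault(lnc, set()).add(prot)
    return partners


def rank_candidates(
    lnc_id: str,
    positives: Iterable[tuple[str, str]],
    sim: SimilarityMatrix,
) -> list[str]:
    """Non-partner proteins ordered by ascending similarity to the lncRNA.

    The lncRNA-candidate score is max similarity of the candidate to any
    known partner of the lncRNA; ties break lexicographically by id.
    """
    partners = _partners_of(positives).get(lnc_id)
    if not partners:
        raise ValueError(f"lncRNA {lnc_id!r} has no known positive partner")
    candidates = [pid for pid in sim.ids if pid not in partners]
    keyed = [
        (max(sim.score(pid, partner) for partner in partners), pid) for pid in candidates
    ]
    keyed.sort()
    return [pid for _, pid in keyed]


def build_negatives(
    positives: Sequence[tuple[str, str]],
    sim: SimilarityMatrix,
    config: NegativeSamplingConfig | None = None,
    strict: bool = False,
) -> list[tuple[str, str]]:
    """Draw exactly one negative per positive pair (so |D-| = |D+|).

    lncRNAs are split into two seeded random halves (first half larger for
    odd counts).  Positives whose lncRNA falls in half 1 draw uniformly from
    the bottom ``ceil(low_fraction * n_candidates)`` of that lncRNA's
    ranking; half 2 draws from the remaining candidates.  Draws are redrawn
    on collision so negatives are unique and disjoint from the positives.

    At realistic scale the designated pools are always large enough.  On
    tiny datasets an lncRNA with several positives can exhaust its pool; by
    default the pool is then extended with the nearest unused candidates
    from the rest of the ranking (half 1 extends upward, half 2 downward),
    so the half constraint holds whenever it is structurally satisfiable.
    ``strict=True`` errors instead of extending.  An error is always raised
    when every candidate of an lncRNA is used up.
    """
    if not positives:
        raise ValueError("positive set is empty")
    config = config or NegativeSamplingConfig()
    rng = np.random.default_rng(config.seed)

    pos_set = set(positives)
    lncs = sorted({lnc for lnc, _ in positives})
    perm = rng.permutation(len(lncs))
    half1 = {lncs[i] for i in perm[: math.ceil(len(lncs) / 2)]}

    rankings = {lnc: rank_candidates(lnc, positives, sim) for lnc in lncs}
    negatives: list[tuple[str, str]] = []
    used: set[tuple[str, str]] = set()

    for lnc, _prot in positives:
        ranking = rankings[lnc]
        n_low = math.ceil(config.low_fraction * len(ranking))
        if lnc in half1:
            pool, overflow = ranking[:n_low], ranking[n_low:]
        else:
            pool, overflow = ranking[n_low:], ranking[:n_low][::-1]
        available = sorted(p for p in pool if (lnc, p) not in used)
        if not available:
            fallback = [p for p in overflow if (lnc, p) not in used]
            if strict or not fallback:
                raise RuntimeError(
                    f"candidate pool exhausted for lncRNA {lnc!r}; "
                    "provide a larger protein set or lower low_fraction"
                )
            available = fallback[:1]  # nearest-ranked unused candidate
        choice = available[int(rng.integers(len(available)))]
        negatives.append((lnc, choice))
        used.add((lnc, choice))

    assert not used & pos_set and len(negatives) == len(positives)
    return negatives
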