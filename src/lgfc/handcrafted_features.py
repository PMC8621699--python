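"""Handcrafted composition feature encoders and the A1/A2 assembly.

Selected encoders (fixed order):

* lncRNA:  ``red`` (coding-potential descriptors), ``dnc`` (16), ``3mer`` (64)
  -> A1;
* protein: ``aac`` (20), ``3mer`` over the 7-group alphabet (343), ``4mer``
  (2401) -> A2.

Unselected encoders can be added through :func:`register_encoder`; the
ranking harness in :mod:`lgfc.evaluation` runs over any registered set.

Denominator convention: the k-mer frequencies divide by the *sequence
length* ``N`` (not ``N - k + 1``), and the dinucleotide composition divides
by ``N - 1``, so a clean sequence's k-mer vector sums to ``(N - k + 1) / N``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from lgfc.sequence_encoding import GROUP_ROWS, reduce_alphabet

RNA_BASES = "ACGU"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

DINUCS = ["".join(p) for p in itertools.product(RNA_BASES, repeat=2)]
TRINUCS = ["".join(p) for p in itertools.product(RNA_BASES, repeat=3)]


def _kmer_index(alphabet: str, k: int) -> dict[str, int]:
    return {"".join(p): i for i, p in enumerate(itertools.product(alphabet, repeat=k))}


def dnc(rna_seq: str) -> np.ndarray:
    """Dinucleotide composition: count(rs) / (N - 1), lexicographic AA..UU (16)."""
    n = len(rna_seq)
    if n < 2:
        raise ValueError("dnc requires length >= 2")
    idx = _kmer_index(RNA_BASES, 2)
    out = np.zeros(16)
    for i in range(n - 1):
        pair = rna_seq[i : i + 2]
        j = idx.get(pair)
        if j is not None:  # dinucleotides containing N are skipped
            out[j] += 1
    return out / (n - 1)


def rna_kmer(rna_seq: str, k: int = 3) -> np.ndarray:
    """RNA k-mer frequencies count/N in lexicographic ACGU order (4^k)."""
    n = len(rna_seq)
    if n < k:
        raise ValueError(f"rna_kmer requires length >= {k}")
    idx = _kmer_index(RNA_BASES, k)
    out = np.zeros(4**k)
    for i in range(n - k + 1):
        j = idx.get(rna_seq[i : i + k])
        if j is not None:
            out[j] += 1
    return out / n


def aac(protein_seq: str) -> np.ndarray:
    """Amino-acid composition as percentages 100*count/N (20 residues).

    ``X`` is excluded from the numerators but counts toward ``N``, so vectors
    of X-containing sequences sum to less than 100.
    """
    n = len(protein_seq)
    if n == 0:
        raise ValueError("aac requires a non-empty sequence")
    out = np.zeros(20)
    pos = {a: i for i, a in enumerate(AA20)}
    for c in protein_seq:
        j = pos.get(c)
        if j is not None:
            out[j] += 1
    return out * (100.0 / n)


def protein_kmer(protein_seq: str, k: int = 3) -> np.ndarray:
    """k-mer frequencies over the reduced 7-group alphabet, count/N (7^k).

    The sequence is group-reduced first, so permuting residues within one
    group leaves the vector unchanged.
    """
    if k not in (3, 4):
        raise ValueError("protein_kmer supports k in {3, 4}")
    n = len(protein_seq)
    if n < k:
        raise ValueError(f"protein_kmer requires length >= {k}")
    reduced = reduce_alphabet(protein_seq)
    idx = _kmer_index(GROUP_ROWS, k)
    out = np.zeros(7**k)
    for i in range(n - k + 1):
        j = idx.get(reduced[i : i + k])
        if j is not None:  # windows containing the pad symbol are skipped
            out[j] += 1
    return out / n


# --------------------------------------------------------------------------
# coding-potential descriptor block (RED)
# --------------------------------------------------------------------------

# Fickett TESTCODE lookup tables (Fickett 1982), as used by downstream
# coding-potential tools; DNA alphabet, U handled via U->T.
_FICKETT_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_FICKETT_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]
_FICKETT_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.63, 0.48, 0.29],
    "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24],
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.24, 0.30, 0.23],
    "G": [0.21, 0.40, 0.47, 0.50, 0.52, 0.60, 0.61, 0.50, 0.43],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.17],
}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _fickett_lookup(value: float, paras: list[float], probs: list[float]) -> float:
    for cutoff, prob in zip(paras, probs):
        if value >= cutoff:
            return prob
    return probs[-1]


def fickett_score(rna_seq: str) -> float:
    """Fickett TESTCODE statistic from positional base bias and composition."""
    seq = rna_seq.replace("U", "T")
    n = len(seq)
    if n < 2:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [sum(1 for i in range(frame, n, 3) if seq[i] == base) for frame in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        content = seq.count(base) / n
        score += (
            _fickett_lookup(position, _FICKETT_POSITION_PARA, _FICKETT_POSITION_PROB[base])
            * _FICKETT_POSITION_WEIGHT[base]
        )
        score += (
            _fickett_lookup(content, _FICKETT_CONTENT_PARA, _FICKETT_CONTENT_PROB[base])
            * _FICKETT_CONTENT_WEIGHT[base]
        )
    return score


_STOPS = {"UAA", "UAG", "UGA"}


def find_longest_orf(rna_seq: str, *, require_stop: bool = False) -> tuple[int, int, bool]:
    """Longest AUG-initiated ORF over the three forward frames.

    Returns ``(start, length_nt, has_stop)``; length includes the stop codon
    when present.  Without an in-frame stop the ORF runs to the last complete
    codon (skipped entirely if ``require_stop``).  Ties keep the earliest
    start.  Returns ``(-1, 0, False)`` when no ORF exists.
    """
    best = (-1, 0, False)
    n = len(rna_seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if rna_seq[i : i + 3] == "AUG":
                j = i + 3
                has_stop = False
                while j + 3 <= n:
                    if rna_seq[j : j + 3] in _STOPS:
                        j += 3
                        has_stop = True
                        break
                    j += 3
                length = j - i
                if has_stop or not require_stop:
                    if length > best[1]:
                        best = (i, length, has_stop)
                # restart scan after this start codon (nested AUGs give
                # shorter ORFs in the same frame; skip to after the ORF)
                i = j if has_stop else n
            else:
                i += 3
    return best


def nucleotide_ctd(rna_seq: str) -> np.ndarray:
    """Composition/transition/distribution descriptors over {A,C,G,U} (30).

    * composition: frequency of each base (4);
    * transition: frequency of each unordered pair of distinct adjacent
      bases among clean adjacent positions (6);
    * distribution: for each base, the relative position (percent of length)
      of its 1st, 25%, 50%, 75% and last occurrence (20; zeros if absent).
    """
    n = len(rna_seq)
    if n == 0:
        raise ValueError("empty sequence")
    comp = np.array([rna_seq.count(b) for b in RNA_BASES], dtype=float) / n

    pairs = ["AC", "AG", "AU", "CG", "CU", "GU"]
    pair_idx = {p: i for i, p in enumerate(pairs)}
    trans = np.zeros(6)
    n_adj = 0
    for i in range(n - 1):
        a, b = rna_seq[i], rna_seq[i + 1]
        if a in RNA_BASES and b in RNA_BASES:
            n_adj += 1
            if a != b:
                key = "".join(sorted((a, b)))
                trans[pair_idx[key]] += 1
    if n_adj:
        trans /= n_adj

    dist = np.zeros(20)
    for bi, base in enumerate(RNA_BASES):
        positions = [i + 1 for i, c in enumerate(rna_seq) if c == base]
        if not positions:
            continue
        m = len(positions)
        for qi, q in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
            rank = max(1, math.ceil(q * m))
            dist[bi * 5 + qi] = positions[rank - 1] / n * 100.0
    return np.concatenate([comp, trans, dist])


#: names of the scalar slots in the RED vector, in order, before the CTD block
RED_SCALAR_NAMES = (
    "orf_length",
    "orf_coverage",
    "orf_integrity",
    "fickett",
    "hexamer",
    "isoelectric_point",
    "gravy",
    "instability",
)
RED_DIM = len(RED_SCALAR_NAMES) + 30


def red_features(
    rna_seq: str,
    hexamer_table: Mapping[str, float] | None = None,
    *,
    require_stop: bool = False,
) -> np.ndarray:
    """Coding-potential descriptor vector (38 = 8 scalars + 30 CTD).

    Order: ORF length (nt), ORF coverage, ORF integrity (+1 iff the longest
    ORF has both AUG and stop, else -1), Fickett score, hexamer score (0 and
    flagged when no table is supplied), then isoelectric point, GRAVY and
    instability index of the translated longest ORF, then nucleotide CTD.

    With no ORF the ORF slots are (0, 0, -1) and the peptide slots 0.
    """
    n = len(rna_seq)
    if n < 3:
        raise ValueError("red_features requires length >= 3")
    start, orf_len, has_stop = find_longest_orf(rna_seq, require_stop=require_stop)

    if orf_len == 0:
        orf_block = [0.0, 0.0, -1.0]
        pep_block = [0.0, 0.0, 0.0]
    else:
        orf_block = [float(orf_len), orf_len / n, 1.0 if has_stop else -1.0]
        coding = rna_seq[start : start + orf_len]
        if has_stop:
            coding = coding[:-3]
        peptide = str(Seq(coding.replace("N", "A")).translate()) if coding else ""
        peptide = peptide.replace("*", "")
        if peptide:
            pa = ProteinAnalysis(peptide)
            pep_block = [pa.isoelectric_point(), pa.gravy(), pa.instability_index()]
        else:
            pep_block = [0.0, 0.0, 0.0]

    if hexamer_table is None:
        hexamer = 0.0
    else:
        scores = [
            hexamer_table[rna_seq[i : i + 6]]
            for i in range(n - 5)
            if rna_seq[i : i + 6] in hexamer_table
        ]
        hexamer = float(np.mean(scores)) if scores else 0.0

    scalars = np.array(orf_block + [fickett_score(rna_seq), hexamer] + pep_block)
    return np.concatenate([scalars, nucleotide_ctd(rna_seq)])


# --------------------------------------------------------------------------
# encoder registry and A1/A2 assembly
# --------------------------------------------------------------------------

EncoderFn = Callable[[str], np.ndarray]

_LNC_ENCODERS: dict[str, EncoderFn] = {}
_PROT_ENCODERS: dict[str, EncoderFn] = {}


def register_encoder(name: str, fn: EncoderFn, side: str = "lnc") -> None:
    """Register an additional sequence encoder (``side`` is 'lnc' or 'prot').

    Registered encoders participate in the random-forest feature-combination
    ranking; re-registering a name overwrites it with a warning.
    """
    table = _LNC_ENCODERS if side == "lnc" else _PROT_ENCODERS
    if name in table:
        warnings.warn(f"encoder {name!r} re-registered")
    table[name] = fn


def registered_encoders(side: str = "lnc") -> dict[str, EncoderFn]:
    return dict(_LNC_ENCODERS if side == "lnc" else _PROT_ENCODERS)


register_encoder("red", lambda s: red_features(s), "lnc")
register_encoder("dnc", dnc, "lnc")
register_encoder("3mer", lambda s: rna_kmer(s, 3), "lnc")
register_encoder("aac", aac, "prot")
register_encoder("3mer", lambda s: protein_kmer(s, 3), "prot")
register_encoder("4mer", lambda s: protein_kmer(s, 4), "prot")

A1_COMPONENTS = ("red", "dnc", "3mer")
A2_COMPONENTS = ("aac", "3mer", "4mer")


@dataclass
class HandcraftedVector:
    """A1/A2 concatenations with named component slices."""

    a1: np.ndarray
    a2: np.ndarray
    a1_slices: dict[str, slice] = field(default_factory=dict)
    a2_slices: dict[str, slice] = field(default_factory=dict)

    def component(self, vector: str, name: str) -> np.ndarray:
        slices = self.a1_slices if vector == "a1" else self.a2_slices
        arr = self.a1 if vector == "a1" else self.a2
        return arr[slices[name]]


def _concat(parts: list[tuple[str, np.ndarray]]) -> tuple[np.ndarray, dict[str, slice]]:
    slices, arrays, off = {}, [], 0
    for name, arr in parts:
        slices[name] = slice(off, off + arr.size)
        arrays.append(arr)
        off += arr.size
    return np.concatenate(arrays), slices


def assemble_handcrafted(
    rna_seq: str,
    protein_seq: str,
    hexamer_table: Mapping[str, float] | None = None,
) -> HandcraftedVector:
    """Compute A1 = [red, dnc, 3mer] and A2 = [aac, 3mer, 4mer] for a pair."""
    a1, s1 = _concat(
        [
            ("red", red_features(rna_seq, hexamer_table)),
            ("dnc", dnc(rna_seq)),
            ("3mer", rna_kmer(rna_seq, 3)),
        ]
    )
    a2, s2 = _concat(
        [
            ("aac", aac(protein_seq)),
            ("3mer", protein_kmer(protein_seq, 3)),
            ("4mer", protein_kmer(protein_seq, 4)),
        ]
    )
    return HandcraftedVector(a1=a1, a2=a2, a1_slices=s1, a2_slices=s2)


def read_hexamer_table(path) -> dict[str, float]:
    """Read a hexamer log-ratio table: TSV ``hexamer<TAB>log_ratio``."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            hexamer, value = line.split("\t")
            table[hexamer.upper().replace("T", "U")] = float(value)
    return table
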