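"""Sequence/pair-table IO, dataset filters and assembly.

File dialects:

* sequences: plain FASTA,
* pair tables: TSV with header ``lnc_id<TAB>prot_id<TAB>label``.

Normalization policy (applied on load, documented here once):

* RNA: uppercased, ``T`` mapped to ``U``; any symbol outside ``{A,C,G,U,N}``
  mapped to ``N`` (or rejected with ``strict=True``).
* protein: uppercased; the ambiguous/rare residues ``B,Z,U,O`` mapped to
  ``X`` (or rejected with ``strict=True``); any other non-standard symbol is
  always an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGUN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
_PROTEIN_REMAP = {"B": "X", "Z": "X", "U": "X", "O": "X"}

Kind = Literal["rna", "protein"]


class ParseError(ValueError):
    """Raised for malformed FASTA/pair-table input."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a validated, normalized sequence."""

    id: str
    seq: str
    kind: Kind

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("empty sequence id")
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        alphabet = RNA_ALPHABET if self.kind == "rna" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ParseError(
                f"record {self.id!r}: invalid {self.kind} symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str, kind: Kind, *, strict: bool = False) -> str:
    """Apply the module-level normalization policy to a raw sequence string."""
    seq = raw.upper().replace(" ", "").replace("*", "")
    if kind == "rna":
        seq = seq.replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            if strict:
                raise ParseError(f"invalid RNA symbols {sorted(bad)}")
            seq = "".join(c if c in RNA_ALPHABET else "N" for c in seq)
    else:
        remapped = "".join(_PROTEIN_REMAP.get(c, c) for c in seq)
        if strict and remapped != seq:
            raise ParseError("non-standard protein residues (B/Z/U/O) present")
        seq = remapped
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise ParseError(f"invalid protein symbols {sorted(bad)}")
    return seq


def read_fasta(path: str | Path, kind: Kind, *, strict: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving order.

    Parameters
    ----------
    path:
        FASTA file path.
    kind:
        ``"rna"`` or ``"protein"``; selects the normalization policy.
    strict:
        Reject (rather than remap) non-standard symbols.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        try:
            seq = normalize_sequence(str(rec.seq), kind, strict=strict)
        except ParseError as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=seq, kind=kind))
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (fixed line width); inverse of :func:`read_fasta`."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def filter_lncrnas(records: Sequence[SequenceRecord], min_len: int = 200) -> list[SequenceRecord]:
    """Drop RNA records shorter than ``min_len`` nucleotides (default 200 nt)."""
    kept = [r for r in records if len(r) >= min_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_lncrnas: removed %d/%d records below %d nt", removed, len(records), min_len)
    return kept


Pair = tuple[str, str, int]


@dataclass
class InteractionDataset:
    """Positive and negative (lncRNA, protein) pairs plus a sequence registry."""

    pairs: list[Pair]
    registry: dict[str, SequenceRecord]
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        for lnc, prot, label in self.pairs:
            if label not in (0, 1):
                raise ValueError(f"label must be 0/1, got {label!r}")
            key = (lnc, prot)
            if key in seen and seen[key] != label:
                raise ValueError(f"pair {key} appears with contradictory labels")
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen[key] = label
        missing = sorted(
            {i for lnc, prot, _ in self.pairs for i in (lnc, prot) if i not in self.registry}
        )
        if missing:
            raise ValueError(f"pair ids missing from registry: {missing}")

    @property
    def positives(self) -> list[Pair]:
        return [p for p in self.pairs if p[2] == 1]

    @property
    def negatives(self) -> list[Pair]:
        return [p for p in self.pairs if p[2] == 0]

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, _, label in self.pairs], dtype=np.int64)

    def lnc_ids(self) -> list[str]:
        return sorted({lnc for lnc, _, _ in self.pairs})

    def prot_ids(self) -> list[str]:
        return sorted({prot for _, prot, _ in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)


def assemble_dataset(
    pos_pairs: Iterable[tuple[str, str]],
    neg_pairs: Iterable[tuple[str, str]],
    registry: Mapping[str, SequenceRecord],
    name: str = "dataset",
) -> InteractionDataset:
    """Merge positive and negative pair lists into a validated dataset.

    Duplicates within one list are dropped with a warning; a pair occurring in
    both lists is a contradiction and raises.
    """
    pos_list = [(l, p) for l, p in pos_pairs]
    neg_list = [(l, p) for l, p in neg_pairs]
    pos = list(dict.fromkeys(pos_list))
    neg = list(dict.fromkeys(neg_list))
    if len(pos_list) != len(pos):
        warnings.warn(f"{len(pos_list) - len(pos)} duplicate positive pairs removed")
    if len(neg_list) != len(neg):
        warnings.warn(f"{len(neg_list) - len(neg)} duplicate negative pairs removed")
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"pairs labelled both positive and negative: {sorted(overlap)[:5]}")
    pairs: list[Pair] = [(l, p, 1) for l, p in pos] + [(l, p, 0) for l, p in neg]
    return InteractionDataset(pairs=pairs, registry=dict(registry), name=name)


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    quotas = [total * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    # round-half-up ordering on remainders, index as tie-break
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[: total - sum(counts)]:
        counts[i] += 1
    return counts


def split_dataset(
    ds: InteractionDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[InteractionDataset, InteractionDataset, InteractionDataset]:
    """Label-stratified train/valid/test partition, deterministic for a seed."""
    if any(f < 0 or f > 1 for f in fractions) or not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must lie in [0,1] and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    split_totals = _largest_remainder(len(ds), fractions)

    by_label: dict[int, list[Pair]] = {0: [], 1: []}
    for pair in ds.pairs:
        by_label[pair[2]].append(pair)
    labels_present = [lb for lb in (1, 0) if by_label[lb]]

    buckets: list[list[Pair]] = [[], [], []]
    taken = {lb: 0 for lb in labels_present}
    shuffled = {}
    for lb in labels_present:
        idx = rng.permutation(len(by_label[lb]))
        shuffled[lb] = [by_label[lb][i] for i in idx]

    for s in range(3):
        want = split_totals[s]
        if s == 2:
            per_class = [len(shuffled[lb]) - taken[lb] for lb in labels_present]
        else:
            sizes = [len(shuffled[lb]) for lb in labels_present]
            total = sum(sizes)
            per_class = _largest_remainder(want, [sz / total for sz in sizes])
            # never allocate more than what is left in a class
            for i, lb in enumerate(labels_present):
                avail = len(shuffled[lb]) - taken[lb]
                if per_class[i] > avail:
                    per_class[i] = avail
        for i, lb in enumerate(labels_present):
            start = taken[lb]
            buckets[s].extend(shuffled[lb][start : start + per_class[i]])
            taken[lb] += per_class[i]

    out = []
    for s, suffix in enumerate(("train", "valid", "test")):
        out.append(
            InteractionDataset(pairs=buckets[s], registry=ds.registry, name=f"{ds.name}-{suffix}")
        )
    return tuple(out)  # type: ignore[return-value]


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a pair-table TSV (``lnc_id``, ``prot_id``, optional ``label``)."""
    df = pd.read_csv(path, sep="\t", dtype={"lnc_id": str, "prot_id": str})
    required = {"lnc_id", "prot_id"}
    if not required <= set(df.columns):
        raise ParseError(f"pair table must have columns {sorted(required)}, got {list(df.columns)}")
    return df


def write_pairs(pairs: Iterable[Pair], path: str | Path) -> None:
    """Write (lnc_id, prot_id, label) rows as the TSV dialect read_pairs accepts."""
    df = pd.DataFrame(pairs, columns=["lnc_id", "prot_id", "label"])
    df.to_csv(path, sep="\t", index=False)
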