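"""Fixed-length one-hot encodings for the global and local CNN branches.

Two preprocessing views of a variable-length sequence:

* *global*: crop/pad to a fixed length ``L`` and one-hot encode, giving an
  ``alphabet x L`` matrix (4 rows for RNA, 7 reduced-group rows for protein);
* *local*: slice into overlapping windows of size ``w = ceil(L / W)`` taken
  at stride ``w - S``, one-hot encode each window and stack exactly ``C``
  channels (crop extra windows, append all-``N`` windows when short).

Unknown/padding symbols encode as uniform columns (``1/4`` resp. ``1/7``) so
every encoding column is a probability vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

RNA_ROWS = "ACGU"
RNA_INDEX = {c: i for i, c in enumerate(RNA_ROWS)}

#: conjoint-triad reduction of the 20 amino acids to 7 groups
#: (dipole moment / side-chain volume classes)
PROTEIN_GROUPS = {
    "1": "AGV",
    "2": "ILFP",
    "3": "YMTS",
    "4": "HNQW",
    "5": "RK",
    "6": "DE",
    "7": "C",
}
GROUP_OF = {aa: g for g, members in PROTEIN_GROUPS.items() for aa in members}
GROUP_ROWS = "1234567"
GROUP_INDEX = {c: i for i, c in enumerate(GROUP_ROWS)}

CropMode = Literal["head", "center", "tail"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from floor (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EncodingConfig:
    """Geometry of the global and local sequence encodings.

    ``w = ceil(L / W)`` is the window size; windows are taken at stride
    ``w - S`` so ``S`` symbols overlap between consecutive windows.  ``C``
    channel caps default to the number of windows produced by a sequence of
    exactly length ``L`` (so the global and local views stay consistent).
    """

    L_lnc: int
    L_pro: int
    W: int = 10
    S_lnc: int | None = None  # default: floor(w/2)
    S_pro: int | None = None
    C_lnc: int | None = None
    C_pro: int | None = None
    crop: CropMode = "head"

    def __post_init__(self) -> None:
        if self.L_lnc < 1 or self.L_pro < 1 or self.W < 1:
            raise ValueError("L_lnc, L_pro and W must be positive")

    def window(self, kind: str) -> tuple[int, int, int]:
        """Return (window size w, overlap S, channel cap C) for a molecule kind."""
        L = self.L_lnc if kind == "rna" else self.L_pro
        w = math.ceil(L / self.W)
        S = self.S_lnc if kind == "rna" else self.S_pro
        if S is None:
            S = w // 2
        if S >= w:
            raise ValueError(f"overlap S={S} must be smaller than window size w={w}")
        C = self.C_lnc if kind == "rna" else self.C_pro
        if C is None:
            C = len(_window_offsets(L, w, w - S))
        if C < 1:
            raise ValueError("channel cap C must be >= 1")
        return w, S, C

    def resolved(self) -> "EncodingConfig":
        """Copy with every derived default (S, C) made explicit."""
        w_l, s_l, c_l = self.window("rna")
        w_p, s_p, c_p = self.window("protein")
        return replace(self, S_lnc=s_l, S_pro=s_p, C_lnc=c_l, C_pro=c_p)


def compute_fixed_lengths(dataset) -> tuple[int, int]:
    """Mean length of the unique RNA and protein sequences, round-half-up.

    These means are the fixed lengths ``L_lnc`` / ``L_pro`` the global view
    crops or pads every sequence to.
    """
    rna_lens = [len(r) for r in dataset.registry.values() if r.kind == "rna"]
    pro_lens = [len(r) for r in dataset.registry.values() if r.kind == "protein"]
    if not rna_lens or not pro_lens:
        raise ValueError("dataset registry must contain both RNA and protein sequences")
    return round_half_up(float(np.mean(rna_lens))), round_half_up(float(np.mean(pro_lens)))


def pad_symbol(kind: str) -> str:
    return "N" if kind == "rna" else "X"


def global_preprocess(seq: str, L: int, *, pad: str = "N", crop: CropMode = "head") -> str:
    """Crop/pad ``seq`` to exactly ``L`` symbols.

    Shorter sequences are right-padded with ``pad``; longer ones keep the
    leading ``L`` symbols by default (``crop`` selects head/center/tail).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    n = len(seq)
    if n == L:
        return seq
    if n < L:
        return seq + pad * (L - n)
    if crop == "head":
        return seq[:L]
    if crop == "tail":
        return seq[n - L :]
    start = (n - L) // 2
    return seq[start : start + L]


def _window_offsets(n: int, w: int, stride: int) -> list[int]:
    """Window start offsets: full windows at 0, stride, ...; plus one padded
    partial window if symbols remain uncovered."""
    if n <= 0:
        return []
    offsets = list(range(0, max(n - w, 0) + 1, stride))
    last_end = offsets[-1] + w if offsets else 0
    if last_end < n:
        offsets.append(offsets[-1] + stride if offsets else 0)
    return offsets


def local_preprocess(seq: str, config: EncodingConfig, kind: str = "rna") -> list[str]:
    """Slice ``seq`` into exactly ``C`` window sequences of length ``w``.

    Windows start at 0 and advance by ``w - S``; a trailing partial window is
    right-padded.  The list is cropped to the first ``C`` windows or extended
    with all-padding windows.
    """
    w, S, C = config.window(kind)
    stride = w - S
    pad = pad_symbol(kind)
    windows = []
    for off in _window_offsets(len(seq), w, stride):
        chunk = seq[off : off + w]
        windows.append(chunk + pad * (w - len(chunk)))
    windows = windows[:C]
    windows.extend([pad * w] * (C - len(windows)))
    return windows


def onehot_rna(seq: str) -> np.ndarray:
    """One-hot encode an RNA sequence as a 4 x len column-stochastic matrix.

    ``A/C/G/U`` give unit columns; ``N`` (and padding) gives the uniform
    column ``[1/4, 1/4, 1/4, 1/4]``.
    """
    mat = np.zeros((4, len(seq)), dtype=np.float32)
    for j, c in enumerate(seq):
        if c == "N":
            mat[:, j] = 0.25
        else:
            try:
                mat[RNA_INDEX[c], j] = 1.0
            except KeyError:
                raise ValueError(f"invalid RNA symbol {c!r} at position {j}") from None
    return mat


def reduce_alphabet(protein_seq: str) -> str:
    """Map a protein sequence to the 7-group alphabet ``1..7``; ``X`` -> ``N``."""
    out = []
    for c in protein_seq:
        if c == "X":
            out.append("N")
        else:
            try:
                out.append(GROUP_OF[c])
            except KeyError:
                raise ValueError(f"invalid protein residue {c!r}") from None
    return "".join(out)


def onehot_protein(seq: str) -> np.ndarray:
    """One-hot encode a protein (or pre-reduced) sequence as 7 x len.

    Accepts either the 20-letter alphabet (reduced internally) or group
    symbols ``1..7``; ``X``/``N`` columns are uniform ``1/7``.
    """
    reduced = "".join(
        c if c in GROUP_INDEX or c == "N" else ("N" if c == "X" else GROUP_OF.get(c, "?"))
        for c in seq
    )
    if "?" in reduced:
        j = reduced.index("?")
        raise ValueError(f"invalid protein symbol {seq[j]!r} at position {j}")
    mat = np.zeros((7, len(reduced)), dtype=np.float32)
    for j, c in enumerate(reduced):
        if c == "N":
            mat[:, j] = 1.0 / 7.0
        else:
            mat[GROUP_INDEX[c], j] = 1.0
    return mat


def encode_global(seq: str, kind: str, L: int, crop: CropMode = "head") -> np.ndarray:
    """Global view: crop/pad then one-hot -> ``alphabet x L`` matrix."""
    fixed = global_preprocess(seq, L, pad=pad_symbol(kind), crop=crop)
    return onehot_rna(fixed) if kind == "rna" else onehot_protein(fixed)


def encode_local(seq: str, kind: str, config: EncodingConfig) -> np.ndarray:
    """Local view: windows -> ``C x alphabet x w`` one-hot tensor."""
    windows = local_preprocess(seq, config, kind)
    enc = onehot_rna if kind == "rna" else onehot_protein
    return np.stack([enc(w) for w in windows])
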