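"""Structure tracks and their cosine-series reduction to B1/B2.

An RNA contributes three per-position tracks (secondary-structure 0/1,
hydrogen-bond propensity, van der Waals propensity) and a protein five
(Chou-Fasman, Grantham, Zimmerman, Kyte-Doolittle, Bull-Breese).  Each
variable-length track is reduced to its first 10 cosine-series terms

    X'_k = (2/L) * sum_{n=0}^{L-1} X_n * cos[(pi/L) * (n + 1/2) * (k + 1/2)]

(a DCT-IV up to scaling), giving the fixed-size vectors B1 (3*10 = 30) and
B2 (5*10 = 50).

Folding engines: the default ``nussinov`` engine maximizes Watson-Crick +
GU wobble base pairs (hairpin loops >= ``min_loop``) with a deterministic
traceback; a thermodynamic MFE engine (ViennaRNA) is used when requested
and importable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

try:  # optional JIT; a vectorized numpy fallback keeps results identical
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class PropensityScale:
    """A named per-symbol numeric scale (4 nucleotides or 20 residues)."""

    name: str
    table: dict[str, float]
    source: str = ""

    def lookup(self, symbol: str) -> float:
        """Value for ``symbol``; padding/unknown (N/X) is neutral 0.0."""
        if symbol in ("N", "X"):
            return 0.0
        try:
            return self.table[symbol]
        except KeyError:
            raise KeyError(f"scale {self.name!r} has no value for symbol {symbol!r}") from None


def read_scale(path: str | Path, name: str | None = None) -> PropensityScale:
    """Read a ``symbol<TAB>value`` TSV with an optional ``#source:`` header."""
    path = Path(path)
    source = ""
    table: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#source:"):
            source = line[len("#source:") :].strip()
            continue
        if line.startswith("#"):
            continue
        symbol, value = line.split("\t")
        table[symbol] = float(value)
    return PropensityScale(name=name or path.stem, table=table, source=source)


_SCALE_FILES = {
    "chou_fasman_helix": "chou_fasman_helix.tsv",
    "chou_fasman_sheet": "chou_fasman_sheet.tsv",
    "chou_fasman_turn": "chou_fasman_turn.tsv",
    "grantham": "grantham_polarity.tsv",
    "zimmerman": "zimmerman_polarity.tsv",
    "kyte_doolittle": "kyte_doolittle.tsv",
    "bull_breese": "bull_breese.tsv",
    "rna_hbond": "rna_hbond.tsv",
    "rna_vdw": "rna_vdw.tsv",
}


def builtin_scale(name: str) -> PropensityScale:
    """Load one of the bundled scales by short name (see ``_SCALE_FILES``)."""
    fname = _SCALE_FILES[name]
    with resources.as_file(resources.files("lgfc.data").joinpath(fname)) as p:
        return read_scale(p, name=name)


def default_scales(chou_fasman: str = "helix") -> dict[str, PropensityScale]:
    """The scale set used by :func:`assemble_structure`."""
    return {
        "rna_hbond": builtin_scale("rna_hbond"),
        "rna_vdw": builtin_scale("rna_vdw"),
        "chou_fasman": builtin_scale(f"chou_fasman_{chou_fasman}"),
        "grantham": builtin_scale("grantham"),
        "zimmerman": builtin_scale("zimmerman"),
        "kyte_doolittle": builtin_scale("kyte_doolittle"),
        "bull_breese": builtin_scale("bull_breese"),
    }


# --------------------------------------------------------------------------
# RNA secondary structure
# --------------------------------------------------------------------------

_PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
# pair matrix for coded bases; N (4) pairs with nothing
_PAIR_MATRIX = np.zeros((5, 5), dtype=np.uint8)
for _a, _b in _PAIRABLE:
    _PAIR_MATRIX[_BASE_CODE[_a], _BASE_CODE[_b]] = 1


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def _nussinov_dp_python(codes: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if _PAIR_MATRIX[codes[i], codes[j]] and dp[i + 1, j - 1] + 1 > best:
                best = dp[i + 1, j - 1] + 1
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


def _nussinov_kernel(codes, min_loop, pair_matrix):  # pragma: no cover - jitted
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if pair_matrix[codes[i], codes[j]] and dp[i + 1, j - 1] + 1 > best:
                best = dp[i + 1, j - 1] + 1
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


if _HAVE_NUMBA:
    _nussinov_dp_jit = njit(cache=True)(_nussinov_kernel)


@dataclass(frozen=True)
class DotBracket:
    """Vienna dot-bracket string aligned to its RNA sequence."""

    structure: str

    def __post_init__(self) -> None:
        depth = 0
        for c in self.structure:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif c != ".":
                raise ValueError(f"invalid dot-bracket symbol {c!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")

    def __len__(self) -> int:
        return len(self.structure)

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


def _traceback(codes: np.ndarray, dp: np.ndarray, min_loop: int) -> list[str]:
    """Deterministic traceback: prefer pairing position i, leftmost partner."""
    n = codes.shape[0]
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop or dp[i, j] == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if not _PAIR_MATRIX[codes[i], codes[k]]:
                continue
            inner = dp[i + 1, k - 1] if k - 1 > i + 1 else 0
            right = dp[k + 1, j] if k + 1 <= j else 0
            if inner + right + 1 == dp[i, j]:
                struct[i] = "("
                struct[k] = ")"
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return struct


def nussinov_pair_count(rna_seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (WC + GU, hairpin >= min_loop)."""
    codes = np.array([_BASE_CODE[c] for c in rna_seq], dtype=np.int8)
    if codes.size == 0:
        return 0
    dp = _fill_dp(codes, min_loop)
    return int(dp[0, -1])


def _fill_dp(codes: np.ndarray, min_loop: int) -> np.ndarray:
    if _HAVE_NUMBA:
        return _nussinov_dp_jit(codes, min_loop, _PAIR_MATRIX)
    return _nussinov_dp_python(codes, min_loop)


def fold_rna(rna_seq: str, engine: str = "nussinov", min_loop: int = 3) -> DotBracket:
    """Predict a nested secondary structure for ``rna_seq``.

    ``engine='nussinov'`` (default, built-in) maximizes base pairs;
    ``engine='vienna'`` delegates to ViennaRNA's MFE fold when importable.
    """
    if engine == "vienna":
        try:
            import RNA  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "ViennaRNA python bindings not installed; use engine='nussinov'"
            ) from exc
        structure, _ = RNA.fold(rna_seq)
        return DotBracket(structure)
    if engine != "nussinov":
        raise ValueError(f"unknown folding engine {engine!r}; use 'nussinov' or 'vienna'")
    if not rna_seq:
        raise ValueError("cannot fold an empty sequence")
    codes = np.array([_BASE_CODE[c] for c in rna_seq], dtype=np.int8)
    if codes.size <= min_loop + 1:
        return DotBracket("." * len(rna_seq))
    dp = _fill_dp(codes, min_loop)
    return DotBracket("".join(_traceback(codes, dp, min_loop)))


def encode_rna_ss(db: DotBracket) -> np.ndarray:
    """Binary track: brackets (paired) -> 1, dots (unpaired) -> 0."""
    return np.array([0.0 if c == "." else 1.0 for c in db.structure])


def propensity_track(seq: str, scale: PropensityScale) -> np.ndarray:
    """Per-symbol scale lookup; N/X contribute the neutral value 0.0."""
    return np.array([scale.lookup(c) for c in seq])


# --------------------------------------------------------------------------
# cosine-series reduction
# --------------------------------------------------------------------------


def fourier_first_k(x: np.ndarray, k: int = 10) -> np.ndarray:
    """First ``k`` cosine-series terms of a track (DCT-IV style, scaled 2/L).

    The summation runs over the L existing samples n = 0..L-1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-D vector")
    L = x.size
    n = np.arange(L)
    ks = np.arange(k)
    basis = np.cos((np.pi / L) * np.outer(n + 0.5, ks + 0.5))  # (L, k)
    return (2.0 / L) * (x @ basis)


B1_TRACKS = ("ss", "hbond", "vdw")
B2_TRACKS = ("chou_fasman", "grantham", "zimmerman", "kyte_doolittle", "bull_breese")


@dataclass
class StructureVector:
    """Fourier-reduced structure features: b1 (30, RNA) and b2 (50, protein)."""

    b1: np.ndarray
    b2: np.ndarray
    n_terms: int = 10

    def b1_track(self, name: str) -> np.ndarray:
        i = B1_TRACKS.index(name)
        return self.b1[i * self.n_terms : (i + 1) * self.n_terms]

    def b2_track(self, name: str) -> np.ndarray:
        i = B2_TRACKS.index(name)
        return self.b2[i * self.n_terms : (i + 1) * self.n_terms]


def rna_structure_tracks(
    rna_seq: str,
    scales: dict[str, PropensityScale] | None = None,
    engine: str = "nussinov",
    min_loop: int = 3,
) -> dict[str, np.ndarray]:
    """The three per-position RNA tracks: ss (0/1), hbond, vdw."""
    scales = scales or default_scales()
    db = fold_rna(rna_seq, engine=engine, min_loop=min_loop)
    return {
        "ss": encode_rna_ss(db),
        "hbond": propensity_track(rna_seq, scales["rna_hbond"]),
        "vdw": propensity_track(rna_seq, scales["rna_vdw"]),
    }


def protein_structure_tracks(
    protein_seq: str, scales: dict[str, PropensityScale] | None = None
) -> dict[str, np.ndarray]:
    """The five per-position protein tracks."""
    scales = scales or default_scales()
    return {name: propensity_track(protein_seq, scales[name]) for name in B2_TRACKS}


def assemble_structure(
    rna_seq: str,
    protein_seq: str,
    scales: dict[str, PropensityScale] | None = None,
    engine: str = "nussinov",
    n_terms: int = 10,
    min_loop: int = 3,
) -> StructureVector:
    """Reduce every track to ``n_terms`` cosine terms and concatenate.

    b1 = [ss, hbond, vdw] (3 * n_terms); b2 = [chou_fasman, grantham,
    zimmerman, kyte_doolittle, bull_breese] (5 * n_terms).
    """
    scales = scales or default_scales()
    rna = rna_structure_tracks(rna_seq, scales, engine=engine, min_loop=min_loop)
    prot = protein_structure_tracks(protein_seq, scales)
    b1 = np.concatenate([fourier_first_k(rna[t], n_terms) for t in B1_TRACKS])
    b2 = np.concatenate([fourier_first_k(prot[t], n_terms) for t in B2_TRACKS])
    return StructureVector(b1=b1, b2=b2, n_terms=n_terms)
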