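"""Merging an ensemble of OCR streams into one consensus transcription.

The streams for one label (up to eight: four image variants × two engines)
are treated like homologous biological sequences: obvious failures are
pruned by Levenshtein distance, the survivors are progressively aligned
with a global affine-gap aligner, and the per-column plurality is read off
as the consensus text.  Instead of a PAM/BLOSUM matrix, scoring uses a
*visual similarity* matrix over characters: +2 for identical glyphs down to
−2 for grossly different shapes (a period vs. a W), with a gap-open
penalty of −3 and a gap-extension penalty of −0.5.

The gap convention is that the first gap symbol of a run costs the open
penalty and each subsequent symbol the extension penalty, so a length-2 gap
costs −3.5.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

try:
    import edlib as _edlib
except ImportError:  # pragma: no cover - edlib ships with the environment
    _edlib = None

from .engines import OCRStream

__all__ = [
    "GAP",
    "SimilarityMatrix",
    "AlignmentParams",
    "AlignedPair",
    "MSAResult",
    "ConsensusText",
    "levenshtein",
    "prune_outliers",
    "pre_substitutions",
    "pairwise_align",
    "build_msa",
    "call_consensus",
    "default_similarity_matrix",
]

#: Reserved gap sentinel; never a legal character of any OCR text.
GAP = "\x00"

_NEG = -1.0e30


def _levenshtein_dp(a: str, b: str) -> int:
    """Plain O(nm) fallback used when edlib cannot handle the alphabet."""
    if len(a) < len(b):
        a, b = b, a
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=prev.dtype)
        cur[0] = i
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution/insertion/deletion = 1)."""
    if a == b:
        return 0
    if _edlib is not None:
        try:
            d = _edlib.align(a, b)["editDistance"]
            if d >= 0:
                return int(d)
        except (ValueError, MemoryError):
            pass
    return _levenshtein_dp(a, b)


# --- similarity matrix ------------------------------------------------------


def _category(c: str) -> str:
    if c.isalpha():
        return "letter"
    if c.isdigit():
        return "digit"
    if c.isspace():
        return "space"
    return "punct"


@dataclass(frozen=True)
class SimilarityMatrix:
    """Character-pair visual-similarity scores in [−2, +2].

    Defined through confusability classes plus class-pair scores; any pair
    the classes do not cover falls back to a category rule.  The shipped
    default (see :func:`default_similarity_matrix`) scores +2 for identical
    characters, +1 for case pairs and within-class lookalikes, 0 for
    otherwise-dissimilar same-kind alphanumerics and punctuation pairs, −1
    for letter vs digit, and −2 across gross shape categories (punctuation
    or whitespace vs anything else).
    """

    classes: dict[str, str] = field(default_factory=dict)  # char -> class id
    class_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    within_class: float = 1.0
    identical: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for (ci, cj), s in self.class_scores.items():
            if not -2.0 <= s <= 2.0:
                raise ValueError(f"score {s} for ({ci},{cj}) outside [-2, 2]")
            rev = self.class_scores.get((cj, ci))
            if rev is not None and rev != s:
                raise ValueError(f"asymmetric scores for ({ci},{cj})")
        if not -2.0 <= self.within_class <= 2.0:
            raise ValueError("within-class score outside [-2, 2]")
        if self.identical != 2.0:
            raise ValueError("identical characters must score +2")
        for c in self.classes:
            if self.score(c, c) != 2.0:  # contract: diagonal is +2
                raise ValueError(f"score({c!r},{c!r}) != 2")

    def score(self, a: str, b: str) -> float:
        if a == b:
            return self.identical
        if a.casefold() == b.casefold():
            return self.within_class
        ca, cb = self.classes.get(a), self.classes.get(b)
        if ca is not None and cb is not None:
            if ca == cb:
                return self.within_class
            s = self.class_scores.get((ca, cb))
            if s is None:
                s = self.class_scores.get((cb, ca))
            if s is not None:
                return s
        ka, kb = _category(a), _category(b)
        if ka == kb:
            return 0.0
        if {ka, kb} == {"letter", "digit"}:
            return -1.0
        return -2.0

    def table_for(self, alphabet: Sequence[str]) -> np.ndarray:
        """Dense score lookup for a concrete alphabet (vectorized DP)."""
        k = len(alphabet)
        t = np.empty((k, k))
        for i, a in enumerate(alphabet):
            for j in range(i, k):
                t[i, j] = t[j, i] = self.score(a, alphabet[j])
        return t

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        """Load a matrix file.

        Two-column lines ``<characters>\\t<class id>`` declare class
        membership; three-column lines ``<class>\\t<class>\\t<score>``
        declare class-pair scores.  ``#`` starts a comment.
        """
        classes: dict[str, str] = {}
        scores: dict[tuple[str, str], float] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                members, cid = parts
                for c in members:
                    if c in classes and classes[c] != cid:
                        raise ValueError(
                            f"character {c!r} assigned to classes "
                            f"{classes[c]!r} and {cid!r}"
                        )
                    classes[c] = cid
            elif len(parts) == 3:
                ci, cj, s_raw = parts
                try:
                    s = float(s_raw)
                except ValueError as exc:
                    raise ValueError(f"bad score {s_raw!r}") from exc
                scores[(ci, cj)] = s
            else:
                raise ValueError(f"malformed matrix line: {raw!r}")
        return cls(classes=classes, class_scores=scores)


def default_similarity_matrix() -> SimilarityMatrix:
    """The shipped lookalike table (a documented default, configurable)."""
    groups = {
        "thin": "l1I|!",
        "round": "O0o",
        "ess": "S5s",
        "zee": "Z2z",
        "bee": "B8",
        "gee": "G6",
        "emen": "mn",
        "ee3": "E3",
        "uvee": "uv",
    }
    classes = {c: cid for cid, members in groups.items() for c in members}
    return SimilarityMatrix(classes=classes)


@dataclass(frozen=True)
class AlignmentParams:
    """Affine gap penalties: open −3, extension −0.5 by default."""

    gap_open: float = -3.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("need gap_open <= gap_extend <= 0")


# --- affine-gap global alignment (Gotoh), vectorized row-wise ---------------


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float
               ) -> tuple[float, list[str]]:
    """Maximize Σ column scores with affine gaps over score matrix ``S``.

    ``S[i, j]`` scores pairing item i of sequence *a* with item j of *b*.
    Returns the optimal score and the operation list (``'M'`` pair,
    ``'X'`` item-of-a vs gap, ``'Y'`` gap vs item-of-b).  Three DP layers:
    M (pair), Ix (gap run in b), Iy (gap run in a); horizontal in-row
    dependencies of Iy are resolved with a running-max prefix trick, which
    is exact because the extension penalty is linear in run length.
    """
    n, m = S.shape
    go, ge = gap_open, gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if m:
        Iy[0, 1:] = go + ge * np.arange(m)
    cols = np.arange(m + 1)
    for i in range(1, n + 1):
        diag = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]),
                          Iy[i - 1, :-1])
        M[i, 1:] = S[i - 1, :] + diag
        M[i, 0] = _NEG
        Ix[i, :] = np.maximum(np.maximum(M[i - 1, :], Iy[i - 1, :]) + go,
                              Ix[i - 1, :] + ge)
        base = np.maximum(M[i, :], Ix[i, :]) + go - ge * (cols + 1)
        run = np.maximum.accumulate(base)
        Iy[i, 1:] = ge * cols[1:] + run[:-1]
        Iy[i, 0] = _NEG

    ops: list[str] = []
    i, j = n, m
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    best = max(finals)
    state = "MXY"[int(np.argmax(finals))]  # argmax prefers M, then X
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            want = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, val in (("M", M[i, j]), ("X", Ix[i, j]), ("Y", Iy[i, j])):
                if abs(val - want) <= tol:
                    state = cand
                    break
        elif state == "X":
            ops.append("X")
            want = Ix[i, j]
            i -= 1
            if abs(M[i, j] + go - want) <= tol:
                state = "M"
            elif abs(Ix[i, j] + ge - want) <= tol:
                state = "X"
            else:
                state = "Y"
        else:
            ops.append("Y")
            want = Iy[i, j]
            j -= 1
            if abs(M[i, j] + go - want) <= tol:
                state = "M"
            elif abs(Iy[i, j] + ge - want) <= tol:
                state = "Y"
            else:
                state = "X"
    ops.reverse()
    return float(best), ops


def _encode(strings: Sequence[str], matrix: SimilarityMatrix
            ) -> tuple[list[str], list[np.ndarray], np.ndarray]:
    """Map strings onto a joint alphabet and build the dense score table."""
    alphabet = sorted({c for s in strings for c in s})
    index = {c: i for i, c in enumerate(alphabet)}
    codes = [np.array([index[c] for c in s], dtype=np.intp) for s in strings]
    table = matrix.table_for(alphabet) if alphabet else np.zeros((0, 0))
    return alphabet, codes, table


@dataclass(frozen=True)
class AlignedPair:
    a: str
    b: str
    score: float


def pairwise_align(
    a: str,
    b: str,
    matrix: Optional[SimilarityMatrix] = None,
    params: AlignmentParams = AlignmentParams(),
) -> AlignedPair:
    """Optimal global alignment of two texts under the visual scoring.

    Ties are broken toward pairing characters over gapping, then toward a
    gap in the second text.  The gap sentinel must not occur in the inputs.
    """
    if GAP in a or GAP in b:
        raise ValueError("input contains the reserved gap sentinel")
    matrix = matrix or default_similarity_matrix()
    _, (ca, cb), table = _encode([a, b], matrix)
    S = table[np.ix_(ca, cb)] if len(a) and len(b) else np.zeros((len(a), len(b)))
    score, ops = _affine_dp(S, params.gap_open, params.gap_extend)
    ga, gb = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
        elif op == "X":
            ga.append(a[i]); gb.append(GAP); i += 1
        else:
            ga.append(GAP); gb.append(b[j]); j += 1
    return AlignedPair("".join(ga), "".join(gb), score)


# --- outlier pruning --------------------------------------------------------


def prune_outliers(
    streams: Sequence[OCRStream],
    cutoff: int = 128,
) -> tuple[list[OCRStream], list[OCRStream]]:
    """Drop complete OCR failures before alignment.

    Finds the globally closest pair of streams (minimum pairwise Levenshtein
    distance) and removes any stream whose distance to *both* anchors
    exceeds ``cutoff``.  With two streams or fewer, nothing is pruned; the
    anchor pair always survives, so at most n−2 streams are removed.
    Returns (survivors, pruned), both in input order.
    """
    if len(streams) <= 2:
        return list(streams), []
    n = len(streams)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(streams[i].text, streams[j].text)
    ai, aj = min(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda p: (d[p[0], p[1]], p),
    )
    survivors, pruned = [], []
    for k, s in enumerate(streams):
        if k in (ai, aj) or min(d[k, ai], d[k, aj]) <= cutoff:
            survivors.append(s)
        else:
            pruned.append(s)
    return survivors, pruned


# --- pre-alignment substitutions -------------------------------------------

#: Ordered default rules: strip space before sentence punctuation, collapse
#: space runs.  Character-substitution pairs can be appended by the caller.
DEFAULT_PRE_RULES: tuple[tuple[str, str], ...] = (
    (r"[ \t]+([.,;:])", r"\1"),
    (r" {2,}", " "),
)


def pre_substitutions(
    text: str,
    rules: Sequence[tuple[str, str]] = DEFAULT_PRE_RULES,
) -> str:
    """Fix systematic engine quirks before alignment (ordered regex rules)."""
    for pattern, repl in rules:
        text = re.sub(pattern, repl, text)
    return text


# --- progressive MSA --------------------------------------------------------


@dataclass
class MSAResult:
    """Gapped rows (one per surviving stream) of equal length."""

    rows: list[str]
    stream_ids: list[str]  # parallel to rows: "engine@variant" identifiers
    seed_index: int  # row of the most central stream (alignment seed)

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("MSA rows must have equal length")


def stream_key(s: OCRStream) -> str:
    return f"{s.engine_id}@{s.variant_id}"


def build_msa(
    streams: Sequence[OCRStream],
    matrix: Optional[SimilarityMatrix] = None,
    params: AlignmentParams = AlignmentParams(),
) -> MSAResult:
    """Progressive (center-star-style) multiple alignment of the streams.

    The seed is the most central stream (minimum summed Levenshtein distance
    to the others); remaining streams merge in ascending distance from the
    seed.  Each merge aligns the new text against the current profile
    (column score = mean visual similarity against the column's non-gap
    symbols); a gap column, once introduced, stays ("once a gap, always a
    gap").  Stripping gaps from any row reproduces its input text exactly.
    """
    if not streams:
        raise ValueError("no streams to align")
    for s in streams:
        if GAP in s.text:
            raise ValueError("stream text contains the reserved gap sentinel")
    matrix = matrix or default_similarity_matrix()
    ids = [stream_key(s) for s in streams]
    if len(streams) == 1:
        return MSAResult([streams[0].text], ids, 0)

    n = len(streams)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(streams[i].text, streams[j].text)
    seed = int(np.argmin(d.sum(axis=1)))
    order = sorted((k for k in range(n) if k != seed), key=lambda k: (d[seed, k], k))

    texts = [s.text for s in streams]
    alphabet = sorted({c for t in texts for c in t})
    index = {c: i for i, c in enumerate(alphabet)}
    table = matrix.table_for(alphabet) if alphabet else np.zeros((0, 0))
    k_alpha = len(alphabet)

    rows: list[list[str]] = [list(texts[seed])]
    row_order = [seed]
    for k in order:
        seq = texts[k]
        ncols = len(rows[0])
        counts = np.zeros((k_alpha, ncols))
        for row in rows:
            for j, c in enumerate(row):
                if c != GAP:
                    counts[index[c], j] += 1
        nongap = counts.sum(axis=0)
        codes = np.array([index[c] for c in seq], dtype=np.intp)
        if len(seq) and ncols:
            S = (table[codes] @ counts) / np.maximum(nongap, 1)
        else:
            S = np.zeros((len(seq), ncols))
        _, ops = _affine_dp(S, params.gap_open, params.gap_extend)
        new_rows: list[list[str]] = [[] for _ in rows]
        new_row: list[str] = []
        si = pj = 0
        for op in ops:
            if op == "M":
                for r, nr in zip(rows, new_rows):
                    nr.append(r[pj])
                new_row.append(seq[si])
                si += 1
                pj += 1
            elif op == "X":  # new column for this stream's extra character
                for nr in new_rows:
                    nr.append(GAP)
                new_row.append(seq[si])
                si += 1
            else:  # profile column the new stream lacks
                for r, nr in zip(rows, new_rows):
                    nr.append(r[pj])
                new_row.append(GAP)
                pj += 1
        rows = new_rows + [new_row]
        row_order.append(k)

    return MSAResult(
        rows=["".join(r) for r in rows],
        stream_ids=[ids[k] for k in row_order],
        seed_index=0,
    )


@dataclass(frozen=True)
class ConsensusText:
    """Consensus transcription with per-character column support."""

    text: str
    #: votes for the emitted char / total rows, one per character; empty
    #: when post-processing has edited the text and broken the column map
    support: tuple[float, ...]
    pruned_stream_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if GAP in self.text:
            raise ValueError("consensus text contains the gap sentinel")
        if self.support and len(self.support) != len(self.text):
            raise ValueError("one support value per consensus character")


def call_consensus(
    msa: MSAResult,
    pruned_stream_ids: Sequence[str] = (),
) -> ConsensusText:
    """Read the per-column plurality off the alignment.

    The gap competes as a candidate; when it wins the column emits nothing.
    Ties go to the seed row's symbol when it is among the leaders, else to
    the lexicographically smallest leader.
    """
    n_rows = len(msa.rows)
    chars: list[str] = []
    support: list[float] = []
    for j in range(msa.column_count):
        col = [row[j] for row in msa.rows]
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        leaders = sorted(c for c, v in counts.items() if v == top)
        seed_char = col[msa.seed_index]
        winner = seed_char if seed_char in leaders else leaders[0]
        if winner == GAP:
            continue
        chars.append(winner)
        support.append(counts[winner] / n_rows)
    return ConsensusText("".join(chars), tuple(support),
                         tuple(pruned_stream_ids))
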