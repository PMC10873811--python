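"""Post-consensus text cleanup: substitutions, word repair, spell check.

After the consensus transcription is read off the alignment, three repair
passes run in order:

1. ordered substitution rules (configurable regex pairs) fix residual
   engine quirks;
2. intra-word space repair joins fragments like ``Herb arium`` when the
   join is a lexicon word and neither fragment is;
3. lexicon spell correction replaces an out-of-lexicon token when it has a
   *unique* lexicon neighbour within the correction radius — zero or
   several candidates mean the token is left alone (abstention over
   hallucination, in keeping with verbatim transcription).

Numeral-only tokens (dates, collector numbers, coordinates) are exempt from
spell correction: label data are dense in numbers no wordlist can vouch
for.  Every change is logged as a positional edit so the output can be
replayed from the input exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .consensus import levenshtein

__all__ = [
    "Lexicon",
    "SubstitutionRule",
    "SubstitutionRules",
    "Edit",
    "CleanupResult",
    "DEFAULT_POST_RULES",
    "load_lexicon",
    "post_cleanup",
    "apply_edits",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class Edit:
    """One positional change: replace text[start:end] (== old) with new."""

    start: int
    end: int
    old: str
    new: str
    stage: str


def apply_edits(text: str, edits: Sequence[Edit]) -> str:
    """Replay a change log against the original text."""
    for e in edits:
        if text[e.start:e.end] != e.old:
            raise ValueError(f"change log does not match text at {e.start}")
        text = text[: e.start] + e.new + text[e.end:]
    return text


@dataclass
class Lexicon:
    """Accepted vocabulary for spell correction.

    Lookups are case-aware first, with a case-folded fallback, so a lexicon
    holding ``Herbarium`` accepts ``Herbarium`` and (via folding)
    ``herbarium``.  ``max_edit`` is the correction radius in edit distance.
    """

    terms: frozenset[str]
    max_edit: int = 1
    _folded: dict[str, str] = field(default_factory=dict, repr=False)
    _by_len: dict[int, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("empty lexicon (disable correction instead)")
        for t in sorted(self.terms):
            self._folded.setdefault(t.casefold(), t)
            self._by_len.setdefault(len(t), []).append(t)

    def __contains__(self, token: str) -> bool:
        return token in self.terms or token.casefold() in self._folded

    def candidates(self, token: str) -> list[str]:
        """Lexicon terms within ``max_edit`` of ``token`` (case-folded)."""
        folded = token.casefold()
        out: set[str] = set()
        for length in range(len(token) - self.max_edit,
                            len(token) + self.max_edit + 1):
            for term in self._by_len.get(length, ()):
                if levenshtein(folded, term.casefold()) <= self.max_edit:
                    out.add(term)
        return sorted(out)


def load_lexicon(paths: Iterable[str | Path], max_edit: int = 1) -> Lexicon:
    """Merge one-term-per-line UTF-8 wordlists into a deduplicated lexicon.

    Mixed-case duplicates are all retained (case-folded lookup finds any of
    them).  An empty merged lexicon is an error, since a lexicon only
    exists to drive correction.
    """
    terms: set[str] = set()
    for p in paths:
        text = Path(p).read_text(encoding="utf-8")
        terms.update(line.strip() for line in text.splitlines() if line.strip())
    if not terms:
        raise ValueError("no terms loaded; refusing an empty lexicon")
    return Lexicon(frozenset(terms), max_edit=max_edit)


@dataclass(frozen=True)
class SubstitutionRule:
    """One ordered rewrite: regex pattern → replacement.

    ``scope='word'`` anchors the pattern to whole tokens; ``'anywhere'``
    applies it as-is.
    """

    pattern: str
    replacement: str
    scope: str = "anywhere"

    def compiled(self) -> re.Pattern:
        pat = self.pattern
        if self.scope == "word":
            pat = rf"\b(?:{pat})\b"
        return re.compile(pat)


@dataclass(frozen=True)
class SubstitutionRules:
    rules: tuple[SubstitutionRule, ...] = ()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstitutionRules":
        """TSV columns: pattern, replacement, optional scope."""
        rules = []
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"malformed rule line: {raw!r}")
            scope = parts[2] if len(parts) == 3 else "anywhere"
            rules.append(SubstitutionRule(parts[0], parts[1], scope))
        return cls(tuple(rules))


#: Starter substitution set for residual OCR artifacts.  Deliberately small
#: and conservative; real deployments grow this from observed corrections.
DEFAULT_POST_RULES = SubstitutionRules((
    SubstitutionRule(r"[ \t]+([.,;:])", r"\1"),
    SubstitutionRule(r" {2,}", " "),
))


@dataclass
class CleanupResult:
    text: str
    changes: list[Edit]


def _sub_stage(text: str, rules: SubstitutionRules, stage: str) -> CleanupResult:
    changes: list[Edit] = []
    for rule in rules.rules:
        rx = rule.compiled()
        while True:
            m = rx.search(text)
            if m is None:
                break
            new = m.expand(rule.replacement)
            if new == m.group(0):
                break  # rule is a fixed point here; avoid infinite loop
            changes.append(Edit(m.start(), m.end(), m.group(0), new, stage))
            text = text[: m.start()] + new + text[m.end():]
    return CleanupResult(text, changes)


def _join_stage(text: str, lex: Lexicon) -> CleanupResult:
    """Join split words: 'Herb arium' → 'Herbarium' when only the join is
    in the lexicon."""
    changes: list[Edit] = []
    while True:
        tokens = list(_TOKEN_RE.finditer(text))
        done = True
        for a, b in zip(tokens, tokens[1:]):
            between = text[a.end(): b.start()]
            if between != " ":
                continue
            ta, tb = a.group(0), b.group(0)
            joined = ta + tb
            if joined in lex and ta not in lex and tb not in lex:
                changes.append(Edit(a.start(), b.end(),
                                    f"{ta} {tb}", joined, "join"))
                text = text[: a.start()] + joined + text[b.end():]
                done = False
                break
        if done:
            return CleanupResult(text, changes)


def _spell_stage(text: str, lex: Lexicon) -> CleanupResult:
    changes: list[Edit] = []
    offset = 0
    for m in list(_TOKEN_RE.finditer(text)):
        tok = m.group(0)
        if tok in lex or not any(c.isalpha() for c in tok):
            continue
        cands = lex.candidates(tok)
        if len(cands) != 1:
            continue  # abstain on zero or ambiguous candidates
        new = cands[0]
        start, end = m.start() + offset, m.end() + offset
        changes.append(Edit(start, end, tok, new, "spell"))
        text = text[:start] + new + text[end:]
        offset += len(new) - len(tok)
    return CleanupResult(text, changes)


def post_cleanup(
    text: str,
    rules: SubstitutionRules = DEFAULT_POST_RULES,
    lexicon: Optional[Lexicon] = None,
) -> CleanupResult:
    """Apply the three repair passes; returns cleaned text plus change log.

    Idempotent: running the result through again yields no further changes.
    Tokens already in the lexicon are never altered.  Replaying the change
    log with :func:`apply_edits` reproduces the output from the input.
    """
    changes: list[Edit] = []
    step = _sub_stage(text, rules, "substitution")
    text, changes = step.text, step.changes
    if lexicon is not None:
        step = _join_stage(text, lexicon)
        text = step.text
        changes += step.changes
        step = _spell_stage(text, lexicon)
        text = step.text
        changes += step.changes
    return CleanupResult(text, changes)
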