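"""Pipeline assembly, the 510-permutation sweep, and gold-standard scoring.

A *permutation* is one pipeline configuration: a nonempty subset of the
eight OCR streams (four pre-processing variants × two engines) plus a
post-processing on/off flag — (2⁸ − 1) × 2 = 510 in total.  Each
permutation's output is scored against a verbatim gold-standard
transcription by character-level Levenshtein distance; the permutation with
the fewest cumulative errors over the whole gold standard wins.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .consensus import (
    AlignmentParams,
    ConsensusText,
    SimilarityMatrix,
    build_msa,
    call_consensus,
    default_similarity_matrix,
    levenshtein,
    pre_substitutions,
    prune_outliers,
    stream_key,
)
from .engines import EngineAdapter, OCRStream, run_engine
from .preproc import LabelImage, PreprocParams, PreprocVariant, apply_variant
from .textclean import DEFAULT_POST_RULES, Lexicon, SubstitutionRules, post_cleanup

__all__ = [
    "ENGINE_IDS",
    "STREAM_KEYS",
    "Permutation",
    "GoldLabel",
    "EvaluationReport",
    "PipelineConfig",
    "enumerate_permutations",
    "compute_streams",
    "run_permutation",
    "evaluate",
    "sweep",
    "read_gold_tsv",
    "write_gold_tsv",
]

ENGINE_IDS = ("easyocr", "tesseract")

#: Canonical stream order, matching the usual report column layout:
#: (variant, engine) for V1..V4 × (EasyOCR, Tesseract).
STREAM_KEYS: tuple[tuple[str, str], ...] = tuple(
    (variant.value, engine)
    for variant in PreprocVariant
    for engine in ENGINE_IDS
)

_STREAM_COLUMNS = {
    ("V1_none", "easyocr"): "EasyOCR",
    ("V1_none", "tesseract"): "Tesseract",
    ("V2_deskew", "easyocr"): "Deskew then EasyOCR",
    ("V2_deskew", "tesseract"): "Deskew then Tesseract",
    ("V3_binarize", "easyocr"): "Binarize then EasyOCR",
    ("V3_binarize", "tesseract"): "Binarize then Tesseract",
    ("V4_denoise", "easyocr"): "Denoise then EasyOCR",
    ("V4_denoise", "tesseract"): "Denoise then Tesseract",
}


@dataclass(frozen=True)
class Permutation:
    """One pipeline configuration: stream subset + post-processing flag."""

    included: frozenset[tuple[str, str]]  # (variant_id, engine_id)
    postprocess: bool

    def __post_init__(self) -> None:
        if not self.included:
            raise ValueError("a permutation needs at least one stream")
        unknown = self.included - set(STREAM_KEYS)
        if unknown:
            raise ValueError(f"unknown streams {sorted(unknown)}")

    @property
    def name(self) -> str:
        bits = "".join("Y" if k in self.included else "N" for k in STREAM_KEYS)
        return f"{bits}+post" if self.postprocess else bits


def enumerate_permutations() -> list[Permutation]:
    """All (2⁸ − 1) × 2 = 510 configurations, in deterministic order."""
    perms = []
    for mask in range(1, 1 << len(STREAM_KEYS)):
        included = frozenset(
            k for i, k in enumerate(STREAM_KEYS) if mask & (1 << i)
        )
        for post in (False, True):
            perms.append(Permutation(included, post))
    return perms


@dataclass
class PipelineConfig:
    """Everything a permutation run needs besides the streams themselves."""

    matrix: SimilarityMatrix = field(default_factory=default_similarity_matrix)
    align: AlignmentParams = field(default_factory=AlignmentParams)
    levenshtein_cutoff: int = 128
    post_rules: SubstitutionRules = DEFAULT_POST_RULES
    lexicon: Optional[Lexicon] = None
    preproc: PreprocParams = field(default_factory=PreprocParams)

    def content_hash(self) -> str:
        """Stable digest of the configuration, embedded in report provenance."""
        payload = {
            "classes": sorted(self.matrix.classes.items()),
            "class_scores": sorted(
                (a, b, s) for (a, b), s in self.matrix.class_scores.items()
            ),
            "gap_open": self.align.gap_open,
            "gap_extend": self.align.gap_extend,
            "cutoff": self.levenshtein_cutoff,
            "post_rules": [
                (r.pattern, r.replacement, r.scope) for r in self.post_rules.rules
            ],
            "lexicon": sorted(self.lexicon.terms) if self.lexicon else None,
            "preproc": vars(self.preproc).copy() if hasattr(self.preproc, "__dict__")
            else str(self.preproc),
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def compute_streams(
    img: LabelImage,
    adapters: Mapping[str, EngineAdapter],
    params: Optional[PreprocParams] = None,
) -> dict[tuple[str, str], OCRStream]:
    """Run every (variant, engine) combination once for one label image.

    Each pre-processed variant is computed once and shared by both engines;
    the returned mapping is keyed like :data:`STREAM_KEYS` and can back any
    number of permutations without recomputation.
    """
    streams: dict[tuple[str, str], OCRStream] = {}
    for variant in PreprocVariant:
        processed = apply_variant(img, variant, params)
        for engine_id, adapter in adapters.items():
            streams[(variant.value, engine_id)] = run_engine(adapter, processed)
    return streams


def run_permutation(
    streams: Mapping[tuple[str, str], OCRStream],
    perm: Permutation,
    cfg: Optional[PipelineConfig] = None,
) -> ConsensusText:
    """Run one permutation over precomputed streams for one label.

    Steps: select streams → pre-alignment substitutions → Levenshtein
    outlier pruning → progressive MSA → consensus → (post-cleanup if the
    permutation asks for it).  A single-stream permutation bypasses pruning
    and alignment: the consensus of one text is itself.
    """
    cfg = cfg or PipelineConfig()
    missing = [k for k in perm.included if k not in streams]
    if missing:
        raise KeyError(
            f"permutation needs streams {sorted(missing)} that were not computed"
        )
    selected = [streams[k] for k in STREAM_KEYS if k in perm.included]
    cleaned = [
        OCRStream(pre_substitutions(s.text), s.engine_id, s.variant_id, s.label_id)
        for s in selected
    ]
    if len(cleaned) == 1:
        result = ConsensusText(
            cleaned[0].text, tuple(1.0 for _ in cleaned[0].text), ()
        )
    else:
        survivors, pruned = prune_outliers(cleaned, cfg.levenshtein_cutoff)
        msa = build_msa(survivors, cfg.matrix, cfg.align)
        result = call_consensus(msa, [stream_key(s) for s in pruned])
    if perm.postprocess:
        out = post_cleanup(result.text, cfg.post_rules, cfg.lexicon)
        support = result.support if not out.changes else ()
        result = ConsensusText(out.text, support, result.pruned_stream_ids)
    return result


@dataclass(frozen=True)
class GoldLabel:
    """A verbatim gold-standard transcription (label errors left intact)."""

    label_id: str
    verbatim_text: str


@dataclass
class EvaluationReport:
    """Per-label and cumulative Levenshtein error for one permutation."""

    permutation: Permutation
    per_label: dict[str, int]
    missing_labels: list[str]
    provenance: dict

    @property
    def cumulative_error(self) -> int:
        return sum(self.per_label.values())


def _normalize(text: str, normalization: str) -> str:
    if normalization == "strip":
        return text.strip()
    if normalization == "none":
        return text
    if normalization == "collapse_ws":
        return " ".join(text.split())
    raise ValueError(f"unknown normalization {normalization!r}")


def evaluate(
    outputs: Mapping[str, str],
    gold: Sequence[GoldLabel],
    permutation: Optional[Permutation] = None,
    normalization: str = "strip",
    provenance: Optional[dict] = None,
) -> EvaluationReport:
    """Score outputs against the gold standard.

    Per-label error is the Levenshtein distance between the (normalized)
    output and the verbatim transcription; the default normalization strips
    leading/trailing whitespace only.  A label without an output counts as
    its full gold length and is flagged.  Duplicate gold ids are an error.
    """
    seen: set[str] = set()
    for g in gold:
        if g.label_id in seen:
            raise ValueError(f"duplicate gold label id {g.label_id!r}")
        seen.add(g.label_id)
    per_label: dict[str, int] = {}
    missing: list[str] = []
    for g in gold:
        truth = _normalize(g.verbatim_text, normalization)
        if g.label_id not in outputs:
            per_label[g.label_id] = len(truth)
            missing.append(g.label_id)
        else:
            per_label[g.label_id] = levenshtein(
                _normalize(outputs[g.label_id], normalization), truth
            )
    prov = {"tool": "herbocr", "version": __version__,
            "normalization": normalization}
    if provenance:
        prov.update(provenance)
    perm = permutation or Permutation(frozenset(STREAM_KEYS), False)
    return EvaluationReport(perm, per_label, missing, prov)


def sweep(
    streams_per_label: Mapping[str, Mapping[tuple[str, str], OCRStream]],
    gold: Sequence[GoldLabel],
    permutations: Optional[Sequence[Permutation]] = None,
    cfg: Optional[PipelineConfig] = None,
    normalization: str = "strip",
) -> pd.DataFrame:
    """Score every permutation against the gold standard; rank ascending.

    Streams are computed once per (variant, engine) and reused across all
    permutations.  The returned frame mirrors the usual summary layout: one
    Y/N column per stream, the post-process flag, and the cumulative error,
    sorted from fewest to most errors; per-label errors sit in the
    ``per_label`` column as dicts.
    """
    cfg = cfg or PipelineConfig()
    perms = list(permutations) if permutations is not None else enumerate_permutations()
    prov = {"config_hash": cfg.content_hash()}
    rows = []
    for perm in perms:
        outputs = {}
        for g in gold:
            streams = streams_per_label.get(g.label_id, {})
            try:
                outputs[g.label_id] = run_permutation(streams, perm, cfg).text
            except KeyError:
                pass  # label lacks a required stream -> scored as missing
        report = evaluate(outputs, gold, perm, normalization, prov)
        row = {
            "Total OCR errors": report.cumulative_error,
            **{
                _STREAM_COLUMNS[k]: "Y" if k in perm.included else "N"
                for k in STREAM_KEYS
            },
            "Post process": "Y" if perm.postprocess else "N",
            "per_label": report.per_label,
            "permutation": perm.name,
        }
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.sort_values(
        ["Total OCR errors", "permutation"], inplace=True, kind="mergesort"
    )
    frame.reset_index(drop=True, inplace=True)
    frame.attrs["provenance"] = {
        "tool": "herbocr", "version": __version__, **prov
    }
    return frame


# --- gold-standard TSV ------------------------------------------------------


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out = []
    it = iter(range(len(text)))
    i = 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def read_gold_tsv(path: str | Path) -> list[GoldLabel]:
    """Read ``label_id<TAB>text`` (header required; tabs/newlines escaped)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t")[:2] != ["label_id", "text"]:
        raise ValueError("gold TSV must start with a 'label_id\\ttext' header")
    gold = []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        label_id, _, text = raw.partition("\t")
        gold.append(GoldLabel(label_id, _unescape(text)))
    return gold


def write_gold_tsv(gold: Sequence[GoldLabel], path: str | Path) -> None:
    lines = ["label_id\ttext"]
    lines += [f"{g.label_id}\t{_escape(g.verbatim_text)}" for g in gold]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
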