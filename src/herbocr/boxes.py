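"""Bounding-box geometry and reconciliation of crowd label annotations.

Volunteers outline every label on an imaged herbarium sheet and classify it
(typewritten / handwritten / both / barcode / other).  Each sheet is seen by
several independent annotators, so per physical label we hold a handful of
slightly different outlines and votes.  This module turns those into a single
reconciled box and type per label, cleans click-style correction annotations,
and scores detector predictions against ground truth with intersection over
union (IoU).

Coordinates are 0-based pixel indices; a box stores an inclusive minimum and
exclusive maximum corner, so ``area = (x_max - x_min) * (y_max - y_min)``.
Boundary points count as inside for click containment.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "LABEL_TYPES",
    "UNRESOLVED",
    "BoundingBox",
    "LabelAnnotation",
    "ReconciledLabel",
    "CorrectionClick",
    "TaggedClick",
    "MatchReport",
    "InvalidGeometryError",
    "iou",
    "reconcile_annotations",
    "clean_correction_clicks",
    "score_predictions",
    "labels_to_json",
    "labels_from_json",
]

#: Closed vocabulary of label classes used throughout the pipeline.
LABEL_TYPES = ("typewritten", "handwritten", "both", "barcode", "other")

#: Sentinel type for annotation sets with no strict majority.
UNRESOLVED = "unresolved"

_CLICK_VERDICTS = ("correct", "incorrect", "missed")


class InvalidGeometryError(ValueError):
    """Raised for degenerate (zero-area or inverted) boxes."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle: inclusive min corner, exclusive max."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if min(self.x_min, self.y_min, self.x_max, self.y_max) < 0:
            raise InvalidGeometryError(f"negative coordinate in {self!r}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidGeometryError(f"degenerate box {self!r}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive point containment."""
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def as_list(self) -> list[float]:
        return [self.x_min, self.y_min, self.x_max, self.y_max]


@dataclass(frozen=True)
class LabelAnnotation:
    """One outline + type vote for one label, from a participant or a model."""

    box: BoundingBox
    label_type: str
    source_id: str = ""
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label_type not in LABEL_TYPES:
            raise ValueError(
                f"label_type {self.label_type!r} not in {LABEL_TYPES}"
            )


@dataclass(frozen=True)
class ReconciledLabel:
    """Consensus of several annotations of the same physical label."""

    box: BoundingBox
    label_type: str  # majority class, or UNRESOLVED
    n_contributing: int
    outliers_removed: int = 0

    @property
    def resolved(self) -> bool:
        return self.label_type != UNRESOLVED

    def __post_init__(self) -> None:
        if self.n_contributing < 1:
            raise ValueError("n_contributing must be >= 1")


@dataclass(frozen=True)
class CorrectionClick:
    """A correct/incorrect/missed click placed on a sheet by a participant."""

    point: tuple[float, float]
    verdict: str
    target_sheet: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in _CLICK_VERDICTS:
            raise ValueError(f"verdict {self.verdict!r} not in {_CLICK_VERDICTS}")


@dataclass(frozen=True)
class TaggedClick:
    """A retained correction click tagged with the label containing it."""

    click: CorrectionClick
    label_index: int  # index into the reconciled-label list passed in


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1].

    Symmetric; 1 for identical boxes, 0 for disjoint ones.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def reconcile_annotations(
    outlines: Sequence[LabelAnnotation],
    outlier_iou_threshold: float = 0.5,
) -> ReconciledLabel:
    """Average several outlines of one label and vote on its type.

    Outliers are removed iteratively: while any outline's mean IoU against
    the other survivors falls below ``outlier_iou_threshold``, the worst
    such outline is dropped and the means recomputed (one gross outlier
    must not drag down the agreement score of an otherwise consistent
    pair).  The surviving boxes are averaged corner-wise and the surviving
    type votes resolved by strict majority (ties and split votes give
    :data:`UNRESOLVED`, for human review).

    Raises ``ValueError`` on empty input or when every outline is an outlier
    of every other (no trustworthy core remains; the caller routes the sheet
    to human review).
    """
    if not outlines:
        raise ValueError("no outlines to reconcile")
    if len(outlines) == 1:
        only = outlines[0]
        return ReconciledLabel(only.box, only.label_type, 1, 0)

    keep = list(outlines)
    while len(keep) >= 2:
        means = []
        for i, a in enumerate(keep):
            others = [iou(a.box, b.box) for j, b in enumerate(keep) if j != i]
            means.append(sum(others) / len(others))
        worst = min(range(len(keep)), key=lambda i: means[i])
        if means[worst] >= outlier_iou_threshold:
            break
        if len(keep) == 2:  # both below threshold: no trustworthy core
            keep = []
            break
        del keep[worst]
    if not keep:
        raise ValueError(
            "all outlines are mutual outliers; route to human review"
        )
    n = len(keep)
    box = BoundingBox(
        sum(a.box.x_min for a in keep) / n,
        sum(a.box.y_min for a in keep) / n,
        sum(a.box.x_max for a in keep) / n,
        sum(a.box.y_max for a in keep) / n,
    )
    votes = Counter(a.label_type for a in keep)
    top, top_n = votes.most_common(1)[0]
    label_type = top if top_n * 2 > n else UNRESOLVED
    return ReconciledLabel(box, label_type, n, len(outlines) - n)


def clean_correction_clicks(
    clicks: Sequence[CorrectionClick],
    labels: Sequence[ReconciledLabel],
) -> list[TaggedClick]:
    """Drop clicks that fall outside every known label box.

    Retained clicks are tagged with the containing label; when boxes are
    nested, the smallest-area containing box wins.  Output order follows the
    input; the result is a subset of the input and the operation is
    idempotent.
    """
    out: list[TaggedClick] = []
    for click in clicks:
        x, y = click.point
        best: Optional[int] = None
        for idx, lab in enumerate(labels):
            if lab.box.contains(x, y):
                if best is None or lab.box.area < labels[best].box.area:
                    best = idx
        if best is not None:
            out.append(TaggedClick(click, best))
    return out


@dataclass
class MatchReport:
    """Greedy prediction-vs-truth matching summary."""

    matches: list[tuple[int, int, float]]  # (pred index, truth index, IoU)
    phantoms: list[int] = field(default_factory=list)  # unmatched pred indices
    misses: list[int] = field(default_factory=list)  # unmatched truth indices

    @property
    def mean_iou(self) -> Optional[float]:
        if not self.matches:
            return None
        return sum(m[2] for m in self.matches) / len(self.matches)


def score_predictions(
    preds: Sequence[LabelAnnotation],
    truths: Sequence[LabelAnnotation],
) -> MatchReport:
    """Score detector predictions against ground-truth annotations.

    Greedy one-to-one matching in descending IoU order (ties broken by
    prediction order, then truth order); only overlapping pairs (IoU > 0)
    can match.  Unmatched predictions are phantom labels, unmatched truths
    are misses.
    """
    pairs = []
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            v = iou(p.box, t.box)
            if v > 0:
                pairs.append((-v, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for neg_v, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j, -neg_v))
    phantoms = [i for i in range(len(preds)) if i not in used_p]
    misses = [j for j in range(len(truths)) if j not in used_t]
    return MatchReport(matches=matches, phantoms=phantoms, misses=misses)


# --- label-record JSON (the web-client contract: type + coordinates) -------


def labels_to_json(
    sheet_id: str,
    labels: Iterable[LabelAnnotation | ReconciledLabel],
    texts: Optional[dict[int, str]] = None,
) -> str:
    """Serialize label records for one sheet.

    Schema: ``{"sheet": id, "labels": [{"type", "bbox", "source"?,
    "confidence"?, "text"?}]}``.  ``texts`` maps label list-index to OCR text
    (attached only to typewritten labels, the ones eligible for OCR).
    """
    records = []
    for idx, lab in enumerate(labels):
        rec: dict = {"type": lab.label_type, "bbox": lab.box.as_list()}
        if isinstance(lab, LabelAnnotation):
            if lab.source_id:
                rec["source"] = lab.source_id
            if lab.confidence is not None:
                rec["confidence"] = lab.confidence
        if texts and idx in texts and lab.label_type == "typewritten":
            rec["text"] = texts[idx]
        records.append(rec)
    return json.dumps({"sheet": sheet_id, "labels": records}, ensure_ascii=False)


def labels_from_json(doc: str) -> tuple[str, list[LabelAnnotation], dict[int, str]]:
    """Inverse of :func:`labels_to_json`; returns (sheet_id, labels, texts)."""
    obj = json.loads(doc)
    labels: list[LabelAnnotation] = []
    texts: dict[int, str] = {}
    for idx, rec in enumerate(obj["labels"]):
        labels.append(
            LabelAnnotation(
                box=BoundingBox(*rec["bbox"]),
                label_type=rec["type"],
                source_id=rec.get("source", ""),
                confidence=rec.get("confidence"),
            )
        )
        if "text" in rec:
            texts[idx] = rec["text"]
    return obj["sheet"], labels, texts
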