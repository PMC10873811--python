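"""Box geometry, annotation reconciliation, click cleaning, IoU scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbocr.boxes import (
    BoundingBox,
    CorrectionClick,
    InvalidGeometryError,
    LabelAnnotation,
    ReconciledLabel,
    clean_correction_clicks,
    iou,
    labels_from_json,
    labels_to_json,
    reconcile_annotations,
    score_predictions,
)
from oracles import monte_carlo_iou


def box(x0, y0, x1, y1):
    return BoundingBox(x0, y0, x1, y1)


def ann(b, t="typewritten", src=""):
    return LabelAnnotation(b, t, src)


boxes_st = st.builds(
    lambda x, y, w, h: BoundingBox(x, y, x + w, y + h),
    st.floats(0, 100), st.floats(0, 100),
    st.floats(1, 100), st.floats(1, 100),
)


class TestIoU:
    def test_identity_disjoint_and_hand_computed_overlap(self):
        a = box(0, 0, 10, 10)
        assert iou(a, a) == 1.0
        assert iou(a, box(50, 50, 60, 60)) == 0.0
        # intersection 5x10 = 50, union 100 + 100 - 50 = 150
        assert iou(a, box(5, 0, 15, 10)) == pytest.approx(50 / 150)

    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidGeometryError):
            BoundingBox(0, 0, 0, 10)
        with pytest.raises(InvalidGeometryError):
            BoundingBox(-1, 0, 5, 5)

    @given(a=boxes_st, b=boxes_st)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == iou(b, a)

    def test_agrees_with_point_sampling_oracle(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 50, 8)
            a = box(vals[0], vals[1], vals[0] + vals[2] + 1, vals[1] + vals[3] + 1)
            b = box(vals[4], vals[5], vals[4] + vals[6] + 1, vals[5] + vals[7] + 1)
            est = monte_carlo_iou(a, b, 200_000, rng)
            assert abs(iou(a, b) - est) < 0.01


class TestReconcile:
    def test_unanimous_outlines(self):
        outlines = [ann(box(0, 0, 10, 10)) for _ in range(3)]
        rec = reconcile_annotations(outlines)
        assert rec.box == box(0, 0, 10, 10)
        assert rec.label_type == "typewritten"
        assert rec.outliers_removed == 0 and rec.n_contributing == 3
        assert rec.resolved

    def test_planted_outlier_removed_then_corner_mean(self):
        outlines = [
            ann(box(0, 0, 10, 10)),
            ann(box(0, 0, 10, 10)),
            ann(box(500, 500, 510, 510)),
        ]
        rec = reconcile_annotations(outlines, outlier_iou_threshold=0.5)
        assert rec.box == box(0, 0, 10, 10)
        assert rec.outliers_removed == 1 and rec.n_contributing == 2

    def test_corner_mean_of_survivors(self):
        outlines = [ann(box(0, 0, 10, 10)), ann(box(2, 2, 12, 12))]
        rec = reconcile_annotations(outlines, outlier_iou_threshold=0.3)
        assert rec.box == box(1, 1, 11, 11)

    def test_two_of_three_majority_type(self):
        outlines = [
            ann(box(0, 0, 10, 10), "typewritten"),
            ann(box(0, 0, 10, 10), "typewritten"),
            ann(box(0, 0, 10, 10), "handwritten"),
        ]
        assert reconcile_annotations(outlines).label_type == "typewritten"

    def test_all_distinct_votes_unresolved(self):
        outlines = [
            ann(box(0, 0, 10, 10), "typewritten"),
            ann(box(0, 0, 10, 10), "handwritten"),
            ann(box(0, 0, 10, 10), "barcode"),
        ]
        rec = reconcile_annotations(outlines)
        assert not rec.resolved and rec.label_type == "unresolved"

    def test_empty_and_mutually_outlying_inputs_error(self):
        with pytest.raises(ValueError):
            reconcile_annotations([])
        far = [ann(box(0, 0, 10, 10)), ann(box(100, 100, 110, 110)),
               ann(box(300, 300, 310, 310))]
        with pytest.raises(ValueError, match="human review"):
            reconcile_annotations(far, outlier_iou_threshold=0.5)

    @given(perm=st.permutations(range(3)))
    def test_permutation_invariant(self, perm):
        outlines = [
            ann(box(0, 0, 10, 10), "typewritten"),
            ann(box(1, 1, 11, 11), "typewritten"),
            ann(box(0, 1, 10, 11), "handwritten"),
        ]
        base = reconcile_annotations(outlines)
        shuffled = reconcile_annotations([outlines[i] for i in perm])
        assert shuffled == base


class TestCorrectionClicks:
    LABELS = [
        ReconciledLabel(box(0, 0, 10, 10), "typewritten", 3),
        ReconciledLabel(box(0, 0, 100, 100), "typewritten", 3),
    ]

    def test_interior_exterior_and_nested_containment(self):
        clicks = [
            CorrectionClick((5, 5), "correct"),
            CorrectionClick((200, 200), "incorrect"),
            CorrectionClick((50, 50), "correct"),
        ]
        kept = clean_correction_clicks(clicks, self.LABELS)
        assert [t.click for t in kept] == [clicks[0], clicks[2]]
        # nested boxes: the smallest-area containing box wins
        assert kept[0].label_index == 0
        assert kept[1].label_index == 1

    def test_boundary_point_counts_as_inside(self):
        clicks = [CorrectionClick((10, 10), "correct")]
        kept = clean_correction_clicks(clicks, self.LABELS[:1])
        assert len(kept) == 1

    def test_subset_and_idempotent(self):
        clicks = [CorrectionClick((float(x), 5.0), "correct") for x in range(0, 30, 7)]
        kept = clean_correction_clicks(clicks, self.LABELS[:1])
        assert set(t.click for t in kept) <= set(clicks)
        again = clean_correction_clicks([t.click for t in kept], self.LABELS[:1])
        assert [t.click for t in again] == [t.click for t in kept]

    def test_empty_inputs(self):
        assert clean_correction_clicks([], self.LABELS) == []
        assert clean_correction_clicks(
            [CorrectionClick((1, 1), "correct")], []) == []


class TestScorePredictions:
    def test_perfect_predictions(self):
        truth = [ann(box(0, 0, 10, 10)), ann(box(20, 20, 40, 40))]
        rep = score_predictions(truth, truth)
        assert rep.mean_iou == 1.0
        assert rep.phantoms == [] and rep.misses == []

    def test_phantom_only(self):
        rep = score_predictions([ann(box(0, 0, 10, 10))], [])
        assert rep.matches == [] and rep.mean_iou is None
        assert rep.phantoms == [0]

    def test_greedy_matches_exhaustive_on_2x2(self):
        # pairwise IoUs approx: (a,x)=.91, (a,y)=.33, (b,x)=.24, (b,y)=.82
        a, b = box(0, 0, 10, 10), box(6, 0, 16, 10)
        x = box(0, 0, 10, 11)
        y = box(5, 0, 15, 10)
        preds, truths = [ann(a), ann(b)], [ann(x), ann(y)]
        rep = score_predictions(preds, truths)
        got = {(i, j) for i, j, _ in rep.matches}
        # exhaustive over the two possible 1-1 assignments
        def total(assign):
            return sum(iou(preds[i].box, truths[j].box) for i, j in assign)
        best = max([{(0, 0), (1, 1)}, {(0, 1), (1, 0)}], key=total)
        assert got == best
        assert rep.mean_iou == pytest.approx(total(best) / 2)

    def test_adding_phantom_leaves_matches_unchanged(self):
        truths = [ann(box(0, 0, 10, 10))]
        preds = [ann(box(0, 0, 10, 10))]
        base = score_predictions(preds, truths)
        noisy = score_predictions(preds + [ann(box(500, 0, 510, 10))], truths)
        assert noisy.matches == base.matches
        assert noisy.phantoms == [1]


class TestLabelJson:
    def test_round_trip_and_ocr_eligibility(self):
        labels = [
            ann(box(0, 0, 10, 10), "typewritten", "yolo", ),
            ann(box(20, 0, 30, 10), "handwritten", "yolo"),
        ]
        doc = labels_to_json("sheet-1", labels, texts={0: "Flora", 1: "nope"})
        sheet, parsed, texts = labels_from_json(doc)
        assert sheet == "sheet-1"
        assert [(p.box, p.label_type) for p in parsed] == [
            (l.box, l.label_type) for l in labels
        ]
        assert texts == {0: "Flora"}  # handwritten labels carry no text
        assert labels_from_json(labels_to_json(sheet, parsed, texts)) == (
            sheet, parsed, texts
        )
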