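"""Average precision against an exhaustive PR-curve oracle, metric suite laws."""

import math

import numpy as np
import pytest

from orchardet import Detection, DetectionSet, GroundTruth, average_precision, evaluate
from orchardet.detector import iou


# --- independent oracle -----------------------------------------------------

def oracle_ap(dets_by_image, gts_by_image, thr):
    """Brute-force PR enumeration: walk the score-ranked list, recompute the
    precision/recall point after every detection, then average the best
    precision at each of the 101 recall levels."""
    ranked = []
    for img in sorted(dets_by_image):
        for d in dets_by_image[img]:
            ranked.append((img, d))
    ranked.sort(key=lambda t: (-t[1].score, t[0], t[1].box[1], t[1].box[0]))
    n_gt = sum(len(v) for v in gts_by_image.values())
    if n_gt == 0:
        return math.nan if not ranked else 0.0
    if not ranked:
        return 0.0
    taken = {img: set() for img in gts_by_image}
    points = []
    tp = 0
    for k, (img, d) in enumerate(ranked, start=1):
        gts = gts_by_image.get(img, [])
        cand = []
        for gi, g in enumerate(gts):
            if gi in taken.setdefault(img, set()):
                continue
            v = iou(d.box, g.box)
            if v >= thr:
                cand.append((v, -gi))
        if cand:
            best = max(cand)
            taken[img].add(-best[1])
            tp += 1
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    for r_level in [i / 100 for i in range(101)]:
        best = 0.0
        for rec, prec in points:
            if rec >= r_level - 1e-12 and prec > best:
                best = prec
        ap += best
    return ap / 101


def det(box, score, cid=0):
    return Detection(box=tuple(float(v) for v in box), class_id=cid, score=score)


def gt(box, cid=0):
    return GroundTruth(box=tuple(float(v) for v in box), class_id=cid)


def random_configuration(rng, max_boxes=4):
    """Random small detection/GT sets on a toy integer grid, ties allowed."""
    def random_box():
        x0, y0 = rng.integers(0, 6, 2)
        w, h = rng.integers(1, 5, 2)
        return (float(x0), float(y0), float(x0 + w), float(y0 + h))

    images = ["a", "b"][: int(rng.integers(1, 3))]
    dets, gts = {}, {}
    for img in images:
        dets[img] = [
            det(random_box(), score=float(rng.choice([0.3, 0.5, 0.5, 0.9])))
            for _ in range(rng.integers(0, max_boxes + 1))
        ]
        gts[img] = [gt(random_box()) for _ in range(rng.integers(0, max_boxes + 1))]
    return dets, gts


class TestAveragePrecision:
    def test_perfect_detector(self):
        g = [gt((0, 0, 5, 5)), gt((10, 10, 15, 15))]
        d = [det(x.box, 1.0) for x in g]
        assert average_precision({"i": d}, {"i": g}, 0.5) == pytest.approx(1.0)

    def test_no_detections_zero(self):
        assert average_precision({"i": []}, {"i": [gt((0, 0, 2, 2))]}, 0.5) == 0.0

    def test_nothing_at_all_is_nan(self):
        assert math.isnan(average_precision({"i": []}, {"i": []}, 0.5))

    def test_tp_then_fp_known_curve(self):
        """One TP at rank 1, one FP at rank 2, two GT: PR points (0.5, 1.0)
        then (0.5, 0.5); 101-point AP = 51/101."""
        g = [gt((0, 0, 4, 4)), gt((10, 0, 14, 4))]
        d = [det((0, 0, 4, 4), 0.9), det((20, 20, 24, 24), 0.8)]
        got = average_precision({"i": d}, {"i": g}, 0.5)
        assert got == pytest.approx(51 / 101)
        assert got == pytest.approx(oracle_ap({"i": d}, {"i": g}, 0.5))

    def test_matches_bruteforce_oracle_on_small_configurations(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            dets, gts = random_configuration(rng)
            for thr in (0.3, 0.5, 0.75):
                got = average_precision(dets, gts, thr)
                want = oracle_ap(dets, gts, thr)
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12), f"seed={seed} thr={thr}"

    def test_adding_true_positive_never_decreases_ap(self):
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            dets, gts = random_configuration(rng, max_boxes=3)
            base = average_precision(dets, gts, 0.5)
            extra_gt = gt((50.0, 50.0, 54.0, 54.0))
            dets2 = {k: list(v) for k, v in dets.items()}
            gts2 = {k: list(v) for k, v in gts.items()}
            img = sorted(gts2)[0]
            gts2[img].append(extra_gt)
            dets2[img].append(det(extra_gt.box, 1.0))
            grown = average_precision(dets2, gts2, 0.5)
            if not math.isnan(base):
                assert grown >= base - 1e-12


class TestEvaluate:
    def _as_sets(self, dets):
        return {k: DetectionSet(v, image_id=k) for k, v in dets.items()}

    def test_perfect_detections_all_metrics_one(self):
        g = {"i": [gt((0, 0, 8, 8), 0), gt((20, 20, 30, 30), 1)]}
        d = self._as_sets({"i": [det(x.box, 1.0, x.class_id) for x in g["i"]]})
        rec = evaluate(d, g)
        for f in rec.FIELDS:
            assert getattr(rec, f) == pytest.approx(1.0)

    def test_empty_detections_all_zero(self):
        g = {"i": [gt((0, 0, 8, 8))]}
        rec = evaluate(self._as_sets({"i": []}), g)
        for f in rec.FIELDS:
            assert getattr(rec, f) == 0.0

    def test_hand_enumerated_three_box_scenario(self):
        """2 GT; ranked dets: TP, FP, TP. Precision 2/3, recall 1,
        AP@0.5 from PR points (0.5,1.0), (0.5,0.5), (1.0,2/3)."""
        g = {"i": [gt((0, 0, 4, 4)), gt((10, 0, 14, 4))]}
        d = self._as_sets({"i": [
            det((0, 0, 4, 4), 0.9),
            det((20, 20, 24, 24), 0.8),
            det((10, 0, 14, 4), 0.7),
        ]})
        rec = evaluate(d, g)
        assert rec.precision == pytest.approx(2 / 3)
        assert rec.recall_all == pytest.approx(1.0)
        want_ap = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert rec.ap50 == pytest.approx(want_ap)

    def test_ap_50_95_never_exceeds_ap50(self):
        for seed in range(40):
            rng = np.random.default_rng(2000 + seed)
            dets, gts = random_configuration(rng)
            if sum(len(v) for v in gts.values()) == 0:
                continue
            rec = evaluate(self._as_sets(dets), gts)
            if not math.isnan(rec.ap50):
                assert rec.ap_50_95 <= rec.ap50 + 1e-12

    def test_macro_average_over_classes(self):
        g = {"i": [gt((0, 0, 8, 8), 0), gt((20, 20, 28, 28), 1)]}
        d = self._as_sets({"i": [det((0, 0, 8, 8), 1.0, 0)]})  # class 1 missed
        rec = evaluate(d, g)
        assert rec.ap50 == pytest.approx(0.5)
        assert rec.per_class[0]["ap50"] == pytest.approx(1.0)
        assert rec.per_class[1]["ap50"] == 0.0
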