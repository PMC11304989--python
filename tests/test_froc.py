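import numpy as np
import pytest

from nodulefpr.froc import (
    CPM_FP_RATES,
    Detection,
    ZeroTruthError,
    bootstrap_cpm_diff,
    cpm,
    filter_test_truths,
    froc_curve,
    match_detections,
    random_baseline,
    sensitivity_at,
)
from nodulefpr.volumes import AnnotationRecord, Candidate


def ann(scan, x, y, z, d, agreement=4):
    return AnnotationRecord(scan, (x, y, z), d, agreement=agreement)


def cand(scan, x, y, z, score):
    return Candidate(scan, (x, y, z), score=score)


# ---------------------------------------------------------------------------
# matching


def test_hit_criterion_boundary():
    truth = [ann("s", 0, 0, 0, 10)]  # radius 5
    inside = match_detections([cand("s", 4.5, 0, 0, 0.9)], truth)[0]
    outside = match_detections([cand("s", 5.5, 0, 0, 0.9)], truth)[0]
    assert inside.is_tp
    assert not outside.is_tp and not outside.ignored


def test_multiple_hits_detect_truth_once():
    truth = [ann("s", 0, 0, 0, 10)]
    dets = match_detections(
        [cand("s", 1, 0, 0, 0.9), cand("s", -1, 0, 0, 0.8), cand("s", 30, 0, 0, 0.7)],
        truth,
    )
    froc = froc_curve(dets, n_scans=1, n_truths=1)
    # both hits map to the same truth: sensitivity 1 with a single FP
    assert froc.sensitivity_at(1.0) == 1.0
    assert sum(d.is_tp for d in dets) == 2
    assert sum(d.truth_id is None for d in dets) == 1


def test_matching_order_independent(rng):
    truths = [ann("s", 0, 0, 0, 10), ann("s", 40, 0, 0, 8)]
    cands = [cand("s", rng.uniform(-20, 60), 0, 0, float(s))
             for s in rng.uniform(size=30)]
    dets = match_detections(cands, truths)
    perm = rng.permutation(30)
    dets_shuffled = match_detections([cands[i] for i in perm], truths)
    for i, j in enumerate(perm):
        assert dets_shuffled[i].truth_id == dets[j].truth_id


# ---------------------------------------------------------------------------
# FROC curve


def _toy_detections():
    # 2 scans, truths A and B; candidates: (0.9 TP_A), (0.8 FP), (0.7 TP_B), (0.6 FP)
    return [
        Detection("s1", 0.9, truth_id=("s1", 0)),
        Detection("s1", 0.8),
        Detection("s2", 0.7, truth_id=("s2", 0)),
        Detection("s2", 0.6),
    ]


def test_toy_froc_operating_points():
    froc = froc_curve(_toy_detections(), n_scans=2, n_truths=2)
    assert froc.sensitivity_at(0.5) == pytest.approx(0.5)
    assert froc.sensitivity_at(1.0) == pytest.approx(1.0)


def test_perfect_scorer_full_sensitivity_everywhere():
    dets = [
        Detection("s1", 0.95, truth_id=("s1", 0)),
        Detection("s2", 0.9, truth_id=("s2", 0)),
        Detection("s1", 0.5),
        Detection("s2", 0.4),
    ]
    froc = froc_curve(dets, n_scans=2, n_truths=2)
    for f in (0.0, 0.125, 1.0, 8.0):
        assert froc.sensitivity_at(f) == 1.0
    assert froc.cpm == 1.0


def test_all_false_positives_zero_sensitivity():
    dets = [Detection("s1", s) for s in (0.9, 0.5, 0.1)]
    froc = froc_curve(dets, n_scans=1, n_truths=3)
    for f in CPM_FP_RATES:
        assert froc.sensitivity_at(f) == 0.0
    with pytest.raises(ZeroTruthError):
        froc_curve(dets, n_scans=1, n_truths=0)


def _brute_force_sensitivity(dets, n_scans, n_truths, f):
    """Independent oracle: enumerate thresholds at FP scores (inclusive) and
    the zero-FP endpoint, then interpolate linearly by hand."""
    fp_scores = sorted((d.score for d in dets if d.truth_id is None), reverse=True)
    best = {}
    for d in dets:
        if d.truth_id is not None:
            best[d.truth_id] = max(best.get(d.truth_id, 0.0), d.score)
    tp_scores = list(best.values())
    points = []
    if fp_scores:
        top = fp_scores[0]
        points.append((0.0, sum(s > top for s in tp_scores) / n_truths))
    else:
        # no false positives at all: every hit truth is detected at 0 FP
        points.append((0.0, len(tp_scores) / n_truths))
    for t in sorted(set(fp_scores), reverse=True):
        fp = sum(s >= t for s in fp_scores) / n_scans
        sens = sum(s >= t for s in tp_scores) / n_truths
        points.append((fp, sens))
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if f >= xs[-1]:
        return ys[-1]
    for i in range(1, len(xs)):
        if f <= xs[i]:
            w = (f - xs[i - 1]) / (xs[i] - xs[i - 1])
            return ys[i - 1] + w * (ys[i] - ys[i - 1])
    return ys[-1]


def test_froc_agrees_with_brute_force_oracle(rng):
    for trial in range(25):
        n_scans = int(rng.integers(1, 4))
        n_truths = int(rng.integers(1, 4))
        dets = []
        for _ in range(int(rng.integers(1, 11))):
            scan = f"s{rng.integers(n_scans)}"
            if rng.uniform() < 0.4:
                dets.append(Detection(scan, float(rng.uniform()),
                                      truth_id=(scan, int(rng.integers(n_truths)))))
            else:
                dets.append(Detection(scan, float(rng.uniform())))
        total_truths = n_scans * n_truths
        froc = froc_curve(dets, n_scans=n_scans, n_truths=total_truths)
        for f in (0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 20.0):
            assert froc.sensitivity_at(f) == pytest.approx(
                _brute_force_sensitivity(dets, n_scans, total_truths, f), abs=1e-12
            )


def test_sensitivity_monotone_in_fp_rate(rng):
    dets = [
        Detection("s0", float(rng.uniform()),
                  truth_id=("s0", int(rng.integers(5))) if rng.uniform() < 0.3 else None)
        for _ in range(200)
    ]
    froc = froc_curve(dets, n_scans=4, n_truths=20)
    grid = np.linspace(0, 60, 200)
    sens = [froc.sensitivity_at(f) for f in grid]
    assert np.all(np.diff(sens) >= -1e-12)
    fps = [p[0] for p in froc.operating_points]
    assert np.all(np.diff(fps) > 0)


# ---------------------------------------------------------------------------
# CPM


def test_cpm_is_mean_of_seven_sensitivities():
    assert cpm([0.468, 0.557, 0.623, 0.662, 0.717, 0.756, 0.789]) == pytest.approx(
        0.653, abs=5e-4
    )
    assert cpm([1.0] * 7) == 1.0
    assert cpm([0.578, 0.668, 0.726, 0.778, 0.814, 0.853, 0.875]) == pytest.approx(
        0.756, abs=5e-4
    )
    with pytest.raises(ValueError):
        cpm([0.5] * 6)


def test_cpm_of_result_equals_mean_of_interpolated(rng):
    dets = [Detection("s0", float(rng.uniform()),
                      truth_id=("s0", 0) if rng.uniform() < 0.2 else None)
            for _ in range(60)]
    froc = froc_curve(dets, n_scans=3, n_truths=5)
    assert cpm(froc) == pytest.approx(
        np.mean([froc.sensitivity_at(f) for f in CPM_FP_RATES])
    )
    assert sensitivity_at(froc, 1.0) == froc.sensitivity_at(1.0)


# ---------------------------------------------------------------------------
# bootstrap


def _paired_detections(rng, n_scans=6):
    truths, dets = [], []
    for s in range(n_scans):
        scan = f"s{s}"
        truths.append(ann(scan, 0, 0, 0, 8))
        dets.append(Detection(scan, float(rng.uniform(0.6, 1.0)), (scan, 0)))
        for _ in range(5):
            dets.append(Detection(scan, float(rng.uniform(0.0, 0.5))))
    return dets, truths


def test_bootstrap_identical_systems_ci_is_zero(rng):
    dets, truths = _paired_detections(rng)
    lo, hi = bootstrap_cpm_diff(dets, dets, truths, n_boot=100, seed=0)
    assert lo == 0.0 and hi == 0.0


def test_bootstrap_ci_ordered_and_deterministic(rng):
    dets_a, truths = _paired_detections(rng)
    dets_b = [Detection(d.scan_id, d.score * 0.8, d.truth_id) for d in dets_a]
    for seed in range(5):
        lo, hi = bootstrap_cpm_diff(dets_a, dets_b, truths, n_boot=50, seed=seed)
        assert lo <= hi
    again = bootstrap_cpm_diff(dets_a, dets_b, truths, n_boot=50, seed=3)
    assert again == bootstrap_cpm_diff(dets_a, dets_b, truths, n_boot=50, seed=3)
    with pytest.raises(ValueError):
        bootstrap_cpm_diff(dets_a[:1], dets_b[:1], truths[:1], n_boot=10, seed=0)


# ---------------------------------------------------------------------------
# random baseline and truth filtering


def test_random_baseline_scores_uniform_and_reproducible():
    cands = [cand("s", i, 0, 0, None) for i in range(100)]
    for c in cands:
        c.score = None
    scored = random_baseline(cands, seed=4)
    scores = [c.score for c in scored]
    assert all(0.0 <= s <= 1.0 for s in scores)
    assert scores == [c.score for c in random_baseline(cands, seed=4)]


def test_random_baseline_sensitivity_matches_f_over_n():
    """With uniform scores, expected sensitivity at f FP/scan is f/N."""
    rng = np.random.default_rng(0)
    n_scans, n_fp = 100, 750
    dets, n_truths = [], 0
    for s in range(n_scans):
        scan = f"s{s}"
        for t in range(3):
            dets.append(Detection(scan, float(rng.uniform()), (scan, t)))
            n_truths += 1
        for _ in range(n_fp):
            dets.append(Detection(scan, float(rng.uniform())))
    froc = froc_curve(dets, n_scans=n_scans, n_truths=n_truths)
    for f in (1.0, 2.0, 4.0, 8.0):
        expected = f / n_fp
        sigma = np.sqrt(expected * (1 - expected) / n_truths)
        assert abs(froc.sensitivity_at(f) - expected) <= 3 * sigma + 1e-3


def test_truth_filtering_rules():
    small = ann("s", 0, 0, 0, 2.5)
    good = ann("s", 50, 0, 0, 10, agreement=4)
    contested = ann("s", 100, 0, 0, 10, agreement=2)
    considered, ignored = filter_test_truths([small, good, contested])
    assert considered == [good]
    assert set(map(id, ignored)) == {id(small), id(contested)}


def test_candidate_hitting_only_ignored_is_removed_from_fp_count():
    good = ann("s", 0, 0, 0, 10)
    tiny = ann("s", 50, 0, 0, 2.5)
    cands = [cand("s", 0, 0, 0, 0.9), cand("s", 50, 0, 0, 0.8),
             cand("s", 100, 0, 0, 0.7)]
    with_ignore = match_detections(cands, [good], ignored_truths=[tiny])
    without = match_detections(cands, [good])
    n_fp_with = sum(d.truth_id is None and not d.ignored for d in with_ignore)
    n_fp_without = sum(d.truth_id is None and not d.ignored for d in without)
    assert n_fp_with == 1
    assert n_fp_without == 2
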