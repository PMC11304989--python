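"""Detection scoring: hit criterion, FROC curve, CPM and bootstrap CIs.

A candidate is a true positive when its center lies inside the annotated
lesion boundary — here a sphere of radius diameter/2, since the simulator
annotates spherical extents.  A truth counts as detected once no matter how
many candidates hit it; candidates hitting only excluded ("ignore")
findings count as neither true nor false positives.

The FROC curve reports sensitivity against false positives per scan.  Its
operating points are taken where the false-positive count changes: at each
distinct FP score (threshold inclusive) plus a zero-FP endpoint whose
sensitivity counts the truths scoring strictly above every FP.  Sensitivity
at an arbitrary rate interpolates linearly on the FP axis (a step-function
alternative is available) and holds at the right end.  The competition
performance metric (CPM) is the mean sensitivity at 0.125, 0.25, 0.5, 1,
2, 4 and 8 FPs per scan.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from nodulefpr.volumes import AnnotationRecord, Candidate

__all__ = [
    "CPM_FP_RATES",
    "Detection",
    "FROCResult",
    "ZeroTruthError",
    "match_detections",
    "froc_curve",
    "sensitivity_at",
    "cpm",
    "bootstrap_cpm_diff",
    "random_baseline",
    "filter_test_truths",
]

#: the seven FP/scan rates of the competition performance metric
CPM_FP_RATES: Tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


class ZeroTruthError(ValueError):
    """Raised when sensitivity is requested with no truths to detect."""


@dataclass
class Detection:
    """One scored candidate after matching against the reference standard."""

    scan_id: str
    score: float
    truth_id: Optional[Tuple[str, int]] = None  # set iff true positive
    ignored: bool = False

    @property
    def is_tp(self) -> bool:
        return self.truth_id is not None and not self.ignored


@dataclass
class FROCResult:
    """Operating points plus the CPM summary of one detection system."""

    operating_points: List[Tuple[float, float]]  # (fp_per_scan, sensitivity)
    n_scans: int
    n_truths: int
    interpolation: str = "linear"
    cpm: float = field(init=False)
    cpm_sensitivities: Tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        sens = tuple(self.sensitivity_at(f) for f in CPM_FP_RATES)
        self.cpm_sensitivities = sens
        self.cpm = float(np.mean(sens))

    def sensitivity_at(self, fp_per_scan: float) -> float:
        fps = np.array([p[0] for p in self.operating_points])
        sens = np.array([p[1] for p in self.operating_points])
        if self.interpolation == "step":
            idx = np.searchsorted(fps, fp_per_scan, side="right") - 1
            return float(sens[max(idx, 0)])
        return float(np.interp(fp_per_scan, fps, sens))


# ---------------------------------------------------------------------------
# matching


def _hits(center: Sequence[float], truths: Sequence[AnnotationRecord]) -> Optional[int]:
    """Index of the closest truth whose boundary sphere contains ``center``."""
    best, best_ratio = None, np.inf
    for t_i, truth in enumerate(truths):
        radius = truth.diameter_mm / 2.0
        ratio = math.dist(center, truth.center_world) / radius
        if ratio <= 1.0 and ratio < best_ratio:
            best, best_ratio = t_i, ratio
    return best


def match_detections(
    candidates: Sequence[Candidate],
    truths: Sequence[AnnotationRecord],
    ignored_truths: Sequence[AnnotationRecord] = (),
) -> List[Detection]:
    """Label scored candidates as TP / FP / ignored against the reference.

    A candidate is a TP iff its center lies within diameter/2 of a truth
    center (ties go to the relatively closest truth); candidates hitting
    only an ignored finding are flagged and excluded from the FP tally.
    Matching is independent of candidate ordering.
    """
    by_scan: Dict[str, List[AnnotationRecord]] = defaultdict(list)
    for t in truths:
        by_scan[t.scan_id].append(t)
    ignored_by_scan: Dict[str, List[AnnotationRecord]] = defaultdict(list)
    for t in ignored_truths:
        ignored_by_scan[t.scan_id].append(t)

    out: List[Detection] = []
    for cand in candidates:
        if cand.score is None:
            raise ValueError("candidates must carry scores before matching")
        scan_truths = by_scan.get(cand.scan_id, [])
        hit = _hits(cand.center_world, scan_truths)
        if hit is not None:
            out.append(Detection(cand.scan_id, cand.score,
                                 truth_id=(cand.scan_id, hit)))
            continue
        ign = _hits(cand.center_world, ignored_by_scan.get(cand.scan_id, []))
        out.append(Detection(cand.scan_id, cand.score, ignored=ign is not None))
    return out


# ---------------------------------------------------------------------------
# FROC / CPM


def _operating_points(
    truth_best: np.ndarray, fp_scores: np.ndarray, n_scans: int
) -> List[Tuple[float, float]]:
    """Operating points from per-truth best TP scores and the FP score list."""
    n_truths = len(truth_best)
    fp_sorted = np.sort(fp_scores)  # ascending
    points: List[Tuple[float, float]] = []
    # zero-FP endpoint: truths scoring strictly above every FP
    top = fp_sorted[-1] if len(fp_sorted) else -np.inf
    points.append((0.0, float(np.mean(truth_best > top)) if n_truths else 0.0))
    thresholds = np.unique(fp_sorted)[::-1]  # descending
    for t in thresholds:
        n_fp = len(fp_sorted) - np.searchsorted(fp_sorted, t, side="left")
        sens = float(np.mean(truth_best >= t))
        points.append((float(n_fp) / n_scans, sens))
    return points


def froc_curve(
    detections: Sequence[Detection],
    n_scans: int,
    n_truths: int,
    interpolation: str = "linear",
) -> FROCResult:
    """Sweep score thresholds and build the FROC operating points.

    ``n_truths`` is the number of considered reference findings (truths a
    perfect system should detect); it cannot be inferred from detections
    alone because entirely missed truths leave no trace there.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if n_truths < 1:
        raise ZeroTruthError("sensitivity is undefined with zero truths")
    if interpolation not in ("linear", "step"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    best: Dict[Tuple[str, int], float] = {}
    fp_scores: List[float] = []
    for det in detections:
        if det.ignored:
            continue
        if det.truth_id is not None:
            key = det.truth_id
            best[key] = max(best.get(key, -np.inf), det.score)
        else:
            fp_scores.append(det.score)
    truth_best = np.full(n_truths, -np.inf)
    truth_best[: len(best)] = sorted(best.values(), reverse=True)
    points = _operating_points(truth_best, np.asarray(fp_scores, dtype=float), n_scans)
    return FROCResult(operating_points=points, n_scans=n_scans,
                      n_truths=n_truths, interpolation=interpolation)


def sensitivity_at(froc: FROCResult, fp_per_scan: float) -> float:
    return froc.sensitivity_at(fp_per_scan)


def cpm(result: Union[FROCResult, Sequence[float]]) -> float:
    """Competition performance metric: mean sensitivity at the seven rates.

    Accepts either a :class:`FROCResult` (sensitivities are interpolated
    from its operating points) or the seven sensitivities directly.
    """
    if isinstance(result, FROCResult):
        return result.cpm
    sens = np.asarray(list(result), dtype=float)
    if sens.shape != (len(CPM_FP_RATES),):
        raise ValueError(
            f"expected a FROCResult or {len(CPM_FP_RATES)} sensitivities, "
            f"got shape {sens.shape}"
        )
    if sens.min() < 0.0 or sens.max() > 1.0:
        raise ValueError("sensitivities must lie in [0, 1]")
    return float(sens.mean())


# ---------------------------------------------------------------------------
# bootstrap


def _per_scan_tables(
    detections: Sequence[Detection],
    truths: Sequence[AnnotationRecord],
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """scan_id → (best TP score per truth incl. missed, FP scores)."""
    truth_count: Dict[str, int] = defaultdict(int)
    for t in truths:
        truth_count[t.scan_id] += 1
    best: Dict[str, np.ndarray] = {
        scan: np.full(n, -np.inf) for scan, n in truth_count.items()
    }
    fps: Dict[str, List[float]] = defaultdict(list)
    scans = set(truth_count)
    for det in detections:
        scans.add(det.scan_id)
        if det.ignored:
            continue
        if det.truth_id is not None:
            scan, idx = det.truth_id
            arr = best.setdefault(scan, np.full(idx + 1, -np.inf))
            if idx >= len(arr):
                arr = np.concatenate([arr, np.full(idx + 1 - len(arr), -np.inf)])
                best[scan] = arr
            arr[idx] = max(arr[idx], det.score)
        else:
            fps[det.scan_id].append(det.score)
    return {
        scan: (best.get(scan, np.empty(0)),
               np.asarray(fps.get(scan, []), dtype=float))
        for scan in scans
    }


def _cpm_from_tables(
    tables: Dict[str, Tuple[np.ndarray, np.ndarray]], scan_ids: Sequence[str]
) -> float:
    truth_best = np.concatenate([tables[s][0] for s in scan_ids])
    fp_scores = np.concatenate([tables[s][1] for s in scan_ids])
    if len(truth_best) == 0:
        raise ZeroTruthError("resampled scan set contains no truths")
    points = _operating_points(truth_best, fp_scores, len(scan_ids))
    fps = np.array([p[0] for p in points])
    sens = np.array([p[1] for p in points])
    return float(np.mean(np.interp(CPM_FP_RATES, fps, sens)))


def bootstrap_cpm_diff(
    detections_a: Sequence[Detection],
    detections_b: Sequence[Detection],
    truths: Sequence[AnnotationRecord],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap CI of CPM(A) − CPM(B), resampling scans.

    Scans (not candidates) are resampled with replacement because the CPM
    is defined over a scan population; both systems are re-scored on each
    replicate.  Deterministic given ``seed``.
    """
    tables_a = _per_scan_tables(detections_a, truths)
    tables_b = _per_scan_tables(detections_b, truths)
    scan_ids = sorted(set(tables_a) | set(tables_b))
    if len(scan_ids) < 2:
        raise ValueError("bootstrap needs at least 2 scans")
    for scan in scan_ids:
        tables_a.setdefault(scan, (np.empty(0), np.empty(0)))
        tables_b.setdefault(scan, (np.empty(0), np.empty(0)))
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        sample = [scan_ids[i] for i in rng.integers(len(scan_ids), size=len(scan_ids))]
        if all(len(tables_a[s][0]) == 0 for s in sample):
            sample = list(scan_ids)  # degenerate truth-free draw: use the full set
        diffs[b] = _cpm_from_tables(tables_a, sample) - _cpm_from_tables(tables_b, sample)
    tail = (1.0 - ci) / 2.0
    lo, hi = np.percentile(diffs, [100 * tail, 100 * (1 - tail)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# baselines and truth filtering


def random_baseline(
    candidates: Sequence[Candidate], seed: int = 0
) -> List[Candidate]:
    """Assign each candidate an independent uniform(0, 1) confidence score."""
    rng = np.random.default_rng(seed)
    scores = rng.uniform(size=len(candidates))
    return [
        Candidate(scan_id=c.scan_id, center_world=c.center_world,
                  score=float(s), label=c.label)
        for c, s in zip(candidates, scores)
    ]


def filter_test_truths(
    annotations: Sequence[AnnotationRecord],
    min_diameter_mm: float = 3.0,
    min_agreement: int = 3,
) -> Tuple[List[AnnotationRecord], List[AnnotationRecord]]:
    """Split findings into considered truths and an ignore list.

    Kept iff diameter > ``min_diameter_mm`` (strict) and reader agreement
    ≥ ``min_agreement``.  Excluded findings become "ignore" regions whose
    hits count as neither TP nor FP.
    """
    considered, ignored = [], []
    for ann in annotations:
        if ann.diameter_mm > min_diameter_mm and ann.agreement >= min_agreement:
            considered.append(ann)
        else:
            ignored.append(ann)
    return considered, ignored
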