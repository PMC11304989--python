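"""Desk-scale study harness: the four-arm ablation and the enlargement sweep.

Two study designs run end-to-end on simulator data:

* **ablation** — ±full augmentations × ±unlabeled clinical data, trained on
  labeled phantom scans and evaluated on a common clinical-like test set;
  paired contrasts (Aug+ vs Aug−, Unlab+ vs Unlab−) get bootstrap CIs.
* **enlargement sweep** — nested labeled clinical subsets, each trained
  with and without the phantom scans added, reported as a table of the
  seven CPM sensitivities plus the recomputed CPM column.

Desk-scale defaults trade grid size and scan counts for runtime on a
single CPU: 30-mm ROIs at a coarsened (4, 1.25, 1.25) mm spacing
(8 × 24 × 24 voxels), a narrow network, and a handful of scans per split.
The reference-scale constants (569 phantom scans, 1000 negatives per scan,
(2, 0.625, 0.625) mm spacing, 32/64/128-channel network) remain reachable
through the same configuration objects.  Orderings and identities — not the
reported clinical-scale CPM magnitudes — are what these desk-scale runs
are expected to reproduce.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from nodulefpr.augment import FULL_MENU
from nodulefpr.froc import (
    CPM_FP_RATES,
    bootstrap_cpm_diff,
    cpm,
    filter_test_truths,
    froc_curve,
    match_detections,
)
from nodulefpr.network import Network, NetworkConfig
from nodulefpr.preprocess import (
    ROI,
    extract_roi,
    normalize_intensity,
    oversample_positives,
    sample_negatives,
)
from nodulefpr.simulate import (
    default_phantom_layouts,
    generate_clinical_scan,
    generate_phantom_scan,
    propose_candidates,
)
from nodulefpr.train import LossConfig, OptimConfig, train
from nodulefpr.volumes import NEGATIVE, POSITIVE, AnnotationRecord, Candidate

__all__ = [
    "BenchmarkConfig",
    "Benchmark",
    "ExperimentPlan",
    "build_benchmark",
    "train_and_score",
    "run_ablation",
    "run_enlargement_sweep",
]

#: the three geometry-only augmentations of the baseline (Aug−) training
BASIC_MENU: Tuple[str, ...] = ("flip", "translate", "rotate")


@dataclass
class BenchmarkConfig:
    """Sizes and generator settings of the default synthetic benchmark."""

    spacing: Tuple[float, float, float] = (4.0, 1.25, 1.25)
    grid: Tuple[int, int, int] = (12, 56, 56)
    roi_size_mm: float = 30.0
    n_phantom: int = 10
    n_clinical_train: int = 10
    # ~55-60 considered truths: sensitivity resolves in ~0.018 steps, enough
    # for paired CPM contrasts at this scale
    n_clinical_test: int = 20
    nodules_per_phantom: int = 3
    negatives_per_scan: int = 30
    positive_oversample: int = 10
    candidates_per_test_scan: int = 30
    unlabeled_patches_per_scan: int = 30
    proposal_sensitivity: float = 0.95
    clinical_difficulty: float = 1.0
    #: nodule sizes the desk-scale grid can resolve (the full 5–20 mm
    #: inventory range needs the reference spacing)
    clinical_diameter_range_mm: Tuple[float, float] = (8.0, 16.0)


@dataclass
class Benchmark:
    """Frozen datasets shared by all arms of a study."""

    labeled_phantom: List[ROI]
    labeled_clinical_by_scan: List[List[ROI]]  # one entry per clinical training scan
    unlabeled: List[np.ndarray]
    test_candidates: List[Candidate]
    test_truths: List[AnnotationRecord]
    test_ignored: List[AnnotationRecord]
    test_rois: List[ROI]
    n_test_scans: int
    train_scan_ids: List[str]
    test_scan_ids: List[str]
    config: BenchmarkConfig


@dataclass
class ExperimentPlan:
    """Study definition: arms, shared seeds and problem scale."""

    seeds: List[int] = field(default_factory=lambda: [0, 1, 2])
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    net_cfg: Optional[NetworkConfig] = None
    loss_cfg: LossConfig = field(default_factory=LossConfig)
    opt_cfg: OptimConfig = field(
        default_factory=lambda: OptimConfig(
            lr=3e-3, epochs=10, batch_labeled=16, batch_unlabeled=16,
            steps_per_epoch=12,
        )
    )
    clinical_subset_sizes: Tuple[int, ...] = (2, 5, 10)
    n_boot: int = 500

    def network_config(self, input_shape: Tuple[int, int, int]) -> NetworkConfig:
        if self.net_cfg is not None:
            return self.net_cfg
        # narrow desk-scale variant of the 32/64/128 reference network; the
        # reference dropout rates are sized for 128-wide layers and would
        # swamp a 32-wide net trained for ~100 steps, so they shrink with it
        return NetworkConfig(conv_kernels=(4, 8, 16), fc_nodes=(32, 32),
                             conv_dropout=0.1, fc_dropout=0.3,
                             input_shape=input_shape)


# ---------------------------------------------------------------------------
# benchmark construction


def _scan_to_rois(
    vol, truths: Sequence[AnnotationRecord], cfg: BenchmarkConfig, seed: int
) -> List[ROI]:
    """Positives at truth centers plus sampled nodule-free negatives."""
    nvol = normalize_intensity(vol)
    rois: List[ROI] = []
    for ann in truths:
        rois.append(extract_roi(nvol, ann.center_world, cfg.roi_size_mm,
                                label=POSITIVE))
    for cand in sample_negatives(nvol, truths, n=cfg.negatives_per_scan,
                                 seed=seed, roi_size_mm=cfg.roi_size_mm):
        rois.append(extract_roi(nvol, cand.center_world, cfg.roi_size_mm,
                                candidate=cand, label=NEGATIVE))
    return rois


def build_benchmark(seed: int, cfg: Optional[BenchmarkConfig] = None) -> Benchmark:
    """Generate the frozen train/unlabeled/test datasets for one study seed.

    Training scans (phantom + unlabeled clinical) and test scans use
    disjoint id spaces and disjoint generator seeds, so no scan leaks
    across the split.
    """
    cfg = cfg or BenchmarkConfig()
    root = np.random.default_rng(seed)
    phantom_seed, clin_seed, test_seed, neg_seed, prop_seed = root.integers(
        0, 2**31 - 1, size=5
    )

    # labeled phantom scans
    layouts = default_phantom_layouts(
        n_scans=cfg.n_phantom, seed=int(phantom_seed),
        n_nodules=cfg.nodules_per_phantom, grid=cfg.grid, spacing=cfg.spacing,
    )
    labeled_phantom: List[ROI] = []
    train_scan_ids: List[str] = []
    for s_i, layout in enumerate(layouts):
        vol, truths = generate_phantom_scan(layout, grid=cfg.grid,
                                            spacing=cfg.spacing)
        labeled_phantom.extend(_scan_to_rois(vol, truths, cfg, int(neg_seed) + s_i))
        train_scan_ids.append(layout.scan_id)

    # labeled clinical scans (for the enlargement sweep) reuse the same
    # generator as the test set but disjoint seeds
    labeled_clinical_by_scan: List[List[ROI]] = []
    for s_i in range(cfg.n_clinical_train):
        vol, truths = generate_clinical_scan(
            seed=int(clin_seed) + 2 * s_i, difficulty=cfg.clinical_difficulty,
            grid=cfg.grid, spacing=cfg.spacing,
            scan_id=f"clinical-train-{s_i:03d}",
            diameter_range_mm=cfg.clinical_diameter_range_mm,
        )
        labeled_clinical_by_scan.append(
            _scan_to_rois(vol, truths, cfg, int(neg_seed) + 1000 + s_i)
        )
        train_scan_ids.append(f"clinical-train-{s_i:03d}")

    # unlabeled stream: candidate-centred patches from the clinical training
    # scans, labels discarded
    unlabeled: List[np.ndarray] = []
    for s_i in range(cfg.n_clinical_train):
        vol, truths = generate_clinical_scan(
            seed=int(clin_seed) + 2 * s_i, difficulty=cfg.clinical_difficulty,
            grid=cfg.grid, spacing=cfg.spacing,
            scan_id=f"clinical-train-{s_i:03d}",
            diameter_range_mm=cfg.clinical_diameter_range_mm,
        )
        nvol = normalize_intensity(vol)
        cands = propose_candidates(
            vol, truths, n_per_scan=cfg.unlabeled_patches_per_scan,
            sensitivity=cfg.proposal_sensitivity, seed=int(prop_seed) + s_i,
        )
        for cand in cands:
            unlabeled.append(
                extract_roi(nvol, cand.center_world, cfg.roi_size_mm).patch
            )

    # frozen test set
    test_candidates: List[Candidate] = []
    test_annotations: List[AnnotationRecord] = []
    test_rois: List[ROI] = []
    test_scan_ids: List[str] = []
    for s_i in range(cfg.n_clinical_test):
        scan_id = f"clinical-test-{s_i:03d}"
        vol, truths = generate_clinical_scan(
            seed=int(test_seed) + 3 * s_i, difficulty=cfg.clinical_difficulty,
            grid=cfg.grid, spacing=cfg.spacing, scan_id=scan_id,
            diameter_range_mm=cfg.clinical_diameter_range_mm,
        )
        nvol = normalize_intensity(vol)
        cands = propose_candidates(
            vol, truths, n_per_scan=cfg.candidates_per_test_scan,
            sensitivity=cfg.proposal_sensitivity, seed=int(prop_seed) + 7000 + s_i,
        )
        test_candidates.extend(cands)
        test_annotations.extend(truths)
        test_scan_ids.append(scan_id)
        for cand in cands:
            test_rois.append(
                extract_roi(nvol, cand.center_world, cfg.roi_size_mm,
                            candidate=cand, label=cand.label)
            )
    test_truths, test_ignored = filter_test_truths(test_annotations)

    assert not set(train_scan_ids) & set(test_scan_ids), "train/test scan leak"
    return Benchmark(
        labeled_phantom=labeled_phantom,
        labeled_clinical_by_scan=labeled_clinical_by_scan,
        unlabeled=unlabeled,
        test_candidates=test_candidates,
        test_truths=test_truths,
        test_ignored=test_ignored,
        test_rois=test_rois,
        n_test_scans=cfg.n_clinical_test,
        train_scan_ids=train_scan_ids,
        test_scan_ids=test_scan_ids,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# arm execution


def _evaluate(net: Network, bench: Benchmark):
    """Score the frozen test candidates and build the FROC result."""
    scores = net.predict([roi.patch for roi in bench.test_rois])
    scored = [
        replace_score(cand, float(s))
        for cand, s in zip(bench.test_candidates, scores)
    ]
    detections = match_detections(scored, bench.test_truths, bench.test_ignored)
    froc = froc_curve(detections, bench.n_test_scans, len(bench.test_truths))
    return froc, detections, scored


def replace_score(cand: Candidate, score: float) -> Candidate:
    return Candidate(scan_id=cand.scan_id, center_world=cand.center_world,
                     score=score, label=cand.label)


def train_and_score(
    plan: ExperimentPlan,
    bench: Benchmark,
    seed: int,
    labeled_rois: Sequence[ROI],
    use_unlabeled: bool,
    augmentation: str = "full",
    teacher: Optional[Network] = None,
):
    """Train one arm on the shared benchmark and score the frozen test set.

    ``augmentation`` selects the labeled-stream menu: "basic" is
    flip/translate/rotate, "full" is the whole operator menu.
    Returns (froc_result, detections, network, history).
    """
    if augmentation not in ("basic", "full"):
        raise ValueError(f"unknown augmentation setting {augmentation!r}")
    menu = BASIC_MENU if augmentation == "basic" else FULL_MENU
    roi_shape = labeled_rois[0].patch.shape
    net, history = train(
        labeled_rois,
        bench.unlabeled if use_unlabeled else [],
        net_cfg=plan.network_config(roi_shape),
        loss_cfg=plan.loss_cfg,
        opt_cfg=plan.opt_cfg,
        seed=seed,
        teacher=teacher if use_unlabeled else None,
        labeled_menu=menu,
    )
    froc, detections, _ = _evaluate(net, bench)
    return froc, detections, net, history


def _oversampled(bench: Benchmark, rois: Sequence[ROI], seed: int) -> List[ROI]:
    return oversample_positives(rois, bench.config.positive_oversample, seed=seed)


ARM_NAMES = ("unlab-_aug-", "unlab-_aug+", "unlab+_aug-", "unlab+_aug+")


def run_ablation(plan: ExperimentPlan, out_dir: Optional[str] = None) -> Dict:
    """The four-arm ±augmentation × ±unlabeled study with shared seeds.

    All arms of one seed share the benchmark datasets and the training
    seed; unlabeled-arm pseudo-labels come from the already-trained
    phantom-only arm with the matching augmentation menu.  Emits per-arm
    CPMs and bootstrap CIs for the two paired contrasts.  A diverging arm
    is recorded as failed; the others proceed.
    """
    per_seed: List[Dict] = []
    for seed in plan.seeds:
        bench = build_benchmark(seed, plan.benchmark)
        labeled = _oversampled(bench, bench.labeled_phantom, seed)
        arms: Dict[str, Dict] = {}
        teachers: Dict[str, Optional[Network]] = {}
        for arm in ARM_NAMES:
            use_unl = arm.startswith("unlab+")
            aug = "full" if arm.endswith("aug+") else "basic"
            try:
                froc, detections, net, history = train_and_score(
                    plan, bench, seed, labeled, use_unl, aug,
                    teacher=teachers.get(f"unlab-_aug{'+' if aug == 'full' else '-'}"),
                )
            except Exception as exc:  # noqa: BLE001 - a failed arm must not sink the study
                arms[arm] = {"failed": str(exc)}
                continue
            if not use_unl:
                teachers[arm] = net
            arms[arm] = {
                "cpm": froc.cpm,
                "sensitivities": list(froc.cpm_sensitivities),
                "detections": detections,
                "gate_fraction_final": history[-1].gate_fraction,
            }
        record = {"seed": seed, "arms": arms}
        # paired contrasts on the shared test set
        for name, arm_a, arm_b in (
            ("aug_contrast", "unlab-_aug+", "unlab-_aug-"),
            ("unlab_contrast", "unlab+_aug+", "unlab-_aug+"),
        ):
            if "failed" not in arms.get(arm_a, {"failed": 1}) and \
               "failed" not in arms.get(arm_b, {"failed": 1}):
                record[name] = {
                    "delta_cpm": arms[arm_a]["cpm"] - arms[arm_b]["cpm"],
                    "ci": bootstrap_cpm_diff(
                        arms[arm_a]["detections"], arms[arm_b]["detections"],
                        bench.test_truths, n_boot=plan.n_boot, seed=seed,
                    ),
                }
        per_seed.append(record)

    report = {
        "seeds": list(plan.seeds),
        "per_seed": per_seed,
        "arm_cpm_mean": {
            arm: float(np.mean([
                r["arms"][arm]["cpm"] for r in per_seed
                if "cpm" in r["arms"].get(arm, {})
            ]))
            for arm in ARM_NAMES
        },
        "aug_majority": _majority(per_seed, "unlab-_aug+", "unlab-_aug-"),
        "unlab_majority": _majority(per_seed, "unlab+_aug+", "unlab-_aug+"),
    }
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "ablation.json"), "w") as fh:
            json.dump(_strip_detections(report), fh, indent=2)
    return report


def _majority(per_seed: List[Dict], arm_a: str, arm_b: str) -> float:
    wins = [
        r["arms"][arm_a]["cpm"] >= r["arms"][arm_b]["cpm"]
        for r in per_seed
        if "cpm" in r["arms"].get(arm_a, {}) and "cpm" in r["arms"].get(arm_b, {})
    ]
    return float(np.mean(wins)) if wins else float("nan")


def _strip_detections(obj):
    if isinstance(obj, dict):
        return {k: _strip_detections(v) for k, v in obj.items() if k != "detections"}
    if isinstance(obj, (list, tuple)):
        return [_strip_detections(v) for v in obj]
    return obj


def bootstrap_coverage_simulation(
    delta: float = 0.2,
    p_base: float = 0.6,
    n_outer: int = 100,
    n_scans: int = 40,
    truths_per_scan: int = 2,
    fps_per_scan: int = 10,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Fraction of bootstrap CIs covering a known CPM gap.

    Constructs paired detection sets with a per-scan detection-probability
    gap ``delta``: system A detects each truth with probability
    ``p_base + delta``, system B with ``p_base``; detected truths score
    above every FP, so each replicate's CPM difference equals the resampled
    detection-rate difference and the population CPM gap is exactly
    ``delta``.  Repeats the experiment ``n_outer`` times and reports how
    often the 95% CI covers ``delta``.
    """
    from nodulefpr.froc import Detection, bootstrap_cpm_diff

    root = np.random.default_rng(seed)
    covered = 0
    for rep in range(n_outer):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        det_a, det_b, truths = [], [], []
        for s in range(n_scans):
            scan = f"scan-{s:03d}"
            for t in range(truths_per_scan):
                truths.append(AnnotationRecord(scan, (0.0, 0.0, float(t)), 5.0))
                if rng.uniform() < p_base + delta:
                    det_a.append(Detection(scan, rng.uniform(0.5, 1.0), (scan, t)))
                if rng.uniform() < p_base:
                    det_b.append(Detection(scan, rng.uniform(0.5, 1.0), (scan, t)))
            for _ in range(fps_per_scan):
                fp_score = rng.uniform(0.0, 0.4)
                det_a.append(Detection(scan, fp_score))
                det_b.append(Detection(scan, fp_score))
        lo, hi = bootstrap_cpm_diff(det_a, det_b, truths, n_boot=n_boot,
                                    seed=int(rng.integers(2**31 - 1)))
        if lo <= delta <= hi:
            covered += 1
    return covered / n_outer


def run_enlargement_sweep(plan: ExperimentPlan, out_dir: Optional[str] = None
                          ) -> pd.DataFrame:
    """Train on nested clinical subsets ± phantom scans; emit the study table.

    Rows: (n_clinical, phantom flag); columns: sensitivity at the seven CPM
    rates plus the CPM recomputed from those sensitivities.  The clinical
    subsets are nested (each tier is a prefix of the next) and every row is
    evaluated on the same frozen test set.
    """
    seed = plan.seeds[0]
    bench = build_benchmark(seed, plan.benchmark)
    for size in plan.clinical_subset_sizes:
        if size > len(bench.labeled_clinical_by_scan):
            raise ValueError(
                f"subset size {size} exceeds the {len(bench.labeled_clinical_by_scan)} "
                f"available clinical training scans"
            )
    rows = []
    for size in plan.clinical_subset_sizes:
        clinical = [roi for scan in bench.labeled_clinical_by_scan[:size]
                    for roi in scan]
        for use_phantom in (False, True):
            if size == 0 and not use_phantom:
                continue  # no training data at all
            rois = clinical + (bench.labeled_phantom if use_phantom else [])
            froc, _, _, _ = train_and_score(
                plan, bench, seed, _oversampled(bench, rois, seed),
                use_unlabeled=False, augmentation="basic",
            )
            sens = froc.cpm_sensitivities
            rows.append({
                "n_clinical": size,
                "phantom": plan.benchmark.n_phantom if use_phantom else 0,
                **{f"sens_at_{f}": s for f, s in zip(CPM_FP_RATES, sens)},
                "cpm": cpm(sens),
            })
    table = pd.DataFrame(rows)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "results.csv"), index=False)
    return table
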