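"""Train the false-positive-reduction classifier on a small synthetic set.

Labeled phantom patches train the supervised focal term; unlabeled
clinical patches feed the confidence-gated consistency term and (through a
phantom-trained teacher) the pseudo-label term of the composite objective
L = ls + λ1·lu + λ2·lp.  Runs in about two minutes on one CPU.
"""

from nodulefpr.experiments import BenchmarkConfig, ExperimentPlan, build_benchmark
from nodulefpr.preprocess import oversample_positives
from nodulefpr.train import LossConfig, OptimConfig, train

plan = ExperimentPlan()
cfg = BenchmarkConfig(n_phantom=6, n_clinical_train=6, n_clinical_test=4)
bench = build_benchmark(seed=0, cfg=cfg)
labeled = oversample_positives(bench.labeled_phantom,
                               cfg.positive_oversample, seed=0)
print(f"{len(labeled)} labeled phantom ROIs ({bench.labeled_phantom[0].patch.shape} "
      f"voxels), {len(bench.unlabeled)} unlabeled clinical ROIs")

opt = OptimConfig(lr=3e-3, epochs=6, batch_labeled=16, batch_unlabeled=16,
                  steps_per_epoch=8)
net_cfg = plan.network_config(labeled[0].patch.shape)

print("\n1) teacher: supervised focal loss on phantom data only")
teacher, t_hist = train(labeled, [], net_cfg=net_cfg, opt_cfg=opt, seed=0)
print(f"   ls per epoch: {[round(s.ls, 2) for s in t_hist]}")

print("2) student: + consistency and pseudo-labels from unlabeled data")
net, history = train(labeled, bench.unlabeled, net_cfg=net_cfg, opt_cfg=opt,
                     seed=0, teacher=teacher, loss_cfg=LossConfig())
for s in history:
    print(f"   epoch {s.epoch}: ls={s.ls:6.2f} lu={s.lu:5.2f} lp={s.lp:5.2f} "
          f"L={s.total:6.2f} gate={s.gate_fraction:.2f}")
print("The gate fraction is the share of unlabeled samples whose weak-view"
      "\nconfidence max(p, 1-p) reaches 0.95 — it grows as the network"
      "\nbecomes more certain, switching the consistency term on.  lp stays"
      "\n0 until the teacher scores samples beyond the strict 0.01 / 0.99"
      "\npseudo-label thresholds; a longer-trained teacher assigns more.")
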