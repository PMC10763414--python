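# lossgate

Noise-robust active learning for patch-based pathology image classification.

## The problem

Training a patch-level tissue classifier (benign / dysplasia / malignant)
with active learning (AL) means repeatedly asking a pathologist to label the
"most informative" patches from a large unlabeled pool.  Pools built from
real whole-slide scans contain patches that cannot be labelled at all —
near-empty tiles, foreign substances, out-of-focus regions, air bubbles,
tissue folds.  Uncertainty- and loss-based acquisition functions are drawn
to exactly these artifacts, so a large share of the labelling budget is
wasted on patches the oracle must reject.

`lossgate` implements a loss-prediction AL strategy that avoids this trap.
A **loss prediction module** (LPM) is trained jointly with the backbone
classifier on

```
L = L_target(ŷ, y) + λ · L_loss(l̂, l)
```

where `L_target` is cross-entropy and `L_loss` is a pairwise margin-ranking
hinge, `max(0, −𝟙(l_i, l_j)·(l̂_i − l̂_j) + ε)`, that teaches the LPM to
order samples by their training loss.  During training, the predicted losses
of *correctly classified* examples are accumulated per class over the last
`z` epochs into a trailing average `b_final_t`, and each class receives a
threshold

```
threshold_t = α_t · b_final_t          (α = 1.0 / 1.1 / 1.0 by default)
```

At acquisition time, pool patches with `l̂ ≥ threshold` of their predicted
class — the region where unlabelable patches concentrate — are excluded,
and the budget is spent on the highest-`l̂` survivors, in equal per-class
shares.  Labelled patches join `D_L`; rejected (noisy) ones leave the pool
without yielding a label: `D_U ← D_U − p_n − p_l`, `D_L ← D_L + p_l`.
The headline metric is the **N-ratio**, the percentage of each iteration's
budget spent on noisy patches.

The package ships the six comparison strategies (unfiltered learning loss,
least confidence, entropy, BALD, core-set k-center greedy, random), a fully
seeded synthetic corpus generator that emulates the clean-class / artifact
structure of a workplace pathology pool, and the complete iterative
experiment harness (from-scratch retraining per iteration, multi-trial
aggregation, α-sensitivity sweep).  It is aimed at AL researchers who want
a reproducible, laptop-scale testbed for noise-aware acquisition.

## Worked example

```python
import lossgate as lg

spec = lg.CorpusSpec(n_clean_per_class=300, seed=8)   # 900 clean + 55 noisy pool
corpus = lg.generate_corpus(spec)

cfg = lg.ExperimentConfig(iterations=4, budget=50, initial_labeled=60, trials=2)
proposed = lg.run_experiment(corpus, "proposed", cfg, seed=0)
baseline = lg.run_experiment(corpus, "ll", cfg, seed=0)

import pandas as pd
both = pd.concat([proposed, baseline])
print(lg.noise_summary(both, cfg.budget).round(2).to_string(index=False))
print(lg.aggregate_records(both).round(3).to_string(index=False))
```

prints (seeds fixed, so these numbers reproduce exactly):

```
strategy  mean  total  n_ratio
      ll 13.33   40.0    26.67
proposed  0.50    1.5     1.00
strategy  iteration  accuracy_mean  accuracy_std  n_noisy_mean  n_labeled_mean
      ll          1          0.672         0.022           1.0            60.0
      ll          2          0.493         0.117          26.5           109.0
      ll          3          0.597         0.043           0.0           132.5
      ll          4          0.592         0.025          13.5           182.5
proposed          1          0.672         0.022           1.0            60.0
proposed          2          0.788         0.088           1.0           109.0
proposed          3          0.737         0.043           0.5           158.0
proposed          4          0.808         0.108           0.0           207.5
```

Reading: noisy patches are only 55 of the 955-patch pool (5.8%), yet the
unfiltered learning-loss baseline spent 26.7% of its post-initial budget on
them — loss ranking actively seeks them out — while the threshold gate cut
that to 1.0% and reached higher accuracy with the same budget.  (This toy
run stops after 4 iterations of 50; the default protocol in
`ExperimentConfig()` runs 10 iterations of 100 on a ~3,200-patch pool,
where accuracies reach ~0.98.)

The same experiment is available from the shell:

```
lossgate generate --out corpus/ --n-per-class 300 --seed 8
lossgate compare --corpus corpus/ --strategies proposed,ll,random --out runs/
lossgate sweep-alpha --corpus corpus/ --alphas 0.5,0.8,1.0,1.1,1.2 --out sweep/
lossgate report runs/proposed runs/ll --out report/
```

Every run directory is self-describing (`manifest.json` with the full config
and its hash); `lossgate run --from-manifest RUNDIR --out NEW` re-executes
it and reproduces the selection JSONs byte for byte.

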