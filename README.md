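# hergml

Ligand-based and structure-based Random-Forest classifiers for hERG
liability, in one tested pipeline.

Blockade of the hERG potassium channel is the most common cause of
drug-induced QT prolongation and arrhythmia, so candidate molecules are
screened computationally before synthesis.  Two families of models
dominate: **ligand-based (LB)** classifiers built from physicochemical
descriptors and circular fingerprints, and **structure-based (SB)**
classifiers built from docking scores against the channel's pore.  This
package implements both sides and the machinery to compare them fairly
on a common dataset:

* curation of raw activity tables to one labeled record per standardized
  structure (pK = −log10 molar activity; binder iff pK ≥ 5, i.e. 10 µM);
* the 2059-column LB block (11 physicochemical descriptors + ECFP6- and
  FCFP6-style 1024-bit fingerprints), Murcko scaffold summaries and
  chemical-space PCA;
* aggregation of multi-engine, multi-pose docking score tables into
  per-compound features, by **best pose** (rank-1 score vector, averaged
  over stereoisomers) or by **average** over all poses ("binding space"),
  and multi-engine consensus assembly;
* correlation-based feature selection (CFS merit
  `k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`) with forward best-first search;
* seeded Random Forests (100 trees, unlimited depth), stratified
  ten-fold cross-validation, MaxMin diversity splitting, minimum-vote
  consensus prediction, and the standard metric set (MCC, ACC, AUC,
  precision, SE, SP);
* a four-method applicability domain (fingerprint similarity Tc > 0.7,
  PCA range, centroid distance, kernel density) with a 3-of-4 consensus
  and an accuracy-vs-similarity trend report;
* a synthetic-data generator that emulates the activity sources and
  docking engines with known ground truth, so the entire workflow is
  testable without proprietary data.  See `docs/methods.md` for the
  model behind it and its limits.

## Worked example

```python
from hergml import (GeneratorConfig, generate_cohort, best_first_select,
                    compute_lb_features, ten_fold_cv, ModelSpec,
                    best_pose_features, average_pose_features,
                    assemble_consensus_features)

cohort = generate_cohort(GeneratorConfig(n_compounds=1000, seed=3))
labels = cohort.labels

# ligand-based model with CFS + best-first selection
lb = compute_lb_features(list(zip(cohort.compounds.compound_id,
                                  cohort.compounds.smiles)))
selected = best_first_select(lb, labels.loc[lb.compound_ids])
print(len(selected), selected[:3])
# 11 ['TPSA', 'ecfp6_1004', 'ecfp6_207']

report = ten_fold_cv(lb.subset(selected), labels.loc[lb.compound_ids],
                     ModelSpec(seed=3), seed=3)
print(f"LB  MCC {report.MCC:.3f}  ACC {report.ACC:.3f}  AUC {report.AUC:.3f}")
# LB  MCC 0.650  ACC 0.829  AUC 0.918

# structure-based consensus: best pose vs average over poses
bp = assemble_consensus_features({e: best_pose_features(t)
                                  for e, t in cohort.pose_tables.items()})
av = assemble_consensus_features({e: average_pose_features(t)
                                  for e, t in cohort.pose_tables.items()})
print(f"SB best-pose MCC {ten_fold_cv(bp, labels.loc[bp.compound_ids], ModelSpec(seed=3), seed=3).MCC:.3f}")
print(f"SB average  MCC {ten_fold_cv(av, labels.loc[av.compound_ids], ModelSpec(seed=3), seed=3).MCC:.3f}")
# SB best-pose MCC 0.629
# SB average  MCC 0.673
```

The MCC (Matthews correlation coefficient, −1…1) summarises binary
performance robustly under class imbalance; the average-over-poses SB
featurization consistently beats best-pose-only, and combining LB
descriptors with SB scores improves on SB alone — the comparative
orderings the pipeline is designed to expose.

A `hergml` console script wraps the stages for shell use
(`simulate`, `curate`, `featurize-lb`, `featurize-sb`,
`select-features`, `train`, `evaluate`, `predict`, `ad`, `consensus`,
`run-experiment`); `run-experiment` takes a YAML config naming the
input tables, the feature mode (`lb`, `sb_bp`, `sb_av`, `lb+sb_bp`,
`lb+sb_av`, `consensus`) and a seed, and writes curated data, features,
the model bundle, CV and external reports, AD verdicts and a manifest
to one directory.

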