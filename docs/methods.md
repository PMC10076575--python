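# Methods

`hergml` implements a comparative modelling workflow for hERG liability:
binary binder / non-binder Random-Forest classifiers built from
ligand-based (LB) descriptors, from structure-based (SB) docking
pose-score features, and from their combinations, together with the
supporting stages — activity-data curation, pose-score aggregation,
correlation-based feature selection, evaluation metrics, and a
four-method applicability-domain consensus.  Because the original
campaign's training data (a public-channel/commercial mix) and docking
engines are not redistributable, the package ships a synthetic-data
generator that emulates their statistical structure with known ground
truth; everything downstream of the generator is the real method.

## Curation

Raw activity tables carry one measurement per row (compound id, SMILES,
endpoint IC50/EC50/Ki/Kd, relation, value, unit).  Curation:

1. drops censored measurements (relation `>` or `<`);
2. converts concentrations to pK = −log10(molar value), so pK 5 ≡ 10 µM;
3. standardizes structures with RDKit: functional-group normalization,
   largest-fragment salt stripping, charge neutralization, canonical
   SMILES.  Tautomer canonicalization is deliberately not applied;
4. groups records by canonical structure and takes the **median** pK,
   pooled across endpoint types.  Medians are taken in pK space (the
   choice matters only for even-sized groups);
5. labels binders by pK ≥ 5.0, boundary inclusive.  The threshold is
   configurable.

Unparseable structures are dropped with a logged reason.  Target /
organism filtering is treated as upstream selection: optional columns
are matched exactly when present.

## Ligand-based features

The LB block is 2059 columns: 11 physicochemical descriptors (Crippen
logP, TPSA, molecular weight, rotatable bonds, H-bond donors/acceptors,
heteroatoms, atom and heavy-atom counts, stereocenters, fraction of sp³
carbons) plus two 1024-bit hashed circular fingerprints of diameter 6
(radius 3): connectivity invariants (ECFP6-like) and functional-class
invariants (FCFP6-like).  Tanimoto similarity of two all-zero
fingerprints is defined as 1 (two featureless structures are treated as
identical); this convention is used consistently by the similarity
applicability-domain criterion.

Chemical-space PCA standardizes a 26-descriptor panel (the 11 above plus
15 standard 2-D additions: ring counts, aromaticity, surface, molar
refractivity, atom-class counts, complexity — a documented stand-in for
the original toolkit's unpublished panel) to zero mean / unit variance,
drops constant columns with a warning, and fixes the sign of each
component so its largest-magnitude loading is positive.  Murcko scaffold
summaries group compounds by framework (acyclic molecules under an
explicit `no-scaffold` row) with count, mean pK and population SD.

## Structure-based features

Docking output is modelled as long-format pose-score tables: one row per
(compound, stereoisomer, engine, pose rank, scoring function).  Each
engine contributes its native primary score plus 25 rescoring functions;
the LiGen-style engine adds a 29-column pharmacophore-distance block for
an engine total of 55 (29 is inferred arithmetic: 55 − 1 primary − 25
rescoring).  Validation checks key uniqueness, pose-rank contiguity and
score-name consistency.  Score direction conventions (higher- vs
lower-is-better) are carried as metadata and never used to flip values.

Two per-compound aggregations:

* **best pose (BP)** — each stereoisomer's rank-1 score vector, averaged
  across isomers.  "Top ranked" means the engine's stored pose rank; no
  re-sorting by rescoring columns.
* **average (AV)** — the pooled mean over all poses of all isomers,
  treating the pose ensemble as a sample of the compound's binding
  space.  With equal pose counts per isomer this equals the mean of
  per-isomer means.

A consensus assembly concatenates per-engine matrices with
engine-prefixed column names on the intersection of successfully docked
compounds (compounds undocked by any engine are dropped and logged).

## Feature selection

Correlation-based feature selection scores a subset S (|S| = k) by

    merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

with r̄_cf the mean absolute feature–class correlation and r̄_ff the mean
absolute pairwise feature–feature correlation.  Correlations are Pearson
(point-biserial against the binary class); the discretizing
symmetric-uncertainty variant of the original toolkit was traded for the
continuous measure for determinism and a closed-form test oracle.
Constant features contribute zero correlation.  Note that an exact
duplicate of a selected feature leaves the merit unchanged (redundancy
exactly cancels the apparent gain); only genuinely complementary
features raise it.

Search is forward best-first: a priority queue of subsets ordered by
merit, expanding the best open subset by each unused feature, stopping
after 5 consecutive expansions that fail to improve the best merit
found.  Candidates are processed in lexicographic name order, making the
result deterministic and invariant to column permutation.  On panels of
≤ 10 features the search empirically attains the exhaustive optimum
(asserted in the test suite).  Selection is fit once on the full
training partition, never inside cross-validation folds — a
leakage-safe choice.

## Modelling and evaluation

Random Forests use 100 trees of unlimited depth, seeded; probability
ties at exactly 0.5 resolve to binder (favouring sensitivity under the
binder-heavy class balance).  Settings of the original toolkit with no
scikit-learn analogue (batch size, executor slots) are ignored.
Cross-validation is stratified ten-fold, seeded; out-of-fold predictions
are pooled and scored once.  The diversity split implements MaxMin on
Tanimoto distance: a seeded random first pick, then repeated addition of
the compound with the largest minimum distance to the picked set; the
picked set is the test partition.  Consensus prediction is a minimum-
vote rule (binder iff ≥ `min_votes` of the model votes are binder;
`min_votes=1` is logical OR, `min_votes=n` logical AND).

Metrics are MCC, accuracy, precision, sensitivity, specificity (binder
positive) and ROC AUC computed as the Mann–Whitney rank statistic (ties
0.5) — identical to trapezoidal ROC integration but with a simpler
oracle.  Zero-denominator conventions (MCC→0, ratio metrics→0, flagged)
never arise on non-degenerate inputs.

## Applicability domain

Four criteria per test compound, consensus at ≥ 3 of 4:

1. **similarity**: nearest-neighbor Tanimoto on 1024-bit fingerprints
   strictly greater than 0.7;
2. **range**: first two standardized PCA scores inside the training
   min/max box, boundaries inclusive (the PCA-space reading of the
   range criterion);
3. **Euclidean distance**: distance to the training centroid in
   standardized descriptor space at most the 95th percentile of training
   distances;
4. **probability density**: Gaussian-kernel density, estimated on the
   first five PCA components (avoiding high-dimensional KDE degeneracy)
   with the default bandwidth plug-in rule, at least the cutoff covering
   95% of training points.

The 95th-percentile / 95%-coverage thresholds are package choices — the
referenced AD software's internal defaults are unpublished — and are
calibrated by construction: each descriptor-space criterion retains
≈ 95% (≥ 90% asserted) of its own training points.  The trend report
bins nearest-neighbor Tanimoto into width-0.1 intervals and reports
per-bin accuracy and count (empty bins carry n = 0, accuracy NaN).

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Structures.**  Each compound is head + linker + linker + tail drawn
from a closed grammar of 28 fragments (aryl/heteroaryl heads, short
alkyl/ether/amide linkers, amine-bearing tails — the motifs that
dominate hERG binder scaffolds), concatenated into valid SMILES so that
descriptor and fingerprint computation is real chemistry.  External
validation sets mix in a disjoint alternate sub-grammar with per-slot
probability 0.25 / 0.6 / 1.0 (low / medium / high dissimilarity),
shifting the nearest-neighbor Tanimoto distribution downward.

**Affinity and pK.**  Latent affinity = lipophilicity effect (default
1.0) × scaled logP − polarity effect (0.6) × scaled TPSA + per-fragment
contributions (SD 0.5, a deterministic function of fragment identity and
the master seed, so shared fragments agree across cohorts) + Gaussian
noise (SD 0.5).  Emitted pK = 5.0 + 1.2 × (standardized affinity −
calibration offset) + measurement noise (SD 0.3), with the offset set at
the quantile that puts the configured binder fraction (default
7303/12789 ≈ 0.571) at or above the threshold.  This concentrates pK
mass near 5 — the hard-case structure of the emulated campaign — and
makes labels learnable from descriptors (directly) and fingerprints (via
fragment contributions), while unseen alternate fragments carry
contributions no model can have learned, producing the
accuracy-vs-similarity trend.  Note the two property effects are not
separately identifiable from class contrasts: because logP and TPSA of
real molecules are anticorrelated, disabling only the lipophilicity
effect still leaves a class logP gap.

**Activity records.**  One exact measurement per compound (unit µM, or
nM for pK ≥ 7.5); 10% of compounds gain a replicate in another unit and
5% an extra censored row, exercising duplicate-median aggregation and
censored exclusion.  With measurement noise set to zero, curation
recovers the generated labels exactly.

**Pose scores.**  For engine column f and pose p of compound c:
`loading_f · (affinity_c + dev_p) + bias_f + engine_error_c + eps`, with
loadings drawn once per engine from U(0.3, 1.0) (pharmacophore distances
U(0.1, 0.4) plus a distance-like offset), per-column bias N(0, 0.25),
per-compound engine error N(0, 0.8), shared per-pose geometry deviation
N(0, 1.0) and per-column pose noise at 30% of the deviation SD.  Pose
rank 1 is the best raw primary score; lower-is-better engines emit the
primary column negated.  Stereoisomers (20% of compounds, pairs) share
affinity and engine error but draw independent pose deviations.  2.4%
of compounds per engine fail to dock.

The shared pose deviation is the load-bearing choice: best-pose
selection picks the pose with the largest optimistic deviation (an
extreme-value draw that column-averaging cannot remove), while the
pooled average shrinks it by 1/n_poses — so average-score models
reliably outperform best-pose models, and adding LB descriptors to an SB
model adds independent signal.  The per-compound engine error bounds
single-channel SB performance below the LB model, mirroring the relative
information content of the two channels in the emulated campaign.  All
magnitudes are artifact choices; the emulated engines publish no score
distributions.

**What the generator does not emulate:** 3-D conformations, physically
meaningful score values or inter-function correlation structure beyond
one latent factor, assay heterogeneity, activity cliffs sharper than
fragment-level effects, and the scaffold frequency distribution of the
real campaign.  Passing tests therefore demonstrate correctness and the
direction of the method's comparative orderings under a controlled
model, not performance levels transferable to real hERG data.

## Problem sizes and numerical choices

Tests and the acceptance script run the comparative experiment at 2000
training compounds (10 seeds for ordering properties), 500-compound
external sets per dissimilarity level, and 300-compound cohorts for unit
properties — sizes at which every reported statistic is stable under
reseeding.  Degenerate inputs are handled explicitly: empty cohorts and
empty bins pass through without error, empty feature selections return
with a warning, single-class training raises, and pose tables with
duplicate keys or rank gaps fail validation with the offending keys
named.

## Known limitations

* Docking and the physics of the 25 rescoring functions are out of
  scope; their output schema is emulated only.
* The selection step does not reproduce the original 37-descriptor list
  (the training data is not redistributable); it reproduces the
  procedure.
* No hyperparameter search, gradient-boosting baselines, leverage-based
  AD, or confidence intervals on metric differences.
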