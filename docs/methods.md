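# Methods

This note records the scientific and numerical choices behind `ibspred`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the decisions taken where the
design was genuinely open.

## Problem setting

The task is per-residue binary classification: given a peripheral
membrane protein (PMP) sequence, label each residue as
membrane-interacting (part of the interfacial binding site, IBS) or not.
Two properties dominate the design. First, the positive class is rare —
about 3 % of residues — so accuracy is uninformative and both training
(class weighting) and evaluation (F1, MCC) must be imbalance-aware.
Second, annotated PMPs cluster into a handful of superfamilies, so
random protein-level splits measure "new protein, known family"
generalization, not "new family" generalization; the two are kept
distinct throughout.

## Curation

**Identity and clustering.** Pairwise identity is computed from a global
alignment and divided by the shorter sequence length, the convention of
the CD-HIT family of tools; a fragment of a longer sequence therefore
scores identity 1 against it. Clustering is greedy and incremental:
sequences sorted by descending length (ties to the lexicographically
smaller id) either join the first cluster whose representative they
match at ≥ 40 % identity or found a new cluster. The founding (longest)
member is the representative; keeping representatives only de-biases
superfamily-heavy collections. The 40 % cutoff is the conventional
remote-homology threshold and is configurable.

**Alignment.** Database (UniProt-style) and structure-resolved (PDB)
sequences of the same protein differ by terminal truncation, unresolved
internal stretches, and occasional point mutations. The aligner is
Biopython's `PairwiseAligner` in global mode with BLOSUM62, gap open 10,
gap extend 0.5, and free end gaps — end-gap freedom is what recovers the
offset mapping when one sequence is a near-exact subsequence of the
other. These parameters are exposed, not hard-coded, because reasonable
alternatives exist; the package treats them as a configurable default.

**Label transfer.** Each aligned (non-gap) column carries the source
label to the target position; unaligned target positions get 0.
Mismatched-residue columns still transfer, because structure entries may
carry engineered mutations and discarding them would lose annotation.
Consequences worth noting: transfer can only lose positives, never
create them, and a protein whose transferred vector is all-zero while
the source had positives is a red flag the pipeline surfaces (it means
the annotated region is entirely absent from the target sequence).
When a full-length database sequence inherits labels from a shorter
resolved sequence, unresolved regions end up labeled 0 — a known source
of label noise that motivates building datasets from resolved sequences
directly.

**Splits.** Always by whole protein (largest-remainder rounding of the
80/10/10 fractions, seeded permutation). Residue-level splitting would
leak near-duplicate rows across the evaluation boundary.

## Features

A residue's feature vector is its embedding row concatenated with a
21-column one-hot encoding of its amino acid (alphabetical order of the
20 canonical letters, unknown `X` last). Concatenation is the default
but can be disabled. Embedding backends are deterministic functions
`sequence → L×D matrix` behind a registry; the pLM backends of interest
(ProtTrans, D = 1024; ESM-2 650M, D = 1280) are optional heavyweight
externals, while the shipped `onehot` and `synthetic` backends keep the
pipeline testable offline. Features are stored at float32: pLM encoders
are commonly run at reduced precision, so nothing downstream may assume
more.

## Models

`ResidueClassifier` wraps five families behind one sklearn estimator
surface:

| family | backend | imbalance handling |
|---|---|---|
| `xgboost` | XGBClassifier | `scale_pos_weight` (default n_neg/n_pos ≈ 32 at 3 %) |
| `lgbm` | LGBMClassifier | `scale_pos_weight` |
| `balanced_rf` | RandomForestClassifier | `class_weight="balanced_subsample"` (per-bootstrap reweighting) |
| `slp` | LogisticRegression | optional class-weight map, off by default |
| `mlp` | MLPClassifier, one hidden layer of 64 ReLU units | optional, off by default |

Class weighting for perceptrons is off by default because it has not
been observed to help on this problem; when a class-weight map is
requested for the MLP it is honored by seeded positive-class
oversampling, since the backend accepts neither `class_weight` nor
`sample_weight`.

The decision threshold is 0.5, overridable per prediction call; a
probability exactly at the threshold is called negative, so raising the
threshold never adds positives. Training is single-threaded by default —
that is the configuration under which the boosting backends are
bit-for-bit reproducible for a fixed seed.

**MLP convergence.** Validation-score early stopping (patience 10) is
available as a hyperparameter but off by default: with small datasets
the 10 % validation split saturates within a few epochs and stops the
fit far from convergence. The default is tol-based convergence on
training loss with `max_iter` 300.

**Hyperparameter search.** A budgeted search over a declared space,
scored by validation F1 (MCC is reported alongside in evaluation but F1
is the selection metric). The reference sampler is seeded random search;
an exhaustive grid sampler covers finite spaces, and Bayesian/TPE
samplers can be plugged in through the same interface. The family's
documented defaults can be evaluated as trial 0 so the search result is
never worse than the baseline. Ties resolve to the earliest trial.
Reference budgets are 200 trials for the tree families and 50 for the
perceptrons, configurable down for tests. The defaults in
`default_hyperparameters` are sensible starting points, surfaced in
configuration rather than tuned constants.

## Evaluation

All metrics derive from the confusion matrix with positive class =
membrane-interacting. Degenerate denominators (no predicted positives,
no actual positives, zero marginals in MCC) return 0 by convention so
per-protein reports stay total — a protein with no annotated IBS resolved
as all-negative contributes F1 = 0, not NaN. Reports are produced pooled
(confusion counts summed over residues) and per protein; pooled counts
equal the elementwise sum of per-protein counts by construction. Metrics
are printed at two decimals in human-readable output; machine output
keeps full precision.

## Structure post-processing

**Reclassification.** A false-positive residue whose minimum heavy-atom
distance to any annotated membrane-interacting residue is ≤ 3 Å is
recounted as a true positive. The 3 Å radius is the range of direct
intermolecular contact; the boundary is inclusive ("within 3 Å").
Distances use heavy atoms only — deposited structures usually lack
hydrogens — and are measured to *annotated* positives, not predicted
ones. TN and FN are untouched, so TP+FP and FN+TN are preserved and
precision is monotonically non-decreasing; the reclassified set is also
monotone in the radius. The neighbor search uses a k-d tree over the
annotated residues' atoms and is required (and tested) to agree exactly
with brute-force all-pairs distances. Unresolved false positives are
left unadjusted and logged. The operation is an evaluation-side
correction for under-annotation, not a change to the training labels.

**Membrane plane.** The putative bilayer surface is the total
least-squares plane through the alpha-carbons of annotated IBS residues:
anchor = centroid, normal = direction of least coordinate variance (the
smallest-singular-value right vector), `inlier_rms` = RMS point–plane
distance. The description of the plane as aligned with the "principal
axis" of the IBS is ambiguous between this reading and taking the first
principal axis as the normal; the least-variance reading is the default
and the alternative is exposed as `normal_mode="principal-axis"`. At
least 3 non-collinear IBS alpha-carbons are required; collinearity is
detected from the singular-value spectrum. The normal's sign is fixed
deterministically (positive z, then y, then x component).

## Synthetic data

The generator emulates exactly the features of the real data that the
pipeline's behaviour depends on, and nothing else:

- **Imbalance**: positives are ~3 % of residues in expectation, placed
  as 1–2 contiguous interior patches (IBS regions are contiguous
  secondary-structure elements, not scattered residues).
- **Family structure**: round-robin tags over 9 families by default.
- **Embeddings**: unit isotropic Gaussian noise plus a positive-class
  mean shift of magnitude `signal_strength`, drawn once per seed from
  the unit sphere. The default 10.0 ("strong") makes the classes
  essentially separable by construction — ten noise standard deviations
  between class means; 0.0 removes all label signal. In
  `family-specific` mode each family draws its own shift direction, so a
  classifier trained on a subset of families has no usable signal for
  the rest — the switch that reproduces the unseen-superfamily failure.
- **Structures**: a self-avoiding random walk with 3.8 Å CA steps
  (non-adjacent CAs ≥ 3.5 Å apart), plus a carbonyl-like second atom at
  each CA→CA midpoint so that sequence-adjacent residues are within
  ~1.9 Å — the peptide-bond-scale contact the 3 Å reclassification rule
  relies on. IBS residues' CA z-coordinates are replaced by values
  within `coordinate_noise` of zero, so the fitted membrane plane is
  exactly z = 0 at zero noise.

Everything is a pure function of (config, seed).

What passing tests on this generator shows: the pipeline's mechanics are
correct (features reach the classifier aligned with their labels,
imbalance handling works, the family-holdout contrast behaves as the
theory of the generator predicts, geometry operations are exact). What
it does not show: anything about real pLM embedding geometry, real fold
topology, or real annotation noise — performance numbers on synthetic
fixtures say nothing quantitative about accuracy on experimental data.

## Problem sizes

The shipped experiments run on 60 proteins of length 80–160 (~7000
residues, embedding dimension 32), which is ample for the separable
strong-signal construction while keeping any single experiment in the
seconds-to-minutes range on one CPU. Larger fixtures change none of the
qualitative behaviour.

## Known limitations

- The pLM backends are contracts, not implementations; reproducing
  embedding-based results on real proteins requires installing the
  optional dependencies and downloading multi-gigabyte weights.
- The balanced random forest uses per-bootstrap class *reweighting*;
  implementations that *undersample* the majority class per bootstrap
  will differ in the exact fitted model, though both address the same
  imbalance mechanism.
- Greedy identity clustering matches the external tool's contract, not
  its exact cluster-by-cluster output: the tool uses word-filter
  heuristics and its own alignment engine, so cluster boundaries can
  differ near the cutoff.
- `read_structure` treats author residue numbers as 1-based sequence
  positions; structures with insertion codes or non-sequential numbering
  need renumbering upstream.
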