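# Methods

## Classification model

Each candidate SNV is represented by the reference-strand sequence window
of 2·f+1 bases centred on it (default full window f = 100, i.e. 201 bp).
Windows are taken from the reference as given — no reverse-complementing —
because upstream callers report reference-strand alleles; for unstranded
callers a flag (`collapse_revcomp_a2i`) lets T→C count as A-to-I in the
mismatch statistics. Bases encode one-hot in channel order A, T, C, G;
N and out-of-contig padding encode as the all-zero row, which keeps the
input dimensionality fixed and is signal-neutral. Coordinates are 1-based
and closed, matching VCF, everywhere in the API and file formats.

The classifier is a four-level averaging hierarchy (net → bagged ensemble
→ multi-scale module → gold-set component → separate+pooled average);
every level outputs a probability triple over {editing, SNP, other} and
every combination step is an unweighted arithmetic mean, so the hierarchy
is associative-in-effect: averaging members then modules equals a
weighted mean over leaf nets. Individual nets are softmax MLPs (ReLU
hiddens, default sizes 1000 and 100) fit with Adam; training is
deterministic given the seeds. Fitting is delegated to scikit-learn's
`MLPClassifier`; the fitted weights are extracted into plain numpy arrays
and the forward pass is evaluated in-package, which makes serialized
models (a single `.npz` archive holding a JSON manifest, a spec hash
verified on load, and raw weight blocks) reload bit-exactly.

### Class imbalance and cross-validation

Real candidate lists are dominated by non-editing SNVs. Each ensemble
member is trained on a *balanced bootstrap*: the same number of examples
drawn with replacement from each class, defaulting to the size of the
smallest class. Cross-validation is stratified k-fold (default k = 5)
with balancing applied inside training folds only, never to test folds,
so held-out estimates reflect the natural class mix.

### Seeds

All randomness flows from one master seed through
`derive_seed(master, level, module_index, member_index)`, implemented
with `numpy.random.SeedSequence`; derived seeds are < 2^31. Distinct
hierarchy paths give independent streams, so retraining any sub-tree
reproduces it exactly.

### Calling and tie-breaking

A candidate is called an editing site when its editing probability is
*strictly* greater than the cutoff (default 0.5; the cutoff is a
use-case-dependent precision/recall dial, so the CLI exposes it). Where a
hard class assignment is needed, argmax ties break in the order editing <
SNP < other; exact ties do not occur in float practice but the rule is
fixed for reproducibility.

## Evaluation statistics

* Confusion metrics over an experimentally verified panel: accuracy,
  sensitivity, specificity, GM = √(sens·spec), PPV. The "F1" reported
  alongside such panels in this literature is the harmonic mean of
  sensitivity and specificity — we verified this definition reproduces the
  published tables from back-solved integer counts, and expose it as
  `f1_sens_spec`, with the textbook precision/recall harmonic mean available
  as `f1_textbook`. Validation rate and misclassification rate are defined
  as (tp+fp)/n_predictions and fp/n_predictions; published values of these
  two columns are not exactly derivable from published counts, so our
  definitions approximate them (28.74%/0.60% vs 29.01%/0.62% on the
  reference panel) and are documented rather than fudged.
* ROC-AUC (equals the Mann–Whitney statistic, ties at ½) and PR-AUC (the
  step-wise precision-recall integral); both are delegated to scikit-learn
  and property-tested against brute-force all-pairs / exhaustive-sweep
  oracles on small instances.
* Annotation-free proxies: the A-to-I ratio of a call set, and the
  equal-error-rate FDR — assume every non-A-to-I call is false and that
  the 12 mismatch types err at equal rates, so false A-to-I calls ≈
  (total − A-to-I)/11 and FDR = that over the A-to-I count.
* Reproducibility overlap of two call sets is offered both as Jaccard
  (default) and as intersection over the smaller set, because "overlap
  ratio" is underdetermined in the literature; homologous ratio is the
  fraction of identified sites with an orthologous site in another species.
* Undefined ratios (zero denominators) are reported as absent (`None`),
  never 0.

## Synthetic-data generator

The generator emulates only the statistics the classifier is supposed to
exploit, on an i.i.d. random genome at configurable GC content:

* **composition** — positives are A→G with probability 0.863, negatives
  with probability 0.348 (otherwise a uniform draw over the remaining
  mismatch types); these defaults mirror the composition of real
  separate/pooled gold-standard sets;
* **neighbour preference** — at full signal strength the 5′ neighbour of
  a planted editing site is G with probability 0.05 (depletion) and the
  3′ neighbour with probability 0.70 (enrichment). The literature gives
  the direction but not magnitudes; these values are our fixed convention,
  chosen to be strong but not deterministic;
* **positional decay** — offsets 2..25 carry a class-signature base (C on
  the 5′ side, G on the 3′ side) with probability
  `signal_strength · 0.5 · (1 − (|offset|−1)/25)`, linear in distance;
* `signal_strength` interpolates *every* planted probability between
  genome background (0) and its target (1), so zero strength is an exact
  null.

Planted windows never overlap (rejection sampling against an interval
tree, with a retry limit that raises rather than thrash on infeasible
configurations). SNP and OTHER negatives are distributionally identical by
default — a transition-bias knob can separate them — so the generator
certifies editing-vs-rest discrimination, not three-way separability.
Coverage fields are negative-binomial draws that exist solely to exercise
the depth filter (total ≥ 5, supporting ≥ 3). Outputs (FASTA, VCF, labels
TSV, JSON manifest) are byte-deterministic under the master seed.

What passing tests on this generator do **not** show: robustness to
non-i.i.d. genomic background (repeats, homopolymers, GC structure),
alignment-induced artifact patterns, strand ambiguity, or cross-cell-type
heterogeneity — the gold sets partitioned from one synthetic dataset are
exchangeable, unlike real cell types.

## Problem sizes in the test suite

The default verification profile uses reduced hierarchies so the suite
runs in well under a minute of training time on one CPU: 41–51-bp windows,
members with a single 32-unit hidden layer, 10–12 Adam epochs, 2–20
members, and 150–1500 candidates per class (the ensemble and
importance-recovery checks use 1000 training / 500 test per class over 5
and 3 seeds respectively). The paper-faithful sizes (201-bp windows,
1000/100 hidden units, 20 members × 2 scales × 11 modules × 2 components)
remain the library defaults and are reachable through the same flags.

## Known limitations

* Three-way SNP/OTHER separation is only meaningful when the generator's
  transition-bias knob (or real labels) makes the classes distinct.
* The exact "modified" element of the original 5-fold cross-validation
  procedure is not public; we use stratified folds with in-fold balancing.
* Training epochs, optimizer and initialisation are not dictated by the
  source architecture; they are config fields with logged defaults.
* The permutation importance operation reports drops in macro one-vs-rest
  AUC; it is model-agnostic but, like all permutation importances,
  understates the joint contribution of correlated positions.
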