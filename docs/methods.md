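# Methods

## Problem setting and model

The package classifies candidate RNA sequences into miRNA precursor
hairpins (positive class, label 1 throughout) and pseudo-hairpins. The
classification model is deliberately generic: any *scorer* mapping a
feature vector to a real s(x), higher meaning more precursor-like, can be
used. The shipped default is a scikit-learn random forest whose score is
the fraction of trees voting positive; a Gaussian naive Bayes factory is
included as a smooth-score alternative, and any classifier exposing
`predict_proba` adapts via `classifiers._proba_trainer`.

The contribution-bearing step is not the classifier but the decision
rule. On imbalanced data the default cut (score ≥ 0.5) is strongly biased
toward the majority class, so the package selects the threshold on the
ROC curve instead:

1. **Pooled internal CV.** A stratified k₁-fold split of the training
   data (default k₁ = 10); each instance is scored by a model trained on
   the other folds; the out-of-fold (score, label) pairs are pooled into
   one set. Pooling, rather than vertical/threshold averaging of
   per-fold curves, is the chosen curve-averaging strategy: the selected
   threshold should reflect the pooled score distribution the final
   model will see.
2. **ROC construction.** Scores are sorted decreasing; one operating
   point is emitted per distinct score value v (decision rule: positive
   iff s ≥ v), preceded by the all-negative point (T = +∞). Tied scores
   move together, so the emitted points are exactly the achievable
   confusion matrices of threshold rules — verified in tests against
   brute-force enumeration of every cutpoint.
3. **Selection.** The point maximising the evaluation functional —
   Gm = √(SE·SP) by default, F1 or any `ConfusionCounts -> float`
   callable alternatively — is chosen. Ties break toward higher
   sensitivity, then toward the lower threshold: in screening
   applications a missed precursor costs more than a spurious candidate.
4. **Persisted threshold.** The stored T is the midpoint between the
   selected distinct score and the next higher distinct score (the score
   itself at the top extreme; +∞ for the all-negative rule), making
   classification robust to small score jitter when the final model is
   retrained. The function returning the selected ROC point reports the
   raw distinct score; the midpoint transformation happens at model
   assembly.
5. **Final fit.** The scorer is retrained on the full training set and
   bundled with threshold, k₁, seed, metric name and tuned parameters.
   Whether to retrain after threshold selection is not forced by the
   procedure itself; retraining is standard practice and is recorded in
   the model manifest.

Parameter tuning precedes threshold selection: a Cartesian grid (axes in
lexicographic name order; default random-forest grid 10, 21, …, 219
trees, λ = 20 points) is scored by mean Gm over k₂ stratified folds
(default k₂ = 5, trading roughly half the tuning time against 10-fold at
slightly inferior selection quality), each grid point at the classifier's
default 0.5 cut, with one fold split shared across points so the
per-point table is deterministic. Tuning at the default threshold treats
tuning strictly as the step preceding threshold selection; a
`nest_roc_select` flag runs ROC-select inside the tuning loop for users
who accept k₁ extra fits per grid point.

## Features

Seven dedicated attributes are always computed in extended mode:

| name | definition | range |
|---|---|---|
| tri_A/U/G/C | frequency of structure triplet "X(((" — map ')' to '(' in the dot-bracket string, count interior positions i whose window structure[i−1..i+1] is "(((" and whose nucleotide is X, divide by L−2 | [0,1] |
| orf | longest run of consecutive non-stop codons (stops UAA/UAG/UGA) over the three forward frames, in codons; forward strand only, since a hairpin candidate has a defined orientation | 0..⌊L/3⌋ |
| loops | cumulative unpaired bases in internal loops and bulges of the MFE structure (see loop decomposition below) | ≥ 0 |
| dm | percent of bases masked by symmetric DUST, window 64, subwindow score threshold 15 (lowered from the usual 20 to catch milder low-complexity runs) | [0,100] |

The DUST scan is implemented in-process: intervals of the triplet
sequence score Σc_t(c_t−1)/2 normalised by (l−1); an interval is masked
when 10·score > threshold and no proper subinterval scores higher
("perfect" intervals), considering only intervals within a 64-base
window. The implementation reproduces NCBI `dustmasker -level 15` output
exactly on the test battery (homopolymers, di-/tri-repeats, random and
embedded-repeat sequences); masked-interval coverage (merged union) is
counted when intervals overlap.

The base representation is tiered because the exact historical feature
sets of earlier tools are not fully reproducible without their original
scripts; the tiers are a documented substitute, and `FeatureSpec` is
deliberately configurable so externally computed columns can be used
instead:

* **Tier A** (default, any backend): GC content; dG = MFE/L;
  MFEI1 = dG/GC; MFEI2 = dG/#stems; MFEI4 = MFE/#pairs; dP = #pairs/L;
  per-type pair densities |A−U|/L, |G−C|/L, |G−U|/L; mean pairs per
  stem. Degenerate structures (no pairs or stems) set the affected
  ratios to 0 instead of failing, so genome-window negatives never
  crash extraction.
* **Tier B** (partition function, ViennaRNA only): ensemble free energy
  / L, MFE-structure frequency, ensemble diversity / L, mean positional
  Shannon entropy of pair probabilities.
* **Tier C**: z-scores of dG and dP against n_shuffle = 100
  dinucleotide-preserving shuffles (Altschul–Erickson Euler-walk scheme;
  the exact dinucleotide count multiset is asserted on every shuffle);
  sd = 0 yields z = 0.

Per-record randomness derives from `(seed, crc32(record id))`, so feature
tables are reproducible and independent of batch composition. Records
containing N are excluded from extraction (folding is undefined on N) and
reported in a failure list rather than aborting the batch.

## Secondary structure

Two backends satisfy one contract (deterministic single-structure MFE
folding): ViennaRNA (default; thermodynamic nearest-neighbour model) and
a built-in Nussinov-style maximum-pairing dynamic programme (minimum
hairpin loop 3, canonical + G-U pairs, energy proxy −1 kcal/mol per
pair) so the package and its tests run without any external
thermodynamics code. Feature values are backend-dependent, so bundles
carry a backend tag and classification refuses a mismatched runtime.

Dot-bracket parsing uses the standard loop-tree decomposition: every
pair whose interior is not a single stacked pair closes a loop; a loop
with exactly one enclosed helix and ≥ 1 unpaired base is an internal
loop or bulge and contributes all its unpaired bases to `loops`;
hairpin loops, multiloops and exterior bases do not. Stems are maximal
runs of directly stacked pairs. Multi-hairpin structures are allowed —
no structural assumptions are imposed on candidates.

## Negative-set construction

Window lengths are resampled from the empirical positive length
distribution (exact distribution equality is ill-defined for finite
draws; a two-sample KS test at α = 0.01 verifies the match in tests),
chromosomes are drawn proportionally to length, starts uniformly;
windows containing N are rejected and redrawn within a bounded retry
budget (assembly gaps cannot be folded). Windows come from the given
strand by default; a flag samples the reverse complement with
probability 0.5. Emitted ids encode `source:start-end`, 1-based
inclusive.

Homology exclusion defaults to a deterministic, dependency-free
seed-and-extend scan (shared 11-mers extended to maximal exact runs;
candidates with a run ≥ 20 nt against any reference are removed). When a
BLASTN executable is configured, filtering uses its E-values at the
1e-2 cutoff instead — E-values are database- and version-dependent, so
this mode is delegated rather than reimplemented, and a configured but
missing executable is an error, never a silent mode switch.

Structural QC reports the fractions of records with MFE/L < −0.05 and
pairing density > 0.15. These criteria are deliberately loose — most
fold-prone sequences satisfy them — so they characterise a negative set
rather than filter it.

## Evaluation

The outer harness is stratified k-fold CV (default 10) with the whole
pipeline (tuning, then threshold selection) nested inside each training
partition; train/test id-disjointness is asserted per fold. Outer-fold
confusion counts are pooled before computing SE/SP/Gm (micro-averaging;
stable when folds hold few positives), with a macro flag for per-fold
averaging. Fold assignment can be keyed by instance id, making results
invariant to input order. Friedman rank tests (rank 1 = best Gm, average
ranks on ties) use the χ² approximation with Nemenyi critical difference
CD = q_α·√(k(k+1)/(6N)), q tabulated for k ≤ 10 at α ∈ {0.05, 0.10};
the Wilcoxon signed-rank test drops zero differences and is exact for
n ≤ 25 (normal approximation above). On five all-positive differences
the exact two-sided p is 0.0625 — the smallest attainable at n = 5 —
and that exact value is what the implementation reports.

## Synthetic data

Generators are pure functions of `(seed, call-site tag)` streams, so
adding calls never perturbs existing outputs. Hairpins are explicit
stem-loops: random 5' arm (GC bias configurable, default 0.5), random
loop, 3' arm = reverse complement with configurable point mismatches and
bulge insertions; stems of 15–30 pairs with loops of 4–10 nt mimic
precursor-like dimensions, and dataset negatives are i.i.d. sequences
length-matched to the generated positives so length carries no class
signal. Ids come from one shuffled namespace. Two-Gaussian score
problems and shifted-Gaussian feature matrices (default shift 1.5 sd per
axis — strongly overlapping single features) exercise the threshold
machinery without folding or classifiers.

What passing tests on these fixtures shows: the algorithmic pipeline is
correct (oracle-exact threshold selection, leak-free nesting, calibrated
statistics) and the imbalance behaviour is reproduced (ROC-select beats
the default cut out-of-sample in ≥ 95% of seeded 50:2500 repetitions).
What it does not show: performance on real precursors, whose hairpins
are evolutionarily constrained, GC-heterogeneous and multi-loop in ways
the generator does not emulate; synthetic hairpins vs i.i.d. background
are far more separable (Gm ≥ 90 at desk scale) than miRBase positives vs
genomic pseudo-hairpins.

## Numerical and scale choices

* SE/SP/Gm are percentages (0–100) in all public APIs; internal ROC
  arithmetic is on counts.
* Test and acceptance problem sizes are desk-scale by design: 50:2500
  synthetic instances (imbalance 50, between the published taxon sets'
  3.5 and 122.8), 20 repetitions for the win-rate experiment, 400
  random score sets for the oracle check, reduced grids (3–5 points)
  and fold counts in end-to-end smoke tests. Defaults in the library
  itself (k₁ = 10, k₂ = 5, 20-point tree grid) are the method's
  standard operating configuration.
* Fold determinism: scikit-learn `StratifiedKFold(shuffle=True,
  random_state=seed)` everywhere; the random forest's `random_state` is
  pinned by the trainer factory, so a bundle retrained from the same
  inputs reproduces scores to floating-point identity.
* Degenerate inputs: constant-score classifiers degrade to the
  majority/minority rule without error; single-class folds and metric
  evaluation on single-class samples raise immediately with actionable
  messages.

## Known limitations

* The Nussinov fallback maximises pairing count, not stability: random
  sequences reach high pairing densities under it, so thermodynamic
  discrimination (MFE-based features, QC pass-rate contrasts) is much
  weaker than under ViennaRNA. It exists for portability, not accuracy.
* Tier B features require ViennaRNA; there is no fallback partition
  function.
* The built-in homology filter is an exact-match heuristic; it does not
  model gapped or degenerate similarity. Use the BLASTN mode for
  production negative sets.
* Melting-temperature features and web-sourced precomputed feature sets
  are out of scope.
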