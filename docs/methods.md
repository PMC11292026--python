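# Methods

## Problem setting

A single gene's curated missense benchmark consists of a disease set
(variants with pathogenic clinical assertions or HGMD "DM" status), a
neutral set (variants asserted benign, or present only in population-scale
resources and therefore *presumed* benign), and a VUS set that is scored
but never used for training. Pathogenicity predictors emit one numeric
score per variant; a threshold turns the score into a binary call. The
package measures how well developer-default thresholds work on such a
benchmark and learns gene-specific replacements.

## Classification semantics

Each tool is described by a `ToolSpec`: direction (ascending = higher
score ⇒ more pathogenic; SIFT4G is the one descending tool), comparison
(inclusive = a score exactly at the threshold is pathogenic), default
threshold, and score bounds. The packaged registry holds the ten tools of
record with the sub-score conventions standard for Mendelian work
(CADD-phred, BayesDel AddAF, Eigen raw coding, PolyPhen-2 HumVar); the
BayesDel AddAF default 0.0692655 follows the published AddAF convention
and is logged as an assumption at load time. Where a tool's documentation
is ambiguous about the comparison operator, strict is used — the choice
matters only for variants scoring exactly at the threshold.

Missing scores are handled by per-tool complete-case analysis: a variant
without a score for tool T is dropped from T's confusion matrix and
counted, never imputed.

## Metrics

Sensitivity, specificity, accuracy and PPV are the usual confusion-matrix
ratios; a zero denominator yields NaN for these. MCC is computed with
exact integer products before a single floating division and is defined
as 0 when any marginal is empty (a constant classifier carries no
signal). Reports render percentages at 0 decimal places and MCC at 2;
internal computation is always full precision, and every rendered number
also appears unrounded in the run manifest.

`reconstruct_confusion` inverts a published table's rounded Sn/Sp back to
integer counts (nearest integer, halves away from zero). The
reconstruction is exact only up to the printed rounding, so a derived PPV
can disagree with a printed one by a single count's worth — the
round-trip property guaranteed (and tested) is that re-deriving Sn/Sp
from the reconstructed counts lands within the rounding resolution
(50/n percentage points) of the inputs.

## Threshold sweep

Candidate thresholds are the distinct observed scores plus one sentinel
beyond each extreme, so the all-pathogenic and all-benign partitions are
reachable. Evaluating any threshold strictly between two consecutive
observed scores induces the same partition as the nearer observed score
under the tool's native comparison operator, so this candidate set is
complete by construction; midpoint candidates would add nothing and are
not used. The sweep is a sort plus vectorised rank lookups (O(n log n));
the test suite keeps an O(n²) from-scratch re-evaluation as an
independent oracle and checks exact agreement on a thousand randomized
instances.

Ties on maximal MCC are broken toward the highest specificity, then the
most stringent threshold (largest for ascending, smallest for
descending): in a diagnostic setting a false pathogenic call is the more
costly error. The choice is deterministic and row-order invariant.

A consequence worth knowing: with inclusive semantics on separable data
the learned threshold sits exactly on the smallest disease score seen in
training, so a held-out variant scoring below every training disease
score is (correctly) called benign. Generalisation is measured by
cross-validation, not assumed.

ROC points fall out of the same sweep; AUC is trapezoidal. No smoothing,
interpolation, or confidence intervals — MCC, not AUC, is the objective.

## Majority-rule ensemble

A panel calls a variant pathogenic when strictly more than half its
members do ("agreement of over 50%"); an even split is benign, which
makes two-tool panels unanimity panels. Variants missing any member score
are excluded from that panel's evaluation and counted. The framework
always reports single-tool and panel MCC side by side: whether a panel
beats the best single tool is a queryable result, not an assumption.

## Validation

- **k-fold CV** (default k = 5): simple random, seeded fold assignment,
  sizes differing by at most one; a draw leaving any fold without one of
  the classes is redrawn with an incremented seed (logged, bounded
  retries). A `stratified=True` mode exists for users. Per fold the
  threshold is learned on the k−1 training folds only and all five
  metrics are computed on the held-out fold; the summary reports the mean
  and *sample* standard deviation (ddof = 1) over the k folds.
- **Transfer**: thresholds optimised on the training (primary) dataset
  are applied unchanged to an independent test (secondary) dataset,
  alongside the defaults, plus a majority-vote row for the top-three
  training tools.
- **VUS re-scoring**: calibrated thresholds applied to unlabeled
  variants, with per-variant pathogenic-vote counts and concordance
  flags.
- **Contamination**: a seeded fraction of disease records is relabeled
  neutral (direction configurable; the default models pathogenic variants
  hiding among presumed-benign population records), the threshold is
  re-optimised and metrics are recomputed against the contaminated
  labels. Default grid: fractions {0.05, 0.10, 0.20} × 10 seeds. Exactly
  `round(fraction × n_disease)` records flip, halves away from zero.

## Synthetic benchmark generator

The generator's defaults state the world the pipeline is built for:
167 disease and 74 neutral variants (241 total) on a 422-residue protein
whose pathogenic variants fall inside one of two DNA-binding domain
intervals (defaults 4–130 and 210–269, UniProt-style annotation supplied
as config, not hard-coded) with probability 0.9; ten tools; disease
scores Beta(8, 2) and neutral scores Beta(2, 8) rescaled to each tool's
declared range (Normal(±1, 1) for the unbounded Eigen raw score);
inter-tool correlation 0.5; missing-score rate 0.02; no contamination.

Rationale for the values not fixed by the setting itself: Beta(8, 2) vs
Beta(2, 8) gives class means 0.8/0.2 — a strongly but not perfectly
separating predictor, the regime where threshold choice matters;
correlation 0.5 reflects that several tools are meta-predictors sharing
inputs; 2% missingness matches the occasional absent dbNSFP score. These
are configuration defaults, chosen once, not tuned to any test outcome.

Correlation is induced by a per-variant latent liability: each tool's
quantile is Φ(√ρ·z + √(1−ρ)·e) with z shared and e tool-specific, pushed
through the class-conditional marginal, so marginals are exact while
tools correlate at ρ. For descending tools the draw is reflected within
the score range, reversing the class-conditional ordering (disease scores
low) while the config distributions stay on the common "pathogenicity"
scale. VUS records are scored as a fair mixture of the two classes.
All randomness flows from the single config seed; identical config and
seed reproduce identical tables byte for byte.

What the generator does **not** emulate: nucleotide context, allele
frequencies, database-specific quirks, per-tool idiosyncratic score
shapes (real SIFT4G mass concentrates near 0, so its default threshold
fares worse here than on real data), or correlated missingness. A green
test on synthetic data therefore establishes the machinery — sweep
optimality, CV hygiene, report arithmetic — not any claim about real
tools' relative performance.

## Curation decisions

- Duplicate key is the genomic `chrom:pos:ref:alt` identifier: two
  nucleotide changes causing the same amino-acid substitution stay
  distinct, matching per-variant scoring granularity. Merged duplicates
  union their sources and concatenate distinct assertions; an uncertain
  assertion anywhere in the group forces the VUS label, otherwise a
  disease claim dominates.
- No allele-frequency filter is applied to population sources: presence
  in a controls/biobanks cohort alone is "presumed benign".
- A record asserted pathogenic *and* present in a population resource is
  contradictory; the default policy excludes and counts it, with
  `disease_wins` / `neutral_wins` selectable.
- An unlabeled record carrying a clinical (non-population) source but no
  usable assertion is binned as VUS — uncertain by default rather than
  guessed.
- Coordinates are GRCh38 only; build liftover is upstream scope and
  GRCh37 input is rejected, not converted.

## Known limitations

- Threshold transfer assumes the two datasets share score columns and
  scale; no recalibration of the scores themselves is attempted.
- The contamination experiment evaluates against the contaminated labels
  (as a blinded analyst would); it does not report metrics against the
  true labels, which the generator would permit.
- No confidence intervals on single-run metrics; uncertainty is exposed
  only through the CV fold spread and the contamination seed grid.
- `reconstruct_confusion` cannot disambiguate printed tables whose
  rounded Sn/Sp/PPV triples are jointly inconsistent with any single
  integer matrix; it fixes Sn/Sp and lets PPV fall where it may.
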