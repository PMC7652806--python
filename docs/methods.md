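# Methods

## Labeling model

A SNP call for one sample at one position is labeled by comparing the
unordered allele pair implied by the VCF genotype with the unordered
array-genotype pair at the same position:

* **excluded** — either genotype is missing (`./.` in the VCF or `.` in
  the array table). Excluded sites never enter training.
* **correct** — the pairs are identical.
* **incorrect** — any other case (a mismatch in at least one allele).

For multi-allelic records the called genotype *pattern* is reinterpreted
within every biallelic subset {ref, alt_i} (index 0 → ref, any non-zero
index → alt_i); the call is correct if the array pair matches the called
pair or any reinterpretation. This is the most permissive deterministic
reading of "at least one alternative allele allowed for a match", and it
makes the multi-allelic rule a strict relaxation of biallelic matching.

Assumptions: array alleles are already expressed on the reference forward
strand (no A/B or TOP/BOT conversion; a `strict_array` flag rejects array
alleles outside {ref} ∪ alts); chromosome names match the VCF verbatim
unless an alias map is supplied; array positions absent from the VCF are
reported as excluded-by-absence, not as errors, because calling is assumed
to have been restricted to array positions.

## Features

Seven VCF-derivable variables per (site, sample):

| variable | type | source | notes |
|---|---|---|---|
| QUAL | quantitative | column 6 | Phred-scaled P(alt allele is wrong) |
| GQ | quantitative | FORMAT/GQ | Phred-scaled conditional genotype quality; frequently absent |
| DP | quantitative | INFO/DP | depth over all samples |
| DP2 | quantitative | FORMAT/DP | depth for the individual |
| CALL | categorical | FORMAT/GT | 1 = ./., 2 = 0/0, 3 = 0/1, 4 = 1/1 |
| UP_TRIO | categorical | reference | bases pos−3..pos−1, forward strand |
| DOWN_TRIO | categorical | reference | bases pos+1..pos+3, forward strand |

Quantitative features are z-scored with training-set mean and *population*
standard deviation (documented so tests are exact); "transformed into the
standard normal distribution" is read as z-scoring, with a rank-based
inverse-normal option behind `FeatureSpec(standardize="rank_int")` for
sensitivity analysis. Features whose training missingness exceeds
`missingness_threshold` (default 0.2) are dropped — on benchmark-like data
this removes GQ, which lacks an estimate for ~24% of records; remaining
missing values in retained features are imputed with the training mean.
Categoricals are one-hot encoded against a vocabulary fixed at fit time:
the four CALL codes, and for trios all 64 ACGT triplets plus any
N-padded triplets observed in training (chromosome ends are padded with
N). Unseen levels at transform time encode as all-zeros (lenient default)
or raise (strict). Encoding is deterministic; the column metadata maps any
column index back to its (feature, level).

## Rare-event mitigation

With ~2% positives the unweighted loss is dominated by the correct class.
Two mitigations, selectable per run:

* **Class weights** `w_c = (N_c + N_i)/(2 N_c)`, `w_i = (N_c + N_i)/(2 N_i)`
  enter the loss as per-row multipliers. The frequency-weighted mean
  weight is exactly 1 (algebraic identity, asserted to 1e-12), so the
  overall loss scale is unchanged.
* **Oversampling** duplicates incorrect rows (sampling with replacement)
  until their count reaches `ratio` × the correct count, with presets
  OVERSAMPLED30/60/100. Every original incorrect row is included at least
  once before the remainder is drawn — with only hundreds of distinct
  minority rows, dropping any of them loses information. A target below
  the existing minority count is rejected (oversampling only enlarges).
  Oversampling happens *after* the OPTset split, so the early-stopping
  subset contains no duplicates.

## Network and training

Eight dense layers, default widths (128, 64, 48, 32, 16, 8, 4, 1)
(configurable; exactly eight, non-increasing, head of width 1), ReLU in
layers 1–7, sigmoid head emitting **P(call is incorrect)** — the rare
class is the positive class in every metric, and a printed "probability
of being correct" is simply the complement. Inverted dropout (rate 0.2)
is applied after the activations of layers 1–5 during training. The
network, backpropagation and Adam are implemented in NumPy
(`snpveracity.nn`); gradients are verified against central differences in
the test suite, and training is bit-for-bit reproducible given the
configuration seed because all randomness (initialization, shuffling,
dropout) flows from one `numpy.random.Generator`.

Optimization: Adam with the standard published defaults (step 1e-3,
β₁ 0.9, β₂ 0.999), batch size 512, at most 500 epochs. A stratified 10%
OPTset is split from the training rows (scikit-learn stratified split);
training stops after 25 consecutive epochs without OPTset-loss
improvement and the best-epoch weights are restored (so the delivered
model is the one the monitor preferred, not the last one). With
`optset_fraction=0` early stopping is disabled and training runs to
`max_epochs`. Per-epoch loss, precision and recall on both the training
rows and the OPTset are recorded, sufficient to re-plot learning curves.

During development we also swept narrower stacks (first width 16–64);
they performed consistently worse on held-out recovery of synthetic
signal, so the wide default stands. Very narrow stacks (bottlenecks of
width 2) can die entirely (all-negative ReLU pre-activations); the test
suite pins this boundary.

## Cutoff estimation

The metric (F1 or SUMSS) is piecewise constant in the cutoff, so the
optimum is found *exactly* over the candidate set {distinct observed
probabilities} ∪ {0, 1}; ties return the smallest maximizer, and the
classification rule at the boundary is `p ≥ cutoff ⇒ incorrect` (cutoff 0
therefore means "everything positive"). A dense-grid brute-force oracle
(step 0.001) cross-checks the optimizer in the tests. The reported cutoff
is the mean over `n_bootstrap` (default 100) full-size resamples drawn
with replacement from the training predictions; single-class resamples
are redrawn up to a retry cap. Robustness is assessed by repeating the
whole estimate on 20 independent sub-samples (treated as full-size
resamples; no sub-sample size is prescribed) and reporting the spread.
Validation data are always evaluated at cutoffs estimated on training
data — never re-fit on validation.

## Synthetic generator

The generator emulates the benchmark's *labeled feature table*: a fixed
fraction of rows (default 2%, exact count by rounding, so class counts
are deterministic) is incorrect, and the two classes differ in DP, DP2,
QUAL and genotype-class composition. Default per-class moments are the
benchmark training-data characteristics (correct: DP 37.91 ± 11.66,
DP2 9.53 ± 4.16, QUAL 484.15 ± 430.14; incorrect: 30.68 ± 13.21,
6.20 ± 4.09, 365.74 ± 318.29; genotype-class proportions from the
published per-class counts). Floors follow the published ranges (DP,
DP2 ≥ 1; QUAL ≥ 10); DP and DP2 are rounded to integers.

Quantitative features are drawn from lower-truncated normals whose
*realized* moments match the configured values: the parent (μ, σ) is
solved from the target mean/SD and floor (the SD-to-(mean−floor) ratio of
a lower-truncated normal is monotone in the truncation z-score, so the
solution is unique via Brent's method). This matters because the QUAL
floor sits only ~1.1 SD below the QUAL mean — naive truncation of
N(mean, sd) would inflate the realized mean by ~20%. When a target is
infeasible (mean at or below the floor, or SD ≥ mean − floor) the
generator warns and falls back to naive truncation, which piles mass just
above the floor. One visible consequence of moment matching: the
correct-class QUAL distribution is strongly right-skewed with substantial
density near the floor, like the heavy-tailed QUAL distributions of real
callers.

The `separation` knob scales the class signal: the incorrect-class means
move away from the correct-class means linearly in `s`
(`m_i(s) = m_c + s·(m_i − m_c)`), while SDs and genotype composition
interpolate only on s ∈ [0, 1] and stay at their class values beyond.
Thus s = 0 is an exact null (both classes share one distribution), s = 1
reproduces the benchmark conditions, and s > 1 exaggerates the mean
differences without sharpening the distributions. GQ carries no class
signal and is masked missing at rate 0.244 (its values, drawn from a
clipped normal around 55, are arbitrary — the feature exists to exercise
the missingness-dropping path). Trios are uniform over the 64 triplets
(no context signal), and no correlation between features is modeled —
real QUAL and DP are strongly dependent; the generator's marginals-only
design means passing tests demonstrate pipeline correctness, not
real-data performance.

`generate_fixture_files` round-trips the table through real formats: a
synthesized reference FASTA containing the recorded trios around each
site (sites every 10 bp, ≥ 4 bp from the ends), a VCF v4.2 carrying
QUAL/INFO:DP/GT:GQ:DP (parseable by pysam/bcftools), and an array TSV
written so concordance labeling reproduces the generated labels exactly.

## Problem sizes used in checks

The repository's own end-to-end checks run at desk scale, chosen so each
check's statistics are decisive: **signal recovery** uses n = 20,000
sites (2% incorrect), separation 10.0, OVERSAMPLED100, bootstrap SUMSS
cutoff, 80/20 train/validation split — at that separation the class
distributions are essentially disjoint (the floors capture the incorrect
class), so held-out sensitivity and specificity ≥ 0.9 is a correctness
oracle: a miss indicates a pipeline defect, not irreducible overlap. At
moderate separation (~3.5) even the Bayes classifier sits near the
0.9/0.9 corner on these marginals, and the 128 uninformative trio columns
let the network partially memorize the few hundred distinct minority
rows, so that regime tests Bayes-proximity rather than correctness.
**Null calibration** uses n = 10,000 at separation 0; held-out SUMSS is
asserted within 0.15 of 1.0, ≈ 3 binomial standard errors of the held-out
sensitivity with ~100 minority rows (1/√100 ≈ 0.1 dominates the band;
specificity contributes negligibly).

## Numerical choices and degenerate inputs

* Population (ddof 0) SD in the standardizer; summary tables report
  sample (ddof 1) SD as characteristics tables conventionally do.
* Zero-variance features are dropped with a warning; an all-dropped
  quantitative block is a fatal configuration error.
* BCE probabilities are clipped at 1e-12 from both ends.
* Non-finite training loss raises immediately with diagnostics.
* `encode_call` in lenient mode maps any heterozygous index pattern
  (e.g. 1/2) to code 3 and any non-reference homozygote (e.g. 2/2) to 4;
  strict mode accepts only the four canonical patterns.
* Ties in cutoff optimization return the smallest maximizer; F1 is 0 when
  its denominator is 0; SUMSS raises on an empty class.
* Deterministic per-stage seeds are derived from the master seed by
  hashing the stage name (all below 2³¹) and recorded in the provenance
  file alongside package and dependency versions and input digests.

## Known limitations

* The generator models marginal distributions only (no QUAL–DP
  correlation, no linkage along the chromosome, no read-level error
  structure), and DP2 ≤ DP is not enforced; conclusions drawn at
  separation 1 are about pipeline behavior under idealized conditions.
* The published benchmark performance (training F1 ≈ 0.4, validation
  F1 ≈ 0.2, cutoffs between ~0.1 and ~0.86) depends on the four cattle
  genomes, which are not available; those numbers are qualitative context
  for this reimplementation, not reproduction targets.
* Strand conversion of array alleles (A/B, TOP/BOT) and indel
  concordance are out of scope; array genotypes must arrive on the
  reference forward strand.
* Whether sites with a missing NGS genotype (CALL code 1) should ever
  enter training is ambiguous in the source protocol; they are excluded
  here (the CALL vocabulary still reserves code 1 so a configured
  pipeline that keeps them encodes cleanly).
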