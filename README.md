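# snpveracity

Classify SNP calls from whole-genome sequencing pipelines as **correct** or
**incorrect** using only features derivable from a standard VCF file.

## The problem

Variant calls from short-read sequencing carry a small but consequential
error rate: when the same individuals are genotyped both by sequencing and
by a high-density SNP microarray, roughly 2% of sequencing genotypes
disagree with the array. Flagging those discordant calls from VCF
annotations alone is a *rare-event* classification problem — with a 98:2
class ratio, naive classifiers (and maximum-likelihood logistic
regression) collapse onto the majority class.

`snpveracity` implements an end-to-end pipeline for this problem:

1. **Concordance labeling** — each VCF genotype is compared with the
   array genotype at the same position: *correct* means full agreement of
   the unordered allele pair, *incorrect* means a mismatch in at least one
   allele, and sites with a missing genotype on either platform are
   *excluded*. Multi-allelic records count as correct if any biallelic
   reinterpretation of the called genotype over {ref, alt_i} matches the
   array pair.
2. **Feature encoding** — seven VCF-derivable explanatory variables:
   quantitative QUAL, GQ, DP (site depth over all samples) and DP2
   (per-individual depth), z-score standardized on training data; and
   categorical CALL (coded genotype: 1 = ./., 2 = 0/0, 3 = 0/1, 4 = 1/1)
   and the reference-base trios immediately up- and downstream of the
   site, one-hot encoded. Features with excessive training missingness
   (default > 20%, which in practice removes GQ) are dropped.
3. **Rare-event mitigation** — either class weights
   `w_class = (N_correct + N_incorrect) / (2 N_class)` applied as per-row
   loss multipliers (WEIGHTED), or oversampling of the incorrect class
   with replacement up to 30% / 60% / 100% of the correct-class count
   (OVERSAMPLED30/60/100).
4. **Classifier** — an eight-layer feed-forward network (default widths
   128-64-48-32-16-8-4-1), ReLU activations in layers 1–7, a sigmoid
   output unit emitting P(call is incorrect), dropout 0.2 after each of
   the first five layers, Adam on binary cross-entropy, and early
   stopping (patience 25) monitored on a stratified 10% subset of the
   training rows (the OPTset).
5. **Cutoff estimation** — the probability threshold converting P(incorrect)
   into a binary class is optimized for either
   `F1 = 2TP/(2TP+FN+FP)` or `SUMSS = TN/(TN+FP) + TP/(TP+FN)`
   (specificity + sensitivity), exactly over the finite candidate set of
   observed probabilities, and the final estimate is the mean over
   bootstrap resamples of the training data, with a 20-sub-sample
   robustness check.

A synthetic-data generator reproduces the class imbalance and per-class
DP/DP2/QUAL and genotype-class distributions of the Danish Red cattle
benchmark that motivated the pipeline, so everything is testable without
access to the original genomes.

## Worked example

Run the whole pipeline on synthetic data with well-separated classes
(5,000 sites, 2% incorrect, OVERSAMPLED100, SUMSS-optimized cutoff):

```bash
snpveracity pipeline --simulate-n 5000 --separation 8.0 \
    --strategy oversample --ratio 1.0 --metric sumss \
    --seed 4 --max-epochs 60 --out-dir demo/
```

prints (abridged):

```json
{
  "strategy": "oversample",
  "ratio": 1.0,
  "n_train": 3750,
  "n_validation": 1250,
  "cutoff": {"metric": "sumss", "bootstrap_mean": 0.4137, "bootstrap_sd": 0.4524},
  "validation": {
    "tp": 25, "fn": 0, "tn": 1220, "fp": 5,
    "f1": 0.909, "sumss": 1.996, "recall": 1.0,
    "tp_pct": 100.0, "tn_pct": 99.59
  },
  "stopped_epoch": 39, "best_epoch": 14
}
```

Reading the numbers: of the 25 truly incorrect calls held out for
validation, all 25 were flagged (TP% = 100, i.e. sensitivity 1.0) while
99.59% of the 1,225 truly correct calls were left alone (TN%,
specificity), giving SUMSS ≈ 2.0 — near-perfect recovery of the simulated
signal. The probability cutoff (0.41) was estimated purely from training
predictions; training stopped at epoch 39 after 25 epochs without OPTset
loss improvement, restoring the epoch-14 weights.

On real data, replace simulation with files:

```bash
snpveracity pipeline --vcf calls.vcf --array array.tsv \
    --reference genome.fa --strategy oversample --ratio 1.0 \
    --metric sumss --seed 1 --out-dir run/
```

where `array.tsv` has columns `chrom  pos  allele1  allele2` (missing
alleles as `.`). The individual stages are also exposed as `simulate`,
`label`, `featurize`, `train`, `predict`, `cutoff` and `evaluate`
subcommands, and as library functions under `snpveracity.*`.

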