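"""Synthetic data with the statistical structure of the cattle benchmark.

The generator emulates a labeled SNP-call data set: ~2% of calls are
incorrect, and the two classes differ in the marginal distributions of
site depth (DP), per-individual depth (DP2) and site quality (QUAL) as
well as in their genotype-class composition.  Default per-class moments
and genotype proportions are the training-data characteristics of the
Danish Red cattle benchmark this package models; a ``separation``
parameter linearly scales the class differences (0 = identical classes,
the null; >1 = exaggerated signal).

Quantitative features are drawn from lower-truncated normals whose
*realized* (post-truncation) mean and SD are matched to the configured
values by solving for the parent parameters; DP/DP2 are rounded to
integers with floor 1, QUAL has floor 10.  GQ is drawn only to be masked
missing at the configured rate (it is dropped downstream and carries no
class signal).  Trio contexts are uniform over the 64 ACGT trios; no
correlation between features is modeled by default.

``generate_fixture_files`` round-trips the generated truth through real
file formats: a reference FASTA, a VCF and an array-genotype TSV written
such that concordance labeling reproduces the generated labels exactly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .errors import ConfigError, ConfigWarning

_BASES = np.array(list("ACGT"))

#: genotype-class proportions per class (from the benchmark's training data)
GENOTYPE_COUNTS_CORRECT = {"0/0": 882_838, "0/1": 571_549, "1/1": 773_608}
GENOTYPE_COUNTS_INCORRECT = {"0/0": 19_725, "0/1": 12_910, "1/1": 14_285}


def _normalize(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Per-class (mean, sd) pairs are the realized moments of the truncated
    sampling distributions.  ``separation`` interpolates/extrapolates the
    incorrect-class parameters away from the correct-class ones:
    ``theta_inc(s) = theta_cor + s * (theta_inc - theta_cor)``.
    """

    n_sites: int = 10_000
    incorrect_fraction: float = 0.02
    separation: float = 1.0
    gq_missing_fraction: float = 0.244
    seed: int = 0

    dp_correct: tuple[float, float] = (37.91, 11.66)
    dp_incorrect: tuple[float, float] = (30.68, 13.21)
    dp2_correct: tuple[float, float] = (9.53, 4.16)
    dp2_incorrect: tuple[float, float] = (6.20, 4.09)
    qual_correct: tuple[float, float] = (484.15, 430.14)
    qual_incorrect: tuple[float, float] = (365.74, 318.29)

    genotype_probs_correct: dict[str, float] = field(
        default_factory=lambda: _normalize(GENOTYPE_COUNTS_CORRECT)
    )
    genotype_probs_incorrect: dict[str, float] = field(
        default_factory=lambda: _normalize(GENOTYPE_COUNTS_INCORRECT)
    )

    dp_floor: float = 1.0
    dp2_floor: float = 1.0
    qual_floor: float = 10.0

    array_missing_fraction: float = 0.0
    chrom: str = "1"
    sample_id: str = "S1"

    def __post_init__(self) -> None:
        for name, frac in (
            ("incorrect_fraction", self.incorrect_fraction),
            ("gq_missing_fraction", self.gq_missing_fraction),
            ("array_missing_fraction", self.array_missing_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {frac}")
        if self.separation < 0:
            raise ConfigError("separation must be >= 0")
        for name in ("dp", "dp2", "qual"):
            for cls in ("correct", "incorrect"):
                _, sd = getattr(self, f"{name}_{cls}")
                if sd <= 0:
                    raise ConfigError(f"{name}_{cls} sd must be > 0")


def _hazard(a: float) -> float:
    """phi(a)/(1-Phi(a)) for the standard normal."""
    return norm.pdf(a) / norm.sf(a)


def _truncated_moments_std(a: float) -> tuple[float, float]:
    """(mean, sd) of a standard normal truncated below at a."""
    lam = _hazard(a)
    mean = lam
    var = 1.0 + a * lam - lam * lam
    return mean, float(np.sqrt(max(var, 0.0)))


def truncnorm_parent_params(
    mean: float, sd: float, lower: float
) -> tuple[float, float] | None:
    """Parent (mu, sigma) such that the normal truncated below at ``lower``
    has realized moments (mean, sd); None when infeasible.

    The ratio sd/(mean-lower) of a lower-truncated normal increases
    monotonically from 0 towards 1 with the truncation z-score, so a
    unique solution exists iff mean > lower and sd < mean - lower.
    """
    if mean <= lower:
        return None
    r = sd / (mean - lower)
    if r >= 0.995:  # numerically at the exponential limit
        return None

    def ratio(a: float) -> float:
        m, s = _truncated_moments_std(a)
        return s / (m - a) - r

    a = brentq(ratio, -12.0, 12.0, xtol=1e-12)
    m_std, s_std = _truncated_moments_std(a)
    sigma = sd / s_std
    mu = lower - a * sigma
    return mu, sigma


def _sample_truncated(
    rng: np.random.Generator, n: int, mean: float, sd: float, lower: float
) -> np.ndarray:
    """Lower-truncated normal sample with realized moments (mean, sd) when
    feasible; otherwise naive truncation of N(mean, sd) with a warning."""
    params = truncnorm_parent_params(mean, sd, lower)
    if params is None:
        warnings.warn(
            f"truncation at {lower} infeasible for target mean {mean}, sd {sd}; "
            "falling back to naive truncation (realized moments will differ)",
            ConfigWarning,
            stacklevel=3,
        )
        mu, sigma = mean, sd
    else:
        mu, sigma = params
    a = (lower - mu) / sigma
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def _interp(cor: tuple[float, float], inc: tuple[float, float], s: float):
    """Effective incorrect-class (mean, sd) at separation ``s``.

    The mean difference from the correct class scales linearly with ``s``
    (so s=0 is the null and s>1 exaggerates the signal); the sd
    interpolates only on [0, 1], staying at the class's own value beyond —
    separation moves the classes apart, it does not sharpen them.
    """
    return (
        cor[0] + s * (inc[0] - cor[0]),
        cor[1] + min(s, 1.0) * (inc[1] - cor[1]),
    )


def _class_params(config: SyntheticConfig) -> dict[str, dict]:
    s = config.separation
    sp = min(s, 1.0)  # class composition interpolates only on [0, 1]
    inc_probs_raw = {
        g: config.genotype_probs_correct[g]
        + sp * (config.genotype_probs_incorrect[g] - config.genotype_probs_correct[g])
        for g in config.genotype_probs_correct
    }
    inc_probs = _normalize({g: max(p, 0.0) for g, p in inc_probs_raw.items()})
    return {
        "correct": {
            "dp": config.dp_correct,
            "dp2": config.dp2_correct,
            "qual": config.qual_correct,
            "genotype_probs": config.genotype_probs_correct,
        },
        "incorrect": {
            "dp": _interp(config.dp_correct, config.dp_incorrect, s),
            "dp2": _interp(config.dp2_correct, config.dp2_incorrect, s),
            "qual": _interp(config.qual_correct, config.qual_incorrect, s),
            "genotype_probs": inc_probs,
        },
    }


def _random_trios(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.array(
        ["".join(t) for t in rng.choice(_BASES, size=(n, 3))], dtype=object
    )


def generate_feature_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the labeled site table.

    Exactly ``round(incorrect_fraction * n_sites)`` rows are incorrect
    (deterministic minority count).  Columns: chrom, pos, sample, ref,
    alt, gt, qual, gq, dp, dp2, up_trio, down_trio, array_allele1/2,
    label.  Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    n_inc = round(config.incorrect_fraction * n)
    labels = np.array(["correct"] * (n - n_inc) + ["incorrect"] * n_inc)
    rng.shuffle(labels)

    params = _class_params(config)
    qual = np.empty(n)
    dp = np.empty(n, dtype=int)
    dp2 = np.empty(n, dtype=int)
    gt = np.empty(n, dtype=object)
    for cls in ("correct", "incorrect"):
        mask = labels == cls
        m = int(mask.sum())
        if m == 0:
            continue
        p = params[cls]
        qual[mask] = np.round(
            _sample_truncated(rng, m, *p["qual"], config.qual_floor), 2
        )
        dp[mask] = np.maximum(
            np.rint(_sample_truncated(rng, m, *p["dp"], config.dp_floor)), 1
        ).astype(int)
        dp2[mask] = np.maximum(
            np.rint(_sample_truncated(rng, m, *p["dp2"], config.dp2_floor)), 1
        ).astype(int)
        genotypes = list(p["genotype_probs"].keys())
        probs = np.array(list(p["genotype_probs"].values()))
        gt[mask] = rng.choice(np.array(genotypes, dtype=object), size=m, p=probs)

    ref = rng.choice(_BASES, size=n)
    # alt drawn uniformly from the three non-reference bases
    shift = rng.integers(1, 4, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]

    # array genotype: identical pair for correct rows; for incorrect rows,
    # one of the two other genotypes over {ref, alt}, chosen uniformly
    pair_by_gt = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1)}
    arr1 = np.empty(n, dtype=object)
    arr2 = np.empty(n, dtype=object)
    for i in range(n):
        alleles = (ref[i], alt[i])
        called = tuple(sorted(alleles[j] for j in pair_by_gt[gt[i]]))
        if labels[i] == "correct":
            chosen = called
        else:
            others = [
                tuple(sorted((alleles[a], alleles[b])))
                for a, b in ((0, 0), (0, 1), (1, 1))
            ]
            others = [o for o in others if o != called]
            chosen = others[rng.integers(0, len(others))]
        arr1[i], arr2[i] = chosen

    if config.array_missing_fraction > 0:
        miss = rng.random(n) < config.array_missing_fraction
        arr1[miss] = "."
        arr2[miss] = "."
        labels = labels.astype(object)
        labels[miss] = "excluded"

    gq = np.clip(np.round(rng.normal(55.0, 25.0, size=n)), 0, 99)
    gq = gq.astype(object)
    gq[rng.random(n) < config.gq_missing_fraction] = np.nan

    pos = 4 + 10 * np.arange(n)
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "sample": config.sample_id,
            "ref": ref,
            "alt": alt,
            "gt": gt,
            "qual": qual,
            "gq": pd.to_numeric(gq, errors="coerce"),
            "dp": dp,
            "dp2": dp2,
            "up_trio": _random_trios(rng, n),
            "down_trio": _random_trios(rng, n),
            "array_allele1": arr1,
            "array_allele2": arr2,
            "label": labels,
        }
    )


def _write_fasta(path: str, chrom: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _write_vcf(path: str, table: pd.DataFrame, chrom: str, length: int, sample: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description='
            '"Combined depth across samples">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for row in table.sort_values("pos").itertuples(index=False):
            gq = "." if pd.isna(row.gq) else str(int(row.gq))
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:.2f}\t.\tDP={row.dp}\tGT:GQ:DP\t"
                f"{row.gt}:{gq}:{row.dp2}\n"
            )


def generate_fixture_files(config: SyntheticConfig, out_dir: str) -> dict[str, str]:
    """Emit a matching (reference FASTA, VCF, array TSV, truth TSV) quadruple.

    Sites are placed every 10 bp starting at position 4 (>= 4 bases from
    either end), and the reference is built so the recorded up/down trios
    are literally present around each site; concordance labeling of the
    emitted files reproduces the generated labels exactly.
    """
    table = generate_feature_table(config)
    n = len(table)
    length = int(table["pos"].max()) + 10
    rng = np.random.default_rng(int(config.seed) + 99_991)
    seq = rng.choice(_BASES, size=length)
    for row in table.itertuples(index=False):
        p = row.pos - 1  # 0-based index of the site
        seq[p - 3 : p] = list(row.up_trio)
        seq[p] = row.ref
        seq[p + 1 : p + 4] = list(row.down_trio)

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "vcf": os.path.join(out_dir, "calls.vcf"),
        "array": os.path.join(out_dir, "array.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "table": os.path.join(out_dir, "table.tsv"),
    }
    _write_fasta(paths["reference"], config.chrom, "".join(seq))
    _write_vcf(paths["vcf"], table, config.chrom, length, config.sample_id)
    table[["chrom", "pos", "array_allele1", "array_allele2"]].rename(
        columns={"array_allele1": "allele1", "array_allele2": "allele2"}
    ).to_csv(paths["array"], sep="\t", index=False)
    table[["chrom", "pos", "sample", "label"]].to_csv(
        paths["truth"], sep="\t", index=False
    )
    table.to_csv(paths["table"], sep="\t", index=False)
    return paths
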