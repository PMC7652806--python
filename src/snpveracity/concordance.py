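"""Genotype concordance between NGS calls and array genotypes.

Each SNP call in a VCF is compared with the microarray genotype at the same
position and labeled ``correct`` (full agreement of the unordered allele
pair), ``incorrect`` (mismatch in at least one allele) or ``excluded``
(either genotype missing).  For multi-allelic NGS records the called
genotype pattern is additionally reinterpreted within each biallelic subset
``{ref, alt_i}``; agreement with any reinterpretation counts as correct.

Array alleles are assumed to be expressed on the reference forward strand
(A/B or TOP/BOT conversions are out of scope).  Coordinates are 1-based as
in VCF; chromosome names must match the VCF verbatim unless an alias map is
supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import (
    ContractViolationError,
    EmptyIntersectionError,
    MalformedRecordError,
)

LABEL_CORRECT = "correct"
LABEL_INCORRECT = "incorrect"
LABEL_EXCLUDED = "excluded"
LABELS = (LABEL_CORRECT, LABEL_INCORRECT, LABEL_EXCLUDED)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class NgsCall:
    """One sequencing-based SNP call for one sample.

    ``genotype`` holds allele indices into ``(ref_allele,) + alt_alleles``
    or ``None`` for a missing call (``./.``).  ``qual`` is the Phred-scaled
    site quality, ``gq`` the Phred-scaled genotype quality (absent for many
    records), ``dp_site`` the read depth combined over all samples and
    ``dp_sample`` the depth for this individual.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotype: tuple[int, int] | None
    qual: float | None
    gq: float | None
    dp_site: int | None
    dp_sample: int | None
    sample_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ContractViolationError(f"pos must be >= 1, got {self.pos}")
        if self.qual is not None and self.qual < 0:
            raise ContractViolationError(f"QUAL must be >= 0, got {self.qual}")


@dataclass(frozen=True)
class ArrayGenotype:
    """An array genotype: an unordered base pair, or None when missing."""

    chrom: str
    pos: int
    alleles: tuple[str, str] | None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            bad = set(self.alleles) - _VALID_BASES
            if bad:
                raise ContractViolationError(
                    f"array alleles must be in A/C/G/T, got {sorted(bad)}"
                )


@dataclass(frozen=True)
class LabeledSite:
    ngs: NgsCall
    array: ArrayGenotype
    label: str


def resolve_genotype(call: NgsCall) -> tuple[str, str] | None:
    """Map genotype allele indices to an order-normalized base pair.

    Returns ``None`` for a missing genotype.  Raises
    :class:`MalformedRecordError` when an index falls outside the record's
    allele list.
    """
    gt = call.genotype
    if gt is None or any(a is None for a in gt):
        return None
    alleles = (call.ref_allele,) + tuple(call.alt_alleles)
    for idx in gt:
        if not 0 <= idx < len(alleles):
            raise MalformedRecordError(
                f"{call.chrom}:{call.pos} genotype index {idx} outside "
                f"allele list of length {len(alleles)}"
            )
    a, b = (alleles[gt[0]], alleles[gt[1]])
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def _candidate_pairs(call: NgsCall) -> set[tuple[str, str]]:
    """Candidate genotype set for matching: the called pair plus every
    reinterpretation of the called genotype pattern within a biallelic
    subset ``{ref, alt_i}`` (index 0 -> ref, any non-zero index -> alt_i)."""
    called = resolve_genotype(call)
    if called is None:
        return set()
    candidates = {called}
    gt = call.genotype
    assert gt is not None
    for alt in call.alt_alleles:
        pair = tuple(sorted(call.ref_allele if i == 0 else alt for i in gt))
        candidates.add(pair)  # type: ignore[arg-type]
    return candidates


def label_site(ngs: NgsCall, array: ArrayGenotype, strict_array: bool = False) -> str:
    """Label one (site, sample) comparison.

    ``excluded`` if either genotype is missing; ``correct`` if the array's
    unordered pair is in the NGS candidate genotype set; else ``incorrect``.
    With ``strict_array=True``, array alleles outside {ref} ∪ alts raise
    :class:`ContractViolationError` instead of yielding ``incorrect``.
    """
    if (ngs.chrom, ngs.pos) != (array.chrom, array.pos):
        raise ContractViolationError(
            f"position mismatch: NGS {ngs.chrom}:{ngs.pos} vs "
            f"array {array.chrom}:{array.pos}"
        )
    called = resolve_genotype(ngs)
    if called is None or array.alleles is None:
        return LABEL_EXCLUDED
    if strict_array:
        allowed = {ngs.ref_allele, *ngs.alt_alleles}
        if not set(array.alleles) <= allowed:
            raise ContractViolationError(
                f"{array.chrom}:{array.pos} array alleles {array.alleles} "
                f"not expressible over ref/alt {sorted(allowed)}"
            )
    pair = tuple(sorted(array.alleles))
    return LABEL_CORRECT if pair in _candidate_pairs(ngs) else LABEL_INCORRECT


def genotype_string(genotype: tuple[int, int] | None) -> str:
    """Canonical unphased genotype string with sorted indices ('./.', '0/1', ...)."""
    if genotype is None or any(a is None for a in genotype):
        return "./."
    a, b = sorted(genotype)
    return f"{a}/{b}"


def read_array_table(path: str) -> pd.DataFrame:
    """Read an array-genotype TSV with columns chrom, pos, allele1, allele2.

    Missing alleles are encoded as '.'.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "allele1": str, "allele2": str}
    )
    required = {"chrom", "pos", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ContractViolationError(
            f"array table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def iter_vcf_calls(
    vcf_path: str, sample_ids: Sequence[str] | None = None
) -> Iterator[NgsCall]:
    """Stream NgsCall objects from a VCF, one per (record, sample)."""
    with pysam.VariantFile(vcf_path) as vf:
        samples = list(sample_ids) if sample_ids else list(vf.header.samples)
        missing = set(samples) - set(vf.header.samples)
        if missing:
            raise ContractViolationError(
                f"samples {sorted(missing)} not present in {vcf_path}"
            )
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            dp_site = rec.info.get("DP")
            for sid in samples:
                sd = rec.samples[sid]
                gt = sd.get("GT")
                if gt is not None and any(a is None for a in gt):
                    gt = None
                yield NgsCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    genotype=tuple(gt) if gt is not None else None,
                    qual=rec.qual,
                    gq=sd.get("GQ"),
                    dp_site=int(dp_site) if dp_site is not None else None,
                    dp_sample=sd.get("DP"),
                    sample_id=sid,
                )


@dataclass
class ClassSummary:
    """Per-class characteristics mirroring a data-set characteristics table:
    genotype-class counts and mean±SD plus range of DP, DP2 and QUAL."""

    n: int = 0
    genotype_counts: dict[str, int] = field(default_factory=dict)
    dp: dict[str, float] = field(default_factory=dict)
    dp2: dict[str, float] = field(default_factory=dict)
    qual: dict[str, float] = field(default_factory=dict)


@dataclass
class ConcordanceSummary:
    n_compared: int
    n_correct: int
    n_incorrect: int
    n_excluded: int
    n_absent_from_vcf: int
    per_class: dict[str, ClassSummary]

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "n_excluded": self.n_excluded,
            "n_absent_from_vcf": self.n_absent_from_vcf,
            "pct_correct": _pct(self.n_correct, self.n_correct + self.n_incorrect),
            "pct_incorrect": _pct(self.n_incorrect, self.n_correct + self.n_incorrect),
            "per_class": {
                k: {
                    "n": v.n,
                    "genotype_counts": v.genotype_counts,
                    "dp": v.dp,
                    "dp2": v.dp2,
                    "qual": v.qual,
                }
                for k, v in self.per_class.items()
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _pct(num: int, den: int) -> float | None:
    return round(100.0 * num / den, 2) if den else None


def _moment_block(values: pd.Series) -> dict[str, float]:
    vals = pd.to_numeric(values, errors="coerce").dropna()
    if vals.empty:
        return {}
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def summarize_labels(table: pd.DataFrame, n_absent_from_vcf: int = 0) -> ConcordanceSummary:
    """Build the per-class summary (counts, genotype classes, DP/DP2/QUAL
    moments and ranges) from a labeled site table."""
    per_class: dict[str, ClassSummary] = {}
    for label in (LABEL_CORRECT, LABEL_INCORRECT):
        sub = table[table["label"] == label]
        per_class[label] = ClassSummary(
            n=len(sub),
            genotype_counts=sub["gt"].value_counts().to_dict(),
            dp=_moment_block(sub["dp"]),
            dp2=_moment_block(sub["dp2"]),
            qual=_moment_block(sub["qual"]),
        )
    counts = table["label"].value_counts()
    return ConcordanceSummary(
        n_compared=len(table),
        n_correct=int(counts.get(LABEL_CORRECT, 0)),
        n_incorrect=int(counts.get(LABEL_INCORRECT, 0)),
        n_excluded=int(counts.get(LABEL_EXCLUDED, 0)),
        n_absent_from_vcf=n_absent_from_vcf,
        per_class=per_class,
    )


def label_dataset(
    vcf_path: str,
    array_path: str,
    sample_ids: Sequence[str] | None = None,
    strict_array: bool = False,
    chrom_aliases: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ConcordanceSummary]:
    """Label every (array site found in the VCF, sample) pair.

    Returns the labeled site table (one row per comparison, carrying the
    VCF-derivable features) and a per-class summary.  Array sites absent
    from the VCF are counted as excluded-by-absence in the summary only.

    ``chrom_aliases`` maps array chromosome names onto VCF names when the
    two sources disagree (e.g. ``{"chr1": "1"}``).
    """
    array_df = read_array_table(array_path)
    aliases = dict(chrom_aliases or {})
    array_map: dict[tuple[str, int], ArrayGenotype] = {}
    for row in array_df.itertuples(index=False):
        chrom = aliases.get(str(row.chrom), str(row.chrom))
        a1, a2 = str(row.allele1), str(row.allele2)
        alleles = None if "." in (a1, a2) else (a1, a2)
        array_map[(chrom, int(row.pos))] = ArrayGenotype(chrom, int(row.pos), alleles)

    rows = []
    seen: set[tuple[str, int]] = set()
    for call in iter_vcf_calls(vcf_path, sample_ids):
        key = (call.chrom, call.pos)
        arr = array_map.get(key)
        if arr is None:
            continue
        seen.add(key)
        label = label_site(call, arr, strict_array=strict_array)
        rows.append(
            {
                "chrom": call.chrom,
                "pos": call.pos,
                "sample": call.sample_id,
                "ref": call.ref_allele,
                "alt": ",".join(call.alt_alleles),
                "gt": genotype_string(call.genotype),
                "qual": call.qual,
                "gq": call.gq,
                "dp": call.dp_site,
                "dp2": call.dp_sample,
                "array_allele1": arr.alleles[0] if arr.alleles else ".",
                "array_allele2": arr.alleles[1] if arr.alleles else ".",
                "label": label,
            }
        )
    if not rows:
        raise EmptyIntersectionError(
            f"no overlapping positions between {vcf_path} and {array_path}"
        )
    table = pd.DataFrame(rows)
    summary = summarize_labels(table, n_absent_from_vcf=len(array_map) - len(seen))
    return table, summary


def write_labels(table: pd.DataFrame, path: str) -> None:
    """Write the labeling result as TSV (chrom, pos, sample, label)."""
    table[["chrom", "pos", "sample", "label"]].to_csv(path, sep="\t", index=False)
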