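"""Explanatory-variable encoding.

Seven VCF-derivable variables describe each SNP call: the quantitative
QUAL, GQ, DP (site depth over all samples) and DP2 (per-individual depth),
and the categorical CALL (coded genotype: 1 = ./., 2 = 0/0, 3 = 0/1,
4 = 1/1), UP_TRIO and DOWN_TRIO (three reference bases up-/downstream of
the site, read left-to-right on the forward strand).

Quantitative features are z-score standardized with moments estimated on
training data only (population standard deviation); features whose training
missingness exceeds a threshold (default 0.2) are dropped, remaining
missing values are imputed with the training mean.  Categorical features
are one-hot encoded against a vocabulary fixed at fit time.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, ContractViolationError, DegenerateFeatureWarning

QUANTITATIVE = ("QUAL", "GQ", "DP", "DP2")
CATEGORICAL = ("CALL", "UP_TRIO", "DOWN_TRIO")

#: site-table column backing each feature
_SOURCE_COLUMNS = {
    "QUAL": "qual",
    "GQ": "gq",
    "DP": "dp",
    "DP2": "dp2",
    "CALL": "gt",
    "UP_TRIO": "up_trio",
    "DOWN_TRIO": "down_trio",
}

CALL_LEVELS = (1, 2, 3, 4)
ALL_TRIOS = tuple("".join(t) for t in itertools.product("ACGT", repeat=3))


def encode_call(genotype, strict: bool = False) -> int:
    """Integer genotype code: 1 = ./., 2 = 0/0, 3 = 0/1, 4 = 1/1.

    ``genotype`` may be a GT string ('0/1', '1|0', './.') or an index pair.
    In lenient mode (default) any heterozygous pattern (e.g. 1/2) maps to 3
    and any non-reference homozygote (e.g. 2/2) to 4; strict mode accepts
    only the four canonical patterns.
    """
    if genotype is None:
        return 1
    if isinstance(genotype, str):
        g = genotype.replace("|", "/")
        if g in (".", "./.", "./", "/."):
            return 1
        try:
            idx = tuple(int(p) for p in g.split("/"))
        except ValueError as exc:
            raise ContractViolationError(f"unparseable genotype {genotype!r}") from exc
    else:
        idx = tuple(genotype)
        if any(i is None for i in idx):
            return 1
    if len(idx) != 2:
        raise ContractViolationError(f"genotype must be diploid, got {genotype!r}")
    a, b = sorted(idx)
    if (a, b) == (0, 0):
        return 2
    if (a, b) == (0, 1):
        return 3
    if (a, b) == (1, 1):
        return 4
    if strict:
        raise ContractViolationError(f"genotype pattern {genotype!r} not allowed in strict mode")
    return 3 if a != b else 4


def context_trio(reference, chrom: str, pos: int, side: str) -> str:
    """Three reference bases adjacent to ``pos`` (1-based, forward strand).

    ``side='up'`` returns positions pos-3..pos-1, ``side='down'`` returns
    pos+1..pos+3, both left-to-right; positions beyond the chromosome ends
    are padded with 'N'.  ``reference`` is any mapping from chromosome name
    to a sliceable sequence (``pyfaidx.Fasta`` or a plain dict of strings).
    """
    if side not in ("up", "down"):
        raise ContractViolationError(f"side must be 'up' or 'down', got {side!r}")
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise LookupError(f"chromosome {chrom!r} absent from reference") from exc
    length = len(seq)
    positions = range(pos - 3, pos) if side == "up" else range(pos + 1, pos + 4)
    bases = []
    for p in positions:
        if 1 <= p <= length:
            bases.append(str(seq[p - 1 : p]).upper())
        else:
            bases.append("N")
    return "".join(bases)


@dataclass
class FeatureSpec:
    """Which variables enter the model and how categoricals are leveled."""

    quantitative: tuple[str, ...] = QUANTITATIVE
    categorical: tuple[str, ...] = CATEGORICAL
    missingness_threshold: float = 0.2
    standardize: str = "zscore"  # or "rank_int" (rank-based inverse normal)
    strict_levels: bool = False
    category_levels: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = (set(self.quantitative) - set(QUANTITATIVE)) | (
            set(self.categorical) - set(CATEGORICAL)
        )
        if unknown:
            raise ConfigError(f"unknown features: {sorted(unknown)}")
        if not 0.0 <= self.missingness_threshold <= 1.0:
            raise ConfigError("missingness_threshold must be in [0, 1]")
        if self.standardize not in ("zscore", "rank_int"):
            raise ConfigError(f"unknown standardize mode {self.standardize!r}")


@dataclass
class StandardizationParams:
    """Per-feature training moments; transform maps x -> (x - mean)/sd."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()
    # sorted training values per feature, only for rank-based INT
    rank_reference: dict[str, np.ndarray] = field(default_factory=dict)


def fit_standardizer(columns: pd.DataFrame) -> StandardizationParams:
    """Estimate per-feature mean and population SD, ignoring missing values.

    Zero-variance features are dropped with a :class:`DegenerateFeatureWarning`.
    """
    means, sds, dropped = {}, {}, []
    for name in columns.columns:
        vals = pd.to_numeric(columns[name], errors="coerce").dropna().to_numpy(float)
        if len(vals) < 2 or float(np.std(vals)) == 0.0:
            warnings.warn(
                f"feature {name} has zero variance on training data; dropped",
                DegenerateFeatureWarning,
                stacklevel=2,
            )
            dropped.append(name)
            continue
        means[name] = float(np.mean(vals))
        sds[name] = float(np.std(vals))  # population SD (ddof=0)
    return StandardizationParams(means=means, sds=sds, dropped=tuple(dropped))


def one_hot(value, levels: Sequence, strict: bool = False) -> np.ndarray:
    """Binary indicator vector over ``levels``; all zeros for an unseen
    value in lenient mode, error in strict mode."""
    vec = np.zeros(len(levels), dtype=float)
    try:
        vec[list(levels).index(value)] = 1.0
    except ValueError:
        if strict:
            raise ContractViolationError(f"value {value!r} not in fixed levels")
    return vec


def drop_high_missingness(
    columns: pd.DataFrame, threshold: float
) -> tuple[list[str], dict[str, float]]:
    """Retain features whose training missing fraction is <= threshold.

    Returns (retained feature names, per-feature missing-fraction report).
    """
    report: dict[str, float] = {}
    retained: list[str] = []
    for name in columns.columns:
        frac = float(pd.to_numeric(columns[name], errors="coerce").isna().mean())
        report[name] = frac
        if frac > threshold:
            warnings.warn(
                f"feature {name} missing for {frac:.1%} of training rows "
                f"(> {threshold:.0%}); dropped",
                DegenerateFeatureWarning,
                stacklevel=2,
            )
        else:
            retained.append(name)
    if not retained:
        raise ConfigError("all quantitative features dropped by missingness filter")
    return retained, report


@dataclass
class FeatureMatrix:
    """Encoded numeric matrix with row identity, labels and full metadata.

    ``y`` codes 1 = incorrect, 0 = correct.  ``columns`` records the
    deterministic column order; metadata suffices to map any column back to
    (feature, level).
    """

    index: pd.DataFrame  # chrom, pos, sample
    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    spec: FeatureSpec
    params: StandardizationParams

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column_info(self, i: int) -> tuple[str, object | None]:
        """Map a column index back to (feature, level); level is None for
        quantitative columns."""
        name = self.columns[i]
        if "=" in name:
            feat, level = name.split("=", 1)
            if feat == "CALL":
                return feat, int(level)
            return feat, level
        return name, None

    def to_tsv(self, path: str, sidecar_path: str | None = None) -> None:
        """Persist as TSV (index + label + numeric columns) plus a JSON
        sidecar holding the FeatureSpec and StandardizationParams."""
        df = pd.concat(
            [
                self.index.reset_index(drop=True),
                pd.Series(self.y, name="label_incorrect"),
                pd.DataFrame(self.X, columns=list(self.columns)),
            ],
            axis=1,
        )
        df.to_csv(path, sep="\t", index=False)
        sidecar = sidecar_path or path + ".meta.json"
        spec = asdict(self.spec)
        spec["category_levels"] = {k: list(v) for k, v in self.spec.category_levels.items()}
        meta = {
            "columns": list(self.columns),
            "spec": spec,
            "params": {
                "means": self.params.means,
                "sds": self.params.sds,
                "dropped": list(self.params.dropped),
            },
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def read_tsv(cls, path: str, sidecar_path: str | None = None) -> "FeatureMatrix":
        sidecar = sidecar_path or path + ".meta.json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
        spec_d = dict(meta["spec"])
        spec_d["quantitative"] = tuple(spec_d["quantitative"])
        spec_d["categorical"] = tuple(spec_d["categorical"])
        spec_d["category_levels"] = {
            k: tuple(v) for k, v in spec_d["category_levels"].items()
        }
        spec = FeatureSpec(**spec_d)
        params = StandardizationParams(
            means=meta["params"]["means"],
            sds=meta["params"]["sds"],
            dropped=tuple(meta["params"]["dropped"]),
        )
        cols = meta["columns"]
        return cls(
            index=df[["chrom", "pos", "sample"]],
            X=df[cols].to_numpy(float),
            y=df["label_incorrect"].to_numpy(int),
            columns=tuple(cols),
            spec=spec,
            params=params,
        )


class FeatureEncoder:
    """Fit on training rows; transform any labeled site table consistently.

    Fitting drops quantitative features with excessive missingness,
    estimates standardization moments, and fixes the categorical vocabulary
    (all four CALL codes; all 64 ACGT trios plus any padded trios observed
    in training).  Transforming never re-estimates anything.
    """

    def __init__(self, spec: FeatureSpec | None = None):
        self.spec = spec or FeatureSpec()
        self.params: StandardizationParams | None = None
        self.retained_quantitative: tuple[str, ...] = ()
        self.levels: dict[str, tuple] = {}
        self.missingness_report: dict[str, float] = {}

    @property
    def columns(self) -> tuple[str, ...]:
        cols = list(self.retained_quantitative)
        for feat in self.spec.categorical:
            cols.extend(f"{feat}={lvl}" for lvl in self.levels[feat])
        return tuple(cols)

    def fit(self, table: pd.DataFrame) -> "FeatureEncoder":
        quant = pd.DataFrame(
            {f: table[_SOURCE_COLUMNS[f]] for f in self.spec.quantitative}
        )
        retained, report = drop_high_missingness(
            quant, self.spec.missingness_threshold
        )
        self.missingness_report = report
        params = fit_standardizer(quant[retained])
        self.retained_quantitative = tuple(
            f for f in retained if f not in params.dropped
        )
        if self.spec.standardize == "rank_int":
            for f in self.retained_quantitative:
                vals = pd.to_numeric(quant[f], errors="coerce").dropna()
                params.rank_reference[f] = np.sort(vals.to_numpy(float))
        self.params = params

        self.levels = {}
        for feat in self.spec.categorical:
            if feat in self.spec.category_levels:
                self.levels[feat] = tuple(self.spec.category_levels[feat])
            elif feat == "CALL":
                self.levels[feat] = CALL_LEVELS
            else:
                observed = {
                    str(v) for v in table[_SOURCE_COLUMNS[feat]].dropna().unique()
                }
                self.levels[feat] = tuple(sorted(set(ALL_TRIOS) | observed))
        return self

    def _quantitative_block(self, table: pd.DataFrame) -> np.ndarray:
        assert self.params is not None
        out = np.empty((len(table), len(self.retained_quantitative)), dtype=float)
        for j, f in enumerate(self.retained_quantitative):
            vals = pd.to_numeric(
                table[_SOURCE_COLUMNS[f]], errors="coerce"
            ).to_numpy(float)
            mean, sd = self.params.means[f], self.params.sds[f]
            vals = np.where(np.isnan(vals), mean, vals)  # training-mean imputation
            if self.spec.standardize == "rank_int":
                ref = self.params.rank_reference[f]
                # mid-rank within the training sample, mapped through the
                # standard-normal quantile function
                r = (
                    np.searchsorted(ref, vals, side="left")
                    + np.searchsorted(ref, vals, side="right")
                ) / 2.0
                out[:, j] = norm.ppf((r + 0.5) / (len(ref) + 1.0))
            else:
                out[:, j] = (vals - mean) / sd
        return out

    def _categorical_block(self, table: pd.DataFrame) -> np.ndarray:
        blocks = []
        for feat in self.spec.categorical:
            levels = self.levels[feat]
            if feat == "CALL":
                values = [encode_call(g) for g in table[_SOURCE_COLUMNS[feat]]]
            else:
                values = [str(v) for v in table[_SOURCE_COLUMNS[feat]]]
            level_index = {lvl: k for k, lvl in enumerate(levels)}
            block = np.zeros((len(table), len(levels)), dtype=float)
            for i, v in enumerate(values):
                k = level_index.get(v)
                if k is None:
                    if self.spec.strict_levels:
                        raise ContractViolationError(
                            f"{feat} value {v!r} not in fit-time levels"
                        )
                    continue  # lenient: all-zero row for unseen level
                block[i, k] = 1.0
            blocks.append(block)
        return np.concatenate(blocks, axis=1) if blocks else np.empty((len(table), 0))

    def transform(self, table: pd.DataFrame) -> FeatureMatrix:
        if self.params is None:
            raise ConfigError("encoder not fitted")
        labeled = table[table["label"] != "excluded"].reset_index(drop=True)
        X = np.concatenate(
            [self._quantitative_block(labeled), self._categorical_block(labeled)],
            axis=1,
        )
        y = (labeled["label"] == "incorrect").to_numpy(int)
        return FeatureMatrix(
            index=labeled[["chrom", "pos", "sample"]].copy(),
            X=X,
            y=y,
            columns=self.columns,
            spec=self.spec,
            params=self.params,
        )


def add_context_trios(table: pd.DataFrame, reference) -> pd.DataFrame:
    """Annotate a labeled site table with UP_TRIO/DOWN_TRIO columns drawn
    from an indexed reference."""
    out = table.copy()
    out["up_trio"] = [
        context_trio(reference, c, int(p), "up")
        for c, p in zip(out["chrom"], out["pos"])
    ]
    out["down_trio"] = [
        context_trio(reference, c, int(p), "down")
        for c, p in zip(out["chrom"], out["pos"])
    ]
    return out


def build_feature_matrix(
    table: pd.DataFrame,
    reference=None,
    spec: FeatureSpec | None = None,
) -> tuple[FeatureMatrix, FeatureEncoder]:
    """Fit an encoder on a labeled site table and encode it.

    Adds context trios from ``reference`` when the table lacks them.
    Excluded sites are omitted from the matrix.  Returns the matrix and the
    fitted encoder (reuse the encoder to transform validation data).
    """
    if "up_trio" not in table.columns or "down_trio" not in table.columns:
        if reference is None:
            raise ContractViolationError(
                "table lacks context trios and no reference was given"
            )
        table = add_context_trios(table, reference)
    encoder = FeatureEncoder(spec).fit(table[table["label"] != "excluded"])
    return encoder.transform(table), encoder
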