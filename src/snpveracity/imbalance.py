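"""Rare-event mitigation: class weighting and minority oversampling.

With ~2% of SNP calls in the incorrect class, an unweighted classifier can
achieve low loss by ignoring the rare class.  Two mitigations are
provided:

* loss weights per class, ``w_class = 0.5 * (N_correct + N_incorrect) /
  N_class``, so the frequency-weighted mean weight is exactly 1;
* oversampling of the incorrect class with replacement up to a fixed
  fraction of the correct-class count (named presets OVERSAMPLED30/60/100
  for ratios 0.30, 0.60 and 1.00).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedWeightError

#: named oversampling presets: target incorrect count as fraction of correct
PRESETS = {"OVERSAMPLED30": 0.30, "OVERSAMPLED60": 0.60, "OVERSAMPLED100": 1.00}


@dataclass(frozen=True)
class ClassWeights:
    w_correct: float
    w_incorrect: float


def class_weights(n_correct: int, n_incorrect: int) -> ClassWeights:
    """Loss weights making the frequency-weighted mean weight equal 1:

    w_correct = (N_c + N_i) / (2 N_c),  w_incorrect = (N_c + N_i) / (2 N_i).
    """
    if n_correct <= 0 or n_incorrect <= 0:
        raise UndefinedWeightError(
            f"both classes must be non-empty, got ({n_correct}, {n_incorrect})"
        )
    total = n_correct + n_incorrect
    return ClassWeights(
        w_correct=0.5 * total / n_correct,
        w_incorrect=0.5 * total / n_incorrect,
    )


@dataclass(frozen=True)
class OversamplePlan:
    ratio: float
    seed: int
    target_incorrect_count: int


def make_plan(n_correct: int, n_incorrect: int, ratio: float, seed: int) -> OversamplePlan:
    if not 0.0 < ratio <= 1.0:
        raise ConfigError(f"oversampling ratio must be in (0, 1], got {ratio}")
    target = round(ratio * n_correct)
    if target < n_incorrect:
        raise ConfigError(
            f"oversampling target {target} below existing incorrect count "
            f"{n_incorrect}; oversampling only enlarges the rare class"
        )
    return OversamplePlan(ratio=ratio, seed=seed, target_incorrect_count=target)


def oversample_indices(y: np.ndarray, ratio: float, seed: int) -> np.ndarray:
    """Row indices of the augmented training set.

    All correct rows (y == 0) appear once and unchanged; the incorrect rows
    are every original incorrect row once plus ``target - n_incorrect``
    draws with replacement from the incorrect pool.  Deterministic given
    ``seed``.
    """
    y = np.asarray(y)
    correct_idx = np.flatnonzero(y == 0)
    incorrect_idx = np.flatnonzero(y == 1)
    if len(incorrect_idx) == 0:
        raise ConfigError("cannot oversample: no incorrect rows")
    plan = make_plan(len(correct_idx), len(incorrect_idx), ratio, seed)
    rng = np.random.default_rng(seed)
    extra = rng.choice(
        incorrect_idx, size=plan.target_incorrect_count - len(incorrect_idx), replace=True
    )
    return np.concatenate([correct_idx, incorrect_idx, extra])


def oversample_incorrect(table: pd.DataFrame, ratio: float, seed: int) -> pd.DataFrame:
    """Oversample a labeled table (column ``label`` or ``label_incorrect``).

    Every output row is an exact duplicate of an input row; see
    :func:`oversample_indices` for the composition contract.
    """
    if "label_incorrect" in table.columns:
        y = table["label_incorrect"].to_numpy(int)
    elif "label" in table.columns:
        y = (table["label"] == "incorrect").to_numpy(int)
    else:
        raise ConfigError("table has neither 'label' nor 'label_incorrect'")
    idx = oversample_indices(y, ratio, seed)
    return table.iloc[idx].reset_index(drop=True)
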