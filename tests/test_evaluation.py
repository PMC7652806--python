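"""Metrics and cutoff estimation: formula agreement on exhaustive grids,
brute-force oracle equivalence for the cutoff optimizer, bootstrap
behavior."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpveracity import evaluation
from snpveracity.errors import ContractViolationError, UndefinedMetricError
from snpveracity.evaluation import (
    ConfusionCounts,
    bootstrap_cutoff,
    confusion,
    evaluate,
    f1_metric,
    optimal_cutoff,
    subsample_robustness,
    sumss_metric,
)


def test_confusion_basic_tally():
    c = confusion(["incorrect", "incorrect", "correct", "correct"],
                  [0.9, 0.1, 0.2, 0.7], 0.5)
    assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)


def test_confusion_boundary_cutoffs():
    labels = [1, 1, 0, 0]
    probs = [0.9, 0.1, 0.2, 1.0]
    c0 = confusion(labels, probs, 0.0)
    assert c0.fn == 0 and c0.tn == 0  # everything classified incorrect
    c1 = confusion(labels, probs, 1.0)
    assert c1.tp == 0 and c1.fp == 1  # only prob == 1.0 crosses


def test_confusion_length_mismatch():
    with pytest.raises(ContractViolationError):
        confusion([1, 0], [0.5], 0.5)


@pytest.mark.parametrize(
    "counts, expected",
    [((3, 1, 0, 1), 0.75), ((0, 5, 10, 0), 0.0), ((4, 0, 10, 0), 1.0)],
)
def test_f1_examples(counts, expected):
    assert f1_metric(ConfusionCounts(*counts)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "counts, expected",
    [((8, 2, 9, 1), 1.7), ((10, 0, 10, 0), 2.0), ((0, 10, 10, 0), 1.0)],
)
def test_sumss_examples(counts, expected):
    assert sumss_metric(ConfusionCounts(*counts)) == pytest.approx(expected)


def test_sumss_undefined_for_empty_class():
    with pytest.raises(UndefinedMetricError):
        sumss_metric(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))


def test_metric_formulas_against_exhaustive_grid():
    """F1 and SUMSS from ConfusionCounts agree with direct formula
    evaluation over a grid of small count 4-tuples."""
    for tp, fn, tn, fp in itertools.product(range(0, 7), repeat=4):
        c = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
        den = 2 * tp + fn + fp
        assert f1_metric(c) == pytest.approx(2 * tp / den if den else 0.0)
        if tp + fn and tn + fp:
            assert sumss_metric(c) == pytest.approx(tn / (tn + fp) + tp / (tp + fn))


def test_optimal_cutoff_example():
    assert optimal_cutoff([1, 0, 0, 1], [0.9, 0.2, 0.4, 0.8], "f1") == pytest.approx(0.8)


def test_optimal_cutoff_flat_metric_returns_smallest_candidate():
    # identical probabilities: F1 flat in (0, p]; smallest maximizer returned
    cut = optimal_cutoff([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3], "f1")
    assert cut == pytest.approx(0.0)


def _dense_grid_oracle(y, p, metric, step=0.001):
    best_val, best_cut = -np.inf, None
    for cut in np.arange(0.0, 1.0 + step, step):
        c = confusion(y, p, min(cut, 1.0))
        val = f1_metric(c) if metric == "f1" else sumss_metric(c)
        if val > best_val + 1e-12:
            best_val, best_cut = val, cut
    return best_val, best_cut


@pytest.mark.parametrize("metric", ["f1", "sumss"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_optimal_cutoff_matches_dense_grid_oracle(metric, seed):
    """The exact candidate search attains the same metric value as a
    brute-force dense-grid scan."""
    rng = np.random.default_rng(seed)
    n = 600
    y = (rng.random(n) < 0.15).astype(int)
    p = np.clip(rng.beta(2, 5, size=n) + 0.3 * y, 0, 1)
    cut = optimal_cutoff(y, p, metric)
    c = confusion(y, p, cut)
    ours = f1_metric(c) if metric == "f1" else sumss_metric(c)
    oracle_val, _ = _dense_grid_oracle(y, p, metric)
    assert ours >= oracle_val - 1e-12


@given(seed=st.integers(0, 50))
@settings(max_examples=25, deadline=None)
def test_optimal_cutoff_monotone_invariance(seed):
    """A strictly increasing transform maps the optimum to the transformed
    candidate with the same metric value."""
    rng = np.random.default_rng(seed)
    n = 200
    y = (rng.random(n) < 0.2).astype(int)
    p = rng.random(n)
    cut = optimal_cutoff(y, p, "f1")
    q = p**2  # strictly increasing on [0, 1]
    cut_t = optimal_cutoff(y, q, "f1")
    v1 = f1_metric(confusion(y, p, cut))
    v2 = f1_metric(confusion(y, q, cut_t))
    assert v1 == pytest.approx(v2, abs=1e-12)


def test_bootstrap_on_separated_classes_has_zero_sd():
    """With constant per-class probabilities every two-class resample
    yields the same cutoff, so the bootstrap SD is 0 and the mean equals
    the point estimate."""
    y = np.array([1] * 10 + [0] * 90)
    p = np.where(y == 1, 0.9, 0.1)
    est = bootstrap_cutoff(y, p, "f1", n_bootstrap=25, seed=0)
    assert est.bootstrap_sd == 0.0
    assert est.bootstrap_mean == pytest.approx(0.9)
    assert est.bootstrap_mean == pytest.approx(est.point_cutoff)


def test_bootstrap_mean_within_resample_range():
    rng = np.random.default_rng(4)
    y = (rng.random(400) < 0.1).astype(int)
    p = np.clip(rng.random(400) + 0.2 * y, 0, 1)
    est = bootstrap_cutoff(y, p, "sumss", n_bootstrap=40, seed=1)
    assert min(est.cutoffs) <= est.bootstrap_mean <= max(est.cutoffs)
    # reproducible given seed
    again = bootstrap_cutoff(y, p, "sumss", n_bootstrap=40, seed=1)
    assert est.cutoffs == again.cutoffs


def test_subsample_robustness_reproducible_and_degenerate():
    rng = np.random.default_rng(5)
    y = (rng.random(300) < 0.1).astype(int)
    p = np.clip(rng.random(300) + 0.3 * y, 0, 1)
    a = subsample_robustness(y, p, "f1", n_subsamples=5, n_bootstrap=10, seed=3)
    b = subsample_robustness(y, p, "f1", n_subsamples=5, n_bootstrap=10, seed=3)
    assert a == b
    single = subsample_robustness(y, p, "f1", n_subsamples=1, n_bootstrap=10, seed=3)
    assert single["sd"] == 0.0 and single["degenerate"]


def test_subsample_spread_shrinks_with_sample_size():
    """The cutoff estimate stabilizes as the data set grows."""
    def spread(n, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.1).astype(int)
        p = np.clip(rng.normal(0.3, 0.15, n) + 0.35 * y, 0, 1)
        return subsample_robustness(y, p, "sumss", n_subsamples=8, n_bootstrap=15, seed=9)["sd"]

    assert spread(25600, 1) < spread(400, 1)


def test_evaluate_report_consistency():
    y = [1, 1, 0, 0, 0]
    p = [0.9, 0.8, 0.1, 0.2, 0.1]
    rep = evaluate(y, p, 0.5)
    assert rep["tp_pct"] == 100.0 and rep["tn_pct"] == 100.0 and rep["f1"] == 1.0
    c = ConfusionCounts(rep["tp"], rep["fn"], rep["tn"], rep["fp"])
    assert rep["f1"] == pytest.approx(f1_metric(c))
    assert rep["sumss"] == pytest.approx(sumss_metric(c))


def test_evaluate_all_correct_predictions_on_imbalanced_data():
    y = np.array([1] * 2 + [0] * 98)
    p = np.zeros(100)
    rep = evaluate(y, p, 0.5)
    assert rep["tn_pct"] == 100.0 and rep["tp_pct"] == 0.0
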