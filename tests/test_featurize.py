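"""Feature encoding: CALL codes, context trios, standardization, one-hot
vocabularies and missingness-driven feature dropping."""

import numpy as np
import pandas as pd
import pyfaidx
import pytest

from snpveracity import featurize, synthetic
from snpveracity.errors import ConfigError, ContractViolationError, DegenerateFeatureWarning
from snpveracity.featurize import (
    FeatureEncoder,
    FeatureMatrix,
    FeatureSpec,
    context_trio,
    drop_high_missingness,
    encode_call,
    fit_standardizer,
    one_hot,
)


@pytest.mark.parametrize(
    "gt, expected",
    [
        ("./.", 1),
        (None, 1),
        ("0/0", 2),
        ("0/1", 3),
        ("1/0", 3),
        ("1|0", 3),
        ("1/1", 4),
        ((0, 1), 3),
        ("1/2", 3),  # lenient: heterozygous pattern
        ("2/2", 4),  # lenient: non-reference homozygote
    ],
)
def test_encode_call(gt, expected):
    assert encode_call(gt) == expected


def test_encode_call_strict_rejects_extra_alleles():
    with pytest.raises(ContractViolationError):
        encode_call("1/2", strict=True)


@pytest.mark.parametrize(
    "pos, side, expected",
    [
        (5, "up", "ACG"),
        (5, "down", "ACG"),
        (1, "up", "NNN"),
        (2, "up", "NNA"),
        (9, "down", "NNN"),
        (8, "down", "TNN"),
    ],
)
def test_context_trio_on_toy_reference(pos, side, expected):
    ref = {"1": "AACGTACGT"}
    assert context_trio(ref, "1", pos, side) == expected


def test_context_trio_missing_chromosome():
    with pytest.raises(LookupError):
        context_trio({"1": "ACGT"}, "2", 2, "up")


def test_context_trio_agrees_with_pyfaidx(fixture_bundle):
    cfg, paths = fixture_bundle
    fa = pyfaidx.Fasta(paths["reference"])
    table = pd.read_csv(paths["table"], sep="\t", dtype={"chrom": str})
    sub = table.head(50)
    ups = [context_trio(fa, r.chrom, r.pos, "up") for r in sub.itertuples()]
    downs = [context_trio(fa, r.chrom, r.pos, "down") for r in sub.itertuples()]
    assert ups == list(sub["up_trio"])
    assert downs == list(sub["down_trio"])


def test_fit_standardizer_population_moments():
    params = fit_standardizer(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    assert params.means["x"] == pytest.approx(2.0)
    assert params.sds["x"] == pytest.approx(0.8164966, abs=1e-6)
    z = (np.array([1.0, 2.0, 3.0]) - params.means["x"]) / params.sds["x"]
    assert z == pytest.approx([-1.2247449, 0.0, 1.2247449], abs=1e-6)


def test_fit_standardizer_drops_constant_column():
    with pytest.warns(DegenerateFeatureWarning):
        params = fit_standardizer(pd.DataFrame({"x": [5.0, 5.0, 5.0], "y": [1.0, 2.0, 4.0]}))
    assert params.dropped == ("x",)
    assert "y" in params.means


def test_one_hot_basics():
    assert one_hot(3, [1, 2, 3, 4]).tolist() == [0, 0, 1, 0]
    assert one_hot("ZZZ", ["AAA", "ACG"]).sum() == 0  # lenient unseen
    with pytest.raises(ContractViolationError):
        one_hot("ZZZ", ["AAA"], strict=True)


@pytest.mark.parametrize(
    "missing_frac, threshold, kept",
    [(0.244, 0.2, False), (0.05, 0.2, True), (0.01, 0.0, False), (0.0, 0.0, True)],
)
def test_drop_high_missingness(missing_frac, threshold, kept):
    n = 1000
    vals = np.arange(n, dtype=float)
    vals[: int(missing_frac * n)] = np.nan
    df = pd.DataFrame({"GQ": vals, "DP": np.arange(n, dtype=float)})
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained, report = drop_high_missingness(df, threshold)
    assert ("GQ" in retained) is kept
    assert report["GQ"] == pytest.approx(missing_frac, abs=1e-9)


def _site_table(n=300, seed=5, **kw):
    return synthetic.generate_feature_table(
        synthetic.SyntheticConfig(n_sites=n, seed=seed, **kw)
    )


def test_build_feature_matrix_shape_and_columns():
    """GQ (24.4% missing) is dropped, leaving 3 standardized columns plus
    one-hot blocks for CALL (4) and the two trios (64 each)."""
    table = _site_table()
    with pytest.warns(DegenerateFeatureWarning):
        matrix, encoder = featurize.build_feature_matrix(table)
    assert encoder.retained_quantitative == ("QUAL", "DP", "DP2")
    assert matrix.n_features == 3 + 4 + 64 + 64
    assert matrix.n_rows == (table["label"] != "excluded").sum()
    # training columns standardized to mean 0, population sd 1
    for j in range(3):
        assert matrix.X[:, j].mean() == pytest.approx(0.0, abs=1e-9)
        assert matrix.X[:, j].std() == pytest.approx(1.0, abs=1e-9)


def test_one_hot_blocks_sum_to_one_per_row():
    table = _site_table()
    with pytest.warns(DegenerateFeatureWarning):
        matrix, encoder = featurize.build_feature_matrix(table)
    start = len(encoder.retained_quantitative)
    for feat in encoder.spec.categorical:
        width = len(encoder.levels[feat])
        block = matrix.X[:, start : start + width]
        assert np.all(block.sum(axis=1) == 1.0)
        start += width


def test_column_metadata_round_trip():
    table = _site_table()
    with pytest.warns(DegenerateFeatureWarning):
        matrix, encoder = featurize.build_feature_matrix(table)
    assert matrix.column_info(0) == ("QUAL", None)
    assert matrix.column_info(3) == ("CALL", 1)
    feats = {matrix.column_info(i)[0] for i in range(matrix.n_features)}
    assert feats == {"QUAL", "DP", "DP2", "CALL", "UP_TRIO", "DOWN_TRIO"}


def test_encoding_is_deterministic():
    t1, t2 = _site_table(), _site_table()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1, _ = featurize.build_feature_matrix(t1)
        m2, _ = featurize.build_feature_matrix(t2)
    assert m1.X.tobytes() == m2.X.tobytes()
    assert m1.columns == m2.columns


def test_transform_never_reestimates_moments():
    """Validation rows are standardized with training moments: a shifted
    validation set keeps its shift in z-space."""
    table = _site_table(n=400)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        encoder = FeatureEncoder().fit(table)
        shifted = table.copy()
        shifted["dp"] = shifted["dp"] + 10
        base = encoder.transform(table)
        moved = encoder.transform(shifted)
    j = list(encoder.retained_quantitative).index("DP")
    sd = encoder.params.sds["DP"]
    assert moved.X[:, j] - base.X[:, j] == pytest.approx(10.0 / sd, abs=1e-9)


def test_matrix_tsv_round_trip(tmp_path):
    table = _site_table(n=150)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, _ = featurize.build_feature_matrix(table)
    path = str(tmp_path / "m.tsv")
    matrix.to_tsv(path)
    back = FeatureMatrix.read_tsv(path)
    assert back.columns == matrix.columns
    assert np.allclose(back.X, matrix.X)
    assert (back.y == matrix.y).all()


def test_empty_transform_keeps_metadata():
    table = _site_table(n=200)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        encoder = FeatureEncoder().fit(table)
        empty = encoder.transform(table.iloc[0:0])
    assert empty.n_rows == 0
    assert empty.n_features == len(encoder.columns)


def test_rank_int_mode_is_monotone_and_bounded():
    table = _site_table(n=300)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enc = FeatureEncoder(FeatureSpec(standardize="rank_int")).fit(table)
        mat = enc.transform(table)
    j = list(enc.retained_quantitative).index("DP")
    z = mat.X[:, j]
    dp = table.loc[table["label"] != "excluded", "dp"].to_numpy(float)
    order = np.argsort(dp, kind="stable")
    assert np.all(np.diff(z[order]) >= -1e-12)
    assert np.all(np.abs(z) < 4.5)
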