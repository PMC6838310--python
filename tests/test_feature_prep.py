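"""Missingness screen, chained-equation imputation, grouped dummy coding
and standardization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from deprisk import generate_cohort, inject_missingness
from deprisk.feature_prep import (
    decode_dummies,
    encode_dummies,
    impute,
    screen_missingness,
    standardize,
)
from deprisk.synthetic_cohort import FeatureSchema, LabeledFeatureTable

from conftest import small_cohort_spec


def _table_from_frame(df, kinds, levels=None):
    n = len(df)
    schema = FeatureSchema(kinds=kinds, levels=levels or {},
                           sources={k: "sociodemographic" for k in kinds})
    return LabeledFeatureTable(
        data=df,
        outcome=pd.Series(np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)],
                          index=df.index),
        cohort=pd.Series(["training_reference"] * (n // 2)
                         + ["training_patient"] * (n - n // 2), index=df.index),
        schema=schema,
    )


# -- missingness screen ----------------------------------------------------


def test_screen_keeps_complete_features(small_table):
    out, dropped = screen_missingness(small_table)
    assert dropped == []
    assert out.data.shape == small_table.data.shape


@pytest.mark.parametrize("n_missing,kept", [(6, False), (5, True)])
def test_screen_boundary_is_strict(n_missing, kept):
    """More than 5% missing drops a feature; exactly 5% survives."""
    idx = [f"s{i}" for i in range(100)]
    x = pd.Series(np.arange(100.0), index=idx)
    x.iloc[:n_missing] = np.nan
    df = pd.DataFrame({"a": x, "b": np.ones(100)}, index=idx)
    table = _table_from_frame(df, {"a": "continuous", "b": "continuous"})
    out, dropped = screen_missingness(table, max_rate=0.05)
    assert ("a" in out.data.columns) is kept
    assert ("a" in dropped) is (not kept)


# -- imputation ------------------------------------------------------------


def test_impute_no_missing_is_identity(small_table):
    out = impute(small_table, seed=0)
    pd.testing.assert_frame_equal(out.data, small_table.data)


def test_impute_duplicate_column_recovers_exactly():
    """A missing cell in a perfect copy of a complete column is recovered
    from the duplicate (noise-free limit of the predictive draw)."""
    rng = np.random.default_rng(0)
    idx = [f"s{i}" for i in range(60)]
    a = rng.standard_normal(60)
    b = a.copy()
    b[10] = np.nan
    df = pd.DataFrame({"a": a, "b": b}, index=idx)
    table = _table_from_frame(df, {"a": "continuous", "b": "continuous"})
    out = impute(table, n_imputations=3, seed=1)
    assert out.data.loc["s10", "b"] == pytest.approx(a[10], abs=1e-6)


def test_impute_mask_and_recover_beats_column_sd():
    spec = small_cohort_spec(seed=13)
    truth = generate_cohort(spec)
    masked = inject_missingness(truth, 0.05, seed=99)
    out = impute(masked, seed=2)
    assert not out.data.isna().any().any()
    errs = []
    for feat, kind in truth.schema.kinds.items():
        if kind != "continuous":
            continue
        miss = masked.data[feat].isna()
        if not miss.any():
            continue
        resid = (out.data.loc[miss, feat].astype(float)
                 - truth.data.loc[miss, feat].astype(float))
        errs.append(np.sqrt((resid**2).mean()) / truth.data[feat].astype(float).std())
    assert errs, "expected at least one masked continuous feature"
    assert np.median(errs) < 1.0


def test_impute_deterministic(small_table):
    masked = inject_missingness(small_table, 0.04, seed=3)
    a = impute(masked, seed=4)
    b = impute(masked, seed=4)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_impute_rejects_fully_missing_column():
    idx = [f"s{i}" for i in range(10)]
    df = pd.DataFrame({"a": np.ones(10), "b": [np.nan] * 10}, index=idx)
    table = _table_from_frame(df, {"a": "continuous", "b": "continuous"})
    with pytest.raises(ValueError, match="no observed values"):
        impute(table, seed=0)


# -- dummy coding ----------------------------------------------------------


def test_encode_ordinal_gives_three_severity_columns(small_table):
    design, groups = encode_dummies(small_table)
    cols = [c for c in design.columns if c.startswith("sadness")]
    assert cols == ["sadness; mild", "sadness; moderate", "sadness; severe"]
    gids = {groups.group_ids[design.columns.index(c)] for c in cols}
    assert len(gids) == 1  # one penalty group for the whole dummy set


def test_encode_binary_and_continuous(small_table):
    design, groups = encode_dummies(small_table)
    assert "smoking; yes" in design.columns
    assert "smoking; no" not in design.columns  # reference level dropped
    assert "bmi" in design.columns
    bmi_gid = groups.group_ids[design.columns.index("bmi")]
    assert (groups.group_ids == bmi_gid).sum() == 1  # singleton group


def test_group_and_column_counts(small_table):
    design, groups = encode_dummies(small_table)
    schema = small_table.schema
    n_features = len(schema.features)
    assert groups.n_groups == n_features
    expected_cols = 0
    for f, kind in schema.kinds.items():
        if kind == "continuous":
            expected_cols += 1
        elif kind == "ordinal":
            expected_cols += 3
        else:
            expected_cols += len(schema.levels[f]) - 1
    assert design.p == expected_cols


def test_encode_decode_roundtrip(small_table):
    design, groups = encode_dummies(small_table)
    back = decode_dummies(design, groups, small_table.schema)
    for feat in small_table.schema.features:
        expected = small_table.data[feat]
        got = back[feat]
        if small_table.schema.kinds[feat] == "continuous":
            assert np.allclose(got.astype(float), expected.astype(float))
        else:
            assert (got.to_numpy(dtype=object)
                    == expected.to_numpy(dtype=object)).all()


def test_encode_rejects_undeclared_level():
    idx = [f"s{i}" for i in range(8)]
    df = pd.DataFrame({"color": ["red"] * 4 + ["blue"] * 3 + ["green"]}, index=idx)
    table = _table_from_frame(df, {"color": "categorical"},
                              levels={"color": ("red", "blue")})
    with pytest.raises(ValueError, match="undeclared level"):
        encode_dummies(table)


# -- standardization -------------------------------------------------------


def test_standardize_centers_continuous_only(small_table):
    raw, _ = encode_dummies(small_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = standardize(raw)
    j = out.columns.index("bmi")
    assert out.X[:, j].mean() == pytest.approx(0.0, abs=1e-12)
    assert out.X[:, j].std() == pytest.approx(1.0, abs=1e-12)
    dummy_cols = [jj for jj, c in enumerate(out.columns) if "; " in c]
    assert np.isin(out.X[:, dummy_cols], [0.0, 1.0]).all()


def test_standardize_idempotent_on_standardized_column():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    x = (x - x.mean()) / x.std()
    from deprisk.feature_prep import DesignMatrix
    d = DesignMatrix(X=x[:, None], y=(rng.random(50) < 0.5).astype(float),
                     columns=["x"], is_dummy=np.array([False]))
    out = standardize(d)
    assert np.allclose(out.X[:, 0], x, atol=1e-12)


def test_standardize_drops_constant_column_with_warning():
    rng = np.random.default_rng(1)
    from deprisk.feature_prep import DesignMatrix
    X = np.column_stack([rng.standard_normal(30), np.full(30, 2.0)])
    d = DesignMatrix(X=X, y=(rng.random(30) < 0.5).astype(float),
                     columns=["x", "const"], is_dummy=np.array([False, False]))
    with pytest.warns(UserWarning, match="constant"):
        out = standardize(d)
    assert out.columns == ["x"]


def test_standardize_reuses_training_parameters(small_spec):
    from deprisk import generate_extrapolation_set

    train = generate_cohort(small_spec)
    extrap = generate_extrapolation_set(small_spec)
    raw_train, _ = encode_dummies(train)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        strain = standardize(raw_train)
    raw_ex, _ = encode_dummies(extrap)
    sex_ = standardize(raw_ex, params=strain.scaling)
    assert sex_.columns == strain.columns
    j = sex_.columns.index("pep_001")
    # planted shift: extrapolation means, under training scaling, sit off 0
    assert abs(sex_.X[:, j].mean()) > 0.1
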