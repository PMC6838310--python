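"""AICc, Akaike weights, unique models, and the two averaging paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deprisk.ensemble_averaging import (
    AveragedModel,
    EnsembleResult,
    FittedModel,
    aicc,
    akaike_weights,
    average_ensemble,
    dominant_model_average,
    extract_and_average,
    identify_unique_models,
    run_ensemble,
    selection_fractions,
)

from conftest import small_cohort_spec


# -- AICc ------------------------------------------------------------------


def test_aicc_worked_example():
    # AIC = 100 + 6 = 106; correction 2*3*4/168
    assert aicc(-50.0, 3, 172) == pytest.approx(106 + 24 / 168)
    assert aicc(-50.0, 3, 172) == pytest.approx(106.142857, abs=1e-6)


def test_aicc_reduces_to_aic_for_null_model():
    assert aicc(-40.0, 0, 100) == pytest.approx(80.0)


def test_aicc_approaches_aic_for_large_n():
    assert aicc(-50.0, 3, 10**9) == pytest.approx(106.0, abs=1e-6)


def test_aicc_undefined_when_correction_blows_up():
    with pytest.raises(ValueError):
        aicc(-50.0, 171, 172)


# -- Akaike weights --------------------------------------------------------


def test_weights_single_model():
    assert np.allclose(akaike_weights([123.4]), [1.0])


def test_weights_two_equal_models():
    assert np.allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])


def test_weights_worked_example():
    w = akaike_weights([100.0, 102.0, 110.0])
    # direct formula: exp(-delta/2) / sum, delta = (0, 2, 10)
    raw = np.exp(-0.5 * np.array([0.0, 2.0, 10.0]))
    assert np.allclose(w, raw / raw.sum(), atol=1e-12)
    assert np.allclose(w, [0.7275, 0.2676, 0.0049], atol=5e-4)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-500, 500), min_size=1, max_size=10),
       st.floats(-1e4, 1e4))
def test_weights_sum_to_one_and_shift_invariant(values, shift):
    w = akaike_weights(values)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(w, akaike_weights([v + shift for v in values]), atol=1e-9)


def test_weight_monotone_in_aicc():
    w = akaike_weights([10.0, 12.0, 11.0])
    assert w[0] > w[2] > w[1]


# -- unique models and averaging on constructed ensembles ------------------


def _model(repeat, features, coef, weight, intercept=0.0):
    return FittedModel(
        repeat=repeat, features=tuple(sorted(features)), coef=dict(coef),
        intercept=intercept, k=len(features), n=100, log_likelihood=-50.0,
        lam=0.1, aicc=100.0, weight=weight,
    )


def _result(models, feature_names, columns):
    return EnsembleResult(models=models, n=100, feature_names=feature_names,
                          columns=columns)


def test_unique_models_probabilities_and_counts():
    models = [
        _model(1, ["a"], {"a": 1.0}, 0.3),
        _model(2, ["a"], {"a": 1.0}, 0.2),
        _model(3, ["b"], {"b": 2.0}, 0.5),
    ]
    res = _result(models, ["a", "b"], ["a", "b"])
    uniques = identify_unique_models(res)
    assert sum(u.occurrences for u in uniques) == 3
    probs = {u.features: u.probability for u in uniques}
    assert probs[("a",)] == pytest.approx(0.5)
    assert probs[("b",)] == pytest.approx(0.5)


def test_all_identical_models_single_unique():
    models = [_model(i, ["a"], {"a": 1.0}, 0.25) for i in range(1, 5)]
    res = _result(models, ["a"], ["a"])
    uniques = identify_unique_models(res)
    assert len(uniques) == 1
    assert uniques[0].probability == pytest.approx(1.0)
    assert uniques[0].occurrences == 4


def test_dominant_path_taken_when_strongly_supported():
    models = [_model(i, ["a"], {"a": 2.0}, 0.245) for i in range(1, 5)]
    models.append(_model(5, ["b"], {"b": 1.0}, 0.02))
    res = _result(models, ["a", "b"], ["a", "b"])
    m = dominant_model_average(res, probability_threshold=0.9)
    assert m is not None and m.dominant
    assert m.features == ("a",)
    # members' weights renormalize; constant coefficient is preserved
    assert m.coef["a"] == pytest.approx(2.0)


def test_no_dominant_model_when_support_split():
    models = [
        _model(1, ["a"], {"a": 1.0}, 0.5),
        _model(2, ["b"], {"b": 1.0}, 0.28),
        _model(3, ["c"], {"c": 1.0}, 0.22),
    ]
    res = _result(models, ["a", "b", "c"], ["a", "b", "c"])
    assert dominant_model_average(res, 0.9) is None


def test_equal_weights_many_combinations_no_dominant():
    models = [_model(i, [f], {f: 1.0}, 0.25)
              for i, f in enumerate(["a", "b", "c", "d"], 1)]
    res = _result(models, ["a", "b", "c", "d"], ["a", "b", "c", "d"])
    assert dominant_model_average(res, 0.9) is None


def test_extraction_threshold_inclusive():
    """Fractions 1.0 and 0.93 are retained at threshold 0.9; 0.89 is not."""
    R = 100
    models = []
    for i in range(1, R + 1):
        feats = ["a"]
        if i <= 93:
            feats.append("b")
        if i <= 89:
            feats.append("c")
        coef = {f: 1.0 for f in feats}
        models.append(_model(i, feats, coef, 1.0 / R))
    res = _result(models, ["a", "b", "c"], ["a", "b", "c"])
    fr = selection_fractions(res)
    assert fr == {"a": 1.0, "b": 0.93, "c": 0.89}
    m = extract_and_average(res, fraction_threshold=0.9)
    assert set(m.features) == {"a", "b"}


def test_average_of_constant_coefficient_is_exact():
    models = [_model(i, ["a"], {"a": 0.7}, w, intercept=-1.0)
              for i, w in enumerate([0.4, 0.35, 0.25], 1)]
    res = _result(models, ["a"], ["a"])
    m = extract_and_average(res, 0.9)
    assert m.coef["a"] == pytest.approx(0.7)
    assert m.intercept == pytest.approx(-1.0)


def test_partial_presence_shrinks_toward_zero():
    """beta 0.5 in models carrying total weight 0.6, absent elsewhere -> 0.3."""
    models = [
        _model(1, ["a", "b"], {"a": 0.5, "b": 1.0}, 0.6),
        _model(2, ["b"], {"b": 1.0}, 0.4),
    ]
    res = _result(models, ["a", "b"], ["a", "b"])
    m = extract_and_average(res, fraction_threshold=0.5)
    assert m.coef["a"] == pytest.approx(0.3)
    assert m.coef["b"] == pytest.approx(1.0)


def test_extraction_errors_when_nothing_qualifies():
    models = [
        _model(1, ["a"], {"a": 1.0}, 0.5),
        _model(2, ["b"], {"b": 1.0}, 0.5),
    ]
    res = _result(models, ["a", "b"], ["a", "b"])
    with pytest.raises(ValueError, match="threshold"):
        extract_and_average(res, 0.9)
    fallback = average_ensemble(res, 0.9, 0.9)
    assert fallback.features == ()


def test_shrinkage_bound_holds():
    rng = np.random.default_rng(0)
    R = 20
    models = []
    w = rng.random(R)
    w /= w.sum()
    for i in range(R):
        present = rng.random() < 0.6
        coef = {"a": float(rng.normal())} if present else {}
        models.append(_model(i + 1, ["a"] if present else [], coef, float(w[i])))
    res = _result(models, ["a"], ["a"])
    m = extract_and_average(res, fraction_threshold=0.0)
    max_abs = max((abs(mm.coef.get("a", 0.0)) for mm in models), default=0.0)
    assert abs(m.coef["a"]) <= max_abs + 1e-12


# -- the real ensemble on a small cohort -----------------------------------


@pytest.fixture(scope="module")
def small_ensemble():
    import warnings
    from deprisk import generate_cohort
    from deprisk.feature_prep import encode_dummies, standardize

    spec = small_cohort_spec(seed=17, informative_features=[
        ("pep_001", "continuous", 1.5),
        ("bmi", "continuous", 1.5),
    ])
    table = generate_cohort(spec)
    raw, groups = encode_dummies(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = standardize(raw)
    groups = groups.subset(design.columns)
    result = run_ensemble(design, groups, R=8, seed=123, n_folds=5, n_lambda=40)
    return design, groups, result


def test_run_ensemble_reproducible(small_ensemble):
    import warnings
    design, groups, result = small_ensemble
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        again = run_ensemble(design, groups, R=8, seed=123, n_folds=5, n_lambda=40)
    assert [m.features for m in again.models] == [m.features for m in result.models]
    assert np.allclose([m.weight for m in again.models],
                       [m.weight for m in result.models])
    assert np.allclose([m.aicc for m in again.models],
                       [m.aicc for m in result.models])


def test_strong_signal_reaches_full_selection_fraction(small_ensemble):
    _, _, result = small_ensemble
    fr = selection_fractions(result)
    assert fr["pep_001"] == pytest.approx(1.0)
    assert fr["bmi"] == pytest.approx(1.0)
    assert all(0.0 <= v <= 1.0 for v in fr.values())


def test_ensemble_weights_and_unique_probs_sum_to_one(small_ensemble):
    _, _, result = small_ensemble
    assert sum(m.weight for m in result.models) == pytest.approx(1.0, abs=1e-12)
    uniques = identify_unique_models(result)
    assert sum(u.probability for u in uniques) == pytest.approx(1.0, abs=1e-12)
    assert sum(u.occurrences for u in uniques) == result.R


def test_planted_effect_monotone_in_size():
    """A larger planted effect never lowers that feature's selection
    fraction (checked over two replicate seeds)."""
    import warnings
    from deprisk import generate_cohort
    from deprisk.feature_prep import encode_dummies, standardize

    fractions = {}
    for effect in (0.3, 1.8):
        vals = []
        for seed in (31, 32):
            spec = small_cohort_spec(
                seed=seed,
                informative_features=[("pep_001", "continuous", effect)])
            table = generate_cohort(spec)
            raw, groups = encode_dummies(table)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                design = standardize(raw)
            groups = groups.subset(design.columns)
            res = run_ensemble(design, groups, R=6, seed=5, n_folds=5, n_lambda=30)
            vals.append(selection_fractions(res)["pep_001"])
        fractions[effect] = np.mean(vals)
    assert fractions[1.8] >= fractions[0.3]


def test_ensemble_roundtrips_through_json(small_ensemble):
    _, _, result = small_ensemble
    back = EnsembleResult.from_dict(result.to_dict())
    assert [m.to_dict() for m in back.models] == [m.to_dict() for m in result.models]
    assert back.feature_names == result.feature_names
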