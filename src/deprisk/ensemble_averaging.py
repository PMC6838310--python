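"""Repeated-CV group-LASSO ensembles with AICc-weighted model averaging.

The model-selection procedure refits group-LASSO with 10-fold
cross-validated penalty selection R times (default 100) on the *same*
data; only the random fold partition changes between repeats, so the
spread of selected models measures selection uncertainty.  Each repeat's
model is scored by small-sample-corrected AIC,

    AIC  = -2 logL + 2k
    AICc = AIC + 2k(k+1) / (n - k - 1),

and converted to an Akaike weight w_i = exp(-Delta_i/2) / sum exp(-Delta/2),
interpreted as the probability that model i is the best approximating model.
Repeats sharing one feature combination form a *unique model* whose
probability is the sum of its members' weights.

Two averaging paths mirror how the analysis resolves (or fails to resolve)
selection uncertainty: when one unique model carries probability above a
threshold (default 0.9) the final model is that combination, with
coefficients averaged over its member repeats; otherwise features with
selection fraction >= 0.9 are retained and each coefficient is the
Akaike-weighted average over all repeats, with repeats that omitted the
feature contributing zero (shrinking it toward zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .feature_prep import DesignMatrix, GroupStructure, ScalingParams
from .group_lasso import (
    cross_validate,
    fit_path,
    lambda_path,
    logistic_loglik,
    predict_proba,
)

__all__ = [
    "FittedModel",
    "UniqueModel",
    "EnsembleResult",
    "AveragedModel",
    "run_ensemble",
    "selection_fractions",
    "aicc",
    "akaike_weights",
    "identify_unique_models",
    "dominant_model_average",
    "extract_and_average",
    "average_ensemble",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class FittedModel:
    """One ensemble member: the model chosen by one CV repeat."""

    repeat: int
    features: tuple[str, ...]
    coef: dict[str, float]
    intercept: float
    k: int
    n: int
    log_likelihood: float
    lam: float
    aicc: float = math.nan
    weight: float = math.nan
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "repeat": self.repeat,
            "features": list(self.features),
            "coef": {k: float(v) for k, v in self.coef.items()},
            "intercept": float(self.intercept),
            "k": self.k,
            "n": self.n,
            "log_likelihood": float(self.log_likelihood),
            "lambda": float(self.lam),
            "aicc": float(self.aicc),
            "weight": float(self.weight),
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            repeat=int(d["repeat"]), features=tuple(d["features"]),
            coef={k: float(v) for k, v in d["coef"].items()},
            intercept=float(d["intercept"]), k=int(d["k"]), n=int(d["n"]),
            log_likelihood=float(d["log_likelihood"]), lam=float(d["lambda"]),
            aicc=float(d["aicc"]), weight=float(d["weight"]),
            converged=bool(d["converged"]),
        )


@dataclass
class UniqueModel:
    """A distinct feature combination and its pooled evidence."""

    features: tuple[str, ...]
    occurrences: int
    probability: float
    member_repeats: tuple[int, ...] = ()


@dataclass
class EnsembleResult:
    """All R repeats plus their selection-fraction / unique-model summaries."""

    models: list[FittedModel]
    n: int
    feature_names: list[str]
    columns: list[str] = field(default_factory=list)
    scaling: ScalingParams | None = None

    @property
    def R(self) -> int:
        return len(self.models)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "feature_names": list(self.feature_names),
            "columns": list(self.columns),
            "scaling": self.scaling.to_dict() if self.scaling else None,
            "models": [m.to_dict() for m in self.models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleResult":
        return cls(
            models=[FittedModel.from_dict(m) for m in d["models"]],
            n=int(d["n"]), feature_names=list(d["feature_names"]),
            columns=list(d.get("columns", [])),
            scaling=ScalingParams.from_dict(d["scaling"]) if d.get("scaling") else None,
        )


@dataclass
class AveragedModel:
    """The final prediction model after feature extraction and averaging."""

    features: tuple[str, ...]
    coef: dict[str, float]
    intercept: float
    fraction_threshold: float
    dominant: bool
    selection_fractions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coef": {k: float(v) for k, v in self.coef.items()},
            "intercept": float(self.intercept),
            "fraction_threshold": self.fraction_threshold,
            "dominant": self.dominant,
            "selection_fractions": {k: float(v) for k, v in self.selection_fractions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AveragedModel":
        return cls(
            features=tuple(d["features"]),
            coef={k: float(v) for k, v in d["coef"].items()},
            intercept=float(d["intercept"]),
            fraction_threshold=float(d["fraction_threshold"]),
            dominant=bool(d["dominant"]),
            selection_fractions={k: float(v) for k, v in
                                 d.get("selection_fractions", {}).items()},
        )


# --------------------------------------------------------------------------
# Information criteria
# --------------------------------------------------------------------------


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    AIC = -2 logL + 2k, plus the correction 2k(k+1)/(n-k-1); undefined when
    n - k - 1 <= 0.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    aic = -2.0 * log_likelihood + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights: exp(-Delta_i/2) normalized to sum to one.

    Delta_i is each value's excess over the minimum; subtracting the
    minimum before exponentiating makes the computation overflow-safe and
    leaves the weights invariant to any constant shift of the criterion.
    """
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0 or not np.isfinite(a).any():
        raise ValueError("at least one finite criterion value is required")
    delta = a - np.nanmin(a)
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(a)] = 0.0
    return w / w.sum()


# --------------------------------------------------------------------------
# Ensemble
# --------------------------------------------------------------------------


def _repeat_seed(master_seed: int, repeat: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), 7, int(repeat)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_ensemble(
    design: DesignMatrix,
    groups: GroupStructure,
    R: int = 100,
    seed: int = 0,
    n_folds: int = 10,
    n_lambda: int = 100,
    ratio: float = 0.01,
    cv_rule: str = "1se",
    k_mode: str = "features",
    logl_mode: str = "penalized",
) -> EnsembleResult:
    """Repeat CV penalty selection R times and score each chosen model.

    The data are fixed; only the fold partition (seeded per repeat,
    derived deterministically from the master seed) varies.  Each repeat
    fits the full path on all samples down to its chosen lambda and
    records the model at that penalty: selected features, penalized
    coefficients, log-likelihood at the fitted probabilities, AICc and
    (after all repeats) Akaike weight.

    ``k_mode`` counts model size as selected *features* (a dummy group
    counts one; default) or as *parameters* (nonzero columns).
    ``logl_mode='refit'`` scores each model by an unpenalized logistic
    refit on its selected columns instead of the penalized fit.
    """
    if R < 2:
        raise ValueError("ensemble size R must be at least 2")
    if k_mode not in ("features", "parameters"):
        raise ValueError("k_mode must be 'features' or 'parameters'")
    if logl_mode not in ("penalized", "refit"):
        raise ValueError("logl_mode must be 'penalized' or 'refit'")

    lambdas = lambda_path(design, groups, n_lambda=n_lambda, ratio=ratio)
    feature_names = groups.group_features()
    models: list[FittedModel] = []
    n_dropped = 0
    for i in range(1, R + 1):
        cv = cross_validate(
            design, groups, n_folds=n_folds, seed=_repeat_seed(seed, i),
            rule=cv_rule, lambdas=lambdas,
        )
        sub_path = lambdas[: cv.chosen_index + 1]
        fit = fit_path(design, groups, sub_path)[-1]
        if not fit.converged:
            n_dropped += 1
            logger.warning("repeat %d did not converge; excluded from weighting", i)
            continue
        feats = tuple(sorted(fit.selected_features(groups)))
        nonzero = fit.coef != 0.0
        coef = {c: float(v) for c, v in zip(design.columns, fit.coef) if v != 0.0}
        k = len(feats) if k_mode == "features" else int(nonzero.sum())
        if logl_mode == "refit" and nonzero.any():
            logl = _refit_loglik(design, nonzero)
        else:
            logl = logistic_loglik(design.y, predict_proba(design, fit))
        models.append(FittedModel(
            repeat=i, features=feats, coef=coef, intercept=float(fit.intercept),
            k=k, n=design.n, log_likelihood=logl, lam=fit.lam,
        ))
    if n_dropped:
        logger.warning("%d of %d repeats excluded for non-convergence", n_dropped, R)
    if not models:
        raise RuntimeError("no ensemble repeat converged")
    for m in models:
        m.aicc = aicc(m.log_likelihood, m.k, m.n)
    weights = akaike_weights([m.aicc for m in models])
    for m, w in zip(models, weights):
        m.weight = float(w)
    return EnsembleResult(
        models=models, n=design.n, feature_names=feature_names,
        columns=list(design.columns), scaling=design.scaling,
    )


def _refit_loglik(design: DesignMatrix, nonzero: np.ndarray) -> float:
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
    clf.fit(design.X[:, nonzero], design.y)
    p = clf.predict_proba(design.X[:, nonzero])[:, 1]
    return logistic_loglik(design.y, p)


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------


def selection_fractions(result: EnsembleResult) -> dict[str, float]:
    """Per-feature proportion of ensemble repeats that selected it."""
    R = result.R
    counts = {f: 0 for f in result.feature_names}
    for m in result.models:
        for f in m.features:
            counts[f] += 1
    return {f: c / R for f, c in counts.items()}


def identify_unique_models(result: EnsembleResult) -> list[UniqueModel]:
    """Group repeats by their selected feature combination.

    Each unique combination gets an occurrence count and a model
    probability equal to the summed Akaike weights of its members;
    returned sorted by probability, descending.
    """
    grouped: dict[tuple[str, ...], list[FittedModel]] = {}
    for m in result.models:
        grouped.setdefault(m.features, []).append(m)
    out = [
        UniqueModel(
            features=feats,
            occurrences=len(ms),
            probability=float(sum(m.weight for m in ms)),
            member_repeats=tuple(m.repeat for m in ms),
        )
        for feats, ms in grouped.items()
    ]
    out.sort(key=lambda u: (-u.probability, -u.occurrences, u.features))
    return out


def _weighted_average(
    models: Sequence[FittedModel],
    weights: Sequence[float],
    features: Sequence[str],
    result: EnsembleResult,
    fraction_threshold: float,
    dominant: bool,
) -> AveragedModel:
    fractions = selection_fractions(result)
    columns: list[str] = []
    feature_set = set(features)
    for col in result.columns:
        feat = _feature_of_column(col)
        if feat in feature_set:
            columns.append(col)
    coef = {c: 0.0 for c in columns}
    intercept = 0.0
    for m, w in zip(models, weights):
        intercept += w * m.intercept
        for c in columns:
            coef[c] += w * m.coef.get(c, 0.0)
    return AveragedModel(
        features=tuple(features), coef=coef, intercept=float(intercept),
        fraction_threshold=fraction_threshold, dominant=dominant,
        selection_fractions={f: fractions[f] for f in features},
    )


def _feature_of_column(col: str) -> str:
    return col.split("; ")[0]


def dominant_model_average(
    result: EnsembleResult, probability_threshold: float = 0.9
) -> AveragedModel | None:
    """Average within a single strongly supported unique model, if any.

    When one unique model's probability exceeds the threshold, its feature
    combination is the final model; coefficients are averaged over only its
    member repeats with weights renormalized within them.  Returns None
    when no unique model dominates, signalling the feature-extraction path.
    """
    uniques = identify_unique_models(result)
    best = uniques[0]
    if best.probability <= probability_threshold:
        return None
    members = [m for m in result.models if m.features == best.features]
    total = sum(m.weight for m in members)
    weights = [m.weight / total for m in members]
    logger.info(
        "dominant unique model (probability %.3f, %d features) taken",
        best.probability, len(best.features),
    )
    return _weighted_average(
        members, weights, best.features, result,
        fraction_threshold=float("nan"), dominant=True,
    )


def extract_and_average(
    result: EnsembleResult, fraction_threshold: float = 0.9
) -> AveragedModel:
    """Feature extraction + model averaging across all repeats.

    Features with selection fraction >= threshold (inclusive) are
    retained; each retained column's coefficient is the Akaike-weighted
    average over all R models, counting zero where the feature was not
    selected.  The intercept is averaged with the same weights.
    """
    fractions = selection_fractions(result)
    retained = [f for f in result.feature_names if fractions[f] >= fraction_threshold]
    if not retained:
        best = max(fractions.values(), default=0.0)
        raise ValueError(
            f"no feature reaches selection fraction {fraction_threshold} "
            f"(best observed: {best:.2f}); review the threshold"
        )
    weights = [m.weight for m in result.models]
    return _weighted_average(
        result.models, weights, retained, result,
        fraction_threshold=fraction_threshold, dominant=False,
    )


def average_ensemble(
    result: EnsembleResult,
    fraction_threshold: float = 0.9,
    probability_threshold: float = 0.9,
) -> AveragedModel:
    """Resolve an ensemble to its final model: dominant path, else extraction.

    Falls back to an intercept-only model (Akaike-weighted intercept, no
    features) when neither path applies — i.e. no dominant unique model
    and no feature reaches the extraction threshold, as happens on data
    without signal.
    """
    model = dominant_model_average(result, probability_threshold)
    if model is not None:
        return model
    try:
        return extract_and_average(result, fraction_threshold)
    except ValueError:
        logger.warning(
            "no dominant model and no feature at fraction >= %.2f; "
            "falling back to intercept-only model", fraction_threshold,
        )
        intercept = float(sum(m.weight * m.intercept for m in result.models))
        return AveragedModel(
            features=(), coef={}, intercept=intercept,
            fraction_threshold=fraction_threshold, dominant=False,
        )
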