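"""Design-matrix preparation: missingness screen, chained-equation
imputation, grouped dummy coding and standardization.

Categorical and ordinal features are expanded to reference-coded indicator
columns that share one penalty group, so the group-LASSO selects or drops a
feature's whole dummy set together; continuous features are singleton
groups.  Scaling statistics are estimated on the training set only and
stored for reuse on evaluation data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .synthetic_cohort import SEVERITY_LABELS, FeatureSchema, LabeledFeatureTable

__all__ = [
    "GroupStructure",
    "DesignMatrix",
    "ScalingParams",
    "screen_missingness",
    "impute",
    "encode_dummies",
    "decode_dummies",
    "standardize",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class GroupStructure:
    """Mapping from design-matrix columns to penalty groups.

    Columns are listed in design order; ``group_ids[j]`` is the group of
    column ``j``; ``feature_of[col]`` names the source feature, and
    ``feature_columns`` inverts it.  All dummies of one categorical feature
    share a group; each continuous feature is a singleton group.
    """

    columns: list[str]
    group_ids: np.ndarray
    feature_of: dict[str, str]

    def __post_init__(self) -> None:
        self.group_ids = np.asarray(self.group_ids, dtype=np.int64)
        if len(self.columns) != len(self.group_ids):
            raise ValueError("columns and group_ids length mismatch")

    @property
    def n_groups(self) -> int:
        return int(self.group_ids.max()) + 1 if len(self.group_ids) else 0

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_ids, minlength=self.n_groups)

    @property
    def feature_columns(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for col in self.columns:
            out.setdefault(self.feature_of[col], []).append(col)
        return out

    def group_features(self) -> list[str]:
        """Feature name per group, in group-id order."""
        names: dict[int, str] = {}
        for col, g in zip(self.columns, self.group_ids):
            names[int(g)] = self.feature_of[col]
        return [names[g] for g in range(self.n_groups)]

    def subset(self, keep_columns: Sequence[str]) -> "GroupStructure":
        keep = [c for c in self.columns if c in set(keep_columns)]
        feats_seen: dict[str, int] = {}
        gids = []
        for c in keep:
            f = self.feature_of[c]
            if f not in feats_seen:
                feats_seen[f] = len(feats_seen)
            gids.append(feats_seen[f])
        return GroupStructure(
            columns=keep,
            group_ids=np.asarray(gids, dtype=np.int64),
            feature_of={c: self.feature_of[c] for c in keep},
        )


@dataclass
class ScalingParams:
    """Per-column centering/scaling fitted on the training design."""

    columns: list[str]
    center: np.ndarray
    scale: np.ndarray
    is_dummy: np.ndarray

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "center": [float(v) for v in self.center],
            "scale": [float(v) for v in self.scale],
            "is_dummy": [bool(v) for v in self.is_dummy],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalingParams":
        return cls(
            columns=list(d["columns"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            is_dummy=np.asarray(d["is_dummy"], dtype=bool),
        )


@dataclass
class DesignMatrix:
    """Numeric design matrix with outcome and column metadata."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    is_dummy: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.y):
            raise ValueError("row count must equal outcome length")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names must match X width")
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains missing or non-finite values")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


# --------------------------------------------------------------------------
# Missingness screen
# --------------------------------------------------------------------------


def screen_missingness(
    table: LabeledFeatureTable, max_rate: float = 0.05
) -> tuple[LabeledFeatureTable, list[str]]:
    """Drop features whose missing fraction strictly exceeds ``max_rate``.

    The boundary is exclusive: a feature missing in exactly 5% of samples
    survives a 5% screen.
    """
    if not 0.0 < max_rate < 1.0:
        raise ValueError("max_rate must be in (0, 1)")
    frac = table.data.isna().mean()
    dropped = sorted(frac.index[frac > max_rate])
    if dropped:
        logger.info("missingness screen dropped %d feature(s): %s", len(dropped), dropped)
        table = table.drop_features(dropped)
    return table, dropped


# --------------------------------------------------------------------------
# Chained-equation imputation
# --------------------------------------------------------------------------


def _predictor_matrix(data: pd.DataFrame, schema: FeatureSchema,
                      exclude: str) -> np.ndarray:
    """Numeric predictor matrix from all features except ``exclude``.

    Categorical predictors are one-hot coded; ordinal predictors enter as
    their numeric severity.  Assumes ``data`` is fully filled.
    """
    cols: list[np.ndarray] = []
    for feat in schema.features:
        if feat == exclude:
            continue
        kind = schema.kinds[feat]
        if kind == "categorical":
            levels = schema.levels[feat]
            vals = data[feat].to_numpy(dtype=object)
            for lv in levels[1:]:
                cols.append((vals == lv).astype(float))
        else:
            cols.append(data[feat].to_numpy(dtype=float))
    return np.column_stack(cols)


def _standardize_predictors(P: np.ndarray) -> np.ndarray:
    mu = P.mean(axis=0)
    sd = P.std(axis=0)
    sd[sd == 0] = 1.0
    return (P - mu) / sd


def impute(
    table: LabeledFeatureTable,
    n_imputations: int = 5,
    seed: int = 0,
    n_sweeps: int = 3,
) -> LabeledFeatureTable:
    """Multiple imputation by chained equations, pooled to one table.

    Each chain initialises missing cells from the observed mean/mode, then
    sweeps over incomplete columns regressing each on all other features:
    Bayesian-flavoured draws come from a linear model plus residual noise
    for continuous targets, and from multinomial-logistic predicted
    probabilities for categorical/ordinal targets.  The ``n_imputations``
    chains are pooled cell-wise by mean (continuous) or mode
    (categorical/ordinal; ties go to the lower level).  Deterministic for a
    given seed.
    """
    schema = table.schema
    data = table.data
    incomplete = [f for f in schema.features if data[f].isna().any()]
    if not incomplete:
        return table
    for feat in incomplete:
        if data[feat].notna().sum() == 0:
            raise ValueError(f"feature {feat!r} has no observed values to impute from")

    chains: list[pd.DataFrame] = []
    for chain in range(n_imputations):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5, chain]))
        filled = data.copy()
        # Initial fill: mean / mode.
        for feat in incomplete:
            obs = data[feat].dropna()
            if schema.kinds[feat] == "continuous":
                filled[feat] = data[feat].fillna(float(obs.astype(float).mean()))
            else:
                mode = obs.mode().iloc[0]
                filled[feat] = data[feat].fillna(mode)
        for _sweep in range(n_sweeps):
            for feat in incomplete:
                miss = data[feat].isna().to_numpy()
                P = _standardize_predictors(_predictor_matrix(filled, schema, feat))
                kind = schema.kinds[feat]
                if kind == "continuous":
                    yobs = data[feat].to_numpy(dtype=float)[~miss]
                    A = np.column_stack([np.ones((~miss).sum()), P[~miss]])
                    # Small ridge for stability when p approaches n_obs.
                    AtA = A.T @ A + 1e-8 * np.eye(A.shape[1])
                    beta = np.linalg.solve(AtA, A.T @ yobs)
                    resid = yobs - A @ beta
                    dof = max(len(yobs) - A.shape[1], 1)
                    sigma = float(np.sqrt(resid @ resid / dof))
                    Amiss = np.column_stack([np.ones(miss.sum()), P[miss]])
                    draw = Amiss @ beta + rng.normal(0.0, sigma, size=miss.sum())
                    col = filled[feat].to_numpy(dtype=float)
                    col[miss] = draw
                    filled[feat] = col
                else:
                    yobs = data[feat][~miss]
                    classes = np.unique(yobs.to_numpy())
                    if len(classes) == 1:
                        filled.loc[miss, feat] = classes[0]
                        continue
                    clf = LogisticRegression(max_iter=200, C=1.0)
                    clf.fit(P[~miss], yobs.astype(str if kind == "categorical" else float))
                    probs = clf.predict_proba(P[miss])
                    idx = np.array([rng.choice(len(clf.classes_), p=pr / pr.sum())
                                    for pr in probs])
                    drawn = clf.classes_[idx]
                    if kind == "ordinal":
                        col = filled[feat].astype("Int64").to_numpy(dtype=object)
                        col[miss] = [int(v) for v in drawn]
                        filled[feat] = pd.array([int(v) for v in col], dtype="Int64")
                    else:
                        col = filled[feat].to_numpy(dtype=object)
                        col[miss] = drawn
                        filled[feat] = col
        chains.append(filled)

    pooled = data.copy()
    for feat in incomplete:
        miss = data[feat].isna()
        kind = schema.kinds[feat]
        stacked = pd.concat([c[feat][miss] for c in chains], axis=1)
        if kind == "continuous":
            pooled.loc[miss, feat] = stacked.astype(float).mean(axis=1)
        else:
            # Mode across chains; ties resolved to the lowest level.
            def _mode(row):
                counts = row.value_counts()
                top = counts[counts == counts.max()].index
                if kind == "ordinal":
                    return min(int(v) for v in top)
                order = {lv: i for i, lv in enumerate(schema.levels[feat])}
                return sorted(top, key=lambda v: order[v])[0]

            vals = stacked.apply(_mode, axis=1)
            if kind == "ordinal":
                col = pooled[feat].astype("Int64")
                col[miss] = pd.array(vals.astype(int), dtype="Int64")
                pooled[feat] = col
            else:
                pooled.loc[miss, feat] = vals
    return LabeledFeatureTable(
        data=pooled, outcome=table.outcome.copy(), cohort=table.cohort.copy(),
        schema=schema,
    )


# --------------------------------------------------------------------------
# Dummy coding
# --------------------------------------------------------------------------


def _level_names(kind: str, feat: str, schema: FeatureSchema) -> list[tuple[object, str]]:
    """(raw level value, display label) pairs, reference level first."""
    if kind == "categorical":
        return [(lv, lv) for lv in schema.levels[feat]]
    # Ordinal severities 0-3 with the conventional labels.
    return [(k, SEVERITY_LABELS[k]) for k in (0, 1, 2, 3)]


def encode_dummies(
    table: LabeledFeatureTable,
) -> tuple[DesignMatrix, GroupStructure]:
    """Expand a complete feature table into a grouped design matrix.

    Each categorical/ordinal feature with L declared levels becomes L-1
    indicator columns named ``"<feature>; <level>"`` (the lowest level is
    the reference), all sharing one penalty group; continuous features pass
    through as singleton groups.  Values outside a feature's declared level
    set raise an error.
    """
    schema = table.schema
    data = table.data
    if data.isna().any().any():
        raise ValueError("encode_dummies requires a complete (imputed) table")

    cols: list[np.ndarray] = []
    names: list[str] = []
    gids: list[int] = []
    is_dummy: list[bool] = []
    feature_of: dict[str, str] = {}
    for g, feat in enumerate(schema.features):
        kind = schema.kinds[feat]
        if kind == "continuous":
            cols.append(data[feat].to_numpy(dtype=float))
            names.append(feat)
            gids.append(g)
            is_dummy.append(False)
            feature_of[feat] = feat
            continue
        pairs = _level_names(kind, feat, schema)
        valid = {p[0] for p in pairs}
        raw = (data[feat].astype(float).astype(int).to_numpy() if kind == "ordinal"
               else data[feat].to_numpy(dtype=object))
        unseen = set(np.unique(raw)) - valid
        if unseen:
            raise ValueError(f"feature {feat!r} has undeclared level(s): {sorted(map(str, unseen))}")
        for lv, label in pairs[1:]:
            col = f"{feat}; {label}"
            cols.append((raw == lv).astype(float))
            names.append(col)
            gids.append(g)
            is_dummy.append(True)
            feature_of[col] = feat

    X = np.column_stack(cols)
    design = DesignMatrix(
        X=X, y=table.outcome.to_numpy(dtype=float), columns=names,
        is_dummy=np.asarray(is_dummy, dtype=bool), sample_ids=table.sample_ids,
    )
    groups = GroupStructure(columns=names, group_ids=np.asarray(gids, dtype=np.int64),
                            feature_of=feature_of)
    return design, groups


def decode_dummies(design: DesignMatrix, groups: GroupStructure,
                   schema: FeatureSchema) -> pd.DataFrame:
    """Invert :func:`encode_dummies` (used to verify the coding is lossless)."""
    out: dict[str, object] = {}
    feat_cols = groups.feature_columns
    name_by_col = dict(zip(design.columns, range(design.p)))
    for feat, cols in feat_cols.items():
        kind = schema.kinds[feat]
        if kind == "continuous":
            out[feat] = design.X[:, name_by_col[feat]]
            continue
        pairs = _level_names(kind, feat, schema)
        ref = pairs[0][0]
        sub = design.X[:, [name_by_col[c] for c in cols]]
        levels = [lv for lv, _ in pairs[1:]]
        vals = np.full(design.n, ref, dtype=object)
        for j, lv in enumerate(levels):
            vals[sub[:, j] == 1.0] = lv
        out[feat] = (pd.array([int(v) for v in vals], dtype="Int64")
                     if kind == "ordinal" else vals)
    return pd.DataFrame(out, index=design.sample_ids)


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------


def standardize(
    design: DesignMatrix, params: ScalingParams | None = None
) -> DesignMatrix:
    """Center/scale continuous columns; leave indicators on the 0/1 scale.

    With ``params=None`` the statistics are fitted on this (training)
    design and constant columns are dropped with a warning; with stored
    training ``params`` the same transform is replayed on new data, which
    therefore need not end up with zero column means.
    """
    if params is None:
        sd = design.X.std(axis=0, ddof=0)
        constant = sd == 0
        if constant.any():
            dropped = [c for c, f in zip(design.columns, constant) if f]
            warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
        keep = ~constant
        cols = [c for c, k in zip(design.columns, keep) if k]
        is_dummy = design.is_dummy[keep]
        X = design.X[:, keep]
        center = np.where(is_dummy, 0.0, X.mean(axis=0))
        scale = np.where(is_dummy, 1.0, X.std(axis=0, ddof=0))
        params = ScalingParams(columns=cols, center=center, scale=scale,
                               is_dummy=is_dummy)
    else:
        idx = {c: j for j, c in enumerate(design.columns)}
        missing = [c for c in params.columns if c not in idx]
        if missing:
            raise ValueError(f"columns required by scaling params absent: {missing}")
        X = design.X[:, [idx[c] for c in params.columns]]
    Xs = (X - params.center) / params.scale
    return DesignMatrix(
        X=Xs, y=design.y, columns=list(params.columns),
        is_dummy=params.is_dummy.copy(), sample_ids=list(design.sample_ids),
        scaling=params,
    )
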