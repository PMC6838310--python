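"""End-to-end pipeline: simulate -> quantify -> prepare -> ensemble ->
average -> evaluate, plus table/config I/O and the run manifest.

A run is fully determined by its :class:`PipelineConfig` (which embeds the
cohort spec and a master seed).  Stage seeds are derived from the master
seed by fixed offsets so stages can be rerun in isolation.  The two study
configurations differ only in ``exclude_features``: the second analysis
drops the symptom total score so that individual features can compete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble_averaging import (
    AveragedModel,
    EnsembleResult,
    average_ensemble,
    identify_unique_models,
    run_ensemble,
    selection_fractions,
)
from .evaluate import ROCResult, auc, performance_band, predict_probability, roc_points
from .feature_prep import (
    DesignMatrix,
    GroupStructure,
    encode_dummies,
    impute,
    screen_missingness,
    standardize,
)
from .mrm_preprocess import build_peptide_table, pca_outlier_flags
from .synthetic_cohort import (
    CohortSpec,
    FeatureSchema,
    LabeledFeatureTable,
    generate_cohort,
    generate_extrapolation_set,
    generate_transition_table,
    inject_missingness,
)

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "run_pipeline",
    "load_feature_table",
    "write_feature_table",
    "prepare_designs",
]

logger = logging.getLogger(__name__)

# Fixed per-stage seed offsets (stages are independently re-runnable).
_SEED_MISSINGNESS = 101
_SEED_IMPUTE = 202
_SEED_ENSEMBLE = 303


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    R: int = 100
    n_folds: int = 10
    fraction_threshold: float = 0.9
    dominant_threshold: float = 0.9
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    cv_rule: str = "1se"
    k_mode: str = "features"
    logl_mode: str = "penalized"
    n_imputations: int = 5
    exclude_features: list[str] = field(default_factory=list)
    use_transitions: bool = True
    pca_outlier_sd: float = 4.0
    missingness_max_rate: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("fraction_threshold", "dominant_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["informative_features"] = [
            list(t) for t in self.cohort.informative_features
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = dict(d.pop("cohort", {}))
        if "informative_features" in cohort:
            cohort["informative_features"] = [
                (f, k, float(e)) for f, k, e in cohort["informative_features"]
            ]
        return cls(cohort=CohortSpec(**cohort), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Run outputs: final model, unique-model table, per-cohort performance."""

    model: AveragedModel
    ensemble: EnsembleResult
    fractions: dict[str, float]
    auc_training: float
    auc_extrapolation: float
    band_training: str
    band_extrapolation: str
    roc_training: ROCResult
    roc_extrapolation: ROCResult
    outlier_samples: list[str]
    dropped_features: list[str]
    manifest: dict


# --------------------------------------------------------------------------
# Feature-table file I/O (CSV + schema sidecar)
# --------------------------------------------------------------------------


def write_feature_table(table: LabeledFeatureTable, path: str | Path,
                        schema_path: str | Path) -> None:
    """Write a table as CSV (``NA`` for missing) plus a YAML schema sidecar."""
    df = table.data.copy()
    df.insert(0, "cohort", table.cohort)
    df.insert(0, "outcome", table.outcome)
    df.index.name = "sample_id"
    df.to_csv(path, na_rep="NA")
    with open(schema_path, "w") as fh:
        yaml.safe_dump(table.schema.to_dict(), fh, sort_keys=False)


def load_feature_table(path: str | Path, schema_path: str | Path) -> LabeledFeatureTable:
    """Read a feature table, validating every column against its schema.

    Unknown columns are rejected; continuous columns must parse as
    numbers, ordinal values must lie in 0-3, and categorical values must
    belong to the declared level set.  ``NA`` marks missing cells.
    """
    with open(schema_path) as fh:
        schema = FeatureSchema.from_dict(yaml.safe_load(fh))
    df = pd.read_csv(path, index_col="sample_id", na_values=["NA"],
                     keep_default_na=False, dtype=str)
    for required in ("outcome", "cohort"):
        if required not in df.columns:
            raise ValueError(f"feature table missing required column {required!r}")
    feature_cols = [c for c in df.columns if c not in ("outcome", "cohort")]
    unknown = [c for c in feature_cols if c not in schema.kinds]
    if unknown:
        raise ValueError(f"columns not declared in schema: {unknown}")
    absent = [c for c in schema.kinds if c not in feature_cols]
    if absent:
        raise ValueError(f"schema features absent from table: {absent}")

    data = {}
    for feat in schema.features:
        raw = df[feat]
        kind = schema.kinds[feat]
        if kind == "continuous":
            try:
                data[feat] = raw.astype(float)
            except ValueError as exc:
                raise ValueError(f"non-numeric value in continuous column {feat!r}: {exc}")
        elif kind == "ordinal":
            vals = raw.astype("Float64")
            bad = vals.dropna()[~vals.dropna().isin([0, 1, 2, 3])]
            if len(bad):
                raise ValueError(
                    f"ordinal column {feat!r} has out-of-range value(s) at row(s) "
                    f"{bad.index.tolist()[:5]}"
                )
            data[feat] = vals.astype("Int64")
        else:
            levels = set(schema.levels[feat])
            obs = raw.dropna()
            bad = obs[~obs.isin(levels)]
            if len(bad):
                raise ValueError(
                    f"categorical column {feat!r} has undeclared level(s) "
                    f"{sorted(bad.unique().tolist())}"
                )
            data[feat] = raw.where(raw.notna(), other=None).astype(object)
    outcome = df["outcome"].astype(int)
    if not outcome.isin([0, 1]).all():
        raise ValueError("outcome column must be binary 0/1")
    return LabeledFeatureTable(
        data=pd.DataFrame(data, index=df.index),
        outcome=outcome, cohort=df["cohort"].astype(str), schema=schema,
    )


# --------------------------------------------------------------------------
# Pipeline stages
# --------------------------------------------------------------------------


def _apply_recovered_ratios(table: LabeledFeatureTable,
                            ratios: pd.DataFrame) -> LabeledFeatureTable:
    data = table.data.copy()
    peptides = [c for c in ratios.columns if c in data.columns]
    sub = ratios.loc[table.sample_ids, peptides]
    data[peptides] = sub
    return LabeledFeatureTable(data=data, outcome=table.outcome,
                               cohort=table.cohort, schema=table.schema)


def prepare_designs(
    train_table: LabeledFeatureTable,
    extrap_table: LabeledFeatureTable,
    config: PipelineConfig,
) -> tuple[DesignMatrix, "GroupStructure", DesignMatrix, list[str]]:
    """Screen, impute, exclude, encode and standardize both cohorts.

    Imputation runs once on the combined table (training + extrapolation
    rows), mirroring a single upstream imputation of the study data set.
    The returned designs are the standardized training design (reference +
    training patients) and the evaluation design (reference + extrapolation
    patients) standardized with the training parameters.
    """
    combined = train_table.concat(extrap_table)
    combined, dropped = screen_missingness(combined, config.missingness_max_rate)
    combined = impute(combined, n_imputations=config.n_imputations,
                      seed=config.seed + _SEED_IMPUTE)
    if config.exclude_features:
        combined = combined.drop_features(config.exclude_features)

    train_ids = train_table.sample_ids
    ref_ids = [s for s, c in train_table.cohort.items() if c == "training_reference"]
    extrap_ids = extrap_table.sample_ids

    design_train_raw, groups = encode_dummies(combined.subset(train_ids))
    design_train = standardize(design_train_raw)
    groups = groups.subset(design_train.columns)

    eval_table = combined.subset(ref_ids + extrap_ids)
    design_eval_raw, _ = encode_dummies(eval_table)
    design_eval = standardize(design_eval_raw, params=design_train.scaling)
    return design_train, groups, design_eval, dropped


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and (optionally) write the run directory.

    Stages: cohort simulation (with raw transition tables), MRM
    quantification + PCA outlier screen, missingness screen + imputation +
    dummy coding + standardization, the R-repeat CV group-LASSO ensemble,
    AICc-weighted averaging (dominant-model path when one unique model
    exceeds the probability threshold, else feature extraction), and
    ROC/AUC evaluation on the training and extrapolation cohorts.
    Deterministic for a given config + master seed.
    """
    spec = config.cohort
    logger.info("simulating cohort (seed=%d)", spec.seed)
    train_table = generate_cohort(spec)
    extrap_table = generate_extrapolation_set(spec)

    outliers: list[str] = []
    if config.use_transitions:
        transitions = generate_transition_table(spec, include_extrapolation=True)
        ratio_table = build_peptide_table(transitions)
        flags = pca_outlier_flags(ratio_table, k_sd=config.pca_outlier_sd)
        outliers = flags.index[flags].tolist()
        train_table = _apply_recovered_ratios(train_table, ratio_table.ratios)
        extrap_table = _apply_recovered_ratios(extrap_table, ratio_table.ratios)

    if spec.missing_rate > 0:
        train_table = inject_missingness(train_table, spec.missing_rate,
                                         seed=config.seed + _SEED_MISSINGNESS)
        extrap_table = inject_missingness(extrap_table, spec.missing_rate,
                                          seed=config.seed + _SEED_MISSINGNESS + 1)

    design_train, groups, design_eval, dropped = prepare_designs(
        train_table, extrap_table, config
    )
    logger.info("design: %d samples x %d columns in %d groups",
                design_train.n, design_train.p, groups.n_groups)

    ensemble = run_ensemble(
        design_train, groups, R=config.R, seed=config.seed + _SEED_ENSEMBLE,
        n_folds=config.n_folds, n_lambda=config.n_lambda,
        ratio=config.lambda_min_ratio, cv_rule=config.cv_rule,
        k_mode=config.k_mode, logl_mode=config.logl_mode,
    )
    fractions = selection_fractions(ensemble)
    model = average_ensemble(
        ensemble, fraction_threshold=config.fraction_threshold,
        probability_threshold=config.dominant_threshold,
    )

    p_train = predict_probability(model, design_train)
    p_eval = predict_probability(model, design_eval)
    roc_train = roc_points(design_train.y, p_train, cohort="training")
    roc_eval = roc_points(design_eval.y, p_eval, cohort="extrapolation")
    auc_train = auc(design_train.y, p_train)
    auc_eval = auc(design_eval.y, p_eval)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "stages": {
            "cohort": {"rows": train_table.n_samples + extrap_table.n_samples,
                       "features": len(spec.schema().features)},
            "design_train": {"rows": design_train.n, "columns": design_train.p,
                             "groups": groups.n_groups},
            "design_eval": {"rows": design_eval.n, "columns": design_eval.p},
            "ensemble": {"R": ensemble.R},
        },
        "dropped_features": dropped,
        "pca_outliers": outliers,
        "averaging_path": "dominant" if model.dominant else (
            "extraction" if model.features else "intercept_only"
        ),
    }
    report = PipelineReport(
        model=model, ensemble=ensemble, fractions=fractions,
        auc_training=auc_train, auc_extrapolation=auc_eval,
        band_training=performance_band(auc_train),
        band_extrapolation=performance_band(auc_eval),
        roc_training=roc_train, roc_extrapolation=roc_eval,
        outlier_samples=outliers, dropped_features=dropped,
        manifest=manifest,
    )
    if config.output_dir is not None:
        write_report(report, config, Path(config.output_dir))
    return report


# --------------------------------------------------------------------------
# Report files
# --------------------------------------------------------------------------


def model_report_frame(report: PipelineReport) -> pd.DataFrame:
    """Retained features with selection fractions and averaged coefficients."""
    model = report.model
    rows = []
    for col, b in model.coef.items():
        feat = col.split("; ")[0]
        rows.append({
            "column": col,
            "feature": feat,
            "selection_fraction": report.fractions.get(feat, float("nan")),
            "average_coefficient": b,
        })
    rows.append({"column": "(intercept)", "feature": "(intercept)",
                 "selection_fraction": float("nan"),
                 "average_coefficient": model.intercept})
    return pd.DataFrame(rows)


def unique_models_frame(report: PipelineReport) -> pd.DataFrame:
    rows = [
        {
            "features": " + ".join(u.features) if u.features else "(null model)",
            "n_features": len(u.features),
            "occurrences": u.occurrences,
            "probability": u.probability,
        }
        for u in identify_unique_models(report.ensemble)
    ]
    return pd.DataFrame(rows)


def write_report(report: PipelineReport, config: PipelineConfig,
                 out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    model_report_frame(report).to_csv(out_dir / "model_report.csv", index=False)
    unique_models_frame(report).to_csv(out_dir / "unique_models.csv", index=False)
    for roc in (report.roc_training, report.roc_extrapolation):
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
            out_dir / f"roc_{roc.cohort}.csv", index=False
        )
    summary = {
        "auc": {"training": report.auc_training,
                "extrapolation": report.auc_extrapolation},
        "band": {"training": report.band_training,
                 "extrapolation": report.band_extrapolation},
        "n_retained_features": len(report.model.features),
        "retained_features": list(report.model.features),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
    config.to_yaml(out_dir / "config.yaml")
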