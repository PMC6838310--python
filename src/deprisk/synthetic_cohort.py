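"""Synthetic case-control cohorts with the structure of a targeted-proteomics
depression study.

Generates three groups — a reference group of subthreshold individuals, a
training patient group, and an extrapolation patient group with attenuated
effects — over a mixed feature panel: continuous log2 peptide abundance
ratios (correlated within protein blocks), numeric and categorical
sociodemographic factors, and ordinal (0-3) depressive-symptom severities
plus their total score.  Raw transition-level MRM peak-area tables are
generated alongside so the quantification pre-processing can be validated
against known ground truth.

All randomness is driven by ``numpy.random.Generator`` seeded from the
cohort spec; identical spec + seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CohortSpec",
    "FeatureSchema",
    "LabeledFeatureTable",
    "TransitionTable",
    "DSM_SYMPTOMS",
    "SYMPTOM_DOMAINS",
    "TOTAL_SCORE_FEATURE",
    "default_informative_features",
    "generate_cohort",
    "generate_extrapolation_set",
    "generate_transition_table",
    "inject_missingness",
    "is_subthreshold",
    "ids_total_score",
]

# --------------------------------------------------------------------------
# Feature panel layout
# --------------------------------------------------------------------------

#: The nine DSM diagnostic symptom domains used by the subthreshold rule.
DSM_SYMPTOMS: tuple[str, ...] = (
    "sadness",
    "anhedonia",
    "weight_appetite_change",
    "sleep_disturbance",
    "psychomotor_change",
    "fatigue",
    "worthlessness_guilt",
    "concentration_problems",
    "suicidal_thoughts",
)

#: Ordinal symptom domains (severity 0-3) making up the clinical panel;
#: 29 domains plus the total score give the default 30 clinical features.
SYMPTOM_DOMAINS: tuple[str, ...] = DSM_SYMPTOMS + (
    "irritability",
    "anxiety",
    "leaden_paralysis",
    "mood_reactivity",
    "mood_variation",
    "early_insomnia",
    "middle_insomnia",
    "late_insomnia",
    "hypersomnia",
    "appetite_decrease",
    "appetite_increase",
    "panic_phobia",
    "somatic_complaints",
    "sympathetic_arousal",
    "gastrointestinal",
    "interpersonal_sensitivity",
    "low_self_esteem",
    "future_pessimism",
    "capacity_for_pleasure",
    "sexual_interest",
)

TOTAL_SCORE_FEATURE = "ids_total"

#: Severity labels used when ordinal features are dummy-coded downstream.
SEVERITY_LABELS = {0: "none", 1: "mild", 2: "moderate", 3: "severe"}

# Sociodemographic panel: (name, kind, levels-or-None, reference marginal).
# Marginals loosely follow the reference group of the emulated study
# population (adults with subthreshold depressive symptoms).
_SOCIODEMOGRAPHIC_PANEL: tuple[tuple[str, str, tuple[str, ...] | None], ...] = (
    ("age", "continuous", None),
    ("bmi", "continuous", None),
    ("weekly_alcohol", "continuous", None),
    ("childhood_life_events", "continuous", None),
    ("childhood_trauma", "continuous", None),
    ("negative_life_events", "continuous", None),
    ("sex", "categorical", ("male", "female")),
    ("education", "categorical", ("basic", "intermediate", "high")),
    ("physical_activity", "categorical", ("low", "moderate", "high")),
    ("smoking", "categorical", ("no", "yes")),
    ("alcohol_abuse", "categorical", ("no", "yes")),
    ("drug_use", "categorical", ("no", "yes")),
    ("partner", "categorical", ("no", "yes")),
    ("children", "categorical", ("no", "yes")),
    ("employment", "categorical", ("employed", "unemployed", "retired", "disabled")),
    ("work_absence", "categorical", ("no", "yes", "not_applicable")),
    ("family_history", "categorical", ("no", "yes")),
    ("heart_disease", "categorical", ("no", "yes")),
    ("diabetes", "categorical", ("no", "yes")),
    ("other_chronic_disease", "categorical", ("no", "yes")),
    ("antiinflammatory_drug", "categorical", ("no", "yes")),
    ("heart_medication", "categorical", ("no", "yes")),
)

_CATEGORICAL_BASE_PROBS: dict[str, tuple[float, ...]] = {
    "sex": (0.35, 0.65),
    "education": (0.08, 0.42, 0.50),
    "physical_activity": (0.23, 0.48, 0.29),
    "smoking": (0.69, 0.31),
    "alcohol_abuse": (0.79, 0.21),
    "drug_use": (0.93, 0.07),
    "partner": (0.31, 0.69),
    "children": (0.56, 0.44),
    "employment": (0.77, 0.17, 0.02, 0.04),
    "work_absence": (0.35, 0.43, 0.22),
    "family_history": (0.27, 0.73),
    "heart_disease": (0.99, 0.01),
    "diabetes": (0.97, 0.03),
    "other_chronic_disease": (0.74, 0.26),
    "antiinflammatory_drug": (0.98, 0.02),
    "heart_medication": (0.90, 0.10),
}

# Reference-group marginal severity distribution for ordinal symptoms; the
# patient group shifts the underlying latent variable upward.
_ORDINAL_BASE_PROBS = (0.55, 0.25, 0.13, 0.07)


def _ordinal_cutpoints(probs: Sequence[float]) -> np.ndarray:
    cum = np.cumsum(probs)[:-1]
    return norm.ppf(cum)


# --------------------------------------------------------------------------
# Schema and table containers
# --------------------------------------------------------------------------


@dataclass
class FeatureSchema:
    """Feature-kind metadata for a :class:`LabeledFeatureTable`.

    ``kinds`` maps feature name -> ``continuous`` | ``categorical`` |
    ``ordinal``; ``levels`` holds the declared level set of categorical
    features (order matters: the first level is the reference);
    ``sources`` maps feature -> ``proteomic`` | ``sociodemographic`` |
    ``clinical``; ``proteins`` maps peptide features to their protein.
    """

    kinds: dict[str, str]
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.kinds)

    def proteomic_features(self) -> list[str]:
        return [f for f, s in self.sources.items() if s == "proteomic"]

    def to_dict(self) -> dict:
        return {
            "kinds": dict(self.kinds),
            "levels": {k: list(v) for k, v in self.levels.items()},
            "sources": dict(self.sources),
            "proteins": dict(self.proteins),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        return cls(
            kinds=dict(d["kinds"]),
            levels={k: tuple(v) for k, v in d.get("levels", {}).items()},
            sources=dict(d.get("sources", {})),
            proteins=dict(d.get("proteins", {})),
        )


@dataclass
class LabeledFeatureTable:
    """A sample x feature table with a binary outcome and cohort tags.

    ``data`` holds one column per feature: float64 for continuous, pandas
    ``Int64`` (nullable) for ordinal severities, ``object`` strings for
    categorical levels.  ``outcome`` is 1 for patients, 0 for the reference
    group; ``cohort`` tags each row ``training_reference`` /
    ``training_patient`` / ``extrapolation_patient``.
    """

    data: pd.DataFrame
    outcome: pd.Series
    cohort: pd.Series
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not (self.data.index.equals(self.outcome.index) and self.data.index.equals(self.cohort.index)):
            raise ValueError("data, outcome and cohort must share one sample index")
        for feat, kind in self.schema.kinds.items():
            if feat not in self.data.columns:
                raise ValueError(f"schema feature {feat!r} missing from data")
            if kind == "ordinal":
                vals = self.data[feat].dropna()
                bad = ~vals.astype(float).isin([0.0, 1.0, 2.0, 3.0])
                if bad.any():
                    raise ValueError(f"ordinal feature {feat!r} has values outside 0-3")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def subset(self, ids: Sequence[str]) -> "LabeledFeatureTable":
        ids = list(ids)
        return LabeledFeatureTable(
            data=self.data.loc[ids].copy(),
            outcome=self.outcome.loc[ids].copy(),
            cohort=self.cohort.loc[ids].copy(),
            schema=self.schema,
        )

    def concat(self, other: "LabeledFeatureTable") -> "LabeledFeatureTable":
        return LabeledFeatureTable(
            data=pd.concat([self.data, other.data]),
            outcome=pd.concat([self.outcome, other.outcome]),
            cohort=pd.concat([self.cohort, other.cohort]),
            schema=self.schema,
        )

    def drop_features(self, names: Iterable[str]) -> "LabeledFeatureTable":
        names = [n for n in names if n in self.data.columns]
        schema = FeatureSchema(
            kinds={k: v for k, v in self.schema.kinds.items() if k not in names},
            levels={k: v for k, v in self.schema.levels.items() if k not in names},
            sources={k: v for k, v in self.schema.sources.items() if k not in names},
            proteins={k: v for k, v in self.schema.proteins.items() if k not in names},
        )
        return LabeledFeatureTable(
            data=self.data.drop(columns=names),
            outcome=self.outcome,
            cohort=self.cohort,
            schema=schema,
        )


@dataclass
class TransitionTable:
    """Long-format transition-level MRM peak areas.

    ``data`` columns: sample_id, protein_id, peptide_id, transition_id,
    endogenous_area, sis_area.  ``true_log2_ratios`` (sample x peptide) is
    the generator's ground truth, kept so the quantification pre-processing
    can be validated by round trip.
    """

    data: pd.DataFrame
    true_log2_ratios: pd.DataFrame | None = None

    REQUIRED_COLUMNS = (
        "sample_id",
        "protein_id",
        "peptide_id",
        "transition_id",
        "endogenous_area",
        "sis_area",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"transition table missing columns: {missing}")
        if (self.data["sis_area"] <= 0).any():
            raise ValueError("SIS peak areas must be strictly positive")
        if (self.data["endogenous_area"] < 0).any():
            raise ValueError("endogenous peak areas must be non-negative")
        per_pep = self.data.groupby("peptide_id")["transition_id"].nunique()
        bad = per_pep[(per_pep < 3) | (per_pep > 4)]
        if len(bad):
            raise ValueError(
                f"each peptide needs 3-4 transitions; offenders: {bad.index.tolist()[:5]}"
            )


# --------------------------------------------------------------------------
# Cohort specification
# --------------------------------------------------------------------------


def default_informative_features(effect: float = 0.8) -> list[tuple[str, str, float]]:
    """The default planted-signal configuration: 12 informative features.

    Six peptides (one per correlation block, standardized mean shift
    ``effect``), three sociodemographic factors and three ordinal symptoms
    (latent/log-odds shift ``effect``) — mirroring the 12-feature panel the
    analysis is expected to recover.
    """
    peptides = [f"pep_{i:03d}" for i in (1, 26, 51, 76, 101, 126)]
    planted = [(p, "continuous", effect) for p in peptides]
    planted += [
        ("bmi", "continuous", effect),
        ("childhood_trauma", "continuous", effect),
        ("education", "categorical", effect),
        ("sadness", "ordinal", effect),
        ("fatigue", "ordinal", effect),
        ("leaden_paralysis", "ordinal", effect),
    ]
    return planted


@dataclass
class CohortSpec:
    """Generative settings for one synthetic study.

    ``informative_features`` lists (feature id, kind, standardized effect)
    triples; effects are mean shifts in latent/standardized units for the
    patient group.  ``extrapolation_attenuation`` multiplies every planted
    effect for the extrapolation patient group, emulating weaker disease
    indications in pre-onset individuals.
    """

    n_reference: int = 86
    n_patients_train: int = 86
    n_patients_extrap: int = 37
    n_proteomic: int = 146
    n_sociodemographic: int = 22
    n_clinical: int = 30
    informative_features: list[tuple[str, str, float]] = field(
        default_factory=default_informative_features
    )
    extrapolation_attenuation: float = 0.5
    correlation_block_size: int = 5
    block_correlation: float = 0.3
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_reference", "n_patients_train", "n_patients_extrap",
                     "n_proteomic", "n_sociodemographic", "n_clinical"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.extrapolation_attenuation <= 1.0:
            raise ValueError("extrapolation_attenuation must be in [0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.correlation_block_size <= 0:
            raise ValueError("correlation_block_size must be positive")
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must be in [0, 0.05]")
        if self.n_sociodemographic > len(_SOCIODEMOGRAPHIC_PANEL):
            raise ValueError(
                f"n_sociodemographic cannot exceed {len(_SOCIODEMOGRAPHIC_PANEL)}"
            )
        if self.n_clinical > len(SYMPTOM_DOMAINS) + 1:
            raise ValueError(
                f"n_clinical cannot exceed {len(SYMPTOM_DOMAINS) + 1}"
            )
        schema = self.schema()
        for feat, kind, _effect in self.informative_features:
            if feat not in schema.kinds:
                raise ValueError(f"informative feature {feat!r} not in generated schema")
            if schema.kinds[feat] != kind:
                raise ValueError(
                    f"informative feature {feat!r} declared {kind!r} but schema says "
                    f"{schema.kinds[feat]!r}"
                )

    # -- schema ------------------------------------------------------------

    def peptide_names(self) -> list[str]:
        return [f"pep_{i + 1:03d}" for i in range(self.n_proteomic)]

    def symptom_names(self) -> list[str]:
        return list(SYMPTOM_DOMAINS[: self.n_clinical - 1])

    def schema(self) -> FeatureSchema:
        kinds: dict[str, str] = {}
        levels: dict[str, tuple[str, ...]] = {}
        sources: dict[str, str] = {}
        proteins: dict[str, str] = {}
        bs = self.correlation_block_size
        for j, pep in enumerate(self.peptide_names()):
            kinds[pep] = "continuous"
            sources[pep] = "proteomic"
            proteins[pep] = f"prot_{j // bs + 1:02d}"
        for name, kind, lv in _SOCIODEMOGRAPHIC_PANEL[: self.n_sociodemographic]:
            kinds[name] = kind
            sources[name] = "sociodemographic"
            if lv is not None:
                levels[name] = lv
        for name in self.symptom_names():
            kinds[name] = "ordinal"
            sources[name] = "clinical"
        kinds[TOTAL_SCORE_FEATURE] = "continuous"
        sources[TOTAL_SCORE_FEATURE] = "clinical"
        return FeatureSchema(kinds=kinds, levels=levels, sources=sources, proteins=proteins)

    def effect_map(self, attenuation: float = 1.0) -> dict[str, float]:
        return {feat: eff * attenuation for feat, _kind, eff in self.informative_features}


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _rng_for(spec: CohortSpec, stream: int) -> np.random.Generator:
    # Independent, reproducible substreams; the reference stream is shared
    # between the training and extrapolation tables so the reference group
    # is generated exactly once.
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


_STREAM_REFERENCE = 0
_STREAM_TRAIN = 1
_STREAM_EXTRAP = 2
_STREAM_TRANSITIONS = 3


def _sample_block(spec: CohortSpec, n: int, effects: Mapping[str, float],
                  rng: np.random.Generator, schema: FeatureSchema) -> pd.DataFrame:
    """Draw n samples of every feature under the given planted effects."""
    cols: dict[str, object] = {}

    # Proteomic: compound-symmetric Gaussian blocks, unit marginal variance.
    peptides = spec.peptide_names()
    rho = spec.block_correlation
    bs = spec.correlation_block_size
    n_blocks = math.ceil(len(peptides) / bs)
    shared = rng.standard_normal((n, n_blocks))
    indep = rng.standard_normal((n, len(peptides)))
    for j, pep in enumerate(peptides):
        z = math.sqrt(rho) * shared[:, j // bs] + math.sqrt(1.0 - rho) * indep[:, j]
        cols[pep] = z + effects.get(pep, 0.0)

    # Sociodemographic.
    for name, kind, lv in _SOCIODEMOGRAPHIC_PANEL[: spec.n_sociodemographic]:
        eff = effects.get(name, 0.0)
        if kind == "continuous":
            cols[name] = rng.standard_normal(n) + eff
        else:
            base = np.asarray(_CATEGORICAL_BASE_PROBS[name], dtype=float)
            L = len(lv)
            score = np.arange(L) / (L - 1)  # log-odds shift grows with level
            logits = np.log(base) + eff * score
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            draws = rng.choice(L, size=n, p=probs)
            cols[name] = np.asarray(lv, dtype=object)[draws]

    # Ordinal symptoms: thresholded latent Gaussian.
    cuts = _ordinal_cutpoints(_ORDINAL_BASE_PROBS)
    symptom_values = {}
    for name in spec.symptom_names():
        z = rng.standard_normal(n) + effects.get(name, 0.0)
        sev = np.searchsorted(cuts, z)
        symptom_values[name] = sev
        cols[name] = pd.array(sev, dtype="Int64")

    # Total score: deterministic aggregate of the symptom severities, as a
    # questionnaire total is of its items.
    total = np.sum(np.column_stack(list(symptom_values.values())), axis=1)
    cols[TOTAL_SCORE_FEATURE] = total.astype(float)

    return pd.DataFrame(cols, columns=schema.features)


def generate_cohort(spec: CohortSpec) -> LabeledFeatureTable:
    """Generate the training cohort: reference group + training patients.

    Reference samples are drawn from the baseline law; training patients
    from the same law with every planted effect applied at full size.
    """
    schema = spec.schema()
    ref = _sample_block(spec, spec.n_reference, {}, _rng_for(spec, _STREAM_REFERENCE), schema)
    pat = _sample_block(spec, spec.n_patients_train, spec.effect_map(1.0),
                        _rng_for(spec, _STREAM_TRAIN), schema)
    ref.index = [f"ref_{i + 1:03d}" for i in range(spec.n_reference)]
    pat.index = [f"pat_{i + 1:03d}" for i in range(spec.n_patients_train)]
    data = pd.concat([ref, pat])
    outcome = pd.Series(
        np.r_[np.zeros(spec.n_reference, int), np.ones(spec.n_patients_train, int)],
        index=data.index, name="outcome",
    )
    cohort = pd.Series(
        ["training_reference"] * spec.n_reference + ["training_patient"] * spec.n_patients_train,
        index=data.index, name="cohort",
    )
    return LabeledFeatureTable(data=data, outcome=outcome, cohort=cohort, schema=schema)


def generate_extrapolation_set(spec: CohortSpec) -> LabeledFeatureTable:
    """Generate the extrapolation patient group only.

    Patients are drawn with every planted effect multiplied by
    ``spec.extrapolation_attenuation``; the reference group is not
    regenerated — evaluation shares the training table's reference rows.
    """
    schema = spec.schema()
    eff = spec.effect_map(spec.extrapolation_attenuation)
    pat = _sample_block(spec, spec.n_patients_extrap, eff, _rng_for(spec, _STREAM_EXTRAP), schema)
    pat.index = [f"ext_{i + 1:03d}" for i in range(spec.n_patients_extrap)]
    outcome = pd.Series(np.ones(spec.n_patients_extrap, int), index=pat.index, name="outcome")
    cohort = pd.Series(["extrapolation_patient"] * spec.n_patients_extrap,
                       index=pat.index, name="cohort")
    return LabeledFeatureTable(data=pat, outcome=outcome, cohort=cohort, schema=schema)


def generate_transition_table(
    spec: CohortSpec,
    include_extrapolation: bool = True,
    noise_sd: float = 0.05,
) -> TransitionTable:
    """Generate raw transition-level peak areas for every cohort sample.

    Each peptide gets 3-4 transitions with distinct lognormal base
    intensities.  Per sample and transition, the SIS area is the base
    intensity times a sample-level spike factor; the endogenous area is the
    SIS area times ``2**(true log2 ratio + noise)`` where the true ratio is
    the cohort table's peptide value and the noise is Gaussian on the log2
    scale with SD ``noise_sd``.  The true ratios are returned as ground
    truth for round-trip validation.
    """
    cohort = generate_cohort(spec)
    if include_extrapolation:
        cohort = cohort.concat(generate_extrapolation_set(spec))
    schema = cohort.schema
    peptides = spec.peptide_names()
    truth = cohort.data[peptides].astype(float)

    rng = _rng_for(spec, _STREAM_TRANSITIONS)
    n_samples = cohort.n_samples
    sample_ids = np.asarray(cohort.sample_ids, dtype=object)

    records: list[pd.DataFrame] = []
    for pep in peptides:
        n_trans = int(rng.integers(3, 5))
        # Distinct base intensities so "most abundant" is well defined.
        base = np.exp(rng.normal(np.log(1e5), 1.0, size=n_trans))
        base.sort()
        spike = np.exp(rng.normal(0.0, 0.2, size=(n_samples, n_trans)))
        sis = base[None, :] * spike
        noise = rng.normal(0.0, noise_sd, size=(n_samples, n_trans))
        endo = sis * np.exp2(truth[pep].to_numpy()[:, None] + noise)
        records.append(pd.DataFrame({
            "sample_id": np.repeat(sample_ids, n_trans),
            "protein_id": schema.proteins[pep],
            "peptide_id": pep,
            "transition_id": np.tile([f"{pep}_t{t + 1}" for t in range(n_trans)], n_samples),
            "endogenous_area": endo.ravel(),
            "sis_area": sis.ravel(),
        }))
    data = pd.concat(records, ignore_index=True)
    return TransitionTable(data=data, true_log2_ratios=truth)


def inject_missingness(
    table: LabeledFeatureTable, rate: float, seed: int
) -> LabeledFeatureTable:
    """Mask non-proteomic cells MCAR with the given probability.

    Proteomic columns are never masked (the assay yields complete peptide
    data); rates above 5% are rejected because the downstream missingness
    screen is defined to exclude such features by construction.
    """
    if not 0.0 <= rate <= 0.05:
        raise ValueError("missingness rate must be in [0, 0.05]")
    data = table.data.copy()
    if rate > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
        maskable = [f for f in table.schema.features
                    if table.schema.sources.get(f) != "proteomic"]
        for feat in maskable:
            mask = rng.random(len(data)) < rate
            if mask.any():
                col = data[feat]
                if col.dtype == object:
                    col = col.where(~mask, other=None)
                else:
                    col = col.mask(mask)
                data[feat] = col
    return LabeledFeatureTable(
        data=data, outcome=table.outcome.copy(), cohort=table.cohort.copy(),
        schema=table.schema,
    )


# --------------------------------------------------------------------------
# Clinical scoring helpers
# --------------------------------------------------------------------------


def is_subthreshold(symptoms: Mapping[str, int]) -> bool:
    """Subthreshold-depression eligibility from nine DSM symptom severities.

    A symptom is present when its severity is above zero.  Eligible iff at
    least two symptoms are present, including at least one core symptom
    (sadness or anhedonia).
    """
    missing = [s for s in DSM_SYMPTOMS if s not in symptoms]
    if missing:
        raise ValueError(f"missing symptom domains: {missing}")
    sev = {s: int(symptoms[s]) for s in DSM_SYMPTOMS}
    for name, v in sev.items():
        if not 0 <= v <= 3:
            raise ValueError(f"severity for {name!r} out of range 0-3: {v}")
    n_present = sum(v > 0 for v in sev.values())
    core = sev["sadness"] > 0 or sev["anhedonia"] > 0
    return n_present >= 2 and core


def ids_total_score(items: Sequence[int]) -> int:
    """Total severity score of the 30-item depressive-symptom inventory."""
    items = list(items)
    if len(items) != 30:
        raise ValueError(f"expected 30 items, got {len(items)}")
    for i, v in enumerate(items):
        if int(v) != v or not 0 <= int(v) <= 3:
            raise ValueError(f"item {i} out of range 0-3: {v!r}")
    return int(sum(int(v) for v in items))
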