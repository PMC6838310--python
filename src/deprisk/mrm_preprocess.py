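"""MRM quantification pre-processing.

Turns transition-level peak areas (endogenous + stable-isotope internal
standard) into the sample x peptide matrix of log2 abundance ratios used as
proteomic features, and screens samples for outliers by principal-component
analysis of those ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import TransitionTable

__all__ = [
    "QuantifierChoice",
    "PeptideRatioTable",
    "select_quantifier_transition",
    "compute_log_ratio",
    "build_peptide_table",
    "pca_outlier_flags",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantifierChoice:
    """The single transition chosen to quantify a peptide."""

    peptide_id: str
    transition_id: str
    endogenous_area: float
    sis_area: float


@dataclass
class PeptideRatioTable:
    """Sample x peptide matrix of log2(endogenous / SIS) abundance ratios."""

    ratios: pd.DataFrame
    peptide_proteins: dict[str, str]
    quantifiers: dict[str, str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.ratios.to_numpy(dtype=float)).all():
            raise ValueError("peptide ratio table contains non-finite values")


def select_quantifier_transition(
    transitions: Sequence[tuple[str, float, float]],
    peptide_id: str = "",
) -> QuantifierChoice:
    """Pick the quantifier transition for one peptide.

    The quantifier is the most abundant transition in both the endogenous
    and the SIS channel.  When no transition dominates both channels
    simultaneously, the transition with the highest endogenous + SIS summed
    area is taken instead (and the compromise is logged).
    """
    if len(transitions) == 0:
        raise ValueError("no transitions supplied")
    for tid, endo, sis in transitions:
        if sis <= 0:
            raise ValueError(f"transition {tid!r} has non-positive SIS area")
        if endo < 0:
            raise ValueError(f"transition {tid!r} has negative endogenous area")
    endo_best = max(transitions, key=lambda t: t[1])
    sis_best = max(transitions, key=lambda t: t[2])
    if endo_best[0] == sis_best[0]:
        tid, endo, sis = endo_best
    else:
        tid, endo, sis = max(transitions, key=lambda t: t[1] + t[2])
        logger.info(
            "peptide %s: endogenous-max (%s) and SIS-max (%s) transitions differ; "
            "using highest summed area (%s)",
            peptide_id or "?", endo_best[0], sis_best[0], tid,
        )
    return QuantifierChoice(
        peptide_id=peptide_id, transition_id=tid,
        endogenous_area=float(endo), sis_area=float(sis),
    )


def compute_log_ratio(endogenous: float, sis: float) -> float:
    """log2 abundance ratio of the endogenous peptide to its SIS standard."""
    if endogenous <= 0 or sis <= 0:
        raise ValueError(
            f"abundance ratio requires positive areas, got endogenous={endogenous}, sis={sis}"
        )
    return math.log2(endogenous / sis)


def build_peptide_table(raw: TransitionTable) -> PeptideRatioTable:
    """Collapse a transition table to one log2 ratio per sample x peptide.

    The quantifier transition is chosen once per peptide from peak areas
    summed across all samples, so every sample of a peptide is quantified
    on the same transition and the resulting column is coherent.
    """
    df = raw.data
    # Canonical (sorted) axes make the result invariant to input row order.
    samples = np.sort(pd.unique(df["sample_id"]))
    peptides = np.sort(pd.unique(df["peptide_id"]))

    counts = df.groupby(["peptide_id", "sample_id"]).size()
    expected = pd.MultiIndex.from_product([peptides, samples],
                                          names=["peptide_id", "sample_id"])
    missing = expected.difference(counts.index)
    if len(missing):
        offenders = [f"{p}/{s}" for p, s in list(missing)[:10]]
        raise ValueError(
            f"{len(missing)} sample x peptide pairs have no transitions: {offenders}"
        )

    sums = df.groupby(["peptide_id", "transition_id"])[
        ["endogenous_area", "sis_area"]].sum()
    quantifiers: dict[str, str] = {}
    for pep in peptides:
        trans = [(tid, row["endogenous_area"], row["sis_area"])
                 for tid, row in sums.loc[pep].iterrows()]
        quantifiers[pep] = select_quantifier_transition(trans, peptide_id=pep).transition_id

    chosen = df[df["peptide_id"].map(quantifiers) == df["transition_id"]]
    if (chosen["endogenous_area"] <= 0).any():
        bad = chosen[chosen["endogenous_area"] <= 0]
        raise ValueError(
            "non-positive endogenous area on quantifier transition for "
            f"{bad[['sample_id', 'peptide_id']].values[:5].tolist()}"
        )
    ratios = np.log2(chosen["endogenous_area"].to_numpy()
                     / chosen["sis_area"].to_numpy())
    wide = (pd.DataFrame({
        "sample_id": chosen["sample_id"].to_numpy(),
        "peptide_id": chosen["peptide_id"].to_numpy(),
        "ratio": ratios,
    }).pivot(index="sample_id", columns="peptide_id", values="ratio")
      .reindex(index=samples, columns=peptides))
    wide.index.name = "sample_id"
    wide.columns.name = None

    proteins = (df.drop_duplicates("peptide_id")
                  .set_index("peptide_id")["protein_id"].to_dict())
    return PeptideRatioTable(ratios=wide, peptide_proteins=proteins,
                             quantifiers=quantifiers)


def pca_outlier_flags(ratios: PeptideRatioTable | pd.DataFrame,
                      k_sd: float = 4.0) -> pd.Series:
    """Flag outlying samples on the first two principal components.

    The ratio matrix is column-centered and decomposed by SVD; a sample is
    flagged when its score on PC1 or PC2 exceeds ``k_sd`` standard
    deviations of that component's scores.  Degenerate data (all samples
    identical) yields zero scores and no flags.
    """
    mat = ratios.ratios if isinstance(ratios, PeptideRatioTable) else ratios
    X = mat.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA outlier screen requires a complete matrix")
    if X.shape[0] < 3:
        raise ValueError("PCA outlier screen needs at least 3 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    # Scores = U * s from the thin SVD; at most two components are needed.
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :2] * s[:2]
    sd = scores.std(axis=0, ddof=1)
    flags = np.zeros(X.shape[0], dtype=bool)
    for j in range(scores.shape[1]):
        if sd[j] > 0 and np.isfinite(k_sd):
            flags |= np.abs(scores[:, j]) > k_sd * sd[j]
    out = pd.Series(flags, index=mat.index, name="pca_outlier")
    n_flag = int(out.sum())
    if n_flag:
        logger.warning("PCA outlier screen flagged %d sample(s): %s",
                       n_flag, out.index[out].tolist())
    else:
        logger.info("PCA outlier screen: no outlier samples identified")
    return out
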