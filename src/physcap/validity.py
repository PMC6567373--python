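"""Construct-validity statistics.

Pairwise linear associations — among conceptual-model domains, between
domains and health-related measures, and among health-related measures —
each fitted twice: unadjusted, and adjusted for Age, Gender, Height,
Weight, MMSE and number of medications.  Agreement between device-derived
and stopwatch-timed test durations is quantified with Bland-Altman limits
of agreement.

Significance is flagged at p <= 0.05 with no multiplicity correction,
replicating the original reporting convention (a known limitation: with
~15 x 9 unadjusted fits, about 5 % of null associations will flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["linear_assoc", "association_matrix", "bland_altman",
           "AssocResult", "BlandAltmanResult", "COVARIATES",
           "HEALTH_MEASURES"]

#: adjustment set used by every adjusted fit
COVARIATES = ["Age", "Gender", "Height", "Weight", "MMSE", "NM"]

#: health-related measures entering the association analyses
HEALTH_MEASURES = ["IADL", "FALL_history", "CES-D", "PA", "SPPB", "HAND",
                   "PWR", "TMTA", "GaitSpeed"]

MIN_COMPLETE_CASES = 10


@dataclass
class AssocResult:
    beta: float
    p: float
    n: int


@dataclass
class BlandAltmanResult:
    """Mean difference (bias) and 95 % limits of agreement, in seconds."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd: float


def linear_assoc(outcome: pd.Series, predictor: pd.Series,
                 covariates: pd.DataFrame | None = None) -> AssocResult:
    """OLS slope and two-sided p-value of ``predictor`` for ``outcome``.

    Covariates, when given, enter the model additively.  Listwise deletion
    across all variables; at least 10 complete cases are required.
    Collinear design matrices raise a rank-deficiency error rather than
    silently dropping terms.
    """
    df = pd.DataFrame({"__y": outcome, "__x": predictor})
    if covariates is not None and len(covariates.columns):
        df = df.join(covariates)
    df = df.dropna()
    if len(df) < MIN_COMPLETE_CASES:
        raise ValueError(f"only {len(df)} complete cases; need at least "
                         f"{MIN_COMPLETE_CASES}")
    exog = sm.add_constant(df.drop(columns="__y"))
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear "
                         "predictor/covariates)")
    fit = sm.OLS(df["__y"], exog).fit()
    return AssocResult(beta=float(fit.params["__x"]),
                       p=float(fit.pvalues["__x"]), n=int(len(df)))


def association_matrix(domains: pd.DataFrame, cohort: pd.DataFrame,
                       adjusted: bool = False,
                       covariates: list[str] = COVARIATES,
                       health_measures: list[str] | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """All three association families as one long table.

    Families: ``domain~domain`` (every ordered pair of domain scores),
    ``health~domain`` (each health-related measure on each domain) and
    ``health~health`` (every ordered pair of health measures).  Subjects
    are aligned on the index; each fit uses its own complete cases.

    Returns columns predictor, outcome, family, beta, p, n, adjusted,
    significant (p <= ``alpha``).
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    if health_measures is None:
        health_measures = [m for m in HEALTH_MEASURES if m in cohort.columns]
    cov = cohort[covariates] if adjusted else None
    data = domains.join(cohort, how="outer")
    rows = []

    def one(outcome: str, predictor: str, family: str):
        try:
            res = linear_assoc(data[outcome], data[predictor],
                               cov.reindex(data.index) if cov is not None else None)
        except ValueError:
            return
        rows.append({"predictor": predictor, "outcome": outcome,
                     "family": family, "beta": res.beta, "p": res.p,
                     "n": res.n, "adjusted": adjusted,
                     "significant": res.p <= alpha})

    dom = list(domains.columns)
    for y in dom:
        for x in dom:
            if x != y:
                one(y, x, "domain~domain")
    for y in health_measures:
        for x in dom:
            one(y, x, "health~domain")
    for y in health_measures:
        for x in health_measures:
            if x != y:
                one(y, x, "health~health")
    return pd.DataFrame(rows)


def association_pivot(table: pd.DataFrame, family: str) -> pd.DataFrame:
    """Rectangular beta layout (outcomes as columns) for one family."""
    sub = table[table["family"] == family]
    return sub.pivot(index="predictor", columns="outcome", values="beta")


def bland_altman(device: np.ndarray | pd.Series,
                 reference: np.ndarray | pd.Series) -> BlandAltmanResult:
    """Bland-Altman agreement of paired duration measurements.

    Differences d = device - reference; bias = mean(d); the 95 % limits of
    agreement are bias +- 1.96 SD(d).
    """
    device = np.asarray(device, float)
    reference = np.asarray(reference, float)
    if device.shape != reference.shape:
        raise ValueError("paired series must have equal length")
    d = device - reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return BlandAltmanResult(bias=bias, loa_lower=bias - 1.96 * sd,
                             loa_upper=bias + 1.96 * sd, sd=sd)
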