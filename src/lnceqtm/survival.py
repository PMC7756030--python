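"""Methylation risk-score survival screening of DMS-mediated lncRNAs.

For each lncRNA in a subtype network, a multivariate Cox proportional-hazards
model is fitted over the methylation levels of its network-adjacent DMSs
(tumor samples with clinical follow-up only).  Each patient's integrated risk
score is the linear combination

    RiskScore = sum_i cox_i * meth_i

of the probe beta values weighted by the fitted Cox coefficients.  Patients
are split at the median risk score (ties go to the low-risk group), and the
high/low groups are compared with the two-group log-rank test; a model is
flagged prognostic when the log-rank p falls below ``survival_alpha``.  No
multiple-testing correction is applied across lncRNA models (a BH-adjusted
column is emitted for transparency).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .config import Thresholds
from .network import EQTMNetwork

log = logging.getLogger(__name__)


def fit_cox(beta_tumor: pd.DataFrame, probe_ids: list[str],
            clinical: pd.DataFrame) -> pd.Series:
    """Multivariate Cox partial-likelihood fit over probe methylation levels.

    Patients are the intersection of tumor samples and clinical records with
    non-NA betas on all probes; ties use the Efron approximation (lifelines
    default).  Raises ValueError on degenerate input and propagates
    lifelines' ConvergenceError on collinear/non-convergent designs.

    Returns the per-probe coefficient Series (index = probe_ids).
    """
    if not probe_ids:
        raise ValueError("fit_cox needs at least one probe")
    missing = [p for p in probe_ids if p not in beta_tumor.index]
    if missing:
        raise ValueError(f"probes absent from beta matrix: {missing}")
    covar = beta_tumor.loc[probe_ids].T  # patients x probes
    patients = covar.index.intersection(clinical.index)
    covar = covar.loc[patients].dropna(axis=0, how="any")
    df = covar.join(clinical.loc[covar.index, ["time", "event"]])
    if df["event"].sum() < 1:
        raise ValueError("no observed events among usable patients")
    if len(df) <= len(probe_ids) + 1:
        raise ValueError("too few usable patients for the Cox design")
    dup = covar.T.duplicated()
    if dup.any():
        raise ConvergenceError(
            f"duplicate covariate columns: {list(covar.columns[dup])}")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return cph.params_.reindex(probe_ids)


def risk_score(cox_coefs: pd.Series, beta_tumor: pd.DataFrame,
               clinical: pd.DataFrame | None = None) -> pd.Series:
    """Per-patient integrated risk score: sum_i cox_i * meth_i.

    Patients with a missing beta on any scored probe are excluded (logged).
    When ``clinical`` is given, scoring is restricted to patients with
    follow-up records.
    """
    covar = beta_tumor.loc[cox_coefs.index].T
    if clinical is not None:
        covar = covar.loc[covar.index.intersection(clinical.index)]
    complete = covar.dropna(axis=0, how="any")
    n_dropped = len(covar) - len(complete)
    if n_dropped:
        log.info("risk_score: excluded %d patients with missing betas",
                 n_dropped)
    return complete @ cox_coefs


def median_split(scores: pd.Series) -> pd.Series:
    """Split patients at the median score: above -> high, at/below -> low.

    Raises ValueError when fewer than 4 patients are scored, when all scores
    are identical, or when either group would be empty.
    """
    if len(scores) < 4:
        raise ValueError("median split needs >= 4 scored patients")
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical: split undefined")
    med = float(scores.median())
    groups = pd.Series(np.where(scores > med, "high", "low"),
                       index=scores.index, name="risk_group")
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise ValueError("median split produced an empty group")
    return groups


def logrank_and_km(groups: pd.Series, clinical: pd.DataFrame
                   ) -> tuple[float, dict[str, pd.DataFrame]]:
    """Two-group log-rank p and product-limit Kaplan–Meier curves.

    Returns (p_value, {"high": curve, "low": curve}) where each curve is a
    DataFrame of (time, survival) points.  Raises ValueError when no events
    are observed in either arm.
    """
    clin = clinical.loc[groups.index]
    hi, lo = groups == "high", groups == "low"
    if clin["event"].sum() == 0:
        raise ValueError("no events in either arm: log-rank undefined")
    res = logrank_test(clin.loc[hi, "time"], clin.loc[lo, "time"],
                       event_observed_A=clin.loc[hi, "event"],
                       event_observed_B=clin.loc[lo, "event"])
    curves = {}
    for name, mask in (("high", hi), ("low", lo)):
        kmf = KaplanMeierFitter()
        kmf.fit(clin.loc[mask, "time"], clin.loc[mask, "event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({"time": sf.index.to_numpy(),
                                     "survival": sf.iloc[:, 0].to_numpy()})
    return float(res.p_value), curves


@dataclass
class RiskModel:
    """One lncRNA's fitted risk model and its survival separation."""

    gene_id: str
    probe_ids: list[str]
    cox_coefs: pd.Series
    risk_scores: pd.Series
    median_score: float
    groups: pd.Series
    logrank_p: float
    significant: bool
    km_curves: dict = field(default_factory=dict)


def screen_prognostic(network: EQTMNetwork, beta_tumor: pd.DataFrame,
                      clinical: pd.DataFrame,
                      thresholds: Thresholds | None = None
                      ) -> tuple[list[RiskModel], pd.DataFrame]:
    """Fit/score/split/test one candidate risk model per network lncRNA.

    Per-model failures (degenerate designs, non-convergence, no events) are
    logged and skipped, never fatal.  Returns the fitted models and a results
    table ranked by log-rank p, with a BH-adjusted column for transparency.
    """
    thresholds = thresholds or Thresholds()
    models: list[RiskModel] = []
    skipped: dict[str, str] = {}
    for gene_id, sub in network.edges.groupby("gene_id"):
        probes = sorted(sub["probe_id"].unique())
        try:
            coefs = fit_cox(beta_tumor, probes, clinical)
            scores = risk_score(coefs, beta_tumor, clinical)
            groups = median_split(scores)
            p, curves = logrank_and_km(groups, clinical)
        except (ValueError, ConvergenceError) as exc:
            skipped[gene_id] = str(exc)
            log.info("screen_prognostic: %s skipped (%s)", gene_id, exc)
            continue
        models.append(RiskModel(
            gene_id=gene_id, probe_ids=probes, cox_coefs=coefs,
            risk_scores=scores, median_score=float(scores.median()),
            groups=groups, logrank_p=p,
            significant=p < thresholds.survival_alpha, km_curves=curves))

    if models:
        table = pd.DataFrame({
            "gene_id": [m.gene_id for m in models],
            "n_probes": [len(m.probe_ids) for m in models],
            "probes": [",".join(m.probe_ids) for m in models],
            "coefs": [",".join(f"{c:.4g}" for c in m.cox_coefs) for m in models],
            "logrank_p": [m.logrank_p for m in models],
            "significant": [m.significant for m in models],
        })
        table["logrank_q_bh"] = multipletests(table["logrank_p"],
                                              method="fdr_bh")[1]
        table = table.sort_values("logrank_p", kind="mergesort").reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=["gene_id", "n_probes", "probes", "coefs",
                                      "logrank_p", "significant", "logrank_q_bh"])
    if skipped:
        log.info("screen_prognostic: %d lncRNA models skipped", len(skipped))
    table.attrs["skipped"] = skipped
    return models, table
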