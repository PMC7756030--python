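"""Differential methylation site (DMS) calling between tumor and normal cohorts.

A DMS is a single CpG whose mean beta value differs between the cohorts with
Benjamini–Hochberg ``q < fdr_alpha`` (two-sample two-tailed t-test) and an
absolute mean difference ``|delta| > delta_beta``.  Only probes mapped to at
least one lncRNA enter testing, and the BH family is formed jointly over all
testable mapped probes of a dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Thresholds

log = logging.getLogger(__name__)


def test_probe(tumor_values, normal_values,
               ttest_mode: str = "student") -> tuple[float, float, float, float]:
    """Two-sample two-tailed t-test for one probe.

    NAs are dropped per group.  ``student`` uses the pooled-variance test;
    ``welch`` the unequal-variance variant.  Groups that are constant and
    equal give (t=0, p=1); constant groups with different means (zero pooled
    variance) are untestable and raise ValueError.

    Returns (t_stat, p_value, mean_tumor, mean_normal).
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    t, n = t[~np.isnan(t)], n[~np.isnan(n)]
    if len(t) < 2 or len(n) < 2:
        raise ValueError("need >=2 non-NA values per group")
    mt, mn = float(t.mean()), float(n.mean())
    if t.var(ddof=1) == 0 and n.var(ddof=1) == 0:
        if mt == mn:
            return 0.0, 1.0, mt, mn
        raise ValueError("zero pooled variance with unequal means: untestable")
    res = stats.ttest_ind(t, n, equal_var=(ttest_mode == "student"))
    return float(res.statistic), float(res.pvalue), mt, mn


@dataclass
class DMSResult:
    """Output of :func:`call_dms`.

    Attributes
    ----------
    tests : probe-level table for every testable mapped probe
        (probe_id, mean_tumor, mean_normal, delta, t_stat, p_value, fdr_q,
        direction, is_dms).
    records : probe-level table restricted to called DMSs.
    links : one row per (DMS probe, mapped gene) with biotype_class.
    n_untestable : probes excluded before testing, with reasons logged.
    """

    tests: pd.DataFrame
    links: pd.DataFrame
    n_untestable: int = 0
    untestable_reasons: dict = field(default_factory=dict)

    @property
    def records(self) -> pd.DataFrame:
        return self.tests.loc[self.tests["is_dms"]]


def _vectorized_ttest(tumor: np.ndarray, normal: np.ndarray, ttest_mode: str):
    """Row-wise two-sample t-test with per-row NA omission."""
    res = stats.ttest_ind(tumor, normal, axis=1,
                          equal_var=(ttest_mode == "student"),
                          nan_policy="omit")
    return np.asarray(res.statistic, float), np.asarray(res.pvalue, float)


def call_dms(beta_tumor: pd.DataFrame, beta_normal: pd.DataFrame,
             pairs: pd.DataFrame, thresholds: Thresholds | None = None,
             ttest_mode: str = "student") -> DMSResult:
    """Call DMSs over all lncRNA-mapped, testable probes.

    Parameters
    ----------
    beta_tumor, beta_normal : probes x samples beta matrices sharing a probe
        universe (row indices need not be ordered identically).
    pairs : probe-to-gene mapping (columns probe_id, gene_id, biotype_class).
    thresholds : q-value and delta cut-offs (strict inequalities).
    ttest_mode : ``student`` (pooled variance) or ``welch``.
    """
    thresholds = thresholds or Thresholds()
    thresholds.validate()

    mapped = pd.Index(pairs["probe_id"].unique())
    universe = mapped.intersection(beta_tumor.index).intersection(beta_normal.index)
    if universe.empty:
        raise ValueError("no mapped probes present in both beta matrices")
    tum = beta_tumor.loc[universe].to_numpy(dtype=float)
    nor = beta_normal.loc[universe].to_numpy(dtype=float)

    n_t = (~np.isnan(tum)).sum(axis=1)
    n_n = (~np.isnan(nor)).sum(axis=1)
    enough = (n_t >= 2) & (n_n >= 2)

    mean_t = np.full(len(universe), np.nan)
    mean_n = np.full(len(universe), np.nan)
    mean_t[enough] = np.nanmean(tum[enough], axis=1)
    mean_n[enough] = np.nanmean(nor[enough], axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = np.full(len(universe), np.nan)
        var_n = np.full(len(universe), np.nan)
        var_t[enough] = np.nanvar(tum[enough], axis=1, ddof=1)
        var_n[enough] = np.nanvar(nor[enough], axis=1, ddof=1)
    degenerate = enough & (var_t == 0) & (var_n == 0)
    identical = degenerate & (mean_t == mean_n)

    testable = enough & (~degenerate | identical)
    reasons = {}
    if (~enough).any():
        reasons["fewer_than_2_values_per_group"] = int((~enough).sum())
    untestable_deg = degenerate & ~identical
    if untestable_deg.any():
        reasons["zero_pooled_variance"] = int(untestable_deg.sum())
    n_untestable = int((~testable).sum())
    if n_untestable:
        log.info("call_dms: excluded %d untestable probes (%s)",
                 n_untestable, reasons)

    t_stat = np.full(len(universe), np.nan)
    p_val = np.full(len(universe), np.nan)
    run = testable & ~identical
    if run.any():
        t_stat[run], p_val[run] = _vectorized_ttest(tum[run], nor[run], ttest_mode)
    t_stat[identical] = 0.0
    p_val[identical] = 1.0
    # rows where scipy still produced a non-finite result are untestable
    bad = run & ~np.isfinite(p_val)
    if bad.any():
        reasons["nonfinite_statistic"] = int(bad.sum())
        testable = testable & ~bad
        n_untestable += int(bad.sum())

    tests = pd.DataFrame({
        "probe_id": universe,
        "mean_tumor": mean_t,
        "mean_normal": mean_n,
        "delta": mean_t - mean_n,
        "t_stat": t_stat,
        "p_value": p_val,
    }).loc[np.asarray(testable)].reset_index(drop=True)
    if tests.empty:
        raise ValueError("zero testable probes")

    tests["fdr_q"] = multipletests(tests["p_value"], method="fdr_bh")[1]
    tests["direction"] = np.where(tests["delta"] > 0, "up", "down")
    tests["is_dms"] = ((tests["fdr_q"] < thresholds.fdr_alpha)
                       & (tests["delta"].abs() > thresholds.delta_beta))

    dms_ids = set(tests.loc[tests["is_dms"], "probe_id"])
    links = pairs.loc[pairs["probe_id"].isin(dms_ids),
                      ["probe_id", "gene_id", "biotype_class"]]
    links = links.merge(tests.loc[tests["is_dms"],
                                  ["probe_id", "delta", "direction", "fdr_q"]],
                        on="probe_id").reset_index(drop=True)
    return DMSResult(tests=tests, links=links,
                     n_untestable=n_untestable, untestable_reasons=reasons)


def summarize_dms(links: pd.DataFrame) -> dict:
    """Per-biotype-class DMS bookkeeping.

    Returns a dict with, per class: number of distinct DMS probes, number of
    distinct DMS-containing lncRNAs, percent of DMS probes upregulated
    (``NA`` for an empty class), and the per-lncRNA DMS counts ranked
    descending.  A probe mapped to two genes contributes to both genes'
    counts but only once to the class DMS count.
    """
    if links.empty:
        raise ValueError("summarize_dms requires at least one DMS record")
    summary: dict[str, dict] = {}
    for klass in ("lincRNA", "other_lncRNA"):
        sub = links.loc[links["biotype_class"] == klass]
        probes = sub.drop_duplicates("probe_id")
        n_dms = len(probes)
        per_gene = (sub.drop_duplicates(["probe_id", "gene_id"])
                    .groupby("gene_id").size()
                    .sort_values(ascending=False, kind="mergesort"))
        summary[klass] = {
            "n_dms": n_dms,
            "n_lncrnas": int(per_gene.size),
            "pct_up": (round(100.0 * (probes["direction"] == "up").mean(), 2)
                       if n_dms else None),
            "per_gene_dms_counts": per_gene.to_dict(),
        }
    return summary
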