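"""Cancer-specific lnc-eQTM network construction.

For every (DMS probe, mapped lncRNA) pair, the Pearson correlation between
the probe's methylation and the lncRNA's log2 expression is computed in the
tumor cohort and in the normal cohort separately.  Pairs whose correlation
changes between conditions — absolute PCC difference strictly above the
threshold — become edges of the cancer-specific network.  Each edge carries a
sign class (red/blue in the original visualisations); by default this is the
sign of the tumor-condition correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .annotation import strip_version
from .config import Thresholds

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["probe_id", "gene_id", "biotype_class", "pcc_tumor",
                "pcc_normal", "delta_pcc", "sign_class", "n_tumor", "n_normal"]


def pcc(x_values, y_values, min_pairs: int = 10) -> tuple[float, int]:
    """Pearson product-moment coefficient over complete observation pairs.

    Returns (coefficient, number of complete pairs used).  Raises ValueError
    when fewer than ``min_pairs`` complete pairs remain or either variable is
    constant over them.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_pairs:
        raise ValueError(f"only {n} complete pairs (< min_pairs={min_pairs})")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance over complete pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, n


def pcc_difference(pcc_tumor: float, pcc_normal: float) -> float:
    """Absolute difference of the two per-condition Pearson coefficients."""
    for v in (pcc_tumor, pcc_normal):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"PCC {v!r} outside [-1, 1]")
    return abs(pcc_tumor - pcc_normal)


def sign_class(pcc_tumor: float, pcc_normal: float, mode: str = "tumor") -> str:
    """Edge sign convention.

    ``tumor``: sign of the cancer-condition PCC (ties at exactly 0 are
    positive).  ``normal``: sign of the normal-condition PCC.  ``stronger``:
    sign of whichever condition has the larger |PCC|.
    """
    if mode == "tumor":
        ref = pcc_tumor
    elif mode == "normal":
        ref = pcc_normal
    elif mode == "stronger":
        ref = pcc_tumor if abs(pcc_tumor) >= abs(pcc_normal) else pcc_normal
    else:
        raise ValueError(f"unknown sign mode {mode!r}")
    return "positive" if ref >= 0 else "negative"


@dataclass
class EQTMNetwork:
    """A subtype-specific lnc-eQTM network: retained edges plus a label."""

    edges: pd.DataFrame
    label: str = ""
    n_candidates: int = 0
    n_uncomputable: int = 0

    @property
    def dms_nodes(self) -> set:
        return set(self.edges["probe_id"])

    @property
    def lncrna_nodes(self) -> set:
        return set(self.edges["gene_id"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(label=self.label)
        for row in self.edges.itertuples(index=False):
            g.add_node(row.probe_id, kind="dms")
            g.add_node(row.gene_id, kind="lncRNA", biotype=row.biotype_class)
            g.add_edge(row.probe_id, row.gene_id,
                       pcc_tumor=row.pcc_tumor, pcc_normal=row.pcc_normal,
                       delta_pcc=row.delta_pcc, sign=row.sign_class)
        return g


def build_network(dms_tests: pd.DataFrame, pairs: pd.DataFrame,
                  beta_tumor: pd.DataFrame, beta_normal: pd.DataFrame,
                  expr_tumor: pd.DataFrame, expr_normal: pd.DataFrame,
                  thresholds: Thresholds | None = None,
                  sign_mode: str = "tumor", label: str = "") -> EQTMNetwork:
    """Assemble the subtype-specific lnc-eQTM network.

    Candidate pairs are every (DMS probe, mapped lncRNA); an edge is retained
    iff ``|pcc_tumor - pcc_normal| > thresholds.delta_pcc``.  Expression
    matrices must be log2-scaled.  Gene identifiers are matched after
    stripping version suffixes.  An empty result is a valid (warned) network.
    """
    thresholds = thresholds or Thresholds()
    thresholds.validate()

    dms_ids = set(dms_tests.loc[dms_tests["is_dms"], "probe_id"])
    cand = pairs.loc[pairs["probe_id"].isin(dms_ids)].drop_duplicates(
        ["probe_id", "gene_id"])

    expr_t_ix = {strip_version(g): g for g in expr_tumor.index}
    expr_n_ix = {strip_version(g): g for g in expr_normal.index}
    t_samples = beta_tumor.columns.intersection(expr_tumor.columns)
    n_samples = beta_normal.columns.intersection(expr_normal.columns)

    rows, n_uncomputable = [], 0
    for row in cand.itertuples(index=False):
        key = strip_version(row.gene_id)
        if key not in expr_t_ix or key not in expr_n_ix:
            continue
        try:
            r_t, n_t = pcc(beta_tumor.loc[row.probe_id, t_samples],
                           expr_tumor.loc[expr_t_ix[key], t_samples],
                           thresholds.min_pairs)
            r_n, n_n = pcc(beta_normal.loc[row.probe_id, n_samples],
                           expr_normal.loc[expr_n_ix[key], n_samples],
                           thresholds.min_pairs)
        except ValueError as exc:
            n_uncomputable += 1
            log.debug("pair (%s, %s) uncomputable: %s",
                      row.probe_id, row.gene_id, exc)
            continue
        d = pcc_difference(r_t, r_n)
        if d > thresholds.delta_pcc:
            rows.append((row.probe_id, row.gene_id, row.biotype_class,
                         r_t, r_n, d, sign_class(r_t, r_n, sign_mode),
                         n_t, n_n))

    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if edges.empty:
        log.warning("build_network(%s): no edges retained at delta_pcc > %g",
                    label, thresholds.delta_pcc)
    if n_uncomputable:
        log.info("build_network(%s): %d candidate pairs uncomputable",
                 label, n_uncomputable)
    return EQTMNetwork(edges=edges, label=label, n_candidates=len(cand),
                       n_uncomputable=n_uncomputable)


def network_stats(net: EQTMNetwork, top: int = 10) -> dict:
    """Edge/sign/node counts and the highest-degree nodes."""
    e = net.edges
    g = net.to_networkx()
    degree = sorted(g.degree, key=lambda kv: (-kv[1], kv[0])) if len(g) else []
    return {
        "label": net.label,
        "n_edges": len(e),
        "n_positive": int((e["sign_class"] == "positive").sum()),
        "n_negative": int((e["sign_class"] == "negative").sum()),
        "n_dms": len(net.dms_nodes),
        "n_lncrnas": len(net.lncrna_nodes),
        "top_degree": degree[:top],
    }


def write_edge_list(net: EQTMNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sif(net: EQTMNetwork, path) -> None:
    """Cytoscape SIF export: probe <sign_class> gene, one edge per line."""
    with open(path, "w") as fh:
        for row in net.edges.itertuples(index=False):
            fh.write(f"{row.probe_id}\t{row.sign_class}\t{row.gene_id}\n")


def write_graphml(net: EQTMNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def write_node_attributes(net: EQTMNetwork, path) -> None:
    g = net.to_networkx()
    rows = [{"node": n, "kind": d.get("kind"),
             "biotype": d.get("biotype", ""), "degree": g.degree(n)}
            for n, d in g.nodes(data=True)]
    pd.DataFrame(rows, columns=["node", "kind", "biotype", "degree"]).to_csv(
        path, sep="\t", index=False)
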