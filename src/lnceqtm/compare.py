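"""Cross-subtype comparison of two lnc-eQTM networks.

Common and specific DMS probes / DMS-mediated lncRNAs are plain set algebra
on the node identities; common edges are matched on (probe_id, gene_id).
The opposite-direction fraction is computed over the common DMS probes, each
probe carrying the majority sign of its edges within a subtype (exact sign
ties are excluded, with a logged count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .network import EQTMNetwork

log = logging.getLogger(__name__)


def _probe_signs(net: EQTMNetwork) -> dict[str, str]:
    """Majority edge sign per DMS probe; ties map to None."""
    signs: dict[str, str | None] = {}
    for probe, sub in net.edges.groupby("probe_id"):
        pos = int((sub["sign_class"] == "positive").sum())
        neg = int((sub["sign_class"] == "negative").sum())
        if pos > neg:
            signs[probe] = "positive"
        elif neg > pos:
            signs[probe] = "negative"
        else:
            signs[probe] = None
    return signs


@dataclass
class ComparisonResult:
    common_genes: set
    specific_genes_a: set
    specific_genes_b: set
    common_probes: set
    specific_probes_a: set
    specific_probes_b: set
    common_edges: pd.DataFrame
    opposite_fraction: float | None
    n_opposite: int
    n_compared: int
    n_sign_ties: int
    per_gene_dms_counts: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "common_genes": sorted(self.common_genes),
            "specific_genes_a": sorted(self.specific_genes_a),
            "specific_genes_b": sorted(self.specific_genes_b),
            "common_probes": sorted(self.common_probes),
            "specific_probes_a": sorted(self.specific_probes_a),
            "specific_probes_b": sorted(self.specific_probes_b),
            "n_common_edges": len(self.common_edges),
            "opposite_fraction": self.opposite_fraction,
            "n_opposite": self.n_opposite,
            "n_compared": self.n_compared,
            "n_sign_ties": self.n_sign_ties,
        }


def compare_networks(net_a: EQTMNetwork, net_b: EQTMNetwork) -> ComparisonResult:
    """Set overlaps, per-edge PCC pairing, and the opposite-sign fraction.

    ``opposite_fraction`` is 100 * (# common probes whose majority signs
    disagree) / (# common probes with a defined sign in both subtypes),
    rounded to 2 decimals; None when no probe is comparable.
    """
    genes_a, genes_b = net_a.lncrna_nodes, net_b.lncrna_nodes
    probes_a, probes_b = net_a.dms_nodes, net_b.dms_nodes
    common_genes = genes_a & genes_b
    common_probes = probes_a & probes_b

    key = ["probe_id", "gene_id"]
    common_edges = net_a.edges.merge(net_b.edges, on=key,
                                     suffixes=("_a", "_b"))

    signs_a, signs_b = _probe_signs(net_a), _probe_signs(net_b)
    n_opposite = n_compared = n_ties = 0
    for probe in common_probes:
        sa, sb = signs_a.get(probe), signs_b.get(probe)
        if sa is None or sb is None:
            n_ties += 1
            continue
        n_compared += 1
        if sa != sb:
            n_opposite += 1
    if n_ties:
        log.info("compare_networks: %d common probes excluded from the "
                 "opposite fraction (sign ties)", n_ties)
    fraction = (round(100.0 * n_opposite / n_compared, 2)
                if n_compared else None)

    return ComparisonResult(
        common_genes=common_genes,
        specific_genes_a=genes_a - genes_b,
        specific_genes_b=genes_b - genes_a,
        common_probes=common_probes,
        specific_probes_a=probes_a - probes_b,
        specific_probes_b=probes_b - probes_a,
        common_edges=common_edges,
        opposite_fraction=fraction,
        n_opposite=n_opposite,
        n_compared=n_compared,
        n_sign_ties=n_ties,
        per_gene_dms_counts=per_gene_dms_profile(net_a, net_b, common_genes),
    )


def per_gene_dms_profile(net_a: EQTMNetwork, net_b: EQTMNetwork,
                         common_genes: set) -> pd.DataFrame:
    """Distinct adjacent DMS probes per common gene, in each network."""
    def counts(net: EQTMNetwork) -> dict[str, int]:
        sub = net.edges.drop_duplicates(["probe_id", "gene_id"])
        return sub.groupby("gene_id")["probe_id"].nunique().to_dict()

    ca, cb = counts(net_a), counts(net_b)
    rows = [(g, ca.get(g, 0), cb.get(g, 0)) for g in sorted(common_genes)]
    return pd.DataFrame(rows, columns=["gene_id", "count_a", "count_b"])
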