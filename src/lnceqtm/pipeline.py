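"""Per-subtype orchestration of the full lnc-eQTM analysis, plus comparison.

Stage order per subtype: matrix preprocessing -> probe-to-lncRNA mapping ->
DMS calling -> differential-correlation network -> survival screening.  Every
stage writes its tables under the output directory, and a run manifest
records thresholds, options, and in/out counts at every filter so the
bookkeeping is auditable.  All stages are pure functions of inputs + config:
rerunning on the same inputs yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .annotation import read_gtf, map_probes, strip_version
from .compare import ComparisonResult, compare_networks
from .config import PipelineOptions, Thresholds
from .dms import DMSResult, call_dms, summarize_dms
from .network import (EQTMNetwork, build_network, network_stats,
                      write_edge_list, write_graphml, write_node_attributes,
                      write_sif)
from .preprocessing import (filter_all_na_probes, filter_zero_genes,
                            log2_with_zero_replacement, min_positive,
                            validate_beta)
from .survival import screen_prognostic

log = logging.getLogger(__name__)


@dataclass
class SubtypeInputs:
    """File paths of one subtype's raw inputs."""

    gtf: Path
    probes: Path
    beta_tumor: Path
    beta_normal: Path
    expr_tumor: Path
    expr_normal: Path
    clinical: Path | None = None

    def validate(self) -> None:
        for name in ("gtf", "probes", "beta_tumor", "beta_normal",
                     "expr_tumor", "expr_normal"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name} input missing: {p}")
        if self.clinical is not None and not Path(self.clinical).is_file():
            raise FileNotFoundError(f"clinical input missing: {self.clinical}")


@dataclass
class SubtypeResult:
    label: str
    genes: pd.DataFrame
    pairs: pd.DataFrame
    beta_tumor: pd.DataFrame
    beta_normal: pd.DataFrame
    expr_tumor: pd.DataFrame
    expr_normal: pd.DataFrame
    dms: DMSResult
    network: EQTMNetwork
    survival_table: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _preprocess_expression(expr_t: pd.DataFrame, expr_n: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Shared zero-gene filter, shared zero-replacement floor, log2."""
    common = expr_t.index.intersection(expr_n.index)
    combined = expr_t.loc[common].join(expr_n.loc[common])
    kept, n_removed = filter_zero_genes(combined)
    floor = min_positive(kept)
    out_t = log2_with_zero_replacement(expr_t.loc[kept.index], floor=floor)
    out_n = log2_with_zero_replacement(expr_n.loc[kept.index], floor=floor)
    counts = {"n_genes_in": len(common), "n_all_zero_removed": n_removed,
              "zero_replacement_floor": floor}
    return out_t, out_n, counts


def _preprocess_methylation(beta_t: pd.DataFrame, beta_n: pd.DataFrame
                            ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """All-NA probe removal over the combined tumor+normal matrix."""
    validate_beta(beta_t)
    validate_beta(beta_n)
    common = beta_t.index.intersection(beta_n.index)
    combined = beta_t.loc[common].join(beta_n.loc[common])
    kept, n_removed = filter_all_na_probes(combined)
    counts = {"n_probes_in": len(common), "n_all_na_removed": n_removed}
    return beta_t.loc[kept.index], beta_n.loc[kept.index], counts


def run_subtype(inputs: SubtypeInputs, label: str,
                thresholds: Thresholds | None = None,
                options: PipelineOptions | None = None,
                out_dir: str | Path | None = None) -> SubtypeResult:
    """Execute the full per-subtype analysis; write stage outputs if asked.

    A missing clinical file skips the survival stage with a warning; any
    other stage error aborts with the stage name and cause.
    """
    thresholds = thresholds or Thresholds()
    options = options or PipelineOptions()
    thresholds.validate()
    options.validate()
    inputs.validate()
    manifest: dict = {"label": label, "thresholds": thresholds.as_dict(),
                      "options": options.as_dict(), "counts": {}}

    def stage(name):
        log.info("[%s] stage: %s", label, name)
        return name

    try:
        name = stage("read")
        genes = read_gtf(inputs.gtf)
        probes = lio.read_probe_manifest(inputs.probes)
        beta_t, beta_n = (lio.read_matrix(inputs.beta_tumor),
                          lio.read_matrix(inputs.beta_normal))
        expr_t, expr_n = (lio.read_matrix(inputs.expr_tumor),
                          lio.read_matrix(inputs.expr_normal))
        clinical = (lio.read_clinical(inputs.clinical)
                    if inputs.clinical is not None else None)
        manifest["counts"]["annotation"] = {
            "n_lncrna_genes": len(genes), "n_probes_manifest": len(probes)}

        name = stage("preprocess")
        expr_t, expr_n, expr_counts = _preprocess_expression(expr_t, expr_n)
        beta_t, beta_n, beta_counts = _preprocess_methylation(beta_t, beta_n)
        manifest["counts"]["expression"] = expr_counts
        manifest["counts"]["methylation"] = beta_counts

        name = stage("map")
        pairs = map_probes(probes, genes, flank=options.probe_flank)
        expr_genes = {strip_version(g) for g in expr_t.index}
        pairs = pairs.loc[
            pairs["probe_id"].isin(beta_t.index)
            & pairs["gene_id"].map(strip_version).isin(expr_genes)
        ].reset_index(drop=True)
        manifest["counts"]["mapping"] = {
            "n_pairs": len(pairs),
            "n_mapped_probes": pairs["probe_id"].nunique(),
            "n_mapped_genes": pairs["gene_id"].nunique()}

        name = stage("dms")
        dms = call_dms(beta_t, beta_n, pairs, thresholds, options.ttest_mode)
        manifest["counts"]["dms"] = {
            "n_tested": len(dms.tests),
            "n_untestable": dms.n_untestable,
            "n_dms": int(dms.tests["is_dms"].sum())}
        summary = summarize_dms(dms.links) if not dms.links.empty else None
        manifest["counts"]["dms_by_class"] = summary

        name = stage("network")
        net = build_network(dms.tests, pairs, beta_t, beta_n, expr_t, expr_n,
                            thresholds, options.sign_mode, label)
        stats = network_stats(net)
        manifest["counts"]["network"] = {
            k: v for k, v in stats.items() if k != "top_degree"}

        name = stage("survival")
        surv_table = None
        if clinical is None:
            log.warning("[%s] no clinical file: survival stage skipped", label)
            manifest["counts"]["survival"] = "skipped (no clinical input)"
            models = []
        else:
            models, surv_table = screen_prognostic(net, beta_t, clinical,
                                                   thresholds)
            manifest["counts"]["survival"] = {
                "n_models": len(surv_table),
                "n_significant": int(surv_table["significant"].sum())
                if not surv_table.empty else 0,
                "n_skipped": len(surv_table.attrs.get("skipped", {}))}
    except Exception as exc:
        raise RuntimeError(f"[{label}] stage '{name}' failed: {exc}") from exc

    result = SubtypeResult(label=label, genes=genes, pairs=pairs,
                           beta_tumor=beta_t, beta_normal=beta_n,
                           expr_tumor=expr_t, expr_normal=expr_n, dms=dms,
                           network=net, survival_table=surv_table,
                           manifest=manifest)
    if out_dir is not None:
        write_subtype_outputs(result, models, Path(out_dir))
    return result


def write_subtype_outputs(result: SubtypeResult, models, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.pairs.to_csv(out_dir / "probe_gene_pairs.tsv", sep="\t", index=False)
    result.dms.tests.to_csv(out_dir / "dms_tests.tsv", sep="\t", index=False,
                            float_format="%.6g")
    result.dms.links.to_csv(out_dir / "dms_links.tsv", sep="\t", index=False,
                            float_format="%.6g")
    write_edge_list(result.network, out_dir / "network_edges.tsv")
    write_sif(result.network, out_dir / "network.sif")
    write_graphml(result.network, out_dir / "network.graphml")
    write_node_attributes(result.network, out_dir / "network_nodes.tsv")
    if result.survival_table is not None:
        result.survival_table.to_csv(out_dir / "survival_models.tsv",
                                     sep="\t", index=False, float_format="%.6g")
        for m in models:
            if m.significant:
                for grp, curve in m.km_curves.items():
                    curve.to_csv(out_dir / f"km_{m.gene_id}_{grp}.tsv",
                                 sep="\t", index=False, float_format="%.6g")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True, default=str))


def run_compare(result_a: SubtypeResult, result_b: SubtypeResult,
                out_dir: str | Path | None = None) -> ComparisonResult:
    """Cross-subtype comparison; requires a shared annotation universe."""
    if not result_a.genes["gene_id"].equals(result_b.genes["gene_id"]):
        raise ValueError("annotation universes differ between subtype runs")
    comp = compare_networks(result_a.network, result_b.network)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "comparison.json").write_text(
            json.dumps(comp.as_dict(), indent=1, sort_keys=True))
        comp.per_gene_dms_counts.to_csv(out / "common_gene_dms_counts.tsv",
                                        sep="\t", index=False)
        comp.common_edges.to_csv(out / "common_edges.tsv", sep="\t",
                                 index=False, float_format="%.6g")
        _write_report(result_a, result_b, comp, out / "report.txt")
    return comp


def _write_report(a: SubtypeResult, b: SubtypeResult, comp: ComparisonResult,
                  path: Path) -> None:
    lines = [f"lnc-eQTM comparison: {a.label} vs {b.label}", ""]
    for r in (a, b):
        c = r.manifest["counts"]
        lines.append(f"[{r.label}] DMSs: {c['dms']['n_dms']} "
                     f"(tested {c['dms']['n_tested']})")
        n = c["network"]
        lines.append(f"[{r.label}] network: {n['n_edges']} edges "
                     f"({n['n_positive']} positive + {n['n_negative']} negative), "
                     f"{n['n_dms']} DMSs, {n['n_lncrnas']} lncRNAs")
        s = c.get("survival")
        if isinstance(s, dict):
            lines.append(f"[{r.label}] prognostic models: "
                         f"{s['n_significant']} of {s['n_models']} significant")
    lines += ["",
              f"common DMSmlncRNAs: {len(comp.common_genes)} "
              f"(specific: {len(comp.specific_genes_a)} / "
              f"{len(comp.specific_genes_b)})",
              f"common DMSs: {len(comp.common_probes)} "
              f"(specific: {len(comp.specific_probes_a)} / "
              f"{len(comp.specific_probes_b)})",
              f"opposite-direction fraction: {comp.opposite_fraction}% "
              f"({comp.n_opposite}/{comp.n_compared}, "
              f"{comp.n_sign_ties} sign ties excluded)"]
    path.write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- YAML config

def load_pipeline_config(path: str | Path):
    """Parse a YAML pipeline config into (subtype inputs, thresholds, options,
    output dir)."""
    cfg = yaml.safe_load(Path(path).read_text())
    thresholds = Thresholds(**cfg.get("thresholds", {}))
    options = PipelineOptions(**cfg.get("options", {}))
    subtypes = {}
    for label, paths in cfg["subtypes"].items():
        clin = paths.get("clinical")
        subtypes[label] = SubtypeInputs(
            gtf=Path(paths["gtf"]), probes=Path(paths["probes"]),
            beta_tumor=Path(paths["beta_tumor"]),
            beta_normal=Path(paths["beta_normal"]),
            expr_tumor=Path(paths["expr_tumor"]),
            expr_normal=Path(paths["expr_normal"]),
            clinical=Path(clin) if clin else None)
    return subtypes, thresholds, options, Path(cfg.get("output_dir", "out"))


def run_all(config_path: str | Path) -> dict:
    """Run every configured subtype and, when there are two, the comparison."""
    subtypes, thresholds, options, out_dir = load_pipeline_config(config_path)
    results = {}
    for label, inputs in subtypes.items():
        results[label] = run_subtype(inputs, label, thresholds, options,
                                     out_dir / label)
    if len(results) >= 2:
        labels = list(results)
        run_compare(results[labels[0]], results[labels[1]],
                    out_dir / "comparison")
    return results
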