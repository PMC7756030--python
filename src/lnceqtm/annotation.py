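"""Gene / probe annotation handling and CpG-probe-to-lncRNA mapping.

lncRNA loci come from GENCODE-dialect GTF gene lines; 450k CpG probes come
from a manifest TSV of 1-based genomic positions.  A probe maps to every
lncRNA whose gene span (GTF gene line, 1-based inclusive, optionally padded
by a flank) contains its position, on either strand.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: biotypes classified as long intergenic non-coding RNA
LINCRNA_BIOTYPES = frozenset({"lincRNA"})

#: default biotypes classified as "other lncRNA" (non-exhaustive by design;
#: covers antisense, pseudogene-derived and overlap-class lncRNA biotypes)
DEFAULT_OTHER_LNCRNA_BIOTYPES = frozenset({
    "antisense",
    "transcribed_processed_pseudogene",
    "sense_overlapping",
    "sense_intronic",
    "3prime_overlapping_ncRNA",
    "bidirectional_promoter_lncRNA",
    "macro_lncRNA",
    "non_coding",
})

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand",
                "biotype_raw", "biotype_class"]


def classify_biotype(biotype_raw: str,
                     other_lncrna_biotypes: frozenset[str] = DEFAULT_OTHER_LNCRNA_BIOTYPES,
                     ) -> str | None:
    """Classify a raw biotype string as ``lincRNA`` / ``other_lncRNA`` / None.

    Returns ``None`` for any biotype that is not an accepted lncRNA class
    (protein_coding, miRNA, empty string, ...).  Total function: never raises.
    """
    if biotype_raw in LINCRNA_BIOTYPES:
        return "lincRNA"
    if biotype_raw in other_lncrna_biotypes:
        return "other_lncRNA"
    return None


def strip_version(gene_id: str) -> str:
    """Drop a trailing GENCODE-style version suffix (``ENSG....N`` -> ``ENSG...``)."""
    return re.sub(r"\.\d+$", "", gene_id)


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if "gene_id" not in attrs:
        raise ValueError(f"GTF line {lineno}: missing gene_id attribute")
    return attrs


def read_gtf(path: str | Path,
             other_lncrna_biotypes: frozenset[str] = DEFAULT_OTHER_LNCRNA_BIOTYPES,
             ) -> pd.DataFrame:
    """Read GTF gene lines and keep lncRNA loci.

    One record per ``gene`` feature line whose ``gene_type`` is an accepted
    lncRNA biotype; all other gene lines are dropped (count logged).
    Coordinates are kept 1-based inclusive, as in the GTF.
    """
    records = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"GTF line {lineno}: bad coordinates") from exc
            if start_i > end_i:
                raise ValueError(f"GTF line {lineno}: start > end")
            if strand not in ("+", "-"):
                raise ValueError(f"GTF line {lineno}: bad strand {strand!r}")
            attr = _parse_attributes(attrs, lineno)
            biotype_raw = attr.get("gene_type", "")
            klass = classify_biotype(biotype_raw, other_lncrna_biotypes)
            if klass is None:
                n_dropped += 1
                continue
            records.append((attr["gene_id"],
                            attr.get("gene_name", attr["gene_id"]),
                            chrom, start_i, end_i, strand, biotype_raw, klass))
    log.info("read_gtf: kept %d lncRNA gene lines, dropped %d non-lncRNA",
             len(records), n_dropped)
    return pd.DataFrame.from_records(records, columns=GENE_COLUMNS)


def _check_chrom_dialects(probe_chroms, gene_chroms) -> None:
    p_chr = {c.startswith("chr") for c in probe_chroms}
    g_chr = {c.startswith("chr") for c in gene_chroms}
    if p_chr and g_chr and p_chr.isdisjoint(g_chr):
        p_ex = next(iter(probe_chroms))
        g_ex = next(iter(gene_chroms))
        raise ValueError(
            "chromosome naming mismatch between probe manifest and gene "
            f"annotation (e.g. probe {p_ex!r} vs gene {g_ex!r}); harmonise "
            "the 'chr' prefix before mapping")


def map_probes(probes: pd.DataFrame, genes: pd.DataFrame,
               flank: int = 0) -> pd.DataFrame:
    """Map each CpG probe to every lncRNA gene span containing it.

    A pair is emitted for every (probe, gene) on the same chromosome with
    ``start - flank <= pos <= end + flank`` (1-based inclusive on both ends);
    strand is ignored.  A probe overlapping k genes yields k pairs.  Output is
    sorted by (chrom, pos, gene_id).

    Parameters
    ----------
    probes : DataFrame with columns probe_id, chrom, pos.
    genes : DataFrame as returned by :func:`read_gtf`.
    flank : bp added symmetrically to each gene span (0 = gene body only).

    Returns
    -------
    DataFrame with columns probe_id, gene_id, biotype_class, chrom, pos.
    """
    if probes.empty or genes.empty:
        raise ValueError("map_probes requires non-empty probe and gene tables")
    _check_chrom_dialects(set(probes["chrom"]), set(genes["chrom"]))

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            # IntervalTree is half-open; +1 makes the 1-based end inclusive
            tree.addi(row.start - flank, row.end + flank + 1,
                      (row.gene_id, row.biotype_class))
        trees[chrom] = tree

    rows = []
    for probe in probes.itertuples(index=False):
        tree = trees.get(probe.chrom)
        if tree is None:
            continue
        for iv in tree.at(probe.pos):
            gene_id, klass = iv.data
            rows.append((probe.probe_id, gene_id, klass, probe.chrom, probe.pos))
    pairs = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "biotype_class", "chrom", "pos"])
    pairs = pairs.sort_values(["chrom", "pos", "gene_id"], kind="mergesort")
    return pairs.reset_index(drop=True)


def probes_to_bed(probes: pd.DataFrame) -> pd.DataFrame:
    """Probe positions as 0-based half-open BED intervals (export helper)."""
    return pd.DataFrame({
        "chrom": probes["chrom"],
        "start": probes["pos"] - 1,
        "end": probes["pos"],
        "name": probes["probe_id"],
    })
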