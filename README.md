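# lnceqtm

Discovery of **lncRNA expression quantitative trait methylations (lnc-eQTMs)**
from paired tumor/normal cohorts: CpG sites whose methylation is coupled to the
expression of a long non-coding RNA in a cancer-specific way, plus the
downstream prognostic value of those sites.

The package is aimed at computational epigenomics work on TCGA-style data —
Illumina 450k beta-value matrices, RNA-seq lncRNA expression matrices, GENCODE
annotation, and clinical follow-up — and ships a seeded synthetic-study
generator with planted ground truth so every statistical stage can be
validated end to end.

## The method

For each cancer subtype, with tumor (T) and normal (N) cohorts:

1. **Preprocessing.** lncRNAs with zero expression in every sample are
   removed; remaining zeros are set to the minimum positive value of the
   matrix and everything is log2-transformed. CpG probes that are NA in every
   sample are removed.
2. **Probe→lncRNA mapping.** A probe maps to every lncRNA gene span
   (GENCODE GTF gene line, 1-based inclusive) containing its position;
   lncRNAs are classed as *lincRNA* vs *other lncRNA* (antisense,
   sense_overlapping, pseudogene-derived, ...).
3. **Differential methylation (DMS calling).** Per mapped probe, a two-tailed
   two-sample Student's *t*-test of tumor vs normal betas; a probe is a DMS
   when the Benjamini–Hochberg *q* < 0.05 and the absolute mean beta
   difference |Δβ| > 0.3.
4. **Differential-correlation network.** For every (DMS, mapped lncRNA)
   pair, the Pearson correlation *r* between methylation and log2 expression
   is computed separately per condition; the pair becomes a cancer-specific
   edge when |r_T − r_N| > 0.3. Edge sign follows the tumor-condition
   correlation.
5. **Subtype comparison.** Common/specific DMSs and network lncRNAs
   (*DMSmlncRNAs*) between two subtypes, and the fraction of common DMSs
   whose edge sign flips between subtypes.
6. **Survival.** Per network lncRNA, a multivariate Cox model over its
   adjacent DMS betas gives the integrated risk score
   RiskScore = Σᵢ coxᵢ · methᵢ; patients are median-split and the high/low
   groups compared with the log-rank test (prognostic if *p* < 0.05).

## Worked example

Generate a two-subtype synthetic study (shared annotation, partially shared
planted signal) and run everything:

```sh
lnceqtm simulate --seed 7 --out demo/sim --two-subtypes
lnceqtm compare --bundle-a demo/sim/A --bundle-b demo/sim/B --out demo/out
cat demo/out/comparison/report.txt
```

```
lnc-eQTM comparison: A vs B

[A] DMSs: 53 (tested 167)
[A] network: 45 edges (15 positive + 30 negative), 45 DMSs, 41 lncRNAs
[A] prognostic models: 4 of 41 significant
[B] DMSs: 53 (tested 167)
[B] network: 44 edges (26 positive + 18 negative), 44 DMSs, 40 lncRNAs
[B] prognostic models: 3 of 40 significant

common DMSmlncRNAs: 31 (specific: 10 / 9)
common DMSs: 20 (specific: 25 / 24)
opposite-direction fraction: 30.0% (6/20, 0 sign ties excluded)
```

Reading this: each subtype's generator planted 53–55 differentially
methylated CpGs (Δβ = 0.4), of which 53 were recovered at *q* < 0.05 and
|Δβ| > 0.3; every gene hosting a planted DMS was coupled to it in the normal
condition only, and those couplings surface as the network's ΔPCC > 0.3
edges. The two subtypes were planted with ~50% shared DMSs, which is what
the common/specific decomposition recovers. Per-stage tables (DMS tests,
edge lists, SIF/GraphML exports for Cytoscape, survival models, KM curves,
run manifest) are written under `demo/out/`.

The same pipeline runs on real data: point a YAML config at your GTF, probe
manifest, beta/expression matrices and clinical table and use
`lnceqtm run-all --config pipeline.yaml` (see `lnceqtm --help`).

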