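# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator's assumptions, the defaults that matter, and the
design choices made where the procedure was genuinely open.

## Pipeline model

**Preprocessing.** Expression filtering and the log2 transform operate per
cancer-type dataset: the all-zero-gene filter and the zero-replacement floor
(the minimum positive value of the matrix) are computed over the combined
tumor+normal expression matrix of a subtype, then applied to each cohort, so
both cohorts live on one scale. Replacing zeros with the global minimum
positive value treats zeros as left-censored ("below detection") rather than
structurally absent; the transform is monotone and produces no −∞. The
per-matrix (rather than per-gene) scope of the floor is a documented choice;
the alternative changes only genes whose minimum positive value differs
strongly from the global one. All-NA probe removal likewise uses the
combined matrix, so tumor and normal share a probe universe — the two-sample
test downstream needs both groups per probe.

**Probe mapping.** The overlap unit is the full gene span from the GTF gene
line (1-based inclusive; strand ignored), with an optional symmetric flank
(default 0 bp — gene body only; promoter-window mapping is a config
extension, not a default). Probes overlapping k genes yield k pairs and are
never deduplicated. Gene identifiers are matched across annotation and
expression after stripping GENCODE version suffixes. Biotype classing is
driven entirely by the GTF `gene_type` string: `lincRNA` on one side, a
configurable non-exhaustive set of other lncRNA biotypes (antisense,
sense_overlapping, transcribed_processed_pseudogene, sense_intronic, and the
rarer overlap/promoter classes) on the other; anything else is dropped.

**DMS calling.** The test is the pooled-variance two-sample t-test (taking
"Student's t-test" literally; Welch is a config option), two-tailed, with
NAs dropped per group and at least two values per group required. Probes
with zero pooled variance and unequal means are untestable and excluded with
a logged reason; constant-and-equal probes get t = 0, p = 1.
Benjamini–Hochberg q-values are computed over a single family: all testable
probes mapped to at least one lncRNA in the subtype (not per biotype class,
and not the full array — the analysis concerns lncRNA-resident CpGs only).
Both criteria are strict inequalities: q < 0.05 and |Δβ| > 0.3. The default
Δβ threshold of 0.3 is a large effect for 450k data; with cohort sizes in
the tens it dominates the q-value criterion.

**Differential-correlation network.** Pearson correlations use complete
pairs only with `min_pairs = 10` (correlations on fewer complete
observations, or on a constant vector, are flagged uncomputable and the pair
skipped). An edge requires |r_T − r_N| strictly above 0.3; no correlation
p-value or permutation filter is applied. Edge sign is not defined by the
source procedure; the default here is the sign of the tumor-condition
correlation (ties at exactly 0 count as positive), with sign-of-normal and
sign-of-the-stronger-|r| available as config modes. Networks are exported
as edge-list TSV, Cytoscape SIF, and GraphML.

**Subtype comparison.** Common DMSs/lncRNAs are plain set intersections of
node identities; common edges are matched on (probe, gene). The
opposite-direction fraction is computed over common DMS probes, each probe
carrying the majority sign of its edges within a subtype; exact sign ties
are excluded with a logged count. Fractions are reported to two decimals.

**Survival.** One candidate risk model per network lncRNA, over the betas of
its network-adjacent DMSs, tumor samples with follow-up only. The Cox fit
uses lifelines' partial likelihood with the Efron tie approximation; designs
with duplicate covariate columns, too few usable patients, or no events are
skipped with a logged reason, never fatal. The integrated risk score is the
exact linear form Σᵢ coxᵢ·methᵢ (the methylation-based formula; an
expression-based variant sits behind `risk_covariate="expression"` for
completeness, since prose descriptions of such scores sometimes name the
expression values instead). The median split sends scores equal to the
median to the low-risk group (deterministic tie rule); a model whose split
would leave a group empty, or whose scores are constant, is skipped.
Significance is the raw two-group log-rank p < 0.05 per model, with a
BH-adjusted column emitted alongside for transparency but not used for
flagging.

**Known limitation — selection optimism.** Fitting the Cox weights and then
log-rank-testing the median split of the resulting score *on the same data*
is anticonservative whenever a model has two or more probes: the weights are
chosen adaptively, so under a global null the false-flag rate rises well
above the nominal 5% (we measure ~30% at 2–3 covariates, n = 200). With a
single covariate the split is invariant to the coefficient's magnitude and
sign, and the rate is nominal (~2% over 240 null models). The validation
suite therefore measures null calibration on single-probe models; multi-probe
p-values should be read as descriptive rankings, not calibrated error rates.
A held-out or permutation-based calibration would fix this but is outside
the procedure being implemented.

## Synthetic-data generator

The generator emulates the *shape* of a TCGA lung-cancer study — two
conditions, optional two subtypes over a shared annotation universe — with
every planted signal recorded in a truth file.

* **Annotation.** Non-overlapping gene spans (default 2–10 kb) on synthetic
  chromosomes (default 2 × 1 Mb), round-robin assignment, uniform random
  gaps; a sizing error is raised when the requested genes cannot fit.
  Exactly `round(n_genes · fraction_lincRNA)` genes are lincRNAs; the rest
  draw a raw biotype from the other-lncRNA classes. Each gene hosts 2–4
  probes at uniform positions; intergenic probes (default 20) land outside
  every span and exercise the unmapped-probe paths.
* **Methylation.** Betas are Beta-distributed with concentration κ = 30
  (within-cohort SD ≈ 0.09 at mean 0.5 — typical for 450k within-tissue
  variation) around a per-probe baseline mean drawn from U(0.15, 0.85).
  Exactly `round(frac_dms · n_in_gene_probes)` in-gene probes are planted as
  DMSs: their cohort means differ by `dms_effect` (default 0.4) in a random
  recorded direction, with baselines placed so both means stay inside
  (0, 1) with a 0.05 margin (`dms_effect ≥ 0.9` is rejected). NAs are
  injected entrywise at `frac_probe_na` (default 2%), and
  `frac_all_na_probes` never-planted probes are fully NA in both cohorts.
* **Expression.** Each gene hosting a planted DMS is coupled to its first
  planted probe: log2 expression = b₀ + c·β + ε with condition-specific
  coupling c (default 4.0 normal, 0.0 tumor) and ε ~ N(0, 0.25); raw
  expression is 2^(level). This makes the population Pearson correlation
  per condition computable in closed form, r = cσ_β/√(c²σ_β² + σ_ε²) — with
  the defaults, r ≈ 0.76 in normal and 0 in tumor, i.e. a planted
  ΔPCC ≈ 0.76 against the 0.3 edge threshold. Uncoupled genes get
  independent N(0, 1) log2 variation. Dropout is modelled as left-censoring
  at a detection limit: exactly the lowest `frac_expression_zero` (default
  5%) of entries become zero — the missingness model the downstream
  replace-zeros-with-the-minimum rule inverts, so planted correlations
  survive preprocessing by construction. `frac_all_zero_genes` uncoupled
  genes are fully zero to exercise the expression filter.
* **Survival.** Exponential event times with log-hazard
  log λ₀ + Σ coefᵢ·(βᵢ − ½); the centring at ½ is absorbed into the free
  baseline (default λ₀ = 5·10⁻⁴/day, median ~1,400 days) and keeps the day
  scale realistic for any coefficient. Default planted coefficients
  (5.0, 5.0) on the first planted probes of two distinct genes give a
  high/low split-group hazard ratio around 2.5 — a strong prognostic
  effect, sized so the design power at n = 250 clears 90% despite 30%
  independent censoring (each patient censored with probability
  `censor_rate` at a uniform fraction of their event time). NA betas are
  imputed with the probe mean when computing hazards, so the truth is
  defined for every patient.
* **Randomness.** One `numpy` Generator per file kind (annotation, planting,
  methylation, expression, clinical), all spawned from the master seed:
  identical configs produce byte-identical files, and enlarging one file
  kind does not perturb the draws of another.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: Illumina type I/II probe chemistry, batch and
purity effects, copy-number confounding, correlated probe blocks within a
locus, count-based expression noise, and covariate-dependent censoring.
Recovery rates on synthetic data are upper bounds for real cohorts.

## Validation problem sizes

The Monte-Carlo validation experiments use: a 1,000-probe family at
n = 50/50 over 200 replicates for null FDR; 100 planted DMSs of 1,000
probes over 5 seeds for sensitivity; 12 seeds of a 40-gene study at
n = 100/100 (plus matched zero-coupling runs) for edge recovery; 20 seeds at
n = 250 tumors for Cox sign recovery and log-rank power; and 8 seeds of
40 single-probe models at n = 200 for null false-flag calibration. These
sizes put the binomial Monte-Carlo error comfortably inside the margins the
checks assert while keeping a full validation run around a minute.

## Numerical details

* BH q-values via statsmodels (`fdr_bh`); cross-checked against the step-up
  definition in the test suite.
* Pearson via `numpy.corrcoef` on complete pairs; cross-checked against the
  covariance formula at 1e−12.
* Cox: lifelines `CoxPHFitter` defaults (Efron ties, Newton iterations with
  lifelines' convergence tolerance); log-rank and Kaplan–Meier via
  lifelines, cross-checked against the observed/expected chi-square tables.
* Interval queries via `intervaltree` (half-open internally; +1 on the end
  converts the 1-based inclusive gene span), cross-checked against the
  brute-force double loop.
* TSV matrices use the `NA` literal and `%.6g` floats; all outputs are pure
  functions of inputs + config, so reruns are byte-identical.
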