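"""Seeded synthetic two-cohort methylation/expression studies with planted truth.

The generator emulates the shape of a TCGA-style lung-cancer dataset: a
GENCODE-dialect GTF of lncRNA loci on synthetic chromosomes, a 450k-style CpG
probe manifest, per-cohort beta-value and expression matrices, and a clinical
follow-up table — together with a truth file recording every planted signal,
so each downstream stage has a ground-truth test surface.

Planted signals:

* differentially methylated probes whose mean beta differs by ``dms_effect``
  between tumor and normal (direction randomised and recorded);
* condition-specific linear methylation→expression coupling in log2 space,
  giving each planted eQTM pair a computable population Pearson correlation
  per condition (and therefore a known ΔPCC);
* exponential survival whose log-hazard is a linear combination of planted
  probe betas, plus independent random censoring.

Null beta values are Beta-distributed (moderate concentration) so they live
on the [0, 1] support of 450k arrays.  One RNG stream per file kind, all
derived from the master seed: adding probes never perturbs expression draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio

_BETA_MARGIN = 0.05  # keep planted means this far inside (0, 1)
_OTHER_BIOTYPES = ("antisense", "sense_overlapping",
                   "transcribed_processed_pseudogene")
_UNCOUPLED_LOG2_SD = 1.0  # biological spread of uncoupled genes, log2 units
_MIN_GENE_GAP = 100  # bp between adjacent gene spans

#: geometry fields that must agree between the two subtypes of one study
ANNOTATION_FIELDS = ("n_genes", "fraction_lincRNA", "n_probes_per_gene",
                     "n_intergenic_probes", "n_chromosomes",
                     "chromosome_length", "gene_length")


@dataclass
class SimulationConfig:
    """All knobs of one synthetic subtype study.  Seeded and validated."""

    seed: int = 0
    n_tumor: int = 50
    n_normal: int = 50
    n_genes: int = 60
    fraction_lincRNA: float = 0.5
    n_probes_per_gene: tuple[int, int] = (2, 4)
    n_intergenic_probes: int = 20
    dms_effect: float = 0.4
    frac_dms: float = 0.3
    coupling_normal: float = 4.0
    coupling_tumor: float = 0.0
    noise_sd: float = 0.25
    beta_concentration: float = 30.0
    frac_expression_zero: float = 0.05
    frac_all_zero_genes: float = 0.05
    frac_probe_na: float = 0.02
    frac_all_na_probes: float = 0.02
    hazard_coefs: tuple[float, ...] = (5.0, 5.0)
    censor_rate: float = 0.3
    baseline_hazard: float = 5e-4
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    gene_length: tuple[int, int] = (2_000, 10_000)
    frac_shared_planted: float = 0.5
    sample_prefix: str = "S"

    def validate(self) -> None:
        fracs = ("fraction_lincRNA", "frac_dms", "frac_expression_zero",
                 "frac_all_zero_genes", "frac_probe_na", "frac_all_na_probes",
                 "censor_rate", "frac_shared_planted")
        for name in fracs:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        counts = ("n_tumor", "n_normal", "n_genes", "n_chromosomes",
                  "chromosome_length")
        for name in counts:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_intergenic_probes < 0:
            raise ValueError("n_intergenic_probes must be >= 0")
        lo, hi = self.n_probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("n_probes_per_gene must be an increasing "
                             "range of positive integers")
        if not 0 < self.dms_effect < 1 - 2 * _BETA_MARGIN:
            raise ValueError(
                f"dms_effect={self.dms_effect!r} pushes planted means outside "
                f"(0, 1) (must be in (0, {1 - 2 * _BETA_MARGIN}))")
        if self.noise_sd <= 0 or self.beta_concentration <= 0:
            raise ValueError("noise_sd and beta_concentration must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent RNG per file kind, derived from the master seed."""
        kinds = ("annotation", "plant", "methylation", "expression", "clinical")
        children = np.random.SeedSequence(self.seed).spawn(len(kinds))
        return {k: np.random.default_rng(s) for k, s in zip(kinds, children)}


@dataclass
class PlantedTruth:
    """Ground truth of every planted signal in a generated study."""

    dms: dict[str, dict] = field(default_factory=dict)
    eqtm_pairs: list[dict] = field(default_factory=list)
    prognostic_probes: dict[str, float] = field(default_factory=dict)

    @property
    def dms_probe_ids(self) -> set:
        return set(self.dms)

    def to_json(self, path: str | Path) -> None:
        payload = {"dms": self.dms, "eqtm_pairs": self.eqtm_pairs,
                   "prognostic_probes": self.prognostic_probes}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(dms=payload["dms"], eqtm_pairs=payload["eqtm_pairs"],
                   prognostic_probes=payload["prognostic_probes"])


# ---------------------------------------------------------------- annotation

def generate_annotation(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping lncRNA loci and CpG probes on synthetic chromosomes.

    Returns (genes, probes); ``probes`` carries a ``host_gene`` column (empty
    string for intergenic probes) used only by the generator itself — the
    written manifest omits it so the mapping stage must rediscover it.
    """
    config.validate()
    rng = rng or config.streams()["annotation"]

    n_linc = round(config.n_genes * config.fraction_lincRNA)
    is_linc = np.zeros(config.n_genes, dtype=bool)
    is_linc[rng.permutation(config.n_genes)[:n_linc]] = True

    gene_rows = []
    chrom_of = [f"chr{1 + (i % config.n_chromosomes)}"
                for i in range(config.n_genes)]
    for c in range(config.n_chromosomes):
        idx = [i for i in range(config.n_genes)
               if chrom_of[i] == f"chr{c + 1}"]
        if not idx:
            continue
        lengths = rng.integers(config.gene_length[0],
                               config.gene_length[1] + 1, size=len(idx))
        occupied = int(lengths.sum()) + (len(idx) + 1) * _MIN_GENE_GAP
        slack = config.chromosome_length - occupied
        if slack < 0:
            raise ValueError(
                f"chromosome chr{c + 1} too short ({config.chromosome_length} "
                f"bp) for {len(idx)} genes needing {occupied} bp")
        extra = np.floor(rng.dirichlet(np.ones(len(idx) + 1)) * slack).astype(int)
        pos = 1
        for k, i in enumerate(idx):
            pos += _MIN_GENE_GAP + int(extra[k])
            start, end = pos, pos + int(lengths[k]) - 1
            pos = end + 1
            gene_rows.append((
                f"SYNG{i + 1:06d}.1", f"LNC{i + 1}", chrom_of[i], start, end,
                "+" if rng.random() < 0.5 else "-",
                "lincRNA" if is_linc[i]
                else str(rng.choice(_OTHER_BIOTYPES)),
            ))
    genes = pd.DataFrame(gene_rows, columns=[
        "gene_id", "symbol", "chrom", "start", "end", "strand", "biotype_raw"])
    genes["biotype_class"] = np.where(genes["biotype_raw"] == "lincRNA",
                                      "lincRNA", "other_lncRNA")
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    probe_rows = []
    for g in genes.itertuples(index=False):
        n_p = int(rng.integers(config.n_probes_per_gene[0],
                               config.n_probes_per_gene[1] + 1))
        span = g.end - g.start + 1
        n_p = min(n_p, span)
        offsets = np.sort(rng.choice(span, size=n_p, replace=False))
        for off in offsets:
            probe_rows.append((g.chrom, g.start + int(off), g.gene_id))
    spans = {c: [(g.start, g.end) for g in genes.itertuples(index=False)
                 if g.chrom == c]
             for c in genes["chrom"].unique()}
    placed = 0
    attempts = 0
    while placed < config.n_intergenic_probes:
        attempts += 1
        if attempts > 1000 * max(config.n_intergenic_probes, 1):
            raise ValueError("cannot place intergenic probes: chromosomes "
                             "too densely covered by genes")
        chrom = f"chr{1 + int(rng.integers(config.n_chromosomes))}"
        pos = 1 + int(rng.integers(config.chromosome_length))
        if any(s <= pos <= e for s, e in spans.get(chrom, [])):
            continue
        probe_rows.append((chrom, pos, ""))
        placed += 1
    probes = pd.DataFrame(probe_rows, columns=["chrom", "pos", "host_gene"])
    probes = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    probes.insert(0, "probe_id", [f"cg{i + 1:08d}" for i in range(len(probes))])
    probes["strand"] = "+"
    return genes, probes


# --------------------------------------------------------------- methylation

def select_planted_dms(config: SimulationConfig, probes: pd.DataFrame,
                       rng: np.random.Generator,
                       forced_ids: list[str] | None = None) -> list[str]:
    """Pick exactly ``round(frac_dms * n_in_gene)`` in-gene probes as DMSs."""
    in_gene = probes.loc[probes["host_gene"] != "", "probe_id"].tolist()
    n_dms = round(config.frac_dms * len(in_gene))
    if forced_ids is not None:
        forced = [p for p in forced_ids if p in set(in_gene)]
        if len(forced) != len(forced_ids):
            raise ValueError("forced planted probes must be in-gene probes")
        pool = [p for p in in_gene if p not in set(forced)]
        extra = n_dms - len(forced)
        if extra < 0:
            raise ValueError("more forced probes than planted slots")
        chosen = forced + list(rng.choice(pool, size=extra, replace=False))
    else:
        chosen = list(rng.choice(in_gene, size=n_dms, replace=False))
    return sorted(chosen)


def generate_methylation(config: SimulationConfig, probes: pd.DataFrame,
                         truth: PlantedTruth,
                         rng: np.random.Generator | None = None,
                         plant_rng: np.random.Generator | None = None,
                         forced_dms_ids: list[str] | None = None,
                         sample_prefix: str | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cohort beta matrices with planted DMS probes and missingness.

    Null probes share one Beta-distributed mean across cohorts; planted
    probes differ by ``dms_effect`` in the mean (direction randomised and
    recorded in ``truth``).  ``frac_probe_na`` entries become NA and
    ``frac_all_na_probes`` probes (never planted ones) are fully NA in both
    cohorts.
    """
    config.validate()
    streams = config.streams()
    rng = rng or streams["methylation"]
    plant_rng = plant_rng or streams["plant"]
    prefix = sample_prefix if sample_prefix is not None else config.sample_prefix

    planted = select_planted_dms(config, probes, plant_rng, forced_dms_ids)
    planted_set = set(planted)
    n_probes = len(probes)
    kappa = config.beta_concentration

    mean_n = np.empty(n_probes)
    mean_t = np.empty(n_probes)
    host = probes.set_index("probe_id")["host_gene"]
    for i, pid in enumerate(probes["probe_id"]):
        if pid in planted_set:
            up = plant_rng.random() < 0.5
            lo, hi = _BETA_MARGIN, 1 - _BETA_MARGIN - config.dms_effect
            base = plant_rng.uniform(lo, hi)
            if up:
                mean_n[i], mean_t[i] = base, base + config.dms_effect
            else:
                mean_n[i], mean_t[i] = base + config.dms_effect, base
            truth.dms[pid] = {
                "delta": float(mean_t[i] - mean_n[i]),
                "direction": "up" if up else "down",
                "mean_tumor": float(mean_t[i]),
                "mean_normal": float(mean_n[i]),
                "gene_ids": [host[pid]] if host[pid] else [],
            }
        else:
            mean_n[i] = mean_t[i] = plant_rng.uniform(0.15, 0.85)

    def draw(means: np.ndarray, n: int) -> np.ndarray:
        a = means[:, None] * kappa
        b = (1 - means[:, None]) * kappa
        return np.clip(rng.beta(a, b, size=(n_probes, n)), 0.0, 1.0)

    tum = draw(mean_t, config.n_tumor)
    nor = draw(mean_n, config.n_normal)

    n_all_na = round(config.frac_all_na_probes * n_probes)
    null_ids = [p for p in probes["probe_id"] if p not in planted_set]
    if n_all_na > len(null_ids):
        raise ValueError("frac_all_na_probes leaves no room for planted probes")
    all_na = set(rng.choice(null_ids, size=n_all_na, replace=False))
    all_na_mask = probes["probe_id"].isin(all_na).to_numpy()
    tum[all_na_mask] = np.nan
    nor[all_na_mask] = np.nan
    if config.frac_probe_na > 0:
        tum[rng.random(tum.shape) < config.frac_probe_na] = np.nan
        nor[rng.random(nor.shape) < config.frac_probe_na] = np.nan

    t_cols = [f"{prefix}T{i + 1:03d}" for i in range(config.n_tumor)]
    n_cols = [f"{prefix}N{i + 1:03d}" for i in range(config.n_normal)]
    beta_t = pd.DataFrame(tum, index=probes["probe_id"].to_numpy(), columns=t_cols)
    beta_n = pd.DataFrame(nor, index=probes["probe_id"].to_numpy(), columns=n_cols)
    beta_t.index.name = beta_n.index.name = "probe_id"
    return beta_t, beta_n


# ---------------------------------------------------------------- expression

def _beta_sd(mean: float, kappa: float) -> float:
    return float(np.sqrt(mean * (1 - mean) / (kappa + 1)))


def _population_pcc(coupling: float, sd_beta: float, noise_sd: float) -> float:
    if coupling == 0:
        return 0.0
    num = coupling * sd_beta
    return float(num / np.hypot(num, noise_sd))


def generate_expression(config: SimulationConfig, genes: pd.DataFrame,
                        probes: pd.DataFrame,
                        beta_tumor: pd.DataFrame, beta_normal: pd.DataFrame,
                        truth: PlantedTruth,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cohort raw expression, coupling planted eQTM pairs to betas.

    Every gene hosting a planted DMS probe is coupled (in log2 space, then
    exponentiated to the raw scale) to its first such probe with the
    condition-specific coupling strength; the resulting population PCC per
    condition is recorded in ``truth``.  All-zero genes are drawn from the
    uncoupled genes; random zeros are injected everywhere.
    """
    config.validate()
    rng = rng or config.streams()["expression"]

    first_planted: dict[str, str] = {}
    for row in probes.itertuples(index=False):  # probes sorted by position
        if row.host_gene and row.probe_id in truth.dms \
                and row.host_gene not in first_planted:
            first_planted[row.host_gene] = row.probe_id

    uncoupled = [g for g in genes["gene_id"] if g not in first_planted]
    n_all_zero = round(config.frac_all_zero_genes * config.n_genes)
    if n_all_zero > len(uncoupled):
        raise ValueError("frac_all_zero_genes exceeds the uncoupled gene pool")
    all_zero = set(rng.choice(uncoupled, size=n_all_zero, replace=False))

    kappa = config.beta_concentration

    def impute(rowvals: pd.Series) -> np.ndarray:
        v = rowvals.to_numpy(dtype=float)
        if np.isnan(v).any():
            v = np.where(np.isnan(v), np.nanmean(v), v)
        return v

    out = {}
    for cond, beta, n, coupling in (
            ("tumor", beta_tumor, config.n_tumor, config.coupling_tumor),
            ("normal", beta_normal, config.n_normal, config.coupling_normal)):
        values = np.empty((config.n_genes, n))
        for i, g in enumerate(genes["gene_id"]):
            b0 = rng.uniform(3.0, 8.0)
            if g in first_planted:
                probe = first_planted[g]
                level = (b0 + coupling * impute(beta.loc[probe])
                         + rng.normal(0.0, config.noise_sd, size=n))
            else:
                level = b0 + rng.normal(0.0, _UNCOUPLED_LOG2_SD, size=n)
            values[i] = np.exp2(level)
        if config.frac_expression_zero > 0:
            # dropout as left-censoring at a detection limit: exactly the
            # lowest frac_expression_zero of entries become zero, which is
            # the missingness model the downstream replace-zeros-with-the-
            # minimum-positive-value rule inverts
            k = round(config.frac_expression_zero * values.size)
            if k > 0:
                limit = np.partition(values, k - 1, axis=None)[k - 1]
                values[values <= limit] = 0.0
        values[genes["gene_id"].isin(all_zero).to_numpy()] = 0.0
        out[cond] = pd.DataFrame(values, index=genes["gene_id"].to_numpy(),
                                 columns=beta.columns)
        out[cond].index.name = "gene_id"

    for gene, probe in sorted(first_planted.items()):
        rec = truth.dms[probe]
        m_t, m_n = rec["mean_tumor"], rec["mean_normal"]
        truth.eqtm_pairs.append({
            "probe_id": probe, "gene_id": gene,
            "pcc_tumor_target": _population_pcc(
                config.coupling_tumor, _beta_sd(m_t, kappa), config.noise_sd),
            "pcc_normal_target": _population_pcc(
                config.coupling_normal, _beta_sd(m_n, kappa), config.noise_sd),
        })
    return out["tumor"], out["normal"]


# ------------------------------------------------------------------ clinical

def generate_clinical(config: SimulationConfig, beta_tumor: pd.DataFrame,
                      truth: PlantedTruth,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw exponential survival with log-hazard linear in planted betas.

    ``hazard_coefs`` are assigned, in order, to the first planted eQTM probes
    of distinct genes (falling back to any planted DMS probes when there are
    no eQTM pairs).  NA betas are imputed with the probe mean for hazard
    computation.  Censoring: each patient is independently censored with
    probability ``censor_rate``, at a uniform fraction of their event time.
    """
    config.validate()
    rng = rng or config.streams()["clinical"]

    carriers: list[str] = []
    seen_genes: set[str] = set()
    for pair in truth.eqtm_pairs:
        if pair["gene_id"] not in seen_genes:
            carriers.append(pair["probe_id"])
            seen_genes.add(pair["gene_id"])
    if not carriers:
        carriers = sorted(truth.dms)
    carriers = carriers[:len(config.hazard_coefs)]
    coefs = dict(zip(carriers, config.hazard_coefs))
    truth.prognostic_probes = {p: float(c) for p, c in coefs.items()}

    n = beta_tumor.shape[1]
    xb = np.zeros(n)
    for probe, coef in coefs.items():
        v = beta_tumor.loc[probe].to_numpy(dtype=float)
        if np.isnan(v).any():
            v = np.where(np.isnan(v), np.nanmean(v), v)
        # betas centred at 1/2 so baseline_hazard keeps its day scale for
        # any coefficient magnitude (the constant is absorbed either way)
        xb += coef * (v - 0.5)
    lam = config.baseline_hazard * np.exp(xb)
    time = rng.exponential(1.0 / lam)
    censored = rng.random(n) < config.censor_rate
    time = np.where(censored, time * rng.uniform(0.01, 1.0, size=n), time)
    clinical = pd.DataFrame({
        "time": np.round(time, 2),
        "event": (~censored).astype(int),
    }, index=beta_tumor.columns)
    clinical.index.name = "sample_id"
    clinical["time"] = clinical["time"].clip(lower=0.01)
    return clinical


# --------------------------------------------------------------- file bundle

def _write_gtf(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##description: synthetic lncRNA annotation\n")
        for g in genes.itertuples(index=False):
            attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                     f'gene_type "{g.biotype_raw}";')
            fh.write(f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def generate_study(config: SimulationConfig, out_dir: str | Path,
                   label: str = "",
                   genes: pd.DataFrame | None = None,
                   probes: pd.DataFrame | None = None,
                   forced_dms_ids: list[str] | None = None) -> dict[str, Path]:
    """Generate one subtype bundle on disk; returns the path of every file.

    ``label`` prefixes all sample identifiers, so two labelled bundles have
    disjoint samples.  Pre-generated annotation tables can be supplied to
    share one annotation universe across subtypes.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = config.streams()

    if genes is None or probes is None:
        genes, probes = generate_annotation(config, streams["annotation"])
    truth = PlantedTruth()
    prefix = f"{label}_{config.sample_prefix}" if label else config.sample_prefix
    beta_t, beta_n = generate_methylation(
        config, probes, truth, rng=streams["methylation"],
        plant_rng=streams["plant"], forced_dms_ids=forced_dms_ids,
        sample_prefix=prefix)
    expr_t, expr_n = generate_expression(
        config, genes, probes, beta_t, beta_n, truth, rng=streams["expression"])
    clinical = generate_clinical(config, beta_t, truth, rng=streams["clinical"])

    paths = {
        "gtf": out / "annotation.gtf",
        "probes": out / "probes.tsv",
        "beta_tumor": out / "beta_tumor.tsv",
        "beta_normal": out / "beta_normal.tsv",
        "expr_tumor": out / "expr_tumor.tsv",
        "expr_normal": out / "expr_normal.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    _write_gtf(genes, paths["gtf"])
    lio.write_probe_manifest(probes[["probe_id", "chrom", "pos", "strand"]],
                             paths["probes"])
    lio.write_matrix(beta_t, paths["beta_tumor"])
    lio.write_matrix(beta_n, paths["beta_normal"])
    lio.write_matrix(expr_t, paths["expr_tumor"])
    lio.write_matrix(expr_n, paths["expr_normal"])
    lio.write_clinical(clinical, paths["clinical"])
    truth.to_json(paths["truth"])
    return paths


def generate_two_subtype_study(config_a: SimulationConfig,
                               config_b: SimulationConfig,
                               out_dir: str | Path,
                               labels: tuple[str, str] = ("A", "B")
                               ) -> dict[str, dict[str, Path]]:
    """Two subtype bundles sharing one annotation universe.

    The planted DMS sets of the two subtypes overlap by
    ``config_b.frac_shared_planted`` of subtype B's planted count, so the
    expected common/specific structure is known by design.  Sample
    identifiers are disjoint (label-prefixed).
    """
    for f in ANNOTATION_FIELDS:
        if getattr(config_a, f) != getattr(config_b, f):
            raise ValueError(f"annotation geometry field {f!r} differs "
                             "between subtype configs")
    config_a.validate()
    config_b.validate()

    genes, probes = generate_annotation(config_a)
    out = Path(out_dir)

    paths_a = generate_study(config_a, out / labels[0], label=labels[0],
                             genes=genes, probes=probes)
    truth_a = PlantedTruth.from_json(paths_a["truth"])
    planted_a = sorted(truth_a.dms_probe_ids)

    in_gene = probes.loc[probes["host_gene"] != "", "probe_id"].tolist()
    n_dms_b = round(config_b.frac_dms * len(in_gene))
    n_shared = min(round(config_b.frac_shared_planted * n_dms_b), len(planted_a))
    share_rng = np.random.default_rng(
        np.random.SeedSequence([config_b.seed, 1]))
    shared = list(share_rng.choice(planted_a, size=n_shared, replace=False))
    pool = [p for p in in_gene if p not in set(planted_a)]
    if n_dms_b - n_shared > len(pool):
        raise ValueError("not enough unplanted in-gene probes for a "
                         "disjoint subtype-B planted set")
    specific = list(share_rng.choice(pool, size=n_dms_b - n_shared,
                                     replace=False))
    paths_b = generate_study(config_b, out / labels[1], label=labels[1],
                             genes=genes, probes=probes,
                             forced_dms_ids=sorted(shared + specific))
    return {labels[0]: paths_a, labels[1]: paths_b}
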