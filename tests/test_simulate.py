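"""Synthetic-study generator: exact bookkeeping, determinism, planted truth."""

import filecmp
import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lnceqtm import io as lio
from lnceqtm.simulate import (PlantedTruth, SimulationConfig,
                              generate_annotation, generate_clinical,
                              generate_expression, generate_methylation,
                              generate_study, generate_two_subtype_study)


def _pieces(config):
    streams = config.streams()
    genes, probes = generate_annotation(config, streams["annotation"])
    truth = PlantedTruth()
    bt, bn = generate_methylation(config, probes, truth,
                                  rng=streams["methylation"],
                                  plant_rng=streams["plant"])
    return streams, genes, probes, truth, bt, bn


class TestAnnotation:
    def test_exact_lincRNA_fraction_and_probe_counts(self):
        cfg = SimulationConfig(seed=1, n_genes=10, fraction_lincRNA=0.5,
                               n_probes_per_gene=(3, 3), n_intergenic_probes=0)
        genes, probes = generate_annotation(cfg)
        assert len(genes) == 10
        assert (genes["biotype_class"] == "lincRNA").sum() == 5
        assert len(probes) == 30
        assert (probes["host_gene"] != "").all()

    def test_gene_spans_do_not_overlap_within_chromosome(self):
        cfg = SimulationConfig(seed=2, n_genes=40)
        genes, _ = generate_annotation(cfg)
        for _, sub in genes.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()

    def test_probes_fall_inside_host_spans(self):
        cfg = SimulationConfig(seed=3)
        genes, probes = generate_annotation(cfg)
        span = genes.set_index("gene_id")[["start", "end"]]
        hosted = probes[probes["host_gene"] != ""]
        starts = span.loc[hosted["host_gene"], "start"].to_numpy()
        ends = span.loc[hosted["host_gene"], "end"].to_numpy()
        assert ((hosted["pos"].to_numpy() >= starts)
                & (hosted["pos"].to_numpy() <= ends)).all()

    def test_chromosome_too_short_raises(self):
        cfg = SimulationConfig(seed=4, n_genes=50, chromosome_length=20_000)
        with pytest.raises(ValueError, match="too short"):
            generate_annotation(cfg)

    def test_same_seed_identical_annotation(self):
        cfg = SimulationConfig(seed=5)
        g1, p1 = generate_annotation(cfg)
        g2, p2 = generate_annotation(cfg)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(p1, p2)


class TestMethylation:
    def test_planted_effect_recovered_within_sampling_error(self):
        cfg = SimulationConfig(seed=6, n_tumor=50, n_normal=50)
        *_, truth, bt, bn = _pieces(cfg)
        kappa = cfg.beta_concentration
        for pid, rec in truth.dms.items():
            diff = np.nanmean(bt.loc[pid]) - np.nanmean(bn.loc[pid])
            # 3 * SE of a mean difference of Beta draws at n=50/50
            sd = np.sqrt(0.25 / (kappa + 1))
            assert abs(diff - rec["delta"]) < 3 * sd * np.sqrt(2 / 50)

    def test_exact_all_na_probe_count(self):
        cfg = SimulationConfig(seed=7, frac_all_na_probes=0.1)
        *_, bt, bn = _pieces(cfg)
        n_probes = len(bt)
        all_na = (bt.isna().all(axis=1) & bn.isna().all(axis=1)).sum()
        assert all_na == round(0.1 * n_probes)

    def test_values_in_unit_interval(self):
        cfg = SimulationConfig(seed=8)
        *_, bt, bn = _pieces(cfg)
        for m in (bt, bn):
            v = m.to_numpy()
            assert np.all((v[~np.isnan(v)] >= 0) & (v[~np.isnan(v)] <= 1))

    def test_null_probe_pvalues_uniform(self):
        """t-test p-values over null replicates follow U(0,1) (KS check)."""
        cfg = SimulationConfig(seed=9, n_genes=20, frac_dms=0.0,
                               frac_probe_na=0.0, frac_all_na_probes=0.0,
                               n_tumor=30, n_normal=30, n_intergenic_probes=0)
        from scipy import stats as ss
        pvals = []
        for seed in range(60):
            *_, bt, bn = _pieces(replace(cfg, seed=100 + seed))
            res = ss.ttest_ind(bt.to_numpy(), bn.to_numpy(), axis=1)
            pvals.extend(res.pvalue[:10])
        assert ss.kstest(pvals, "uniform").pvalue > 0.01

    def test_oversized_effect_rejected(self):
        with pytest.raises(ValueError, match="dms_effect"):
            SimulationConfig(dms_effect=0.95).validate()


class TestExpression:
    def test_exact_all_zero_gene_count(self):
        cfg = SimulationConfig(seed=10, frac_all_zero_genes=0.2, n_genes=10,
                               frac_dms=0.1)
        streams, genes, probes, truth, bt, bn = _pieces(cfg)
        et, en = generate_expression(cfg, genes, probes, bt, bn, truth,
                                     rng=streams["expression"])
        assert ((et == 0).all(axis=1) & (en == 0).all(axis=1)).sum() == 2

    def test_expression_non_negative_and_planted_targets_recorded(self):
        cfg = SimulationConfig(seed=11)
        streams, genes, probes, truth, bt, bn = _pieces(cfg)
        et, en = generate_expression(cfg, genes, probes, bt, bn, truth,
                                     rng=streams["expression"])
        assert (et.to_numpy() >= 0).all() and (en.to_numpy() >= 0).all()
        assert truth.eqtm_pairs
        for pair in truth.eqtm_pairs:
            assert pair["probe_id"] in truth.dms
            assert 0.4 < pair["pcc_normal_target"] < 1
            assert pair["pcc_tumor_target"] == 0.0


class TestClinical:
    def test_zero_censor_rate_all_events(self):
        cfg = SimulationConfig(seed=12, censor_rate=0.0)
        streams, genes, probes, truth, bt, bn = _pieces(cfg)
        clin = generate_clinical(cfg, bt, truth, rng=streams["clinical"])
        assert (clin["event"] == 1).all()
        assert (clin["time"] > 0).all()
        assert len(clin) == cfg.n_tumor

    def test_prognostic_probes_recorded_with_coefficients(self):
        cfg = SimulationConfig(seed=13, hazard_coefs=(5.0, -3.0))
        streams, genes, probes, truth, bt, bn = _pieces(cfg)
        generate_expression(cfg, genes, probes, bt, bn, truth,
                            rng=streams["expression"])
        generate_clinical(cfg, bt, truth, rng=streams["clinical"])
        assert sorted(truth.prognostic_probes.values()) == [-3.0, 5.0]
        assert set(truth.prognostic_probes) <= truth.dms_probe_ids


class TestStudyBundle:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=14, n_genes=20, n_tumor=15, n_normal=15)
        p1 = generate_study(cfg, tmp_path / "a")
        p2 = generate_study(cfg, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_truth_file_lists_exact_planted_count(self, small_bundle,
                                                  small_config):
        truth = json.loads(small_bundle["truth"].read_text())
        probes = lio.read_probe_manifest(small_bundle["probes"])
        genes_span = pd.read_csv(small_bundle["probes"], sep="\t")
        # in-gene probes = all probes minus the configured intergenic ones
        n_in_gene = len(probes) - small_config.n_intergenic_probes
        assert len(truth["dms"]) == round(small_config.frac_dms * n_in_gene)

    def test_two_subtype_bundles_share_annotation_disjoint_samples(self, tmp_path):
        a = SimulationConfig(seed=15, n_genes=20, n_tumor=12, n_normal=12)
        b = replace(a, seed=16)
        paths = generate_two_subtype_study(a, b, tmp_path, labels=("X", "Y"))
        assert paths["X"]["gtf"].read_text() == paths["Y"]["gtf"].read_text()
        sx = set(lio.read_matrix(paths["X"]["beta_tumor"]).columns)
        sy = set(lio.read_matrix(paths["Y"]["beta_tumor"]).columns)
        assert sx.isdisjoint(sy)

    def test_two_subtype_planted_overlap_matches_design(self, tmp_path):
        a = SimulationConfig(seed=17, n_genes=30, frac_shared_planted=0.5)
        b = replace(a, seed=18)
        paths = generate_two_subtype_study(a, b, tmp_path)
        ta = PlantedTruth.from_json(paths["A"]["truth"])
        tb = PlantedTruth.from_json(paths["B"]["truth"])
        n_b = len(tb.dms_probe_ids)
        expected_shared = min(round(0.5 * n_b), len(ta.dms_probe_ids))
        assert len(ta.dms_probe_ids & tb.dms_probe_ids) == expected_shared

    def test_mismatched_geometry_rejected(self, tmp_path):
        a = SimulationConfig(seed=19, n_genes=20)
        b = SimulationConfig(seed=20, n_genes=25)
        with pytest.raises(ValueError, match="geometry"):
            generate_two_subtype_study(a, b, tmp_path)
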