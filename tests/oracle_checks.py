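"""Independent brute-force oracles for the pipeline's core primitives.

Each check compares a package primitive against a from-first-principles
computation: interval mapping vs a double loop, BH q-values vs the step-up
definition, Pearson's r vs the covariance formula, and the log-rank p vs the
observed/expected chi-square tables.
"""

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lnceqtm.annotation import map_probes
from lnceqtm.network import pcc
from lnceqtm.survival import logrank_and_km


def check_mapping_vs_double_loop(seed=0):
    rng = np.random.default_rng(seed)
    genes = pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(30)],
        "symbol": [f"G{i}" for i in range(30)],
        "chrom": [f"chr{rng.integers(1, 3)}" for _ in range(30)],
        "start": (s := rng.integers(1, 3000, 30)),
        "end": s + rng.integers(0, 400, 30),
        "strand": "+", "biotype_raw": "lincRNA", "biotype_class": "lincRNA"})
    probes = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(150)],
        "chrom": [f"chr{rng.integers(1, 3)}" for _ in range(150)],
        "pos": rng.integers(1, 3500, 150)})
    got = set(zip(map_probes(probes, genes)["probe_id"],
                  map_probes(probes, genes)["gene_id"]))
    expected = {(p.probe_id, g.gene_id)
                for p in probes.itertuples()
                for g in genes.itertuples()
                if p.chrom == g.chrom and g.start <= p.pos <= g.end}
    assert got == expected


def check_bh_vs_step_up(seed=1):
    rng = np.random.default_rng(seed)
    p = rng.random(50)
    q = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p)
    q_hand, running = np.empty(50), 1.0
    for rank in range(50, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * 50 / rank)
        q_hand[i] = running
    np.testing.assert_allclose(q, q_hand, atol=1e-12)


def check_pcc_vs_covariance_formula(seed=2):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=25), rng.normal(size=25)
    r, _ = pcc(x, y)
    xd, yd = x - x.mean(), y - y.mean()
    assert abs(r - (xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd))) < 1e-12


def check_logrank_vs_observed_expected():
    times = np.array([2.0, 3, 5, 7, 11, 13, 17, 19])
    events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    labels = np.array(["high"] * 4 + ["low"] * 4)
    clin = pd.DataFrame({"time": times, "event": events},
                        index=pd.Index([f"P{i}" for i in range(8)],
                                       name="sample_id"))
    p, _ = logrank_and_km(pd.Series(labels, index=clin.index), clin)
    o1 = e1 = v = 0.0
    for t in sorted(set(times[events == 1])):
        risk = times >= t
        n, n1 = risk.sum(), (risk & (labels == "high")).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == "high")).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    p_hand = float(stats.chi2.sf((o1 - e1) ** 2 / v, df=1))
    assert abs(p - p_hand) < 1e-9


def run_all_oracles():
    check_mapping_vs_double_loop()
    check_bh_vs_step_up()
    check_pcc_vs_covariance_formula()
    check_logrank_vs_observed_expected()
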