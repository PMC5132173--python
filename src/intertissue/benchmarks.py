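"""Self-contained benchmark experiments on synthetic data.

Each function regenerates its inputs from a base seed, runs the relevant
pipeline stages, and returns summary numbers: recovery rates for planted
differential crosstalk and modules, agreement with brute-force oracles,
quantile-normalization exactness, and eQTL power/FDR calibration.  The
``scripts/acceptance.py`` entry point reports these; the test suite
asserts on them.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from . import connectivity as conn
from . import eqtl as eq
from . import network as net
from . import preprocess as pp
from . import synthetic as syn
from .synthetic import CrosstalkSpec, EqtlSpec, ModuleSpec, SimConfig

ADIPOSE_PAIRS = [("liver", "SAT"), ("liver", "VAT"), ("SAT", "VAT")]


def _adjusted_rand(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score
    return float(adjusted_rand_score(list(a), list(b)))


# ---------------------------------------------------------------------------
# Differential inter-tissue connectivity recovery
# ---------------------------------------------------------------------------

def differential_connectivity_recovery(base_seed: int = 0, n_seeds: int = 20,
                                       n_genes: int = 200, target_r: float = 0.6,
                                       n_perm: int = 99) -> dict:
    """Simulate the study design (4 tissues x n_genes x 60 individuals,
    28/32 groups) with two genes coupled across liver/SAT/VAT only in the
    unhealthy group, and measure how often (a) both planted genes occupy
    the top-2 score ranks and (b) both reach permutation p < 0.05."""
    top2 = 0
    perm_sig = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_genes, seed=base_seed + i,
            crosstalk_spec=[
                CrosstalkSpec("G0001", ADIPOSE_PAIRS, {"MUO": target_r}),
                CrosstalkSpec("G0002", ADIPOSE_PAIRS, {"MUO": target_r}),
            ])
        study, truth = syn.simulate_study(cfg)
        study = pp.align_individuals(study)
        records = conn.differential_connectivity_scores(study)
        top2 += {r.gene for r in records[:2]} == set(truth.crosstalk_genes)
        null = conn.score_permutation_null(study, n_perm=n_perm,
                                           seed=base_seed + i)
        pmap = dict(zip(null["gene"], null["empirical_p"]))
        perm_sig += all(pmap[g] < 0.05 for g in truth.crosstalk_genes)
    return {
        "top2_rate": top2 / n_seeds,
        "perm_significant_rate": perm_sig / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

def _tom_triple_loop(a: np.ndarray) -> np.ndarray:
    a = np.array(a, float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
                out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def _average_linkage_heights(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    clusters = {i: [i] for i in range(d.shape[0])}
    nxt = d.shape[0]
    heights = []
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                ca, cb = clusters[ids[ai]], clusters[ids[bi]]
                dist = np.mean([d[x, y] for x in ca for y in cb])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, ids[ai], ids[bi])
        heights.append(best[0])
        clusters[nxt] = clusters.pop(best[1]) + clusters.pop(best[2])
        nxt += 1
    return np.array(heights)


def _hwe_fraction_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hets = range(n_rare % 2, n_rare + 1, 2)
    probs = {}
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[h] = (Fraction(2) ** h
                    / (Fraction(factorial(h)) * factorial(rare_hom)
                       * factorial(common_hom)))
    total = sum(probs.values())
    obs = probs[n_ab] / total
    return float(sum(p / total for p in probs.values() if p / total <= obs))


def oracle_equivalence(base_seed: int = 0, n_tom: int = 30, tom_size: int = 50,
                       n_linkage: int = 20, n_hwe: int = 200) -> dict:
    """Max deviation of TOM, average-linkage heights, the HWE exact test
    and Pearson r from independent brute-force oracles."""
    rng = np.random.default_rng(base_seed)

    tom_dev = 0.0
    for _ in range(n_tom):
        a = rng.random((tom_size, tom_size))
        a = (a + a.T) / 2
        tom_dev = max(tom_dev, float(np.max(np.abs(
            net.tom_similarity(a) - _tom_triple_loop(a)))))

    link_dev = 0.0
    for _ in range(n_linkage):
        x = rng.normal(size=(20, 5))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        Z = net.hierarchical_cluster(d)
        link_dev = max(link_dev, float(np.max(np.abs(
            np.sort(Z[:, 2]) - np.sort(_average_linkage_heights(d))))))

    hwe_dev = 0.0
    for _ in range(n_hwe):
        n = int(rng.integers(1, 201))
        n_aa = int(rng.integers(0, n + 1))
        n_ab = int(rng.integers(0, n - n_aa + 1))
        n_bb = n - n_aa - n_ab
        hwe_dev = max(hwe_dev, abs(eq.hwe_exact_p(n_aa, n_ab, n_bb)
                                   - _hwe_fraction_oracle(n_aa, n_ab, n_bb)))

    pearson_dev = 0.0
    for _ in range(200):
        x, y = rng.normal(size=20), rng.normal(size=20)
        mx, my = x.mean(), y.mean()
        oracle = (((x - mx) * (y - my)).sum()
                  / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
        pearson_dev = max(pearson_dev, abs(conn.pearson_r(x, y) - oracle))

    return {"tom_max_abs_dev": tom_dev, "linkage_max_abs_dev": link_dev,
            "hwe_max_abs_dev": hwe_dev, "pearson_max_abs_dev": pearson_dev}


# ---------------------------------------------------------------------------
# Module recovery
# ---------------------------------------------------------------------------

def module_recovery(base_seed: int = 0, n_seeds: int = 20, n_genes: int = 200,
                    within_r: float = 0.7) -> dict:
    """Plant four within-tissue modules (sizes 60-80) among noise genes,
    run the network pipeline (beta=6 unsigned, TOM, average linkage,
    dynamic cut at min size 50) per the healthy group, and score recovery
    against the planted truth."""
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    config = net.NetworkConfig()
    aris = []
    mm_pass = mm_total = 0
    for i in range(n_seeds):
        cfg = SimConfig(n_genes=n_genes, seed=base_seed + i, module_spec=[
            ModuleSpec("liver", genes[0:60], within_r),
            ModuleSpec("muscle", genes[0:70], within_r),
            ModuleSpec("SAT", genes[0:80], within_r),
            ModuleSpec("VAT", genes[100:160], within_r),
        ])
        study, truth = syn.simulate_study(cfg)
        study = pp.align_individuals(study)
        corr = net.build_block_correlation(study, "MHO")
        dissim = net.tom_dissimilarity(net.soft_threshold(corr, config))
        partition = net.dynamic_tree_cut(net.hierarchical_cluster(dissim),
                                         corr.nodes, config)
        true_labels = [truth.module_assignment.get((n.gene, n.tissue), "grey")
                       for n in corr.nodes]
        aris.append(_adjusted_rand(true_labels, partition.labels))

        eigengenes, _ = net.group_eigengenes(study, partition, "MHO")
        membership = net.module_membership(study, partition, eigengenes, "MHO")
        for row, (label, true_label) in enumerate(zip(partition.labels,
                                                      true_labels)):
            if true_label == "grey":
                continue
            mm_total += 1
            if label != net.UNASSIGNED:
                value = membership.iloc[row][label]
                mm_pass += bool(np.isfinite(value) and value > 0.6)
    return {
        "ari_ge_080_rate": float(np.mean(np.asarray(aris) >= 0.8)),
        "mean_ari": float(np.mean(aris)),
        "planted_mm_above_060_rate": mm_pass / mm_total,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Quantile normalization exactness
# ---------------------------------------------------------------------------

def quantile_normalization_exactness(base_seed: int = 0, n_trials: int = 20) -> dict:
    """Fraction of random matrices for which every column's sorted values
    are bit-identical after normalization and renormalizing changes
    nothing."""
    rng = np.random.default_rng(base_seed)
    identical = idempotent = 0
    for _ in range(n_trials):
        m = rng.normal(size=(50, 8)) * 2 + 8
        out = pp.quantile_normalize(m)
        ref = np.sort(out[:, 0])
        identical += all(np.array_equal(np.sort(out[:, j]), ref)
                         for j in range(out.shape[1]))
        idempotent += np.array_equal(pp.quantile_normalize(out), out)
    return {"sorted_columns_identical_rate": identical / n_trials,
            "idempotent_rate": idempotent / n_trials}


# ---------------------------------------------------------------------------
# eQTL power and FDR calibration
# ---------------------------------------------------------------------------

def _eqtl_run(seed: int, planted: bool) -> pd.DataFrame:
    spec = [EqtlSpec("rs_planted", "G0005", "liver", 1.0, 0.3)] if planted else []
    cfg = SimConfig(n_genes=50, seed=seed, eqtl_spec=spec,
                    background_snps_per_probe=2)
    study, _ = syn.simulate_study(cfg)
    geno = study.genotypes
    qc = eq.snp_qc(geno)
    passing = {r.snp_id for r in qc if r.passed}
    keep = geno.snps["id"].isin(passing).to_numpy()
    geno = eq.GenotypeMatrix(snps=geno.snps[keep].reset_index(drop=True),
                             individuals=geno.individuals,
                             dosages=geno.dosages[keep])
    pairs = eq.cis_pairs(geno.snps[["id", "chrom", "pos"]],
                         study.probe_positions)
    expr = study.tissues["liver"]
    records = eq.map_cis(geno, expr, pairs)
    records = eq.permutation_fdr(records, geno, expr, pairs, n_perm=10,
                                 seed=seed)
    return eq.eqtl_table(records).dropna(subset=["fdr"])


def eqtl_power_and_fdr(base_seed: int = 0, n_reps: int = 20) -> dict:
    """Power for a planted 1-SD cis effect (MAF 0.3, n=60, 1 Mb window,
    Spearman, 10 permutations) and the per-probe false-positive rate at
    FDR < 0.05 under a global null."""
    hits = 0
    for i in range(n_reps):
        table = _eqtl_run(base_seed + i, planted=True)
        planted = table[table["probe"] == "G0005"]
        hits += bool(len(planted) and (planted["fdr"] < 0.05).iloc[0])
    null_props = []
    for i in range(n_reps):
        table = _eqtl_run(base_seed + 10_000 + i, planted=False)
        null_props.append(float((table["fdr"] < 0.05).mean()) if len(table) else 0.0)
    return {"planted_fdr_power": hits / n_reps,
            "null_fdr_positive_rate": float(np.mean(null_props)),
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Structural contracts
# ---------------------------------------------------------------------------

def structural_contracts(base_seed: int = 0, n_genes: int = 40) -> dict:
    """Exactness checks on the block matrix (symmetry, unit diagonal,
    block indexing), group-swap invariance of scores, and node-order
    invariance of the partition."""
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    cfg = SimConfig(n_genes=n_genes, seed=base_seed, module_spec=[
        ModuleSpec("liver", genes[:25], 0.8)])
    study, _ = syn.simulate_study(cfg)
    study = pp.align_individuals(study)

    corr = net.build_block_correlation(study, "MHO")
    dim_ok = corr.values.shape == (4 * n_genes, 4 * n_genes)
    sym_dev = float(np.max(np.abs(corr.values - corr.values.T)))
    diag_dev = float(np.max(np.abs(np.diag(corr.values) - 1.0)))
    block_ok = True
    for (ta, tb), (ra, rb) in corr.block_index.items():
        tissues_in_rows = {corr.nodes[i].tissue for i in range(ra.start, ra.stop)}
        tissues_in_cols = {corr.nodes[i].tissue for i in range(rb.start, rb.stop)}
        block_ok &= tissues_in_rows == {ta} and tissues_in_cols == {tb}

    fwd = conn.differential_connectivity_scores(study, ("MHO", "MUO"))
    rev = conn.differential_connectivity_scores(study, ("MUO", "MHO"))
    swap_dev = float(max(abs(a.score - b.score) for a, b in zip(fwd, rev)))

    config = net.NetworkConfig(min_module_size=20)
    dissim = net.tom_dissimilarity(net.soft_threshold(corr, config))
    part = net.dynamic_tree_cut(net.hierarchical_cluster(dissim), corr.nodes,
                                config)
    rng = np.random.default_rng(base_seed)
    perm = rng.permutation(len(corr.nodes))
    part2 = net.dynamic_tree_cut(
        net.hierarchical_cluster(dissim[np.ix_(perm, perm)]),
        [corr.nodes[i] for i in perm], config)
    lab2 = dict(zip(part2.nodes, part2.labels))
    node_order_ari = _adjusted_rand(part.labels, [lab2[n] for n in part.nodes])

    return {
        "block_matrix_dimension_ok": float(dim_ok),
        "symmetry_max_abs_dev": sym_dev,
        "unit_diagonal_max_abs_dev": diag_dev,
        "block_indexing_ok": float(block_ok),
        "group_swap_max_abs_dev": swap_dev,
        "node_order_ari": node_order_ari,
    }
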