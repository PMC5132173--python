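import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import intertissue as it
from intertissue.network import (MODULE_COLORS, UNASSIGNED, NetworkConfig,
                                 dendrogram_to_newick, module_covariate_association,
                                 pick_power, _scale_free_fit)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def tom_triple_loop(a):
    """Literal triple-loop TOM oracle."""
    a = np.array(a, float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def average_linkage_oracle(d):
    """Brute-force average linkage: merge the closest pair of clusters,
    distance = mean pairwise leaf distance; lowest-index pair on ties."""
    d = np.asarray(d, float)
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
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
        dist, ia, ib = best
        heights.append(dist)
        clusters[next_id] = clusters.pop(ia) + clusters.pop(ib)
        next_id += 1
    return np.array(heights)


def power_iteration_first_pc(z, iters=4000, seed=0):
    """First right-singular vector of z by power iteration on z.T z."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=z.shape[1])
    m = z.T @ z
    for _ in range(iters):
        v = m @ v
        v /= np.linalg.norm(v)
    return v


# ---------------------------------------------------------------------------
# Block correlation matrix
# ---------------------------------------------------------------------------

class TestBlockCorrelation:
    def make_two_tissue_study(self, duplicate=False, seed=0, n=30, genes=3):
        rng = np.random.default_rng(seed)
        inds = [f"S{i}" for i in range(2 * n)]
        a = rng.normal(size=(genes, 2 * n))
        b = a.copy() if duplicate else rng.normal(size=(genes, 2 * n))
        tissues = {
            "liver": it.TissueExpression("liver", [f"g{k}" for k in range(genes)], inds, a),
            "SAT": it.TissueExpression("SAT", [f"g{k}" for k in range(genes)], inds, b),
        }
        pheno = pd.DataFrame({"group": ["A"] * n + ["B"] * n},
                             index=pd.Index(inds, name="individual_id"))
        return it.MultiTissueStudy(tissues=tissues, phenotypes=pheno)

    def test_structure_two_tissues_three_genes(self):
        study = self.make_two_tissue_study()
        corr = it.build_block_correlation(study, "A")
        assert corr.values.shape == (6, 6)
        np.testing.assert_array_equal(corr.values, corr.values.T)
        np.testing.assert_array_equal(np.diag(corr.values), np.ones(6))
        off = corr.block("liver", "SAT")
        np.testing.assert_allclose(off, corr.block("SAT", "liver").T)
        assert [n.tissue for n in corr.nodes] == ["liver"] * 3 + ["SAT"] * 3

    def test_duplicated_tissue_gives_identical_blocks(self):
        study = self.make_two_tissue_study(duplicate=True)
        corr = it.build_block_correlation(study, "A")
        np.testing.assert_allclose(corr.block("liver", "SAT"),
                                   corr.block("liver", "liver"), atol=1e-12)

    def test_null_offdiagonal_mean_abs_r(self):
        # E|r| under the null ~ sqrt(2/pi)/sqrt(n-1)
        vals = []
        for seed in range(15):
            study = self.make_two_tissue_study(seed=seed, genes=40)
            corr = it.build_block_correlation(study, "A")
            vals.append(np.abs(corr.block("liver", "SAT")).mean())
        expected = np.sqrt(2 / np.pi) / np.sqrt(30 - 1)
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)

    def test_insufficient_individuals_names_block(self):
        study = self.make_two_tissue_study(n=4)
        with pytest.raises(ValueError, match=r"block \(liver"):
            it.build_block_correlation(study, "A", min_shared=10)


class TestBlockBalance:
    def test_same_distribution_not_flagged(self, study_factory):
        flags = 0
        for seed in range(10):
            study, _ = study_factory(n_genes=25, seed=seed + 50)
            corr = it.build_block_correlation(study, "MHO")
            flags += it.block_balance_check(corr).flagged
        assert flags <= 1

    def test_strong_within_blocks_flagged(self, module_study):
        study, _ = module_study
        corr = it.build_block_correlation(study, "MHO")
        assert it.block_balance_check(corr).flagged


# ---------------------------------------------------------------------------
# Soft threshold / scale-free fit
# ---------------------------------------------------------------------------

class TestSoftThreshold:
    def test_arithmetic_examples(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert it.soft_threshold(r, NetworkConfig(beta=6))[0, 1] == pytest.approx(0.015625)
        r[0, 1] = r[1, 0] = -0.5
        assert it.soft_threshold(r, NetworkConfig(beta=6))[0, 1] == pytest.approx(0.015625)
        signed = it.soft_threshold(r, NetworkConfig(beta=6, signed=True))
        assert signed[0, 1] == pytest.approx(0.000244140625)

    def test_beta_one_unsigned_is_abs_correlation(self):
        rng = np.random.default_rng(1)
        r = np.corrcoef(rng.normal(size=(5, 30)))
        a = it.soft_threshold(r, NetworkConfig(beta=1))
        expected = np.abs(r)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(a, expected)

    def test_diagonal_zeroed(self):
        r = np.eye(3)
        assert it.soft_threshold(r, NetworkConfig()).diagonal().sum() == 0


class TestPickPower:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(0)
        r = np.corrcoef(rng.normal(size=(30, 20)))
        beta, fit = pick_power(r, candidate_betas=[6])
        assert beta == 6 and len(fit) == 1

    def test_scale_free_connectivity_reaches_high_r2(self):
        # Pareto-distributed connectivity (exponent 2.5), the classic
        # scale-free signature
        rng = np.random.default_rng(2)
        k = (1 - rng.random(2000)) ** (-1.0 / 1.5)
        r2, slope = _scale_free_fit(k[k < 1e4], n_bins=10)
        assert r2 > 0.8 and slope < 0

    def test_pure_noise_falls_back_to_default(self, caplog):
        rng = np.random.default_rng(3)
        r = np.corrcoef(rng.normal(size=(60, 25)))
        beta, fit = pick_power(r, candidate_betas=[2, 4], default_beta=6,
                               r2_target=0.98)
        assert beta == 6


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

class TestTOM:
    def test_complete_triangle(self):
        a = np.ones((3, 3))
        tom = it.tom_similarity(a)
        np.testing.assert_allclose(tom, np.ones((3, 3)))
        np.testing.assert_allclose(it.tom_dissimilarity(a), np.zeros((3, 3)), atol=1e-12)

    def test_three_node_chain(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        tom = it.tom_similarity(a)
        assert tom[0, 2] == pytest.approx(0.5)

    def test_zero_adjacency(self):
        a = np.zeros((4, 4))
        tom = it.tom_similarity(a)
        assert tom.sum() == pytest.approx(4.0)  # identity diagonal only
        d = it.tom_dissimilarity(a)
        assert np.all(d[~np.eye(4, dtype=bool)] == 1.0)

    def test_out_of_range_entries_error(self):
        with pytest.raises(ValueError):
            it.tom_similarity(np.array([[0, 1.5], [1.5, 0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((30, 30))
        a = (a + a.T) / 2
        tom = it.tom_similarity(a)
        np.testing.assert_allclose(tom, tom_triple_loop(a), atol=1e-10)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Clustering and dynamic cut
# ---------------------------------------------------------------------------

class TestHierarchicalCluster:
    def test_two_separated_blocks_merge_last_at_one(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        Z = it.hierarchical_cluster(d)
        assert Z[-1, 2] == pytest.approx(1.0)
        assert np.all(np.diff(Z[:, 2]) >= 0)

    def test_equidistant_points_merge_lowest_indices_first(self):
        d = np.ones((3, 3))
        np.fill_diagonal(d, 0)
        Z = it.hierarchical_cluster(d)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_asymmetric_input_errors(self):
        d = np.zeros((3, 3))
        d[0, 1] = 0.5
        with pytest.raises(ValueError):
            it.hierarchical_cluster(d)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, 5))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        Z = it.hierarchical_cluster(d)
        np.testing.assert_allclose(np.sort(Z[:, 2]),
                                   np.sort(average_linkage_oracle(d)), atol=1e-10)


def planted_two_block_dissim(seed, block=60, noise=0, within=0.05, between=1.0):
    rng = np.random.default_rng(seed)
    n = 2 * block + noise
    d = np.full((n, n), between)
    d[:block, :block] = within
    d[block:2 * block, block:2 * block] = within
    d += rng.uniform(0, 0.01, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d


class TestDynamicTreeCut:
    def test_two_planted_blocks_recovered(self):
        d = planted_two_block_dissim(0)
        Z = it.hierarchical_cluster(d)
        nodes = [it.GeneTissueNode(f"g{i}", "liver") for i in range(d.shape[0])]
        part = it.dynamic_tree_cut(Z, nodes, NetworkConfig(min_module_size=50))
        sizes = sorted(len(part.members(m)) for m in part.modules)
        assert sizes == [60, 60]
        assert part.modules[0] == "turquoise"

    def test_small_block_stays_grey(self):
        d = planted_two_block_dissim(1, block=30)
        Z = it.hierarchical_cluster(d)
        nodes = [it.GeneTissueNode(f"g{i}", "liver") for i in range(d.shape[0])]
        part = it.dynamic_tree_cut(Z, nodes, NetworkConfig(min_module_size=50))
        assert part.modules == []
        assert set(part.labels) == {UNASSIGNED}

    def test_min_size_above_leaf_count_all_grey(self):
        d = planted_two_block_dissim(2, block=10)
        Z = it.hierarchical_cluster(d)
        nodes = [it.GeneTissueNode(f"g{i}", "liver") for i in range(d.shape[0])]
        part = it.dynamic_tree_cut(Z, nodes, NetworkConfig(min_module_size=50))
        assert set(part.labels) == {UNASSIGNED}

    def test_partition_invariant_to_node_order(self, module_study):
        study, _ = module_study
        corr = it.build_block_correlation(study, "MHO")
        dis = it.tom_dissimilarity(it.soft_threshold(corr, NetworkConfig()))
        Z = it.hierarchical_cluster(dis)
        part = it.dynamic_tree_cut(Z, corr.nodes, NetworkConfig())

        rng = np.random.default_rng(0)
        perm = rng.permutation(len(corr.nodes))
        dis2 = dis[np.ix_(perm, perm)]
        nodes2 = [corr.nodes[i] for i in perm]
        part2 = it.dynamic_tree_cut(it.hierarchical_cluster(dis2), nodes2,
                                    NetworkConfig())
        lab2 = dict(zip(part2.nodes, part2.labels))
        reordered = [lab2[n] for n in part.nodes]
        assert adjusted_rand_score(part.labels, reordered) == pytest.approx(1.0)

    def test_color_naming_by_descending_size(self):
        d = planted_two_block_dissim(3, block=60, noise=0)
        # enlarge first block to 70 by shrinking... simpler: blocks 60/60 with
        # extra 10 nodes appended to block one
        rng = np.random.default_rng(4)
        extra = np.full((10, d.shape[0]), 1.0) + rng.uniform(0, 0.01, (10, d.shape[0]))
        extra[:, :60] = 0.05
        d2 = np.vstack([np.hstack([d, extra.T[: d.shape[0]]]),
                        np.hstack([extra, np.full((10, 10), 0.05)])])
        d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        nodes = [it.GeneTissueNode(f"g{i}", "liver") for i in range(d2.shape[0])]
        part = it.dynamic_tree_cut(it.hierarchical_cluster(d2), nodes,
                                   NetworkConfig(min_module_size=50))
        sizes = {m: len(part.members(m)) for m in part.modules}
        assert sizes["turquoise"] == 70 and sizes["blue"] == 60


class TestNewickExport:
    def test_round_trips_through_dendropy(self):
        import dendropy
        d = planted_two_block_dissim(5, block=5)
        Z = it.hierarchical_cluster(d)
        names = [f"leaf{i}" for i in range(10)]
        nwk = dendrogram_to_newick(Z, names)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(names)


# ---------------------------------------------------------------------------
# Eigengenes and membership
# ---------------------------------------------------------------------------

class TestModuleEigengene:
    def test_identical_profiles(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=25)
        x = np.tile(profile, (4, 1))
        eig, varex = it.module_eigengene(x)
        assert varex == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig / np.linalg.norm(eig),
                                   z / np.linalg.norm(z), atol=1e-10)

    def test_antipodal_members(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        eig, varex = it.module_eigengene(np.vstack([x, -x]))
        assert varex == pytest.approx(1.0)
        # orientation contract: correlation with the first member nonnegative
        assert np.corrcoef(eig, x)[0, 1] > 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_power_iteration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(12, 30))
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        eig, _ = it.module_eigengene(x)
        oracle = power_iteration_first_pc(z, seed=seed)
        sign = np.sign(np.dot(eig, oracle))
        np.testing.assert_allclose(eig, sign * oracle, atol=1e-8)

    def test_too_few_individuals_errors(self):
        with pytest.raises(ValueError):
            it.module_eigengene(np.ones((3, 2)))


class TestModuleMembership:
    def test_planted_members_have_high_own_module_mm(self, module_study):
        study, truth = module_study
        corr = it.build_block_correlation(study, "MHO")
        dis = it.tom_dissimilarity(it.soft_threshold(corr, NetworkConfig()))
        part = it.dynamic_tree_cut(it.hierarchical_cluster(dis), corr.nodes,
                                   NetworkConfig())
        eig, varex = it.group_eigengenes(study, part, "MHO")
        mm = it.module_membership(study, part, eig, "MHO")
        tl = [truth.module_assignment.get((n.gene, n.tissue), "grey")
              for n in corr.nodes]
        own = [mm.iloc[i][lab] for i, (lab, t) in enumerate(zip(part.labels, tl))
               if lab != UNASSIGNED and t != "grey"]
        assert np.mean(np.asarray(own) > 0.6) > 0.9

    def test_unrelated_node_mm_near_zero(self, module_study):
        study, truth = module_study
        corr = it.build_block_correlation(study, "MHO")
        dis = it.tom_dissimilarity(it.soft_threshold(corr, NetworkConfig()))
        part = it.dynamic_tree_cut(it.hierarchical_cluster(dis), corr.nodes,
                                   NetworkConfig())
        eig, _ = it.group_eigengenes(study, part, "MHO")
        mm = it.module_membership(study, part, eig, "MHO")
        grey_mm = mm.loc[[l == UNASSIGNED for l in part.labels], part.modules[0]]
        assert np.nanmean(np.abs(grey_mm)) < 0.25


class TestCovariateAssociation:
    def test_self_covariate_perfect(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=40)
        eig = pd.DataFrame({"turquoise": e}, index=[f"S{i}" for i in range(40)])
        cov = pd.DataFrame({"age": e}, index=eig.index)
        out = module_covariate_association(eig, cov)
        assert out.r.iloc[0] == pytest.approx(1.0)
        assert out.p.iloc[0] < 1e-20

    def test_planted_age_tracking_detected(self):
        # power at r=0.5, n=60 exceeds 80% at alpha=0.05 (Fisher-z power)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            age = rng.normal(45, 10, size=60)
            e = 0.5 * (age - age.mean()) / age.std() + np.sqrt(0.75) * rng.normal(size=60)
            eig = pd.DataFrame({"m": e}, index=[f"S{i}" for i in range(60)])
            cov = pd.DataFrame({"age": age}, index=eig.index)
            hits += module_covariate_association(eig, cov).p.iloc[0] < 0.05
        assert hits >= 16

    def test_constant_covariate_flagged(self):
        eig = pd.DataFrame({"m": np.arange(10.0)}, index=[f"S{i}" for i in range(10)])
        cov = pd.DataFrame({"sexcode": np.ones(10)}, index=eig.index)
        out = module_covariate_association(eig, cov)
        assert out.flag.iloc[0] == "constant"
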