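"""Weighted inter-tissue co-expression networks.

Nodes are (gene, tissue) pairs.  Per phenotype group, a block correlation
matrix is assembled in tissue-major order: diagonal blocks hold
within-tissue gene-gene correlations, off-diagonal blocks the
inter-tissue correlations of every gene in one tissue with every gene in
another, over matched individuals.  Soft thresholding turns correlations
into adjacencies, the topological overlap measure (TOM) into a
clustering dissimilarity, and a dynamic height cut of the average-linkage
dendrogram yields modules (named by the WGCNA color convention).  Module
eigengenes, module membership (kME) and covariate checks follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .preprocess import MultiTissueStudy

log = logging.getLogger("intertissue")

#: WGCNA module color sequence, assigned by descending module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
UNASSIGNED = "grey"


@dataclass(frozen=True, order=True)
class GeneTissueNode:
    gene: str
    tissue: str

    def __str__(self) -> str:  # node id used in exports
        return f"{self.gene}@{self.tissue}"


@dataclass
class NetworkConfig:
    """Parameters of network construction and module detection.

    ``beta`` is the soft-threshold exponent; the unsigned network
    a_ij = |r_ij|^beta groups strong positive and negative correlations
    together.  ``cut_height_fraction`` sets the adaptive dendrogram cut
    at that fraction of the maximum merge height (the Dynamic Tree Cut
    convention): branches that only join the rest of the tree above the
    cut become module candidates, while leaves first merging above it
    stay unassigned.
    """

    beta: int = 6
    signed: bool = False
    min_module_size: int = 50
    linkage_method: str = "average"
    cut_height_fraction: float = 0.95
    absorb_height_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class BlockCorrelationMatrix:
    """(T*G) x (T*G) symmetric correlation matrix with block metadata."""

    nodes: list[GeneTissueNode]
    values: np.ndarray
    block_index: dict[tuple[str, str], tuple[slice, slice]]
    group: str = ""

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for node in self.nodes:
            if node.tissue not in seen:
                seen.append(node.tissue)
        return seen

    def block(self, tissue_a: str, tissue_b: str) -> np.ndarray:
        key = (tissue_a, tissue_b) if (tissue_a, tissue_b) in self.block_index \
            else (tissue_b, tissue_a)
        rows, cols = self.block_index[key]
        sub = self.values[rows, cols]
        return sub if key == (tissue_a, tissue_b) else sub.T


@dataclass
class ModulePartition:
    nodes: list[GeneTissueNode]
    labels: list[str]

    @property
    def assignments(self) -> dict[GeneTissueNode, str]:
        return dict(zip(self.nodes, self.labels))

    @property
    def modules(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab != UNASSIGNED and lab not in seen:
                seen.append(lab)
        sizes = {m: sum(1 for l in self.labels if l == m) for m in seen}
        rank = {m: (MODULE_COLORS.index(m) if m in MODULE_COLORS else len(MODULE_COLORS))
                for m in seen}
        return sorted(seen, key=lambda m: (-sizes[m], rank[m], m))

    def members(self, module: str) -> list[GeneTissueNode]:
        return [n for n, l in zip(self.nodes, self.labels) if l == module]


# ---------------------------------------------------------------------------
# Node matrix and block correlation
# ---------------------------------------------------------------------------

def node_matrix(study: MultiTissueStudy, group: str
                ) -> tuple[list[GeneTissueNode], list[str], np.ndarray]:
    """Stack all tissues' expression of one group into a nodes x
    individuals matrix in tissue-major node order."""
    members = set(study.individuals_in_group(group))
    first = next(iter(study.tissues.values()))
    cols = [k for k, ind in enumerate(first.individuals) if ind in members]
    individuals = [first.individuals[k] for k in cols]
    nodes: list[GeneTissueNode] = []
    blocks = []
    for tissue, te in study.tissues.items():
        if te.individuals != first.individuals:
            raise ValueError("study must be aligned (identical column order) "
                             "before network construction")
        nodes.extend(GeneTissueNode(g, tissue) for g in te.genes)
        blocks.append(te.values[:, cols])
    return nodes, individuals, np.vstack(blocks)


def _corr_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs correlation between rows of a and rows of b over the
    columns finite in both matrices (column-complete convention)."""
    ok = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    a, b = a[:, ok], b[:, ok]
    da = a - a.mean(axis=1, keepdims=True)
    db = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((da * da).sum(axis=1))
    sb = np.sqrt((db * db).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (da @ db.T) / np.outer(sa, sb)
    return np.clip(r, -1.0, 1.0)


def build_block_correlation(study: MultiTissueStudy, group: str,
                            min_shared: int = 10) -> BlockCorrelationMatrix:
    """Assemble the block correlation matrix of one group in tissue-major
    node order; each block uses the individuals complete in both of its
    tissues."""
    nodes, _, _ = node_matrix(study, group)
    members = set(study.individuals_in_group(group))
    first = next(iter(study.tissues.values()))
    cols = [k for k, ind in enumerate(first.individuals) if ind in members]

    tissues = study.tissue_names
    mats = {t: study.tissues[t].values[:, cols] for t in tissues}
    sizes = {t: len(study.tissues[t].genes) for t in tissues}
    offsets = {}
    off = 0
    for t in tissues:
        offsets[t] = off
        off += sizes[t]
    total = off

    values = np.empty((total, total))
    block_index: dict[tuple[str, str], tuple[slice, slice]] = {}
    for i, ta in enumerate(tissues):
        for tb in tissues[i:]:
            ok = (np.isfinite(mats[ta]).all(axis=0)
                  & np.isfinite(mats[tb]).all(axis=0))
            if ok.sum() < min_shared:
                raise ValueError(
                    f"block ({ta}, {tb}) in group {group!r} has only "
                    f"{int(ok.sum())} complete individuals (minimum {min_shared})"
                )
            sub = _corr_cross(mats[ta], mats[tb])
            ra = slice(offsets[ta], offsets[ta] + sizes[ta])
            rb = slice(offsets[tb], offsets[tb] + sizes[tb])
            values[ra, rb] = sub
            values[rb, ra] = sub.T
            block_index[(ta, tb)] = (ra, rb)
    values = (values + values.T) / 2.0  # exact symmetry
    np.fill_diagonal(values, 1.0)
    return BlockCorrelationMatrix(nodes=nodes, values=values,
                                  block_index=block_index, group=group)


# ---------------------------------------------------------------------------
# Block balance diagnostic
# ---------------------------------------------------------------------------

@dataclass
class BlockBalanceResult:
    table: pd.DataFrame
    t_statistic: float
    p_value: float
    flagged: bool
    note: str = ""


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def block_balance_check(corr: BlockCorrelationMatrix,
                        alpha: float = 0.05) -> BlockBalanceResult:
    """Mean/SD per block plus a Welch t-test (on Fisher-z entries) of
    within-tissue vs inter-tissue correlation strength."""
    rows = []
    within, inter = [], []
    for (ta, tb), (ra, rb) in corr.block_index.items():
        sub = corr.values[ra, rb]
        if ta == tb:
            entries = sub[np.triu_indices_from(sub, k=1)]
            within.append(entries)
        else:
            entries = sub.ravel()
            inter.append(entries)
        rows.append({
            "block": f"{ta}|{tb}", "kind": "within" if ta == tb else "inter",
            "mean_r": float(np.nanmean(entries)), "sd_r": float(np.nanstd(entries, ddof=1)),
            "n_entries": int(entries.size),
        })
    table = pd.DataFrame(rows)
    if not inter:
        return BlockBalanceResult(table, float("nan"), float("nan"), False,
                                  note="not applicable: single tissue")
    zw = _fisher_z(np.concatenate(within))
    zi = _fisher_z(np.concatenate(inter))
    t, p = stats.ttest_ind(zw, zi, equal_var=False)
    flagged = bool(p < alpha)
    if flagged:
        log.warning("block_balance_check: within vs inter imbalance (p=%.3g)", p)
    return BlockBalanceResult(table, float(t), float(p), flagged)


# ---------------------------------------------------------------------------
# Soft thresholding and scale-free fit
# ---------------------------------------------------------------------------

def soft_threshold(corr: BlockCorrelationMatrix | np.ndarray,
                   config: NetworkConfig | None = None) -> np.ndarray:
    """Adjacency from correlation: |r|^beta (unsigned) or
    ((1+r)/2)^beta (signed).  The returned diagonal is 0 — the
    convention used by both the connectivity sums and the TOM formula,
    whose neighbour sums exclude the node itself."""
    config = config or NetworkConfig()
    r = corr.values if isinstance(corr, BlockCorrelationMatrix) else np.asarray(corr, float)
    if config.signed:
        a = ((1.0 + r) / 2.0) ** config.beta
    else:
        a = np.abs(r) ** config.beta
    np.fill_diagonal(a, 0.0)
    return a


def pick_power(corr: BlockCorrelationMatrix | np.ndarray,
               candidate_betas: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12),
               signed: bool = False, r2_target: float = 0.8,
               default_beta: int = 6, n_bins: int = 10) -> tuple[int, pd.DataFrame]:
    """Scale-free topology criterion: per candidate beta, the R^2 of
    log10(frequency) vs log10(mean connectivity) over connectivity bins;
    returns the smallest beta reaching ``r2_target`` (with a decreasing
    fit), else ``default_beta`` with a warning."""
    if len(candidate_betas) < 1:
        raise ValueError("need at least one candidate beta")
    rows = []
    chosen = None
    for beta in candidate_betas:
        a = soft_threshold(corr, NetworkConfig(beta=beta, signed=signed,
                                               min_module_size=2))
        k = a.sum(axis=0)
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append({"beta": beta, "scale_free_r2": r2, "slope": slope,
                     "mean_k": float(k.mean())})
        if chosen is None and np.isfinite(r2) and r2 >= r2_target and slope < 0:
            chosen = beta
    fit = pd.DataFrame(rows)
    if chosen is None:
        log.warning("pick_power: no candidate reached scale-free R^2 >= %.2f; "
                    "using default beta=%d", r2_target, default_beta)
        chosen = default_beta
    return chosen, fit


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return float("nan"), float("nan")
    edges = np.geomspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    means = np.array([k[which == b].mean() if freq[b] else np.nan
                      for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(means) & (means > 0)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    res = stats.linregress(np.log10(means[ok]), np.log10(freq[ok]))
    return float(res.rvalue ** 2), float(res.slope)


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned TOM: (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj (u != i,j) and k_i the connectivity; the
    diagonal is 1 by convention."""
    a = np.asarray(adjacency, dtype=float).copy()
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    """1 - TOM, with zero diagonal — the clustering dissimilarity."""
    d = 1.0 - tom_similarity(adjacency)
    np.fill_diagonal(d, 0.0)
    # guard tiny negative round-off so squareform stays valid
    return np.clip((d + d.T) / 2.0, 0.0, None)


# ---------------------------------------------------------------------------
# Clustering and module detection
# ---------------------------------------------------------------------------

def hierarchical_cluster(dissim: np.ndarray, method: str = "average") -> np.ndarray:
    """Average-linkage agglomeration of a symmetric zero-diagonal
    dissimilarity; returns the scipy linkage matrix.  Ties merge in
    nearest-neighbour-chain order, which for equidistant points joins the
    lowest-index pair first."""
    d = np.asarray(dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    condensed = squareform(d, checks=False)
    return hierarchy.linkage(condensed, method=method)


def dynamic_tree_cut(linkage: np.ndarray, nodes: list[GeneTissueNode],
                     config: NetworkConfig | None = None) -> ModulePartition:
    """Dendrogram-only dynamic branch cut.

    Two adaptive height thresholds (fractions of the maximum merge
    height) drive the cut.  A module *core* is a minimal branch with at
    least ``min_module_size`` leaves whose top merge lies below
    ``cut_height_fraction * max_height``.  Each core then absorbs the
    stragglers of its branch: any subtree that joins a single core's
    branch below ``absorb_height_fraction * max_height`` (without
    containing another core) is assigned to that core's module.  Leaves
    outside every such branch — in noise data, everything — stay grey.
    Modules are named by descending size with the WGCNA colors."""
    config = config or NetworkConfig()
    n = len(nodes)
    if n != linkage.shape[0] + 1:
        raise ValueError("node list does not match dendrogram size")
    if config.min_module_size > n:
        log.warning("min_module_size %d exceeds leaf count %d: all grey",
                    config.min_module_size, n)
        return ModulePartition(nodes=list(nodes), labels=[UNASSIGNED] * n)

    heights = linkage[:, 2]
    max_h = float(heights.max())
    h_core = config.cut_height_fraction * max_h
    h_absorb = max(config.absorb_height_fraction * max_h, h_core)

    # per internal node (id n+i): children, height, leaf count
    n_internal = linkage.shape[0]
    size = np.ones(n + n_internal, dtype=int)
    size[n:] = linkage[:, 3].astype(int)

    # candidate: big enough and joined below h_core; core: minimal candidate
    has_candidate_below = np.zeros(n + n_internal, dtype=bool)
    core_of: dict[int, int] = {}     # internal node id -> core index
    cores: list[int] = []
    for i in range(n_internal):
        node = n + i
        left, right = int(linkage[i, 0]), int(linkage[i, 1])
        below = has_candidate_below[left] or has_candidate_below[right]
        candidate = size[node] >= config.min_module_size and heights[i] <= h_core
        if candidate and not below:
            core_of[node] = len(cores)
            cores.append(node)
        has_candidate_below[node] = candidate or below

    # propagate the set of cores contained in every subtree
    core_count = np.zeros(n + n_internal, dtype=int)
    single_core = np.full(n + n_internal, -1, dtype=int)
    for i in range(n_internal):
        node = n + i
        left, right = int(linkage[i, 0]), int(linkage[i, 1])
        count = core_count[left] + core_count[right] + (node in core_of)
        core_count[node] = count
        if node in core_of:
            single_core[node] = core_of[node]
        elif count == 1:
            single_core[node] = max(single_core[left], single_core[right])

    # assign leaves: highest ancestor with exactly one core and height
    # below the absorption limit claims its whole subtree
    labels_idx = np.full(n, -1, dtype=int)
    stack: list[tuple[int, int]] = []
    for i in range(n_internal - 1, -1, -1):
        node = n + i
        if core_count[node] == 1 and heights[i] <= h_absorb:
            stack.append((node, single_core[node]))
    claimed = np.zeros(n + n_internal, dtype=bool)
    while stack:
        node, core = stack.pop()
        if claimed[node]:
            continue
        claimed[node] = True
        if node < n:
            labels_idx[node] = core
        else:
            i = node - n
            stack.append((int(linkage[i, 0]), core))
            stack.append((int(linkage[i, 1]), core))

    # name modules by descending size, ties by smallest leaf index
    module_sizes = {c: int((labels_idx == c).sum()) for c in range(len(cores))}
    order = sorted(module_sizes,
                   key=lambda c: (-module_sizes[c], int(np.argmax(labels_idx == c))))
    names = {c: (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                 else f"module_{rank + 1}")
             for rank, c in enumerate(order)}
    labels = [names[c] if c >= 0 else UNASSIGNED for c in labels_idx]
    return ModulePartition(nodes=list(nodes), labels=labels)


def dendrogram_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Newick string with branch lengths = parent height - child height."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# Eigengenes, module membership, covariates
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant member profile: cannot standardize")
    return (x - mu) / sd


def module_eigengene(member_values: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular vector of the row-standardized member x
    individual matrix, sign-aligned so its correlation with the mean
    member profile is nonnegative (falling back to the first member when
    the mean profile vanishes).  Also returns the proportion of variance
    explained."""
    x = np.asarray(member_values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("module needs at least 2 member profiles")
    if x.shape[1] < 3:
        raise ValueError("module eigengene needs at least 3 individuals")
    z = _standardize_rows(x)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    reference = z.mean(axis=0)
    if np.allclose(reference, 0.0):
        reference = z[0]
    if np.dot(eig, reference) < 0:
        eig = -eig
    return eig, var_explained


def group_eigengenes(study: MultiTissueStudy, partition: ModulePartition,
                     group: str) -> tuple[pd.DataFrame, dict[str, float]]:
    """Eigengene per module over one group's individuals.

    Returns a (individuals x modules) DataFrame and the per-module
    variance explained."""
    nodes, individuals, matrix = node_matrix(study, group)
    index = {n: i for i, n in enumerate(nodes)}
    eigs = {}
    varex = {}
    for module in partition.modules:
        rows = [index[n] for n in partition.members(module) if n in index]
        sub = matrix[rows, :]
        ok = np.isfinite(sub).all(axis=0)
        eig = np.full(len(individuals), np.nan)
        eig[ok], varex[module] = module_eigengene(sub[:, ok])
        eigs[module] = eig
    return pd.DataFrame(eigs, index=individuals), varex


def module_membership(study: MultiTissueStudy, partition: ModulePartition,
                      eigengenes: pd.DataFrame, group: str) -> pd.DataFrame:
    """kME table: correlation of every node's expression with every
    module eigengene over the same group's individuals.  Constant nodes
    get NaN."""
    nodes, individuals, matrix = node_matrix(study, group)
    if list(eigengenes.index) != individuals:
        raise ValueError("eigengenes were computed on different individuals")
    out = {}
    for module in eigengenes.columns:
        e = eigengenes[module].to_numpy()
        col = np.full(len(nodes), np.nan)
        ok_e = np.isfinite(e)
        for i in range(len(nodes)):
            x = matrix[i, :]
            ok = ok_e & np.isfinite(x)
            if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(e[ok]) > 0:
                col[i] = np.corrcoef(x[ok], e[ok])[0, 1]
        out[module] = col
    mm = pd.DataFrame(out, index=[str(n) for n in nodes])
    mm.insert(0, "module", partition.labels)
    mm.insert(0, "tissue", [n.tissue for n in nodes])
    mm.insert(0, "gene", [n.gene for n in nodes])
    return mm


def module_covariate_association(eigengenes: pd.DataFrame,
                                 covariates: pd.DataFrame) -> pd.DataFrame:
    """Correlation of each eigengene with each covariate (Pearson for
    numeric, point-biserial via 0/1 coding for binary) plus two-sided p."""
    cov = covariates.loc[eigengenes.index]
    rows = []
    for module in eigengenes.columns:
        e = eigengenes[module].to_numpy(dtype=float)
        for name in cov.columns:
            c = cov[name]
            if not pd.api.types.is_numeric_dtype(c):
                levels = sorted(c.dropna().unique())
                if len(levels) != 2:
                    rows.append({"module": module, "covariate": name,
                                 "r": np.nan, "p": np.nan, "flag": "non-binary"})
                    continue
                c = (c == levels[1]).astype(float)
            x = c.to_numpy(dtype=float)
            ok = np.isfinite(e) & np.isfinite(x)
            flag = ""
            if ok.sum() < 4 or np.ptp(x[ok]) == 0 or np.ptp(e[ok]) == 0:
                r, p, flag = np.nan, np.nan, "constant"
            else:
                r, p = stats.pearsonr(e[ok], x[ok])
            rows.append({"module": module, "covariate": name,
                         "r": float(r) if np.isfinite(r) else np.nan,
                         "p": float(p) if np.isfinite(p) else np.nan,
                         "flag": flag})
    return pd.DataFrame(rows)
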