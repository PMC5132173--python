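"""Per-gene inter-tissue correlation and differential connectivity.

For each gene measured in several tissues of the same individuals, the
expression profiles across tissue pairs are correlated separately within
each phenotype group.  The differential inter-tissue connectivity score
of a gene is the sum over tissue pairs of |r_groupA - r_groupB|; genes
whose cross-tissue coupling differs between groups (the IL1B/IL-6
pattern) rise to the top of this ranking.  A label-permutation null
provides an empirical p-value per gene.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MultiTissueStudy

log = logging.getLogger("intertissue")

DEFAULT_MIN_PAIR_N = 10


@dataclass
class TissuePairCorrelation:
    gene: str
    tissue_pair: tuple[str, str]
    group: str
    r: float
    n: int
    p: float


@dataclass
class DifferentialConnectivityRecord:
    gene: str
    pair_differences: dict[tuple[str, str], float]
    score: float
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)
    empirical_p: float | None = None


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN (flagged missing, never 0)
    when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors of size >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(dx @ dx)
    sy = np.sqrt(dy @ dy)
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.clip((dx @ dy) / (sx * sy), -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p from t = r * sqrt((n-2)/(1-r^2)) on n-2 df."""
    if n < 4:
        raise ValueError("correlation_pvalue requires n >= 4")
    if not np.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


# ---------------------------------------------------------------------------
# Per-gene inter-tissue correlations
# ---------------------------------------------------------------------------

def tissue_pairs(study: MultiTissueStudy) -> list[tuple[str, str]]:
    return list(itertools.combinations(study.tissue_names, 2))


def gene_intertissue_correlations(
    study: MultiTissueStudy, gene: str, group: str,
    min_pair_n: int = DEFAULT_MIN_PAIR_N,
) -> list[TissuePairCorrelation]:
    """One record per unordered tissue pair in which the gene is measured,
    over that group's pairwise-complete individuals."""
    present = [t for t, te in study.tissues.items() if gene in te.gene_index]
    if len(present) < 2:
        log.warning("gene %s present in <2 tissues; no inter-tissue correlations", gene)
        return []
    members = set(study.individuals_in_group(group))
    out = []
    for ta, tb in itertools.combinations(present, 2):
        tea, teb = study.tissues[ta], study.tissues[tb]
        cols = [k for k, ind in enumerate(tea.individuals) if ind in members]
        # alignment guarantees identical column ordering across tissues
        xa = tea.values[tea.gene_index[gene], cols]
        xb = teb.values[teb.gene_index[gene], cols]
        xa, xb = _pairwise_complete(xa, xb)
        if xa.size < min_pair_n:
            log.warning("gene %s pair (%s,%s) group %s: only %d complete individuals",
                        gene, ta, tb, group, xa.size)
        r = pearson_r(xa, xb) if xa.size >= 3 else float("nan")
        p = correlation_pvalue(r, xa.size) if xa.size >= 4 else float("nan")
        out.append(TissuePairCorrelation(gene, (ta, tb), group, r, int(xa.size), p))
    return out


# ---------------------------------------------------------------------------
# Vectorized per-gene cross-tissue correlation over all genes
# ---------------------------------------------------------------------------

def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation of matching rows of two genes x individuals matrices,
    pairwise-complete over columns.  NaN for rows that are constant or
    have < 3 complete columns."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.all():
        n = a.shape[1]
        da = a - a.mean(axis=1, keepdims=True)
        db = b - b.mean(axis=1, keepdims=True)
        sa = np.sqrt((da * da).sum(axis=1))
        sb = np.sqrt((db * db).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (da * db).sum(axis=1) / (sa * sb)
        r[(sa == 0) | (sb == 0)] = np.nan
        return np.clip(r, -1.0, 1.0)
    out = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        xa, xb = a[i, ok[i]], b[i, ok[i]]
        if xa.size >= 3:
            out[i] = pearson_r(xa, xb)
    return out


def _group_pair_correlations(
    study: MultiTissueStudy, genes: list[str], group_members: set[str],
) -> dict[tuple[str, str], np.ndarray]:
    """For every tissue pair: vector of per-gene cross-tissue r."""
    mats = {}
    for t, te in study.tissues.items():
        cols = [k for k, ind in enumerate(te.individuals) if ind in group_members]
        idx = [te.gene_index[g] for g in genes]
        mats[t] = te.values[np.ix_(idx, cols)]
    return {
        (ta, tb): _rowwise_corr(mats[ta], mats[tb])
        for ta, tb in itertools.combinations(study.tissue_names, 2)
    }


def _common_genes(study: MultiTissueStudy) -> list[str]:
    names = study.tissue_names
    common = set(study.tissues[names[0]].genes)
    for t in names[1:]:
        common &= set(study.tissues[t].genes)
    return [g for g in study.tissues[names[0]].genes if g in common]


def differential_connectivity_scores(
    study: MultiTissueStudy, groups: tuple[str, str] | None = None,
) -> list[DifferentialConnectivityRecord]:
    """Per gene: |r_A - r_B| per tissue pair and their sum, sorted by the
    sum descending.  Pairs where either group's r is undefined are
    excluded from the sum and flagged."""
    if groups is None:
        groups = tuple(study.group_labels)
    ga, gb = groups
    genes = _common_genes(study)
    ra = _group_pair_correlations(study, genes, set(study.individuals_in_group(ga)))
    rb = _group_pair_correlations(study, genes, set(study.individuals_in_group(gb)))

    records = []
    pairs = list(ra)
    for i, gene in enumerate(genes):
        diffs: dict[tuple[str, str], float] = {}
        flagged = []
        for pair in pairs:
            d = abs(ra[pair][i] - rb[pair][i])
            if np.isfinite(d):
                diffs[pair] = float(d)
            else:
                flagged.append(pair)
        records.append(DifferentialConnectivityRecord(
            gene=gene, pair_differences=diffs,
            score=float(sum(diffs.values())), flagged_pairs=flagged,
        ))
    records.sort(key=lambda rec: (-rec.score, rec.gene))
    return records


def _scores_for_membership(study: MultiTissueStudy, genes: list[str],
                           members_a: set[str], members_b: set[str]) -> np.ndarray:
    ra = _group_pair_correlations(study, genes, members_a)
    rb = _group_pair_correlations(study, genes, members_b)
    diffs = np.stack([np.abs(ra[p] - rb[p]) for p in ra])
    return np.nansum(diffs, axis=0)


def score_permutation_null(
    study: MultiTissueStudy, n_perm: int = 99, seed: int = 0,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Empirical per-gene p for the differential connectivity score.

    Group labels are permuted over the matched individual set; empirical
    p = (1 + #{permuted score >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if groups is None:
        groups = tuple(study.group_labels)
    ga, gb = groups
    genes = _common_genes(study)
    members_a = study.individuals_in_group(ga)
    members_b = study.individuals_in_group(gb)
    pool = np.array(members_a + members_b)
    na = len(members_a)

    observed = _scores_for_membership(study, genes, set(members_a), set(members_b))

    alpha_resolution = 1.0 / (n_perm + 1)
    if alpha_resolution > 0.05:
        log.warning("n_perm=%d gives minimum attainable p=%.3f", n_perm, alpha_resolution)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(genes))
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        s = _scores_for_membership(study, genes, set(perm[:na]), set(perm[na:]))
        exceed += s >= observed
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame({"gene": genes, "score": observed, "empirical_p": pvals})


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------

#: Significance stars at the thresholds used for the per-gene tables.
STAR_THRESHOLDS = [(0.001, "***"), (0.05, "**"), (0.1, "*")]


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def scores_table(study: MultiTissueStudy,
                 records: list[DifferentialConnectivityRecord],
                 groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Wide per-gene table: each group's r per tissue pair, |dr|, score."""
    if groups is None:
        groups = tuple(study.group_labels)
    ga, gb = groups
    genes = [rec.gene for rec in records]
    ra = _group_pair_correlations(study, genes, set(study.individuals_in_group(ga)))
    rb = _group_pair_correlations(study, genes, set(study.individuals_in_group(gb)))
    data: dict[str, object] = {"gene": genes}
    for pair in ra:
        tag = f"{pair[0]}-{pair[1]}"
        data[f"r_{ga}_{tag}"] = ra[pair]
        data[f"r_{gb}_{tag}"] = rb[pair]
        data[f"absdiff_{tag}"] = np.abs(ra[pair] - rb[pair])
    data["score"] = [rec.score for rec in records]
    if records and records[0].empirical_p is not None:
        data["empirical_p"] = [rec.empirical_p for rec in records]
    return pd.DataFrame(data)


def correlation_table(study: MultiTissueStudy, gene: str,
                      groups: list[str] | None = None) -> pd.DataFrame:
    """Per-gene tissue-pair correlation table with significance stars
    (the Tables 2/3 layout)."""
    if groups is None:
        groups = study.group_labels
    rows: dict[tuple[str, str], dict[str, str]] = {}
    for group in groups:
        for rec in gene_intertissue_correlations(study, gene, group):
            cell = rows.setdefault(rec.tissue_pair, {})
            cell[group] = (f"{rec.r:.2f}{significance_stars(rec.p)}"
                           if np.isfinite(rec.r) else "NA")
    out = pd.DataFrame.from_dict(rows, orient="index", columns=groups)
    out.index = [f"{a}—{b}" for a, b in out.index]
    out.index.name = "tissues"
    return out
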