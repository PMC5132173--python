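"""Expression preprocessing for matched multi-tissue studies.

Raw per-tissue expression matrices (genes x samples) are quantile
normalized and log2 transformed, filtered to a gene list of interest
(here: insulin-related genes supplied as a plain-text file), and aligned
so that every tissue's columns follow one canonical individual ordering.
A Table-1-style cohort summary contrasts the two phenotype groups
(metabolically healthy vs unhealthy obese, MHO/MUO) on every phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("intertissue")

#: Minimum shared individuals required per tissue pair within a group.
DEFAULT_MIN_SHARED = 10


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TissueExpression:
    """Expression of one tissue: genes x individuals, log2 scale.

    ``values`` rows follow ``genes``, columns follow ``individuals``.
    Missing individuals (not sampled in this tissue) appear as NaN columns
    only after :func:`align_individuals`; before alignment the matrix is
    dense over the tissue's own individuals.
    """

    tissue: str
    genes: list[str]
    individuals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene IDs in tissue {self.tissue!r}")
        if self.values.shape != (len(self.genes), len(self.individuals)):
            raise ValueError(
                f"tissue {self.tissue!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.individuals)} individuals"
            )

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.individuals)


@dataclass
class MultiTissueStudy:
    """Matched per-tissue expression plus the phenotype table.

    ``phenotypes`` is indexed by individual ID and carries at least the
    group column (two labels, e.g. MHO/MUO), sex and age. ``genotypes``
    and the position annotations are optional and only needed for the
    eQTL stage.
    """

    tissues: dict[str, TissueExpression]
    phenotypes: pd.DataFrame
    group_column: str = "group"
    genotypes: "object | None" = None          # eqtl.GenotypeMatrix
    probe_positions: pd.DataFrame | None = None  # columns: probe, chrom, pos

    def __post_init__(self) -> None:
        pheno_ids = set(self.phenotypes.index)
        for te in self.tissues.values():
            missing = set(te.individuals) - pheno_ids
            if missing:
                raise ValueError(
                    f"tissue {te.tissue!r} individuals missing from phenotype "
                    f"table: {sorted(missing)[:5]}"
                )
        groups = self.group_labels
        if len(groups) != 2:
            raise ValueError(f"expected exactly two group labels, got {groups}")

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.phenotypes[self.group_column].unique().tolist())

    def individuals_in_group(self, group: str) -> list[str]:
        mask = self.phenotypes[self.group_column] == group
        return list(self.phenotypes.index[mask])

    @property
    def tissue_names(self) -> list[str]:
        return list(self.tissues)


# ---------------------------------------------------------------------------
# TSV / text readers & writers (the fixture dialect)
# ---------------------------------------------------------------------------

def write_expression_tsv(expr: TissueExpression, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path, tissue: str) -> TissueExpression:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return TissueExpression(
        tissue=tissue,
        genes=[str(g) for g in df.index],
        individuals=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs an 'individual_id' column")
    return df.set_index("individual_id")


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="individual_id")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a genes x samples matrix.

    Every column is mapped onto the common reference distribution formed
    by the row-wise means of the column-sorted matrix, so that afterwards
    all columns share the same multiset of values.  Ties within a column
    receive the mean of the reference values at their tied ranks.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"non-finite value at row {r}, column {c}")

    order = np.argsort(values, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(values, order, axis=0)
    reference = np.mean(sorted_cols, axis=1)
    # exact idempotence: a rank whose values already agree across columns
    # keeps that value bit-identically
    constant = sorted_cols.min(axis=1) == sorted_cols.max(axis=1)
    reference[constant] = sorted_cols[constant, 0]

    out = np.empty_like(values)
    n = values.shape[0]
    ranks = np.empty(n, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        idx = order[:, j]
        # assign reference by sorted position, then average within tie groups
        ranks[idx] = reference
        colsorted = col[idx]
        boundaries = np.flatnonzero(np.diff(colsorted)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        colout = np.empty(n)
        for s, e in zip(starts, ends):
            colout[s:e] = reference[s:e].mean()
        out[idx, j] = colout
    return out


def log2_transform(values: np.ndarray, offset: float = 1.0) -> np.ndarray:
    """Elementwise log2(value + offset); every argument must be positive."""
    values = np.asarray(values, dtype=float)
    shifted = values + offset
    if np.any(shifted <= 0):
        raise ValueError("log2_transform: value + offset must be positive everywhere")
    return np.log2(shifted)


def normalize_study(study: MultiTissueStudy, log_offset: float = 1.0,
                    already_log: bool = True) -> MultiTissueStudy:
    """Quantile-normalize each tissue; optionally log2-transform first.

    Synthetic fixtures are generated on the log2 scale, so the default
    skips the log step and only equalizes sample distributions.
    """
    tissues = {}
    for name, te in study.tissues.items():
        vals = te.values if already_log else log2_transform(te.values, log_offset)
        tissues[name] = replace(te, values=quantile_normalize(vals))
    return replace(study, tissues=tissues)


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

def filter_genes(expr: TissueExpression, gene_list: Iterable[str]) -> TissueExpression:
    """Restrict to genes in ``gene_list``, preserving matrix row order.

    Returns the filtered expression; the count retained and the list genes
    absent from the matrix are logged.  An empty intersection is an error.
    """
    wanted = set(gene_list)
    keep = [i for i, g in enumerate(expr.genes) if g in wanted]
    if not keep:
        raise ValueError(
            f"tissue {expr.tissue!r}: no overlap between matrix genes and gene list"
        )
    absent = sorted(wanted - set(expr.genes))
    log.info(
        "filter_genes[%s]: retained %d/%d genes; %d list genes absent from matrix",
        expr.tissue, len(keep), len(expr.genes), len(absent),
    )
    if absent:
        log.debug("filter_genes[%s]: absent genes: %s", expr.tissue, absent)
    return replace(
        expr,
        genes=[expr.genes[i] for i in keep],
        values=expr.values[keep, :],
    )


def filter_study(study: MultiTissueStudy, gene_list: Iterable[str]) -> MultiTissueStudy:
    gene_list = list(gene_list)
    return replace(
        study,
        tissues={t: filter_genes(te, gene_list) for t, te in study.tissues.items()},
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_individuals(study: MultiTissueStudy,
                      min_shared: int = DEFAULT_MIN_SHARED) -> MultiTissueStudy:
    """Reorder every tissue's columns onto one canonical individual ordering.

    The canonical ordering is the phenotype-table order restricted to
    individuals seen in at least one tissue.  Individuals missing from a
    tissue become NaN columns, so downstream tissue-pair operations can use
    pairwise-complete individuals.  Errors if any tissue pair shares fewer
    than ``min_shared`` individuals within either group.
    """
    if len(study.tissues) < 2:
        raise ValueError("need at least 2 tissues to align")
    seen: set[str] = set()
    for te in study.tissues.values():
        seen.update(te.individuals)
    canonical = [i for i in study.phenotypes.index if i in seen]

    tissues = {}
    for name, te in study.tissues.items():
        pos = {ind: k for k, ind in enumerate(te.individuals)}
        new = np.full((len(te.genes), len(canonical)), np.nan)
        for k, ind in enumerate(canonical):
            if ind in pos:
                new[:, k] = te.values[:, pos[ind]]
        missing = [i for i in canonical if i not in pos]
        if missing:
            log.info("align_individuals[%s]: %d individuals missing", name, len(missing))
        tissues[name] = replace(te, individuals=list(canonical), values=new)

    names = list(tissues)
    groups = study.group_labels
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ia = set(study.tissues[names[a]].individuals)
            ib = set(study.tissues[names[b]].individuals)
            for g in groups:
                shared = (ia & ib) & set(study.individuals_in_group(g))
                if len(shared) < min_shared:
                    raise ValueError(
                        f"tissue pair ({names[a]}, {names[b]}) shares only "
                        f"{len(shared)} individuals in group {g!r} "
                        f"(minimum {min_shared})"
                    )
    return replace(study, tissues=tissues)


# ---------------------------------------------------------------------------
# Cohort summary (Table-1 style)
# ---------------------------------------------------------------------------

def cohort_summary(phenotypes: pd.DataFrame, group_column: str = "group") -> pd.DataFrame:
    """Per-phenotype group comparison: mean +/- SD and Welch t for numeric
    phenotypes, counts and chi-square (no continuity correction) for
    categorical ones.  Numeric phenotypes constant in both groups get
    p = 1 with a flag.
    """
    groups = sorted(phenotypes[group_column].unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, got {groups}")
    ga, gb = groups
    sub_a = phenotypes[phenotypes[group_column] == ga]
    sub_b = phenotypes[phenotypes[group_column] == gb]

    rows = []
    for col in phenotypes.columns:
        if col == group_column:
            continue
        series = phenotypes[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            xa = sub_a[col].dropna().to_numpy(dtype=float)
            xb = sub_b[col].dropna().to_numpy(dtype=float)
            flag = ""
            if np.ptp(np.concatenate([xa, xb])) == 0:
                p, flag = 1.0, "constant"
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            rows.append({
                "phenotype": col, "type": "numeric",
                "all": _mean_sd(series.dropna()),
                ga: _mean_sd(xa), gb: _mean_sd(xb),
                "p_value": p, "test": "welch_t", "flag": flag,
            })
        else:
            tab = pd.crosstab(phenotypes[col], phenotypes[group_column])
            flag = ""
            if tab.shape[0] < 2:
                p, flag = 1.0, "constant"
            else:
                p = float(stats.chi2_contingency(tab.to_numpy(), correction=False)[1])
            fmt = lambda s: "/".join(str(int(v)) for v in s)
            rows.append({
                "phenotype": col, "type": "categorical",
                "all": fmt(tab.sum(axis=1)) if tab.size else "",
                ga: fmt(tab[ga]) if ga in tab else "",
                gb: fmt(tab[gb]) if gb in tab else "",
                "p_value": p, "test": "chi_square", "flag": flag,
            })
    return pd.DataFrame(rows)


def _mean_sd(x) -> str:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return "NA"
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}" if x.size > 1 else f"{x[0]:.2f}"
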