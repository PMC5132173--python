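"""Module subnetworks and between-group edge comparison.

After module detection, a module's tight core (nodes with module
membership above a cutoff) is extracted and every node pair's
correlation is computed separately in the two phenotype groups, giving
per-edge |r_A - r_B| tables and Cytoscape-ready edge lists.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import correlation_pvalue, pearson_r
from .network import GeneTissueNode, ModulePartition, node_matrix
from .preprocess import MultiTissueStudy

log = logging.getLogger("intertissue")

DEFAULT_R_THRESHOLD = 0.1


@dataclass
class EdgeComparisonRecord:
    node_a: GeneTissueNode
    node_b: GeneTissueNode
    r_a: float
    r_b: float
    abs_difference: float
    p_a: float
    p_b: float
    flag: str = ""


def extract_module_subnetwork(partition: ModulePartition,
                              membership: pd.DataFrame, module: str,
                              mm_cutoff: float = 0.6) -> list[GeneTissueNode]:
    """Nodes assigned to ``module`` whose own-module membership exceeds
    ``mm_cutoff``; logs the per-tissue composition."""
    if module not in partition.modules:
        raise ValueError(f"module {module!r} not present in partition")
    mm = membership.set_index(["gene", "tissue"]) if "gene" in membership.columns \
        else membership
    selected = []
    for node in partition.members(module):
        value = mm.loc[(node.gene, node.tissue), module] if "gene" in membership.columns \
            else membership.loc[str(node), module]
        if np.isfinite(value) and value > mm_cutoff:
            selected.append(node)
    if not selected:
        log.warning("extract_module_subnetwork: no node of %r passes MM > %.2f",
                    module, mm_cutoff)
        return []
    composition = pd.Series([n.tissue for n in selected]).value_counts()
    log.info("module %r at MM > %.2f: %d nodes (%s)", module, mm_cutoff,
             len(selected), ", ".join(f"{t}={c}" for t, c in composition.items()))
    return selected


def group_edge_correlations(study: MultiTissueStudy,
                            nodes: list[GeneTissueNode],
                            groups: tuple[str, str] | None = None
                            ) -> list[EdgeComparisonRecord]:
    """All unordered node pairs with each group's r, both p-values, and
    |r_A - r_B|, sorted by the absolute difference descending."""
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    if groups is None:
        groups = tuple(study.group_labels)

    profiles: dict[str, dict[GeneTissueNode, np.ndarray]] = {}
    for group in groups:
        all_nodes, _, matrix = node_matrix(study, group)
        index = {n: i for i, n in enumerate(all_nodes)}
        profiles[group] = {n: matrix[index[n]] for n in nodes}

    records = []
    for na, nb in itertools.combinations(nodes, 2):
        stats_per_group = {}
        flag = ""
        for group in groups:
            x, y = profiles[group][na], profiles[group][nb]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                stats_per_group[group] = (float("nan"), float("nan"))
                flag = "insufficient_n"
                continue
            r = pearson_r(x[ok], y[ok])
            if not np.isfinite(r):
                flag = "constant_profile"
            p = correlation_pvalue(r, int(ok.sum())) if ok.sum() >= 4 else float("nan")
            stats_per_group[group] = (r, p)
        (ra, pa), (rb, pb) = stats_per_group[groups[0]], stats_per_group[groups[1]]
        records.append(EdgeComparisonRecord(
            node_a=na, node_b=nb, r_a=ra, r_b=rb,
            abs_difference=abs(ra - rb), p_a=pa, p_b=pb, flag=flag,
        ))
    records.sort(key=lambda rec: -(rec.abs_difference
                                   if np.isfinite(rec.abs_difference) else -np.inf))
    return records


def records_to_frame(records: list[EdgeComparisonRecord],
                     groups: tuple[str, str]) -> pd.DataFrame:
    ga, gb = groups
    columns = ["source", "target", "source_gene", "source_tissue",
               "target_gene", "target_tissue", f"r_{ga}", f"r_{gb}",
               "abs_difference", f"p_{ga}", f"p_{gb}", "flag"]
    if not records:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([{
        "source": str(rec.node_a), "target": str(rec.node_b),
        "source_gene": rec.node_a.gene, "source_tissue": rec.node_a.tissue,
        "target_gene": rec.node_b.gene, "target_tissue": rec.node_b.tissue,
        f"r_{ga}": rec.r_a, f"r_{gb}": rec.r_b,
        "abs_difference": rec.abs_difference,
        f"p_{ga}": rec.p_a, f"p_{gb}": rec.p_b,
        "flag": rec.flag,
    } for rec in records])


def export_edge_list(records: list[EdgeComparisonRecord], directory: str | Path,
                     groups: tuple[str, str],
                     r_threshold: float = DEFAULT_R_THRESHOLD,
                     prefix: str = "edges") -> dict[str, Path]:
    """Write per-group and combined edge tables (TSV, Cytoscape edge-table
    importable).  Edges with |r| below ``r_threshold`` in BOTH groups are
    omitted."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records, groups)
    ga, gb = groups
    keep = frame[(frame[f"r_{ga}"].abs() >= r_threshold)
                 | (frame[f"r_{gb}"].abs() >= r_threshold)] if len(frame) else frame

    written = {}
    for group in groups:
        path = directory / f"{prefix}_{group}.tsv"
        cols = ["source", "target", "source_gene", "source_tissue",
                "target_gene", "target_tissue", f"r_{group}", f"p_{group}"]
        (keep[cols] if len(keep) else frame.head(0)[cols]).to_csv(
            path, sep="\t", index=False)
        written[group] = path
    combined = directory / f"{prefix}_combined.tsv"
    keep.to_csv(combined, sep="\t", index=False)
    written["combined"] = combined
    return written


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
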