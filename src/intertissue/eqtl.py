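"""cis-eQTL mapping with permutation-based FDR.

Genotypes (0/1/2 dosages) pass QC on call rate (> 0.95), Hardy-Weinberg
exact test (p > 1e-4) and minor allele frequency (> 0.05).  SNP-probe
pairs within a 1 Mb cis window (inclusive) are tested per tissue by
Spearman rank correlation between dosage and expression; multiple
testing is controlled by permuting expression sample labels (default 10
rounds, per-probe best p) and reporting the permutation FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import TissueExpression

log = logging.getLogger("intertissue")

CIS_WINDOW = 1_000_000
CALL_RATE_MIN = 0.95   # strict: pass requires call rate > 0.95
HWE_P_MIN = 1e-4       # strict: pass requires HWE exact p > 1e-4
MAF_MIN = 0.05         # strict: pass requires MAF > 0.05
DEFAULT_N_PERM = 10


@dataclass
class GenotypeMatrix:
    """SNP x individual dosage matrix (0/1/2; NaN = missing call)."""

    snps: pd.DataFrame          # columns: id, chrom, pos, ref, alt
    individuals: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.snps["id"].duplicated().any():
            dups = self.snps.loc[self.snps["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate SNP ids: {dups[:5]}")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.dosages.shape != (len(self.snps), len(self.individuals)):
            raise ValueError("dosage matrix shape mismatch")

    @property
    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snps["id"])}


@dataclass
class SnpQCRecord:
    snp_id: str
    call_rate: float
    hwe_p: float
    maf: float

    @property
    def passed(self) -> bool:
        return (self.call_rate > CALL_RATE_MIN and self.hwe_p > HWE_P_MIN
                and self.maf > MAF_MIN)

    @property
    def fail_reasons(self) -> list[str]:
        reasons = []
        if not self.call_rate > CALL_RATE_MIN:
            reasons.append("call_rate")
        if not self.hwe_p > HWE_P_MIN:
            reasons.append("hwe")
        if not self.maf > MAF_MIN:
            reasons.append("maf")
        return reasons


@dataclass
class EqtlRecord:
    snp_id: str
    probe_id: str
    tissue: str
    distance: int
    statistic: float
    p: float
    fdr: float | None = None


# ---------------------------------------------------------------------------
# Genotype IO: minimal VCF (GT only) and dosage TSV
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 with a GT-only FORMAT column; missing calls as ./."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.individuals) + "\n")
        for i, row in enumerate(genotypes.snps.itertuples(index=False)):
            calls = "\t".join(
                gt_map.get(d, "./.") if np.isfinite(d) else "./."
                for d in genotypes.dosages[i]
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for variant in vcf:
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0] if variant.ALT else ".")
        gt = np.asarray(variant.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
    snps = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                         "ref": refs, "alt": alts})
    return GenotypeMatrix(snps=snps, individuals=individuals,
                          dosages=np.vstack(rows) if rows else np.empty((0, len(individuals))))


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.individuals)
    out = pd.concat([genotypes.snps.reset_index(drop=True), df], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    individuals = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(snps=df[meta_cols].copy(), individuals=individuals,
                          dosages=df[individuals].to_numpy(dtype=float))


def read_positions_tsv(path: str | Path) -> pd.DataFrame:
    """BED-like probe/SNP annotation: columns id, chrom, pos (1-based);
    alternatively chrom/start/end intervals, reduced to the midpoint."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "pos" not in df.columns:
        if {"start", "end"} <= set(df.columns):
            df["pos"] = ((df["start"] + df["end"]) // 2).astype(int)
        else:
            raise ValueError(f"{path}: need a 'pos' or 'start'/'end' columns")
    return df[["id", "chrom", "pos"]].copy()


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_het_probabilities(n_rare: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities of all attainable heterozygote counts conditional on
    the rare-allele count ``n_rare`` among ``n`` diploid individuals."""
    start = n_rare % 2
    hets = np.arange(start, n_rare + 1, 2)
    hets = hets[(n_rare - hets) // 2 + hets <= n]  # rare homs + hets <= n
    # log P(het) up to a constant: choose multinomial with 2^het factor
    n_common = 2 * n - n_rare
    logp = np.array([
        hets_k * math.log(2)
        - math.lgamma(hets_k + 1)
        - math.lgamma((n_rare - hets_k) // 2 + 1)
        - math.lgamma((n_common - hets_k) // 2 + 1)
        for hets_k in hets
    ])
    logp -= logp.max()
    p = np.exp(logp)
    return hets, p / p.sum()


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test: the summed probability of
    heterozygote counts no more probable than the observed one, given the
    allele counts."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hets, probs = _hwe_het_probabilities(n_rare, n)
    observed = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------

def snp_qc(genotypes: GenotypeMatrix) -> list[SnpQCRecord]:
    """Call rate, HWE exact p and MAF per SNP; thresholds are strict
    inequalities.  Errors if every SNP fails."""
    if len(genotypes.snps) == 0:
        raise ValueError("no SNPs to QC")
    records = []
    for i, snp_id in enumerate(genotypes.snps["id"]):
        d = genotypes.dosages[i]
        called = d[np.isfinite(d)]
        call_rate = called.size / d.size
        if called.size == 0:
            records.append(SnpQCRecord(snp_id, 0.0, 1.0, 0.0))
            continue
        n_bb = int((called == 2).sum())
        n_ab = int((called == 1).sum())
        n_aa = int((called == 0).sum())
        af_alt = (2 * n_bb + n_ab) / (2 * called.size)
        maf = min(af_alt, 1.0 - af_alt)
        records.append(SnpQCRecord(snp_id, call_rate,
                                   hwe_exact_p(n_aa, n_ab, n_bb), maf))
    if not any(rec.passed for rec in records):
        raise ValueError("all SNPs fail QC")
    n_pass = sum(rec.passed for rec in records)
    log.info("snp_qc: %d/%d SNPs pass", n_pass, len(records))
    return records


def qc_table(records: list[SnpQCRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp": rec.snp_id, "call_rate": rec.call_rate, "hwe_p": rec.hwe_p,
        "maf": rec.maf, "pass": rec.passed,
        "fail_reasons": ",".join(rec.fail_reasons),
    } for rec in records])


# ---------------------------------------------------------------------------
# cis pair enumeration
# ---------------------------------------------------------------------------

def cis_pairs(snp_meta: pd.DataFrame, probe_meta: pd.DataFrame,
              window: int = CIS_WINDOW) -> pd.DataFrame:
    """All (SNP, probe) pairs on the same chromosome within ``window`` bp
    (inclusive at exactly the window).  Probes without coordinates are
    skipped with a warning."""
    missing = probe_meta["pos"].isna() | probe_meta["chrom"].isna()
    if missing.any():
        log.warning("cis_pairs: skipping %d probes without coordinates",
                    int(missing.sum()))
        probe_meta = probe_meta[~missing]
    snp_meta = snp_meta.assign(chrom=snp_meta["chrom"].astype(str))
    probe_meta = probe_meta.assign(chrom=probe_meta["chrom"].astype(str))
    rows = []
    for chrom, probes in probe_meta.groupby("chrom"):
        snps = snp_meta[snp_meta["chrom"] == chrom]
        if snps.empty:
            continue
        spos = snps["pos"].to_numpy()
        for probe in probes.itertuples(index=False):
            dist = spos - int(probe.pos)
            hit = np.abs(dist) <= window
            for sid, d in zip(snps["id"].to_numpy()[hit], dist[hit]):
                rows.append({"snp": sid, "probe": probe.id, "distance": int(d)})
    return pd.DataFrame(rows, columns=["snp", "probe", "distance"])


# ---------------------------------------------------------------------------
# Association and permutation FDR
# ---------------------------------------------------------------------------

def _spearman_p(rho: float, n: int) -> float:
    if not np.isfinite(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def map_cis(genotypes: GenotypeMatrix, expression: TissueExpression,
            pairs: pd.DataFrame, statistic: str = "spearman",
            min_n: int = 3) -> list[EqtlRecord]:
    """Per cis pair: association of dosage with expression over shared
    non-missing individuals.  ``statistic`` is 'spearman' (rank
    correlation, t-approximate p) or 'linear' (additive regression
    slope test).  Records are sorted by p ascending."""
    shared = [i for i in expression.individuals if i in set(genotypes.individuals)]
    if len(shared) < min_n:
        raise ValueError(f"only {len(shared)} individuals shared between "
                         "genotypes and expression")
    g_idx = [genotypes.individuals.index(i) for i in shared]
    e_idx = [expression.individuals.index(i) for i in shared]
    dos = genotypes.dosages[:, g_idx]
    expr = expression.values[:, e_idx]
    snp_row = genotypes.snp_index
    gene_row = expression.gene_index

    records = []
    for pair in pairs.itertuples(index=False):
        if pair.snp not in snp_row or pair.probe not in gene_row:
            continue
        d = dos[snp_row[pair.snp]]
        x = expr[gene_row[pair.probe]]
        ok = np.isfinite(d) & np.isfinite(x)
        if ok.sum() < max(min_n, 4):
            continue
        dd, xx = d[ok], x[ok]
        if np.ptp(dd) == 0:
            log.debug("map_cis: constant dosage for %s after subsetting; skipped",
                      pair.snp)
            continue
        if np.ptp(xx) == 0:
            continue
        if statistic == "spearman":
            rho = np.corrcoef(stats.rankdata(dd), stats.rankdata(xx))[0, 1]
            p = _spearman_p(float(rho), int(ok.sum()))
            stat = float(rho)
        elif statistic == "linear":
            res = stats.linregress(dd, xx)
            stat, p = float(res.slope), float(res.pvalue)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        records.append(EqtlRecord(pair.snp, pair.probe, expression.tissue,
                                  int(pair.distance), stat, p))
    records.sort(key=lambda rec: rec.p)
    return records


def _best_p_per_probe(records: list[EqtlRecord]) -> pd.Series:
    frame = pd.DataFrame([{"probe": r.probe_id, "p": r.p} for r in records])
    return frame.groupby("probe")["p"].min()


def permutation_fdr(records: list[EqtlRecord], genotypes: GenotypeMatrix,
                    expression: TissueExpression, pairs: pd.DataFrame,
                    n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                    statistic: str = "spearman",
                    granularity: str = "probe") -> list[EqtlRecord]:
    """Permutation FDR on per-probe best p-values (or per record when
    ``granularity='snp'``).

    Expression sample labels are permuted ``n_perm`` times against fixed
    genotypes; FDR at observed value x = (mean permuted count of best-p
    <= x) / (observed count <= x), clipped to [0,1] and monotone
    non-decreasing in x.  The FDR is attached to each probe's best
    record (other records keep fdr=None).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not records:
        return records
    if granularity == "probe":
        observed = _best_p_per_probe(records).sort_values()
    elif granularity == "snp":
        observed = pd.Series({f"{r.snp_id}|{r.probe_id}": r.p for r in records}).sort_values()
    else:
        raise ValueError(f"unknown granularity {granularity!r}")

    rng = np.random.default_rng(seed)
    perm_values = []
    n_ind = len(expression.individuals)
    for _ in range(n_perm):
        shuffled = [expression.individuals[k] for k in rng.permutation(n_ind)]
        perm_expr = TissueExpression(
            tissue=expression.tissue, genes=list(expression.genes),
            individuals=shuffled, values=expression.values,
        )
        perm_records = map_cis(genotypes, perm_expr, pairs, statistic=statistic)
        if not perm_records:
            continue
        if granularity == "probe":
            perm_values.append(_best_p_per_probe(perm_records).to_numpy())
        else:
            perm_values.append(np.array([r.p for r in perm_records]))
    if not perm_values:
        raise RuntimeError("no permutation produced any association")
    pooled = np.sort(np.concatenate(perm_values))
    n_rounds = len(perm_values)

    obs_sorted = observed.to_numpy()
    n_obs_le = np.arange(1, obs_sorted.size + 1)
    n_perm_le = np.searchsorted(pooled, obs_sorted, side="right") / n_rounds
    fdr = np.clip(n_perm_le / n_obs_le, 0.0, 1.0)
    fdr = np.maximum.accumulate(fdr)  # monotone non-decreasing in p
    fdr_by_key = dict(zip(observed.index, fdr))

    best_record: dict[str, EqtlRecord] = {}
    for rec in records:
        key = rec.probe_id if granularity == "probe" else f"{rec.snp_id}|{rec.probe_id}"
        if granularity == "snp" or key not in best_record or rec.p < best_record[key].p:
            best_record[key] = rec
    for rec in records:
        rec.fdr = None
    for key, rec in best_record.items():
        rec.fdr = float(fdr_by_key[key])
    return records


def eqtl_table(records: list[EqtlRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp": r.snp_id, "probe": r.probe_id, "tissue": r.tissue,
        "distance": r.distance, "statistic": r.statistic, "p": r.p,
        "fdr": r.fdr if r.fdr is not None else np.nan,
    } for r in records])
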