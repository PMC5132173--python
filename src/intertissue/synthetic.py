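"""Synthetic multi-tissue two-group study generator.

Emulates the study design downstream stages were built for: four tissues
(liver, muscle, SAT, VAT) sampled from ~60 matched obese individuals
split into a metabolically healthy (MHO, n=28) and unhealthy (MUO, n=32)
group, with

* within-tissue co-expression modules generated by a latent-factor
  model — member = sqrt(rho)*factor + sqrt(1-rho)*noise, giving an
  analytic expected pairwise correlation of rho;
* group-specific inter-tissue "crosstalk" of designated cytokine-like
  genes: the same gene in the tissues of a pair set shares one
  per-individual factor only in the specified group (the IL1B/IL-6
  pattern);
* age/sex/metabolic covariates drawn to resemble a severely obese
  bariatric-surgery cohort;
* genotypes as binomial(2, MAF) dosages with planted additive cis
  effects on designated probes, in SD units of the probe's residual.

One global seed expands into independent per-component child seeds via
``numpy.random.SeedSequence.spawn`` (order: expression, phenotypes,
genotypes, missingness), so each stage is reproducible on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (MultiTissueStudy, TissueExpression,
                         read_expression_tsv, read_phenotypes_tsv,
                         write_expression_tsv, write_phenotypes_tsv)

log = logging.getLogger("intertissue")

DEFAULT_TISSUES = ("liver", "muscle", "SAT", "VAT")
DEFAULT_GROUPS = ("MHO", "MUO")


@dataclass
class ModuleSpec:
    """A planted within-tissue module: member genes share one latent
    factor with loading sqrt(rho)."""
    tissue: str
    genes: list[str]
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"module rho must lie in [0,1], got {self.rho}")


@dataclass
class CrosstalkSpec:
    """Group-specific inter-tissue coupling of one gene.

    ``tissue_pairs`` lists the tissue pairs to couple; the shared factor
    acts on the union of the named tissues, so a non-clique pair set
    also induces correlation on the omitted pairs.  ``group_targets``
    maps group label -> correlation target in [-1, 1] (groups absent
    from the map stay uncoupled)."""
    gene: str
    tissue_pairs: list[tuple[str, str]]
    group_targets: dict[str, float]

    def __post_init__(self) -> None:
        for r in self.group_targets.values():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"crosstalk target must lie in [-1,1], got {r}")

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for a, b in self.tissue_pairs:
            for t in (a, b):
                if t not in seen:
                    seen.append(t)
        return seen


@dataclass
class EqtlSpec:
    """A planted cis effect: expression of ``probe`` in ``tissue`` gains
    ``effect`` residual-SD units per alternate allele of ``snp``."""
    snp: str
    probe: str
    tissue: str
    effect: float
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"MAF must lie in (0, 0.5], got {self.maf}")


@dataclass
class SimConfig:
    n_individuals: int = 60
    group_sizes: tuple[int, int] = (28, 32)
    group_labels: tuple[str, str] = DEFAULT_GROUPS
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_genes: int = 200
    module_spec: list[ModuleSpec] = field(default_factory=list)
    crosstalk_spec: list[CrosstalkSpec] = field(default_factory=list)
    eqtl_spec: list[EqtlSpec] = field(default_factory=list)
    background_snps_per_probe: int = 0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_individuals:
            raise ValueError(
                f"group sizes {self.group_sizes} must sum to {self.n_individuals}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self._check_conflicts()

    def _check_conflicts(self) -> None:
        claimed: dict[tuple[str, str], str] = {}
        for spec in self.module_spec:
            for gene in spec.genes:
                key = (gene, spec.tissue)
                if key in claimed:
                    raise ValueError(
                        f"gene {gene!r} in tissue {spec.tissue!r} assigned to "
                        f"conflicting correlation targets ({claimed[key]} vs module)")
                claimed[key] = "module"
        for spec in self.crosstalk_spec:
            for tissue in spec.tissues:
                key = (spec.gene, tissue)
                if key in claimed:
                    raise ValueError(
                        f"gene {spec.gene!r} in tissue {tissue!r} assigned to "
                        f"conflicting correlation targets ({claimed[key]} vs crosstalk)")
                claimed[key] = "crosstalk"

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def individual_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(1, self.n_individuals + 1)]


@dataclass
class GroundTruth:
    module_assignment: dict[tuple[str, str], str]     # (gene, tissue) -> module name
    crosstalk_genes: list[str]
    eqtl_pairs: list[tuple[str, str, str, float]]     # (snp, probe, tissue, effect)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_study(config: SimConfig) -> tuple[MultiTissueStudy, GroundTruth]:
    """Generate a matched multi-tissue study plus its ground truth.

    Expression values live on a log2-intensity-like scale (per-gene
    baseline ~ N(8, 1)); correlation structure is what the planted specs
    dictate.  Deterministic for a fixed config seed.
    """
    rng_expr, rng_pheno, rng_geno, _ = _child_rngs(config.seed, 4)
    genes = config.gene_ids()
    individuals = config.individual_ids()
    n = config.n_individuals
    ga, gb = config.group_labels
    groups = np.array([ga] * config.group_sizes[0] + [gb] * config.group_sizes[1])

    values = {t: rng_expr.normal(0.0, config.noise_sd, size=(config.n_genes, n))
              for t in config.tissues}
    gene_row = {g: i for i, g in enumerate(genes)}

    truth_modules: dict[tuple[str, str], str] = {}
    for m, spec in enumerate(config.module_spec):
        if spec.tissue not in values:
            raise ValueError(f"module tissue {spec.tissue!r} not in study tissues")
        factor = rng_expr.normal(0.0, 1.0, size=n)
        for gene in spec.genes:
            if gene not in gene_row:
                raise ValueError(f"module gene {gene!r} not in study genes")
            noise = rng_expr.normal(0.0, 1.0, size=n)
            values[spec.tissue][gene_row[gene]] = (
                np.sqrt(spec.rho) * factor + np.sqrt(1.0 - spec.rho) * noise
            ) * config.noise_sd
            truth_modules[(gene, spec.tissue)] = f"planted_{m}"

    for spec in config.crosstalk_spec:
        if spec.gene not in gene_row:
            raise ValueError(f"crosstalk gene {spec.gene!r} not in study genes")
        shared = rng_expr.normal(0.0, 1.0, size=n)
        row = gene_row[spec.gene]
        for t_idx, tissue in enumerate(spec.tissues):
            if tissue not in values:
                raise ValueError(f"crosstalk tissue {tissue!r} not in study tissues")
            noise = rng_expr.normal(0.0, 1.0, size=n)
            out = np.empty(n)
            for label in (ga, gb):
                mask = groups == label
                r = spec.group_targets.get(label, 0.0)
                # a negative target flips the loading of the first tissue,
                # giving corr r with every other coupled tissue
                sign = -1.0 if (r < 0 and t_idx == 0) else 1.0
                out[mask] = (sign * np.sqrt(abs(r)) * shared[mask]
                             + np.sqrt(1.0 - abs(r)) * noise[mask])
            values[tissue][row] = out * config.noise_sd

    # log2-intensity-like location/scale (does not alter correlations)
    baselines = rng_expr.normal(8.0, 1.0, size=config.n_genes)
    tissues = {}
    for t in config.tissues:
        tissues[t] = TissueExpression(
            tissue=t, genes=list(genes), individuals=list(individuals),
            values=values[t] + baselines[:, None],
        )

    phenotypes = _simulate_phenotypes(rng_pheno, individuals, groups, ga, gb)

    genotypes = None
    probe_positions = None
    eqtl_truth: list[tuple[str, str, str, float]] = []
    if config.eqtl_spec or config.background_snps_per_probe > 0:
        genotypes, probe_positions, eqtl_truth = _plant_genotypes(
            config, tissues, rng_geno)

    study = MultiTissueStudy(tissues=tissues, phenotypes=phenotypes,
                             genotypes=genotypes,
                             probe_positions=probe_positions)
    truth = GroundTruth(module_assignment=truth_modules,
                        crosstalk_genes=[s.gene for s in config.crosstalk_spec],
                        eqtl_pairs=eqtl_truth)
    return study, truth


def _simulate_phenotypes(rng: np.random.Generator, individuals: list[str],
                         groups: np.ndarray, ga: str, gb: str) -> pd.DataFrame:
    """Covariates shaped like a severely obese surgical cohort: the
    unhealthy group is older with higher glucose/HbA1c/BMI on average."""
    n = len(individuals)
    is_b = groups == gb
    age = np.where(is_b, rng.normal(47.6, 10.6, n), rng.normal(41.7, 9.3, n))
    bmi = np.where(is_b, rng.normal(47.4, 8.3, n), rng.normal(43.7, 7.6, n))
    glucose = np.where(is_b, rng.normal(7.1, 2.2, n), rng.normal(5.6, 0.7, n))
    hba1c = np.where(is_b, rng.normal(6.9, 1.5, n), rng.normal(6.2, 0.9, n))
    sex = np.where(rng.random(n) < 0.7, "male", "female")
    return pd.DataFrame({
        "group": groups, "sex": sex,
        "age": np.round(age, 1), "bmi": np.round(bmi, 1),
        "glucose": np.round(np.maximum(glucose, 3.5), 2),
        "hba1c": np.round(np.maximum(hba1c, 4.0), 2),
    }, index=pd.Index(individuals, name="individual_id"))


def _plant_genotypes(config: SimConfig, tissues: dict[str, TissueExpression],
                     rng: np.random.Generator):
    """Probe coordinates spaced 2.5 Mb apart on chr1 (so each probe's cis
    window is private), one SNP 100 kb from each planted probe plus
    optional background SNPs within the window."""
    from .eqtl import GenotypeMatrix

    genes = config.gene_ids()
    probe_pos = {g: 1 + i * 2_500_000 for i, g in enumerate(genes)}
    probe_positions = pd.DataFrame({
        "id": genes, "chrom": "1", "pos": [probe_pos[g] for g in genes],
    })

    snp_rows = []
    dosage_rows = []
    seen = set()
    eqtl_truth = []
    n = config.n_individuals

    for spec in config.eqtl_spec:
        if spec.snp in seen:
            raise ValueError(f"duplicate SNP id {spec.snp!r}")
        seen.add(spec.snp)
        if spec.probe not in probe_pos:
            raise ValueError(f"eQTL probe {spec.probe!r} not in study genes")
        dose = rng.binomial(2, spec.maf, size=n).astype(float)
        snp_rows.append({"id": spec.snp, "chrom": "1",
                         "pos": probe_pos[spec.probe] + 100_000,
                         "ref": "A", "alt": "G"})
        dosage_rows.append(dose)
        te = tissues[spec.tissue]
        row = te.gene_index[spec.probe]
        resid_sd = te.values[row].std(ddof=0)
        te.values[row] = te.values[row] + spec.effect * resid_sd * dose
        eqtl_truth.append((spec.snp, spec.probe, spec.tissue, spec.effect))

    if config.background_snps_per_probe > 0:
        for g in genes:
            for k in range(config.background_snps_per_probe):
                sid = f"bg_{g}_{k}"
                maf = rng.uniform(0.1, 0.5)
                offset = int(rng.integers(-900_000, 900_000))
                snp_rows.append({"id": sid, "chrom": "1",
                                 "pos": max(1, probe_pos[g] + offset),
                                 "ref": "A", "alt": "G"})
                dosage_rows.append(rng.binomial(2, maf, size=n).astype(float))

    genotypes = GenotypeMatrix(
        snps=pd.DataFrame(snp_rows, columns=["id", "chrom", "pos", "ref", "alt"]),
        individuals=config.individual_ids(),
        dosages=np.vstack(dosage_rows) if dosage_rows else
                np.empty((0, n)),
    )
    return genotypes, probe_positions, eqtl_truth


# ---------------------------------------------------------------------------
# Stand-alone genotype simulation
# ---------------------------------------------------------------------------

def simulate_genotypes(n_individuals: int, snp_meta: list[tuple[str, str, int, float]],
                       seed: int = 0, missing_rate: float = 0.0):
    """Dosages drawn per SNP as binomial(2, MAF) independently per
    individual (random mating), with optional missingness.

    ``snp_meta`` rows are (id, chrom, pos, MAF)."""
    from .eqtl import GenotypeMatrix

    ids = [m[0] for m in snp_meta]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate SNP ids: {dup}")
    for _, _, _, maf in snp_meta:
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"MAF must lie in (0, 0.5], got {maf}")
    rng = np.random.default_rng(seed)
    dosages = np.vstack([
        rng.binomial(2, maf, size=n_individuals).astype(float)
        for _, _, _, maf in snp_meta
    ]) if snp_meta else np.empty((0, n_individuals))
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
    snps = pd.DataFrame({
        "id": ids, "chrom": [m[1] for m in snp_meta],
        "pos": [m[2] for m in snp_meta],
        "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(snps=snps,
                          individuals=[f"S{i:03d}" for i in range(1, n_individuals + 1)],
                          dosages=dosages)


# ---------------------------------------------------------------------------
# Fixture writing / round-trip
# ---------------------------------------------------------------------------

def write_fixtures(study: MultiTissueStudy, truth: GroundTruth,
                   directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write the TSV/VCF fixture set consumed by the pipeline readers.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set."""
    from .eqtl import write_vcf

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    written: dict[str, Path] = {}
    for tissue, te in study.tissues.items():
        path = directory / f"expression_{tissue}.tsv"
        write_expression_tsv(te, path)
        written[f"expression_{tissue}"] = path
    pheno = directory / "phenotypes.tsv"
    write_phenotypes_tsv(study.phenotypes, pheno)
    written["phenotypes"] = pheno

    if study.genotypes is not None:
        vcf = directory / "genotypes.vcf"
        write_vcf(study.genotypes, vcf)
        written["genotypes"] = vcf
    if study.probe_positions is not None:
        pp = directory / "probe_positions.tsv"
        study.probe_positions.to_csv(pp, sep="\t", index=False)
        written["probe_positions"] = pp
        snp_pos = directory / "snp_positions.tsv"
        study.genotypes.snps[["id", "chrom", "pos"]].to_csv(snp_pos, sep="\t", index=False)
        written["snp_positions"] = snp_pos

    modules = pd.DataFrame(
        [{"gene": g, "tissue": t, "module": m}
         for (g, t), m in truth.module_assignment.items()])
    modules.to_csv(directory / "truth_modules.tsv", sep="\t", index=False)
    written["truth_modules"] = directory / "truth_modules.tsv"
    pd.DataFrame({"gene": truth.crosstalk_genes}).to_csv(
        directory / "truth_crosstalk.tsv", sep="\t", index=False)
    written["truth_crosstalk"] = directory / "truth_crosstalk.tsv"
    pd.DataFrame(truth.eqtl_pairs,
                 columns=["snp", "probe", "tissue", "effect"]).to_csv(
        directory / "truth_eqtl.tsv", sep="\t", index=False)
    written["truth_eqtl"] = directory / "truth_eqtl.tsv"
    return written


def read_fixtures(directory: str | Path) -> MultiTissueStudy:
    """Load a fixture directory written by :func:`write_fixtures`."""
    from .eqtl import read_positions_tsv, read_vcf

    directory = Path(directory)
    tissues = {}
    for path in sorted(directory.glob("expression_*.tsv")):
        tissue = path.stem.removeprefix("expression_")
        tissues[tissue] = read_expression_tsv(path, tissue)
    phenotypes = read_phenotypes_tsv(directory / "phenotypes.tsv")
    genotypes = None
    probe_positions = None
    if (directory / "genotypes.vcf").exists():
        genotypes = read_vcf(directory / "genotypes.vcf")
    if (directory / "probe_positions.tsv").exists():
        probe_positions = read_positions_tsv(directory / "probe_positions.tsv")
    return MultiTissueStudy(tissues=tissues, phenotypes=phenotypes,
                            genotypes=genotypes, probe_positions=probe_positions)
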