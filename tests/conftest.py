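import numpy as np
import pandas as pd
import pytest

import intertissue as it


def make_study(n_genes=30, seed=0, module_spec=(), crosstalk_spec=(),
               eqtl_spec=(), background_snps=0, align=True):
    cfg = it.SimConfig(n_genes=n_genes, seed=seed,
                       module_spec=list(module_spec),
                       crosstalk_spec=list(crosstalk_spec),
                       eqtl_spec=list(eqtl_spec),
                       background_snps_per_probe=background_snps)
    study, truth = it.simulate_study(cfg)
    if align:
        study = it.align_individuals(study)
    return study, truth


@pytest.fixture(scope="session")
def study_factory():
    return make_study


@pytest.fixture(scope="session")
def crosstalk_study():
    """40-gene study with one MUO-only crosstalk gene at r=0.6 across the
    liver/adipose pairs."""
    pairs = [("liver", "SAT"), ("liver", "VAT"), ("SAT", "VAT")]
    return make_study(n_genes=40, seed=11,
                      crosstalk_spec=[it.CrosstalkSpec("G0001", pairs, {"MUO": 0.6})])


@pytest.fixture(scope="session")
def module_study():
    """Two planted 60-node within-tissue modules (rho 0.8) plus noise."""
    genes = [f"G{i:04d}" for i in range(1, 161)]
    return make_study(n_genes=160, seed=7, module_spec=[
        it.ModuleSpec("liver", genes[:60], 0.8),
        it.ModuleSpec("muscle", genes[60:120], 0.8),
    ])


@pytest.fixture(scope="session")
def eqtl_study():
    """One planted cis effect (1 SD per allele, MAF 0.3) plus background SNPs."""
    return make_study(n_genes=40, seed=5,
                      eqtl_spec=[it.EqtlSpec("rs_planted", "G0010", "liver", 1.0, 0.3)],
                      background_snps=2)
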