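"""Shared fixtures: small synthetic compendia reused across test modules."""

import pytest

from enhancerkit import enhancers as en
from enhancerkit import synthdata as sd

SMALL = dict(
    n_chromosomes=2, chrom_length_bp=614_400, n_tissue_groups=3,
    samples_per_group=4, n_modules=4, enhancers_per_module=50,
    n_genes=30, n_traits=6, background_snp_count=90, marks=("H3K27ac",),
)

QC = dict(
    n_chromosomes=2, chrom_length_bp=409_600, n_tissue_groups=3,
    samples_per_group=4, n_modules=3, enhancers_per_module=40,
    n_genes=20, n_traits=4, background_snp_count=60,
    marks=("H3K27ac", "H3K4me1", "H3K4me3", "H3K36me3", "H3K9me3"),
)


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SynthConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_comp(small_cfg):
    return sd.generate_compendium(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_cfg, small_comp):
    return sd.generate_gwas_catalog(small_cfg, small_comp.truth)


@pytest.fixture(scope="session")
def small_activity(small_comp):
    k27 = {s: small_comp.observed[(s, "H3K27ac")] for s in small_comp.metadata["sample"]}
    return en.call_active_enhancers(small_comp.dhs, small_comp.segmentations, k27)


@pytest.fixture(scope="session")
def qc_cfg():
    return sd.SynthConfig(seed=21, **QC)


@pytest.fixture(scope="session")
def qc_comp(qc_cfg):
    return sd.generate_compendium(qc_cfg)
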