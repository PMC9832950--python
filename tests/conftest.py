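"""Shared fixtures: hand-built variants and small simulated datasets."""

import pytest

from poolmap.io_formats import PoolCounts, VariantRecord
from poolmap.simulate import SimConfig, build_splice_reporter_gene


def make_variant(
    chrom="Fvb1",
    pos=17_218_907,
    ref="C",
    alt="T",
    mutant_parent=(0, 19),
    wildtype_parent=(53, 0),
    mutant_pool=(0, 37),
    wildtype_pool=(32, 12),
):
    """A biallelic SNV with (ref, alt) read counts per role.

    Defaults are the splice-donor candidate's published depth quartet.
    """
    roles = {
        "mutant_parent": mutant_parent,
        "wildtype_parent": wildtype_parent,
        "mutant_pool": mutant_pool,
        "wildtype_pool": wildtype_pool,
    }
    counts = {role: PoolCounts({ref: r, alt: a}) for role, (r, a) in roles.items()}
    return VariantRecord(chrom, pos, ref, alt, counts)


@pytest.fixture
def donor_site_variant():
    """The C->T splice-donor SNV with its four published depth pairs."""
    return make_variant()


@pytest.fixture
def reporter_gene():
    """Five-exon splice-reporter gene (plus strand) and its genome dict."""
    gene, seq = build_splice_reporter_gene(gene_id="toy", chrom="chr1", offset=1001)
    pad = "A" * 1000
    return gene, {"chr1": pad + seq + pad}


@pytest.fixture
def reporter_gene_minus():
    gene, seq = build_splice_reporter_gene(
        gene_id="toy_rc", chrom="chr1", offset=1001, strand="-"
    )
    pad = "A" * 1000
    return gene, {"chr1": pad + seq + pad}


def small_sim_config(seed=0, **overrides):
    """A fast, scaled-down simulation for unit tests (not the study-scale
    defaults used by the acceptance checks)."""
    fields = dict(
        seed=seed,
        chrom_length_bp=2_000_000,
        n_background_variants=60,
        n_background_chromosomes=0,
        causal_pos=1_000_000,
        n_f2=300,
        gene_every_bp=200_000,
    )
    fields.update(overrides)
    return SimConfig(**fields)
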