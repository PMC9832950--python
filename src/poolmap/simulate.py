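"""Synthetic EMS F2 bulked-segregant dataset with known ground truth.

The generator emulates the study design every pipeline stage is tested
against: an EMS-mutagenised diploid parent (G:C->A:T-biased SNVs, all
homozygous) crossed to a wild-type reference accession; an F2 produced
by selfing the F1, with crossovers drawn under a Haldane
(no-interference) model; one fully penetrant recessive causal variant —
a G->A hit on the first base of intron 2 of a designated gene, i.e. a
broken splice donor; two phenotype-selected pools of 37 individuals
each; and pooled short-read counts with Poisson depth (parent/pool
means 22/57/49/58x) and a symmetric per-read error rate.

The default genome is a focal 30-Mb chromosome carrying the causal
locus and the annotated gene grid, plus six unlinked background
chromosomes of the same size.  The background chromosomes matter
because the significance threshold of the scan (median + 3 SD of the
fitted profile, genome-wide) is only meaningful when most of the
genome is unlinked to the causal locus, as in a real multi-chromosome
genome; with the focal chromosome alone the linked signal spans most
of the profile and inflates both terms.  Background chromosomes carry
EMS variants but no annotated genes.

It is a count-level simulator (no reads, no alignment): adequate to
exercise the allele-frequency scan, the genotype filter, and the splice
engine, but it does not model mapping bias, indel realignment noise, or
depth heterogeneity along the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    GeneModel,
    PoolCounts,
    VariantRecord,
    write_fasta,
    write_gff3,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-design parameters of the simulated mapping experiment."""

    seed: int = 0
    chrom: str = "Fvb1"
    chrom_length_bp: int = 30_000_000
    n_background_variants: int = 2_000  # per chromosome
    n_background_chromosomes: int = 6   # unlinked chromosomes Fvb2..; same length
    ems_transition_fraction: float = 0.95
    causal_pos: int = 17_200_000
    causal: bool = True          # False = null run: no causal locus, random phenotypes
    n_f2: int = 400
    pool_size: int = 37
    mean_depth_mutant_parent: float = 22.0
    mean_depth_wildtype_parent: float = 57.0
    mean_depth_mutant_pool: float = 49.0
    mean_depth_wildtype_pool: float = 58.0
    error_rate: float = 0.002
    recomb_rate_cM_per_Mb: float = 4.0
    gene_every_bp: int = 13_000  # gene grid on the focal chromosome

    def __post_init__(self) -> None:
        for rate in (self.ems_transition_fraction, self.error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise ValueError("causal_pos outside the chromosome")

    @property
    def chromosomes(self) -> list[str]:
        stem = self.chrom.rstrip("0123456789") or "chr"
        return [self.chrom] + [
            f"{stem}{i + 2}" for i in range(self.n_background_chromosomes)
        ]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    seed: int
    causal_pos: int | None
    causal_gene_id: str | None
    phenotypes: list[bool]            # True = mutant phenotype
    variant_origin: str = "mutant_parent"  # all variants derive from the EMS parent


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    variants: list[VariantRecord]
    truth: SimTruth
    dosages: np.ndarray = field(repr=False)  # (n_f2, n_variants) mutant-allele dosage
    chroms: np.ndarray = field(repr=False)   # per-variant chromosome
    positions: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# splice-reporter gene template

_CODON_POOL = ["GCA", "CAA", "GAC", "CCA", "GGA", "AAC"]  # no T: no stops, no GT
_EXON_LENS = (201, 300, 300, 300, 237)  # CDS 1338 nt = 445 aa + stop
_INTRON_LEN = 90
#: 3' tail of exon 2 removed by the planted cryptic donor (in-frame)
CRYPTIC_DELETION_BP = 54


def _reporter_cds_codons() -> list[str]:
    codons = ["ATG"]
    for i in range(2, 446):
        codons.append(_CODON_POOL[i % len(_CODON_POOL)])
    codons.append("TGA")
    # planted cryptic donor GT at CDS nt 448 (codon 150), 54 nt before the
    # exon2/intron2 junction at CDS nt 501
    codons[149] = "GTA"
    # exon 3 opens with the same codon the retained intron starts with, so
    # the intron-retention protein is a clean prefix of the reference
    codons[167] = "GTA"
    return codons


def build_splice_reporter_gene(
    gene_id: str = "reporter",
    chrom: str = "chr1",
    offset: int = 1,
    strand: str = "+",
) -> tuple[GeneModel, str]:
    """Construct the five-exon splice-reporter gene and its sequence.

    The gene encodes a 1338-nt CDS (445 aa).  Intron 2 starts ``GTATAA``:
    retaining it reads one matching codon and then an in-frame stop.  A
    single cryptic GT sits 54 bp upstream of the exon2/intron2 junction,
    so a broken donor yields one in-frame 54-bp (18-aa) partial exon
    deletion.  Returns ``(GeneModel, gene_sequence)``; the sequence is
    the gene-span genomic sequence on the forward strand (already
    reverse-complement-mirrored when ``strand == '-'``).
    """
    cds = "".join(_reporter_cds_codons())
    exon_seqs = []
    at = 0
    for ln in _EXON_LENS:
        exon_seqs.append(cds[at : at + ln])
        at += ln
    filler = "C" * (_INTRON_LEN - 8)
    introns = [
        "GT" + filler + "CCCC" + "AG",
        "GTATAA" + filler + "AG",
        "GT" + filler + "CCCC" + "AG",
        "GT" + filler + "CCCC" + "AG",
    ]
    seq = ""
    exons_rel: list[tuple[int, int]] = []
    for i, es in enumerate(exon_seqs):
        exons_rel.append((len(seq) + 1, len(seq) + len(es)))
        seq += es
        if i < len(introns):
            seq += introns[i]
    span = len(seq)
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        seq = seq.translate(comp)[::-1]
        exons_rel = sorted((span - e + 1, span - s + 1) for s, e in exons_rel)
    exons = [(offset + s - 1, offset + e - 1) for s, e in exons_rel]
    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )
    return gene, seq


def reporter_donor2_offset() -> int:
    """1-based offset, within the plus-strand gene span, of the first base
    of intron 2 (the broken donor G)."""
    return _EXON_LENS[0] + _INTRON_LEN + _EXON_LENS[1] + 1


# ---------------------------------------------------------------------------
# simulation stages


def _draw_variants(
    genome_seq: str,
    n: int,
    config: SimConfig,
    rng: np.random.Generator,
    exclude_pos: int | None = None,
) -> dict[int, tuple[str, str]]:
    """Unique-position EMS-biased SNVs with ref bases read from the genome."""
    L = len(genome_seq)
    n_ems = int(round(config.ems_transition_fraction * n))
    need_ems, need_other = n_ems, n - n_ems
    variants: dict[int, tuple[str, str]] = {}
    while need_ems + need_other > 0:
        draw = rng.integers(1, L + 1, size=4 * (need_ems + need_other) + 16)
        for pos in draw:
            pos = int(pos)
            if pos == exclude_pos or pos in variants:
                continue
            ref = genome_seq[pos - 1]
            if need_ems > 0 and ref in "GC":
                variants[pos] = (ref, "A" if ref == "G" else "T")
                need_ems -= 1
            elif need_other > 0:
                alts = [b for b in "ACGT" if b != ref]
                variants[pos] = (ref, alts[int(rng.integers(0, 3))])
                need_other -= 1
            if need_ems + need_other == 0:
                break
    return variants


def simulate_parents(config: SimConfig, rng: np.random.Generator):
    """Genome, gene models, and the homozygous EMS variant list.

    The mutant parent carries every simulated SNV homozygously (plus
    the causal donor mutation when ``config.causal``); the wild-type
    parent is the reference.  Returns ``(genome, genes, variants)``
    where variants is a list of ``(chrom, pos, ref, alt)`` sorted by
    chromosome then position.
    """
    L = config.chrom_length_bp
    n = config.n_background_variants
    if n > L // 100:
        raise ValueError("variant density exceeds 1 per 100 bp")

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    var_list: list[tuple[str, int, str, str]] = []

    for ci, chrom in enumerate(config.chromosomes):
        seq_arr = _BASES[rng.integers(0, 4, size=L)]
        focal = ci == 0
        exclude = None
        if focal:
            # plant the causal splice-reporter gene so its intron-2 donor G
            # sits exactly at causal_pos
            gene_offset = config.causal_pos - reporter_donor2_offset() + 1
            causal_gene, gene_seq = build_splice_reporter_gene(
                gene_id="causal_gene", chrom=chrom, offset=gene_offset
            )
            seq_arr[gene_offset - 1 : gene_offset - 1 + len(gene_seq)] = np.frombuffer(
                gene_seq.encode(), dtype=np.uint8
            )
            exclude = config.causal_pos
        genome_seq = seq_arr.tobytes().decode()
        genome[chrom] = genome_seq

        if focal:
            genes.append(causal_gene)
            gspan = (causal_gene.gene_start, causal_gene.gene_end)
            gid = 0
            for start in range(50_001, L - 3_000, config.gene_every_bp):
                end = start + 2_999
                if start <= gspan[1] and end >= gspan[0] - 10_000:
                    continue
                gid += 1
                genes.append(
                    GeneModel(
                        gene_id=f"bg_g{gid:05d}",
                        chrom=chrom,
                        strand="+" if gid % 2 else "-",
                        exons=[(start, start + 1_199), (start + 1_800, end)],
                        cds_start=start,
                        cds_end=end,
                    )
                )

        chrom_vars = _draw_variants(genome_seq, n, config, rng, exclude_pos=exclude)
        if focal and config.causal:
            assert genome_seq[config.causal_pos - 1] == "G"
            chrom_vars[config.causal_pos] = ("G", "A")
        var_list.extend(
            (chrom, p, r, a) for p, (r, a) in sorted(chrom_vars.items())
        )
    return genome, genes, var_list


def simulate_f2(
    chroms: np.ndarray,
    positions: np.ndarray,
    causal_index: int | None,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """F2 genotypes and phenotypes.

    Each gamete is, per chromosome, a mosaic of the two parental
    haplotypes with crossover count ~ Poisson(genetic length) and
    uniform breakpoints (Haldane, no interference); chromosomes
    assort independently.  Dosage counts mutant-parent alleles (0/1/2);
    the phenotype is mutant iff dosage 2 at the causal locus (fully
    penetrant recessive).  With no causal locus the phenotype is an
    independent 1/4 Bernoulli draw (null design).
    """
    n_var = len(positions)
    morgans = config.chrom_length_bp / 1e6 * config.recomb_rate_cM_per_Mb / 100.0
    blocks = []  # (index array, positions) per chromosome
    for chrom in config.chromosomes:
        idx = np.flatnonzero(chroms == chrom)
        if len(idx):
            blocks.append((idx, positions[idx].astype(float)))
    dosages = np.zeros((config.n_f2, n_var), dtype=np.uint8)
    for i in range(config.n_f2):
        for _ in range(2):  # two gametes
            for idx, pos in blocks:
                k = rng.poisson(morgans)
                start = int(rng.integers(0, 2))
                if k == 0:
                    dosages[i, idx] += start
                else:
                    breaks = np.sort(rng.uniform(0, config.chrom_length_bp, size=k))
                    dosages[i, idx] += ((np.searchsorted(breaks, pos) + start) % 2).astype(
                        np.uint8
                    )
    if causal_index is not None:
        phenotypes = dosages[:, causal_index] == 2
    else:
        phenotypes = rng.random(config.n_f2) < 0.25
    return dosages, phenotypes


def simulate_pools(
    var_list: list[tuple[str, int, str, str]],
    dosages: np.ndarray,
    phenotypes: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Pooled-sequencing read counts for the four samples as VariantRecords."""
    mut_idx = np.flatnonzero(phenotypes)[: config.pool_size]
    wt_idx = np.flatnonzero(~phenotypes)[: config.pool_size]
    if len(mut_idx) < config.pool_size or len(wt_idx) < config.pool_size:
        raise ValueError(
            f"not enough individuals per phenotype class for pools of {config.pool_size}"
        )
    n_var = len(var_list)
    f_mut_pool = dosages[mut_idx].sum(axis=0) / (2 * config.pool_size)
    f_wt_pool = dosages[wt_idx].sum(axis=0) / (2 * config.pool_size)
    e = config.error_rate
    sample_freqs = {
        "mutant_parent": np.full(n_var, 1.0),
        "wildtype_parent": np.full(n_var, 0.0),
        "mutant_pool": f_mut_pool,
        "wildtype_pool": f_wt_pool,
    }
    means = {
        "mutant_parent": config.mean_depth_mutant_parent,
        "wildtype_parent": config.mean_depth_wildtype_parent,
        "mutant_pool": config.mean_depth_mutant_pool,
        "wildtype_pool": config.mean_depth_wildtype_pool,
    }
    counts = {}
    for role in sample_freqs:
        depth = rng.poisson(means[role], size=n_var)
        p_alt = sample_freqs[role] * (1 - e) + (1 - sample_freqs[role]) * e
        alt = rng.binomial(depth, p_alt)
        counts[role] = (depth - alt, alt)
    records = []
    for j, (chrom, pos, ref, alt_allele) in enumerate(var_list):
        sample_counts = {
            role: PoolCounts({ref: int(counts[role][0][j]), alt_allele: int(counts[role][1][j])})
            for role in sample_freqs
        }
        records.append(VariantRecord(chrom, pos, ref, alt_allele, sample_counts))
    return records


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: parents -> F2 -> pools."""
    rng = np.random.default_rng(config.seed)
    genome, genes, var_list = simulate_parents(config, rng)
    chroms = np.array([c for c, _, _, _ in var_list])
    positions = np.array([p for _, p, _, _ in var_list], dtype=np.int64)
    causal_index = None
    if config.causal:
        causal_index = int(
            np.flatnonzero((chroms == config.chrom) & (positions == config.causal_pos))[0]
        )
    dosages, phenotypes = simulate_f2(chroms, positions, causal_index, config, rng)
    records = simulate_pools(var_list, dosages, phenotypes, config, rng)
    truth = SimTruth(
        seed=config.seed,
        causal_pos=config.causal_pos if config.causal else None,
        causal_gene_id="causal_gene" if config.causal else None,
        phenotypes=[bool(x) for x in phenotypes],
    )
    return SimResult(
        config=config,
        genome=genome,
        genes=genes,
        variants=records,
        truth=truth,
        dosages=dosages,
        chroms=chroms,
        positions=positions,
    )


def write_outputs(sim: SimResult, outdir: str) -> None:
    """Emit genome.fa, genes.gff3, pools.vcf and truth.tsv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome, out / "genome.fa")
    write_gff3(sim.genes, out / "genes.gff3")
    write_vcf(sim.variants, out / "pools.vcf")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"seed\t{sim.truth.seed}\n")
        fh.write(f"causal_pos\t{sim.truth.causal_pos}\n")
        fh.write(f"causal_gene_id\t{sim.truth.causal_gene_id}\n")
        fh.write(f"variant_origin\t{sim.truth.variant_origin}\n")
        fh.write(
            "phenotypes\t" + ",".join("M" if p else "W" for p in sim.truth.phenotypes) + "\n"
        )


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
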