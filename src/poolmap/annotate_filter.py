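"""Positional effect annotation and the homozygous-differential filter.

The annotator assigns each variant one effect category per nearby gene
from strand-aware positional windows (donor/acceptor = first/last 2
intronic bases; splice region = exonic bases 1-3 or intronic bases 3-8
from a junction; 5-kb upstream/downstream flanks) and reports the
highest-priority category over all genes.  Window sizes follow the
conventions used by standard variant annotators.

The candidate filter encodes the expectation for a recessive causal
variant mapped in an F2 bulk design: the mutant parent and the
mutant-phenotype pool must be homozygous for the alternate allele, the
wild-type parent homozygous reference, while the wild-type-phenotype
pool may be heterozygous in aggregate (expected alt fraction 1/3, since
the dominant-phenotype pool mixes Aa and AA individuals 2:1).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .io_formats import GeneModel, PoolCounts, VariantRecord


class Effect(Enum):
    SPLICE_SITE_DONOR = 0
    SPLICE_SITE_ACCEPTOR = 1
    SPLICE_SITE_REGION = 2
    CODING = 3
    INTRON = 4
    UPSTREAM = 5
    DOWNSTREAM = 6
    INTRAGENIC = 7
    INTERGENIC = 8

    @property
    def priority(self) -> int:  # smaller = higher priority
        return self.value


DEFAULT_FLANK_BP = 5_000
DEFAULT_HOM_FRAC = 0.90
DEFAULT_MIN_DEPTH = 4


@dataclass
class EffectCall:
    gene_id: str | None
    category: Effect


class Genotype(Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    LOW_DEPTH = "LOW_DEPTH"


@dataclass
class GenotypeCall:
    role: str
    call: Genotype
    alt_fraction: float | None


def _category_for_gene(pos: int, g: GeneModel, flank_bp: int) -> Effect | None:
    """Effect of a position against one gene, or None if out of reach."""
    mrna_start, mrna_end = g.span
    if mrna_start <= pos <= mrna_end:
        introns = g.introns()
        for s, e in g.exons:
            if s <= pos <= e:
                # exonic bases 1-3 adjacent to a spliced junction
                dist_left = pos - s + 1   # 1 = first exon base
                dist_right = e - pos + 1
                left_is_junction = any(ie == s - 1 for _, ie in introns)
                right_is_junction = any(is_ == e + 1 for is_, _ in introns)
                if (left_is_junction and dist_left <= 3) or (right_is_junction and dist_right <= 3):
                    return Effect.SPLICE_SITE_REGION
                if g.cds_start <= pos <= g.cds_end:
                    return Effect.CODING
                return Effect.INTRAGENIC  # untranslated exon base
        for s, e in introns:
            if s <= pos <= e:
                # distances from the intron's 5' (donor) and 3' (acceptor)
                # ends in transcript orientation
                if g.strand == "+":
                    d5, d3 = pos - s + 1, e - pos + 1
                else:
                    d5, d3 = e - pos + 1, pos - s + 1
                if d5 <= 2:
                    return Effect.SPLICE_SITE_DONOR
                if d3 <= 2:
                    return Effect.SPLICE_SITE_ACCEPTOR
                if 3 <= d5 <= 8 or 3 <= d3 <= 8:
                    return Effect.SPLICE_SITE_REGION
                return Effect.INTRON
        return Effect.INTRAGENIC  # unreachable for a valid model
    if g.gene_start <= pos <= g.gene_end:
        return Effect.INTRAGENIC
    # strand-aware flanks
    if g.strand == "+":
        if 0 < g.gene_start - pos <= flank_bp:
            return Effect.UPSTREAM
        if 0 < pos - g.gene_end <= flank_bp:
            return Effect.DOWNSTREAM
    else:
        if 0 < pos - g.gene_end <= flank_bp:
            return Effect.UPSTREAM
        if 0 < g.gene_start - pos <= flank_bp:
            return Effect.DOWNSTREAM
    return None


def classify_effect(
    variant: VariantRecord,
    gene_models: list[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> EffectCall:
    """Highest-priority effect of a variant over all overlapping/nearby genes.

    Genes on other chromosomes or beyond the flank are ignored; with no
    gene in reach the variant is INTERGENIC.  Ties between genes are
    broken by gene id for determinism.
    """
    best: tuple[int, str] | None = None
    best_call: EffectCall | None = None
    for g in gene_models:
        if g.chrom != variant.chrom:
            continue
        cat = _category_for_gene(variant.pos, g, flank_bp)
        if cat is None:
            continue
        key = (cat.priority, g.gene_id)
        if best is None or key < best:
            best = key
            best_call = EffectCall(g.gene_id, cat)
    return best_call if best_call is not None else EffectCall(None, Effect.INTERGENIC)


def genotype_from_counts(
    counts: PoolCounts,
    ref_allele: str,
    alt_allele: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_frac: float = DEFAULT_HOM_FRAC,
    role: str = "",
) -> GenotypeCall:
    """Call HOM_REF / HET / HOM_ALT / LOW_DEPTH from ref/alt read counts.

    ``alt_fraction = alt / (ref + alt)``; HOM_ALT if it is >= hom_frac,
    HOM_REF if <= 1 - hom_frac, LOW_DEPTH if ref+alt < min_depth.
    """
    if not 0.5 < hom_frac <= 1:
        raise ValueError("hom_frac must be in (0.5, 1]")
    ref_n = counts.get(ref_allele)
    alt_n = counts.get(alt_allele)
    depth = ref_n + alt_n
    if depth < min_depth:
        return GenotypeCall(role, Genotype.LOW_DEPTH, None)
    af = alt_n / depth
    if af >= hom_frac:
        call = Genotype.HOM_ALT
    elif af <= 1 - hom_frac:
        call = Genotype.HOM_REF
    else:
        call = Genotype.HET
    return GenotypeCall(role, call, af)


def genotype_variant(
    variant: VariantRecord,
    role: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_frac: float = DEFAULT_HOM_FRAC,
) -> GenotypeCall:
    """Genotype one sample role of a variant (SNV or InDel pseudo-alleles)."""
    ref_n, alt_n = variant.ref_alt_counts(role)
    return genotype_from_counts(
        PoolCounts({"R": ref_n, "A": alt_n}), "R", "A",
        min_depth=min_depth, hom_frac=hom_frac, role=role,
    )


def homozygous_differential_filter(
    variants: list[VariantRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_frac: float = DEFAULT_HOM_FRAC,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Shortlist variants matching the recessive-causal genotype pattern.

    Keep a variant iff mutant_parent and mutant_pool are HOM_ALT,
    wildtype_parent is HOM_REF, and wildtype_pool is HET or HOM_REF.
    LOW_DEPTH in any required role drops the variant with a reason.
    Returns (survivors, dropped-with-reason).
    """
    survivors: list[VariantRecord] = []
    dropped: list[tuple[VariantRecord, str]] = []
    expectations = {
        "mutant_parent": {Genotype.HOM_ALT},
        "mutant_pool": {Genotype.HOM_ALT},
        "wildtype_parent": {Genotype.HOM_REF},
        "wildtype_pool": {Genotype.HET, Genotype.HOM_REF},
    }
    for v in variants:
        reason = None
        for role, allowed in expectations.items():
            gc = genotype_variant(v, role, min_depth, hom_frac)
            if gc.call is Genotype.LOW_DEPTH:
                reason = f"{role} below depth {min_depth}"
                break
            if gc.call not in allowed:
                reason = f"{role} is {gc.call.value}"
                break
        if reason is None:
            survivors.append(v)
        else:
            dropped.append((v, reason))
    return survivors, dropped


def rank_candidates(
    entries: list[tuple[VariantRecord, EffectCall, float]],
) -> list[tuple[VariantRecord, EffectCall, float]]:
    """Order shortlisted variants: effect priority, then ED descending,
    then position ascending."""
    return sorted(entries, key=lambda t: (t[1].category.priority, -t[2], t[0].pos))
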