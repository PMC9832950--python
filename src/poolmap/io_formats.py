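"""Readers and writers for the formats the mapping pipeline consumes.

Coordinate conventions
----------------------
All coordinates crossing a file boundary (VCF, GFF3, TSV reports) are
1-based, fully closed, matching the conventions of those formats.  All
internal interval arithmetic is 0-based half-open.  :func:`to_internal`
and :func:`to_external` are exact inverses.

The four sample roles
---------------------
A pooled-mapping experiment has exactly four samples: the homozygous
mutant parent, the wild-type parent, a pool of mutant-phenotype F2
individuals, and a pool of wild-type-phenotype F2 individuals.  Roles
are always assigned explicitly by name (never by VCF column order) so a
swapped pool cannot silently invert the genome scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from cyvcf2 import VCF

log = logging.getLogger(__name__)

SAMPLE_ROLES = ("mutant_parent", "wildtype_parent", "mutant_pool", "wildtype_pool")

#: pseudo-allele labels used for InDel read counts (ref- and alt-supporting)
INDEL_REF = "REF"
INDEL_ALT = "ALT"

_NUCS = set("ACGT")


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based closed interval -> 0-based half-open."""
    return start - 1, end


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based closed."""
    return start0 + 1, end0


@dataclass
class PoolCounts:
    """Per-site read counts for one sample.

    For SNVs the keys are nucleotides (absent nucleotides count 0); for
    InDels the two pseudo-alleles ``REF`` and ``ALT`` hold the ref- and
    alt-supporting read counts.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for allele, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative read count {n} for allele {allele!r}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def get(self, allele: str) -> int:
        return self.counts.get(allele, 0)


@dataclass
class VariantRecord:
    """One biallelic variant with per-role read counts.

    ``pos`` is the 1-based reference position.  ``variant_class`` is
    ``"SNP"`` iff both alleles are single nucleotides, else ``"INDEL"``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_counts: dict[str, PoolCounts]
    variant_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - _NUCS:
                raise ValueError(f"allele {allele!r} must be a non-empty ACGT string")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        self.variant_class = (
            "SNP" if len(self.ref_allele) == 1 == len(self.alt_allele) else "INDEL"
        )
        missing = [r for r in SAMPLE_ROLES if r not in self.sample_counts]
        if missing:
            raise ValueError(f"missing sample roles: {missing}")

    def counts_for(self, role: str) -> PoolCounts:
        return self.sample_counts[role]

    def ref_alt_counts(self, role: str) -> tuple[int, int]:
        """(ref-supporting, alt-supporting) read counts for one role."""
        pc = self.sample_counts[role]
        if self.variant_class == "SNP":
            return pc.get(self.ref_allele), pc.get(self.alt_allele)
        return pc.get(INDEL_REF), pc.get(INDEL_ALT)


@dataclass
class GeneModel:
    """Strand-aware exon/intron/CDS structure of one gene (one mRNA).

    Exons are 1-based closed genomic intervals sorted by position and
    non-overlapping; intron *i* is the gap between exon *i* and *i+1*.
    ``cds_start``/``cds_end`` are genomic bounds of the coding region and
    must fall inside the exon union.  ``gene_start``/``gene_end`` may
    widen the span beyond the mRNA (positions there are intragenic).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    gene_start: int | None = None
    gene_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: exons overlap ({s1}-{e1}, {s2}-{e2})")
            if s2 - e1 - 1 < 4:
                raise ValueError(f"gene {self.gene_id}: intron shorter than 4 bp")
        self.exons = exons
        if not self._inside_exons(self.cds_start) or not self._inside_exons(self.cds_end):
            raise ValueError(f"gene {self.gene_id}: CDS bounds outside exon union")
        if self.gene_start is None:
            self.gene_start = exons[0][0]
        if self.gene_end is None:
            self.gene_end = exons[-1][1]

    def _inside_exons(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """mRNA span (first exon start, last exon end), 1-based closed."""
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Introns in genomic order, 1-based closed."""
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def introns_transcript_order(self) -> list[tuple[int, int]]:
        ivs = self.introns()
        return ivs if self.strand == "+" else ivs[::-1]

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]


# ---------------------------------------------------------------------------
# VCF


class VcfFormatError(ValueError):
    pass


def read_vcf(
    path: str,
    sample_role_map: dict[str, str],
    split_multiallelic: bool = False,
) -> list[VariantRecord]:
    """Read a VCF v4.2 with per-sample AD into :class:`VariantRecord` s.

    Parameters
    ----------
    sample_role_map
        Maps each of the four roles to a VCF sample name.
    split_multiallelic
        If True, a multi-allelic record is split into one biallelic
        record per ALT (AD columns 0 and i); otherwise such records are
        skipped with a log message.
    """
    unknown = set(sample_role_map) - set(SAMPLE_ROLES)
    if unknown:
        raise VcfFormatError(f"unknown sample roles in config: {sorted(unknown)}")
    missing = set(SAMPLE_ROLES) - set(sample_role_map)
    if missing:
        raise VcfFormatError(f"sample roles not configured: {sorted(missing)}")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for role, name in sample_role_map.items():
        if name not in samples:
            raise VcfFormatError(f"sample {name!r} (role {role}) absent from VCF")
    col = {role: samples.index(name) for role, name in sample_role_map.items()}

    records: list[VariantRecord] = []
    n_skipped = 0
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            bad = sample_role_map["mutant_parent"]
            raise VcfFormatError(
                f"record {v.CHROM}:{v.POS} lacks the AD FORMAT field "
                f"(first configured sample: {bad!r})"
            )
        alts = v.ALT
        if len(alts) != 1 and not split_multiallelic:
            n_skipped += 1
            log.info("skipping multi-allelic record %s:%d", v.CHROM, v.POS)
            continue
        for ai, alt in enumerate(alts, start=1):
            try:
                records.append(
                    _make_record(v.CHROM, v.POS, v.REF, alt, ad, col, alt_index=ai)
                )
            except ValueError as exc:
                log.warning("skipping record %s:%d: %s", v.CHROM, v.POS, exc)
    if n_skipped:
        log.info("skipped %d multi-allelic records", n_skipped)
    return records


def _make_record(chrom, pos, ref, alt, ad, col, alt_index=1) -> VariantRecord:
    is_snp = len(ref) == 1 == len(alt)
    sample_counts = {}
    for role, ci in col.items():
        ref_n = max(int(ad[ci][0]), 0)  # cyvcf2 encodes missing as negative
        alt_n = max(int(ad[ci][alt_index]), 0)
        if is_snp:
            counts = {ref: ref_n, alt: alt_n}
        else:
            counts = {INDEL_REF: ref_n, INDEL_ALT: alt_n}
        sample_counts[role] = PoolCounts(counts)
    return VariantRecord(chrom, int(pos), ref, alt, sample_counts)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    records: list[VariantRecord],
    path: str,
    sample_role_map: dict[str, str] | None = None,
) -> None:
    """Write records as a minimal VCF v4.2 (GT unset, AD populated).

    Output is deterministic: write -> read -> write is byte-identical.
    """
    if sample_role_map is None:
        sample_role_map = {r: r for r in SAMPLE_ROLES}
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        names = [sample_role_map[r] for r in SAMPLE_ROLES]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for rec in records:
            cols = [rec.chrom, str(rec.pos), ".", rec.ref_allele, rec.alt_allele, ".", ".", ".", "GT:AD"]
            for role in SAMPLE_ROLES:
                ref_n, alt_n = rec.ref_alt_counts(role)
                cols.append(f"./.:{ref_n},{alt_n}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` s.

    One mRNA per gene is used (the first encountered, logged if several).
    Genes whose CDS falls outside the exon union, or with overlapping
    exons, are rejected with a warning rather than aborting the run.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            log.warning("gene %s has no mRNA; skipped", gene.id)
            continue
        if len(mrnas) > 1:
            log.info("gene %s has %d mRNAs; using the first", gene.id, len(mrnas))
        mrna = mrnas[0]
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon", order_by="start")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS", order_by="start")]
        if not exons or not cds:
            log.warning("gene %s lacks exon or CDS features; skipped", gene.id)
            continue
        cds_start = min(s for s, _ in cds)
        cds_end = max(e for _, e in cds)
        try:
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    gene_start=gene.start,
                    gene_end=gene.end,
                )
            )
        except ValueError as exc:
            log.warning("rejecting gene %s: %s", gene.id, exc)
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            span = (g.gene_start, g.gene_end)
            fh.write(
                f"{g.chrom}\tpoolmap\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            s, e = g.span
            fh.write(
                f"{g.chrom}\tpoolmap\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tpoolmap\texon\t{es}\t{ee}\t.\t{g.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
                cs = max(es, g.cds_start)
                ce = min(ee, g.cds_end)
                if cs <= ce:
                    fh.write(
                        f"{g.chrom}\tpoolmap\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA and reports


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA into {chrom: uppercase sequence}; duplicate ids error."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


REGION_COLUMNS = ["Variant", "Chromosome_ID", "Start", "End", "Size_Mb", "N_variants", "N_genes"]


def write_regions_report(regions, path: str, variant_label: str = "SNP") -> None:
    """Candidate-region TSV: one row per region (columns as headers above)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                f"{variant_label}\t{r.chrom}\t{r.start}\t{r.end}\t{r.size_mb:.2f}\t{r.n_variants}\t{r.n_genes}\n"
            )


SHORTLIST_COLUMNS = [
    "Gene_ID", "Chromosome_ID", "Position", "Ref", "Alt",
    "mutant_parent", "wildtype_parent", "mutant_pool", "wildtype_pool",
    "Effect", "ED",
]


def write_shortlist_report(rows: list[dict], path: str) -> None:
    """Candidate-variant shortlist TSV mirroring the per-sample depth table."""
    with open(path, "w") as fh:
        fh.write("\t".join(SHORTLIST_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in SHORTLIST_COLUMNS) + "\n")
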