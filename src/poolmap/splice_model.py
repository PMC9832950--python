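"""Mis-splicing consequences of a broken 5' splice-donor site.

When the donor dinucleotide at an intron's 5' end is mutated, U1 snRNP
no longer recognises the junction.  The two outcomes modelled here are
the ones seen in EMS splice-donor mutants:

* **intron retention (IR)** — the intron stays in the mature transcript;
  the reading frame runs into the intron and usually hits a premature
  stop, truncating the protein;
* **cryptic donor / partial exon deletion (PED)** — U1 engages a
  canonical GT inside the upstream exon, splicing out the exon's 3'
  tail together with the intron.  If the deleted tail length is a
  multiple of 3 the protein carries a clean internal deletion.

The engine works in transcript orientation on either strand, rebuilds
each alternative CDS from the genome sequence, translates it, and
classifies the protein change relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq

from .io_formats import GeneModel

DEFAULT_SCAN_BP = 200


class TranscriptKind(Enum):
    REFERENCE = "REFERENCE"
    INTRON_RETENTION = "INTRON_RETENTION"
    CRYPTIC_DONOR = "CRYPTIC_DONOR"


class DiffType(Enum):
    IDENTICAL = "IDENTICAL"
    TRUNCATION = "TRUNCATION"
    INTERNAL_DELETION = "INTERNAL_DELETION"
    OTHER = "OTHER"


@dataclass
class TranscriptVariant:
    kind: TranscriptKind
    spliced_cds: str
    protein: str
    premature_stop: bool
    no_stop: bool = False
    deletion_bp: int = 0


@dataclass
class ProteinDiff:
    shared_prefix_aa: int
    type: DiffType
    aa_removed: int


def _segment_sequence(genome_seq: str, segments: list[tuple[int, int]], strand: str) -> str:
    """Concatenate 1-based closed genomic segments; reverse-complement on '-'."""
    s = "".join(genome_seq[a - 1 : b] for a, b in segments)
    return str(Seq(s).reverse_complement()) if strand == "-" else s


def _transcript_index(segments: list[tuple[int, int]], strand: str, pos: int) -> int:
    """Transcript-string index of genomic position ``pos`` (must lie in a segment)."""
    total = sum(b - a + 1 for a, b in segments)
    offset = 0
    for a, b in segments:
        if a <= pos <= b:
            plus_idx = offset + (pos - a)
            return plus_idx if strand == "+" else total - 1 - plus_idx
        offset += b - a + 1
    raise ValueError(f"position {pos} not covered by transcript segments")


def build_reference_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Spliced coding sequence of a gene, 5'->3' in transcript orientation."""
    seq = genome[gene.chrom]
    pieces = []
    for s, e in gene.exons:
        cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
        if cs <= ce:
            pieces.append((cs, ce))
    cds = _segment_sequence(seq, pieces, gene.strand)
    if len(cds) < 3:
        raise ValueError(f"gene {gene.gene_id}: CDS shorter than one codon")
    return cds


def translate_cds(cds: str) -> tuple[str, bool, bool]:
    """Translate with the standard genetic code.

    Returns ``(protein, premature_stop, no_stop)``.  Translation stops
    at the first stop codon (excluded from the protein);
    ``premature_stop`` is True iff that stop precedes the final codon;
    with no stop anywhere the full-length protein is returned with
    ``no_stop`` set.  Ambiguity codes are rejected.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    n_codons = len(cds) // 3
    aa = str(Seq(cds[: n_codons * 3]).translate())
    stop_idx = aa.find("*")
    if stop_idx == -1:
        return aa, False, True
    return aa[:stop_idx], stop_idx < n_codons - 1, False


def _extract_and_translate(
    kind: TranscriptKind,
    genome_seq: str,
    segments: list[tuple[int, int]],
    gene: GeneModel,
    deletion_bp: int = 0,
) -> TranscriptVariant:
    transcript = _segment_sequence(genome_seq, segments, gene.strand)
    cds5 = gene.cds_start if gene.strand == "+" else gene.cds_end
    cds3 = gene.cds_end if gene.strand == "+" else gene.cds_start
    i5 = _transcript_index(segments, gene.strand, cds5)
    i3 = _transcript_index(segments, gene.strand, cds3)
    cds = transcript[i5 : i3 + 1]
    protein, premature, no_stop = translate_cds(cds)
    return TranscriptVariant(
        kind=kind,
        spliced_cds=cds,
        protein=protein,
        premature_stop=premature,
        no_stop=no_stop,
        deletion_bp=deletion_bp,
    )


def predict_donor_mutation_consequences(
    gene: GeneModel,
    genome: dict[str, str],
    intron_index: int,
    scan_bp: int = DEFAULT_SCAN_BP,
) -> list[TranscriptVariant]:
    """Enumerate transcripts produced when donor ``intron_index`` is broken.

    ``intron_index`` counts introns 1-based in transcript orientation.
    The result always contains the REFERENCE transcript and the
    INTRON_RETENTION outcome; additionally one CRYPTIC_DONOR outcome per
    canonical GT dinucleotide found in the upstream exon within
    ``scan_bp`` of the broken junction, nearest-first.
    """
    introns_t = gene.introns_transcript_order()
    if not 1 <= intron_index <= len(introns_t):
        raise ValueError(f"intron_index {intron_index} out of range 1..{len(introns_t)}")
    if scan_bp <= 0:
        raise ValueError("scan_bp must be > 0")
    seq = genome[gene.chrom]

    n_introns = len(introns_t)
    gidx = intron_index - 1 if gene.strand == "+" else n_introns - intron_index
    results = [_extract_and_translate(TranscriptKind.REFERENCE, seq, list(gene.exons), gene)]

    # intron retention: fuse exons flanking the genomic intron gidx
    ir_segments = (
        gene.exons[:gidx]
        + [(gene.exons[gidx][0], gene.exons[gidx + 1][1])]
        + gene.exons[gidx + 2 :]
    )
    results.append(
        _extract_and_translate(TranscriptKind.INTRON_RETENTION, seq, ir_segments, gene)
    )

    # cryptic donors: canonical GT in the upstream exon (transcript
    # orientation) within scan_bp of the broken junction
    up_gidx = gidx if gene.strand == "+" else gidx + 1
    ua, ub = gene.exons[up_gidx]
    exon_seq = _segment_sequence(seq, [(ua, ub)], gene.strand)
    m = len(exon_seq)
    hits = []  # tail length removed, largest j (= smallest tail) first
    for j in range(m - 2, -1, -1):
        tail = m - j
        if tail > scan_bp:
            break
        if exon_seq[j : j + 2] == "GT":
            hits.append(tail)
    ref_cds_len = len(results[0].spliced_cds)
    for tail in hits:
        keep = m - tail
        if keep == 0:
            continue  # whole exon would vanish; not a partial deletion
        if gene.strand == "+":
            trunc = (ua, ua + keep - 1)
        else:
            trunc = (ub - keep + 1, ub)
        segments = gene.exons[:up_gidx] + [trunc] + gene.exons[up_gidx + 1 :]
        tv = _extract_and_translate(TranscriptKind.CRYPTIC_DONOR, seq, segments, gene)
        tv.deletion_bp = ref_cds_len - len(tv.spliced_cds)
        results.append(tv)
    return results


def diff_proteins(reference: str, variant: str) -> ProteinDiff:
    """Classify the protein change: identical, C-terminal truncation,
    contiguous internal deletion, or other."""
    if not reference or not variant:
        raise ValueError("both proteins must be non-empty")
    lcp = 0
    for a, b in zip(reference, variant):
        if a != b:
            break
        lcp += 1
    if reference == variant:
        return ProteinDiff(lcp, DiffType.IDENTICAL, 0)
    if len(variant) < len(reference):
        if lcp == len(variant):
            return ProteinDiff(lcp, DiffType.TRUNCATION, len(reference) - len(variant))
        lcs = 0
        for a, b in zip(reversed(reference), reversed(variant)):
            if a != b:
                break
            lcs += 1
        if lcp + lcs >= len(variant):
            return ProteinDiff(lcp, DiffType.INTERNAL_DELETION, len(reference) - len(variant))
    return ProteinDiff(lcp, DiffType.OTHER, 0)
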