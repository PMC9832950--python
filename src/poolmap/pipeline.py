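"""End-to-end orchestration: simulate/ingest -> scan -> filter -> splice.

A run consumes either real inputs (VCF + GFF3 + FASTA + role map) or a
simulation block, executes the Euclidean-distance scan, delimits
candidate regions, shortlists variants with the homozygous-differential
filter, ranks them by effect severity, and — when the top candidate
breaks a splice donor — predicts the mis-splicing transcripts.  Every
product is written next to a resolved copy of the configuration, and
``report.json`` is bit-identical across reruns of the same (config,
seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import annotate_filter as af
from . import ed_scan, splice_model
from .io_formats import (
    GeneModel,
    VariantRecord,
    read_fasta,
    read_gff3,
    read_vcf,
    write_regions_report,
    write_shortlist_report,
)
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger(__name__)

DEFAULT_SCAN_PARAMS = {
    "window_bp": ed_scan.DEFAULT_WINDOW_BP,
    "k": ed_scan.DEFAULT_K,
    "min_depth": ed_scan.DEFAULT_MIN_DEPTH,
    "min_variants": ed_scan.DEFAULT_MIN_VARIANTS,
    "merge_gap_bp": ed_scan.DEFAULT_MERGE_GAP_BP,
}
DEFAULT_FILTER_PARAMS = {
    "hom_frac": af.DEFAULT_HOM_FRAC,
    "min_depth": af.DEFAULT_MIN_DEPTH,
    "flank_bp": af.DEFAULT_FLANK_BP,
}
DEFAULT_SPLICE_PARAMS = {"scan_bp": splice_model.DEFAULT_SCAN_BP}


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    params: dict
    n_variants_read: int
    n_variants_scanned: int
    threshold: float
    regions: list[dict]
    top_region: dict | None
    n_filter_survivors: int
    shortlist: list[dict]
    top_candidate: dict | None
    transcripts: list[dict]
    timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("timings_s")  # wall-clock noise stays out of the reproducible report
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _donor_intron_index(gene: GeneModel, pos: int) -> int | None:
    """1-based transcript-order index of the intron whose donor dinucleotide
    covers ``pos``, if any."""
    for ti, (s, e) in enumerate(gene.introns_transcript_order(), start=1):
        donor = (s, s + 1) if gene.strand == "+" else (e - 1, e)
        if donor[0] <= pos <= donor[1]:
            return ti
    return None


def _region_dict(r: ed_scan.CandidateRegion) -> dict:
    return {
        "chrom": r.chrom,
        "start": r.start,
        "end": r.end,
        "size_mb": r.size_mb,
        "n_variants": r.n_variants,
        "n_genes": r.n_genes,
    }


def run_pipeline(config: dict, outdir: str | None = None) -> RunReport:
    """Execute all stages; see the module docstring.

    ``config`` has optional sections ``simulate`` (SimConfig fields) or
    ``inputs`` (vcf/gff/fasta paths + ``roles``), and ``scan`` /
    ``filter`` / ``splice`` parameter overrides.
    """
    timings: dict[str, float] = {}
    scan_p = {**DEFAULT_SCAN_PARAMS, **config.get("scan", {})}
    filt_p = {**DEFAULT_FILTER_PARAMS, **config.get("filter", {})}
    splice_p = {**DEFAULT_SPLICE_PARAMS, **config.get("splice", {})}

    t0 = time.perf_counter()
    genome: dict[str, str] | None = None
    if "simulate" in config:
        sim_config = SimConfig(**config["simulate"])
        sim = simulate_dataset(sim_config)
        variants, genes, genome = sim.variants, sim.genes, sim.genome
        resolved_inputs = {"simulate": asdict(sim_config)}
    elif "inputs" in config:
        inp = config["inputs"]
        variants = read_vcf(inp["vcf"], inp["roles"], inp.get("split_multiallelic", False))
        genes = read_gff3(inp["gff"]) if inp.get("gff") else []
        genome = read_fasta(inp["fasta"]) if inp.get("fasta") else None
        resolved_inputs = {"inputs": dict(inp)}
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' section")
    timings["acquire"] = time.perf_counter() - t0
    log.info("stage acquire: %d variants, %d genes", len(variants), len(genes))

    t0 = time.perf_counter()
    points = ed_scan.scan_profile(variants, min_depth=scan_p["min_depth"])
    points = ed_scan.fit_profile(points, window_bp=scan_p["window_bp"], k=scan_p["k"])
    threshold = ed_scan.compute_threshold(points)
    regions = ed_scan.call_regions(
        points,
        threshold,
        min_variants=scan_p["min_variants"],
        merge_gap_bp=scan_p["merge_gap_bp"],
        gene_models=genes,
    )
    timings["edscan"] = time.perf_counter() - t0
    log.info("stage edscan: %d scanned, threshold %.4f, %d regions",
             len(points), threshold, len(regions))

    # top region = the one holding the global maximum of the fitted profile
    top_region = None
    if regions:
        peak = {}
        for r in regions:
            inside = points[
                (points["chrom"] == r.chrom)
                & points["pos"].between(r.start, r.end)
            ]["ed_fitted"]
            peak[(r.chrom, r.start)] = float(inside.max()) if len(inside) else 0.0
        top_region = max(regions, key=lambda r: peak[(r.chrom, r.start)])

    t0 = time.perf_counter()
    in_region = [
        v for v in variants
        if any(r.chrom == v.chrom and r.contains(v.pos) for r in regions)
    ]
    survivors, dropped = af.homozygous_differential_filter(
        in_region, min_depth=filt_p["min_depth"], hom_frac=filt_p["hom_frac"]
    )
    ed_by_site = {(c, p): e for c, p, e in zip(points["chrom"], points["pos"], points["ed"])}
    entries = []
    for v in survivors:
        call = af.classify_effect(v, genes, flank_bp=filt_p["flank_bp"])
        entries.append((v, call, ed_by_site.get((v.chrom, v.pos), 0.0)))
    ranked = af.rank_candidates(entries)
    timings["annotate"] = time.perf_counter() - t0
    log.info("stage annotate: %d in regions, %d survivors, %d dropped",
             len(in_region), len(survivors), len(dropped))

    shortlist_rows = []
    for v, call, ed in ranked:
        row = {
            "Gene_ID": call.gene_id or ".",
            "Chromosome_ID": v.chrom,
            "Position": v.pos,
            "Ref": v.ref_allele,
            "Alt": v.alt_allele,
            "Effect": call.category.name,
            "ED": round(ed, 5),
        }
        for role in ("mutant_parent", "wildtype_parent", "mutant_pool", "wildtype_pool"):
            r, a = v.ref_alt_counts(role)
            row[role] = f"{r},{a}"
        shortlist_rows.append(row)

    t0 = time.perf_counter()
    transcripts: list[dict] = []
    top_candidate = shortlist_rows[0] if shortlist_rows else None
    if (
        top_candidate
        and top_candidate["Effect"] == "SPLICE_SITE_DONOR"
        and genome is not None
    ):
        v, call, _ = ranked[0]
        gene = next(g for g in genes if g.gene_id == call.gene_id)
        ti = _donor_intron_index(gene, v.pos)
        if ti is not None:
            for tv in splice_model.predict_donor_mutation_consequences(
                gene, genome, ti, scan_bp=splice_p["scan_bp"]
            ):
                transcripts.append(
                    {
                        "kind": tv.kind.value,
                        "cds_bp": len(tv.spliced_cds),
                        "protein_aa": len(tv.protein),
                        "premature_stop": tv.premature_stop,
                        "deletion_bp": tv.deletion_bp,
                    }
                )
    timings["splice"] = time.perf_counter() - t0

    report = RunReport(
        params={
            **resolved_inputs,
            "scan": scan_p,
            "filter": filt_p,
            "splice": splice_p,
        },
        n_variants_read=len(variants),
        n_variants_scanned=len(points),
        threshold=threshold,
        regions=[_region_dict(r) for r in regions],
        top_region=_region_dict(top_region) if top_region else None,
        n_filter_survivors=len(survivors),
        shortlist=shortlist_rows,
        top_candidate=top_candidate,
        transcripts=transcripts,
        timings_s=timings,
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        points.to_csv(out / "points.tsv", sep="\t", index=False)
        write_regions_report(regions, out / "regions.tsv")
        write_shortlist_report(shortlist_rows, out / "shortlist.tsv")
        with open(out / "transcripts.tsv", "w") as fh:
            fh.write("kind\tcds_bp\tprotein_aa\tpremature_stop\tdeletion_bp\n")
            for t in transcripts:
                fh.write(
                    f"{t['kind']}\t{t['cds_bp']}\t{t['protein_aa']}\t"
                    f"{t['premature_stop']}\t{t['deletion_bp']}\n"
                )
        (out / "report.json").write_text(report.to_json() + "\n")
        import yaml

        (out / "resolved_config.yaml").write_text(
            yaml.safe_dump(report.params, sort_keys=True)
        )
    return report
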