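"""Euclidean-distance genome scan on pooled allele frequencies.

For each variant, the two phenotype pools give a vector of nucleotide
frequencies (A, C, G, T for SNVs; two pseudo-alleles for InDels).  The
scan statistic is the Euclidean distance

    ED = sqrt( sum_b (f_mut[b] - f_wt[b])^2 )

which is ~0 at sites unlinked to the causal locus and approaches the
maximum sqrt(2) where the pools are fixed for different alleles.  The
raw per-variant profile is noisy at 20-60x pool depth, so it is smoothed
per chromosome with a tricube-weighted sliding mean of ED^k, a
significance threshold is drawn at median + 3 x sample SD of the fitted
values, and maximal above-threshold runs become candidate regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, VariantRecord, PoolCounts

ED_MAX = math.sqrt(2.0)

#: default half-window comes from this full window (bp) for the smoother
DEFAULT_WINDOW_BP = 2_000_000
DEFAULT_K = 1
DEFAULT_MIN_DEPTH = 4
DEFAULT_MIN_VARIANTS = 10
DEFAULT_MERGE_GAP_BP = 100_000
REGION_GRID_BP = 10_000


@dataclass
class FrequencyVector:
    """Allele-frequency vector for one sample at one site.

    ``freq`` maps allele label -> frequency; components sum to 1 when
    the site is usable (depth >= min_depth).
    """

    freq: dict[str, float]
    depth: int
    usable: bool


@dataclass
class CandidateRegion:
    """Contiguous above-threshold interval (1-based closed bounds)."""

    chrom: str
    start: int
    end: int
    n_variants: int
    n_genes: int = 0
    size_mb: float = field(init=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        self.size_mb = region_size_mb(self)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def allele_frequencies(counts: PoolCounts, min_depth: int = DEFAULT_MIN_DEPTH) -> FrequencyVector:
    """Convert read counts to a frequency vector.

    Sites with total depth below ``min_depth`` (including depth 0) are
    flagged unusable; no division by zero can occur.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = counts.depth
    if depth < min_depth:
        return FrequencyVector({a: 0.0 for a in counts.counts}, depth, usable=False)
    return FrequencyVector({a: n / depth for a, n in counts.counts.items()}, depth, usable=True)


def ed_statistic(f_mut: FrequencyVector, f_wt: FrequencyVector) -> float:
    """Euclidean distance between two pool frequency vectors.

    Symmetric in its arguments; both vectors must live on the same
    allele space (SNV nucleotides vs InDel pseudo-alleles).
    """
    if not (f_mut.usable and f_wt.usable):
        raise ValueError("ed_statistic requires two usable frequency vectors")
    if set(f_mut.freq) != set(f_wt.freq):
        raise ValueError(
            f"mismatched allele spaces: {sorted(f_mut.freq)} vs {sorted(f_wt.freq)}"
        )
    return math.sqrt(sum((f_mut.freq[a] - f_wt.freq[a]) ** 2 for a in f_mut.freq))


def scan_profile(
    variants: list[VariantRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    variant_class: str | None = None,
) -> pd.DataFrame:
    """Per-variant ED track as a DataFrame (chrom, pos, ed, variant_class).

    Variants where either pool is below ``min_depth`` are excluded.
    Rows are sorted by (chrom, pos).
    """
    rows = []
    for v in variants:
        if variant_class is not None and v.variant_class != variant_class:
            continue
        f_mut = allele_frequencies(v.counts_for("mutant_pool"), min_depth)
        f_wt = allele_frequencies(v.counts_for("wildtype_pool"), min_depth)
        if not (f_mut.usable and f_wt.usable):
            continue
        rows.append((v.chrom, v.pos, ed_statistic(f_mut, f_wt), v.variant_class))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ed", "variant_class"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def fit_profile(points: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP, k: int = DEFAULT_K) -> pd.DataFrame:
    """Smooth the ED track: tricube-weighted sliding mean of ed**k.

    For each variant, neighbours on the same chromosome within
    +/- window_bp/2 contribute with tricube weight
    ``(1 - (d/h)^3)^3`` where ``h = window_bp / 2``.  The variant itself
    always contributes (weight 1), so an isolated variant's fitted value
    is its own ed**k.  No bleed across chromosomes.

    Returns a copy with an ``ed_fitted`` column.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    out = points.copy()
    out["ed_fitted"] = np.nan
    h = window_bp / 2.0
    for _, idx in out.groupby("chrom", sort=False).groups.items():
        pos = out.loc[idx, "pos"].to_numpy(dtype=float)
        val = out.loc[idx, "ed"].to_numpy(dtype=float) ** k
        lo = np.searchsorted(pos, pos - h, side="left")
        hi = np.searchsorted(pos, pos + h, side="right")
        fitted = np.empty_like(val)
        for i in range(len(pos)):
            d = np.abs(pos[lo[i] : hi[i]] - pos[i])
            w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
            sw = w.sum()
            fitted[i] = (w * val[lo[i] : hi[i]]).sum() / sw if sw > 0 else val[i]
        out.loc[idx, "ed_fitted"] = fitted
    return out


def compute_threshold(points: pd.DataFrame, column: str = "ed") -> float:
    """Genome-wide significance threshold: median + 3 x sample SD (ddof=1).

    By default the statistic is computed over the raw per-variant ED
    values; the fitted profile is then compared against it.  Computing
    the spread on the raw track keeps the read-sampling noise in the SD
    term, which holds the threshold above the smooth drift bumps that a
    finite pool produces even with no causal locus (the fitted track
    averages that noise away and its 3-SD band collapses onto the drift
    amplitude).  Pass ``column="ed_fitted"`` for the fitted-track
    variant.
    """
    vals = points[column].to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("compute_threshold needs at least 2 points")
    return float(np.median(vals) + 3.0 * np.std(vals, ddof=1))


def _snap_outward(start: int, end: int, grid: int = REGION_GRID_BP) -> tuple[int, int]:
    return (start // grid) * grid, math.ceil(end / grid) * grid


def call_regions(
    points: pd.DataFrame,
    threshold: float,
    min_variants: int = DEFAULT_MIN_VARIANTS,
    merge_gap_bp: int = DEFAULT_MERGE_GAP_BP,
    gene_models: list[GeneModel] | None = None,
) -> list[CandidateRegion]:
    """Delimit candidate regions from the fitted profile.

    Maximal runs of consecutive variants with ``ed_fitted >= threshold``
    (ties inclusive) are found per chromosome; runs separated by less
    than ``merge_gap_bp`` are merged; merged runs with fewer than
    ``min_variants`` above-threshold variants are dropped.  Region
    bounds are the first/last above-threshold variant positions snapped
    outward to the 10-kb grid.  ``n_genes`` counts gene models whose
    span overlaps the region.
    """
    regions: list[CandidateRegion] = []
    for chrom, grp in points.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        above = grp["ed_fitted"].to_numpy() >= threshold
        runs: list[tuple[int, int, int]] = []  # (first_pos, last_pos, n_above)
        i = 0
        n = len(pos)
        while i < n:
            if above[i]:
                j = i
                while j + 1 < n and above[j + 1]:
                    j += 1
                runs.append((int(pos[i]), int(pos[j]), j - i + 1))
                i = j + 1
            else:
                i += 1
        merged: list[list[int]] = []
        for first, last, cnt in runs:
            if merged and first - merged[-1][1] < merge_gap_bp:
                merged[-1][1] = last
                merged[-1][2] += cnt
            else:
                merged.append([first, last, cnt])
        for first, last, cnt in merged:
            if cnt < min_variants:
                continue
            start, end = _snap_outward(first, last)
            n_genes = 0
            if gene_models:
                n_genes = sum(
                    1
                    for g in gene_models
                    if g.chrom == chrom and g.gene_start <= end and g.gene_end >= start
                )
            regions.append(CandidateRegion(chrom, start, end, cnt, n_genes))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def region_size_mb(region) -> float:
    """Region size in Mb, rounded half-up to 2 decimals."""
    from decimal import Decimal, ROUND_HALF_UP

    mb = Decimal(region.end - region.start) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
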