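"""Segregation-ratio tests and CAPS/dCAPS digest distinguishability.

A monogenic recessive trait segregates 3:1 in an F2; the goodness-of-fit
chi-square (1 df, Yates continuity correction by default) tests observed
phenotype counts against that expectation.  The digest logic models a
CAPS/dCAPS genotyping assay: a SNP creating or destroying a restriction
site is scored by whether the two alleles' PCR amplicons yield different
fragment-length patterns after digestion.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist


@dataclass
class SegregationResult:
    n_dominant: int
    n_recessive: int
    expected_ratio: tuple[float, float]
    chi_square: float
    critical_value: float
    consistent: bool


@dataclass
class DigestResult:
    fragments_ref: list[int]
    fragments_alt: list[int]
    distinguishable: bool


def segregation_chi_square(
    n_dominant: int,
    n_recessive: int,
    ratio: tuple[float, float] = (3, 1),
    yates: bool = True,
    alpha: float = 0.05,
) -> SegregationResult:
    """Chi-square goodness-of-fit of phenotype counts to a Mendelian ratio.

    With ``yates=True`` (default for this 1-df test) each deviation is
    shrunk by 0.5 before squaring: sum(max(|O-E| - 0.5, 0)^2 / E).  The
    critical value is the 1-df chi-square quantile at ``1 - alpha``.
    """
    if n_dominant < 0 or n_recessive < 0 or n_dominant + n_recessive == 0:
        raise ValueError("counts must be nonnegative with positive total")
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("ratio parts must be positive")
    total = n_dominant + n_recessive
    share = ratio[0] / (ratio[0] + ratio[1])
    expected = (total * share, total * (1 - share))
    if min(expected) == 0:
        raise ValueError("zero expected count")
    observed = (n_dominant, n_recessive)
    if yates:
        stat = sum(max(abs(o - e) - 0.5, 0.0) ** 2 / e for o, e in zip(observed, expected))
    else:
        stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    crit = float(_chi2_dist.ppf(1 - alpha, df=1))
    return SegregationResult(
        n_dominant=n_dominant,
        n_recessive=n_recessive,
        expected_ratio=tuple(ratio),
        chi_square=float(stat),
        critical_value=crit,
        consistent=stat < crit,
    )


def digest_fragments(amplicon: str, recognition: str, cut_offset: int) -> list[int]:
    """Fragment lengths from digesting an amplicon with one enzyme.

    Every occurrence of the recognition sequence (overlapping allowed,
    scanned left to right) contributes a cut at ``site_start +
    cut_offset`` (0-based within the site).  Cuts at the amplicon
    boundaries are no-ops.  With no site the amplicon is one fragment.
    """
    if not recognition:
        raise ValueError("recognition sequence must be non-empty")
    if not 0 <= cut_offset <= len(recognition):
        raise ValueError("cut_offset outside recognition sequence")
    cuts = set()
    start = amplicon.find(recognition)
    while start != -1:
        cut = start + cut_offset
        if 0 < cut < len(amplicon):
            cuts.add(cut)
        start = amplicon.find(recognition, start + 1)
    bounds = [0] + sorted(cuts) + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def caps_distinguishes(
    amplicon_ref: str,
    amplicon_alt: str,
    recognition: str,
    cut_offset: int,
) -> DigestResult:
    """Whether a digest separates the two alleles of a SNV amplicon.

    Mirrors the gel readout: homozygotes show one allele's pattern and
    heterozygotes the union, so the alleles are distinguishable iff
    their fragment-length multisets differ.
    """
    if len(amplicon_ref) != len(amplicon_alt):
        raise ValueError("SNV amplicons must be the same length")
    frag_ref = digest_fragments(amplicon_ref, recognition, cut_offset)
    frag_alt = digest_fragments(amplicon_alt, recognition, cut_offset)
    return DigestResult(
        fragments_ref=frag_ref,
        fragments_alt=frag_alt,
        distinguishable=sorted(frag_ref) != sorted(frag_alt),
    )
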