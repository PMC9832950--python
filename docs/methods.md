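# Methods

## Problem setting

`poolmap` maps a monogenic recessive mutation in a diploid plant by
bulked segregant analysis with whole-genome sequencing (BSA-seq).  The
design it models: an EMS-mutagenised mutant is crossed to a wild-type
accession; the F1 is selfed; the F2 segregates the mutant phenotype
3:1; two pools of phenotypically extreme F2 individuals (here 37 + 37)
are sequenced together with both parents; variant calls with per-sample
allele depths (VCF `AD`) are the pipeline input.  Downstream of the
scan, the pipeline shortlists candidate variants by genotype pattern,
annotates their positional effect on gene models, and — for a
splice-donor hit — reconstructs the mis-spliced transcripts and
proteins.

## Euclidean-distance scan

At each biallelic site the two pools give nucleotide-frequency vectors
(InDels use two ref/alt pseudo-alleles).  The statistic is

    ED = sqrt( Σ_b (f_mut[b] − f_wt[b])² ),  b ∈ {A, C, G, T}

bounded by 0 (identical pools) and √2 (pools fixed for different
alleles).  At a fully penetrant recessive locus the mutant pool is
fixed for the mutant allele while the dominant-phenotype pool mixes
heterozygotes and homozygotes 2:1, so its expected mutant-allele
fraction is 1/3 and the expected signal peaks at √2·(2/3) ≈ 0.94.

**Smoothing.** The raw track is noisy at 20–60× pool depth.  `ed_fitted`
is a tricube-weighted sliding mean of `ed**k` computed per chromosome:
neighbours within ±window/2 get weight `(1 − (d/h)³)³`, `h = window/2`.
Defaults: window 2 Mb, `k = 1` (the statistic itself; higher powers
sharpen peaks and are configurable).  The smoother is deterministic and
window-local; an isolated variant keeps its own value.

**Threshold.** Significance is drawn at `median + 3·sample-SD (ddof=1)`
of the per-variant ED values genome-wide, and the fitted profile is
compared against it.  The spread is deliberately computed on the *raw*
track: smoothing removes the read-sampling noise, and the 3-SD band of
the fitted track collapses onto the amplitude of the slow allele-
frequency drift that finite pools (37 individuals) show even with no
causal locus — in null simulations a fitted-track threshold calls 2–4
spurious regions per genome while the raw-track threshold calls none,
at no cost in detection power.  `compute_threshold(column="ed_fitted")`
restores the fitted-track variant.

**Region calling.** Maximal runs of consecutive variants with
`ed_fitted ≥ threshold` (ties inclusive); runs closer than
`merge_gap` (default 100 kb) merge; merged runs with fewer than
`min_variants` (default 10) above-threshold variants are dropped;
bounds snap outward to the 10-kb grid.  The `min_variants` floor
suppresses isolated false positives at realistic depths; all knobs are
exposed.  Sites where either pool has depth < 4 are excluded from the
scan.

## Candidate filter and annotation

A causal recessive variant must be homozygous-alternate in the mutant
parent and the mutant pool, homozygous-reference in the wild-type
parent, and heterozygous *in aggregate* in the wild-type pool (expected
alt fraction 1/3; excluding HET wild pools would discard the true
signal).  Genotypes come from the alt-read fraction with
`hom_frac = 0.90` (tolerates one error read at ~20×) and a depth floor
of 4; low-depth roles drop the variant with a logged reason.

Positional effects use strand-aware windows in the conventions of
standard annotators: splice donor/acceptor = first/last 2 intronic
bases; splice region = exonic bases 1–3 or intronic bases 3–8 from a
junction; CODING inside the CDS; 5-kb UPSTREAM/DOWNSTREAM flanks;
INTRAGENIC inside the gene span but outside the mRNA (untranslated
exon bases, which have no category of their own here, also fall back
to INTRAGENIC).  A variant's reported effect is the highest-priority
category over all genes in reach, donor > acceptor > region > coding >
intron > upstream > downstream > intragenic > intergenic.  Candidates
are ranked by (effect priority, ED descending, position).

## Splice-consequence engine

Given a gene model, genome sequence, and the index of the intron whose
donor is broken, the engine enumerates the two outcomes observed for
EMS donor mutants: **intron retention** (the intron stays in the mature
transcript; the CDS is re-read through it and usually meets a premature
stop) and **cryptic donor** use (one transcript per canonical `GT` in
the upstream exon within `scan_bp` — default 200 bp — of the broken
junction, nearest first; the exon's 3′ tail is spliced out with the
intron).  No splice-strength scoring is attempted: the modelled
mechanism is U1 snRNP engaging the nearest canonical dinucleotide, and
the engine reports all window hits rather than ranking them
energetically.  Each alternative CDS is rebuilt from genomic segments
in transcript orientation (minus-strand genes are reverse-
complemented), translated with the standard code to the first stop,
and diffed against the reference protein (identical / C-terminal
truncation / contiguous internal deletion / other).  Ambiguity codes
in a CDS are an error.  Acceptor mutations and exon skipping are out
of scope.

The bundled five-exon *splice-reporter gene* makes these outcomes
exact: a 1338-nt CDS (445 aa); intron 2 opens `GTATAA`, so retention
reads one codon that matches the first exon-3 codon and then an
in-frame stop (clean truncation); a single cryptic `GT` sits 54 bp
upstream of the exon-2/intron-2 junction, codon-aligned, so the
cryptic-donor product is a 1284-nt CDS encoding 427 aa with a clean
18-residue internal deletion.

## Segregation test and digest markers

The 3:1 goodness-of-fit chi-square uses the Yates continuity
correction by default — `Σ (max(|O−E| − 0.5, 0))² / E`, 1 df — which
reproduces the published statistic for 277:97 (0.128; plain Pearson
gives 0.175).  The critical value is computed from the chi-square
quantile, not hard-coded.  CAPS/dCAPS digest logic cuts an amplicon at
every exact occurrence of a recognition sequence (overlapping allowed;
boundary cuts are no-ops) and declares two SNV alleles distinguishable
iff their fragment-length multisets differ, mirroring the gel readout.
Degenerate recognition bases are not supported.

## Simulator

The generator is a count-level model of the study design, not a read
simulator:

| parameter | default | rationale |
|---|---|---|
| focal chromosome | 30 Mb, "Fvb1" | scaled-down chromosome carrying the causal locus |
| background chromosomes | 6 × 30 Mb | supply the unlinked genome-wide background the threshold needs |
| variants | 2,000 per chromosome (~14,000 total) | comparable to the ~19,000 pool SNPs of a real run |
| EMS bias | 95% G→A / C→T | EMS transition spectrum |
| causal variant | G→A at the first base of intron 2 of the planted reporter gene (position 17,200,000) | splice-donor mutation class |
| F2 size / pools | 400 individuals; 37 + 37 | phenotype-selected pool design |
| crossovers | Haldane (Poisson, no interference), 4 cM/Mb | standard no-interference map model |
| depths | Poisson; means 22 / 57 / 49 / 58× (mutant parent / wt parent / mutant pool / wt pool) | observed per-sample depths |
| error | 0.002 symmetric per read | Illumina-scale substitution error |

Phenotype is fully penetrant recessive (mutant iff homozygous at the
causal site); the null configuration (`causal: false`) omits the causal
variant and assigns phenotypes as independent 1/4 Bernoulli draws, so
pools carry no allele-frequency skew anywhere.  All randomness flows
through one seeded generator; a fixed seed reproduces the VCF
byte-for-byte.

The background chromosomes exist because the median+3SD threshold is a
genome-wide statistic: with only the focal chromosome, the selection
sweep around the causal locus (decaying over ~25 cM ≈ 6 Mb) spans most
of the profile, inflating both the median and the SD until the
threshold exceeds the attainable signal maximum.  Background
chromosomes carry no annotated genes.

What the simulator does *not* model — and what passing tests therefore
do not establish about real data: alignment and mapping bias, InDel
calling artefacts (InDel records are exercised with hand-built VCF
fixtures via the pseudo-allele path), depth heterogeneity along the
genome, crossover interference, incomplete penetrance, and phenotyping
error.

## Numerical choices

Region sizes are `(end − start)/10⁶` rounded half-up to 2 decimals.
Threshold ties are inclusive (`≥`).  File coordinates are 1-based
closed (VCF/GFF convention); internal arithmetic is 0-based half-open.
Gene ties in effect annotation break by gene id; ranking ties break by
position.  Sample roles are always given explicitly by name, never by
VCF column order, so swapped pools cannot silently invert the scan.
`report.json` is bit-identical across reruns of one (config, seed);
wall-clock stage timings are kept out of it and only logged.

## Problem sizes used in the checks

Unit tests run scaled-down simulations (2–4-Mb chromosomes, tens of
variants) for speed; the end-to-end recovery and null checks use the
full default design above, 20 seeds per arm, each run a few seconds on
one core.

## Known limitations

The cryptic-donor search reports every window `GT`, not a
strength-ranked prediction; the annotator handles one mRNA per gene;
multi-allelic records are split or skipped, never jointly modelled;
the simulator draws pool reads at the variant level, so linkage
between reads of one fragment is ignored.
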