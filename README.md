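# poolmap

Bulked-segregant mapping (BSA-seq) of a monogenic recessive mutation
from pooled-sequencing variant calls — from a four-sample VCF to a
delimited candidate region, a filtered causal-variant shortlist, and
predicted consequences of a splice-donor mutation.

**Who it is for.**  Plant geneticists mapping an EMS-induced mutant:
mutant × wild-type cross, selfed F1, two phenotype-selected F2 pools
(plus both parents) sequenced, variants called with per-sample allele
depths.  `poolmap` consumes the VCF (with gene models and genome
FASTA) and automates the downstream analysis; a bundled ground-truth
simulator of the whole design makes every stage testable without any
sequencing data.

**The statistic.**  At each biallelic site the two pools give
nucleotide-frequency vectors, compared by Euclidean distance

    ED = √( Σ_b (f_mut[b] − f_wt[b])² ),   b ∈ {A, C, G, T},

which tends to 0 at sites unlinked to the causal locus and rises
toward √2 where the pools are fixed apart.  The per-variant track is
smoothed with a tricube sliding mean (default window 2 Mb), a
genome-wide threshold is drawn at median + 3·SD, and maximal
above-threshold runs become candidate regions.  Within a region,
variants matching the recessive pattern (mutant parent and mutant pool
homozygous-alternate, wild-type parent homozygous-reference, wild-type
pool ≤ heterozygous) are annotated against the gene models and ranked
by effect severity — splice-site hits first.  For a splice-donor
candidate, the splice engine rebuilds the intron-retention and
cryptic-donor transcripts, translates them, and reports the protein
change.  Segregation-ratio χ² tests and CAPS/dCAPS digest checks
support the marker-based validation steps.

## Worked example

Simulate the default design (EMS parent, 400 F2, 37+37 pools, ~50×
depth; causal splice-donor G→A at Fvb1:17,200,000) and run the whole
pipeline:

```sh
poolmap run --config run.yaml --outdir out/
```

with `run.yaml`:

```yaml
simulate:
  seed: 1
```

prints

```
top region Fvb1:13830000-20320000 (6.49 Mb)
report -> out/report.json
```

The top region (6.49 Mb — the same order as a real single-cross BSA
region) contains the planted causal position; `out/shortlist.tsv`
ranks the donor-site variant first:

```
Gene_ID      Chromosome_ID  Position  Ref  Alt  mutant_parent  wildtype_parent  mutant_pool  wildtype_pool  Effect             ED
causal_gene  Fvb1           17200000  G    A    0,16           69,0             0,45         38,10          SPLICE_SITE_DONOR  1.11959
```

and `out/transcripts.tsv` holds the predicted mis-splicing outcomes of
that donor break:

```
kind              cds_bp  protein_aa  premature_stop  deletion_bp
REFERENCE         1338    445         False           0
INTRON_RETENTION  1428    168         True            0
CRYPTIC_DONOR     1284    427         False           54
```

i.e. retaining intron 2 truncates the 445-aa protein at a premature
stop, while the cryptic donor 54 bp upstream of the broken junction
deletes 18 residues in frame (427 aa).

The stages are also available separately (`poolmap simulate / edscan /
annotate / splice / segtest / caps`); for instance

```sh
$ poolmap segtest --dominant 277 --recessive 97
chi2 = 0.128 (critical 3.84 at alpha 0.05); consistent with 3:1 segregation
```

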