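# breedsig

Genome-wide discovery of **breed genetic signatures** from jointly-called
multi-sample VCFs.

Modern dog breeds are closed, strongly selected populations: many variants
are driven to within-breed fixation while remaining rare or absent
elsewhere.  Given per-sample genotypes (GT), per-allele depths (AD) and
SnpEff-style effect annotations (ANN) plus a two-column sample→breed panel,
`breedsig` scans every locus for alleles that are homozygous in (essentially)
all dogs of one or more breeds, and aggregates the hits into the positional
and relational structures population geneticists actually interpret.  It is
aimed at researchers studying breed differentiation — in dogs or any other
stratified cohort (strains, case/control groups) with the same data shape.

## The statistic

At each locus, for each breed *b* and allele orientation (alternative
allele, reference allele, or STR high/low repeat group), the **breed variant
frequency** is

```
BVF_b = (# dogs of b homozygous for the oriented state) / (# dogs of b with solid calls)
```

where a call is *solid* when the summed read depth of its called allele
types reaches 10 (autosome) or 5 (X), and a breed is *valid* at the locus
when ≥ 3 of its dogs are solid.  Then, excluding universal states (carried
homozygously by every solid dog — artifacts of the reference individual) and
candidates with < 300 solid reference samples:

* **GS** (genetic signature): BVF ≥ 0.9 in at least one valid breed;
* **BSGS** (breed-specific GS): BVF ≥ 0.9 in exactly one breed *and*
  BVF ≤ 0.1 in every other valid breed;
* **pair signature**: BVF ≥ 0.9 in exactly two breeds, ≤ 0.1 in the rest.

Both orientations are scanned and the results combined.  STR loci are
detected among multi-allelic INDELs whose alleles decompose as
`anchor + unit^k` for a single primitive 1–6 bp unit; their repeat counts
are split into low/high groups by 1-D two-centroid K-means seeded with the
minimum and maximum counts, and a breed fixed in the high (low) group is an
**expansion** (**contraction**) signature.

Downstream aggregation: gene **hotspots** (≥ 5 BSGS of one breed per gene
label), high-density **stretches** (maximal runs of ≥ 10 BSGS at
≥ 10/kb), multi-type breed-specific **structures** (runs of ≥ 10 BSGS with
inter-member gaps ≤ 100 kb, flagged when they contain protein-changing
variants), 10-kb **block** summaries with an X-PAR report, breed
**similarity** (shared-GS counts normalised by the geometric mean of the two
breeds' counts, plus a min-max standardised score), and per-dog breed
**composition** (mean 0/0.5/1 carry score over each breed's GS catalog).

## Worked example

Every stage runs against the built-in planted-truth simulator, so the whole
pipeline can be exercised without any external data.  `--min-reference-n 20`
scales the reference-support filter (full-cohort default 300) to the 40-dog
synthetic cohort:

```bash
breedsig simulate --seed 7 --out-dir demo
# wrote demo/cohort.vcf (231 planted features)

breedsig discover-bsgs --vcf demo/cohort.vcf --panel demo/panel.tsv \
    --out-prefix demo/run --min-reference-n 20
# discover-bsgs: demo/run.bsgs_snp.tsv, demo/run.bsgs_indel.tsv, demo/run.bsgs_str.tsv
```

`demo/run.bsgs_str.tsv` (selected columns) shows breed-specific STR
expansions and contractions in the field's allele-range notation:

```
chrom  pos      breed            signature_type  unit  carrier_repeat_range  reference_repeat_range
chr1   1500000  Akita            EXPANSION       TTCT  A(TTCT)8-10           A(TTCT)0-3
chr1   1529000  AlaskanMalamute  CONTRACTION     AC    G(AC)0                G(AC)3-4
chr1   1558000  ChowChow         EXPANSION       T     C(T)8-10              C(T)0-3
```

The Akita row reads: every solid Akita is homozygous for alleles with 8–10
copies of the `TTCT` unit, while every other valid breed is fixed at 0–3
copies — a five-unit expansion private to the Akita.  The SNP catalog
(`run.bsgs_snp.tsv`) likewise lists each breed-specific SNP with its
carrier breed, gene label and effect term (e.g. the planted
`EIPR1 missense_variant` for the Akita at chr1:100000, `is_functional=True`).

`breedsig stats` tabulates coding vs non-coding fractions per catalog and
runs the exact two-sided Fisher test between the INDEL and SNP coding
fractions; on the demo cohort it prints a 2×2 of 2/7 vs 2/42 coding with
p = 0.129.  Other subcommands: `discover-gs`, `discover-pair`,
`discover-str`, `segments` (hotspots + stretches), `structures`, `blocks`
(10-kb tiling + PAR summary), `similarity`, and `infer-breed` for per-dog
composition.  All thresholds live in a flat key=value config
(`--config`) or per-flag overrides, and output is byte-identical for any
`--threads` value.

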