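# Methods

## Model and procedure

`breedsig` treats signature discovery as a deterministic set condition on
per-breed homozygote frequencies, not as a statistical test.  The pipeline
has three stages, applied per locus:

1. **Quality filter.**  A sample's call is *solid* when its genotype is
   non-missing and the summed AD of the *distinct* allele types it carries
   meets the chromosome-class depth threshold.  Using called-allele depth
   (rather than total site depth) makes the rule identical for bi-allelic
   and multi-allelic loci: a `1/1` call is judged on AD[1] alone, a `1/2`
   call on AD[1]+AD[2].  Missing genotypes (`./.`) and depth-unknown samples
   (absent or malformed AD) are distinct states, both non-solid.  Breed
   validity (≥ `min_breed_n` solid dogs) is recomputed independently at
   every locus, so a breed can be valid at one site and invalid at the
   next.
2. **Variant selector.**  Loci are classified into bi-allelic SNPs,
   bi-allelic INDELs, multi-allelic INDEL candidates (the STR detection
   pool) and OTHER; OTHER (multi-allelic SNPs, MNPs) is excluded from all
   scans.  Optional region / effect-term / class restrictions commute with
   post-hoc filtering of the unrestricted output.
3. **Population frequency analyzer.**  BVF per valid breed per orientation;
   GS / BSGS / pair-exclusive records by the inclusive ≥ 0.9 / ≤ 0.1
   conditions; universal-state exclusion; reference-support filter.

Assumptions inherited from the data model: the VCF is jointly called and
site-level hard filters were applied upstream; genotypes are diploid and
unphased; X-chromosome hemizygosity is not modelled (genotypes are used as
written).  Heterozygous dogs count in BVF denominators but never in
numerators.  Breeds that are invalid at a locus are ignored on *both* sides
of the specificity condition — a signature may be reported while an invalid
breed silently carries it; this is the intended behaviour of the frequency
conditions, not an oversight.  A locus can qualify in both orientations for
different breeds; it is then reported as two independent records.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bvf_high` / `bvf_low` | 0.9 / 0.1 | carrier / exclusivity cutoffs (inclusive) |
| `min_breed_n` | 3 dogs | per-locus breed validity |
| `min_reference_n` | 300 samples | solid non-carrier samples in valid breeds, per candidate per orientation |
| `depth_autosome` / `depth_x` | 10 / 5 reads | solid-call depth by chromosome class |
| `max_short_indel` | 10 bp (exclusive) | ref/alt length difference for *breed-specific short INDEL* reporting; not applied to GS |
| `hotspot_min` | 5 | BSGS per gene label per breed |
| `stretch_min`, `stretch_density` | 10, 10/kb | high-density stretch definition |
| `structure_gap`, `structure_min` | 100 kb (inclusive), 10 | breed-specific structure definition |
| `block_size`, `block_high` | 10 kb, 40 | genome tiling; "high" blocks hold **more than** `block_high` signatures |
| `unit_len_min..max` | 1–6 bp | admissible STR repeat units |
| `repeat_diff_report` | 3 units | large expansion/contraction flag |
| `par_region` | chrX:0–6,600,000 | canine X pseudoautosomal region |

`min_reference_n` is an absolute count, so it must be scaled to the cohort:
the synthetic 40-dog cohort uses 20 (all tests and the acceptance script
state this explicitly); 300 matches a ~400-dog cohort.

## STR typing

A multi-allelic INDEL locus is accepted as an STR when all alleles decompose
as `anchor + unit^k (+ shared suffix)` for a **single primitive** unit with
k varying across alleles.  The search prefers the shortest primitive unit,
then the longest common anchor, then the shortest residual suffix — a unique
canonical representation (`ATAT` ladders resolve to unit `AT`).  A shared
suffix is permitted because variant callers differ in how much right context
they keep.  Loci needing two unit types are rejected; rejection is a value,
not an error.

Distinct repeat counts are split into low/high groups by two-centroid 1-D
K-means (Lloyd to convergence), seeded with the minimum and maximum counts;
a count equidistant from both centroids joins the low group
(deterministic, conservative toward contraction).  Counts are unweighted —
the clustering is over distinct allele counts, not per-dog genotypes, which
matches the allele-range notation of the reports.  Seeded Lloyd is a local
optimiser: on arbitrary count multisets it can converge away from the
globally optimal contiguous 2-partition.  On the STR model family the
pipeline actually feeds it — two integer groups whose gap is at least the
larger within-group spread plus one — it provably coincides with the global
optimum, and the oracle-equivalence suite checks exactly that family.  The
group call of a dog is LOW/HIGH when both called alleles fall in one group,
MIXED when they straddle, NO_CALL when not solid; MIXED dogs stay in the
denominator.

## Positional aggregation

Segment length is `(last − first)/1000` kb with **no** +1, and density is
`count / length_kb`; both print at two decimals with half-up rounding.  This
convention reproduces the published per-row arithmetic exactly (13 members
over 1,166 bp → 1.17 kb at 11.15/kb; 204 members over 185,776 bp → 185.78 kb
at 1.10/kb) and is re-verified by the acceptance script.  A stretch is a
window of consecutive members that qualifies (count and density) and is
*maximal* — extending it by one member on either side no longer qualifies;
overlapping maximal windows are coalesced by keeping the longest span
(ties: more members, then leftmost).  Zero-span windows (all members at one
coordinate) are treated as infinitely dense.  Blocks are 1-based closed
intervals `[k·10000+1, (k+1)·10000]`; a signature at position 10,000 falls
in block 0 and 10,001 in block 1.  The PAR summary restricts to blocks fully
inside the PAR interval.

## Relatedness and composition

The sharing matrix counts every GS toward each of its k carrier breeds and
all k·(k−1)/2 pairs.  Similarity is `N_ij / sqrt(N_ii · N_jj)`; both the raw
score and a min-max standardisation over the off-diagonal entries are
reported, since either scale is useful depending on whether absolute or
relative relatedness is of interest.  Composition scores a dog 0 / 0.5 / 1
per GS locus (homozygous non-oriented / heterozygous / homozygous oriented,
with the stored orientation driving the scoring, so reference-orientation
signatures score hom-ref as 1); loci where the dog is not solid score 0 but
stay in the denominator, which is the breed's total GS count.

## Enrichment test

The coding/non-coding tabulation uses a configurable coding-term set
(missense, nonsense, start/stop, synonymous, frameshift, in-frame
insertions/deletions, coding-sequence); percentages use decimal half-up
rounding.  The two-sided Fisher test is computed in exact integer
arithmetic: p is the sum of hypergeometric point probabilities not exceeding
the observed table's, over all tables with the observed margins.  The exact
convention avoids the floating-point tie tolerances general-purpose
implementations apply, which matters when the test is compared against
exhaustive enumeration; `scipy.stats.fisher_exact` serves as an independent
cross-check in the test suite.  Sidedness is a deliberate choice: two-sided,
the standard exact convention.

## Synthetic cohort

The simulator emulates only the statistical structure the discovery
definitions respond to: within-breed fixation, cross-breed exclusivity,
bimodal STR repeat counts, positional clustering (one dense stretch, one
gene hotspot, one multi-type structure, PAR block enrichment on X) and noisy
depths (negative-binomial-like draws with a configurable dropout fraction
below the solid threshold, so QC paths are exercised).  It has no
demographic or coalescent realism, no linkage, no mutation model — so a
passing planted-truth suite demonstrates that the definitions are
implemented correctly, not that they are robust to population structure,
admixture or call errors beyond depth dropout.

Default scale: 8 breeds × 5 dogs, two 5-Mb autosomes plus an 8-Mb X,
≈ 4,700 loci (≈ 230 planted features + 4,500 background), generated and
scanned in a few seconds on one CPU.  Background loci are constructed with
exactly 2 hom-ref / 2 hom-alt / 1 het dogs per breed (or 2 low / 2 high /
1 mixed for STR-like loci): no subset of ≥ 3 solid dogs can then reach
BVF ≥ 0.9 in any orientation, so planted-truth *precision* is exactly
checkable under arbitrary depth dropout.  Near-miss decoys each violate
exactly one rule: one discordant het dog in the carrier breed (frequency),
three low-depth carrier dogs (validity), or low-depth reference breeds
(reference support).  ANN strings are emitted in the same pipe-delimited
dialect the reader parses.

## Numerical and degenerate-input choices

* All threshold comparisons are inclusive (≥ high, ≤ low, ≥ depth).
* No solid dogs at a locus → no valid breeds, no records, one warning on
  the vacuous universal check.
* Similarity standardisation with a constant off-diagonal → NA with a
  warning; breeds with zero signatures → NA rows.
* Correlations need n ≥ 3 and non-constant vectors, else NaN with a warning.
* Degenerate Fisher margins (zero row or column) → p = 1.
* Multi-allelic SNP sites are dropped rather than decomposed (the upstream
  pool definitions are bi-allelic); the classifier is exhaustive and
  mutually exclusive, so the choice is visible, not silent.

## Limitations

No haplotype phasing, LD/haplotype-block inference, population-structure
correction or likelihood-based ancestry model; composition is the
deterministic carry score only.  Compound or interrupted repeats are
rejected rather than modelled.  Parallelism partitions by chromosome with
ordered reassembly and is a correctness contract (identical output for any
`--threads`), not a performance claim.
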