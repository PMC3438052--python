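# Methods

## The model of allele-specific chromatin state

At a heterozygous SNP, every read that overlaps the site can be assigned
to the chromosome copy it came from by the allele it carries. The screen
treats each assay's reads at a site as draws from a per-assay allele
fraction and asks three questions:

1. **ASHM** — do at least two histone-modification datasets *differ* in
   their allele fractions? The omnibus statistic is an exact test of
   independence on the alleles × modifications count table. Testing
   *differences between datasets*, not departure from 50/50 within one
   dataset, is what buys robustness: a difference in nucleosome
   occupancy between chromosomes scales every modification's allele
   ratio identically and leaves independence intact, and a truly
   homozygous site contributes a single allele row, making the table
   untestable rather than spuriously significant.
2. **ASM** — among bisulfite reads at a partially methylated position,
   is methylation associated with the allele carried at the linked
   heterozygote (2×2 Fisher, per strand)?
3. **ASE/ASP** — do RNA or PolII reads depart from the 50/50 allele
   ratio (two-sided binomial)?

All assays share the filters: bases with Phred quality < 13 are ignored;
only candidates with imputation probability ≥ 0.5 **and** at least two
bisulfite reads per allele enter any caller; the ASHM background set is
restricted to sites with ≥ 35 summed modification reads (the floor at
which a call was attainable), and that set is the denominator of every
enrichment. Thresholds are fixed: 1e-7 (ASHM, ASE/ASP), 1e-8 (ASM, a
Bonferroni-style figure for millions of methylation tests), HWE
exclusion strictly below 0.05. Boundary conventions are inclusive on
the retention side throughout (p_het = 0.5 retained, 35 reads retained,
HWE p = 0.05 retained, quality 13 retained).

## The exact r×c independence test

The p-value is the total conditional probability, given both margins, of
all tables at most as probable as the observed one (the min-likelihood
two-sided definition; ties count, with a relative slack of 1e-7).

Implementation: a network (stage-wise DP) algorithm. Conditional on the
margins, columns with equal totals are exchangeable, so stages are
*groups* of equal-margin columns and branches are multisets of column
allocations (orbits under column permutation), each carrying a
permutation-count multiplicity. A backward pass computes, per
(stage, remaining-row-margins) node, the min/max attainable completion
log-probability and the total completion mass; the forward pass then
resolves whole subtrees against the observed probability whenever the
bounds decide them, and otherwise branches, merging paths that reach a
node with identical accumulated weight. Work is metered against a node
budget (default 3×10⁶ elementary steps); beyond it the Pearson χ²
p-value (no continuity correction) is returned with an `approximate`
flag. Large tables whose χ² p-value exceeds 1e-3 are reported as the
flagged approximation without attempting exact computation — the
traversal only prunes well when the observed table is improbable, and
three orders of magnitude above the calling threshold the distinction
cannot change a call. Small tables (N ≤ 40, or within the enumeration
budget) are always computed exactly. The engine reproduces
`fisher.test` (R) on r×c tables and brute-force enumeration on every
2×2 table with total ≤ 24.

The per-modification and expression binomial tests use the closed
symmetric form `min(1, 2·P(X ≤ min(k, n−k)))`, which at p = 1/2 equals
the min-likelihood convention (and the n-vs-0 closed form `2·0.5ⁿ`).
The HWE test enumerates heterozygote counts conditional on allele
counts and sums probabilities no larger than the observed one.

## Clustering and driver identification

Significant sites become signed profiles over modifications: magnitude
−log₁₀ of the per-modification binomial p (capped at 300; untested
modifications contribute 0), sign anchored per site to the allele
favored by the site's most significant modification. Similarity is the
squared Pearson correlation across modifications — chosen because the
anchor makes profiles well-defined only up to a global flip, and r² is
flip-invariant. Distance 1 − r², average linkage (a robust default for
profile data; configurable in code). Zero-variance profiles get r = 0,
logged.

The cut is found by descending through merge heights: at each candidate
cut, every cluster's driver set is computed — modifications with
binomial p below 0.01 on a consistent side in at least half of the
cluster's sites, after sign-aligning members to the member with the
largest profile norm (the per-site anchor can flip between sites of one
cluster when two driver marks are equally strong, so alignment is
required before side-consistency means anything). The chosen cut is the
lowest at which all driver sets are pairwise distinct; driver sets are
compared up to a global sign flip, because which allele is "A" at a
site is arbitrary. If even the two-cluster cut repeats a driver set, a
single cluster is returned with a warning.

## ASM mechanism annotation

Most strong ASM is caused by SNPs destroying the guanine of a CpG, which
abolishes methylation of the partner cytosine on one allele. "Directly
adjacent" is operationalised as ≤ 1 bp between the methylation query
position and a heterozygote with p_het ≥ 0.5 — exactly the CpG-partner
geometry. Epialleles are the significant calls without the flag.
Strand handling: plus-strand bisulfite reads cannot genotype C/T
heterozygotes (unmethylated C reads as T) and minus-strand reads cannot
genotype G/A heterozygotes (the same ambiguity in minus-strand space);
the ambiguous strand is dropped both for methylation observations and
for validation support counting. Methylation is never called at a known
polymorphic position. Each methylation observation carries its query
position (`pos`) — without it, per-position testing and the adjacency
flag would be impossible.

## The synthetic generator

The generator emulates the *tables* the real screen consumes, not the
sequencing that produced them: reads are exchangeable allele
observations with Phred qualities from a two-point {Q10: 10%, Q30: 90%}
distribution (so the quality filter does real work), depths are Poisson
around configured means, and a single synthetic chromosome (10 Mb)
carries everything, since all proximity logic is coordinate-local.

Implanted effects, with defaults:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 2000 | heterozygote candidates |
| `ashm_fraction` | 0.03 | sites with a cluster pattern (equal weights over the six) |
| `skew` | 0.9 | driver-mark allele fraction on the designated allele |
| `mean_chip_depth` | 3 /site/mod | background ChIP coverage (~69× summed, above the 35× floor) |
| `driver_chip_depth` | 150 | ChIP coverage of a driver mark at its site |
| `occupancy_shift_fraction` | 0.01 | all 23 marks skewed identically |
| `false_het_fraction` | 0.02 | truly homozygous candidates with p_het ≥ 0.5 |
| `asm_fraction` × `cpg_disrupting_fraction` | 0.05 × 0.8 | CpG-SNP ASM sites (G/A alleles; methylation tracks the intact G at pos−1) |
| `epiallele_fraction` | 0.01 | allele-linked methylation with intact DNA, query ~37 bp away |
| `epiallele_meth_delta` | 0.9 | methylation difference between alleles at epialleles |
| `mean_bis_depth` | 40 /strand | bisulfite coverage |
| `ase_fraction`, `ase_linked_fraction` | 0.03, 0.2 | ASE sites; fraction placed within `ase_link_distance` (10 kb) of an ASHM site |
| `mean_rna_depth` | 80 | RNA coverage (PolII at half) |
| `annotation_enrichment_fold` | 20 | implanted fold of ASHM proximity to imprinted regions at 10 kb |
| `sequencing_error_rate` | 0.002 | per-base miscalls (uniform over other bases) |

Allele designation for every implanted skew is uniform per site (no
parent-of-origin information exists in the model). Population genotype
counts for the HWE filter are drawn under HWE (n = 100, random allele
frequency) at real sites and with gross heterozygote excess (90%) at
false-het sites, emulating duplication artefacts.

**Depth defaults are power-calculated.** The published significance
thresholds are fixed constants, so the generator must occupy the regime
where an implanted effect *can* clear them — in the real screen that
regime is the well-covered tail of millions of tested positions. A
CpG-linked 2×2 at 20 reads/allele gives p ≈ 3×10⁻¹⁰ (threshold 10⁻⁸);
an epiallele at Δmeth 0.9 gives p ≈ 6×10⁻⁹; 80 RNA reads at skew 0.9
give p ≈ 5×10⁻¹⁴ (threshold 10⁻⁷); a driver mark at 150 reads and skew
0.9 against 22 null columns of ~3 reads gives a median exact omnibus p
near 10⁻⁸, i.e. ≈ 65% recovery at 10⁻⁷ for single-driver patterns (the
hardest case — two-driver patterns are recovered essentially always).
Uniformly deep coverage would *not* work: with all 23 columns at 50
reads, the 22 signal-free columns dilute a single driver's contrast to
p ~ 10⁻⁴ regardless of test. Deep driver coverage is also the realistic
geometry — immunoprecipitation enriches exactly the loci that carry the
mark.

What the generator does **not** emulate: alignment and mapping bias,
reference bias, duplicate reads, local CpG context and co-methylation,
linkage between neighbouring sites, realistic per-modification coverage
distributions, or multiple chromosomes. Passing tests therefore show
that the statistical machinery is correct and that the confounder
immunities hold mechanistically; they do not show that real-data error
modes (notably mapping bias, which mimics allelic imbalance) are
handled — on real data those must be addressed upstream.

## Pipeline behaviour and degenerate inputs

Stages run in protocol order (validate → count → ASM/ASHM/ASE → cluster
→ enrich); every output TSV carries version/seed/threshold headers and
reruns are byte-identical under a fixed seed. Zero-margin 2×2 tables
and single-row/column omnibus tables return p = 1 (untestable, never
significant). Sites missing from bisulfite support count as
unsupported; sites missing population genotypes keep their QC status
with the HWE marked not-assessed. Ties in the favored allele yield no
favored allele. The enrichment background includes called sites (their
contribution at realistic call rates is negligible); distances to
regions are edge distances with inside = 0 and inclusive windows;
site-to-site distances are absolute position differences. An optional
allow-list on site identifiers models restriction to a reference
variation release.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 300–800-site simulations; the confounder-immunity
check uses 10⁴ occupancy-shift plus 10⁴ false-het sites; pattern
recovery uses 600 sites with 72 implants; enrichment recovery pools 200
replicates of 500 sites; the acceptance script runs the default
2,000-site conditions. These sizes give every check a comfortable
signal-to-noise margin while the whole suite completes in about a
minute of CPU.

## Known limitations

* The exact omnibus test degrades to a flagged χ² beyond its complexity
  budget; near-threshold decisions on very large tables should be
  re-run with a larger budget.
* Driver identification assumes drivers are consistent within a cluster;
  heterogeneous clusters return conservative (possibly empty) driver
  sets.
* The haplotype-assignment utility consumes a user-supplied marker
  table; no marker catalogue ships with the package.
* SNP-level calls are not aggregated to genes or regions; region-level
  DMR calling and parent-of-origin inference are out of scope.
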