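# Methods

## The mapping population and its likelihood model

The pipeline targets a **CP population**: a single full-sib family from two
outbred parents, in which each marker segregates in one of five
configurations — lm×ll, nn×np (one parent heterozygous), hk×hk (both
heterozygous, shared alleles), ef×eg and ab×cd (both heterozygous,
distinguishable alleles).  Offspring genotypes are unphased codes from the
type's alphabet (e.g. `lm`/`ll`; `hh`/`hk`/`kk`; `ac`/`ad`/`bc`/`bd`),
`--` for missing.

**Two-point estimation.**  For a marker pair, each parent transmits one of
two haplotypes; given a parental phase, a gamete is parental with
probability (1−r)/2 per arrangement and recombinant with probability r/2.
The probability of every observable joint genotype class is therefore a
polynomial of degree ≤ 2 in r whose coefficients depend only on the two
segregation types and the two parental phases.  The implementation
precomputes these coefficients per type pair, evaluates the exact
log-likelihood of the observed class counts on a grid over r ∈ [0, 0.5]
(1,001 points) for each of the ≤ 4 phase combinations, and refines the
maximizer — bounded scalar minimization for single-pair queries, parabolic
interpolation in the vectorized all-pairs path.  The reported phase is the
maximizing one, ties broken toward coupling.  LOD = log₁₀ L(r̂) − log₁₀
L(0.5).  Pairs in which neither parent is heterozygous at both loci (e.g.
lm×ll × nn×np) share no meioses and are reported as r̂ = 0.5, LOD = 0,
n_informative = 0.  This single engine covers all type pairs, including
hk×hk × hk×hk where the double heterozygote is phase-ambiguous — the class
probabilities already sum over the ambiguity, so the grid/Brent maximizer
returns the same MLE an EM iteration would.  A unit suite checks the
estimator against an independent brute-force grid search (step 10⁻⁴) on
200 random mixed-type pairs, with agreement required within 10⁻³.

**Distortion filter.**  Each marker's genotype-class counts are tested
against Mendelian expectation (1:1, 1:2:1, or 1:1:1:1) by a χ² test with
(classes − 1) degrees of freedom, missing codes excluded.  Markers with
p < α are excluded before pair estimation.  Default α = 0.01, no
multiplicity correction; both choices are configurable.  At α = 0.01 about
1% of genuinely Mendelian markers are excluded by chance; that is the
expected operating characteristic, not an error.

**Grouping.**  Single-linkage connected components over edges with
LOD ≥ 5.0 **and** r̂ ≤ 0.4 (both configurable).  Group counts are also
reported over the diagnostic LOD 5→15 sweep (step 1); mapping always
proceeds at the grouping threshold.  Singleton components are excluded as
`unlinked`.  At LOD 5 with thousands of null pairs an occasional spurious
cross-group edge is expected (the familiar pseudo-linkage phenomenon that
motivates sweeping to higher LODs); the sweep makes it visible.

**Ordering (regression mapping).**  Within a group, markers enter in
decreasing information order (sum of pair LODs).  Each insertion point
minimizes the weighted least-squares objective
Σ w_ij (x_j − x_i − d_ij)², where d_ij is the Kosambi distance of r̂_ij and
w_ij = LOD².  After each insertion a ripple permutes every sliding window
of three; after the last insertion the order is polished by alternating
ripple and single-marker reinsertion passes to a fixed point (≤ 10
rounds).  Final positions are the weighted least-squares fit along the
final order, shifted so the first marker sits at 0 cM; markers are emitted
sorted by fitted position.  Pairs with r̂ ≥ 0.5 or zero LOD carry no
weight; pairs with r̂ above the grouping ceiling 0.4 still contribute
distances, mirroring the role of the 0.4 ceiling as a linkage-evidence
criterion rather than a distance bound.  LOD² weighting (rather than LOD)
was adopted because squared weights downplay long, noisy distances; with
plain LOD weights the orderer mis-ordered roughly one adjacent pair per
10-marker group at n = 107.  This greedy construction is a reconstruction
of regression mapping as commonly implemented; the original tool's exact
objective (e.g. its jump statistic) is not public, so this is an
approximation by design.

**Map function.**  Kosambi in both directions:
d = 25·ln((1+2r)/(1−2r)) cM and r = tanh(d/50)/2.

## Physical-map integration

A marker anchors a BAC clone when its sequence aligns to one of the
clone's end reads (BES) with alignment length ≥ 150 bp for
microsatellites, ≥ 100 bp for SNPs, and identity strictly > 95%
("larger than" is read as inclusive for length, "greater than" as strict
for identity; both operators are configurable because the verbal
thresholds are ambiguous at the boundary).  The best surviving hit per
marker is chosen by (bitscore desc, e-value asc, subject id asc); a marker
whose two best hits score identically on different contigs is assigned to
neither (conservative: fabricating an anchor would fabricate conflicts).

The **built-in aligner** is an exact-seed (k = 21), ungapped,
maximum-scoring-segment extender (match +1, mismatch −2) over both
strands, reporting BLAST-tabular records with e-value 0 — identity and
length are the deciding statistics at this stage.  Real BLASTn `-outfmt 6`
output drops in unchanged.  No gapped alignment and no e-value theory: a
deliberate non-goal.

**Lengths and coverage.**  A contig's physical length is its
consensus-band count × 1.428 kb; a single BAC counts 141 kb (the library's
mean insert).  Per-LG sums count every attachment (redundant); the
non-redundant totals count each element once, however many LGs it touches.
The difference equals exactly the extra placements of multi-LG contigs, an
identity asserted in the tests.  Lengths are held exact in kb internally;
Mb values are rounded to 2 decimals only at the reporting boundary.

**Conflicts.**  A contig with accepted anchors on ≥ 2 linkage groups is
chimeric-suspect; the assembly error-rate estimate is
100 × conflicting / anchored contigs, rounded to the nearest integer
percent.  Markers at two distant positions on the *same* LG are not a
conflict (the criterion is two different LGs); spans > 20 cM are logged as
warnings.  Conflicting contigs stay in the map, flagged.

**Orientation.**  Elements with ≥ 2 markers on one LG are reported
`orientable`.  An actual forward/reverse call would need BES coordinates
*within* the contig, which the FPC-style physical-map record does not
carry, so orientation is left `unoriented` — a documented limitation.

**Duplicated markers.**  Loci amplified by one primer pair are two records
`BASE-1`/`BASE-2`.  A mapped pair on two distinct LGs is `wgd_consistent`
(annotated with the shared orthologous chromosome when the homology
assignment agrees); a pair on one LG is `intra_lg` (segmental
duplication); a pair with an unmapped locus is unclassifiable.

## Comparative synteny

Queries (BES or markers) keep a single top reference hit with
e-value ≤ 10⁻⁵, ordered by (bitscore desc, e-value asc, chromosome asc,
start asc) — a deterministic reading of "top hits".  Coordinates become
0-based half-open internally; BLAST's 1-based inclusive convention exists
only at the file boundary.  Each linkage group's homolog is its modal
chromosome provided the modal fraction reaches 0.5 (configurable); a
two-to-one summary reports, per chromosome, the assigned LGs and whether
there are exactly two.  Placements from one LG on one chromosome merge
into synteny blocks while the bp gap stays ≤ 1 Mb (the merge criterion is
not stated in the source analysis; 1 Mb is this package's default,
exposed in config).  Segmental loss is measured as the merged-block span
over the chromosome length (supplied table, else the maximum placement
end — a documented fallback), flagging LGs below 0.8.  Mate-pair
(both-end) chromosome consistency is computed as a diagnostic only.

## The synthetic-data generator

The generator emulates the mapping design: a CP family of **107
offspring** (the genotyped family size), ~10 linkage groups of ~80 cM with
~20 markers drawn from a realistic mix of the five segregation types
(25/25/20/15/15%), 2% missing genotypes, 5% distorted markers, an
FPC-style contig set with consensus-band lengths, BES of 700 bp carrying
marker sequences verbatim, and a reference genome in which every
chromosome hosts exactly two LGs.

* **Crossovers** occur independently per adjacent interval with
  probability equal to the inverse Kosambi of the true cM gap.  No
  explicit interference model: this choice makes Kosambi-based estimation
  consistent with the truth, so parameter-recovery tests are well-posed.
* **Distortion** resamples the heterozygous parent's transmitted allele
  with probability 0.75 — a strong, χ²-detectable signal
  (E[χ²] ≈ 27 at n = 107).
* **Contigs** are anchored by 1–2 markers; a second anchor is the nearest
  free marker and only if within 5 cM, so a contig's genetic footprint
  respects its physical size.  Chimeric contigs receive an extra BES
  embedding a marker from a different LG.  Marker sequences are embedded
  with 0 substitutions by default; an error knob exercises the 95%
  identity filter.  Genotyping error defaults to 0 and is exposed as a knob.
* **Reference hits** place each BES collinearly with its contig's cM
  anchor (spread across the contig's physical span, Gaussian jitter
  40 kb), with e-values far below the cutoff; decoys land on wrong
  chromosomes with e-values above the cutoff.  Per-LG loss intervals
  suppress true hits over a contiguous fraction of the chromosome.

What the generator does **not** emulate: sequence-level realism (GC,
repeats beyond the embedded SSR motifs), crossover interference, lab
genotyping error structure, or the real marker/contig counts that depend
on wet-lab genotyping.  Tests passing on this generator therefore
demonstrate correctness of the estimators and bookkeeping under the
stated statistical model, not performance on real chromatograms.

## Problem sizes and test conditions

The deterministic headline numbers (486.34 Mb, 12.41 Mb, 498.75 Mb, 3% =
13/463, 71.32 cM, 1.933 cM spacing, 10.82 Mb/LG, 1,050 kb, 1,209 markers,
8 vs 5 duplicated-marker classes) are recomputed through the real
integration and report code from their printed inputs: the shipped per-LG
summary and duplicated-marker tables and a constructed 463-contig /
340,577-CB / 88-BAC map.

The statistical checks use desk-scale simulations chosen for power per
second: estimator-vs-oracle on 200 pairs at n = 107; bias at n = 1,000
over r ∈ {0.05, 0.1, 0.2, 0.3} (30 replicates each, fully informative
ab×cd pairs); and a 20-seed recovery study on 10 LGs × 10 markers with
gaps uniform in [5, 8] cM at n = 107, which must recover the group count
and every within-group order (or its reversal) in ≥ 95% of seeds.  The
recovery study uses fully informative ab×cd markers: with the realistic
mixed-type panel, pairs like lm×ll × nn×np share no meioses, so *no*
method can order such neighborhoods reliably at n = 107 — the mixed-type
condition tests the data, not the machinery.  The residual failure mode
at these settings is an occasional spurious cross-LG edge at LOD ≈ 5
among thousands of null pairs, i.e. exactly the multiple-testing effect
the LOD sweep exists to expose.

## Known limitations

* Two-point (not multipoint) ordering; no sex-specific or consensus maps.
* The CP genotype dialect is a reconstruction; original input files for
  the real dataset are not public.
* Orientation of multi-marker contigs is detected but not resolved (no
  intra-contig BES coordinates).
* The naive aligner is ungapped and seed-limited (a single ≥ 21 bp exact
  seed is required); it exists to make the pipeline self-contained, not
  to replace BLAST on diverged sequences.
* Chromosome lengths default to the maximum placement end when no length
  table is supplied, biasing covered fractions upward at sparse coverage.
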