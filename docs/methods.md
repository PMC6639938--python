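# Methods

## Signature matching

An intact Alu element begins with a conserved decamer (consensus
`GGCCGGGCGC`). The signature set is this consensus plus every sequence at
Hamming distance exactly 1 — 3·10 + 1 = 31 sequences — which absorbs a
single substitution anywhere in the motif. Matching is membership in the
precomputed set (an O(1) lookup per window), which is equivalent by
construction to a per-window Hamming-distance ≤ 1 test; the equivalence is
property-tested against a brute-force scan. Windows containing any
non-ACGT character never match. Reads and reference are always scanned on
both strands: sequencing reads arrive in either orientation, so
single-strand scanning would halve discovery sensitivity. Because the
method keys on the intact 5′ end, 5′-truncated elements are invisible to
it by design.

## REF– discovery

For every signature hit in a read with ≥ 25 bases of upstream flank on the
hit's strand, the 35-mer (flank₂₅ + signature₁₀) is recorded and counted
exactly over the whole read stream. A 35-mer becomes a candidate when

1. its support lies in `[min_support, max_support]` (defaults 3 and 100:
   at 20–40× coverage, ≥ 3 suppresses 35-mers created by sequencing error,
   ≤ 100 suppresses repeat-derived artifacts; both are configurable);
2. the 25 bp flank occurs at exactly one position in the reference,
   counting both strands (a flank present once forward and once
   reverse-complemented elsewhere is *not* unique);
3. the 10 reference bases continuing the flank differ from the observed
   signature — otherwise the junction already exists in the reference.

Distinct 35-mers pointing at the same breakpoint and flank (signature
one-mismatch variants arising from element divergence or read errors) are
merged, summing support and keeping the best-supported signature, so one
locus yields one candidate. Internally all coordinates are 0-based
half-open; every user-facing file is 1-based inclusive.

The reference index maps each canonical 25-mer to its occurrence list.
Occurrence storage is capped (default 4) with exact total counts kept
separately: the pipeline only ever distinguishes absent / unique /
repeated, and the cap bounds memory on repeat-rich genomes. 25 was kept as
the flank length because it must simultaneously guarantee unique
localisation and leave 7 bases for allele discrimination within the
32-base k-mer budget used throughout.

## REF+ discovery

Four monotone stages, each consuming the previous stage's output (the
per-stage counts are logged so a user can print their own cascade table):

1. **Signature scan** of the reference, both strands.
2. **TSD test.** The 5-mer immediately 5′ of the signature (on the
   element's strand) is sought at each distance d ∈ [270, 350] downstream
   of the signature start, inclusive; the nearest exact copy wins, and the
   seed is then extended outward to its maximal exact length (reported TSD
   ≥ 5 bp). The window endpoints are anchored at the signature start and
   the first base of the downstream copy; the extension is capped at 50 bp
   so a TSD abutting the polyA tail cannot run away through the
   homopolymer. Minus-strand hits are processed on the reverse-complement
   coordinate frame and mapped back.
3. **Homology.** The element span (signature start through the downstream
   TSD copy) is aligned locally to an AluY consensus by Smith–Waterman
   with match +1, mismatch −2, gap open −5, gap extend −2 (affine cost of
   a length-L gap: 5 + 2L). Raw scores are converted to bits with the
   ungapped Karlin–Altschul parameters for +1/−2 (λ = 1.28, K = 0.46):
   bits = (λS − ln K)/ln 2. Candidates are kept above 100 bits — the AluY
   consensus scores ≈ 533 bits against itself, random 300-mers score far
   below 100, and a copy with 20 % divergence still clears the bar. The
   aligner is cross-checked in the tests against an independent
   Smith–Waterman implementation (scikit-bio), gaps included. A
   multi-record Alu library may be supplied; the best score over records
   is used.
4. **Outgroup absence** (optional). The junction 32-mer (flank₂₅ + first
   7 bases of the element) is looked up in the outgroup genome's canonical
   32-mer set; the candidate passes if absent. This is deliberately
   coarse — a presence test, not a synteny mapping — and is skipped (flag
   "unknown", candidate retained, warning logged) when no outgroup is
   given.

REF+ output is a candidate list, not a validated set of human-specific
polymorphic elements: elements monomorphic in one cohort can be
polymorphic in another, so over-inclusion is preferred and downstream
genotype-based filtering decides.

## Breakpoint 32-mer pairs

Both alleles of a breakpoint share the 25 bp flank 5′ of the insertion
point on the element's strand and differ in the final 7 bases. Allele A is
always the reference state: for REF– loci, A continues with the reference
sequence and B with the element's first 7 bases; for REF+ loci, A carries
the element's first 7 bases (the element is in the reference) and B the 7
bases following the downstream TSD copy. 7 bases is the minimum that keeps
the two alleles reliably distinguishable; fewer would too often coincide
with the reference continuation. The 25 + 7 split of the 32-base budget is
the default; alternative splits are deliberately not exposed.

Pair-level filters, evaluated on the whole pair set so the result is
independent of processing order:

- **duplicates** — any canonical 32-mer shared by two or more pairs
  removes all pairs involved;
- **closely located** — breakpoints on one chromosome closer than
  `min_distance` (default 32, one k-mer length: closer pairs read into
  each other's k-mers) remove all pairs involved;
- **GC-rich** — either 32-mer with GC fraction > `gc_max` (default 0.80;
  GC-extreme k-mers show strong coverage bias in short-read data);
- **reference occurrence** — allele A must occur exactly once in the
  reference and allele B never (canonical counting, brute-force scan at
  desk scale).

Pair databases are TSV with `#ref=` / `#k=32` headers; merging databases
requires matching reference tags, deduplicates by (chromosome, breakpoint,
class) and sorts deterministically.

## Genotype calling

Counts (n_A, n_B) of a pair's two 32-mers over a read stream are modelled
as independent Poisson draws with per-genotype intensities

| genotype | intensity A | intensity B |
|---|---|---|
| AA (or A) | λ | ε |
| AB | λ/2 | λ/2 |
| BB (or B) | ε | λ |

with a flat prior over the hypotheses (three for diploid loci, two for
haploid). The call is the maximum-posterior genotype if its posterior
reaches `min_posterior` (default 0.99), else NC. λ is the expected k-mer
count of a homozygous allele and is calibrated per individual as the
median of n_A + n_B over informative pairs (≥ 100 required; otherwise a
user-supplied coverage is used) — the median is λ for both homozygotes
(λ + ε ≈ λ) and heterozygotes (λ/2 + λ/2). ε = max(0.01λ, 0.1) absorbs
sequencing-error leakage into the absent allele. This classifier is a
self-contained replacement for an external empirical-Bayes genotyper: it
needs no SNV marker database for calibration, at the cost of assuming the
Alu pair counts themselves are representative of coverage. At 20× and
above the classifier is insensitive to the exact ε; at very low coverage
(< 10×) calls degrade to NC rather than flipping.

Cohort filters, given calls for many individuals: (a) elements whose
fraction of unexpected-ploidy calls (diploid call where haploid expected
or vice versa; NC never counts, and is excluded from the denominator)
exceeds `max_unexpected` (default 0.02); (b) elements failing the exact
Hardy–Weinberg test at `hwe_alpha` (default 10⁻⁴) over autosomal diploid
calls; (c) REF– elements with zero B alleles in the whole cohort — a REF–
locus was discovered *from reads*, so an all-AA cohort means the marker
does not work; monomorphic REF+ elements are legitimate (the cohort may
simply lack the deletion allele) and are kept. Ploidy expectation:
autosomes diploid; chrY haploid in males, absent in females; chrX is
treated as an autosome here since the rule targets chrY artifacts.

The HWE test conditions on the allele counts and sums the probabilities of
all heterozygote configurations no more probable than the observed one
(minor-configuration summation), computed in log space via a gammaln
closed form; the tests verify it against direct enumeration for every
genotype table with n ≤ 50.

## Simulator

`plant_insertions` draws breakpoints uniformly (length-weighted across
chromosomes), duplicates the 15 bases 5′ of each breakpoint as the TSD,
and inserts element + polyA + TSD-copy on one haplotype (heterozygous by
default; fractions of homozygous and designed-absent loci are available
for genotyping experiments). The element body receives i.i.d.
substitutions at the chosen rate — signature included, so signature-killing
mutations are part of the simulated detectability. polyA length is uniform
on [5, 80]. Breakpoints keep a minimum separation (default 200 bp):
uniformly random placement occasionally collides two insertions within one
k-mer length, which makes "every clean insertion is recoverable"
ill-posed; the separation removes that confound while leaving placement
otherwise uniform. Placement/zygosity/polyA draws use an RNG stream
separate from the mutation stream, so at a fixed seed the planted
positions — and hence the FN2 set — are identical across mutation rates.

`simulate_reads` samples fragments uniformly with Gaussian insert size
(default outer distance 500, SD 50 — the conventional short-read default,
clipped below at two read lengths), takes a 151 bp read from each fragment
end (mate 2 reverse-complemented), and applies i.i.d. substitution errors
(default 0.5 %) to ACGT bases; N passes through. Requested coverage is
depth over the haploid genome length, so each haplotype of a diploid
receives half.

`evaluate_discovery` matches discoveries to planted breakpoints within
± 5 bp (TSD placement makes the exact reported base convention-dependent)
and classifies each miss: **FN2** when the 35 bp insertion window overlaps
an N run, else **FN1** when the 25 bp flank is not reference-unique, else
"missed-other" (typically insufficient support at low coverage, or a
mutated signature). FN2 is tested before FN1 deliberately: a flank
containing N is both un-locatable and unsequenced, and it is the
N-overlap — not the localisability — that makes such a miss depth- and
mutation-rate-independent. Detected + FN1 + FN2 + missed-other partitions
the planted set.

What the simulations do and do not show: the generator reproduces the
insertion anatomy, coverage statistics and substitution errors of real
short-read data, but its genomes are uniform-random (no genome-wide repeat
structure beyond the planted duplications), its errors have no quality
profile or indels, and its insert sizes are exactly Gaussian. Passing the
suite demonstrates the algorithms' correctness and their qualitative
sensitivity behaviour, not population-scale performance on real genomes,
which additionally depends on real repeat content and cohort structure.

## Problem sizes and numerical choices

The standing test/acceptance configurations: clean end-to-end discovery on
1 Mb with 100 insertions at error-free 40×; FN decomposition on a ~310 kb
genome containing a duplicated 20 kb block and an N run, 60 insertions,
30×, mutation rates 0/0.05/0.10; coverage curve on 400 kb, 60 insertions,
5–40×; genotyping on 600 kb with 200 designed loci (100 het / 50 hom / 50
absent) at 30×. These sizes exercise every code path with comfortable
statistical margins (e.g. ≥ 12 expected supporting reads per breakpoint at
40×) while keeping the whole suite fast on a single core. At 5 %
divergence the expected saturated sensitivity is bounded by
P(≤ 1 mutation in the decamer) ≈ 0.91, which the coverage-curve assertions
reflect.

Determinism: every random quantity derives from an explicit seed;
fixtures, simulators and CLI runs are byte-reproducible under a fixed
seed. Ties in the genotype posterior (possible only in degenerate
zero-count cases) resolve to the first hypothesis in a fixed order and, in
practice, fall under the posterior threshold and return NC.

## Known limitations

- 5′-truncated Alu insertions (~16 % of real insertions) and
  deletion-mediated polymorphisms are out of reach of the signature-based
  method by construction.
- The REF+ outgroup stage is a junction-presence test, not an orthology
  mapping; candidates passing it are not guaranteed lineage-specific.
- Exact-match flanks make the method sensitive to SNVs inside the 25 bp
  flank (a real-data failure mode the uniform-random simulator
  underrepresents).
- The locate index holds all canonical 25-mers in memory; it is sized for
  desk-scale genomes up to tens of Mb, not for a full mammalian genome in
  this implementation.
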