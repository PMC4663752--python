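# Methods

This note documents the models, conventions and numerical choices behind
`vigmap`, and what the synthetic-data tests do and do not demonstrate.

## Assembly statistics

`nx(lengths, x)` is the classical Nx: the length of the sequence at which
the cumulative sum of descending-sorted lengths first reaches x% of the
assembly total. `ng(lengths, G, x)` replaces the denominator with the
estimated genome size `G` and returns 0 when the assembly never reaches
x% of `G` — a sentinel, not an error, so NG graphs (NG1..NG100) can be
drawn to their termination point and compared across assemblies of
different coverage.

Two reporting conventions are pinned by published assembly tables and kept
deliberately:

* **mean length is floor division** of total by count. This is forced by
  cells like 504,793,233/8,910 = 56,654.68 printed as 56,654. One published
  cell (473,173,317/3,611 = 131,036.64 printed as 131,037) follows
  round-half-up instead — the source table mixes conventions; the package
  floors everywhere and documents the outlier rather than matching it.
* **percentages are reported to one decimal, ties half-up** (Python's
  builtin `round` would band to even).

Coverage has two dialects because published tables use both without saying
so: `length` (total bp / genome size) and `nongap` ((total − N) / genome
size). Both are exposed; `summarize` reports the `length` dialect.

The telomere scan counts non-overlapping occurrences of the plant telomere
motif `TTTAGGG` *and* its reverse complement in each terminal window
(defaults: 1,000 bp window, ≥ 3 copies). The defaults are a package choice
— sources typically report the finding, not the threshold — set to accept
degraded tandem arrays while rejecting chance hits (the expected count of a
specific 7-mer in 1 kb of random sequence is ≈ 0.06 per orientation).

The k-mer genome-size estimator divides the total retained k-mer mass
Σ m·c(m) by the modal multiplicity, after discarding rows below a cutoff
(default 4) that removes the sequencing-error peak; a histogram whose
retained rows are a monotonically decaying tail has no coverage peak and is
an error. The estimator assumes a mostly single-copy genome; heterozygosity
and high-copy repeats bias it, which is why the test pins the contract with
an ideal spike and a Poisson simulation (recovery within 5% at 30×), not
with real shotgun data.

## Linkage mapping

The F2 model: each individual is the sum of two independent F1 gametes; a
gamete is recombinant between two loci with probability r. For a marker
pair, the likelihood of the 3×3 joint-genotype table follows by summing
over the 4×4 ordered gamete pairs. `estimate_rf` maximises this by EM
(the E-step computes the expected number of recombinant gametes per
observed class; r ← E[R]/2N), initialised at r₀ = 0.25, tolerance 1e-8 on
r, ≤ 1,000 iterations. Both linkage phases are fitted — repulsion is
coupling with one marker's homozygote codes swapped — and the
higher-likelihood phase is kept. LOD compares the fitted r against r = 0.5.
Pairs with fewer than 20 doubly-typed individuals are refused.

Grouping is the connected components of the graph with an edge where
LOD ≥ 3.0 and r ≤ 0.35 (conventional plant-mapping thresholds; the source
projects report only the outcome, 11 linkage groups). Ordering minimises
the sum of adjacent r — the travelling-salesman objective — by greedy
nearest-neighbour chaining from every start followed by 2-opt; for ≤ 8
markers the tests verify the result equals the exhaustive-permutation
optimum. Determinism: ties break lexicographically by marker id and the
whole order is flipped so the smaller terminal id comes first.

Map distances: Haldane d = −50·ln(1−2r) (no interference; also the
simulator's crossover model, so round-trip tests use it) and Kosambi
d = 25·ln((1+2r)/(1−2r)) (the default for reporting, as is common in plant
maps). Both reject r ≥ 0.5.

**Resolution caveat**: with markers ~0.1 cM apart and 500–1,000 plants,
adjacent-marker order is near the information limit — r ≈ 0.001 with a
standard error of the same magnitude. The recovery tests therefore assert
exact grouping always, but ordering (Kendall τ ≥ 0.95) at the separations
they simulate (2 cM between markers, n = 500). At study-realistic density
the estimated within-group order is only rank-correlated with the truth,
which is also why anchoring is driven by the map, whose marker *positions*
(not the estimated order) carry the information.

## Anchoring and pseudomolecules

Probe placement is exact string search of both allele variants of each
121-mer probe, both strands, over all scaffolds; `n_hits` counts every
occurrence genome-wide and only uniquely, identically matching probes are
used downstream.

Misassembly detection compares each scaffold's usable markers against the
map: markers from more than one linkage group → `inter_lg_chimera`;
within one group, after collapsing ties at 0.01 cM, a cM sequence in
physical order that is neither non-decreasing nor non-increasing →
`order_conflict`. At most one record per scaffold per kind; the headline
statistic is the number of contradicted scaffolds (the counting unit is a
package choice — per-scaffold matches the magnitude of published
misassembly counts). Detection only: breaking chimeras at inferred
breakpoints is out of scope (the original workflow confirmed such regions
manually).

Anchoring orders the clean scaffolds within each group by median marker cM
(robust to one misplaced marker; ties break by scaffold id) and orients
them by the sign of the Spearman correlation between physical position and
cM. Scaffolds with one marker, or all markers within 0.01 cM, cannot be
oriented from the map; a synteny-hint table (scaffold → strand) is
consulted, else the orientation is unknown and emitted as `+` with a `?`
flag. Gaps between adjacent scaffolds convert the cM interval between the
two junction-nearest markers at `bp_per_cm` (default: genome size / total
map length — a single global ratio, since no finer conversion is defined)
minus both overhangs; tied markers or a negative/undefined result fall back
to the fixed 1,000-N sentinel, and positive estimates are clamped below at
100 N. AGP v2.0 is emitted with 1-based inclusive `W` rows and `N`
(estimated) or `U` (sentinel) gap rows; internal coordinates are 0-based
half-open. Every build asserts pseudomolecule length = Σ components + Σ
gaps, and the tests rebuild the FASTA from the AGP byte-for-byte.

Group relabelling to an external chromosome nomenclature is a majority
vote of reference labels over each group's markers, ties to the smaller
label, with conflicts reported.

## Variant filters

All thresholds are read literally from the filtering rules they implement
and boundaries are inclusive: error sites need high-quality depth ≥ 10,
alternate frequency ≥ 0.70 and strand-bias p > 0.01; marker candidates need
a homozygous-alternate call at frequency ≥ 0.90, no other variant within
±60 bp in either parent, a 121-mer flank occurring exactly once in the
assembly, and no call in the other parent at the site. `depth_hq` must be
supplied by the upstream pileup as the count of reads meeting the
base-quality floor (30); frequency is computed over those reads. The flank
uniqueness screen is exact 121-mer counting — a deterministic stand-in for
an alignment-based uniqueness search, strictly stricter for identical
duplications and blind to diverged near-duplicates.

The strand-bias test is the two-sided Fisher exact test on the
allele × strand 2×2 table, computed as the hypergeometric sum of all
tables (fixed margins) whose probability does not exceed the observed
table's, with the standard 1+1e-7 relative guard against floating-point
ties. Two-sidedness by minimum-likelihood is a convention choice — "no
strand bias (p > 0.01)" does not fix sidedness — and the tests verify
equality with an independent implementation over every table with row sums
≤ 30 (one representative per symmetry orbit).

Marker spacing uses first-fit greedy sweeping per scaffold (accept the
first candidate ≥ 100 kb past the last accepted), which provably maximises
the number selected; when a per-scaffold quota is given the sweep instead
chases an even grid over the scaffold, still subject to the spacing floor.

Homopolymer classification: an indel is homopolymer-associated when the
maximal run of the inserted/deleted base touching the site is ≥ 4
("more than three consecutive nucleotides"). Edits apply right-to-left so
coordinates stay valid, refuse reference mismatches by name, and emit an
old→new coordinate map (positions inside replaced spans map to nothing);
inverting the edit set through that map restores the input exactly.

## Overlap merging

Candidate bridged pairs are those whose flanking-contig overhangs together
exceed the library insert size, or whose estimated gap is negative. The
terminal windows (10 kb) are aligned by exact 21-mer seeds voting for an
offset, then a semi-global edit-distance extension anchored at the left
suffix and the right start (free right tail), which is terminal-consistent
by construction; identity is matches / alignment columns, counting indel
columns. The merge thresholds (≥ 500 bp aligned, ≥ 95% identity) and the
10 kb window are fixed in config. The junction sits at the alignment column
midpoint (a deterministic choice; any junction inside the overlap is
equivalent for clean overlaps), giving |merged| = |L| + |R| − overlap for
gap-free alignments. The seeded aligner is validated against a full
dynamic-programming overlap alignment on ≤ 2 kb windows in the tests.

Containment removal screens pairs by shared 21-mers (sampled every 25 bp,
both orientations) and verifies by infix alignment of the shorter sequence
against the longer; the shorter is dropped when
1 − dist/|q| ≥ min_cov × min_ident (a combined budget: unaligned ends
surface as terminal gaps in the distance). Processing longest-first
guarantees the longer member of a mutually contained pair survives.

## Comparison module

Family deltas are per-family size differences against a chosen reference
assembly, aggregated into increased/reduced family counts and
gained/lost gene totals (the conservation identity gained − lost =
Σ deltas is asserted); a singleton is a gene whose family has exactly one
member overall. Clustering itself (e.g. MCL over all-vs-all protein hits)
is consumed as a membership table, not run. Recombination tracks
interpolate cM linearly between flanking markers (clamped at the terminal
markers), so window spans sum exactly to the group's map length; cM/gene
divides by the count of genes starting in the window (NaN when empty).
The mapping-population rule n = 100/(cM/gene) is the expectation of one
recombinant between neighbouring genes among 2n gametes.

## Synthetic data

The generator emulates the study design at a tractable scale: by default
2 linkage groups × 1 Mb, markers every 100 kb with unique 121-mer contexts,
1.1 cM/Mb (a 540 Mb genome over a ~600 cM map), telomere arrays at both
termini, 15% interspersed repeats (exact copies from a 6-element library,
200–5,000 bp — enough to create non-unique flanks, not a repeat-evolution
model), a 500-plant F2 with 0.5% genotyping error and 2% missing data, and
a 16-piece fragmentation. Crossovers are a Poisson process on the map
(count ~ Poisson(L/100), uniform positions — Haldane, no interference).
Defects are planted constructively so recall is well-defined: chimeras join
marker-bearing pieces from different groups; inversions reverse-complement
an internal span covering ≥ 2 but not all markers of a ≥ 3-marker piece
(whole-piece reversal is mere orientation and is planted separately by the
random per-scaffold strand flip). Cuts land at inter-marker midpoints so
every piece keeps ≥ 1 marker and no probe context is severed. Variant
tables plant a valid class plus decoy classes that each violate exactly one
filter dimension (depth 9; frequencies 0.75 and 0.60; strand counts
(2,0,0,28), Fisher p ≈ 0.002; a heterozygous call; a second SNP 40 bp away
in either parent; a repeat-interior non-unique flank; an other-parent call
at the site).

Everything is a deterministic function of the configuration seed
(per-component child streams, all below 2³¹).

**What passing tests show — and don't.** Planted-truth recovery shows the
implementations compute what they claim on data matching their model
assumptions: exact repeats, uniform crossover rate, error-free probe
contexts, abundant markers per scaffold. Real data add diverged repeats,
segregation distortion, heterogeneous recombination, array-genotyping
artefacts and scaffolds with zero markers; the detection and recovery rates
reported by the tests and the acceptance script are therefore upper bounds
under idealised conditions, not estimates of field performance. The
headline sequencing-derived numbers of the original project (contig N50,
anchored totals, contradiction counts) depend on the real read data and are
documented, not asserted.

## Problem sizes

The test suite and acceptance script use: 2 LGs × 1 Mb / 500 F2 for the
end-to-end study; 4 LGs × 1.5 Mb, 44 scaffolds, 12 chimeras + 8 inversions
for misassembly detection; 50 markers at 2 cM / n = 500 plus 3 × 200
replicate pairs for linkage recovery; all 2×2 tables with row sums ≤ 30
for the Fisher check; ≤ 2 kb windows for the alignment oracle. The full
suite runs in about a minute on one CPU.
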