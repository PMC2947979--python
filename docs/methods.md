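# Methods

This note records the statistical models implemented in `dsrnatk`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make the outputs
reproducible.

## Read model and preprocessing

Raw reads are collapsed to non-redundant (NR) sequences with clone counts;
3′ adapters are removed by exact suffix match — the leftmost position where
a prefix of the adapter (≥ `min_overlap`, default 5 nt) matches through the
read's 3′ end — and reads without a recognizable adapter are retained
untrimmed. Trimmed products shorter than 15 nt (configurable) are discarded
as unmappable. Exact matching was chosen over error-tolerant alignment
because it is deterministic and desk-verifiable; with modern base quality
the difference is marginal for the downstream statistics.

A mapped placement of an NR sequence with `copies` clones and `n_hits`
genomic placements carries weight `copies / n_hits`. This fractional
weighting conserves library mass exactly (the weights of all placements of
one NR sequence sum to its clone count), at the cost of attributing some
signal to the wrong copy of a repeat. The alternatives — discarding
multi-mappers (loses repeat-derived dsRNA, which is a large fraction of the
signal in plants) or counting each hit fully (inflates repeats) — distort
the category totals more. All coordinates are 0-based half-open internally;
GFF3 is converted on input.

## Classification

Each read receives exactly one category. Overlapping features are resolved
by a fixed priority (rRNA > tRNA > snoRNA > snRNA > miRNA > transposon >
CDS exon > 5′UTR > 3′UTR > intron > other ncRNA), ties within a category by
largest overlap then leftmost feature, and reads overlapping nothing are
intergenic. The priority is configurable; the default puts structural
ncRNAs above the mRNA moieties they are frequently nested in (tRNAs inside
introns/UTRs), which is the assignment a curator would make. Strand bias
per category is `lods = log10((S + c)/(A + c))` with pseudocount c = 1 over
sense/antisense weight; log10 makes a "100–1000-fold sense-enriched"
category read directly as lods 2–3. A read is sense/antisense only to a
stranded feature; unstranded features contribute to neither side.

Duplex typing calls a covered locus **inter**-molecular (two complementary
transcripts) when both strands carry ≥ 5 weight and the minority strand
holds ≥ 20% of the total, otherwise **intra** (fold-back). The thresholds
are exposed; 5/0.2 was chosen so that a handful of antisense mis-mapped
reads cannot turn a hairpin into a heteroduplex, and the call is monotone
in the minority strand weight by construction.

## Hotspots

Covered segments (maximal runs of combined-strand depth > 0) stand in for
individual dsRNA molecules. Their lengths are modelled per chromosome as
geometric on {1, 2, …}, fitted by the method of moments, p̂ = 1/L̄ — the
simplest estimator consistent with parameterizing by the average molecule
size per chromosome; chromosomes with fewer than two segments fall back to
a pooled fit. The tail probability of a length-L segment is
(1 − p̂)^(L−1). Segments supported by fewer than 2 distinct reads are
removed before testing (single-read "segments" are indistinguishable from
library noise and would otherwise dilute the Benjamini–Hochberg family);
BH runs genome-wide across all remaining segments and hotspots are called
at q ≤ 0.05. Segmentation is strand-combined — a double-stranded molecule
yields reads on both strands — with the strand composition retained as an
attribute (lods) rather than a partition. smRNA hotspots use the identical
machinery on the small-RNA library. Novel transcription units are hotspots
with zero annotation overlap, flagged by ≥ 1 bp overlap with any smRNA
hotspot and carrying the 19–26 nt size-class spectrum of their small RNAs.

## Differential windows and substrates

"Sliding-window" analysis is implemented as a non-overlapping 1 kb tiling
with post-hoc merging of adjacent significant bins into regions; a true
sliding step is available through the bin width/step parameters. Read
weight is apportioned to bins by fractional overlap, so binning conserves
library mass exactly. The per-bin test is two-sided Fisher's exact on the
rounded table [bin A, rest of A; bin B, rest of B]; Fisher was chosen
because these are unreplicated count libraries, the test is exact at any
depth, and it can be verified against an enumeration oracle. The p-value
is computed from the vectorized hypergeometric pmf over the table support
(the standard two-sided definition: total probability of tables no more
probable than observed); this is numerically identical to
`scipy.stats.fisher_exact` (asserted to 1e-12 in the tests) and ~25×
faster, which matters when scanning 10⁴–10⁵ bins. Fold change uses
per-million normalized counts with pseudocount 0.5 to stabilize empty
bins; significance requires fold ≥ 2 and p < 0.001. Direction "A>B" means
the first library is enriched; swapping libraries mirrors directions and
preserves p-values exactly. Substrate calls are bins significant A>B in
both the dsRNA and smRNA assays, annotated by majority-overlap category.

## Phasing

The statistic is a Howell-style slot-occupancy test. A window of m cycles
(default 9) of D nt (default 21) has m·D slots; a slot is occupied if ≥ 1
small-RNA 5′ end lands on it (duplicates don't count twice). Minus-strand
5′ ends are shifted +2 nt before the modulus, the 2-nt 3′-overhang
convention of siRNA duplexes. With n occupied slots, k of them in the best
register, p = P(K ≥ k) under the hypergeometric null × D (Bonferroni over
registers), capped at 1. Windows slide across each locus in D-nt steps; at
loci shorter than one window all full cycles are used; windows with < 4
occupied slots are not tested (a window with 3 slots can reach nominal
p < 1e-3 vacuously). Only 20–22 nt reads contribute by default, reflecting
the 21-nt product size of the dicing reaction. The Bonferroni bound makes
the test conservative: on unstructured loci the call rate at threshold α
stays well below α (measured ~0.1% at α = 0.1% on 1,000 null loci).

## Conservation

Per-base conservation scores from a multi-species alignment are consumed
as bedGraph; building the alignment is out of scope. Within each moiety
(CDS exon, 5′UTR, 3′UTR, intron, intergenic, transposon), hotspot bases and
the complementary "flanking" bases partition the moiety exactly; each
maximal region contributes its mean score, regions with < 10 scored bases
are dropped as unstable, and the two sides are compared with a two-sided
Wilcoxon rank-sum test **on per-region means**, not per-base values —
per-base scores are strongly autocorrelated and would fabricate precision.
Direction is the sign of the median difference.

## Structure models

The constraint rule is mechanical: position i gets '|' iff read depth on
the transcript's strand is > 0 at the corresponding genomic base, else '.';
minus-strand transcripts read their coverage window reversed so the string
runs 5′→3′. '|' means "must pair with someone" (Vienna dialect), not a
specific partner. Two engines satisfy the same contract:

- **vienna** — minimum free energy via the ViennaRNA Python bindings, with
  the constraint string passed verbatim and enforced; the score is G in
  kcal/mol.
- **builtin** — a constrained Nussinov maximum-base-pairing DP (allowed
  pairs AU/UA/GC/CG/GU/UG, minimum hairpin loop 3), for environments
  without ViennaRNA and as the exhaustively verifiable reference; the
  score is the pair count.

Both engines either pair every '|' position or raise
`ConstraintInfeasibleError` naming the positions — constraints are never
silently relaxed. Infeasibility is real and common when the '|' set is not
actually stem-shaped (e.g. forcing every covered base of an arbitrary
sequence to pair); the pre-check catches positions with no admissible
partner anywhere, and the DP catches global contradictions. The builtin
traceback is deterministic (position i pairs the smallest admissible
partner achieving the optimum, pairing preferred on ties), so outputs are
bit-reproducible. All-'.' constraints reproduce the unconstrained fold
bit-identically on both engines. Per-base read densities exported with a
model are depth divided by the number of covered nucleotides of the
transcript. Exchange formats are CT and FASTA-style dot-bracket, both
round-tripping the pair table.

## Synthetic data

The generator emulates the *structure* of a dsRNA-seq/smRNA-seq study on a
toy genome: (i) a background population of covered segments with exactly
geometric lengths (mean 40 nt by default), laid out non-overlapping with
≥ 1 nt gaps so realized segment lengths equal the drawn ones and planted
elements can never merge with background; (ii) planted hotspots as fully
covered 400-nt segments (10× the background mean); (iii) four libraries
(dsRNA/smRNA × A/B) with one short expressed patch per 1 kb bin whose read
count is Poisson (mean 50 weight/bin by default), the planted bins' A-rate
multiplied by the configured fold (4×) — clustering the bin's reads into a
patch mirrors the clustered nature of real expression and keeps the
coverage landscape from saturating; (iv) phased loci inside planted
differential bins emitting 21-nt reads on one register; (v) a conservation
track at 0.2 background / 0.9 inside hotspots with Gaussian noise
(sd 0.05). One integer seed drives named independent substreams per
component, so outputs are byte-identical under a fixed seed and enabling
one component does not perturb another. Segment reads are shared between
the A and B dsRNA libraries so the structural background does not confound
the differential comparison.

What it does **not** emulate: sequencing error, base quality, mapping
ambiguity (all reads are unique-hit, weight 1), fragment-length biases,
nuclease digestion inefficiency, or realistic sequence composition (the
genome is i.i.d. uniform ACGT — which is why forcing all covered bases of
a random transcript to pair is usually infeasible, unlike for a real
folded RNA). Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated generative model, not
end-to-end accuracy on real libraries.

Truth matching uses ≥ 50% reciprocal overlap, the standard interval-calling
convention.

## Problem sizes and numerics

The validation suite runs: hotspot recovery on a 1 Mb genome with 20,000
background segments and 50 planted hotspots; differential calibration on
10,000 null plus 10 planted bins at ~50 weight/bin; 1,000 null phasing
loci; the exhaustive Fisher sweep over all 2×2 tables with row margins
≤ 30; Nussinov against full structure enumeration at length ≤ 12. These
sizes were chosen as the smallest at which the binomial/BH error bounds in
the checks are comfortably away from their thresholds. Oracle agreement is
exact to ≤ 1e-9 (Fisher, phasing, rank-sum vs permutation) and ≤ 1e-12
(geometric tail). Ties in the two-sided Fisher definition are included
with a 1 + 1e-7 relative tolerance, wide enough for floating-point-equal
probabilities and far below the smallest mathematically distinct pmf ratio
at these margins. BH q-values come from
`scipy.stats.false_discovery_control`. Degenerate inputs are defined, not
special-cased: empty read sets give empty maps/zero tracks, both-zero bins
give fold 1/p 1, a geometric fit at p̂ = 1 gives tail 0 for L > 1, and a
locus with no small-RNA reads is "non-phased, no data".
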