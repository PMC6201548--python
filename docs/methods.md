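# Methods

This note documents the models, conventions and design choices behind
`karyoforge`: what the simulator emulates, how the assembly and analysis
stages make their decisions, and what the packaged experiments do and do not
establish.

## Coordinates and containers

All internal coordinates are 0-based, half-open; conversion to 1-based
inclusive happens only at the AGP and report boundaries. Interval tracks
(CNE, msHSB, assembly gaps) are normalized on load — sorted, clipped to the
chromosome, overlaps merged — so per-window densities are well defined
regardless of input order, and merging never changes any density value.
Percentages are kept at full precision internally and rounded half-even to
two decimals only in reports.

## The synthetic study system

The generator is the package's stand-in for a sequenced, aligned genome
trio; its defaults describe a scaled-down avian-like genome (4
macrochromosomes of 15–25 Mb, 8 microchromosomes of 3–7 Mb, ~120 Mb total).
Real avian genomes are roughly tenfold larger; the scale-down keeps each
simulated replicate around a second while preserving the per-chromosome
event, scaffold and marker densities the analyses operate on.

**CNE landscape.** Conserved non-coding elements (log-normal lengths, median
100 bp, clipped to 20–1000 bp) are placed to hit a genome-wide density of
0.087, the value reported for the chicken genome in multi-species avian
comparisons. The landscape is deliberately structured, because the package's
key contrasts depend on regional heterogeneity:

* a fraction of 100-kb domains (15%) are CNE deserts at 5% of the ambient
  intensity, mimicking the CNE clustering around developmental loci and the
  gene/CNE deserts of real genomes;
* subtelomeric regions (200 kb per end) carry 15% intensity, reflecting the
  repeat-rich, regulation-poor character of chromosome ends;
* msHSB blocks (default 8 blocks of 1.5–4 Mb, matching the "> 1.5 Mb" class
  used for stable-genome contrasts) carry an enriched density whose ratio to
  the genome target defaults to 0.107/0.087; the non-msHSB intensity is
  rescaled so the genome-wide target still holds.

Element counts per region are Poisson rather than quota-filled: a fixed
quota would anti-correlate neighboring window densities and distort the
rank tests' null behavior. A top-up loop nudges the realized genome-wide
density to within ±0.005 of target.

**Planted rearrangements.** Breakpoints are sampled over 1-kb windows with
probability ∝ (1 − cne_fraction)^γ, γ = 8 by default, and windows inside
msHSBs excluded (msHSBs are rearrangement-free by definition). The class
exponents differ: inversions use γ, fissions 8γ. The near-hard fission bias
encodes the empirical observation that avian fissions occur in intervals
containing essentially no CNEs at all; fusions do not sample breakpoints —
they join existing chromosome ends, whose subtelomeric context supplies the
intermediate CNE density observed for fusion breakpoint regions. The
resulting expected class ordering, msHSB > genome-wide > intrachromosomal >
fusion > fission, is a *consequence* of the sampler, not an assertion.

Events are applied as fissions, then fusions, then inversions:

* fissions cut only forward-oriented, unrearranged segments, at least 2 Mb
  from chromosome ends;
* fusions join two whole chromosomes (random orientation of the second) and
  never join two chromosomes sharing an ancestral unit, so fission products
  are not silently re-merged;
* each inversion reverses a span (≥ 0.7 Mb) strictly inside one colinear
  ancestral segment, with 250-kb margins to every existing boundary.

These feasibility rules make the planted multiset *identifiable*: the final
karyotype's homology map decomposes uniquely into the planted events, so
"exact recovery" is a well-posed target. Every operator is a permutation of
ancestral segments — total length and all track bases are conserved
exactly. The order-of-events convention trades a little biological realism
(real histories interleave) for that identifiability; the analyses
themselves never use it.

**Observation model.** The derived karyotype is cut into scaffolds
(default 150) at uniform positions; with probability 0.1 a scaffold is made
chimeric by concatenating a fragment from a different chromosome or ≥ 1 Mb
away, so comparative conflict is always detectable in principle. Alignment
blocks map scaffold segments to ancestor coordinates, minus two kinds of
unalignable sequence: 10 kb at each ancestral chromosome end (telomeres
never align) and an exponential gap (mean 5 kb) at every intra-scaffold
junction (alignment quality decays at breakpoints). Spanning-pair
"physical" coverage at each junction is Poisson: λ = 400 for true joins,
λ = 5 for chimeric ones, loosely matching the coverage ranges reported for
real scaffold split testing. The PCR oracle answers truthfully for
junctions whose unaligned span is < 6 kbp and returns "untestable"
otherwise (6,000 bp exactly is untestable — the strict reading of the
testability rule). BAC-like point markers every 50 kb on the ancestor
report their true hybridization chromosome and order.

## Assembly and anchoring

**Syntenic fragments.** Blocks of one scaffold merge when they share a
reference chromosome and strand, their gaps on both genomes are below the
resolution (default 150 kb) and their order is consistent; merged fragments
shorter than the resolution are discarded. A scaffold join is *conflicting*
when its flanking SFs disagree with the reference: different chromosomes, a
reference gap above the resolution, inverted order, or a strand flip.

**Threshold calibration.** Candidate thresholds are 0 and every observed
coverage + 1; agreement(T) counts PCR-confirmed joins with coverage ≥ T
plus refuted joins with coverage < T; the smallest maximizing T is chosen
(most conservative splitting — with cleanly separated Poisson regimes it
sits just above the largest refuted coverage). Untestable joins contribute
nothing. Reference-assisted assemblers often express this knob as a
coverage *percentage*; here the threshold is an absolute spanning-pair
count, matching how selected thresholds are actually reported in scaffold
split testing.

**PCF construction.** Conflicting joins below threshold are split unless
PCR-confirmed (confirmed structures are inputs and are never split);
missing coverage counts as zero with a logged warning. Fragments are
assigned to the reference chromosome carrying most of their aligned length,
ordered by length-weighted SF reference midpoints, and oriented so the
reference ascends. One PCF per reference chromosome: target-specific
fusions are visible *inside* members (a retained scaffold spanning two
units), while target-specific fissions and cross-scaffold inversions are
invisible to reference ordering by construction — recovering them is the
anchoring stage's job.

**FISH anchoring.** A PCF whose markers agree (one chromosome, concordant
order) is placed whole and oriented when it has two markers at distinct
offsets ('+' for concordance, '−' for reversal, unoriented otherwise).
Disagreeing PCFs (markers on several chromosomes or non-monotone order) are
counted and, under the default "report" policy, left unplaced. The pipeline
uses the "split" policy instead: each member of a disagreeing PCF is placed
by its own markers (majority chromosome, median observed index, internal
concordance for orientation), with unobserved members travelling alongside
their nearest observed neighbor. Member-level placement is what lets FISH
evidence overrule reference order, and is why clean simulations recover the
planted karyotype exactly. AGP output uses fixed 100-bp gap rows (unknown
true gap sizes) of type "contig", evidence "map".

## Homology maps and event counting

Maps are built by walking each chromosome's placed fragments and emitting
their SF chains; adjacent same-unit, same-strand, order-consistent segments
merge across reference gaps up to 1 Mb (bridging scaffold tails lost below
the SF resolution), and segments under 150 kb on the reference are dropped.

Counting conventions: a chromosome concatenating k distinct reference units
contributes k − 1 **fusions** (junction-based); a unit present on m
chromosomes contributes m − 1 **fissions** (piece-based). These are the
unique conventions consistent with the identity
`#chromosomes = #units + fissions − fusions`, which is asserted on every
fixture and simulation. A reference *homolog* is **intact** when each of its
units occupies exactly one chromosome and no chromosome carrying it carries
any other homolog — the homolog grouping matters only for unit sets that
split a reference chromosome into ancestral parts (chicken 4 = q-arm unit
plus the ancestral 4p microchromosome): the budgerigar's 4p is fused while
its 4q unit is whole, so homolog 4 is not intact, giving the published 13
intact homologs under ancestral units. Microchromosome bookkeeping (fused
vs intact) is unit-level over the 17 mapped chicken microchromosomes plus
4p.

**EBR detection** classifies reference-coordinate intervals: consecutive
same-unit segments on different chromosomes bound a *fission* EBR;
same-unit, same-chromosome adjacencies broken in order or strand bound an
*intrachromosomal* EBR; each distinct-unit junction contributes a *fusion*
EBR at each flanking reference breakpoint, extending into the unaligned gap
toward the next same-unit segment or the chromosome end. Intervals are
clipped to ≥ 1 bp inside the chromosome; at a shared breakpoint the class
precedence is fission > fusion > intrachromosomal, so classes partition the
set. EBRs longer than 100 kb are kept but flagged as excluded from CNE
analysis.

**Inversions.** Within each (unit, chromosome) group, the segments' target
order and strands form a signed permutation of their reference ranks; its
sorting-by-reversals distance is summed over groups, taking the minimum
over the permutation and its mirror because a chromosome's global
orientation is arbitrary. Distances are exact up to 10 elements (a cached
breadth-first table covers n ≤ 6; A* with the admissible ceil(b/2)
breakpoint bound covers 7–10); beyond that the breakpoint lower bound is
returned and labeled inexact. Equality of the summed distance with a real
species' published inversion totals is *not* asserted — those derive from
marker-order tables with an unstated counting procedure.

## CNE density statistics

The EBR-vs-flank contrast follows the classic design: EBRs under 1 kb are
extended by 1 kb on each side, then two abutting windows of the (extended)
EBR's size are laid upstream and two downstream; windows clipped at
chromosome ends are flagged truncated, and only EBRs ≤ 100 kb enter.
Kruskal–Wallis runs across the five positional groups and Mann–Whitney U
compares EBR densities with pooled flanks. The genome-wide scan tiles each
chromosome into 1-kb windows from position 0 (final partial windows
dropped), discards windows with ≤ 50% sequenced bases (via the gap track;
with no gap track everything counts as sequenced), and assigns each window
one class with precedence EBR classes > msHSB > rest (largest-overlap
tie-break among EBR classes, then fission > fusion > intra). Distances to
the msHSB-average density are counted in whole windows along the
chromosome; zero-CNE windows on chromosomes with no qualifying window are
reported missing.

The Mann–Whitney implementation enumerates all group assignments exactly
(mid-rank ties included) when the pooled sample is at most 12, and
otherwise uses the normal approximation with tie and continuity
corrections; Kruskal–Wallis uses mid-ranks with the standard tie
correction, defining H = 0 when all observations tie. No multiple-testing
correction is applied anywhere, and reports say so.

## The packaged experiments

`karyoforge.experiments` fixes the replicate studies' conditions; their
problem sizes were chosen once, for statistical resolution at desk scale:

* **Planted recovery** — default simulation with `chimera_rate = 0`: the
  assemble → anchor → homology chain must recover the exact planted event
  multiset, place 100% of SF-covered length and orient every fragment. The
  50-kb marker spacing guarantees ≥ 2 markers per retained fragment
  (≥ 150 kb), which orientation requires.
* **Calibration** — 30 joins drawn half-and-half from Poisson(400) and
  Poisson(5) with truthful PCR; the chosen threshold should separate the
  regimes with full agreement.
* **Class ordering** — 24 inversions, 16 fusions, 12 fissions per replicate
  (about twice the default mix, sharpening the per-class window counts);
  EBRs from the exact homology map, snapped to the 1-kb window grid, then
  the genome-wide scan.
* **Flank depletion** — 25 inversions, 6 fusions, 5 fissions (an
  intrachromosomally dominated EBR set, as in real avian comparisons,
  where intra EBRs outnumber interchromosomal ones about five to one);
  the first 60 detected EBRs enter the one-sided contrast.
* **Type-I error** — a spatially homogeneous CNE field (no deserts, no
  subtelomeric damping) with 60 uniformly placed 2-kb breakpoint intervals
  per replicate; the two-sided flank test's rejection rate at α = 0.05 is
  measured over 200 replicates.

Snapping EBRs to their enclosing 1-kb windows reflects the windowed
resolution of the whole analysis; exact maps would otherwise yield
zero-width breakpoint gaps.

## What passing tests show — and what they do not

The simulator controls everything real data does not: alignment is exact up
to declared unalignable margins, PCR is error-free by default, markers are
dense and unambiguous, and rearrangement classes differ only through their
breakpoint bias. Passing the recovery and contrast tests therefore shows
the *methods* are correct and well-calibrated under their stated
assumptions — not that real genomes satisfy those assumptions. In
particular: repeat-driven misalignment, reference assembly errors,
segmental duplications, marker cross-hybridization and lineage-specific CNE
turnover are all outside the model; absolute densities match the real
system only because the generator was parameterized to the published
genome-wide values; and the recovered-event identifiability depends on the
feasibility rules above, which real histories can violate (e.g. re-fusion
of fission products).

## Numerical and degenerate-input conventions

Empty length multisets, zero-length windows, empty samples, single groups,
unknown junctions/BACs/species and infeasible event counts raise
`ValueError`/`KeyError` rather than guessing. Degenerate rank tests (all
values tied) return p = 1. Determinism is a contract: every stochastic
stage takes a seed or generator, stage streams are spawned from a single
`SeedSequence`, and re-running a pipeline configuration reproduces
byte-identical artifacts (checksummed in the run manifest).
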