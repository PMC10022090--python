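# Methods

## Problem and model

Nanopore R9-class basecalls miscall the length of repeated DNA far more
often than they miscall individual bases, because an exact repeat produces a
near-constant pore signal from which the repeat count is hard to recover.
The package models this directly at the alignment layer. An **n-polymer** is
at least `min_repeats = 3` exact copies of a repeat unit of length
`1 ≤ n ≤ n_max = 6`. Three copies is the point where a unit is bordered on
both sides by another copy of itself (with two copies each unit still abuts
non-repetitive sequence, and few length errors occur); above n = 6 the pore's
5–6 base sensing window resolves the sequence and errors fall off, and
n-polymers with longer units are rare anyway.

All penalties are negative natural logarithms of measured event
frequencies, so minimising total penalty maximises the likelihood of the
implied error/mutation set under an independence assumption. Natural log is
the operative convention throughout: doubling an event's probability lowers
its penalty by exactly ln 2 ≈ 0.69.

### Penalty components

* **Substitutions** `P[i,j] = −log((C_P[i,j]+ε)/(Σ_j C_P[i,:]+ε))`, with
  `ε = 0.01` guarding never-observed events. Matches are charged `P[x,x]`
  (a small positive cost), not zero; tests that need zero-cost matches build
  an explicit affine-only model.
* **Affine gaps**. Indel-length confusion vectors `C_I`, `C_D` count each
  contiguous run once at its run length; a length-0 bucket counts aligned
  columns that carry no such event, putting the normalised frequencies on a
  per-opportunity scale (without it the penalties could never reach the
  magnitude of the default `G_open = 5 ≈ −log 0.0067`). A least-squares fit
  of `penalty(len) ≈ G_open + (len−1)·G_extend` over observed lengths gives
  the model parameters; defaults (5, 1) are used when data are insufficient.
* **Copy-number tensor** `N[n,i,j]`, shape 6×100×100: penalty for observing
  j copies where the reference has i. Rows are normalised independently.
  Two monotonicity families are then enforced: within a row, penalties grow
  with indel size; across rows, a longer polymer is cheaper to change by a
  given amount. Enforcement is a single relaxation pass in topological
  order over the constraint DAG (rows processed away from the source,
  offsets outward), raising each violating entry to its bound plus 1e−6 —
  the fixed point that iterated monotone sweeps would reach. The package
  implements these inequalities in their likelihood sense (the likelier
  event is cheaper); a `printed_direction` flag flips both families for
  anyone wanting the opposite orientation.
* Indices into `N` are clamped to `l_max − 1 = 99`; annotations store true
  copy counts and clamp only at lookup time.

### Reference annotation

For each n, each position that starts a unit of an eligible polymer carries
`l` (total copies in the polymer) and `idx` (0-based unit index). The
scanner finds maximal period-n stretches (`seq[q] == seq[q+n]`, `N` bases
equal to nothing) and annotates every phase class with at least 3 whole
copies, so phase-shifted polymers (AT×4 and TA×3 inside `ATATATAT`) coexist,
as do polymers of different n. The scan is O(|R|·n_max) time and
O(|R|·n_max) space; a brute-force copy-counting scanner serves as the test
oracle. Realignment windows are annotated per window — annotation is a
purely local property, so annotating the substring equals clipping a
contig-level annotation, and windows are read-sized, making the cost
negligible next to the DP.

### Alignment

Five matrices D, I, M, S, L are computed in lockstep per cell, in that
order. D/I are the standard Gotoh gap states. S (shorten) consumes n
reference bases per step and L (lengthen) n read bases; both are written
*forward* from the current cell and hand their values back to M at the
landing cell with no transfer penalty (traceback happens entirely inside M,
using stored predecessor and run-length information). Gating conditions:

* entering S or L from M requires the reference column to start a polymer
  (`l > 0` and `idx == 0`);
* continuing S requires the column to be a unit start of the *same* polymer
  (checked as `run == n·idx`), with at most `l` units deleted in total;
* every L step additionally requires the next n read bases to equal the
  repeat unit, so only genuine extra unit copies can be inserted.

The total charge for changing a polymer of l copies by k units is
`N[n, l, l∓k]`, bookkept from the anchor M value rather than summed per
step. Ties in M's minimum resolve in the fixed order diagonal > S > L > D >
I, making CIGARs deterministic. Ends are anchored (true global alignment in
the window); the first row/column are reachable through gap chains, so an
empty window yields a pure-insertion CIGAR. Non-ACGT read bases are charged
the worst substitution penalty and can never participate in S/L (a repeat
unit containing N annotates nothing, and N compares unequal to everything).

With S and L disabled the recurrences reduce exactly to affine-gap
Needleman–Wunsch; the test suite checks score equality against an
independent Gotoh implementation, and the full model against exhaustive
branch-and-bound path enumeration on small pairs.

### Follow-banding

Realignment trusts the mapped position, so the DP only needs to explore
near the read's original alignment path. The original CIGAR is expanded to
an op-per-base I/D path (each M → I then D); cumulative counters INSs/DELs
locate the band centre on every anti-diagonal, and a cell of the compact
(2b+1) × (path length) matrix maps to full coordinates via
`row = INSs[i] + b − j`, `col = DELs[i] − b + j`. The default half-width is
b = 30 and is CLI-adjustable; S/L forward writes whose target offset falls
outside the band are dropped. Banded penalties can never be smaller than
unbanded ones, with equality whenever the unbanded optimum stays in band.
One useful consequence of the M→ID expansion is that the band always
contains the original path itself, so any consistent seed CIGAR keeps the
terminal cell reachable even at b = 0; the band-failure branch in the
pipeline is purely defensive. Evaluating a CIGAR at b = 0 doubles as the
score-replay used in tests.

### Realignment pipeline

BAM in, BAM out: primary mapped records get their core M/I/D CIGAR rebuilt
by banded realignment against `ref[POS : POS + ref_consumed]`; POS,
sequence, qualities, names, flags and order never change; NM/MD are
recomputed. Soft/hard clips are preserved verbatim and excluded from the
aligned window; secondary, supplementary and unmapped records pass through
untouched, as do records on contigs missing from the FASTA (with a
warning). Multiprocess workers receive deterministic read batches, so the
output is identical for any worker count. Base qualities do not enter the
penalties.

### Concordance

Per-position Gini purity `GP = Σ pᵢ²` over the classes A, C, G, T, deletion;
insertions are scored separately per junction (classes = distinct inserted
strings, ε included) because their variable class count shifts the GP
distribution. Columns below a minimum depth of 5 reads are skipped — GP at
tiny depth is mostly noise. Histograms use 0.01-wide bins on [0, 1]. An
optional per-haplotype mode groups reads by HP tag (untagged reads form an
unphased group) so heterozygous variants do not register as discordance.

### Truth VCF standardization

Both phased haplotypes are materialised (rejecting unphased heterozygotes,
overlapping records and REF mismatches, with coordinates), then treated as
reads: realigned to the reference with the banded aligner, seeded by their
construction CIGAR. Contigs are chunked at the midpoints of variant-free
stretches ≥ 200 bp (configurable), so whole-contig DP is never needed and
chunks are independent. Every contiguous edit run of the realignment
becomes one record (anchor base on the left for indels, right-anchored in
the degenerate chunk-start case); per-haplotype records merge into
genotyped records — multi-allelic 1|2 only when position *and* REF allele
coincide, separate phased records otherwise, which avoids REF-extension
collisions with neighbouring records. Applying the standardized VCF
reproduces the input haplotype sequences byte-for-byte; the suite checks
this round trip on 100 random toy VCFs.

## Synthetic data

The simulator emulates the parts of nanopore data this package acts on:

* references with embedded polymers `(n, copies, count)` on a random
  background, flanks adjusted so embedded polymers are not extended, with a
  `clean_background` mode that scrubs accidental repeats for controlled
  experiments;
* per-polymer copy-number errors drawn from a configurable confusion
  tensor. The default is a parametric family in which the per-polymer
  miscall probability is `min(0.75, 0.0105·copies^1.6 / n)` — about 42% for
  a 10 bp homopolymer, decreasing with unit length — with geometric error
  magnitude (p = 0.65) and a mild insertion bias (55/45). The built-in
  default penalty model is the −log of this same family, regularised; it is
  the package's *prior*, replaceable by `npore train-model` on real data;
* uniform substitutions and affine-shaped background indels at configurable
  rates (defaults 1% and 0.2%/base);
* two CIGARs per read: a truth CIGAR with copy-number indels anchored at
  polymer starts, and a *naive* CIGAR that mimics a context-blind aligner
  by left-shifting indels and merging an insertion with an equal-sized
  nearby deletion (within 20 bp) into an all-M substitution stretch. The
  BAM carries the naive CIGAR, giving realignment a measurable defect to
  repair.

Two preset configurations define the package's standing experiments.
`penalty_estimation_config` isolates the copy-number channel: homopolymers
spaced ≥ 40 bp apart, no background indels, error rows confined to Δ ∈
{0, ±1} (50/26/24), depth 600 over a 2.6 kb reference — deep enough that
every occupied confusion cell carries ≥ ~700 observations and the
−log-frequency estimates sit within ~3 standard errors of 0.03 of the
generating values. Recovery is asserted on the embedded homopolymer rows:
rows for n ≥ 2 are intentionally *not* asserted because they aggregate
cross-unit projections (a 10 bp homopolymer is simultaneously a 5-copy
dinucleotide repeat), so the measured row is a mixture — a real property of
the statistic, visible on real data too. `realignment_config` packs thirty
12 bp homopolymers a few bases apart with a heavy-tailed error row, so that
opposite-sign error pairs within one read are common and the naive merge
produces genuinely discordant pileup columns; realignment then strictly
reduces the number of columns with GP < 0.5 (the suite asserts the strict
direction of effect, not a magnitude).

What passing these tests does *not* show about real data: the simulator has
no signal-level structure (no sequence-dependent substitution bias, no
quality strings, no chimeras or clipping), its naive aligner is a stylised
minimap2, and real confusion tensors are dataset-dependent — the package's
default model is a reasonable prior, not a measurement of any particular
flow cell.

## Numerical and design choices

* Natural log everywhere; ε = 0.01 by default in every estimator.
* Regularisation adjusts by the minimal amount + 1e−6; it never lowers a
  penalty.
* Score comparisons in tests use 1e−9 absolute tolerance; scores are plain
  float64 sums of table lookups, so replay agreement is exact to rounding.
* Deterministic tie-breaks (diagonal > S > L > D > I; gap opening preferred
  over extension at equal cost) make byte-identical CIGARs across runs and
  worker counts.
* Degenerate inputs: empty window → pure insertion; empty read → pure
  deletion; empty sequence annotates to an empty annotation; invalid
  characters raise with the offending position.
* The unbanded `align()` is implemented as the banded engine under a band
  wide enough to cover every cell, so there is one DP code path.
* Problem sizes in the suite (reads ~120–150 bp, references 0.6–2.6 kb,
  depths 12–600 depending on the experiment) were chosen so each standing
  experiment has comfortable statistical margin at desk scale.

## Known limitations

* The strict n-polymer definition (exact copies only) excludes near-repeats
  such as `AAATAAAATAAAT`; a fuzzier definition would widen coverage at
  extra compute cost.
* Only the representation of indels changes; reads are never re-mapped, so
  mapping errors stay.
* The DP is pure Python and processes ~30–60 reads/s at fixture scale;
  whole-genome use would want a compiled kernel.
* Penalties estimated from an input BAM inherit that BAM's alignment
  biases; the effect on penalties is logarithmic (a 2× rate error moves a
  penalty by 0.69), and a second estimation round on realigned output is a
  natural extension, not implemented.
* C_N counting attributes net in-span length change to whole-unit copy
  changes only; events that are not unit-multiples feed the affine
  statistics instead.
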