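# Methods

This note records the models, parameter choices and numerical conventions
behind seedmap, and what the synthetic-data experiments do and do not show.

## Mapping model

A read is placed by exact-seed anchoring followed by banded verification.

**Seeds.**  Non-overlapping seeds of a single fixed length *s* ∈ [6, 14] at
offsets 0, s, 2s, …; when *L* mod *s* ≠ 0 one extra seed is anchored at
*L − s* so the tail is covered.  There is no seed-length step-down: one
length is used for the whole run.  Seeds containing N are emitted but can
never match (the index stores no N-containing k-mer), and N positions in a
read always count as mismatches during verification.

**Hotspots.**  Each seed hit implies a candidate read start (hit position
minus read offset, clamped at −band).  Implied starts on the same reference
are sorted and grouped greedily so that max − min within a group never
exceeds the indel band; this "fuzzy" grouping is what lets a read with a
short indel keep a single hotspot even though its seeds disagree on the
exact diagonal.  A hotspot's vote count is the number of distinct read
offsets contributing (a seed hitting twice in one group still votes once);
its candidate start is the modal implied start (ties toward the smaller
coordinate).  Hotspot order is total and deterministic: votes descending,
then reference ordinal, candidate start, and + before −.

**Verification.**  The full read is aligned end-to-end (no clipping)
against the window [candidate − band, candidate + L + band), truncated at
reference boundaries, with free reference overhangs on both sides and the
path confined to diagonals within the band of the candidate diagonal.
Costs are unit Levenshtein: mismatches and inserted/deleted bases share one
integer error budget, matching how the allowance is specified (an absolute
count, or ⌊fraction × L⌋ per read in percent mode).  No affine gap penalty
and no base-quality weighting: qualities are carried through I/O but never
scored.  Rows whose minimum exceeds the allowance abandon the candidate
early.

**Tie-breaking in traceback.**  Among co-optimal paths the traceback
prefers extending the current gap, then the diagonal; indel events are
additionally left-normalized (shifted to their leftmost equivalent
position) when aggregated into pileups.  Without this, equivalent gap
placements in repetitive context (e.g. homopolymers) scatter one planted
indel across neighbouring anchor positions and fragment its event count.

**Classification and early exit.**  All distinct locations at the minimal
verified distance d\* are retained, up to `max_reported_locations`
(default 100); locations are distinct when they differ in reference,
strand, or by more than the band in start position.  A placement with edit
distance *d* retains at least m − d exact seeds (m = ⌊L/s⌋ non-overlapping
seeds: every substituted or inserted base corrupts at most one of them, and
a deletion corrupts at most the seed spanning its junction), so the vote
scan stops at the first hotspot with fewer than m − d\* votes — it can
neither beat nor tie the incumbent.  This makes the early exit exact rather
than heuristic, which the oracle-equivalence test verifies directly.

**Seeding-failure probability.**  `estimate_mismap_probability` returns
(1 − (1−p)^s)^m — the chance that independent per-base errors at rate *p*
corrupt every non-overlapping seed, the only way the true locus can escape
hotspot generation.  It is a bound on the seeding contribution to
mismapping, not a full model of verification-stage ties.

Known limitation: the verification band is centred on the hotspot's modal
diagonal, so a read whose alignment drifts close to the full band *and*
whose candidate start sits at the far edge of its group could, in
principle, exceed the corridor.  With the default band (5) and realistic
indel sizes (1–3 nt) the corridor has ample slack, and the oracle test
covers exactly this regime.

## Variant calling

Only uniquely mapped reads enter the pileup; multimapped reads are written
to their own file and ignored downstream.  Each read contributes one count
per reference position it covers, following its edit transcript; insertion
events are anchored at the preceding reference position and deletion events
at their first deleted position, both left-normalized.

At each site with depth N ≥ `min_depth` (10), the most frequent
non-reference base with count k ≥ `min_alt` (3) is tested with a two-sided
Fisher's exact test against the table expected from a flat sequencing-error
rate ε (default 1%): (k, N−k) vs (round(εN), N−round(εN)).  A call is
emitted when p ≤ α (0.01) and k/N > 5ε.  Indel events are tested
identically with their event counts.  The contingency-table construction is
a package design decision, deliberately exposed through
`VariantCallingParams` so alternatives can be swapped in; there is no
base-quality or strand-bias filtering by default, consistent with qualities
being unused throughout.  The het/hom flag (alt fraction ≥ 0.2 / ≥ 0.8) is
informational only.

The Fisher p-value sums hypergeometric point probabilities not exceeding
the observed one within relative tolerance 1e−7, computed in log space from
a cached log-factorial table; any zero margin returns p = 1 by convention.
Tests compare it against exact rational enumeration (small totals) and an
independent scipy-based enumeration (all tables with total ≤ 60, worst
relative error below 1e−9).

## Quantification

RNA-seq reads are mapped directly to spliced transcript sequences; spliced
genome alignment is out of scope.  Expression is RPKM over unique reads,
with total mapped reads (unique + multi) as the denominator by default.
Multimapped reads are excluded from counts (an optional uniform-split mode
exists, off by default).  Robustness between two runs is the Pearson
correlation of log10(rpkm + 0.01); the pseudo-count and transform are
parameters, since raw-scale correlation is dominated by the few most
abundant transcripts.

## Simulator: what it emulates, and what it does not

`simulate_genome` draws i.i.d. bases at a chosen GC content and can paste
verbatim repeat units at non-overlapping random positions.
`simulate_reads` draws uniform start positions and strands (optionally
weighted per reference, which is how transcript abundances are modelled),
applies per-base substitutions to a uniformly different base, and insertion
/deletion events at per-base rates with geometric lengths
(p = 0.7, mean ≈ 1.4 nt) — fixed-length requests therefore emit exact-length
reads whenever indel rates are zero, and slightly varying lengths otherwise.
`plant_variants` introduces homozygous SNVs and short indels at sites at
least 150 nt apart, away from reference ends, and rejects indel placements
that are shiftable in repetitive context, so recovery is coordinate-exact;
truth is recorded in left-normalized VCF-style coordinates.

This error model is uniform and context-free: no quality-dependent error
profiles, no homopolymer-length errors (the dominant IonTorrent mode), no
coverage bias, no diploid heterozygosity beyond the planted lists.
Consequently the perfect-recovery and zero-mismap results here demonstrate
the correctness of the algorithmic pipeline under its stated assumptions —
they are not claims about error rates on real instrument data.

Everything is deterministic under an explicit seed (numpy PCG64), and reads
are mapped independently, so outputs are invariant to read order.

## Problem sizes and defaults

The end-to-end experiments use sizes chosen so each check is decisive yet
runs in minutes on one CPU: 500 kb genome × 50,000 error-free 100 nt reads
for the mismapping measurement; 10 × 10 kb genomes × 1,000 error-bearing
reads for oracle equivalence against edlib; a 100 kb genome at 30×
(30,000 reads, 0.5% substitution noise) with 100 SNVs + 10 indels for
variant recovery across allowances 3–7; 100 transcripts × 20,000 75 nt
reads at 1% error for quantification robustness.  Defaults throughout:
seed length 10, allowance 5 errors, indel band 5 (also the placement
tolerance when scoring correctness), max 100 reported locations.

## Numerical and format conventions

Coordinates are 0-based half-open internally and 1-based in every output.
The native output is tab-separated text, one line per alignment, with an
edit transcript (`<n>=` match run, lowercase read base for a mismatch,
`+SEQ` insertion, `-SEQ` deletion) that is self-delimiting and, together
with the reference, reconstructs the full alignment — pileups are built
from the unique-read file alone, with no need for the FASTQ.  SAM export
(via pysam, `=`/`X`/`I`/`D` CIGARs, NM tag, secondary flags for extra
multi locations) is optional interoperability plumbing; BAM is not
produced.  The index lives fully in memory; its on-disk form is a
versioned pickle container holding the seed length, the reference set and
the table.  VCF QUAL is −10·log10(p) capped at 999.
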