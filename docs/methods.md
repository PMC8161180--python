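# Methods

This note documents the models and procedures implemented in `bacsat`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data tests do and do not
establish about real genomes.

## Tandem-repeat detection

A tandem repeat (satellite) is an array of directly adjacent,
near-identical copies of a unit of 10–270 nt.  Detection proceeds in
three stages.

**Seed clustering.**  Every 10-mer of the genome (10 nt being the
minimum unit length) is hashed; a candidate locus opens wherever the same
word recurs within a sliding 800-nt window.  Words containing ambiguity
characters are skipped, and words that are themselves periodic with
period 1–5 nt are discarded, which excludes microsatellites; a unit
shorter than the seed surfaces at a multiple of its true period (a 7-nt
unit appears with a 14-nt period).  The required seed multiplicity
defaults to one less than the minimum copy number (so 3 when requiring
4-copy arrays): an array at the minimum copy number then remains
seedable when one copy has diverged past exact word identity, while the
copy-number requirement itself is enforced on the extended array.
Spurious seed clusters from random sequence are rare (the expected number
of 10-mers recurring three times within one window of a 1-Mb random
genome is well below one) and never survive extension.

**Extension.**  The unit period is estimated from the spacings between
seed occurrences — the modal spacing, with the smallest observed spacing
tried as an alternative candidate, since divergence can remove the seed
from adjacent copies and leave a harmonic of the true period as the mode.
The anchor is the occurrence with the most in-phase partners (central on
ties), because the first occurrence can be a chance hit in the flanking
background.  From the anchor the array is tiled one unit at a time in
both directions; a candidate unit (its length searched within ±2 nt of
the reference, so indel-carrying copies keep the frame) is accepted when
its global alignment score against the running consensus of the
modal-length units, normalized by the unit length, reaches 0.5.  The
scoring scheme is the same +1/−1/−2 scheme used for family clustering.
On this scale random DNA scores about −0.2 (s.d. ≈ 0.09 at 52 nt) while
copies at 10–15% divergence from their consensus score 0.7–0.8, so the
0.5 threshold separates the two populations cleanly; a raw unit-cost
edit-distance identity would not (random 52-mers reach ≈ 0.5 edit
identity).  A unit scoring in [0, 0.5) is still absorbed when the unit
beyond it scores ≥ 0.5 again: periodicity resuming after one weak unit
marks a genuine but heavily diverged internal copy, whereas flanking
background never resumes.

Two corrective passes follow.  *Harmonic refolding*: the array is
re-tiled at every integer sub-multiple of the period (smallest first) and
the finer tiling is kept when it spans the array (one coarse unit of
slack), passes the length-regularity filter, and — decisively — does not
degrade the mean unit-vs-consensus score by more than 0.1.  A genuine
finer period preserves per-base unit similarity; folding a unit into
merely chance-similar halves degrades it.  *Boundary polishing*: a seed
word that also occurs by chance in the flanking background can anchor the
tiling out of phase, leaving hybrid background/copy units at the array
ends.  The true boundary is recovered at base resolution as the maximal
run of positions matching the sequence one period away (run length 10),
followed by single-base maximal extension and a re-tiling from the
polished start.  At zero divergence this restores the exact maximal
periodic extent; under divergence the base-level periodicity is too noisy
for the run test and the polish falls back to the aligned tiling, which
is acceptable because coordinates then matter only up to overlap.

**Regularity filtering.**  An array is accepted when at least 60%
(`min_length_fraction`) of its units have lengths within ±1 nt
(`length_tolerance_nt`) of the modal unit length.  Accepted arrays carry
`homogeneity` (that fraction, by construction in [0.6, 1]), `Ni` (units
with exactly the modal length), and a `similarity_score` — the mean
column agreement of the positional alignment of the Ni modal-length
units, which needs no gaps because the units are equal length; it is
undefined (None) when Ni < 2.  Overlapping detections are merged keeping
the representative with the most units (ties: smaller period, then
leftmost).

## Family clustering

Tandem units have no canonical rotation or strand, so the pairwise
similarity of two units is the maximum normalized global-alignment score
over all cyclic rotations of either argument and both orientations.
Rotating only one argument is not guaranteed symmetric under a global
aligner, so the candidate set includes rotations of both, which makes
symmetry exact.  The normalization denominator is the maximum attainable
score, `match_score × min(|u|, |v|)`; negative normalized scores are
clipped to 0 since clustering only compares against a positive threshold.

Each tandem repeat contributes one representative unit — the positional
majority consensus of its Ni modal-length units — so family sizes count
arrays, not copies.  Clustering is agglomerative: merge the best-scoring
pair of clusters, rebuild the merged cluster's consensus by progressive
profile alignment (members rotated and oriented by their best cyclic
alignment to the growing profile; gap-majority columns dropped from the
reported consensus), re-score the merged cluster against all others
consensus-to-consensus, and stop when the best available merge falls
below the similarity threshold (default 0.6).  In consensus-to-consensus
alignment the letter `N` is scored 0 against everything — an uninformed
column should neither reward nor punish a match.  Consensus case encodes
column agreement over all members: uppercase ≥ 0.8, lowercase ≥ 0.5,
`n` below 0.5 or on a tie between two bases.  Family codes `a_b_c` rank
families by descending member count with ties broken toward the longer,
then lexicographically smaller consensus; `b` is the consensus length,
which can differ by 1–2 nt from the members' modal unit length when
indels pad the profile.

## Characteristic signals

Signals are discovered by exhaustive k-mer enumeration, longest k first
(k from 30 down to 6), over the units and their reverse complements, with
strand pairs collapsed to the lexicographically smaller representative.
Exact k-mers reaching the unit-coverage threshold (default 0.8 — high
enough to claim "present throughout", tolerant of diverged units) are
reported directly; pairs of k-mers at Hamming distance ≤ 2 are merged to
a degenerate pattern (purine difference → R, pyrimidine → Y, otherwise
N) when the merge raises coverage to the threshold.  Reported motifs are
non-nested: a motif that is an IUPAC-substring of an already reported
(longer) motif, on either strand, is suppressed.  Matching is IUPAC-aware
and ambiguity characters in the units never match.  Unit coverage is the
fraction of units matched on either strand; array coverage the fraction
of arrays in which at least half the units match; a strand note flags
units carrying the motif in both orientations at once.  On random units
(40 units of 52 nt) the probability of any k ≥ 10 motif reaching 0.8
coverage is negligible, which the tests confirm over seeded controls.

## MUM-anchored strain comparison

A MUM is a substring occurring exactly once in every compared genome,
counting both strands, and extendable in neither direction.  Enumeration
builds one generalized suffix array (prefix doubling on numpy, O(n log²n))
over the forward and reverse-complement strands of all genomes, each
chunk terminated by a unique sentinel and every ambiguity character coded
uniquely so it never matches.  With k genomes, a MUM is a window of k
consecutive suffixes, one per genome, whose internal LCP minimum L meets
the length floor, whose boundary LCPs are < L (uniqueness), and whose
preceding characters are not all equal (left-maximality);
right-maximality is automatic because two window members differ at L.
Each match and its reverse complement produce mirror windows; the one
with genome 1 on the forward strand is reported.

Anchors are MUMs of length ≥ max(20, ⌈log₄ max genome length⌉) — shorter
matches are expected by chance; the 20-nt floor is this package's
default and is configurable.  Anchors are
chained by weighted longest-increasing-subsequence (weight = length,
strictly increasing starts and ends in every genome, small overlaps
tolerated); between adjacent chained anchors the MUM search recurses on
the gap regions with the minimum length halving per level (floor 8 nt),
stopping on regions shorter than 100 nt.  Collinear consecutive MUMs
separated by less than 2000 nt in every genome are chained transitively
into clusters.

Repeat conservation: each tandem repeat is projected onto every other
genome through a piecewise-constant shift map built from the member MUMs
of its covering cluster — or, when the repeat falls between clusters
(e.g. inside a deletion longer than the cluster gap), from the pooled
anchors of the flanking clusters.  A projected interval overlapping a
repeat in the other genome makes the pair `shared`, with a length ratio
(shorter span / longer span, so a half-truncated array scores ≈ 0.5);
otherwise the repeat is `strain_specific`; `unanchored` is reserved for
the degenerate case of no clusters at all.  The correspondence is by
construction approximate — anchor-offset projection, not base-level
alignment — which suffices for presence/absence and length-ratio calls.

## Length classes and genome profiles

Repeat periods are binned into {10–19, 20–21, 22–50, 51–53, >53}, with a
multiple-of-three flag for the coding class; the pooled length histogram
collapses all periods above 60 into a single bin at 61.  Genome profiles
are assigned by deterministic rules: `poor` at ≤ 8 total repeats;
`rich_52` when at least half the repeats sit in the 51–53 bin *and* the
20–21 bin holds under 10% (and symmetrically `rich_21`); `cereus_coding`
when the 22–50 bin holds ≥ 40% and a majority of all repeats are
multiples of three; otherwise `intermediate`.  The opposite-class
exclusion in the richness labels is needed because genomes carrying
substantial numbers of both short classes form their own intermediate
profile; without it such genomes would be mislabeled rich.

## Synthetic genomes

The generator emulates the observed structure of repeat-rich bacterial
genomes: i.i.d. background at a configurable GC fraction (default 0.40,
mid-range for *Bacillus*); periods drawn per family with weights 0.15 /
0.15 / 0.55 / 0.15 over {20, 21, 52, other}, "other" being a random
multiple of three in 12–120 nt standing in for the coding class; copy
numbers uniform on [4, 37] (most arrays short, occasional long ones);
per-copy substitution divergence and optional ±1-nt indels from a family
ancestor; ancestors screened against 1–5-nt periodicity and against any
internally repeated 10-mer (cyclically), so seed spacings reflect the
true period.  Arrays never overlap and are separated by at least 1000 nt
of background.  Two further choices make the planted coordinates exact
ground truth: the background base immediately flanking each array is
re-drawn if it would continue the array's periodicity (otherwise the true
maximal periodic extent would exceed the planted coordinates and any
correct detector would report a shifted frame), and all randomness flows
from one seeded generator so a seed fully determines the genome.

Derived strains model repeat turnover: a seeded subset of arrays is
deleted or truncated to half its copies, and new arrays (periods re-drawn
from the same mix) are inserted into background gaps; background outside
the arrays is untouched so MUM anchoring remains informative.

**What the synthetic tests do not show.**  The background is i.i.d., not
Markov; real genomes have skewed oligomer content, mobile elements and
rRNA operons that produce non-tandem repeats, and assembly artifacts
that the detector would encounter in practice.  Divergence is uniform
per copy, whereas real arrays show gradients and gene-conversion tracts.
Perfect recovery on planted genomes therefore validates the algorithmic
contracts (coordinates, periods, copy counts, family partitions), not
the biological false-positive rate on real assemblies.

## Problem sizes and runtime

The validation suite uses twenty 1-Mb genomes with 12 arrays each for
recovery measurements (the per-genome array density matches repeat-rich
genomes at desk scale), 200 random 20–60-nt pairs for the cyclic-score
oracle, 50 random ≤ 2-kb pairs for the MUM oracle, and 250-kb strain
pairs for conservation; the full pipeline on a 1-Mb genome runs in about
one second on one CPU, and the complete acceptance script in about one
minute.

## Known limitations

- Arrays at the minimum copy number with high divergence can lack any
  shared seed word entirely and are then undetectable by any exact-seed
  method; measured recall at 10% per-copy divergence is ≈ 0.97–0.99.
- The harmonic-refold test can in principle retain a doubled period when
  a unit's halves are chance-similar *and* the array is short; the
  relative similarity gate makes this rare but not impossible.
- Family clustering is O(n²) in the number of arrays with a further
  rotation factor in the unit length; it is intended for per-genome or
  per-species family calling (hundreds of arrays), not for pan-genome
  catalogues in one pass.
- MUM uniqueness is required in every genome simultaneously; for many
  genomes this becomes restrictive, and pairwise runs are preferable
  beyond three or four strains.
- Strand-aware anchor chaining treats reverse-strand anchors as
  unchainable, so large inversions interrupt the collinear backbone
  rather than being followed.
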