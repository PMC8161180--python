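# bacsat

Tandem-repeat (satellite DNA) analysis for bacterial genomes.

Many *Bacillus* species — and scattered species across other bacterial
groups — carry tandem repeats with a strikingly constant unit length
(typically 20–21 nt or 51–53 nt) but freely varying sequence, alongside a
third class of repeats whose unit length is a multiple of three and which
code for amino-acid repeats in proteins.  `bacsat` is a pipeline for
cataloguing and comparing these repeats: it is aimed at comparative
genomicists who want to detect tandem arrays in assembled genomes, group
them into families, characterize the short signal sequences they share,
classify genomes by their repeat profile, and follow the turnover of
arrays between strains.

## What it computes

**Detection.**  A tandem repeat is found as a cluster of a repeated seed
word (the 10-nt minimum unit length) recurring within an 800-nt window,
extended outwards unit by unit for as long as the adjacent unit still
aligns to the array consensus, with no upper limit on the copy number.
An accepted array must have at least 4 copies, a unit length in 10–270 nt,
and length regularity: at least 60% of its units within ±1 nt of the modal
unit length (the *homogeneity*).  Each array also carries *Ni*, the number
of units with exactly the modal length, and a *similarity score* — the
mean column agreement of the positional alignment of those Ni units.
Units of 1–5 nt (microsatellites) are excluded.

**Families.**  Repeat units have no canonical start or strand, so two
arrays are compared by the best global alignment score (match +1,
mismatch −1, gap −2, normalized by the shorter length) over all cyclic
rotations and both orientations.  Arrays are clustered agglomeratively —
best pair first, consensus recomputed after every merge — until the best
available score drops below 0.6.  Families are coded `Fam_a_b_c`: rank
`a` by descending member count, consensus unit length `b`, member count
`c`.  Consensus letters are uppercase at ≥80% column agreement, lowercase
at ≥50%, `n` below.

**Signals.**  Short characteristic sequences (6–30 nt, optionally with
R/Y/N degeneracy at up to two positions) recurring across a genome's
repeat units of one length class, counting matches on either strand.

**Strain comparison.**  Genomes of related strains are anchored by
maximal unique matches (MUMs — substrings occurring exactly once in every
genome counting both strands), filtered at `max(20, ⌈log₄ genome length⌉)`,
refined recursively between anchors down to 100-nt regions, and chained
into clusters at gaps below 2000 nt.  Tandem-repeat positions are
projected through the anchors to label each repeat *shared* (with a length
ratio) or *strain-specific*.

**Synthetic genomes.**  `bacsat.synth` generates genomes with planted
arrays — periods concentrated at 20–21 and 51–53 nt, copy numbers 4–37,
configurable per-copy divergence and indels, shared family ancestors and
embedded signal motifs, plus derived strains with deleted, truncated, or
inserted arrays — so every stage can be validated against exact ground
truth.

## Worked example

Generate a 120-kb genome with six planted arrays and run detection and
family clustering:

```python
from bacsat import PlantSpec, generate_genome, find_tandem_repeats, build_families

spec = PlantSpec(n_arrays=6, genome_length_nt=120_000, seed=3, copy_range=(4, 12))
genome, truth = generate_genome(spec)
for t in find_tandem_repeats(genome):
    print(f"{t.start_nt:>7} {t.end_nt:>7}  period {t.period_nt:>3}  copies "
          f"{t.n_repeats:>2}  homogeneity {t.homogeneity:.2f}  "
          f"similarity {t.similarity_score:.2f}")
```

prints:

```
   5112    5231  period  20  copies  6  homogeneity 1.00  similarity 1.00
  14877   15560  period 114  copies  6  homogeneity 1.00  similarity 1.00
  18805   19024  period  20  copies 11  homogeneity 1.00  similarity 1.00
  50925   51548  period  52  copies 12  homogeneity 1.00  similarity 1.00
  85657   85876  period  20  copies 11  homogeneity 1.00  similarity 1.00
 114279  114848  period 114  copies  5  homogeneity 1.00  similarity 1.00
```

— exactly the six planted arrays, at their planted coordinates, periods,
and copy numbers (the genome was generated with zero divergence, so every
similarity score is 1.0).  `build_families` on these six arrays yields
four families, `Fam_1_114_2`, `Fam_2_20_2`, `Fam_3_52_1`, `Fam_4_20_1` —
the two-member families are the planted pairs sharing an ancestor unit,
the singletons the arrays whose ancestors were unique.  The per-genome
summary row bins the periods into the length classes:

```
genome_id  size_mb  gc%   total  10-19  20-21  22-50  51-53  >53  mod3  profile
synth_seed3   0.12  40.1      6      0      3      0      1    2     2  poor
```

The same steps are available from the shell:

```sh
bacsat synth --n-arrays 6 --length 120000 --seed 3 --out g.fna --truth truth.tsv
bacsat detect --fasta g.fna --out repeats.tsv
bacsat families --repeats repeats.tsv --out families.tsv
bacsat signals --repeats repeats.tsv --length-class 51-53 --out signals.tsv
bacsat align a.fna b.fna --repeats a.tsv --repeats b.tsv --out conservation.tsv
bacsat summarize --fasta g.fna --repeats repeats.tsv --out summary.tsv
```

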