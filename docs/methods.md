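# Methods

This note documents the models, parameters and numerical choices behind
`amplicony`: what the synthetic-data generators emulate (and what they
deliberately do not), how each analysis is computed, and where the design
was genuinely open.

## The generative model

### Birth-and-death amplification (`simulate.simulate_family`)

The family starts from one ancestral **two-gene block**: a main gene
(B-like, default 543-aa CDS) and a second gene (A-like, default 400-aa
CDS), each with two exons, the whole CDS in exon 2, and the single intron
in the 5'-UTR ending 71 bp upstream of the start codon.  Blocks duplicate
as units under a **Yule (pure-birth) process**: with `n` extant blocks the
next duplication arrives at exponential rate
`n x duplication_rate`, copies the current state of a uniformly chosen
block, and both genes of the pair share the event.  There is no explicit
loss process; "death" is pseudogenization, which leaves the copy in place
(as it does on a non-recombining Y).

Along every lineage, each gene independently accrues:

* **Substitutions** under JC69 at `substitution_rate` per site per My.
  Each site flips with probability `(3/4)(1 - exp(-4d/3))` for branch
  length `d`, uniformly to one of the other three bases.
* **Indels** as a Poisson process at `indel_rate` per locus per My, with
  positions uniform over the locus and sizes drawn from a discrete
  distribution that includes the observed +13 and -8 events alongside
  ±1 and ±3.

**Purifying selection on functional copies.**  A neutral clock calibrated
to synonymous rates would scatter nonsense substitutions through every CDS
over ~20 My, leaving no copy active — real active copies survive because
selection removes chain-terminating changes.  The simulator models this
minimally: while a lineage has no CDS frameshift, substitutions that would
create an in-frame premature stop are rejected (the codon reverts); once a
frameshifting indel lands in the CDS, the copy is dead and evolves fully
neutrally.  Consequently indels of length ≢ 0 (mod 3) inside the CDS are
the pseudogenization channel, in-frame indels are tolerated, and the
active fraction decreases in `indel_rate` (and is 100% at
`indel_rate = 0`).

Truth per locus records the birth time, parent, every indel event (with
its CDS overlap), and an activity flag: active iff the CDS has no
frameshifting indel and direct translation reaches the expected peptide
length (adjusted for in-frame indels).

### Default rates

| parameter | default | units | rationale |
|---|---|---|---|
| `duplication_rate` | 0.25 | blocks/block/My | gives E[copies] ≈ 2·e^(0.25·19.6) ≈ 270, i.e. on the order of ~130 per family as observed in such amplicons; the Yule copy-number distribution is geometric, so single realisations vary widely |
| `substitution_rate` | 0.0039 | subs/site/My | half of (interspecies Ks 0.1517) / (19.6 My split), i.e. the synonymous clock implied by the calibration |
| `indel_rate` | 0.05 | events/locus/My | ~1 event per lineage over the family's age; produces a pseudogene-majority family like the observed ~2:1 pseudo:active ratio |
| `indel_sizes` | {+13: .15, −8: .15, ±1: .2 each, ±3: .15 each} | bp | includes the two observed frameshifting events plus small indels; ±3 provides the in-frame channel |
| `total_time` | 19.6 | My | the cattle/sheep split used as calibration |

Desk-scale stand-ins: the ancestral intron (300 bp), exon 1 (100 bp) and
UTRs are far shorter than their multi-kb real counterparts, so a locus is
~2.6 kb instead of tens of kb.  This inflates the fraction of indels that
hit the CDS, which only rescales the effective pseudogenization rate.

### Expression levels (`assign_expression`)

B-like loci draw levels **log-uniform on [1, max_fold]** (default 60);
A-like loci draw log-uniform on [1, 10] and are rescaled so the realised
A-family mean is exactly `family_a_scale` (default 1/6) times the B-family
mean.  Pseudogenes are transcribed like active copies — the second family
consists of expressed pseudogenes.

### Read pairs (`simulate_read_pairs`)

Fragments are sampled from loci with probability ∝ level × transcript
length; insert length is uniform on [200, 300] bp (the gel-excision
window); mate 1 is the first 36 bases of the fragment and mate 2 the
reverse complement of its last 36 (FR, inward).  Errors are independent
per-base substitutions (default 0.001); quality strings are constant
because the analysis uses mismatch counts, never qualities.  A truth table
maps every pair to its source locus.

### Two divergence regimes

The genealogical family above is the condition for classification and
dating studies.  For the **expression study** it has an intrinsic problem:
under a Yule process most sister loci are young and near-identical, so
36 bp reads with a 2-mismatch budget hit many references and are discarded
as non-unique — per-locus quantification of fresh duplicates is impossible
at this read length no matter the implementation.  The expression study
therefore uses `simulate_star_family`: 20 loci per family, each evolved
independently ~0.12 subs/site from the family ancestor (pairwise ~0.22),
plus byte-identical twins to exercise copy-number collapsing.  This is the
regime in which unique-read quantification is informative; the
genealogical family is quantified alongside it for contrast.

### Ampliconic contigs (`layout_amplicon`, `tile_sequence`)

A contig is a concatenation of oriented repeat units with uniform-random
spacers (random spacers avoid spurious repeats).  Repeated forward units
form DRs, a reverse-complemented unit forms an IR, both with exact truth
intervals.  `tile_sequence` cuts a contig into pieces with exact shared
overlaps, retaining the source as assembly truth.

## The analyses

### Coding assessment (`genes`)

Transcripts are spliced by exon concatenation with a GT–AG consensus
check.  The CDS region (from the model-determined start codon) is globally
aligned to the reference CDS with **match +1, mismatch −1, gap open −5,
gap extend −1**; trailing transcript sequence beyond the reference stop is
free.  Gap placement follows the aligner's first-reported (leftmost-
equivalent) alignment, making indel coordinates deterministic.  The
peptide comes from direct translation of the (possibly frameshifted) CDS
to its first stop; `premature_stop_start` is the 1-based CDS position of
that stop's first base, so `peptide = (stop_start - 1)/3`.  ORF search is
forward-strand only with a required ATG start.

Classification is threshold-only: active iff
`peptide_aa >= max(min_aa=200, ceil(0.40 x reference_aa))`.  The two
defaults bracket the observed active range (shortest active peptide
222 aa of a 543-aa reference → cutoff 218) and are configurable because
the underlying boundary is empirical.  Note the deliberate asymmetry with
the simulator's truth: a frameshifted copy whose shifted-frame stop falls
late can carry a peptide above threshold and be called active — truth-
inactive but classifier-active.  This is real (the observed
insertion- and deletion-frameshifted structural variants encode 431 and
424 aa and are transcribed); the classifier reports the frameshift and
stop position alongside the call, and the confusion is reported rather
than hidden.

### Expression quantification (`expression`)

Byte-identical transcripts collapse into unique references
(`copy_number` = group size; id = lexicographically smallest member).
Each mate is aligned to both strands of every reference allowing ≤ 2
substitutions, seeded by non-overlapping 12-mers (pigeonhole: one chunk
must be exact) and verified by Hamming distance — provably identical to
an exhaustive scan, which the tests check.  A mate is reference-unique iff
all its hits lie on one reference (multiple positions within a reference
do not disqualify); a pair counts iff both mates are reference-unique on
the same reference, on opposite strands inward, with implied insert in
[200, 300].  Ties: fewest mismatches, then '+' strand, then smallest
position.

Categories per reference: **A** all counted pairs, **B** those with at
least one exact mate, **C** both mates exact; C ⊆ B ⊆ A always, and with
error-free reads the three coincide.

`unique_sites` is computed by exhaustive enumeration of all (start,
insert) placements: a placement is unique iff at least one of its two
implied 36-mers occurs, on either strand, in no other reference.  (This
single-mate definition is intentionally weaker than the both-mates pair
rule; the normalisation is a capacity proxy, not an exact expectation.)
`average_length` is the mean reference length within the same gene
family, since families are normalised independently.  References with
`unique_sites = 0` get undefined normalised values and are excluded from
summaries.

### Divergence, dating and trees (`evolution`)

`ng_pair` implements Nei–Gojobori counting: per-codon synonymous-site
fractions from the standard code (changes to stop codons count as
nonsynonymous), pairwise deletion of codons containing a gap or N (and of
stop codons themselves), and difference counts averaged equally over all
minimal substitution pathways, excluding pathways through stop codons
unless none avoids them.  Jukes–Cantor correction
`d = -(3/4) ln(1 - 4p/3)` is applied where `p < 3/4`; saturated pairs are
flagged undefined, not raised.

Duplication age = `max_intrafamily_ks / interspecies_ks_mean x t_split`.
The "most distant locus" maximises its maximum pairwise Ks to the rest;
since both endpoints of the maximal pair tie on that statistic, the tie
breaks toward the larger mean distance to all others (the outlier).  Only
**indel-free** CDS regions enter the codon alignment: a balanced indel
pair (e.g. +3/−3) preserves length while shifting the internal frame, so
any CDS-touching indel disqualifies a locus from the gap-free alignment.

Trees use Saitou–Nei neighbor joining with deterministic tie-breaking
(smallest index pair), negative branch estimates clamped to zero and
counted.  Distances are JC-corrected dS by default or plain JC nucleotide
distance (selectable; the pipeline's bootstrap uses the nucleotide
distance for speed).  Bootstrap resamples **codon columns** (preserving
codon structure), skips replicates with undefined distances (counted in
the log), and reports support as the percentage of completed replicates
containing each internal bipartition of the full-data tree.

### Repeats and assembly (`repeats`)

Dot-plots record every exact 10-mer match, forward and reverse-
complement.  Arm detection chains off-diagonal matches sharing a diagonal
(forward → DR) or anti-diagonal (reverse-complement → IR), merging runs
with internal gaps ≤ 500 bp and discarding arms < `min_arm`; candidates
whose both arms overlap are merged.  Arm identity is computed by global
alignment (same scoring as above) with **gap columns excluded from both
numerator and denominator** ("without considering gaps"), so otherwise-
identical arms with an insertion score 100%.  Reporting tiers: ≥ 99.5%
(high), ≥ 99.0% (extended DR), ≥ 98.5% (extended IR).

Overlap assembly accepts suffix–prefix overlaps only at ≥ `min_identity`
over ≥ `min_overlap` (defaults 99.99%/30 kb; relaxed tier 99.85%/20 kb).
Candidate overlaps are found by exact 64-mer seeds from the prefix of the
incoming sequence (at ≥ 99.85% identity an exact shared 64-mer exists with
overwhelming probability), verified ungapped.  Chains of unambiguous
forward edges merge into contig layouts taking the left sequence's bases
across each overlap; branching nodes end their chain and are reported.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF3 is written 1-based
  inclusive, BED 0-based half-open; the conversions are mutually inverse.
* All generators take explicit seeds; a fixed (config, seed) reproduces
  byte-identical tabular outputs.
* JC correction, Ks and Spearman summaries propagate undefined values as
  flags/NaN rather than exceptions; empty comparisons (no shared gap-free
  codons) are undefined.
* `mutate_jc` leaves N sites untouched; distance 0 returns the input
  unchanged.
* The expected-copy-number cap (default 600) rejects parameter
  combinations before a runaway simulation.

## Problem sizes used by the tests and scripts

Tests run the statistical checks at sizes chosen for stable statistics:
JC convergence on 100 kb; Yule expectation over 200 replicate families
with a miniature ancestral block; expression recovery on 40 loci x 10,000
pairs; aligner-oracle equivalence on 1,000 pairs x 10 references; dating
recovery over 20 replicate families with a 1,600-codon CDS (the longer
CDS keeps the max-Ks statistic's sampling noise well inside the 20%
recovery band); repeat recovery with 5 kb arms; assembly on a 9-tile
1.2 Mb contig with exact 30 kb overlaps.  The pipeline's evolve stage
subsamples to ≤ 30 taxa for the Ks matrix and ≤ 15 for the bootstrap
tree.

## Known limitations

* No gene conversion between repeat arms, although Y-ampliconic families
  plausibly undergo it; arm identities here decay with age.
* No interspersed-repeat (LINE/SINE) content in simulated contigs, and no
  RepeatMasker-style annotation.
* The read model has no indel errors, no quality variation and no PCR
  duplicates; the aligner is substitution-only by design.
* Dating assumes rate constancy and uses a max statistic that is noisy
  for small families; single-family estimates can deviate well beyond the
  replicate-averaged recovery.
* Passing tests on the star-divergence family show the quantification is
  correct given distinguishable loci; they do not make 36 bp reads
  informative about near-identical fresh duplicates, and the pipeline
  reports how few pairs are assignable in that regime rather than
  pretending otherwise.
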