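# Methods

## Data model and coordinates

A `MitoRecord` is a (usually circular) DNA sequence over {A,C,G,T,N} plus an
ordered list of `GeneFeature`s.  Coordinates are 1-based inclusive
(GenBank convention) everywhere; a feature with start > end wraps across the
origin and is legal only on circular molecules.  L-strand features are
stored by their H-strand footprint and reverse-complemented on extraction,
so every statistic that says "coding sense" sees the mRNA-like strand.
Duplicate gene names (the two Leu and Ser tRNAs) are disambiguated by
anticodon.  N is allowed in sequences; N sites are excluded pairwise from
counts and distances.  Validation returns violation messages as data rather
than raising, so batch QC over many records is cheap.

## Feature tables and intergenic accounting

Adjacency is genome order by start coordinate regardless of strand, matching
how mitogenome papers list H- and L-strand genes interleaved in one order.
For adjacent genes, igs = start(next) − end(current) − 1 on the circle; the
last gene pairs with the first.  Summing gene sizes and all signed gaps
tiles the circle exactly (the closure invariant that is property-tested).
The control region is deliberately *excluded* from the adjacency chain:
spacer/overlap counts are among genes only, and the single chain gap that
contains the control region is reported separately (`control_gap`), since
a ~0.9 kb control region would otherwise always be the "largest spacer" and
drown the biologically informative ones such as the ~38 bp gap at the
L-strand replication origin between tRNA-Cys and tRNA-Tyr.

Incomplete stop codons ("T", "TA"), completed to UAA by polyadenylation in
vivo, are reported verbatim and never auto-extended.  Amino-acid counts are
pure length arithmetic: complete stop → L/3 − 1; "TA" → (L−2)/3; "T" →
(L−1)/3, with divisibility enforced.  Nested or duplicate features are
rejected rather than silently ordered.

## Skews and codon-position composition

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C).  A zero denominator flags the
skew as undefined (`None`) instead of propagating NaN.  Per-gene skews are
computed on coding-sense sequences including start/stop codons (the
sensitivity of including stops is < 0.01 at realistic gene lengths); this
coding-sense convention is what makes ND6 flip sign relative to H-strand
genes.  Codon-position composition removes trailing incomplete stop
remnants first and keeps complete stop codons.

## Codon usage

Codon counting uses the vertebrate mitochondrial code via Biopython's
transl_table 2.  Leu and Ser are 6-codon families spanning two codon boxes;
family membership follows amino-acid identity.  The four stop codons form
their own family, so the per-family mean-RSCU = 1 invariant holds for every
observed family.  Complete terminal stops are counted (they appear in usage
reports); incomplete stops contribute no codon; a `--no-stops` /
`include_stops=False` switch removes stops from the frequency denominator.

## Ka/Ks and p-distances

The Nei–Gojobori (1986) counting method is implemented in full:

- *Sites*: for each codon, at each position, the synonymous fraction is
  (# amino-acid-preserving single-nt changes) / (3 − # stop-creating
  changes); stop-creating changes are excluded from the normalization.
  S is averaged over the two sequences; N = 3·codons − S.
- *Differences*: for a codon pair differing at k positions, all k!
  mutational pathways are enumerated with equal weight; pathways through a
  stop codon are skipped, and if every pathway is blocked the average is
  taken over all of them.
- *Correction*: Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p), undefined
  (flagged, not NaN) at p ≥ 3/4; Ka/Ks undefined when dS = 0.  An
  uncorrected pN/pS mode is available.

Codons containing N or gaps are deleted pairwise whole; p-distances use
site-wise pairwise deletion and come in three flavours: codon positions
1+2, all codon positions, and the full gene sequence (stop included).
"Overall" means the unweighted mean over unordered taxon pairs.  The
implementation is verified against an independent recursive
pathway-enumeration oracle on every ordered pair of the 60 sense codons.

## Trees

Distance trees use p-distance on the stop-free 13-PCG concatenation —
simple and fully specified; model-based ML/Bayesian inference is a
non-goal, and monophyly checks accept externally produced newick trees.
Neighbor joining follows Saitou–Nei with the standard Q-criterion,
lexicographic tie-breaking on the joined pair's labels, and negative branch
lengths clamped to zero; the final three lineages are resolved by the
three-point formulas.  NJ is exact on additive matrices (property-tested)
and agrees topologically with scikit-bio's independent implementation.
Monophyly of a taxon set is tested by rooting a clone of the tree at the
outgroup leaf and comparing the MRCA's leaf set with the query set.

## Synthetic data generator

`make_reference_record` lays out 37 genes plus a control region in the
standard vertebrate mitochondrial order with the spacer/overlap pattern of
carangid fishes (11 spacers totaling 66 bp; overlaps at tRNA-Gln/tRNA-Met,
tRNA-Met/ND2, ATP8/ATP6, ATP6/COX3, ND4L/ND4 and ND5/ND6).  Construction is
constraint-aware: start and stop codons of all CDS are pinned first
(complete stops may switch between TAA/TAG to satisfy overlaps), then
stop-free interiors are sampled codon-by-codon against the fixed bases,
checking that no write completes a stop codon in an overlapping gene's
reading frame (with bounded restart on dead ends); remaining positions are
filled i.i.d. from the default base weights A 27.7% / C 29.9% / G 16.6% /
T 25.7%, the C/A-rich average composition of carangid mitogenomes.
Anticodons are annotation metadata, not embedded sequence motifs.  Defaults:
16,553 bp total, ATP8 at 168 bp so its 55-aa count is arithmetically
consistent, COX1 starting GTG, and incomplete stops on ND2, COX2, COX3
(TA), ND3, ND4 and CYTB.

`evolve_on_tree` performs indel-free evolution along a newick guide tree:
per branch, Poisson(t·L) point mutations are proposed (target base weighted
by stationary frequency times kappa = 2.0 for transitions) and accepted
with probability 1 if synonymous, ω per gene if nonsynonymous; stop-creating
changes and edits to frozen incomplete-stop remnants are rejected; stop
codons may toggle TAA↔TAG; sites covered by two genes must satisfy both
frames (acceptance factors multiply).  Non-coding regions evolve neutrally;
the control region carries a 3× rate multiplier, reflecting that
between-species differences concentrate there.  Branch lengths are expected
*proposals* per site, so realized divergence in coding regions is lower
under purifying selection — ω as an acceptance probability is an
approximation to a true codon model, chosen for transparency; it is
adequate for rate-ordering, parameter-recovery and topology-recovery
experiments, which is what the tests use it for.  Default per-gene ω values
span 0.01 (COX1) to 0.10 (ATP8), emulating the observed conservation
ranking.  kappa is kept modest (2.0) because NG86 site counting assumes no
transition bias and its downward bias on Ka/Ks grows with kappa; real
mitochondrial DNA often shows stronger transition bias, which NG86 would
partially absorb into underestimated Ka/Ks.  All randomness flows from a
single integer seed; identical seeds give byte-identical genomes.

What the generator does *not* emulate: realistic tRNA/rRNA secondary
structure, indels and alignment uncertainty, within-genome compositional
gradients, recombination (absent in mtDNA anyway), and saturation at deep
divergences.  Tests passing on synthetic data therefore validate the
*arithmetic and algorithms*, not alignment or annotation quality on real
genomes, which must be supplied pre-annotated.

## Problem sizes and numerical choices

Test simulations use 500-codon genes for Ka/Ks recovery (total path 0.3;
mean estimates over 10 seeds land within ~15% of the simulated ω, inside
the ±30% Monte-Carlo envelope) and the full 16.5 kb genome (11,394 bp PCG
concatenation) for 8-taxon topology recovery with internal branches
≥ 0.02 — sizes at which every property tested is stable across seeds while
the whole suite runs in seconds.  Branch lengths written to newick are
formatted at 6 decimals, the precision to which round-trips are exact.
Ties in NJ are broken lexicographically for determinism.  Degenerate
inputs (all-N sequences, zero-length families, p ≥ 3/4, dS = 0, undefined
skews) are flagged explicitly rather than returning NaN silently.

## Known limitations

- No de novo annotation, no multiple sequence alignment: features and
  alignments are preconditions, as in the intended GenBank-driven workflow.
- NG86 with equal pathway weights and JC correction is the textbook
  estimator; it underestimates Ka/Ks under strong transition bias and
  saturates at large distances.
- The NJ tree is a distance-based proxy; bootstrap support and model-based
  inference are out of scope.
- The spacer/overlap bookkeeping rejects nested genes; genomes with genuine
  gene-within-gene annotations would need pre-processing.
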