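# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## The genome-evolution model

The simulator produces the data a two-round (2R) whole-genome-duplication
history would leave in gene tables and protein sequences. Its state is a
genome (genes with 0-based half-open coordinates, one family id each) plus
one protein sequence per gene.

Operators:

- **Whole-genome duplication** copies every chromosome wholesale; the copy
  carries a `-<label>` suffix (`chr1` → `chr1-2Ra`). There is no
  fractionation mixing: post-duplication gene loss is modelled only by the
  explicit loss operator. Gene and chromosome counts double exactly, so n
  successive doublings with full retention give 2ⁿ copies per family, each
  on a distinct chromosome.
- **Loss** deletes each gene independently with probability 1 − *p*
  (retention *p*). No rate is published for the motivating family, so the
  default *p* = 0.7 is a free parameter; recovery tests sweep *p* over
  0.3–0.8, the range in which a four-member quartet typically keeps 1–3
  members, matching the repertoires the analyses are meant to resolve.
- **Local (tandem) duplication** inserts a same-family copy immediately
  downstream of its template, within the tandem offset (default 50 kb, a
  typical tandem-pair separation; membership in an "adjacent pair" is
  defined through it). Downstream genes shift by a constant to preserve
  non-overlap.
- **Translocation** moves the genes of a source interval to the end of a
  target chromosome, preserving order.
- **Substitution** draws a Poisson(ℓ·L) number of events per sequence of
  length L for branch length ℓ (substitutions/site), hits uniform positions
  outside protected sites, and replaces the residue uniformly over the 19
  alternatives. This single symmetric exchangeability table with no rate
  heterogeneity is deliberately simpler than the JTT+Γ models used for
  inference on real data; it is sufficient for recovery tests because the
  analyses under test are distance- and topology-based, not model-based.
  There is no indel process; sequences evolved from one root are therefore
  already aligned, which the gene-tree recovery tests exploit.

Planted motif cassettes (e.g. seven YGGFM copies in one family's root
sequence) are rejection-sampled so the planted count is exact, and their
sites can be protected from substitution to give motif-recovery tests an
unambiguous ground truth.

**Truth log and replay.** Every operation appends an event; loss events
record the deleted gene ids and substitution epochs record their RNG stream,
so replaying the log from the ancestral parameters reproduces each extant
genome and sequence set byte-for-byte. This is tested over 50 random
configurations. All randomness derives from one master seed through
numpy `SeedSequence` spawn keys, so event order and outputs are reproducible.

## Peptide annotation

The opioid-core anchor is the tetrapeptide `[YF]GGF`; the fifth residue
(M/L/I/…) distinguishes individual peptides but varies across the family, so
it is reported as context and not scored. The melanocortin anchor is `HFRW`.
`X` never matches. Degeneracy is alignment-contextual: a row is classified at
*core columns* (columns where homologs are intact) as intact (0 mismatches),
degenerate (1..max_degenerate mismatches, gaps counting as mismatches) or
absent (all-gap, or beyond the threshold). The published literature never
quantifies "degenerate" versus "relic"; the default max_degenerate = 2 is a
package decision and is an explicit parameter everywhere it matters.
Mature-peptide prediction uses the simplest prohormone-convertase rule:
extend an intact core to the nearest flanking dibasic pair (KK/KR/RK/RR),
excluding the basic residues; monobasic cleavage and C-terminal amidation
are out of scope.

The bundled `synthetic_precursors.fasta` contains SYNTHETIC stand-ins, not
database sequences: random filler (over an alphabet that cannot form motifs
or dibasics by chance) around planted architecture matching the published
motif content of the four human precursors. They make the worked examples
runnable offline; they carry no biological information beyond that
architecture.

## Alignment

Progressive alignment in the Clustal tradition: k-mer distances
(1 − shared/min, multiset intersection, k = 3) feed an average-linkage
(UPGMA) guide tree; profiles are merged in post-order with an affine-gap
Gotoh dynamic program over profile columns. Column–column scores are
average-of-pairs substitution scores (gap pairs contribute zero); a gap of
length k costs open + k·extend with the opening column charged both. Gap
penalties default to the widely used protein settings open 10.0 /
extend 0.20; the substitution table defaults to BLOSUM62 with Gonnet
available by name (the table is configuration, not code). Terminal gaps are
charged by default; a flag makes them free (semi-global). Tie-breaking is
deterministic: residue column ≻ gap in the first profile ≻ gap in the
second. Pairwise alignment is the single-row special case of the profile
merge, verified against exhaustive enumeration for short sequences and
against an independent affine-gap aligner for longer ones. No iterative
refinement and no emulation of manual alignment editing: downstream
consumers are written to tolerate alignment differences.

## Phylogenetics

Distances use pairwise deletion (only mutually ungapped columns; `X` treated
as missing) by default — the common neighbor-joining default — with complete
deletion by flag; the choice is recorded in output. The Kimura protein
correction d = −ln(1 − p − 0.2p²) raises a saturation error at or beyond its
singularity (p ≈ 0.854102, the positive root of the quadratic). Inside the
bootstrap a saturated replicate pair is instead capped at distance 10 so a
single extreme replicate cannot abort a run; the cap only ever affects
replicates, never the reference tree, unless explicitly requested.

Neighbor joining follows Saitou–Nei exactly, with ties in Q broken by the
lowest node-index pair (original taxa in input order, join nodes in creation
order) and negative branch estimates clamped to zero without redistribution.
Bootstrap supports are mapped onto the full-alignment reference tree (the
Clustal convention) rather than a majority-rule consensus. Outgroup rooting
requires the outgroup to form one side of an edge and roots at that edge's
midpoint; anything else is an error rather than a silent fallback.
Duplication nodes are annotated by the species-overlap rule, and dated
against a speciation split as before/after/unresolved (species outside the
split, e.g. outgroups, are ignored). Maximum-likelihood inference, model
selection and Γ rate heterogeneity are out of scope.

## Synteny

Region membership is decided by gene start only, 0-based half-open — simple
megabase-window semantics that avoid double-counting boundary genes. Both
±flank windows around anchor genes (default flank 10 Mb) and
whole-chromosome regions are first-class, set per chromosome. Family
assignment is input data; the package never clusters sequences into
families. Selection keeps families present on ≥ min_chromosomes candidates
(default 3, the classic 3-of-4 criterion), and quartet completeness counts
families retaining all four copies. Synteny tables place each ortholog
group in the column of its majority reference-species chromosome (ties by
name for determinism); groups without a reference anchor go to an explicit
overflow column. In the pipeline, ortholog groups default to genes sharing
an identifier across species — valid for simulated data, where speciation
preserves ids (and analogous to cross-species HGNC naming); curated groups
should be supplied for real data.

## Scenario parsimony

The three orderings of a local duplication against two genome doublings
predict pre-loss layouts of 8, 6 and 5 genes over four chromosomes, with
tandem-adjacent pairs on 4, 2 and 1 of them respectively. Minimum losses to
an observed repertoire are found by exhaustive search over assignments of
predicted chromosomes to (unlabeled) observed chromosome classes and over
the choice of duplicated gene; the spaces are at most a few dozen states.
An observed adjacent pair can only be explained by a retained tandem pair;
two retained genes of a pure tandem pair are necessarily adjacent, which
makes some layouts infeasible rather than expensive. Because every deletion
is a loss, the minimum equals predicted minus observed totals whenever an
assignment is feasible, and shrinking the observed repertoire by one gene
costs exactly one more loss. Structurally unreachable layouts return an
infeasible marker, not an exception. Relative-dating constraints
("LOCAL precedes WGD2") flag orderings infeasible while still reporting
their loss counts; feasible orderings rank by losses with input-order ties.

## Pipeline determinism

Stages run in a fixed order; every stage consumes only declared inputs or
earlier outputs. All text outputs are UTF-8 with LF endings and tab-separated
columns; iteration orders are sorted. The manifest records a SHA-256
checksum per data artifact; the free-running log (which contains timings)
and the manifest itself are excluded. Two runs of the same configuration and
seed produce identical manifests, which is asserted in the test suite on the
bundled fixture.

## Problem sizes

The bundled fixture simulates 60 families on 4 chromosomes through two
doublings across 4 species, aligns 4 families, and uses 100 bootstrap
replicates; recovery studies use 20 two-round histories (retention swept
over 0.3–0.8) and 200 simulated gene trees with branch lengths of 0.05
substitutions/site (~10 substitutions per 200-residue branch — enough signal
for distance trees while far from saturation). These sizes were chosen so
the whole suite and the reproduction script each complete in seconds while
every recovery statistic still has a meaningful denominator; the default
bootstrap count for real analyses remains 1000.

## Known limitations

- No indel evolution, intron structure, or nucleotide/codon models in the
  simulator; alignment-recovery tests therefore plant insertions manually.
- The substitution model is uniform and homogeneous; trees inferred from it
  say nothing about robustness to among-site rate variation.
- Synteny membership by gene start ignores genes straddling a region
  boundary.
- Scenario parsimony counts gene losses only; it does not score chromosome
  rearrangements or model receptor-gene co-retention.
- The bundled precursors are synthetic stand-ins (see above); conclusions
  about real sequences require real inputs.
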