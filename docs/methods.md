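# Methods

This note documents the models, algorithms, parameter choices and
limitations of `corephylo` — what each stage assumes, why the defaults are
what they are, and what the synthetic-data validation does and does not
demonstrate about real data.

## Scope and model of the data

The pipeline targets *closely related* genomes: strains within a species or
species within a genus, where most of the genome aligns at high identity to
a single reference and variation is dominated by substitutions. Everything
is reference-anchored: one reference coordinate system, one call per sample
per reference position. Rearrangements are tolerated only to the extent
that each reference locus has a single orthologous copy in the query;
regions violating that (repeats, duplications) are masked out rather than
modeled. Recombination and horizontal transfer are not modeled or filtered;
like any core-SNP phylogeny, the output tree averages over them.

## Reference selection (MinHash)

Each genome is reduced to the `s` smallest 64-bit hashes of its canonical
k-mers (bottom-s sketch), `k = 21`, `s = 1000` — the community-standard
sketch parameters for genome-scale comparison; k-mers containing non-ACGT
bases are skipped. The hash is the splitmix64 finalizer applied to the
2-bit-packed canonical k-mer, fixed and documented so sketches are
reproducible across platforms. The Jaccard index is estimated from the
shared fraction of the bottom-s sketch of the union and converted to a
distance via `d = −(1/k)·ln(2j/(1+j))`; `j = 0` saturates to a sentinel
distance of 1.0 rather than infinity, so sums over samples stay finite.
The reference is the *complete* genome minimizing the summed distance to
all other samples (drafts and read sets contribute to sums but are not
eligible); ties break to the lexicographically smallest sample id. On
synthetic 100 kb genomes at 1% planted divergence the estimate is within
0.005 of truth (measured ~0.0003 absolute error).

## Repeat masking

The reference is compared against itself (forward and reverse complement,
within and across contigs) with the same suffix-array machinery used for
alignment. Every position covered by an off-diagonal exact self-match of
length ≥ `min_repeat_len = 50` is masked, both copies. 50 bp is far above
chance for random sequence (expected longest exact repeat in a 5 Mb genome
is ~2·log4(L) ≈ 23 bp) yet catches IS elements, rRNA operons and recent
duplications. Masked positions are forced to GAP in every sample's track,
so they can never enter the core.

## Pairwise whole-genome alignment

A generalized suffix array (prefix-doubling construction, Kasai LCP) over
reference + query yields all maximal unique matches (MUMs) of length
≥ `min_anchor_len = 20` per strand; N bases receive unique codes so they
never match anything. Per (reference contig, query contig, strand) the
maximum-weight colinear chain of anchors is selected by dynamic
programming; anchors may over-extend past a true breakpoint by chance, so
bounded overlap between consecutive chain anchors is allowed, penalized by
its size, and trimmed before alignment. Inter-anchor segment pairs with
both sides ≤ `max_fill = 10 kb` are closed with banded affine-gap (Gotoh)
alignment (match +1, mismatch −3, gap open −5, gap extend −2; band =
length difference + 50). Chains are also extended to the sequence ends with
length-balanced flank alignments so variants within an anchor length of an
edge are not lost.

Two guards keep forced global alignment honest:

* a fill or extension of ≥ 30 columns must reach ≥ 70% identity, else the
  segment stays unaligned — random DNA aligns at ~0.45 identity under this
  scoring while homologous segments at ≤ 10% divergence align at ≥ 0.9, so
  the threshold separates cleanly;
* when chains from different query contigs claim the same reference locus,
  the heavier chain wins position-by-position (first-claim).

Deletions in the query become core-excluding gap intervals on the
reference; insertions in the query consume no reference column and are
recorded only inside the edit script. Substitution columns become SNPs only
when both bases are plain ACGT and the position is unmasked; columns pairing
a base with N are ambiguous. Coordinates are 0-based half-open internally
and 1-based inclusive in all emitted reports.

On substitution-only synthetic clades, recovered SNPs equal planted SNPs
exactly (precision = recall = 1.0), including for fragmented, shuffled,
reverse-complemented contig inputs.

## Read mapping and consensus calling

Reads are placed by exact seed k-mers (`seed_k = 15`, seeds with > 64
reference hits are repetitive and skipped) voted onto diagonals on both
strands; each candidate locus is scored gaplessly, with a banded affine
fallback when the mismatch count exceeds 6% of the read length (a true
indel shifts half the read and always exceeds this). A read is kept only if
a single locus achieves the best score — ties mean repeat ambiguity and
drop the read entirely, which costs a little depth but prevents
repeat-driven false SNPs — and if identity over the aligned span is ≥ 0.85.
Paired mates map independently; pairing is file I/O only, since consensus
calling needs coverage, not fragment-size inference.

Pileup columns tally read bases at match/substitution ops only. The
consensus call at a position is base *b* if depth ≥ `min_depth = 5` and
`count[b]/depth ≥ min_allele_fraction = 0.6`; ambiguous (AMBIG) if covered
but no base reaches 60%; GAP below the depth floor. The 0.6 threshold is
the tool's operating point for accepting a variant from reads (at least
60% of mapped reads must agree); 5× is this package's documented minimum
depth. Indels in reads are alignable but never produce consensus indel
calls — the core-SNP model is substitution-only. Raising either threshold
can only remove base calls, never create them (verified as a property).

At 20× coverage with 1% uniform read error, planted SNP recovery from reads
is precision 1.0 and recall ≥ 0.99 (recall loss is coverage gaps, not
miscalls). Background reads from unrelated genomes fail the seed/identity
rules and leave target calls untouched — the premise behind placing
metagenome-embedded targets.

## The allele table and the core genome

The allele table is one dense uint8 track per sample over every reference
position: A/C/G/T, GAP, or AMBIG. Ambiguity excludes a position from the
core exactly like a gap — a column that cannot be trusted in one sample is
not a core column — protecting SNP-column purity at the cost of a slightly
smaller core. The table persists as a JSON header plus per-sample
run-length-encoded text tracks; subset re-analysis and incremental sample
placement are pure functions of the stored table and are bit-identical to
from-scratch runs (tested, including the tree files). Samples whose non-GAP
fraction falls below the aligned-fraction cutoff (default 0.0 = keep all)
are dropped with a log entry; the reference is never dropped.

Core columns are positions where every retained sample calls a plain base;
SNP columns are core columns with ≥ 2 distinct bases. Pairwise SNP count
matrices are reported for the full core and, when an annotation is given,
partitioned into CDS and intergenic counts (which sum exactly to the core
counts).

## Phylogeny

Distances are p-distances over the *full* core alignment — monomorphic
columns included — optionally Jukes-Cantor corrected
(`d = −(3/4)·ln(1−4p/3)`, capped at 5 substitutions/site with a saturation
flag when p ≥ 3/4). Using the full core makes branch lengths
per-site and sidesteps SNP-only ascertainment bias. The tree engine is
Saitou–Nei neighbor joining with the standard Q criterion, first-minimum
tie-breaking (deterministic), and negative branch estimates clamped to zero
with a log note. NJ is exact on additive matrices (property-tested to
n = 12 with recovery of both topology and branch lengths) and statistically
consistent in the closely-related regime this tool targets; for
likelihood-based inference the core alignment is exported in FASTA and
relaxed PHYLIP for external programs, which are deliberately outside the
package.

Bootstraps resample full-core columns with replacement; each internal edge
of the point tree is annotated with the percentage of replicates containing
the same bipartition, reproducible from the run seed. Trees are unrooted;
outgroup rerooting is a display aid.

## Selection screen (NG86)

Gene models come from the reference GFF3 (CDS features grouped by
ID/Parent/locus_tag; strand and phase respected; genes with a reference N
or out-of-frame length are ineligible). A gene is screened iff every sample
has plain base calls across all its CDS positions (0 gapped regions) and it
contains ≥ 1 SNP. Because gene sequences are extracted positionally from
the shared reference coordinate system they are already aligned; this is
equivalent to per-gene realignment for the gap-free genes the screen
admits.

The estimator is the Nei–Gojobori (1986) counting method: per codon,
synonymous site counts from fractional weighting of the nine single-base
mutations (synonymous + nonsynonymous sites = 3, exactly, verified for code
tables 1 and 11); observed codon differences apportioned equally over all
minimal mutational pathways; proportions Jukes-Cantor corrected. Codon
pairs involving a stop codon carry no defined sites: the pairwise routine
rejects internal stops by default, and the gene screen skips such codon
pairs, which handles stops that arise by mutation during evolution. Per
gene, dN and dS are means over all sample pairs (symmetric in the samples,
robust to reference choice) and ω is the ratio of means; significance is a
normal-approximation z-test on the mean pN − pS with binomial variances,
BH-FDR corrected across genes at α = 0.05. Classification: positive (ω > 1,
q ≤ α), purifying (ω < 1, q ≤ α), neutral (q > α), undetermined (dS zero or
saturated). This counting screen preserves the per-gene ω + class + p-value
output contract; branch-site and codon-model likelihood methods are out of
scope, though per-gene FASTA exports support running them externally.

## The simulator

`simulate_clade` draws a random topology (or accepts Newick), an i.i.d.
root genome at the requested GC content, and evolves strict Jukes-Cantor
substitutions along each branch: Poisson(rate·L) events, uniform positions,
uniform alternative base — no rate heterogeneity, no transition bias, no
context dependence. Optional planted deletions (Poisson count, geometric
lengths), tandem-free repeat copies, and a synthetic annotation of
non-overlapping frame-0 CDS genes built from stop-free codons (alternating
strands, ~85% coding to mimic bacterial gene density). Reads have uniform
start positions, equiprobable strands, uniform substitution errors, and a
constant Q30 quality placeholder. All randomness derives from one seed
through named per-operation generators, so each artifact is independently
reproducible and a fixed seed gives byte-identical outputs.

What passing these tests shows: the pipeline's bookkeeping (coordinates,
strands, thresholds, set algebra, tree arithmetic) is exact under the
stated model. What it does not show: robustness to real-world error
profiles (quality-dependent, indel-rich), GC-biased coverage, contamination,
true rearrangements, recombination, or selection acting on real sequence —
the simulator deliberately omits all of these.

## Problem sizes and numerical choices

The validation suite runs clades of 5–8 taxa on 20–200 kb genomes at
0.1–2% per-branch divergence with 20× read coverage — sizes chosen so the
full ground-truth comparison (every position audited) stays exhaustive
while the suite completes in minutes on one CPU; the algorithms are the
same at genome scale, with runtime dominated by the suffix-array and
read-mapping stages, both near-linear in input size. Percentages in the
run report round half-up to one decimal; zero denominators print NA; the
workflow's exit codes are 0 (success), 2 (input error), 3 (degenerate
result such as an empty core), 4 (internal assertion).

## Known limitations

* Reference-anchored orthology only: no all-vs-all alignment mode, no
  rearrangement decomposition beyond per-strand chaining.
* Indels are core-excluding, never called as variants.
* Ambiguity codes other than N are accepted on input but treated as N.
* The built-in tree engine is distance-based; likelihood/Bayesian inference
  is delegated to external tools via the alignment exports.
* Genes overlapping on opposite strands are each annotated in their own
  frame; a SNP may legitimately be synonymous in one and nonsynonymous in
  the other.
* The NG86 screen assumes approximate neutrality of synonymous sites and
  loses power for very short or nearly invariant genes (dS undefined →
  undetermined).
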