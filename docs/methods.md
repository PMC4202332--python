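# Methods

## The model

Each ancestral intron site is a binary presence/absence character on a
rooted species tree.  The whole-genome duplication (WGD) of the
*Saccharomyces* ancestor is made explicit by expanding the tree: the clade
subtended by the tagged WGD node is duplicated into two isomorphic copies
(loci A and B) attached at the WGD node, so a character present at the WGD
node continues independently into both locus lineages.  The expanded tree
for the 20-taxon fixture (8 pre-WGD + 12 post-WGD species) has
8 + 2×12 = 32 tips.  Every expanded branch carries a projection onto the
simplified tree; after event assignment, A and B events are summed per
simplified branch.

Evolution is Dollo: a site is present at the root (or gained exactly once
on a single branch) and once lost on a lineage is never regained.  Under a
fixed gain node the minimal loss set is unique — one loss on the root
branch of every maximal all-absent clade inside the gain clade — so the
reconstruction is deterministic: the gain node is the MRCA of the present
tips, a gain is an *event* only when that node is not the (pruned) root,
and under a multifurcating parent each absent child subtree root incurs its
own loss.  Correctness is checked against an exhaustive oracle that
enumerates every valid gain placement on trees of ≤ 14 tips and takes the
global minimum event count.

Manual gain curation is replaced by an explicit override mechanism: a site
named in the override list is re-assigned with the character forced
ancestrally present, converting the rejected gain into losses on
alternative branches.

### Identifiability of loss events

Raw loss events are not fully identifiable from extant states: if both
child lineages of a node lose the intron independently, any reconstruction
sees one maximal absent clade and infers a single ancestral loss.  The
simulator therefore records two event sets — the *raw* events as they
happened, and the *canonical* minimal set derived (by an independent
bottom-up merge over surviving loci) from the true tip states.  Exact
end-to-end recovery is asserted against the canonical set; raw counts back
the binomial sanity checks of the loss process itself.  Subtrees in which
no locus survives are invisible to reconstruction and excluded from the
canonical set, exactly as per-site pruning excludes them from analysis.

## Splice grammar and S2

Introns are validated against the strict Saccharomycetaceae consensus:
`GTATGT` at position 0 (configurable mismatch tolerance, default 0),
terminal `AG` (exact), length within 49–1050 nt (the annotated
*S. cerevisiae* range), and a `TACTAAC` branch point.  Reported S2
distances rarely state an operational endpoint convention; here
**S2 = intron length − bp_pos − 7**, i.e. nucleotides from the end of
the BP heptamer to the final intron base inclusive of the terminal AG.
When multiple BP motifs occur, the rightmost (3′-proximal) qualifying one
is chosen, which makes S2 well defined and matches yeast BP biology.
Cross-study comparisons of absolute S2 values are therefore qualitative.

## State classification

A row is `PRESENT` when its intron-span content passes the grammar; a
degenerate intron with at least two of the three signals still counts as
present (with a note).  For absent rows the net junction indel is measured
as the difference between the row's ungapped length and the modal ungapped
length among intron-bearing rows over the exon block on the 5′ side of the
intron span.  The block runs from the end of the previous intron span (or
the alignment start) to the span start; a bounded ±N-codon window would
truncate deletions larger than itself (imperfect losses run to 40 codons),
so `flank_codons` (default 10) instead sets the minimum alignable flank for
a confident call.  Net indels that are whole-codon are classified
|k| ≤ 2 → `LOST_PERFECT`, 3 ≤ |k| ≤ 40 → `LOST_IMPERFECT(k)`; frameshifts,
oversized indels and unalignable flanks become `LOST_UNKNOWN` (still
counted as losses downstream).  5′-UTR sites default to `LOST_UNKNOWN` when
absent (`utr_policy`), since codon accounting is meaningless there.
Ties in the modal exon length break toward the smaller value;
classification is deterministic and row-order independent.

Sliding detection scans rows lacking a valid intron at the annotated span
for a valid intron elsewhere in the row, reporting the column offset and
(when an ORF start is supplied) whether the move crosses the start codon.

## The simulator

The generator's defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 235 | ancestral intron-containing gene families |
| `p_second_intron` | 0.06 | ~250 sites from 235 genes |
| `p_root_present` | 0.95 | ancestor held almost all extant introns |
| `gain_rate` | 0.015/branch | a few percent of sites are lineage gains |
| `per_branch_loss_prob` | 0.05 | a few hundred losses over ~60 expanded branches |
| `loss_type_probs` | (0.71, 0.03, 0.26) | perfect / imperfect / unknown mixture |
| `p_locus_retained` | 0.5 | extensive post-WGD single-copy resolution; ≥1 locus always kept |
| `rpg_fraction` | 0.24 | ~59 RPG introns of ~250 |
| intron length | log₂-normal, mean 7.0 (≈128 nt); RPG mean 8.7 (≈415 nt) | RPG introns are the long mode |
| S2 | per-species normal, mean 33–40 for the high-S2 group (U2AF1-less species and *Vanderwaltozyma*/*Tetrapisispora*), 24 otherwise, sd 6, clipped [4, 60] | per-species S2 spread |
| `snorna_sites` | 8 | intronic snoRNAs of *S. cerevisiae* |
| `substitution_rate` | 0.05 | exon noise; 0 for exact-recovery designs |

Loss events are typed once per event; tips under the event inherit the
type.  Perfect losses carry k ∈ {−2..2} codons, imperfect k uniform on
±{3..40}, unknown losses a small frameshifting scar (so an exact classifier
must call them `LOST_UNKNOWN`); lineages outside a gained clade never had
the intron and are recorded as unknown-type absence.  5′-UTR sites force
unknown-type losses, matching the classifier's `utr_policy`.  Sites whose
intron survives nowhere are retained in the truth table (`visible=False`)
but not emitted — they are unobservable in real data.

Emitted alignments are trivially correct by construction: exons are shared
codon blocks (60 codons, accommodating 40-codon deletions plus a 10-codon
flank) with substitution-only noise; intron spans share the 5′ss/BP/3′ss
columns, with per-row S2 tails right-aligned; each inserting row gets its
own gap-columns; deletion scars gap the trailing exon columns 5′ of the
span.  Spurious `TACTAAC` occurrences 3′ of the true BP are scrubbed so the
rightmost-BP search recovers the annotated geometry exactly.  Junction read
counts are negative-binomial around a shared per-site log-normal mean
(dispersion 0.15; zero dispersion makes counts deterministic), scaled by
library size; genomes are emitted as ungapped per-locus contigs so junction
BED records can be re-validated from sequence.

What the simulator does **not** emulate: realistic substitution models and
codon usage, alignment error (alignments are correct by construction),
annotation error in intron boundaries, genome assembly gaps, or RNA-seq
read-level noise.  Passing the end-to-end tests therefore demonstrates the
correctness of the classification → Dollo → summary chain given correct
alignments, not robustness to alignment error — which the strict readers
deliberately refuse to repair.

## Summaries

*snoRNA fates.*  Each (host gene, post-WGD species) is classified from six
locus flags (gene/intron/snoRNA per locus) by a fixed priority cascade
(removed → deintronized → both-retained → single-copy → paralog-intron),
which is exhaustive and mutually exclusive over the 2⁶ flag space and
symmetric in locus order.  Deintronization — a surviving snoRNA at a locus
whose host gene is gone — takes precedence over the retention categories.
snoRNA presence is taken from locus flags (emitted directly by the
simulator), not from sequence search.

*RPG statistics.*  Loss-per-locus rates are losses ÷ defined loci, for
RPG-flagged and other sites separately (a denominator convention stated
explicitly because published per-locus rates are not always derivable from
printed counts).  Bimodality of intron length is operationalized per
species as a 2- vs 1-component Gaussian mixture on log₂ length
(scikit-learn, `n_init=3`, seeded), judged bimodal when ΔBIC > 10; samples
under 10 introns return unimodal.

*Heatmap.*  The four-way export (present / cDNA-replacement loss /
loss-with-indel / unknown) orders species rows by tree traversal with A/B
sub-rows for post-WGD species.  `LOST_UNKNOWN` and `NO_DATA` share the
"unknown" code, as in the figure convention it mirrors; the state matrix
TSV remains the lossless representation.

## Verification designs and problem sizes

The acceptance chain uses: 1,000 random (≤14-tip) Dollo instances against
the exhaustive oracle; 300 noise-free gene families on the 20-taxon tree
for exact state and per-branch loss recovery; a terminal-branch-only loss
design (loss probability 0.25 on the 32 terminal branches of the expanded
tree, all loci retained) so that each of ≥2,000 loss events is classified
as exactly one cell, making the loss-type tallies multinomial with 3-SD
bounds; and grammar validation of every emitted junction in four species
together with its ±1 nt shifts.  These sizes keep the full suite and the
acceptance script to a few seconds while leaving the statistical checks
well-powered.

## Numerical and degenerate-input choices

0-based half-open coordinates internally; GFF3 (1-based inclusive) and BED
(0-based half-open) converted only at the I/O boundary.  Readers reject
malformed input instead of repairing it; writers sort deterministically so
serialization is idempotent.  Sites with zero present tips after pruning
cannot anchor a Dollo character and are skipped with a warning.  Empty
species groups are skipped in S2 summaries; correlation requires ≥3 shared
ids and refuses zero-variance input; per-kb normalization refuses
zero-length introns.  All simulation randomness flows from a single integer
seed through independent named streams (process, alignments, junctions,
snoRNA survival), so identical configurations yield byte-identical outputs.

## Known limitations

Alignment construction is consumed, not performed; branch lengths are
ignored (Dollo parsimony is topology-only); gain curation reproduces
outcomes via overrides without modeling the curation criterion; absolute
S2 values depend on the declared endpoint convention; the bimodality
verdict is a desk-scale surrogate for a full density comparison; and
non-canonical (GC–AG) or U12-type introns are out of scope (absent from
these yeasts).
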