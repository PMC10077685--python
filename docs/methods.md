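# Methods

This note documents the models, conventions and numerical choices behind
mitostruct, and what the simulation-based tests do and do not demonstrate.

## Coordinate and orientation conventions

All coordinates are 0-based half-open on the forward strand; GenBank I/O
converts to/from the 1-based inclusive dialect.  Feature segments are kept
in 5'→3' order of the feature itself (descending for `-` strand features),
so spliced sequences are a plain concatenation.  Every genome is normalized
by rotating the circle so the anchor gene (*cox1* by default — long,
single-copy, intron-rich) starts at position 0 on the `+` strand,
reverse-complementing first if needed.  This makes strand and rotation of
the input assembly irrelevant: all downstream calls (GC skew, MIR
orientation, gene order) are made on a unique canonical representation.
A feature crossing the origin is stored as two segments; spliced-coordinate
arithmetic first re-rotates to a feature-free origin, which exists in any
genome with at least one intergenic base.

GC skew is (G−C)/(G+C) over the whole normalized forward strand, with N
excluded and a warning plus value 0 when G+C = 0.  No published convention
fixes the strand or origin for this statistic, which is why normalization
is applied first; exact agreement with numbers computed under a different
convention is not expected.

## Inverted repeats and MIR orientation

Detection is seed-and-extend: exact 21-mer matches between the sequence and
its reverse complement are binned on anti-diagonals (band 200 nt), each
band group is polished by X-drop extension (+1 match / −2 mismatch, drop
15, minimum net gain 3 so isolated chance matches in flanking sequence do
not move boundaries), and candidate pairs are scored by global-alignment
identity (edit distance over the longer copy).  The search runs on the
doubled sequence so repeats spanning the origin are found; pairs are
deduplicated modulo genome length and nested pairs suppressed.  Defaults
`min_len=500`, `min_identity=0.95` reflect a repeat that contains eight
tRNA genes and is effectively identical within a species; both are
configurable.  Boundary conventions are ours, so cross-tool comparisons
should allow ±25 nt.

The MIR is the arc strictly between the two repeat copies that contains the
marker genes (nad2, nad3, rrnL, rps3; ties broken toward the shorter arc).
Orientation is the strand of *rps3* relative to the anchor, making the call
self-contained per genome rather than dependent on an external reference.
If any marker gene is annotated on both strands the genome carries two
opposite-orientation MIR homologs and the call is `duplicated_both`; this
is checked before the in-segment marker requirement because the duplicated
block itself can outrank the tRNA repeat as the longest inverted pair.

## Homologous intron sites, types, subtypes, anomalies

Two introns are homologous when their insertion points coincide in spliced
coordinates (exonic bases 5' of the intron).  The tolerance default is
6 nt: conspecific exons vary by substitutions, not micro-indels, so true
homologs land on exactly the same coordinate while 6 nt absorbs minor
annotation wobble.  Sites observed only in queries are appended with the
next free ordinal of their gene (reference ordinals never change) and are
flagged novel; they are retained in the matrix but can be excluded.

Type assignment uses global-alignment identity against per-site exemplars
with threshold 0.90: distinct types at one site in these genomes are ~30%
diverged while conspecific copies of one type differ by ≤2%, so the
threshold has a wide safe margin on both sides.  Ties break toward the
lexicographically smaller label.  Subtypes are called only at declared
diagnostic columns (e.g. one SNP plus one 2-bp indel), not by
whole-sequence haplotyping; each column is decided by comparing the query
segment aligned to a ±6 nt window against the window realized with the
reference and with the alternate state (edit distance), which is robust to
gap-placement ambiguity around indels.  Diagnostic columns are curated
knowledge: they are loaded into the registry from a JSON declaration
(`apply_subtype_declarations`), the simulator writes its declarations into
`truth.json`.

Anomaly screening aligns each copy to its type exemplar with affine gap
penalties (match 1, mismatch −2, open −8, extend −0.2); affine gaps are
essential here because an edit-distance path scatters a long foreign
insert across spurious matches.  Query-only runs ≥15 nt are reported as
inserts (captures real 18 nt to >1 kb insertions, ignores slippage);
exemplar coverage <0.80 flags a degenerate (partially deleted) copy.

## dpo fragments

All dpo-annotated segments are clustered by single-linkage at 0.90
strand-agnostic identity; the longest member is the exemplar; fragments are
named dpo1..dpoN by genomic position in a designated naming genome (the
reference by default) then discovery order.  Profiling searches each
exemplar with infix alignment on both strands, keeping hits with identity
≥0.75 over ≥60% of the exemplar; overlapping hits to two fragments keep the
higher identity with a warning.  Hits inside an IRS copy are flagged
`in_repeat` and excluded from clade summaries, which report per-clade
presence fractions and a ≥0.5 consensus.  Clustering is sequence-first
with positional naming; raising the merge threshold can only split
clusters, so catalog size is monotone non-decreasing in it.

## IDP classes, congruence, haplotypes, SNP regions

IDP states are fully categorical — absence, type, subtype and insert
signature — because binary presence cannot separate patterns that differ
only in a subtype.  Variable-site selection and class assignment are exact
partition operations; labels follow the first member's position in the
phylogeny's leaf order when a tree is supplied (class numbering is
internally consistent but not guaranteed to match any external numbering).
Congruence with clades is summarized both as counts (classes confined to a
single clade) and as the adjusted Rand index under the permutation model.
Haplotype collapsing defaults to dropping columns containing missing
states before grouping rows (`strict` mode keeps missing as a state).
SNP positions classify as exon if inside an exonic segment of a
CDS/rRNA/tRNA, else intron if inside an intron feature, else intergenic.

## Minimum gain/loss events

Each site follows Dollo parsimony — intron gains are rare horizontal
transfers, so a single gain is placed on the edge above the MRCA of all
carriers and the unique minimal loss set is the edges above maximal
all-absent subtrees below it.  A site present in every strain is treated as
ancestral presence, not a gain event.  Losses (or gains) of one gene on
one branch merge into a block event when no site that remains present in
the branch's ancestral state lies between them; ancestrally absent sites
do not interrupt adjacency, so e.g. the first and sixth site of a gene are
"neighbors" when sites 2–5 are empty in the clade.  Merging never crosses
gene boundaries; multifurcations are handled per child edge.  The count is
a lower bound on the true number of events and equals it when every site
experiences at most one event on the tree.

## Simulator

The generator emulates the structural processes above at reduced genomic
scale so the full pipeline runs in seconds: a conserved scaffold of 15
protein genes, 2 rRNAs and 20 tRNAs (~45 kb assembled; a `full` profile
scales lengths toward ~140 kb), AT content targeted at 0.71, an exact
inverted-repeat pair of 8 tRNAs flanking a MIR carrying 9 tRNAs plus
nad2/nad3/rrnL/rps3, 24 intron sites distributed over six genes (reduced
profile), 8 dpo exemplars planted between the first repeat and the MIR
genes.  Intron types at multi-type sites are 30–35% diverged; within-type
copies carry 1% substitution noise (diagnostic subtype columns protected),
exons 0.5% — both safely inside the 0.90 type threshold from above and
below.  Along a coalescent tree (msprime, haploid, unit population size;
branch lengths in arbitrary coalescent units) each branch draws Poisson
numbers of intron losses (default 0.08 per present site per unit length,
extending to the adjacent present site of the same gene with probability
0.4 per additional site), gains (0.02 per absent site), subtype switches
(0.03), dpo losses/gains (0.10/0.05) and MIR inversions (0.15 per unit
length); the root state has every site occupied by its founding type,
fragments {1,2,4,5,6} present and forward orientation, mirroring a
basal-clade-like ancestor.  Everything derives from one seed; the same
seed reproduces byte-identical output files.

What passing the simulation battery shows: the pipeline inverts the
generative process exactly under realistic divergence — site mapping,
type/subtype calls, orientation calls and dpo consensus recover the truth,
and the event count never exceeds the logged event number.  What it does
not show: robustness to annotation errors, assembly artifacts,
micro-indels in exons, repeat degeneration, or intron types near the 0.90
identity boundary — real data can present all of these, and thresholds may
then need tuning.

## Problem sizes in the shipped checks

The test battery uses 8-leaf simulations (20 replicates end-to-end), a
33-strain toy matrix for the four-block-loss worked example, 6-leaf trees
with 4 sites for exhaustive oracle comparisons, and 150–300 two-leaf
replicates for Poisson rate checks; the acceptance script runs 12
replicates of the 8-leaf configuration.  These sizes were chosen so a
complete run is a desk-time operation while leaving every code path
exercised; all of them scale up by changing `SimParams`.
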