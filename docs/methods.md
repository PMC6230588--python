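# Methods

This note documents the models, rules and numerical choices behind
trbscribe: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Recombination-signal model

Signals are modelled as heptamer + spacer + nonamer with exact Hamming
match counts against the consensus (`CACAGTG` / `ACAAAAACC`, written in
the coding-flank convention and reverse-complemented on 5′ flanks). No
position weight matrix is used: the source analysis argued only that the
signals are "well conserved with respect to the consensus", so a
transparent per-element count, with all thresholds config-exposed, is the
weakest faithful reading.

Two threshold sets exist and serve different purposes:

- **discovery** minima (default heptamer ≥ 5, nonamer ≥ 6 of 7/9) decide
  which windows are examined as gene candidates at all. They are
  deliberately permissive so that genes with damaged signals are still
  found and can be classified as defective.
- **functionality** minima (default heptamer = 7 exact, nonamer ≥ 7)
  decide rule (b) of the classification. The exact-heptamer requirement
  is anchored on the one naturally defective J gene in the pig locus,
  whose single heptamer change (5th-position G→C, 6/7) renders it
  non-functional; a 6-of-7 functional cut-off would wrongly pass it.

Spacer length is strict 12/23 by default; a ±1 tolerance scan is
available (`scan_rss_with_tolerance`) because natural spacers vary, but
hits at non-canonical spacers are reported as raw tuples since the
signal type admits only canonical spacers.

## Gene discovery grammar

Discovery is signal-anchored and grammar-checked. D genes are 10–25 nt
cores between a reverse 12-signal and a forward 23-signal, both of which
must be convincing (combined score ≥ 15 of 16) — this stops a chance
low-threshold hit adjacent to a real J or V signal from converting that
gene into a D. J genes are parsed from remaining 12-signals and accepted
only with a donor splice site at the expected distance and either a
strong signal or a readable FGXG motif; V genes are parsed upstream of
23-signals through the leader/intron/V-exon grammar (intron delimited by
donor and acceptor motifs at the profile's fixed intron length, searched
within ±60 nt of the expected position to absorb indel lesions). A V
candidate without intron evidence is accepted only when signal strength
is high *and* the gene body is otherwise intact; a candidate with a weak
signal and a broken body (no leader, broken frame) is treated as noise.
C genes carry no signal and are located by seeded homology to the
reference C exon 1 (exact 55-mer seeds voting for an offset, verified by
edit distance ≤ 20%), then parsed into four exons at fixed offsets.

Overlapping hits are deduplicated twice: shifted "echo" signals within
12 nt of a stronger one are collapsed, and V parses sharing a gene body
keep the variant with fewer defects and the stronger signal.

These acceptance rules mean the annotator is tuned for loci whose gene
grammar matches the reference profile (fixed exon lengths ±10%, fixed
intron length ±60). That is exactly what the synthetic generator emits;
a real genomic contig with divergent intron lengths would need a profile
describing it.

## Functionality classification

Rules are applied in order and accumulate defect codes: `a` missing
leader, `RSS`/`RSS-missing` signal defects, `c` splice defect, `d`
coding length outside ±10% of the expected V exon (or outside 40–60 nt
for J), `e` frameshift or stop codon, `FGXG` missing J motif, `anchor`
missing conserved V-domain anchor. F requires every check to pass.
The ORF/P boundary is a documented choice: frame-intact genes whose only
defects are signal or anchor defects are ORF; a missing leader, broken
splice, wrong length, frameshift, stop, or missing FGXG gives P. The
classification is monotone by construction — adding a defect can never
move a verdict toward F — and this is property-tested.

## IMGT-style numbering

The packaged V template spans IMGT positions 1–104 with FR1/FR2/FR3 of
26/17/39 residues and CDR1/CDR2 intervals 27–38 and 56–65 filled
middle-out. Query domains are numbered geometrically when their length
is consistent with the fixed-framework layout (anchors are then
position-computable, with the CDR1/CDR2 split chosen by the W-41 anchor
and FR2 similarity); domains with framework indels fall back to a global
amino-acid alignment against the template (match 2, mismatch −1, gap
open −8, extend −1). A missing 2nd-CYS raises (`unanchored domain`): the
CDR3 cannot be located, and such clones are flagged and excluded from
CDR3 statistics. Any other missing anchor is a defect, not an error,
mirroring in-frame pseudogenes that lost only the 1st-CYS.

## Identity thresholds

Percent identity is computed over a global affine-gap alignment (match 1,
mismatch −1, open −5, extend −1, all config-exposed; Bio.Align's
PairwiseAligner provides the alignment and is checked in the tests
against an exhaustive Gotoh dynamic program). The denominator excludes
terminal-gap columns and counts internal gap columns as mismatches —
documented because the source criterion is silent on both. Subgroup
clustering takes connected components of the identity > 75% graph
(single linkage, the weakest consistent reading of the pairwise
criterion; complete linkage is available). For all-vs-all matrices an
edit-distance screen (edlib) settles pairs more than 8 identity points
from the threshold and the exact aligner rescores the rest, so threshold
decisions are always taken on the exact score. Both thresholds are
strict (`>`), so a pair at exactly 97.0% is *not* an allele — matching
the printed "more than 75%" / ">97%" wording.

## Phylogenetics

p-distances remove every column containing a gap or ambiguity in any
sequence (complete deletion) and count differing sites over retained
sites. Neighbor joining is the canonical Saitou–Nei algorithm with
Q-matrix selection, deterministic smallest-index tie-breaks, and
negative branch estimates clamped to zero with the total deficit
recorded on the tree. Bootstrap resamples alignment columns with
replacement (seeded NumPy generator); supports are the percentage of
replicates containing each internal split of the reference tree
(majority-rule consensus was considered and not needed). NJ correctness
is tested two independent ways: exact recovery of topology and branch
lengths on random additive matrices, and topological agreement with
dendropy's NJ on random non-additive matrices.

The internal progressive aligner (k-mer guide distances, NJ guide tree,
profile–profile Needleman–Wunsch with linear gaps) replaces an external
multiple aligner: the downstream conclusions depend on distances and
topology, not on a specific aligner, and externally produced alignments
can be supplied anywhere one is accepted.

**Grouping expressed sequences.** The published trees assign cDNA groups
to germline genes visually; a reproducible rule had to be chosen. On the
midpoint-rooted tree, each query walks to its nearest ancestor clade
containing at least one reference leaf: exactly one reference there and
the query inherits its name; two or more and the query belongs to a
reference-free clade, which receives a provisional name `<subgroup>S<k>`
numbered after the last germline member, in traversal order. The caveat
is inherent to any topological rule: a query clade attached directly
next to a reference is indistinguishable, by topology alone, from an
allele cluster of that reference; midpoint rooting separates the
divergent (new-gene) case in practice, and the identity threshold has
already filtered queries ≥ 97% before they reach the tree.

## Junction analysis

CDR3 runs strictly between position 104 and the F of FGXG (both anchors
excluded; an inclusive 104–118 junction variant exists for
interoperability). Clone anchoring is deliberately redundant: the V is
located by infix edit-distance search and rescored by exact identity,
the 2nd-CYS is anchored on the last 30 germline nucleotides, the FGXG by
the germline J's constant block, and the final (CYS, FGXG) pair is
jointly re-anchored under the frame constraint because a substitution on
a search-window edge can slip an edit-distance location by a base.

D calling searches exact substrings only (no mismatches): mutated D
stretches resolve to shorter exact matches or none, reproducing the
"no identifiable D" class. The longest match ≥ 5 nt wins; equal-length
matches to several D genes form an unresolved set; two disjoint
above-threshold matches to different D genes flag a double-D junction.
An unresolved set still classifies the rearrangement when all its
members give the same class (e.g. D3-or-D2 joined to a cluster-1 J is
trans either way); otherwise the clone is undetermined.

Percentages and means are rounded half-up to one decimal, matching the
printed tables.

## Synthetic data: what it emulates, and what it does not

The generator emits the pig-like architecture with known truth: 38 V
genes in 24 subgroups (expansion profile 5/5/3/3/2/2 plus singletons),
12 pseudogenes carrying planted lesions cycling through the rule
classes, three D–J–C clusters with 7/7/6 J genes and D lengths 14/17/16,
cluster labels (1, 3, 2) in genomic order, one inverted 3′ V gene, and
one J with the 5th-position heptamer mutation. Repertoires draw V, D and
J with configurable bias, respect 5′→3′ cluster feasibility with a
trans-rearrangement probability (default 0.03, the observed order of
magnitude), trim ends geometrically (default mean 2 nt/end), insert
geometric N additions (default mean 3 nt), enforce productivity by
default (frame-closing N padding, stop-free CDR3), splice to the cluster
C, and apply point substitutions (default 0.005/nt, giving the 97–100%
germline-identity range typical of the expressed collection).

Identifiability margins are deliberate generator design, not biology:
subgroup founders are regenerated until cross-subgroup identity is below
70% so the > 75% criterion has an unambiguous truth; large coding-length
lesions are planted only on single-member subgroups for the same reason;
the three default D genes use disjoint 4-mer vocabularies (G-rich
triplet repeats with distinct second letters) so that a ≥ 5-nt junction
stretch names its source D; J heads are screened against D 5-mers; and
random segments are screened against chance recombination-signal hits at
discovery thresholds. Real loci violate all of these: pig TRBD2 and
TRBD3 are near-identical, which is exactly why the published analysis
carries unresolved-D classes. The ambiguity logic is therefore exercised
in unit tests with a deliberately similar synthetic D set, while
generator-based tests measure recovery under identifiable truth. Passing
tests consequently show that the pipeline's rules are implemented
exactly, not that real-locus ambiguity rates would be reproduced.

Remaining stochastic residue: chimeric windows spanning segment
boundaries can still, rarely, mimic a signal or a D 5-mer; single-base
slips of edit-distance locations are absorbed by the joint re-anchoring
above. The lossless-recovery properties (100% V/J/D and exact CDR3 at
zero trimming/substitution) and the exact agreement between the D caller
and an independent brute-force recount are asserted, not assumed.

## Problem sizes

The default test and acceptance runs use one 38-gene locus (~34 kb),
repertoires of 100 (lossless) and 500 (noisy) clones, 100 random 6–10
taxon trees for NJ recovery, and 100-replicate bootstraps — sizes chosen
so the full suite completes in well under a minute per stage while every
property is exercised at non-trivial scale.

## Known limitations

- The annotator's grammar is profile-bound (fixed intron length, fixed
  leader length, fixed C exon offsets); real assemblies need a matching
  profile and would surface grammar violations as defects rather than
  adapt to them.
- Allele nomenclature (`*01`-style) is out of scope: assignments are
  exact / allele / unassigned.
- The tree-grouping rule is one formalization of a visual procedure; its
  failure mode (reference-adjacent query clades) is documented above.
- p-distance is the only distance model, matching the source analysis;
  no ML/Bayesian inference is provided.
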