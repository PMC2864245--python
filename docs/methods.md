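# Methods

This note documents the models, algorithms and numerical choices behind
`chromomine`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Coordinates and formats

All coordinates are 0-based half-open internally and converted to 1-based
inclusive only when writing GFF3; the conversion is its own inverse and the
FASTA/GFF3 round-trips are lossless (property-tested). Residues are
uppercased on read and U is mapped to T for nucleotide input. Newick output
carries branch lengths at six significant digits and bootstrap supports as
internal node labels. A GenBank reader (no writer) is provided for
annotated single-element records.

## Synthetic genomes (the study conditions)

The generator plants full-anatomy Gypsy-like elements into an i.i.d.
background genome of configurable GC (default 0.5). The default template is
a 5704 bp two-ORF chromovirus: 440 bp LTRs beginning TG and ending CA and
carrying TATA/CAAT boxes; a 60 nt leader that is thymine-rich when no
primer-binding site is planted; a 969 nt *gag* ORF (323 aa) with a
C-X2-C-X4-H-X4-C zinc knuckle; a 3714 nt *pol* ORF (1238 aa) with the
domain order PR–RT–RH–Int–CHD (variants may insert dUTPase or drop CHD); a
12 nt all-purine tract ending 2 nt before the 3'LTR; and a degenerate
primer cassette inside RT — one exact expansion of the GyRT1 forward primer
and, 303 nt downstream, the reverse complement of an expansion of the
ty3-A 3' core, giving a 320 bp amplicon. Templates are validated against
the observed anatomy of real elements (LTRs ≥ 100 bp, TSD 4–6 bp, total
length within 4.4–13.5 kb, CHD only after Int).

Family structure: each family's proteins diverge from a shared synthetic
consensus library by a configurable amino-acid distance
(`consensus_divergence`, default 0.30 — between-family RT–Int identity
~0.5, far below the 90% family threshold, while one shared search profile
still finds every family). The initiator methionines and the primer-cassette
codons are pinned. Copies within a family each diverge from the family
master at `within_divergence / 2` nucleotide substitutions per site, so the
expected pairwise divergence between copies equals `within_divergence`.
The standard survey scene is a 2 Mb genome with 5 families × 6 copies at
`within_divergence = 0.03` and 20% of copies decayed. 0.03 was chosen once
as the scene condition: it keeps copy pairs at ~94% amino-acid identity,
comfortably inside the 90–100% family definition, whereas 0.05 nucleotide
divergence sits exactly at the 90% clustering threshold and the family
definition itself becomes ambiguous.

Intact insertions are flanked by an identical 4–6 bp target-site
duplication copied from the insertion point; decayed copies are truncated
at a random end (losing 30–70%) and carry no TSD. Mutations are
substitutions only by default (truth coordinates stay exact); strands are
random. The truth records every feature, the planted TSD, and whether the
primer cassette still matches the degenerate primers after mutation.

What the generator does **not** emulate: nested insertions, solo LTRs,
recombination between copies, indels (optional, off by default),
codon-usage and GC heterogeneity, segmental duplications, and repeat-rich
backgrounds. Passing the recovery tests therefore demonstrates the
machinery is correct under clean conditions, not that recall on real
assemblies — where decayed nests and tandem repeats dominate — would be as
high.

Protein pairs for rate work evolve under the Poisson model exactly as the
correction assumes: each site of the second sequence differs independently
with probability 1 − e^(−d), d = 2rT, replacement uniform over the 19
alternatives; no rate heterogeneity across sites.

## Profile search

The miner translates the genome in six frames (standard code; ambiguity
codons become X unless all IUPAC expansions agree; stops are `*`) and scans
each frame with a position-specific scoring model built from a gap-free
seed alignment of RT..partial-Int fragments (660 columns). Emissions are
(count + pseudocount)/(total + 20·pseudocount) with pseudocount 0.5,
log2-odds against a uniform 1/20 background; columns with ≥ 50% gaps are
discarded. The alignment is glocal — profile global, sequence local — via a
three-state Viterbi in bits. Gap penalties: open 12; **deletion** extend
0.25 (a 5'- or 3'-truncated copy deletes hundreds of profile columns for a
near-constant cost and stays far above threshold); **insertion** extend 4
(cheap insertions would otherwise let score shoulders trail thousands of
residues past an element, bridging neighbouring copies, and let alignments
"shop" for chance matches in background sequence). Split insert/delete
transition costs are standard profile-HMM practice.

The default bit threshold is 0.15 bits per match column (floor 25):
genuine hits score ≥ 1 bit/column even at 35% amino-acid divergence
(~1000 bits for a full-length diverged copy), while the empirical
scrambled-sequence maximum over 100 seeded 2000-aa trials is below
threshold (FPR 0 in 0.2 Maa; the i.i.d. 2 Mb scene yields zero false
loci). Hits are selected greedily: best end position, traceback, trim to
the maximal-scoring contiguous core (Kadane over the alignment steps, which
removes weakly matching junk at the envelope edges), mask one profile
length around the accepted hit, repeat. Hits are then verified by local
alignment (BLOSUM62, gap open 11 extend 1 — blastp defaults) against a
labelled reference panel (keep if ≥ 25% identity over ≥ 100 aa; label =
best panel member) and merged into loci when on one strand within 1000 nt.

## Element annotation

Each locus is expanded ±15 kb (clipped) and oriented by hit strand; all
structure finding runs in element-forward orientation and maps back. The
LTR pair is sought as a direct repeat with one copy on each side of the
RT–Int anchor: exact 12-mer seeds grouped by diagonal, ungapped x-drop
extension (+1/−2, drop 20) trimmed to the maximal-scoring extent,
candidates filtered at length ≥ 100 and identity ≥ 0.80 within a 15 kb
span and scored by length × identity with a canonical TG...CA bonus.
Because tandem copies of one family offer cross-copy repeat pairs (the
5'LTR of one copy pairs perfectly with the 3'LTR of the next), the top
candidates are re-ranked by insertion evidence: presence of a flank
duplication after boundary refinement, then canonical-end count, then the
innermost span.

Boundary refinement shifts both LTR starts together and both ends together
within ±14 nt of the raw extent, choosing the shift supported by an
identical 4–6 bp flank duplication, then by the TG/CA count over both LTR
copies (0–4; a point mutation can erase one terminal dinucleotide while the
other three still pin the boundary), then the smallest shift, then the
longest duplication. Under the standard scene this recovers element
boundaries and TSDs exactly for every intact copy across all tested seeds;
the raw (unrefined) repeat extent alone can slip a few nucleotides wherever
flanking bases match by chance.

ORFs are maximal, complete start-to-stop spans ≥ 200 codons on both
strands (reported lengths exclude the stop codon); antisense ORFs of coding
regions appear occasionally and are reported as found. Domains are called
by per-domain profile scans with overlaps resolved best-score-first; an
element is a chromovirus iff CHD is found downstream of Int. The PPT is the
longest ≥ 10 nt window of ≥ 90% purines ending within 20 nt of the 3'LTR;
the PBS search looks 30 nt downstream of the 5'LTR for a ≥ 12 nt reverse
complement of a panel tRNA 3' terminus or a ≥ 12 nt copy of the LTR
(self-priming). In-silico PCR matches the forward primer with full IUPAC
degeneracy on both strands and the reverse primer's reverse complement
downstream, reporting products within the 250–400 bp window; only the
17 nt 3' core of ty3-A is matched, its 5' tail being a cloning adapter that
never anneals genomically. Reconstruction from partials greedily merges
fragments sharing a ≥ 200 nt suffix–prefix overlap at ≥ 95% columnwise
identity (columnwise, not edit-distance, so a shifted placement cannot
masquerade as a slightly longer overlap); note that overlaps shorter than
the LTR itself are inherently ambiguous for LTR elements.

## Families, phylogeny

Family identity is the global-alignment amino-acid identity of RT–Int
regions (BLOSUM62, gap 11/1), with matches divided by aligned columns
excluding gap columns; counting gap columns as mismatches is a config
switch because published identity conventions differ and some published
rate rows are only consistent with a different column set than their
printed identities (see below). Families are single-linkage clusters at
≥ 0.90, deterministic and input-order invariant. Copy number counts
non-overlapping nucleotide hits of the family representative (16-mer
seeding, edlib infix alignment, ≥ 100 nt at ≥ 0.80 identity, both
strands); genome fraction is the union length of hits over genome length.

The progressive aligner builds a p-distance guide tree by neighbor joining
and merges profiles with sum-of-pairs column scores (BLOSUM62 for protein,
+5/−4 for nucleotide; linear gap penalty); all tie-breaking is on sequence
names, so the alignment is input-order invariant. Distances are p over
shared ungapped columns, optionally Poisson-corrected d = −ln(1 − p)
(error if p ≥ 1 − 10⁻⁹; computed as −log1p(−p) for small-p accuracy).
Neighbor joining uses the Saitou–Nei Q-criterion with lexicographic
tie-breaking and clamp-and-transfer for negative branch lengths; it is
exact on additive matrices (property-tested on 100 random trees ≤ 12
taxa). Bootstrap resamples alignment columns with replacement; support is
the percentage of replicates containing each bipartition of the point
tree. Clade assignment gives a query the label of the smallest containing
clade whose reference leaves are label-uniform with support ≥ 50%.
Outgroup rooting places the root mid-edge on the branch separating a
monophyletic outgroup.

## Rates and horizontal-transfer criteria

For a pair with identity I, p = 1 − I, d = −ln(1 − p) and r = d/2T with T
the host divergence time in years; rates are reported ×10⁹. The bundled
calibration: Plants/Fungi 1500 Myr, Basidiomycetes/Ascomycetes 1200,
Homobasidiomycetes/Chytridiomycetes 900, Sordariomycetes/Eurotiomycetes
540, Sordariomycetes/Dothideomycetes 490, Tremellomycetes/Agaricomycetes
700. Pairs without a listed divergence time (e.g. moss/lycophyte) raise an
error rather than guessing a T. Recomputing the bundled reference table
from its printed identities reproduces the four cleanest published rates
within 1.5% (the residual is identity rounding); several other rows carry
larger residuals, and two (AltBraTy3-2/NecHaemTy3-4 at 0.880 and
skippy/PyrTriTy3-1 at 0.772) cannot be reproduced from their printed
identities under any listed divergence time — they are flagged
`irreproducible` in the data file and excluded from checks.

The three HT criteria: (1) **incongruence** — a ≥ 50%-supported element
bipartition, mapped to hosts (hosts on both sides are dropped as
paralogy), conflicts with the host tree iff some host split has all four
intersections non-empty; (2) **slowdown** — every element rate strictly
below every host-gene rate over the matched taxon pairs, margin =
min(gene) − max(element); (3) **patchy distribution** — at least one loss
required under single-origin vertical descent (the count of maximal
all-absent subtrees, which equals the small-parsimony change count with a
present root) with presence non-universal. The combined verdict is
"HT-supported" iff slowdown holds together with at least one of the other
two — slowdown is treated as the strongest criterion and is necessary;
the combination rule is exposed in config because reasonable alternatives
exist.

## Pipeline and reproducibility

The pipeline (simulate → mine → annotate → pcr → classify → tree → rates →
ht) reads a JSON config, writes plain-text artifacts plus a JSON manifest
(inputs, outputs, seeds, wall times) and resumes from existing stage
outputs. Every random stage derives from one explicit seed; identical
config + seed gives byte-identical outputs (tested). The acceptance script
runs the standard 2 Mb scene, the 200-replicate rate recovery, 100
additive-matrix NJ recoveries, a pristine element annotation and the HT
demo in a few minutes on one CPU; problem sizes (2 Mb, 5 × 6 copies, 200
replicates) are the package's standard desk-scale study conditions.

## Known limitations

Insertion-age dating from LTR divergence, solo-LTR discovery, nested
elements, E-value statistics for the profile search, maximum-likelihood or
Bayesian phylogenetics, and dN/dS are out of scope. The profile search has
a bit threshold, not a statistical E-value; the empirical null is
calibrated on i.i.d. sequence and will be optimistic on low-complexity or
repeat-rich genomes. The thymine-rich leader observed in elements lacking a
PBS is generated but only surfaced as raw sequence, not detected as a
feature.
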