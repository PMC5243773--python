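# Methods

## Scope and data model

The package analyses three collinear mitochondrial genomes of holopelagic
*Sargassum* and the amplicon assays that type specimens into the three
forms (*S. fluitans III*, *S. natans I*, *S. natans VIII*, always in this
fixed reporting order). Coordinates are 1-based inclusive throughout.
The deposited sequences themselves are not shipped; instead a synthetic-data
module constructs reference genomes that realize the packaged 98-site
variant panel exactly. Everything downstream (scanning, effect annotation,
PCR, typing, phylogeny) is written against genomes in general, so real
sequences can be substituted wherever equal-length collinear FASTA is
accepted.

## The reference panel

`data/variant_table.tsv` lists the 98 polymorphic sites with each form's
allele and, for coding sites, an amino-acid chain. The chain notation
carries one entry per *run of equal alleles* in form order: alleles
(C, C, T) print two entries ("Pro > Ser"), alleles (G, A, G) print three
("Gly > Asp > Gly"), and a synonymous change still prints both states
("Ala > Ala"). This convention is load-bearing: merging by amino acid
instead of by allele would collapse "Ala > Ala" and "Stop > Stop" rows and
break the round-trip contract below. `data/primer_panel.tsv` carries the
two diagnostic primer pairs verbatim (cox2-370F/cox2-776R,
cox3-467F/cox3-901R).

## Synthetic reference construction

The generator is a small constraint solver followed by a seeded random
fill.

**Codon constraints.** For each coding site the solver searches strand ∈
{+, −} × offset ∈ {0, 1, 2} × 64 codons for assignments whose per-form
substitutions translate to the chain (plus strand first, offsets
ascending, codons lexicographic; the codon template carries the first
form's coding base at the site offset). Per *gene*, a single strand and
reading frame must satisfy all of the gene's sites simultaneously — the
frame fixes each site's codon offset through its genomic position mod 3 —
and the first satisfying (strand, phase) is taken. Several genes are
thereby forced onto the minus strand (*tatC*, *rps19*, *orf129*): e.g. the
Ile > Phe change at 7237 (T→A) is only realizable with the substitution at
the first codon position of the reverse complement.

**Stop codons.** Stops are TAA/TAG wherever a choice exists; filler codons
never contain any stop, and every CDS ends in TAA unless a panel site
constrains its terminal codon. Two rows pin terminal stops: 10783
("Glu > Stop") becomes the minus-strand terminal codon of *orf129* (GAA →
TAA; the *fluitans* copy consequently ends in Glu without a stop, the one
place the ends-in-stop rule yields), and 34589 ("Stop > Stop") is the last
codon of *nad7*. For *nad7* the frame is pinned by the Leu > Leu site at
33828 (offset 2), which forces 34589 to offset 1 — and the only stop pair
there is TGA → TAA. TGA is therefore admitted exactly where the panel
forces it; translation uses the standard code, and the mold/protozoan
mitochondrial code (table 4, TGA = Trp) would read through *fluitans*
*nad7*. The panel does not state which code the organism uses; the chains
are only jointly realizable under the standard one.

**Gene layout.** One feature per panel locus (CDS for protein genes and
orfs, rRNA for 23S/16S, tRNA for trn loci), placed left to right:
each feature covers its own sites, excludes all foreign sites, and
features never overlap. CDS margins are 15 bp beyond the outer sites;
rRNAs pad 100 bp, tRNAs span 72 bp. Filler tRNA/orf features from a fixed
name list bring the total to 65 genes, placed in variant-free gaps. The
layout is fully deterministic.

**Primer placement.** The cox2/cox3 footprints are placed by a
deterministic search inside their genes: footprints must be variant-free
(so footprint bases never carry evidence and all three forms amplify
identically), must introduce no in-frame stop codon, and must flank a
window that contains the assay's diagnostic sites — for cox3 both 14466
(separating *fluitans*) and 14516 (the single assayable site separating
the two *natans* forms), for cox2 at least three *fluitans*-vs-*natans*
sites. The window is the maximal prefix of the gene's sites spanning
≤360 bp, keeping products at Sanger scale. Footprint coordinates are
recorded on the layout. The primer *names* suggest positions ~370/467 bp
into the real genes; with the panel's site spacing those offsets are not
jointly satisfiable with a non-overlapping annotation, so the footprints
sit where the constraints allow — the oligo sequences are what matters
and are embedded verbatim.

**Sequence fill.** The unconstrained background is drawn i.i.d. with
AT fraction 0.638 (A=T, C=G); CDS filler codons are drawn from a base
distribution adjusted (by a one-dimensional root solve) so that the
stop-rejected codon distribution still hits the target AT fraction.
With ~34.7 kb the realized AT content concentrates within ±0.01 of the
target. After assembly the build is verified: exact site round-trip, no
internal stops in any form, and each primer binding exactly once genome
wide (≤2 mismatches, 3′ clamp); on the rare spurious near-match the
background is redrawn from a derived seed. All randomness flows from the
single config seed (default 7).

**What the generator does not emulate.** Real gene order and strand
assignments (not printed anywhere; the layout is a constraint-satisfying
surrogate), codon-usage and strand-composition biases, indels, repeats,
and sequencing artefacts beyond i.i.d. substitution noise in cohort
amplicons. Passing tests therefore demonstrate the *pipeline logic* on
data with the study's exact variant structure, not performance on raw
field data.

## Comparison and effects

Collinear genomes are compared columnwise; unequal lengths raise an error
rather than triggering alignment, because the study system is same-length
and collinear and silent alignment would blur the difference counts. N is
missing data, never a difference; p-distances exclude N-columns pairwise.
Effect annotation extracts each form's codon from the genome on the coding
strand, translates, and merges per-form amino acids into the chain by
allele runs. Effect classes: synonymous (all amino acids equal), nonsense
(a differing state is Stop), nonsynonymous otherwise; rRNA/tRNA/intergenic
sites report "–". Generator and annotator are independent
implementations that meet at a round-trip contract: re-annotating the
generated genomes must reproduce all 98 chains byte-for-byte (a test and
a standing invariant). Synteny comparison counts orientation-aware
adjacencies of shared genes missing from the other annotation; a reversed
adjacent pair with flipped strands counts as conserved.

## In-silico PCR and typing

Primer matching is ungapped, ≤2 mismatches, with an exact 3-bp 3′ clamp
(the shape of a priming event a polymerase will extend); both strands are
scanned. A product is a plus-strand forward site and a downstream
minus-strand reverse site within 2,000 bp; zero or multiple products are
errors, not warnings, because the assay presumes a unique band.
Diagnostic profiles take the variant positions strictly *between* the
footprints. Typing reads the observed allele at each profile position
after anchoring the amplicon to the reference product (equal length ⇒
direct; shorter ⇒ best ungapped offset); the call is the unique form
matching every observed non-N allele across assays, else `unknown`
(no form, or several forms, fit) or `conflict` (assays individually match
but disagree). Majority voting is deliberately rejected: the premise of
the assay is that the sites are fixed, so one contradicting site is
information, not noise. A consequence worth knowing: the two *natans*
forms differ at a *single* assayable site (cox3 14516), so one
substitution error there forges a perfect haplotype of the other form
that no site-restricted caller can reject — at 1% per-base noise roughly
1 in 300 *natans* specimens. Confident calls are guaranteed internally
consistent, not error-proof.

## Phylogeny

Neighbour joining over p-distances, all 34,727 columns (with only three
in-scope genomes there are no ambiguous columns to strip, and full ML
inference would add nothing at this scale — the published analysis used a
larger taxon set and a GTR+Γ+I model, which is out of scope here). Ties
in the Q criterion resolve to the lowest node indices; when three nodes
remain, where Q is constant, the closest pair is joined, so the final
cherry is the closest pair and branch lengths reduce to the three-point
formulas (for counts 7/93/96: terminal branches 2, 5, 91). Negative
branch lengths are clamped to zero. The tree is rooted at the last join
with a zero-length edge; on additive matrices the unrooted topology and
all leaf-to-leaf path lengths are exact (property-tested against a
path-length oracle and cross-checked against scikit-bio's NJ).
The bootstrap resamples columns with replacement — implemented as a
multinomial over distinct column patterns, which is exactly equivalent and
makes 1,000 replicates instantaneous — and reports, per internal clade of
the full-data tree, the fraction of replicate trees containing it. For
all-identical inputs supports are undefined and reported as 0.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 34,727 bp | mitogenome length |
| `gene_count` | 65 | annotated features |
| `at_fraction` | 0.638 | AT content target |
| `cohort_sizes` | 53/13/5 | natans VIII / natans I / fluitans III |
| `noise_rate` | 0.0 | per-base amplicon substitution probability |
| `bootstrap_replicates` | 1000 | column resamples |
| `seed` | 7 | sole entropy source |

These defaults are the study conditions; the full pipeline (build, scan,
annotate, type, 1,000-replicate bootstrap) runs in a few seconds on one
core. Property tests use random trios up to 10 kb and random additive
trees up to 8 taxa — sizes at which the brute-force oracles are exact and
instant.

## Known limitations

- The gene layout is a surrogate, not a reconstruction; locus-level
  conclusions transfer only through the panel's site-to-locus assignment.
- Typing supports A/C/G/T/N only; IUPAC ambiguity codes collapse to N on
  input. Chromatogram parsing is out of scope.
- The cox2 primers are known to mismatch benthic *Sargassum* species;
  nothing here models applicability beyond the three holopelagic forms.
- Distances to outgroup species and the published multi-taxon tree require
  external sequences and are out of scope.
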