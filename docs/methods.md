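# Methods

## Problem setting

`introscape` analyses the evolution of a gene family's *architecture* rather
than just its sequences: where introns sit within the coding sequence, how
those positions change across a species tree, how paralogs arise by
duplication, and how the chromosomal neighborhood of each copy evolves. The
motivating system is the vertebrate collagen chaperone HSP47/SERPINH1, a
non-inhibitory serpin: a single-copy gene in tetrapods, coelacanth and
lampreys with a conserved 4-exon/3-intron architecture, but present in three
paralog sets (I–III) in ray-finned fishes, with two additional introns in
exon eI of set-I genes of euteleost fishes.

## Intron position numbering

An intron interrupting a coding sequence after `c` coding nucleotides lies
in codon `q = ceil(c/3)` with `r = c − 3(q−1)` nucleotides of that codon on
its 5′ side. The phase letter encodes `r`: **a** after the 1st nucleotide,
**b** after the 2nd, **c** after the 3rd (i.e. between codons). The codon
number is then projected through a multiple protein alignment onto a
designated reference protein — for serpins, mature human α1-antitrypsin —
by locating the alignment column of the q-th gene residue and counting
reference residues up to that column. This makes positions such as `192a`
comparable across genes regardless of lineage-specific indels.

Two conventions were fixed deliberately:

* **Phase letters** follow the a=1/b=2/c=3 mapping above. It is the only
  assignment in this family consistent with introns `192a` and `225a`
  bounding a 99 bp exon: the offsets are 574 = 3·191+1 and 673 = 3·224+1,
  whose difference is 99 and whose equal remainders force a length ≡ 0
  (mod 3).
* **Reference gaps**: when the projected column holds a reference gap, the
  nearest preceding reference residue is reported with `mappable=False`
  rather than silently interpolating. Auditability beats convenience here.

The exon-length identity `(c2 − c1) mod 3 = (r2 − r1) mod 3` for
consecutive introns is enforced as a property test over random
architectures. Two source-data discrepancies are noted and deliberately not
reproduced: an internal-exon size printed as 271 bp is inconsistent mod 3
with its flanking b→a labels (expects ≡ 2), and a printed 193–196 bp exon
range cannot everywhere satisfy the b→b ≡ 0 (mod 3) constraint. One
passage writes `36c` where the remainder arithmetic (offset 107 = 3·35+2)
and the other passages give `36b`; this package uses `36b`.

A real HSP47 gene is *not* collinear with α1-antitrypsin outside the
192–225 stretch — the printed 233 bp eIII exceeds the collinear 227 bp
because the true alignment carries indels there. The synthetic genes here
are collinear with their reference by construction, so their eIII is 227 bp;
only the 99 bp eII claim assumes collinearity, and it is exercised exactly
under that assumption.

## Gene models

Coordinates are 0-based half-open internally; GFF3 I/O converts from/to the
1-based inclusive standard. Minus-strand genes are normalised to
transcription order at parse time so every downstream computation is
strand-free. When a gene has several transcripts, the longest complete CDS
wins, ties broken lexicographically by transcript ID — the analysis concerns
one architecture per gene. CDS lengths include the stop codon, matching the
convention under which the terminal serpin exon is 303 bp (101 codons).
Architectures are stored CDS-only; UTR extents, which inflate the printed
first-exon sizes, are an optional annotation field and never enter phase
arithmetic. Loss calls are only made on complete genes; partial models
(e.g. a gene whose 192a intron region is hit by assembly error) yield
`unknown`, never a loss.

## Event inference

* **Dollo parsimony** for intron presence/absence: each intron position is
  treated as a character gained exactly once (introns as rare genetic
  markers), with losses free. The gain goes on the branch above the MRCA of
  carriers; the minimal loss set is the set of maximal clades inside the
  gain clade containing no carrier and at least one verified absence.
  Unknown-state leaves constrain nothing. Tests verify minimality against
  an oracle that enumerates every internal-node state assignment on trees
  up to 12 leaves.
* **Duplications** are detected on gene trees by species overlap: an
  internal node whose child clades share at least one species is a
  duplication node. This needs species-tagged leaves (`gene@species`) but
  no reconciliation machinery.
* **Dating** reads node ages off an ultrametric species tree (ages in MY,
  derived from branch lengths, ultrametricity checked to a relative 1e-6):
  an event on a branch is bracketed by the ages of the branch's child and
  parent nodes, rendered older-bound-first (`416–360 MYA`). Ages are user
  inputs; nothing here estimates divergence times.
* **Neighbor joining** (Saitou–Nei) is implemented in-package so its
  determinism is pinned: Q-criterion ties break by the lexicographically
  smallest cluster-label pair, and negative branch lengths are clamped to
  zero with a warning. On additive matrices it recovers the generating
  topology and branch lengths exactly (property-tested on random 5–8-taxon
  trees; cross-checked against scikit-bio's implementation). p-distances
  exclude any column with a gap in either row.

## Synteny

A locus is the focal gene plus ordered upstream/downstream flanking-gene
symbol lists (nearest first). Symbols are the comparison currency; sequence
orthology is out of scope, and paralog suffix mapping (GDPD5_2 ↔ GDPD5) is
an external rename table. The default window is 7 genes per side — the
largest flank discussed in the motivating data (a heptad). Adjacency is
unordered-pair based, so inversions do not break it; side shuffles are
markers present in both loci on opposite sides of the focal gene. A paralog
set's signature is the symbols present in ≥50% of its loci ordered by
median rank; the threshold is this package's own quantification of
"conserved with some variations" and is a parameter, not an inherited
constant. A species whose locus retains ≥half the signature but lacks the
focal gene is reported as a focal-gene loss.

## Sequence features

Per-column conservation is the modal-residue frequency with gaps counted in
the denominator but never as the mode (GENEDOC-shading style), binned at
90–100/70–89/50–69/<50 on integer-rounded percentages. The source study
never defines its percentage; this definition is the closest match to the
visualisation tool it cites and is documented as a choice. The canonical
conserved-residue checklist scores a position conserved at ≥50% carrier
frequency, partial below that, missing at zero. The reactive-center loop is
extracted as P17–P1′ by counting non-gap residues back from a user-supplied
P1 column (the serpin P1 for HSP47 is not published; it is a required
config input). The inhibitory call — ≥75% of hinge residues P15–P9 in
{G,A,S,T,V} — is a standard serpin-literature heuristic, exposed as a
parameter. ER retention is an exact C-terminal `[RKH]DEL` match; the
implementation is tested exhaustively against all 160 000 terminal
tetramers. Percent identity counts identical pairs over columns where both
rows are residues, reported as an integer.

## Synthetic data generator

The simulator exists so the whole pipeline can be exercised against a known
truth without downloads. Design choices:

* **Substitution model**: per-site Poisson substitutions at a configured
  rate (subs/site/MY) with uniform replacement among the 19 alternatives.
  This is deliberately the simplest exchangeable model — the tests target
  mapping/inference logic, not evolutionary realism — and it admits the
  closed-form expected identity
  `1/20 + (19/20)·exp(−(20/19)·rate·2·depth)`, which `calibrate_identity`
  exposes and a Monte-Carlo test confirms to ±3 points over 50 replicates.
* **Default conditions**: an 11-taxon fish+tetrapod ultrametric tree with
  the ray-finned stem spanning 416–360 MY and the euteleost stem 231–190 MY,
  so the scripted duplications and intron gains date to those windows. The
  default rate 8×10⁻⁴ subs/site/MY is calibrated so two lineages separated
  ~1000 MY of path length sit near 47% identity, placing within-set leaf
  identities in the 50–85% band typical of the real family. The root
  protein is 400 residues (mature-serpin scale; CDS 1203 nt including stop,
  giving the 574/99/227/303 exon layout) and ends in `RDEL` so the
  ER-retention scan has a true positive that decays realistically with
  divergence.
* **Events are scripted, not stochastic**: intron gains (offset + length),
  duplications (copying gene and suffixed locus), codon indels (the set-III
  99→93 and 303→306 edits), locus side-shuffles and losses are placed on
  named branches and logged. Replaying the log against the emitted fixtures
  is what the round-trip tests check.
* **Intron lengths** are drawn log-uniform from [78, 2096] nt, the span of
  the conserved-intron sizes reported across the family.
* **Indel-free default**: sequence evolution does not insert or delete
  residues, so reference projection is exact; scripted codon indels (which
  do change lengths) are tracked through homologous site keys so the
  emitted alignment is the true alignment. The generator therefore does not
  emulate alignment error: passing tests show the pipeline is correct given
  a correct alignment, not that any aligner is.
* **Determinism**: a single `numpy` generator seeded from the config drives
  every draw in a fixed traversal order; same seed ⇒ byte-identical
  fixtures (tested).

## Problem sizes

Default test and analysis runs use the 11-taxon tree, 400-residue proteins,
≤3 paralogs per species, 20 scripted histories for round-trip checks, 200
random additive matrices for NJ, and exhaustive Dollo enumeration on trees
up to 12 leaves. These sizes were chosen as the smallest at which every
qualitative feature of the study scenario (three paralog sets, clade-
restricted gains, dated stems, locus churn) is expressed.

## Known limitations

* Projection accuracy is bounded by the supplied alignment; the package
  does not align.
* The species tree and its ages are inputs; no tree inference or molecular
  clock is performed (the NJ tree built here is a distance summary, not a
  replacement for model-based phylogenetics).
* Synteny works on curated symbol lists, not genome coordinates.
* Conservation-bin counts on real alignments depend on a gap-handling
  definition the source data leaves unspecified; results are reproducible
  under this package's definition but not certified against the original
  figures.
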