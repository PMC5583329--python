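"""Domain types for gene structures plus GFF3 / FASTA / alignment / newick I/O.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the standard 1-based inclusive convention.  Minus-strand genes are normalised
to transcription order at parse time, so everything downstream is strand-free:
``cds_exons[0]`` is always the 5'-most coding exon of the mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DomainError, InputError, StructuralError

__all__ = [
    "GeneModel",
    "IntronRecord",
    "MultipleAlignment",
    "read_gff3",
    "write_gff3",
    "introns_of",
    "validate",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_tree",
    "write_tree",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene's CDS exon structure on a genomic sequence, strand-aware.

    ``cds_exons`` holds genomic ``(start, end)`` intervals (0-based half-open)
    ordered 5'->3' in *transcription* order; for minus-strand genes that is
    descending genomic position.
    """

    gene_id: str
    species: str
    seq_id: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]
    partial: bool = False
    utr_extent: tuple[int, int] | None = None  # optional 5'/3' UTR lengths, nt

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_exons:
            raise StructuralError(f"{self.gene_id}: gene model has no CDS exons")
        for s, e in self.cds_exons:
            if not (0 <= s < e):
                raise StructuralError(f"{self.gene_id}: bad exon interval ({s},{e})")
        genomic = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise StructuralError(f"{self.gene_id}: overlapping CDS exons ({s1},{e1})/({s2},{e2})")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != tuple(self.cds_exons):
            raise StructuralError(f"{self.gene_id}: exons not in transcription order for strand {self.strand}")

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        """Coding lengths of the exons in transcription order (nt)."""
        return tuple(e - s for s, e in self.cds_exons)

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)

    @property
    def n_introns(self) -> int:
        return len(self.cds_exons) - 1

    def intron_genomic_length(self, i: int) -> int:
        """Genomic gap (nt) between exons ``i`` and ``i+1`` (0-based, transcription order)."""
        a, b = self.cds_exons[i], self.cds_exons[i + 1]
        gap = b[0] - a[1] if self.strand == "+" else a[0] - b[1]
        if gap < 0:
            raise StructuralError(f"{self.gene_id}: negative intron between exons {i} and {i + 1}")
        return gap

    def with_exons(self, exons: Sequence[tuple[int, int]]) -> "GeneModel":
        return replace(self, cds_exons=tuple(exons))

    def cds_sequence(self, genome: str) -> str:
        """Spliced CDS on the coding strand, given the genomic sequence of ``seq_id``."""
        parts = [genome[s:e] for s, e in sorted(self.cds_exons)]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class IntronRecord:
    """One intron: its 1-based index, coding offset and genomic length.

    ``coding_offset`` is the number of coding nucleotides 5' of the intron —
    the quantity the phase/numbering machinery operates on.
    """

    gene_id: str
    index: int
    coding_offset: int
    length: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise DomainError("intron index is 1-based")
        if self.coding_offset < 1:
            raise DomainError("coding_offset must be >= 1")
        if self.length < 1:
            raise StructuralError(f"{self.gene_id}: intron {self.index} has non-positive length {self.length}")


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows with a designated reference sequence."""

    names: tuple[str, ...]
    rows: tuple[str, ...]
    reference_name: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise InputError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise InputError("duplicate sequence names in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InputError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        if self.reference_name not in self.names:
            raise InputError(f"reference {self.reference_name!r} not in alignment")

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise InputError(f"sequence {name!r} not in alignment") from None

    def degapped(self, name: str) -> str:
        return self.row(name).replace("-", "")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def introns_of(model: GeneModel) -> list[IntronRecord]:
    """Intron records for a model: prefix-sum coding offsets + genomic gap lengths.

    A single-exon model yields an empty list; a zero-length gap between
    adjacent exons is a structural error.
    """
    records = []
    offset = 0
    for i in range(model.n_introns):
        offset += model.exon_lengths[i]
        gap = model.intron_genomic_length(i)
        if gap == 0:
            raise StructuralError(f"{model.gene_id}: zero-length intron between exons {i + 1} and {i + 2}")
        records.append(IntronRecord(model.gene_id, i + 1, offset, gap))
    return records


def validate(model: GeneModel) -> list[dict]:
    """Machine-readable diagnostics; never raises on flagged-partial models.

    Each diagnostic is ``{"code": ..., "severity": ..., "detail": ...}``.
    Structural checks already enforced by the constructors are not repeated.
    """
    diags: list[dict] = []
    if model.partial:
        diags.append({
            "code": "partial_model",
            "severity": "info",
            "detail": "model flagged partial; completeness checks suppressed",
        })
    else:
        if model.cds_length % 3 != 0:
            diags.append({
                "code": "cds_not_multiple_of_3",
                "severity": "error",
                "detail": f"CDS length {model.cds_length} is not a multiple of 3",
            })
    for i in range(model.n_introns):
        if model.intron_genomic_length(i) == 0:
            diags.append({
                "code": "zero_length_intron",
                "severity": "error",
                "detail": f"adjacent exons {i + 1}/{i + 2} with no intervening intron",
            })
    return diags


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/CDS, 1-based inclusive).

    CDS features are grouped by transcript via ``Parent``; when a gene has
    several transcripts the longest complete CDS is kept (ties broken by
    transcript ID).  The ``partial=true`` attribute on gene or mRNA marks
    partial models.
    """
    mrna_gene: dict[str, str] = {}
    mrna_attrs: dict[str, dict[str, str]] = {}
    gene_attrs: dict[str, dict[str, str]] = {}
    cds: dict[str, list[tuple[str, int, int, str]]] = {}

    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise InputError(f"malformed GFF3 line: {line!r}")
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs_text = cols
        attrs = _parse_attributes(attrs_text)
        if ftype == "gene":
            gene_attrs[attrs.get("ID", "")] = attrs
        elif ftype in ("mRNA", "transcript"):
            tid = attrs.get("ID")
            if tid is None:
                raise InputError("mRNA feature without ID")
            mrna_gene[tid] = attrs.get("Parent", tid)
            mrna_attrs[tid] = attrs
        elif ftype == "CDS":
            parent = attrs.get("Parent")
            if parent is None:
                raise InputError(f"CDS without Parent on {seqid}:{start}-{end}")
            cds.setdefault(parent, []).append((seqid, int(start) - 1, int(end), strand))

    models_by_gene: dict[str, list[tuple[str, GeneModel]]] = {}
    for tid, pieces in cds.items():
        gene_id = mrna_gene.get(tid, tid)
        seqids = {p[0] for p in pieces}
        strands = {p[3] for p in pieces}
        if len(seqids) > 1 or len(strands) > 1:
            raise InputError(f"transcript {tid}: CDS on multiple sequences or strands")
        seqid, strand = pieces[0][0], pieces[0][3]
        intervals = sorted((s, e) for _, s, e, _ in pieces)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise StructuralError(f"transcript {tid}: overlapping CDS ({s1},{e1})/({s2},{e2})")
        if strand == "-":
            intervals = intervals[::-1]
        attrs = mrna_attrs.get(tid, {})
        gattrs = gene_attrs.get(gene_id, {})
        partial = attrs.get("partial", gattrs.get("partial", "")).lower() == "true"
        species = attrs.get("species", gattrs.get("species", ""))
        model = GeneModel(
            gene_id=gene_id,
            species=species,
            seq_id=seqid,
            strand=strand,
            cds_exons=tuple(intervals),
            partial=partial,
        )
        # remember which transcript produced this candidate for tie-breaking
        models_by_gene.setdefault(gene_id, []).append((tid, model))

    out = []
    for gene_id, candidates in sorted(models_by_gene.items()):
        complete = [(t, m) for t, m in candidates if m.cds_length % 3 == 0 and not m.partial]
        pool = complete or candidates
        pool.sort(key=lambda tm: (-tm[1].cds_length, tm[0]))
        out.append(pool[0][1])
    return out


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as three-level GFF3 (one transcript per gene)."""
    lines = ["##gff-version 3"]
    for m in models:
        genomic = sorted(m.cds_exons)
        span = (genomic[0][0] + 1, genomic[-1][1])
        attrs = f"ID={m.gene_id}"
        if m.species:
            attrs += f";species={m.species}"
        if m.partial:
            attrs += ";partial=true"
        lines.append("\t".join([m.seq_id, "introscape", "gene", str(span[0]), str(span[1]), ".", m.strand, ".", attrs]))
        tid = f"{m.gene_id}.t1"
        lines.append("\t".join([
            m.seq_id, "introscape", "mRNA", str(span[0]), str(span[1]), ".", m.strand, ".",
            attrs.replace(f"ID={m.gene_id}", f"ID={tid}") + f";Parent={m.gene_id}",
        ]))
        phase = 0
        for s, e in m.cds_exons:
            lines.append("\t".join([
                m.seq_id, "introscape", "CDS", str(s + 1), str(e), ".", m.strand, str(phase),
                f"ID={tid}.cds;Parent={tid}",
            ]))
            phase = (3 - ((e - s) - phase) % 3) % 3
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA / alignment / newick
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_alignment(path: str | Path, reference_name: str) -> MultipleAlignment:
    seqs = read_fasta(path)
    return MultipleAlignment(tuple(seqs), tuple(seqs.values()), reference_name)


def read_tree(path_or_text: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree from a path or a newick string."""
    text = str(path_or_text)
    if not text.lstrip().startswith("("):
        text = Path(path_or_text).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted",
                             preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise InputError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
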