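"""Reference-numbered intron labels with phase letters (e.g. ``192a``).

An intron interrupting a coding sequence after ``c`` coding nucleotides sits
in codon ``q = ceil(c/3)`` with ``r = c - 3(q-1)`` nucleotides of that codon
5' of it; ``r`` in 1..3 maps to the phase letters a/b/c.  The codon number is
then projected onto a reference protein (mature human α1-antitrypsin for
serpins) through a multiple protein alignment, making positions comparable
across genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import ConsistencyError, DomainError, InputError
from .gene_models import GeneModel, IntronRecord, MultipleAlignment, introns_of

__all__ = [
    "IntronLabel",
    "PhaseConvention",
    "RAGG_CONVENTION",
    "phase_of",
    "project_codon",
    "label_introns",
    "exon_length_between",
]

_LABEL_RE = re.compile(r"^(\d+)([a-z])$")


@dataclass(frozen=True)
class PhaseConvention:
    """Bijective mapping remainder (1..3) -> phase letter.

    The remainder counts nucleotides of the interrupted codon lying 5' of the
    intron; the default (Ragg-style) convention is a=1, b=2, c=3 — the only
    family consistent with introns 192a/225a bounding a 99 bp exon.
    """

    letters: tuple[str, str, str] = ("a", "b", "c")

    def __post_init__(self) -> None:
        if len(set(self.letters)) != 3:
            raise InputError("phase letters must be distinct")

    def letter(self, r: int) -> str:
        if r not in (1, 2, 3):
            raise DomainError(f"remainder must be 1..3, got {r}")
        return self.letters[r - 1]

    def remainder(self, letter: str) -> int:
        try:
            return self.letters.index(letter) + 1
        except ValueError:
            raise DomainError(f"unknown phase letter {letter!r}") from None


RAGG_CONVENTION = PhaseConvention()


@dataclass(frozen=True)
class IntronLabel:
    """A reference-numbered intron position such as ``192a``.

    ``mappable`` is False when the reference has a gap in the projected
    alignment column; ``ref_codon`` then holds the nearest preceding
    reference residue number.
    """

    ref_codon: int
    phase_letter: str
    mappable: bool = True

    def __post_init__(self) -> None:
        if self.ref_codon < 0:
            raise DomainError("reference codon must be non-negative")

    def __str__(self) -> str:
        return f"{self.ref_codon}{self.phase_letter}" + ("" if self.mappable else "?")

    @classmethod
    def parse(cls, text: str) -> "IntronLabel":
        mappable = not text.endswith("?")
        m = _LABEL_RE.match(text.rstrip("?"))
        if not m:
            raise InputError(f"cannot parse intron label {text!r}")
        return cls(int(m.group(1)), m.group(2), mappable)


def phase_of(c: int) -> tuple[int, int]:
    """Gene codon number and remainder for a coding offset ``c`` >= 1.

    ``q = ceil(c/3)``; ``r = c - 3(q-1)`` in 1..3.
    """
    if c < 1:
        raise DomainError(f"coding offset must be >= 1, got {c}")
    q = -(-c // 3)
    r = c - 3 * (q - 1)
    return q, r


def project_codon(q: int, aln: MultipleAlignment, gene_name: str) -> tuple[int, bool]:
    """Project gene codon ``q`` to reference numbering via the alignment.

    Returns ``(ref_codon, mappable)``.  Finds the alignment column holding
    the q-th residue of the gene row and counts reference residues at or
    before it; a reference gap there yields the nearest preceding reference
    residue with ``mappable=False``.
    """
    gene_row = aln.row(gene_name)
    ref_row = aln.row(aln.reference_name)
    if q < 1:
        raise DomainError(f"codon number must be >= 1, got {q}")
    seen = 0
    for col, (g, ref) in enumerate(zip(gene_row, ref_row)):
        if g != "-":
            seen += 1
            if seen == q:
                n_ref = sum(1 for ch in ref_row[: col + 1] if ch != "-")
                return n_ref, ref != "-"
    raise DomainError(f"codon {q} beyond the end of {gene_name!r} ({seen} residues)")


def label_introns(
    model: GeneModel,
    aln: MultipleAlignment,
    convention: PhaseConvention = RAGG_CONVENTION,
    cds: str | None = None,
) -> list[IntronLabel]:
    """One reference label per intron of ``model``, 5'->3'.

    When ``cds`` (the spliced coding sequence) is given, its translation is
    checked against the degapped alignment row for the gene; a mismatch is a
    consistency error, catching mispaired inputs before they silently shift
    every label.
    """
    if model.gene_id not in aln.names:
        raise InputError(f"{model.gene_id!r} not in alignment")
    if cds is not None:
        protein = str(Seq(cds).translate()).rstrip("*")
        aligned = aln.degapped(model.gene_id).rstrip("*")
        if protein != aligned:
            raise ConsistencyError(
                f"{model.gene_id}: CDS translation does not match alignment row "
                f"({len(protein)} vs {len(aligned)} residues or content mismatch)"
            )
    labels = []
    for rec in introns_of(model):
        q, r = phase_of(rec.coding_offset)
        n_aa = len(aln.degapped(model.gene_id).rstrip("*"))
        if q > n_aa:
            # intron inside/after the stop codon: clamp to the last residue
            q = n_aa
        ref_codon, mappable = project_codon(q, aln, model.gene_id)
        labels.append(IntronLabel(ref_codon, convention.letter(r), mappable))
    return labels


def exon_length_between(
    label1: IntronLabel,
    label2: IntronLabel,
    introns: list[IntronRecord],
    labels: list[IntronLabel],
) -> int:
    """Length (nt) of the exon bounded by two consecutive labelled introns.

    ``introns``/``labels`` are the gene's parallel intron records and labels;
    the two requested labels must be consecutive in that list.  The returned
    length ``c2 - c1`` always satisfies ``(c2 - c1) % 3 == (r2 - r1) % 3``
    for the labels' phase remainders.
    """
    if len(introns) != len(labels):
        raise InputError("introns and labels must be parallel lists")
    try:
        i = labels.index(label1)
        j = labels.index(label2)
    except ValueError:
        raise DomainError("labels do not belong to this gene") from None
    if j != i + 1:
        raise DomainError(f"labels {label1} and {label2} are not consecutive introns")
    return introns[j].coding_offset - introns[i].coding_offset
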