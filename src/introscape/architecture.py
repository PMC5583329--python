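"""Architecture comparison: label sets, gain/loss matrices, structural edits.

Architectures are summarised as ``Ne/Mi`` patterns (exon/intron counts, e.g.
``4e/3i`` vs ``6e/5i``); gains and losses are called against a configured
ancestral label set, with partial genes yielding ``unknown`` rather than
spurious losses.  The in-silico edits (intron insertion, codon indels) mirror
the structural changes observed between paralog sets and drive the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, InputError
from .gene_models import GeneModel, introns_of
from .intron_numbering import IntronLabel

__all__ = [
    "ArchitectureProfile",
    "GainLossMatrix",
    "profile",
    "compare",
    "insert_intron",
    "apply_codon_indel",
    "size_table",
]

PRESENT = "P"
ABSENT = "A"
UNKNOWN = "U"


@dataclass(frozen=True)
class ArchitectureProfile:
    """A gene's labelled intron set plus exon/intron sizes and pattern string."""

    gene_id: str
    labels: tuple[IntronLabel, ...]
    pattern: str
    exon_sizes: tuple[int, ...]
    intron_sizes: tuple[int, ...]
    partial: bool = False

    @property
    def label_set(self) -> frozenset[IntronLabel]:
        return frozenset(self.labels)


@dataclass(frozen=True)
class GainLossMatrix:
    """Genes x intron labels presence matrix plus per-gene gain/loss calls."""

    table: pd.DataFrame  # values P/A/U
    conserved_labels: tuple[IntronLabel, ...]
    novel_labels: tuple[IntronLabel, ...]
    gains: dict[str, frozenset[IntronLabel]]
    losses: dict[str, frozenset[IntronLabel]]
    unknown: dict[str, frozenset[IntronLabel]]


def profile(model: GeneModel, labels: list[IntronLabel]) -> ArchitectureProfile:
    """Summarise one gene: pattern string plus sizes in transcription order."""
    if len(labels) != model.n_introns:
        raise InputError(f"{model.gene_id}: {len(labels)} labels for {model.n_introns} introns")
    intron_sizes = tuple(r.length for r in introns_of(model)) if model.n_introns else ()
    return ArchitectureProfile(
        gene_id=model.gene_id,
        labels=tuple(labels),
        pattern=f"{model.n_exons}e/{model.n_introns}i",
        exon_sizes=model.exon_lengths,
        intron_sizes=intron_sizes,
        partial=model.partial,
    )


def _sort_key(label: IntronLabel) -> tuple[int, str]:
    return (label.ref_codon, label.phase_letter)


def compare(
    profiles: list[ArchitectureProfile],
    reference_labels: set[IntronLabel],
) -> GainLossMatrix:
    """Gain/loss matrix of gene profiles against an ancestral label set.

    Columns are the union of observed and reference labels, partitioned into
    conserved (ancestral) and novel.  For a complete gene, gains are labels
    outside the reference set and losses are reference labels it lacks; a
    partial gene yields ``unknown`` for absent reference labels, never a loss.
    """
    if not profiles:
        raise InputError("need at least one profile")
    ids = [p.gene_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate gene_ids in profiles")

    all_labels = set(reference_labels)
    for p in profiles:
        all_labels |= p.label_set
    columns = sorted(all_labels, key=_sort_key)
    conserved = tuple(l for l in columns if l in reference_labels)
    novel = tuple(l for l in columns if l not in reference_labels)

    cells, gains, losses, unknown = {}, {}, {}, {}
    for p in profiles:
        row = {}
        for label in columns:
            if label in p.label_set:
                row[str(label)] = PRESENT
            elif p.partial:
                row[str(label)] = UNKNOWN
            else:
                row[str(label)] = ABSENT
        cells[p.gene_id] = row
        gains[p.gene_id] = frozenset(p.label_set - reference_labels)
        if p.partial:
            losses[p.gene_id] = frozenset()
            unknown[p.gene_id] = frozenset(reference_labels - p.label_set)
        else:
            losses[p.gene_id] = frozenset(reference_labels - p.label_set)
            unknown[p.gene_id] = frozenset()

    table = pd.DataFrame.from_dict(cells, orient="index", columns=[str(l) for l in columns])
    return GainLossMatrix(table, conserved, novel, gains, losses, unknown)


def insert_intron(model: GeneModel, coding_offset: int, intron_length: int) -> GeneModel:
    """Split the exon containing ``coding_offset`` with a new intron.

    The coding sequence is untouched — exon count rises by one and downstream
    exons shift by ``intron_length`` genomic nucleotides.  Offsets at exon
    junctions (or 0) are rejected: they would not split anything.
    """
    if intron_length < 1:
        raise DomainError("intron length must be >= 1")
    boundaries = [0]
    for length in model.exon_lengths:
        boundaries.append(boundaries[-1] + length)
    if coding_offset <= 0 or coding_offset >= boundaries[-1]:
        raise DomainError(f"offset {coding_offset} outside the CDS interior")
    if coding_offset in boundaries:
        raise DomainError(f"offset {coding_offset} is an existing exon junction")

    exon_idx = next(i for i in range(model.n_exons) if boundaries[i] < coding_offset < boundaries[i + 1])
    within = coding_offset - boundaries[exon_idx]
    s, e = model.cds_exons[exon_idx]
    sign = 1 if model.strand == "+" else -1

    if model.strand == "+":
        left, right = (s, s + within), (s + within, e)
    else:
        left, right = (e - within, e), (s, e - within)

    new_exons = list(model.cds_exons[:exon_idx]) + [left]
    # shift the 3' part and all downstream exons away to make room
    shift = sign * intron_length
    for s2, e2 in [right] + list(model.cds_exons[exon_idx + 1:]):
        new_exons.append((s2 + shift, e2 + shift))
    if any(s2 < 0 for s2, _ in new_exons):
        # minus-strand shift can push an interval below zero; renormalise
        delta = -min(s2 for s2, _ in new_exons)
        new_exons = [(s2 + delta, e2 + delta) for s2, e2 in new_exons]
    return model.with_exons(new_exons)


def apply_codon_indel(model: GeneModel, exon_index: int, codons: int) -> GeneModel:
    """Grow or shrink one exon by whole codons (3 nt units), keeping frame.

    ``exon_index`` is 0-based in transcription order; positive ``codons``
    inserts, negative deletes.  Deleting an exon entirely is out of domain.
    """
    if not 0 <= exon_index < model.n_exons:
        raise DomainError(f"exon index {exon_index} out of range")
    delta = 3 * codons
    length = model.exon_lengths[exon_index]
    if codons < 0 and -delta >= length:
        raise DomainError(f"deletion of {-codons} codons exceeds exon length {length}")
    if codons == 0:
        return model
    sign = 1 if model.strand == "+" else -1
    new_exons = []
    for i, (s, e) in enumerate(model.cds_exons):
        if i < exon_index:
            new_exons.append((s, e))
        elif i == exon_index:
            new_exons.append((s, e + delta) if sign == 1 else (s - delta, e))
        else:
            new_exons.append((s + sign * delta, e + sign * delta))
    if any(s < 0 for s, _ in new_exons):
        shift = -min(s for s, _ in new_exons)
        new_exons = [(s + shift, e + shift) for s, e in new_exons]
    return model.with_exons(new_exons)


def size_table(profiles: list[ArchitectureProfile]) -> pd.DataFrame:
    """Per-gene exon/intron sizes with per-position min–max rows.

    Positions are named ``exon_1..exon_N`` and ``intron_<label>``; genes
    lacking a position get NA.  Returns an empty frame for empty input.
    """
    if not profiles:
        return pd.DataFrame()
    rows = {}
    for p in profiles:
        row: dict[str, object] = {}
        for i, size in enumerate(p.exon_sizes, start=1):
            row[f"exon_{i}"] = size
        for label, size in zip(p.labels, p.intron_sizes):
            row[f"intron_{label}"] = size
        rows[p.gene_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    exon_cols = sorted((c for c in table.columns if c.startswith("exon_")), key=lambda c: int(c.split("_")[1]))
    intron_cols = sorted(c for c in table.columns if c.startswith("intron_"))
    table = table[exon_cols + intron_cols]
    summary = pd.DataFrame({c: [table[c].min(), table[c].max()] for c in table.columns},
                           index=["min", "max"])
    return pd.concat([table, summary])
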