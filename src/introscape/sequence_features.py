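"""Serpin-oriented protein annotations from a multiple alignment.

Covers per-column conservation binning (GENEDOC-shading style: modal residue
frequency with gaps counted in the denominator), a canonical conserved-residue
checklist, reactive-center-loop (RCL) extraction with an inhibitory-hinge
heuristic, C-terminal ER-retention motif ([RKH]DEL) detection, and pairwise
percent identity over gap-free columns.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .errors import DomainError, InputError
from .gene_models import MultipleAlignment
from .intron_numbering import project_codon

__all__ = [
    "ConservationProfile",
    "ChecklistResult",
    "RCLAnnotation",
    "conservation_profile",
    "checklist",
    "rcl_annotate",
    "er_retention",
    "percent_identity",
]

BINS = ("90-100", "70-89", "50-69", "<50")
ER_RETENTION_RE = re.compile(r"[RKH]DEL$")
# residues counted as "small" in the classical inhibitory-hinge criterion
HINGE_SMALL = frozenset("GASTV")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column modal residue, modal fraction (%) and conservation bin."""

    modal_residues: tuple[str, ...]
    modal_fractions: tuple[float, ...]  # percent, 0..100
    bins: tuple[str, ...]
    bin_totals: dict[str, int]


@dataclass(frozen=True)
class ChecklistResult:
    """Status of canonical conserved positions: conserved / partial / missing."""

    statuses: dict[int, str]  # ref position -> status
    unmappable: tuple[int, ...]
    counts: dict[str, int]


@dataclass(frozen=True)
class RCLAnnotation:
    """Reactive-center-loop annotation for one protein.

    ``rcl`` spans P17..P1' (gaps removed); the hinge is P15..P9.  The
    inhibitory call uses the standard small-residue hinge criterion; HSP47
    family members come out non-inhibitory.
    """

    name: str
    rcl: str
    hinge: str
    inhibitory_call: bool | None  # None: truncated, no call
    er_retention: str | None
    gaps_at_p5_p6: bool
    truncated: bool = False


def _bin_of(pct: int) -> str:
    if pct >= 90:
        return "90-100"
    if pct >= 70:
        return "70-89"
    if pct >= 50:
        return "50-69"
    return "<50"


def conservation_profile(aln: MultipleAlignment) -> ConservationProfile:
    """Column-wise modal residue frequency, binned on integer-rounded percent.

    Gaps count in the denominator but never as the mode; an all-gap column
    has modal fraction 0.  Bin totals always sum to the alignment length.
    """
    if len(aln.rows) < 2:
        raise DomainError("conservation needs >= 2 sequences")
    if aln.n_columns == 0:
        raise DomainError("empty alignment")
    n = len(aln.rows)
    residues, fractions, bins = [], [], []
    totals = {b: 0 for b in BINS}
    for col in range(aln.n_columns):
        counts = Counter(row[col] for row in aln.rows if row[col] != "-")
        if counts:
            residue, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            pct = 100.0 * count / n
        else:
            residue, pct = "-", 0.0
        b = _bin_of(round(pct))
        residues.append(residue)
        fractions.append(pct)
        bins.append(b)
        totals[b] += 1
    return ConservationProfile(tuple(residues), tuple(fractions), tuple(bins), totals)


def checklist(aln: MultipleAlignment, canonical: list[tuple[int, str]]) -> ChecklistResult:
    """Score canonical ``(reference position, residue)`` pairs across the alignment.

    conserved: canonical residue in >= 50% of sequences at the projected
    column; partial: present but < 50%; missing: absent everywhere.
    Positions falling on reference gaps are reported unmappable and excluded
    from the counts.
    """
    ref_row = aln.row(aln.reference_name)
    ref_len = len(ref_row) - ref_row.count("-")
    n = len(aln.rows)
    statuses: dict[int, str] = {}
    unmappable = []
    # column of each reference residue number
    col_of: dict[int, int] = {}
    seen = 0
    for col, ch in enumerate(ref_row):
        if ch != "-":
            seen += 1
            col_of[seen] = col
    for pos, residue in canonical:
        if pos < 1 or pos > ref_len:
            unmappable.append(pos)
            continue
        col = col_of[pos]
        count = sum(1 for row in aln.rows if row[col] == residue.upper())
        if count == 0:
            statuses[pos] = "missing"
        elif count / n >= 0.5:
            statuses[pos] = "conserved"
        else:
            statuses[pos] = "partial"
    counts = Counter(statuses.values())
    return ChecklistResult(statuses, tuple(unmappable),
                           {k: counts.get(k, 0) for k in ("conserved", "partial", "missing")})


def er_retention(protein: str) -> str | None:
    """The C-terminal ER-retention tetrapeptide ([RKH]DEL) or None."""
    if len(protein) < 4:
        return None
    m = ER_RETENTION_RE.search(protein.upper())
    return m.group(0) if m else None


def rcl_annotate(
    aln: MultipleAlignment,
    ref_p1_codon: int,
    hinge_small_fraction: float = 0.75,
) -> dict[str, RCLAnnotation]:
    """Annotate each protein's RCL given the reference P1 residue number.

    The P1 alignment column is projected from reference numbering; per
    protein, P17..P1' are collected by counting non-gap residues back (and
    one forward) from P1.  The inhibitory call requires at least
    ``hinge_small_fraction`` of the hinge residues (P15..P9) to be small
    (G/A/S/T/V); fewer than 9 residues upstream of P1 yields no call.
    Columns P5/P6 are checked for gaps (a paralog-set signature) on the
    alignment itself.
    """
    ref_row = aln.row(aln.reference_name)
    seen = 0
    p1_col = None
    for col, ch in enumerate(ref_row):
        if ch != "-":
            seen += 1
            if seen == ref_p1_codon:
                p1_col = col
                break
    if p1_col is None:
        raise DomainError(f"reference has fewer than {ref_p1_codon} residues")

    out = {}
    for name, row in zip(aln.names, aln.rows):
        # walk back from P1 collecting residue positions P1, P2, ... P17
        positions: list[int] = []  # alignment columns of P1..P17 for this row
        col = p1_col
        while col >= 0 and len(positions) < 17:
            if row[col] != "-":
                positions.append(col)
            col -= 1
        p1_prime = None
        for col in range(p1_col + 1, len(row)):
            if row[col] != "-":
                p1_prime = col
                break
        rcl_cols = list(reversed(positions)) + ([p1_prime] if p1_prime is not None else [])
        rcl = "".join(row[c] for c in rcl_cols)

        truncated = len(positions) < 9
        if truncated:
            hinge = ""
            call = None
        else:
            # positions[i] is P(i+1); hinge = P9..P15
            hinge_cols = [positions[i] for i in range(8, min(15, len(positions)))]
            hinge = "".join(row[c] for c in reversed(hinge_cols))
            small = sum(1 for ch in hinge if ch in HINGE_SMALL)
            call = small / len(hinge) >= hinge_small_fraction

        # P5/P6 gap signature judged on the alignment columns of the
        # *reference* P5/P6 (set III shows gaps there)
        ref_positions = []
        col = p1_col
        while col >= 0 and len(ref_positions) < 6:
            if ref_row[col] != "-":
                ref_positions.append(col)
            col -= 1
        gaps56 = (
            len(ref_positions) >= 6
            and row[ref_positions[4]] == "-"
            and row[ref_positions[5]] == "-"
        )
        out[name] = RCLAnnotation(
            name=name,
            rcl=rcl,
            hinge=hinge,
            inhibitory_call=call,
            er_retention=er_retention(aln.degapped(name)),
            gaps_at_p5_p6=gaps56,
            truncated=truncated,
        )
    return out


def percent_identity(row_a: str, row_b: str) -> int:
    """Identical pairs over columns where both rows are non-gap, as integer %."""
    if len(row_a) != len(row_b):
        raise InputError("aligned rows must have equal length")
    comparable = same = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a == b:
            same += 1
    if comparable == 0:
        raise DomainError("no comparable columns")
    return round(100.0 * same / comparable)
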