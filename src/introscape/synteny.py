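"""Microsynteny: ordered flanking-gene lists and neighborhood conservation.

A locus is the focal gene plus its ordered upstream/downstream flanking gene
symbols (nearest first).  Comparisons operate purely on symbols — orthology
resolution happens upstream via a symbol-mapping table — and quantify shared
marker content (Jaccard), side shuffles, and conserved gene adjacencies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DomainError, InputError

__all__ = [
    "Locus",
    "SyntenyComparison",
    "compare_loci",
    "ancestral_support",
    "classify_copy_loci",
    "read_loci_tsv",
    "write_loci_tsv",
]


@dataclass(frozen=True)
class Locus:
    """Focal gene with ordered flanks; symbols are normalised to uppercase."""

    species: str
    focal_gene: str
    upstream: tuple[str, ...]  # nearest first
    downstream: tuple[str, ...]  # nearest first
    strands: dict[str, str] = field(default_factory=dict, hash=False, compare=False)
    focal_present: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "focal_gene", self.focal_gene.upper())
        object.__setattr__(self, "upstream", tuple(s.upper() for s in self.upstream))
        object.__setattr__(self, "downstream", tuple(s.upper() for s in self.downstream))
        if self.focal_gene in self.upstream or self.focal_gene in self.downstream:
            raise InputError(f"{self.species}: focal gene {self.focal_gene} repeated in flanks")

    def window(self, k: int) -> "Locus":
        """Truncate both flanks to at most ``k`` genes."""
        if k < 1:
            raise DomainError("window must be >= 1")
        return Locus(self.species, self.focal_gene, self.upstream[:k], self.downstream[:k],
                     self.strands, self.focal_present)

    @property
    def markers(self) -> frozenset[str]:
        return frozenset(self.upstream) | frozenset(self.downstream)

    def ordered(self) -> tuple[str, ...]:
        """Full gene order across the locus: reversed upstream, focal, downstream."""
        focal = (self.focal_gene,) if self.focal_present else ()
        return tuple(reversed(self.upstream)) + focal + self.downstream

    def rename(self, mapping: dict[str, str]) -> "Locus":
        """Apply a symbol map (e.g. strip paralog suffixes GDPD5_1 -> GDPD5)."""
        mapping = {k.upper(): v.upper() for k, v in mapping.items()}
        f = lambda s: mapping.get(s, s)
        return Locus(self.species, f(self.focal_gene),
                     tuple(f(s) for s in self.upstream), tuple(f(s) for s in self.downstream),
                     {f(k.upper()): v for k, v in self.strands.items()}, self.focal_present)


@dataclass(frozen=True)
class SyntenyComparison:
    """Shared/shuffled markers and order-conservation scores for a locus pair."""

    shared_markers: frozenset[str]
    same_side: frozenset[str]
    shuffled: frozenset[str]
    adjacency_score: float
    jaccard: float

    def __post_init__(self) -> None:
        assert self.shared_markers == self.same_side | self.shuffled
        assert 0.0 <= self.adjacency_score <= 1.0 and 0.0 <= self.jaccard <= 1.0


def _adjacent_pairs(order: tuple[str, ...]) -> set[tuple[str, str]]:
    # unordered adjacency: inversions do not break adjacency
    return {tuple(sorted(p)) for p in zip(order, order[1:])}


def compare_loci(a: Locus, b: Locus, window: int = 7) -> SyntenyComparison:
    """Compare two loci over a flank window of ``window`` genes per side.

    ``shuffled`` holds markers present in both loci but on opposite sides of
    the focal gene; ``adjacency_score`` is the fraction of A's adjacent gene
    pairs (including focal-gene adjacencies) conserved as adjacencies in B.
    """
    a, b = a.window(window), b.window(window)
    if not a.markers and not b.markers:
        raise DomainError("both loci have empty flanks; comparison undefined")
    shared = a.markers & b.markers
    same = frozenset(
        s for s in shared
        if (s in a.upstream) == (s in b.upstream) and (s in a.downstream) == (s in b.downstream)
    )
    shuffled = frozenset(shared - same)
    union = a.markers | b.markers
    jaccard = len(shared) / len(union) if union else 1.0
    pairs_a = _adjacent_pairs(a.ordered())
    pairs_b = _adjacent_pairs(b.ordered())
    adjacency = len(pairs_a & pairs_b) / len(pairs_a) if pairs_a else 1.0
    return SyntenyComparison(frozenset(shared), same, shuffled, adjacency, jaccard)


def ancestral_support(loci: list[Locus], markers: set[str], window: int = 7) -> dict:
    """Which species' loci carry *all* ancestral marker symbols (conjunctive).

    Mirrors the ancestral-locus argument: a locus supports the ancestral
    arrangement iff every marker co-occurs with the focal gene in its window.
    """
    if not markers:
        raise InputError("marker set must be non-empty")
    markers_u = {m.upper() for m in markers}
    support = {}
    for locus in loci:
        support[locus.species] = markers_u <= locus.window(window).markers
    return {
        "markers": sorted(markers_u),
        "per_species": support,
        "supporting_species": sorted(s for s, ok in support.items() if ok),
    }


def classify_copy_loci(loci_by_set: dict[str, list[Locus]], window: int = 7) -> dict[str, dict]:
    """Conserved flanking signature per paralog set.

    The signature is the symbols present in >= 50% of the set's loci, ordered
    by median position rank.  Loci that retain the signature but lack the
    focal gene are reported as focal-gene losses (the "partial or lost" case).
    """
    out = {}
    for set_name, loci in loci_by_set.items():
        if not loci:
            continue
        windows = [l.window(window) for l in loci]
        counts = Counter()
        ranks: dict[str, list[int]] = {}
        for locus in windows:
            order = locus.ordered()
            for idx, sym in enumerate(order):
                if sym == locus.focal_gene:
                    continue
                counts[sym] += 1
                ranks.setdefault(sym, []).append(idx)
        threshold = len(windows) / 2
        signature = [s for s, c in counts.items() if c >= threshold]
        signature.sort(key=lambda s: (sorted(ranks[s])[len(ranks[s]) // 2], s))
        sig_set = set(signature)
        losses = [
            l.species for l in windows
            if not l.focal_present and sig_set and len(sig_set & l.markers) >= len(sig_set) / 2
        ]
        out[set_name] = {
            "signature": signature,
            "n_loci": len(windows),
            "focal_gene_losses": sorted(losses),
        }
    return out


# ---------------------------------------------------------------------------
# TSV I/O: species, focal_gene, side (U/D), rank, symbol, strand
# ---------------------------------------------------------------------------

def read_loci_tsv(path: str | Path) -> list[Locus]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"species", "focal_gene", "side", "rank", "symbol"}
    if not required <= set(df.columns):
        raise InputError(f"locus TSV must have columns {sorted(required)}")
    loci = []
    for (species, focal), group in df.groupby(["species", "focal_gene"], sort=True):
        up, down, strands = [], [], {}
        focal_present = True
        for _, row in group.sort_values("rank", key=lambda s: s.astype(int)).iterrows():
            side = row["side"].upper()
            if side == "F":
                focal_present = row["symbol"].upper() != "X"
                continue
            (up if side == "U" else down).append(row["symbol"])
            if row.get("strand"):
                strands[row["symbol"].upper()] = row["strand"]
        loci.append(Locus(species, focal, tuple(up), tuple(down), strands, focal_present))
    return loci


def write_loci_tsv(loci: list[Locus], path: str | Path) -> None:
    rows = []
    for locus in loci:
        rows.append({"species": locus.species, "focal_gene": locus.focal_gene, "side": "F",
                     "rank": 0, "symbol": locus.focal_gene if locus.focal_present else "X",
                     "strand": ""})
        for side, flank in (("U", locus.upstream), ("D", locus.downstream)):
            for rank, sym in enumerate(flank, start=1):
                rows.append({"species": locus.species, "focal_gene": locus.focal_gene,
                             "side": side, "rank": rank, "symbol": sym,
                             "strand": locus.strands.get(sym, "")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
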