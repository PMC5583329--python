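"""Distance trees, Dollo gain/loss placement, duplication detection, dating.

The tree-facing operations work on rooted :class:`dendropy.Tree` objects.
Branches are identified by the frozenset of leaf labels below them (their
clade), which is stable across serialisation round-trips.

Dollo parsimony treats each intron (or duplication) as a character gained
exactly once — apt for rare genetic markers — and finds the minimum set of
loss branches explaining the observed presence/absence pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import DomainError, InputError

__all__ = [
    "DistanceMatrix",
    "DolloResult",
    "EventSet",
    "p_distance",
    "distance_matrix",
    "nj_tree",
    "dollo_events",
    "duplication_nodes",
    "node_ages",
    "date_event",
    "format_interval",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise InputError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise InputError("distance matrix diagonal is not zero")
        if np.any(v < 0):
            raise InputError("negative distances")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def p_distance(row_a: str, row_b: str) -> float:
    """Fraction of mismatches over columns where neither row has a gap."""
    if len(row_a) != len(row_b):
        raise InputError("aligned rows must have equal length")
    comparable = mismatch = 0
    for a, b in zip(row_a, row_b):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        comparable += 1
        if a != b:
            mismatch += 1
    if comparable == 0:
        raise DomainError("no comparable (gap-free) columns between the two rows")
    return mismatch / comparable


def distance_matrix(names: list[str], rows: list[str]) -> DistanceMatrix:
    """Pairwise p-distance matrix over aligned rows."""
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(rows[i], rows[j])
    return DistanceMatrix(tuple(names), m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of cluster labels, a cluster's label being its smallest
    leaf label.  Negative branch lengths are clamped to zero with a warning.
    The result is the unrooted NJ tree presented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise DomainError(f"neighbor joining needs >= 3 taxa, got {n}")

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = node

    d: dict[frozenset[str], float] = {}
    for i, a in enumerate(dm.labels):
        for j in range(i + 1, n):
            b = dm.labels[j]
            d[frozenset((a, b))] = float(dm.values[i, j])

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    def clamp(x: float, pair: tuple[str, str]) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.4g} for {pair}; clamped to 0")
            return 0.0
        return x

    active = sorted(nodes)  # cluster labels = smallest leaf label in cluster
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = clamp(dist(a, b) / 2 + (r[a] - r[b]) / (2 * (m - 2)), (a, b))
        lb = clamp(dist(a, b) - la, (b, a))
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        new_label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
        active = sorted(c for c in active if c not in (a, b)) + [new_label]
        active.sort()
        nodes[new_label] = parent

    a, b, c = active
    root = dendropy.Node()
    nodes[a].edge.length = clamp((dist(a, b) + dist(a, c) - dist(b, c)) / 2, (a, b))
    nodes[b].edge.length = clamp((dist(a, b) + dist(b, c) - dist(a, c)) / 2, (b, a))
    nodes[c].edge.length = clamp((dist(a, c) + dist(b, c) - dist(a, b)) / 2, (c, a))
    for label in (a, b, c):
        root.add_child(nodes[label])
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DolloResult:
    """Single-gain / minimal-loss placement for one binary character.

    Branches are named by the clade (frozenset of leaf labels) below them;
    ``gain_clade`` is None for an all-absent character (no event).
    """

    character: str
    gain_clade: frozenset[str] | None
    loss_clades: tuple[frozenset[str], ...]
    age_interval: tuple[float, float] | None = None

    @property
    def n_losses(self) -> int:
        return len(self.loss_clades)


@dataclass
class EventSet:
    """Dollo placements for a set of characters on one species tree."""

    events: dict[str, DolloResult] = field(default_factory=dict)

    def add(self, result: DolloResult) -> None:
        self.events[result.character] = result


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def dollo_events(
    tree: dendropy.Tree,
    presence: dict[str, int | None],
    character: str = "character",
) -> DolloResult:
    """Place one gain and the minimal losses for a presence/absence pattern.

    The gain goes on the branch above the MRCA of all present leaves; losses
    are the maximal clades inside the gain clade containing no present leaf
    and at least one absent leaf.  Leaves mapped to ``None`` (unknown state,
    e.g. partial genes) never force a loss.  An all-absent character yields
    a no-event result.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown_keys = set(presence) - leaves
    if unknown_keys:
        raise InputError(f"presence map names absent leaves: {sorted(unknown_keys)}")
    present = {l for l, s in presence.items() if s == 1}
    absent = {l for l, s in presence.items() if s == 0}
    # leaves not mentioned at all are treated as unknown
    if not present:
        return DolloResult(character, None, ())

    mrca = tree.mrca(taxon_labels=sorted(present)) if len(present) > 1 else next(
        l for l in tree.leaf_node_iter() if l.taxon.label in present
    )
    gain_clade = _leafset(mrca)

    losses: list[frozenset[str]] = []

    def collect(node: dendropy.Node) -> None:
        ls = _leafset(node)
        if not (ls & present):
            if ls & absent:
                losses.append(ls)
            return  # maximal all-absent clade; don't descend
        for child in node.child_nodes():
            collect(child)

    for child in mrca.child_nodes():
        collect(child)
    return DolloResult(character, gain_clade, tuple(sorted(losses, key=sorted)))


# ---------------------------------------------------------------------------
# Duplications and dating
# ---------------------------------------------------------------------------

def leaf_species(label: str) -> str:
    """Species tag of a gene-tree leaf named ``gene@species`` (or the label itself)."""
    return label.split("@", 1)[1] if "@" in label else label


def duplication_nodes(gene_tree: dendropy.Tree) -> set[frozenset[str]]:
    """Internal nodes whose child clades share species — the species-overlap rule.

    Leaves must carry species tags (``gene@species``).  Returns the clades
    (leaf-label frozensets) of the flagged nodes.
    """
    for leaf in gene_tree.leaf_node_iter():
        if "@" not in leaf.taxon.label:
            raise InputError(f"leaf {leaf.taxon.label!r} lacks a @species tag")
    flagged = set()
    for node in gene_tree.preorder_internal_node_iter():
        children = node.child_nodes()
        species_sets = [{leaf_species(l) for l in _leafset(c)} for c in children]
        overlap = False
        for i in range(len(species_sets)):
            for j in range(i + 1, len(species_sets)):
                if species_sets[i] & species_sets[j]:
                    overlap = True
        if overlap:
            flagged.add(_leafset(node))
    return flagged


def node_ages(tree: dendropy.Tree, tol: float = 1e-6) -> dict[frozenset[str], float]:
    """Node ages (distance to leaves) of an ultrametric tree, keyed by clade."""
    ages: dict[frozenset[str], float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._age = 0.0
        else:
            child_ages = []
            for c in node.child_nodes():
                if c.edge.length is None:
                    raise DomainError("tree has missing branch lengths; cannot derive ages")
                child_ages.append(c._age + c.edge.length)
            if max(child_ages) - min(child_ages) > tol * max(1.0, max(child_ages)):
                raise DomainError(f"tree is not ultrametric at clade {sorted(_leafset(node))[:3]}...")
            node._age = max(child_ages)
        ages[_leafset(node)] = node._age
    return ages


def date_event(tree: dendropy.Tree, gain_clade: frozenset[str]) -> tuple[float, float]:
    """Age interval ``[younger, older]`` (MY) of the branch above a clade.

    The bounds are the ages of the clade's root node and its parent; a gain
    on the root branch gets a degenerate interval at the root age unless the
    root carries an edge length.
    """
    ages = node_ages(tree)
    if gain_clade not in ages:
        raise DomainError(f"clade {sorted(gain_clade)} not in tree")
    for node in tree.preorder_node_iter():
        if _leafset(node) == gain_clade:
            younger = ages[gain_clade]
            if node.parent_node is not None:
                older = ages[_leafset(node.parent_node)]
            else:
                older = younger + (node.edge.length or 0.0)
            return (younger, older)
    raise DomainError("clade not found")  # pragma: no cover


def format_interval(interval: tuple[float, float]) -> str:
    """Render ``(190, 231)`` as ``"231–190 MYA"`` (older bound first)."""
    younger, older = interval
    def fmt(x: float) -> str:
        return f"{x:g}"
    return f"{fmt(older)}–{fmt(younger)} MYA"
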