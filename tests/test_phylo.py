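"""Distance trees, Dollo placement, duplication detection and dating.

The Dollo oracle enumerates every assignment of presence/absence states to
internal nodes and keeps those with exactly one gain edge, minimising loss
edges — fully independent of the clade-based algorithm under test.
"""

import itertools

import dendropy
import numpy as np
import pytest

from introscape.errors import DomainError, InputError
from introscape.gene_models import read_tree
from introscape.phylo import (
    DistanceMatrix,
    date_event,
    distance_matrix,
    dollo_events,
    duplication_nodes,
    format_interval,
    nj_tree,
    node_ages,
    p_distance,
)
from introscape.synthetic_data import DEFAULT_SPECIES_TREE, EUTELEOSTS


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGA", 0.25),
        ("ACGT", "ACGT", 0.0),
        ("AC-T", "ACG-", 0.0),  # only columns 1-2 comparable
    ])
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_all_gap_columns_undefined(self):
        with pytest.raises(DomainError):
            p_distance("--A", "AA-")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_taxa):
    """Random binary topology with branch lengths; returns a dendropy tree."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = [dendropy.Node(taxon=ns.get_taxon(t)) for t in taxa]
    for node in nodes:
        node.edge.length = float(rng.uniform(0.5, 3.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.5, 3.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def tree_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = pdm.distance(tree.taxon_namespace.get_taxon(a),
                                       tree.taxon_namespace.get_taxon(b))
    return DistanceMatrix(tuple(labels), m)


def unrooted_splits(tree):
    """Non-trivial bipartitions as frozensets of leaf-label frozensets."""
    labels = frozenset(t.label for t in tree.taxon_namespace)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        for child in node.child_nodes():
            side = frozenset(l.taxon.label for l in child.leaf_iter())
            if 1 < len(side) < len(labels) - 1:
                splits.add(frozenset((side, labels - side)))
    return splits


def branch_length_map(tree):
    """Leaf edge lengths plus internal-split edge lengths of an unrooted tree."""
    labels = frozenset(t.label for t in tree.taxon_namespace)
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = frozenset((side, labels - side))
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return out


class TestNJ:
    def test_four_taxon_additive_exact(self):
        labels = ("A", "B", "C", "D")
        m = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, m))
        splits = unrooted_splits(tree)
        ab = frozenset((frozenset({"A", "B"}), frozenset({"C", "D"})))
        assert splits == {ab}
        lengths = branch_length_map(tree)
        got = {}
        for k, v in lengths.items():
            singles = [s for s in k if len(s) == 1]
            if singles:
                got[next(iter(singles[0]))] = v
        assert got == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [v for k, v in lengths.items() if not any(len(s) == 1 for s in k)]
        assert internal == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), m))
        lengths = {n.taxon.label: n.edge.length for n in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_fewer_than_three_rejected(self):
        with pytest.raises(DomainError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(5, 9))
            true = random_additive_tree(rng, n)
            dm = tree_distances(true)
            est = nj_tree(dm)
            assert unrooted_splits(est) == unrooted_splits(true)
            bl_true = branch_length_map(true)
            bl_est = branch_length_map(est)
            for key, v in bl_true.items():
                assert bl_est[key] == pytest.approx(v, abs=1e-9)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(3)
        true = random_additive_tree(rng, 6)
        dm = tree_distances(true)
        ours = unrooted_splits(nj_tree(dm))
        sk_tree = sk_nj(SkDM(dm.values, list(dm.labels)))
        labels = frozenset(dm.labels)
        theirs = set()
        for node in sk_tree.non_tips(include_self=True):
            for child in node.children:
                side = frozenset(t.name for t in child.tips()) | (
                    frozenset({child.name}) if child.is_tip() else frozenset())
                if 1 < len(side) < len(labels) - 1:
                    theirs.add(frozenset((side, labels - side)))
        assert ours == theirs

    def test_negative_lengths_clamped_with_warning(self):
        # violates the triangle inequality: B's closed-form length is -0.5
        m = np.array([[0, 1, 5], [1, 0, 3], [5, 3, 0]], dtype=float)
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(DistanceMatrix(("A", "B", "C"), m))
        assert all((n.edge.length or 0) >= 0 for n in tree.preorder_node_iter()
                   if n.parent_node is not None)


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

def dollo_oracle(tree, presence):
    """Exhaustive oracle: minimum losses over all single-gain node labelings.

    Enumerates every 0/1 assignment to internal nodes and unknown leaves; a
    scenario is valid if known leaf states match and exactly one edge (or
    the root branch) switches 0 -> 1.  Returns the minimum loss count.
    """
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    unknown = [l for l in leaves if presence.get(l.taxon.label) is None]
    best = None
    for states in itertools.product([0, 1], repeat=len(internal)):
        for leaf_states in itertools.product([0, 1], repeat=len(unknown)):
            state_of = dict(zip((id(n) for n in internal), states))
            for leaf in leaves:
                s = presence.get(leaf.taxon.label)
                if s is None:
                    s = leaf_states[unknown.index(leaf)]
                state_of[id(leaf)] = s
            gains = losses = 0
            for node in nodes:
                if node.parent_node is None:
                    gains += state_of[id(node)]  # gain on the root branch
                    continue
                ps, cs = state_of[id(node.parent_node)], state_of[id(node)]
                if (ps, cs) == (0, 1):
                    gains += 1
                elif (ps, cs) == (1, 0):
                    losses += 1
            if gains != 1:
                continue
            if best is None or losses < best:
                best = losses
    return best


FIXTURE_TREE = DEFAULT_SPECIES_TREE


class TestDollo:
    def test_euteleost_gain_no_losses(self):
        tree = read_tree(FIXTURE_TREE)
        presence = {l.taxon.label: 0 for l in tree.leaf_node_iter()}
        for sp in EUTELEOSTS:
            presence[sp] = 1
        result = dollo_events(tree, presence)
        assert result.gain_clade == frozenset(EUTELEOSTS)
        assert result.loss_clades == ()

    def test_single_present_leaf(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        result = dollo_events(tree, {"A": 1, "B": 0, "C": 0, "D": 0})
        assert result.gain_clade == frozenset({"A"})
        assert result.loss_clades == ()

    def test_all_present(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        result = dollo_events(tree, {l: 1 for l in "ABCD"})
        assert result.gain_clade == frozenset("ABCD")
        assert result.loss_clades == ()

    def test_all_absent_is_no_event(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        result = dollo_events(tree, {l: 0 for l in "ABCD"})
        assert result.gain_clade is None

    def test_loss_inside_gain_clade(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        result = dollo_events(tree, {"A": 1, "B": 0, "C": 1, "D": 1})
        assert result.gain_clade == frozenset("ABCD")
        assert result.loss_clades == (frozenset({"B"}),)

    def test_unknown_leaves_never_force_losses(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        result = dollo_events(tree, {"A": 1, "B": None, "C": 1, "D": 1})
        assert result.loss_clades == ()

    def test_matches_exhaustive_oracle_on_random_patterns(self):
        rng = np.random.default_rng(11)
        for rep in range(15):
            n = int(rng.integers(4, 9))
            tree = random_additive_tree(rng, n)
            labels = [t.label for t in tree.taxon_namespace]
            states = {l: int(rng.integers(0, 2)) for l in labels}
            if rng.random() < 0.5:
                states[labels[int(rng.integers(n))]] = None
            if not any(v == 1 for v in states.values()):
                states[labels[0]] = 1
            result = dollo_events(tree, states)
            assert result.n_losses == dollo_oracle(tree, states)


# ---------------------------------------------------------------------------
# Duplications and dating
# ---------------------------------------------------------------------------

class TestDuplications:
    def test_root_duplication_by_species_overlap(self):
        gt = read_tree("((g1@Dre:1,g1@Ola:1):1,(g2@Dre:1,g2@Ola:1):1);")
        dups = duplication_nodes(gt)
        assert dups == {frozenset({"g1@Dre", "g1@Ola", "g2@Dre", "g2@Ola"})}

    def test_single_copy_tree_has_none(self):
        gt = read_tree("((g@A:1,g@B:1):1,g@C:1);")
        assert duplication_nodes(gt) == set()

    def test_three_paralog_sets_two_duplications(self):
        gt = read_tree(
            "(((s1@X:1,s1@Y:1):1,(s2@X:1,s2@Y:1):1):1,(s3@X:1,s3@Y:1):1);")
        dups = duplication_nodes(gt)
        assert len(dups) == 2
        assert frozenset({"s1@X", "s1@Y", "s2@X", "s2@Y"}) in dups

    def test_untagged_leaf_rejected(self):
        gt = read_tree("((g1@Dre:1,plain:1):1,g2@Dre:1);")
        with pytest.raises(InputError):
            duplication_nodes(gt)


class TestDating:
    def test_fixture_intervals(self):
        tree = read_tree(FIXTURE_TREE)
        fishes = frozenset({"gar", "zebrafish", "cavefish"} | set(EUTELEOSTS))
        assert date_event(tree, fishes) == pytest.approx((360.0, 416.0))
        assert date_event(tree, frozenset(EUTELEOSTS)) == pytest.approx((190.0, 231.0))

    def test_rendering(self):
        assert format_interval((360.0, 416.0)) == "416–360 MYA"
        assert format_interval((190.0, 231.0)) == "231–190 MYA"

    def test_zero_length_branch_degenerate(self):
        tree = read_tree("((A:2,B:2):0,(C:1,D:1):1);")
        assert date_event(tree, frozenset({"A", "B"})) == pytest.approx((2.0, 2.0))

    def test_missing_lengths_rejected(self):
        tree = read_tree("((A,B),(C,D));")
        with pytest.raises(DomainError):
            node_ages(tree)

    def test_non_ultrametric_rejected(self):
        tree = read_tree("((A:1,B:5):1,(C:2,D:2):1);")
        with pytest.raises(DomainError):
            node_ages(tree)
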