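"""Gene-family evolution simulator with a ground-truth log.

Evolves a focal gene along a species tree: proteins accumulate per-site
Poisson substitutions (uniform replacement among the 19 alternatives, so the
expected identity has the closed form in :func:`calibrate_identity`); intron
architectures, paralog duplications, codon indels and flanking-gene
neighborhoods change only through scripted branch events.  Every applied
event is recorded in a truth log, and the emitted fixtures (protein/CDS
FASTA, per-leaf GFF3 + genomic FASTA, alignment with the ancestral reference
row, locus TSV, gene tree) are byte-reproducible from the seed.

The default configuration emulates a vertebrate-like history: a single-copy
gene duplicating twice on the ray-finned-fish stem (paralog sets I–III), a
4-exon/3-intron ancestral architecture whose introns project to reference
positions 192a/225a/300c, two intron gains on the euteleost stem that
project to 36b/102b, set-III codon indels (99→93 bp and 303→306 bp exons),
and locus rearrangements including focal-gene losses.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import DomainError, InputError
from .gene_models import GeneModel, MultipleAlignment, write_fasta, write_gff3
from .synteny import Locus, write_loci_tsv

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "calibrate_identity",
    "rate_for_identity",
    "default_config",
    "DEFAULT_SPECIES_TREE",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per residue so CDS translation always matches the protein
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
STOP = "TAA"

# 11-taxon fish + tetrapod species tree, ultrametric in MY.  Node ages place
# the ray-finned stem at 416-360 MY and the euteleost stem at 231-190 MY, the
# windows the scripted duplication and intron-gain events fall into.
DEFAULT_SPECIES_TREE = (
    "(tetrapods:416,(gar:360,((zebrafish:150,cavefish:150):81,"
    "(cod:190,(stickleback:170,(tilapia:160,(medaka:140,(fugu:120,"
    "(platyfish:100,molly:100):20):20):20):10):20):41):129):56);"
)

EUTELEOSTS = ("cod", "stickleback", "tilapia", "medaka", "fugu", "platyfish", "molly")
FISHES = ("gar", "zebrafish", "cavefish") + EUTELEOSTS


@dataclass
class SimulationConfig:
    """Everything the simulator needs; all randomness flows from ``seed``."""

    species_tree: str = DEFAULT_SPECIES_TREE
    substitution_rate: float = 8e-4  # substitutions / site / MY
    root_protein_length: int = 400
    root_architecture: tuple[tuple[int, int | None], ...] = ((574, None), (673, None), (900, None))
    root_upstream: tuple[str, ...] = ("GDPD5", "KLH35", "RPS3")
    root_downstream: tuple[str, ...] = ("MAP6", "MAGAT2", "DGAT2", "UNRAG", "TSKU", "ACER3", "MYO7A")
    root_paralog: str = "HSP47_1"
    scripted_events: tuple[dict, ...] = ()
    intron_length_range: tuple[int, int] = (78, 2096)  # log-uniform draw bounds
    seed: int = 0


def default_config(seed: int = 0) -> SimulationConfig:
    """The study scenario: sets I–III, euteleost intron gains, set-III indels."""
    events = (
        # two duplications on the ray-finned stem -> paralog sets I-III
        {"branch": FISHES, "type": "duplication", "paralog": "HSP47_1", "new_paralog": "HSP47_3"},
        {"branch": FISHES, "type": "duplication", "paralog": "HSP47_1", "new_paralog": "HSP47_2"},
        # set III: eII shrinks by two codons (99->93 bp), eIV grows by one (303->306 bp)
        {"branch": FISHES, "type": "codon_indel", "paralog": "HSP47_3", "exon": 2, "codons": -2},
        {"branch": FISHES, "type": "codon_indel", "paralog": "HSP47_3", "exon": 4, "codons": 1},
        # euteleost-stem intron gains in exon eI; offsets project to 36b and 102b
        {"branch": EUTELEOSTS, "type": "intron_gain", "paralog": "HSP47_1", "offset": 107},
        {"branch": EUTELEOSTS, "type": "intron_gain", "paralog": "HSP47_1", "offset": 305},
        # neighborhood churn: a side shuffle and focal-gene losses of paralog 2
        {"branch": EUTELEOSTS, "type": "locus_shuffle", "paralog": "HSP47_1", "symbol": "RPS3"},
        {"branch": ("medaka",), "type": "locus_loss", "paralog": "HSP47_2", "symbol": "HSP47_2"},
        {"branch": ("fugu",), "type": "locus_loss", "paralog": "HSP47_2", "symbol": "HSP47_2"},
    )
    return SimulationConfig(scripted_events=events, seed=seed)


def calibrate_identity(rate: float, depth: float) -> float:
    """Expected % identity between two lineages ``depth`` MY from their ancestor.

    Under per-site Poisson substitution with uniform replacement among the 19
    alternative residues, identity decays to the 1/20 floor:
    ``1/20 + (19/20) exp(-(20/19) * rate * 2 * depth)``.
    """
    if rate < 0 or depth < 0:
        raise DomainError("rate and depth must be non-negative")
    return 100.0 * (0.05 + 0.95 * math.exp(-(20.0 / 19.0) * rate * 2.0 * depth))


def rate_for_identity(target_pct: float, depth: float) -> float:
    """Substitution rate whose expected identity at ``depth`` is ``target_pct``."""
    if not 5.0 < target_pct <= 100.0:
        raise DomainError("target identity must be in (5, 100]")
    if depth <= 0:
        raise DomainError("depth must be positive")
    frac = (target_pct / 100.0 - 0.05) / 0.95
    return -math.log(frac) * 19.0 / (20.0 * 2.0 * depth)


# ---------------------------------------------------------------------------
# Internal lineage state
# ---------------------------------------------------------------------------

@dataclass
class _Lineage:
    paralog: str
    sites: list  # list of (key, residue); key = (root_index, insertion_serial)
    introns: list  # list of [coding_offset, genomic_length]
    upstream: list
    downstream: list
    focal_present: bool = True

    @property
    def protein(self) -> str:
        return "".join(res for _, res in self.sites)

    @property
    def cds_length(self) -> int:
        return 3 * len(self.sites) + 3  # + stop codon

    def exon_boundaries(self) -> list[int]:
        return [0] + [off for off, _ in self.introns] + [self.cds_length]


class _Simulator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = dendropy.Tree.get(data=config.species_tree, schema="newick",
                                      rooting="force-rooted", preserve_underscores=True)
        self.serial = 0  # global insertion-key counter
        self.events_by_clade: dict[frozenset, list[dict]] = {}
        leaves = {l.taxon.label for l in self.tree.leaf_node_iter()}
        for ev in config.scripted_events:
            branch = ev["branch"]
            clade = frozenset([branch] if isinstance(branch, str) else branch)
            if not clade <= leaves:
                raise InputError(f"event branch {sorted(clade)} not a subset of tree leaves")
            self.events_by_clade.setdefault(clade, []).append(dict(ev))
        self.truth_events: list[dict] = []
        self.dup_clades: list[frozenset] = []

    # -- lineage mutation ---------------------------------------------------

    def _draw_intron_length(self) -> int:
        lo, hi = self.cfg.intron_length_range
        return int(round(math.exp(self.rng.uniform(math.log(lo), math.log(hi)))))

    def _substitute(self, lin: _Lineage, branch_my: float) -> None:
        n_sub = self.rng.poisson(self.cfg.substitution_rate * branch_my * len(lin.sites))
        for _ in range(n_sub):
            i = int(self.rng.integers(len(lin.sites)))
            key, old = lin.sites[i]
            alternatives = [a for a in AA if a != old]
            lin.sites[i] = (key, alternatives[int(self.rng.integers(19))])

    def _intron_gain(self, lin: _Lineage, offset: int, length: int | None) -> int:
        if not 0 < offset < lin.cds_length:
            raise InputError(f"intron offset {offset} outside CDS")
        if any(off == offset for off, _ in lin.introns):
            raise InputError(f"intron already present at offset {offset}")
        if length is None:
            length = self._draw_intron_length()
        lin.introns.append([offset, length])
        lin.introns.sort()
        return length

    def _codon_indel(self, lin: _Lineage, exon: int, codons: int) -> None:
        b = lin.exon_boundaries()
        if not 1 <= exon <= len(b) - 1:
            raise InputError(f"exon {exon} out of range")
        lo, hi = b[exon - 1], b[exon]
        full = [j for j in range(1, len(lin.sites) + 1) if 3 * (j - 1) >= lo and 3 * j <= hi]
        if not full:
            raise InputError(f"exon {exon} holds no full codon")
        if codons < 0:
            n = -codons
            if n >= len(full):
                raise InputError(f"cannot delete {n} codons from exon {exon}")
            doomed = full[-n:]
            cut = 3 * (doomed[0] - 1)
            del lin.sites[doomed[0] - 1: doomed[-1]]
            for intr in lin.introns:
                if intr[0] > cut:
                    intr[0] -= 3 * n
        elif codons > 0:
            j = full[len(full) // 2]  # insert after the exon's middle full codon
            anchor = lin.sites[j - 1][0][0]
            for k in range(codons):
                self.serial += 1
                lin.sites.insert(j + k, ((anchor, self.serial), AA[int(self.rng.integers(20))]))
            cut = 3 * j
            for intr in lin.introns:
                if intr[0] >= cut:
                    intr[0] += 3 * codons

    def _apply_events(self, lineages: list[_Lineage], clade: frozenset) -> list[tuple[_Lineage, _Lineage]]:
        """Apply this branch's scripted events; returns (source, copy) duplication pairs."""
        dups = []
        for ev in self.events_by_clade.get(clade, []):
            target = next((l for l in lineages if l.paralog == ev.get("paralog")), None)
            if target is None:
                raise InputError(f"event targets unknown paralog {ev.get('paralog')!r}")
            record = {"branch": sorted(clade), "type": ev["type"], "paralog": target.paralog}
            if ev["type"] == "duplication":
                twin = copy.deepcopy(target)
                twin.paralog = ev["new_paralog"]
                suffix = ev["new_paralog"].rsplit("_", 1)[-1]
                twin.upstream = [f"{s}_{suffix}" for s in twin.upstream]
                twin.downstream = [f"{s}_{suffix}" for s in twin.downstream]
                lineages.append(twin)
                dups.append((target, twin))
                record["new_paralog"] = twin.paralog
            elif ev["type"] == "intron_gain":
                length = self._intron_gain(target, ev["offset"], ev.get("length"))
                record.update(offset=ev["offset"], length=length)
            elif ev["type"] == "codon_indel":
                self._codon_indel(target, ev["exon"], ev["codons"])
                record.update(exon=ev["exon"], codons=ev["codons"])
            elif ev["type"] == "locus_shuffle":
                sym = ev["symbol"].upper()
                if sym in target.upstream:
                    target.upstream.remove(sym)
                    target.downstream.append(sym)
                elif sym in target.downstream:
                    target.downstream.remove(sym)
                    target.upstream.append(sym)
                else:
                    raise InputError(f"shuffle symbol {sym} not in locus of {target.paralog}")
                record["symbol"] = sym
            elif ev["type"] == "locus_loss":
                sym = ev["symbol"].upper()
                if sym == target.paralog.upper():
                    target.focal_present = False
                elif sym in target.upstream:
                    target.upstream.remove(sym)
                elif sym in target.downstream:
                    target.downstream.remove(sym)
                else:
                    raise InputError(f"loss symbol {sym} not in locus of {target.paralog}")
                record["symbol"] = sym
            else:
                raise InputError(f"unknown event type {ev['type']!r}")
            self.truth_events.append(record)
        return dups

    # -- traversal ----------------------------------------------------------

    def run(self):
        root_protein = "".join(AA[int(self.rng.integers(20))]
                               for _ in range(self.cfg.root_protein_length))
        if self.cfg.root_protein_length >= 4:
            # ancestral serpin-like C-terminus: ER-retention tetrapeptide
            root_protein = root_protein[:-4] + "RDEL"
        introns = []
        for off, length in self.cfg.root_architecture:
            introns.append([off, length if length is not None else self._draw_intron_length()])
        introns.sort()
        root = _Lineage(
            paralog=self.cfg.root_paralog,
            sites=[((i, 0), r) for i, r in enumerate(root_protein)],
            introns=introns,
            upstream=list(self.cfg.root_upstream),
            downstream=list(self.cfg.root_downstream),
        )
        self.root_protein = root_protein
        self.leaf_genes: dict[str, list[_Lineage]] = {}
        gene_forest = self._descend(self.tree.seed_node, [root], at_root=True)
        return gene_forest

    def _descend(self, node, lineages, at_root=False):
        """Returns {paralog: (newick, leafset)} for the gene tree below ``node``."""
        if not at_root:
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            dups = self._apply_events(lineages, clade)
            branch_my = node.edge.length or 0.0
            for lin in lineages:
                if lin.focal_present:
                    self._substitute(lin, branch_my)
        else:
            dups = []

        if node.is_leaf():
            label = node.taxon.label
            self.leaf_genes[label] = [copy.deepcopy(l) for l in lineages]
            submaps = {
                l.paralog: (f"{l.paralog}@{label}", frozenset([f"{l.paralog}@{label}"]))
                for l in lineages if l.focal_present
            }
        else:
            child_maps = [self._descend(c, [copy.deepcopy(l) for l in lineages]) for c in node.child_nodes()]
            submaps = {}
            for lin in lineages:
                pieces = [m[lin.paralog] for m in child_maps if lin.paralog in m]
                if not pieces:
                    continue
                if len(pieces) == 1:
                    submaps[lin.paralog] = pieces[0]
                else:
                    newick = "(" + ",".join(p[0] for p in pieces) + ")"
                    leafset = frozenset().union(*(p[1] for p in pieces))
                    submaps[lin.paralog] = (newick, leafset)

        # join duplication pairs created on this branch (innermost first)
        for source, twin in reversed(dups):
            if twin.paralog in submaps and source.paralog in submaps:
                s_nwk, s_set = submaps[source.paralog]
                t_nwk, t_set = submaps.pop(twin.paralog)
                joined = frozenset(s_set | t_set)
                submaps[source.paralog] = (f"({s_nwk},{t_nwk})", joined)
                self.dup_clades.append(joined)
            elif twin.paralog in submaps:
                submaps[source.paralog] = submaps.pop(twin.paralog)
        return submaps


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """In-memory fixtures plus the ground-truth log."""

    models: list[GeneModel]
    genomes: dict[str, str]
    proteins: dict[str, str]
    cds: dict[str, str]
    alignment: MultipleAlignment
    loci: list[Locus]
    species_tree: str
    gene_tree: str
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": out / "genes.gff3",
            "genomes": out / "genomes.fna",
            "proteins": out / "proteins.faa",
            "cds": out / "cds.fna",
            "alignment": out / "alignment.afa",
            "loci": out / "loci.tsv",
            "species_tree": out / "species_tree.nwk",
            "gene_tree": out / "gene_tree.nwk",
            "truth": out / "truth.json",
        }
        write_gff3(self.models, paths["gff3"])
        write_fasta(self.genomes, paths["genomes"])
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.cds, paths["cds"])
        write_fasta(dict(zip(self.alignment.names, self.alignment.rows)), paths["alignment"])
        write_loci_tsv(self.loci, paths["loci"])
        paths["species_tree"].write_text(self.species_tree.strip() + "\n")
        paths["gene_tree"].write_text(self.gene_tree.strip() + "\n")
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


REFERENCE_NAME = "REF_ancestor"


def _encode_cds(protein: str) -> str:
    return "".join(CODON[r] for r in protein) + STOP


def _layout_gene(gene_name: str, species: str, lin: _Lineage, strand: str,
                 rng: np.random.Generator) -> tuple[GeneModel, str]:
    """Genomic sequence and model for one leaf gene (50 nt pads, GT..AG introns)."""
    cds = _encode_cds(lin.protein)
    b = lin.exon_boundaries()
    exon_seqs = [cds[b[i]: b[i + 1]] for i in range(len(b) - 1)]
    pad5 = "".join("ACGT"[int(rng.integers(4))] for _ in range(50))
    pad3 = "".join("ACGT"[int(rng.integers(4))] for _ in range(50))
    parts = [pad5]
    exons_plus = []
    pos = len(pad5)
    for i, exon_seq in enumerate(exon_seqs):
        parts.append(exon_seq)
        exons_plus.append((pos, pos + len(exon_seq)))
        pos += len(exon_seq)
        if i < len(lin.introns):
            length = lin.introns[i][1]
            middle = "".join("ACGT"[int(rng.integers(4))] for _ in range(max(0, length - 4)))
            intron_seq = ("GT" + middle + "AG")[:length] if length >= 4 else "G" * length
            parts.append(intron_seq)
            pos += length
    parts.append(pad3)
    genome = "".join(parts)

    if strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        genome = "".join(comp[c] for c in reversed(genome))
        total = len(genome)
        exons = [(total - e, total - s) for s, e in exons_plus]  # transcription order kept
    else:
        exons = exons_plus

    model = GeneModel(
        gene_id=gene_name,
        species=species,
        seq_id=f"chr_{gene_name}",
        strand=strand,
        cds_exons=tuple(exons),
        partial=not lin.focal_present,
    )
    return model, genome


def simulate(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulationResult:
    """Run the simulator; optionally write the fixture bundle to ``out_dir``."""
    sim = _Simulator(config)
    gene_forest = sim.run()

    # gene tree: join surviving root-paralog subtrees (normally just one root gene)
    subtrees = [nwk for nwk, _ in gene_forest.values()]
    gene_tree = (subtrees[0] if len(subtrees) == 1 else "(" + ",".join(subtrees) + ")") + ";"

    models, genomes, proteins, cds_seqs, loci = [], {}, {}, {}, []
    leaf_truth = {}
    leaf_order = sorted(sim.leaf_genes)
    for li, species in enumerate(leaf_order):
        for lin in sim.leaf_genes[species]:
            name = f"{lin.paralog}@{species}"
            strand = "+" if li % 2 == 0 else "-"
            if lin.focal_present:
                proteins[name] = lin.protein
                cds_seqs[name] = _encode_cds(lin.protein)
                model, genome = _layout_gene(name, species, lin, strand, sim.rng)
                models.append(model)
                genomes[model.seq_id] = genome
            loci.append(Locus(species, name, tuple(lin.upstream), tuple(lin.downstream),
                              {}, lin.focal_present))
            leaf_truth[name] = {
                "paralog": lin.paralog,
                "focal_present": lin.focal_present,
                "introns": [list(i) for i in lin.introns],
                "pattern": f"{len(lin.introns) + 1}e/{len(lin.introns)}i",
                "upstream": list(lin.upstream),
                "downstream": list(lin.downstream),
            }

    # true alignment from homologous site keys (REF row = ancestral protein)
    all_keys = {(i, 0) for i in range(len(sim.root_protein))}
    per_gene_sites = {}
    for species in leaf_order:
        for lin in sim.leaf_genes[species]:
            if not lin.focal_present:
                continue
            site_map = dict(lin.sites)
            per_gene_sites[f"{lin.paralog}@{species}"] = site_map
            all_keys |= set(site_map)
    columns = sorted(all_keys)
    names = [REFERENCE_NAME] + sorted(per_gene_sites)
    ref_map = {(i, 0): r for i, r in enumerate(sim.root_protein)}
    rows = []
    for name in names:
        site_map = ref_map if name == REFERENCE_NAME else per_gene_sites[name]
        rows.append("".join(site_map.get(k, "-") for k in columns))
    alignment = MultipleAlignment(tuple(names), tuple(rows), REFERENCE_NAME)

    # realized identities among paralog-set-I leaves (ungapped site overlap)
    idx = {n: i for i, n in enumerate(names)}
    set1 = [n for n in names if n.startswith(config.root_paralog + "@")]
    identities = {}
    for i, a in enumerate(set1):
        for b in set1[i + 1:]:
            ra, rb = rows[idx[a]], rows[idx[b]]
            comparable = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
            same = sum(1 for x, y in comparable if x == y)
            identities[f"{a}|{b}"] = round(100.0 * same / len(comparable), 2)

    truth = {
        "seed": config.seed,
        "substitution_rate": config.substitution_rate,
        "events": sim.truth_events,
        "duplication_clades": [sorted(c) for c in sim.dup_clades],
        "leaves": leaf_truth,
        "identities_set1": identities,
        "reference_name": REFERENCE_NAME,
    }

    result = SimulationResult(
        models=models, genomes=genomes, proteins=proteins, cds=cds_seqs,
        alignment=alignment, loci=loci, species_tree=config.species_tree,
        gene_tree=gene_tree, truth=truth,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
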