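"""End-to-end orchestration: map introns, compare architectures, infer and
date events, compare loci, annotate features — with a run manifest.

Each stage writes its TSV/JSON outputs under the run directory as it
completes, so a failing stage (reported by name) leaves earlier outputs in
place.  All file hashes, parameters and the seed are recorded in
``manifest.json``; the manifest hash covers inputs, parameters and outputs
but not timestamps, so re-running on identical inputs is detectably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, architecture, phylo, sequence_features, synteny
from .errors import IntroscapeError
from .gene_models import read_alignment, read_fasta, read_gff3, read_tree
from .intron_numbering import IntronLabel, label_introns

log = logging.getLogger("introscape")

__all__ = ["PipelineConfig", "RunManifest", "StageError", "run_pipeline"]


class StageError(IntroscapeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths and parameters for a full run."""

    gff3: Path
    genomes: Path
    alignment: Path
    reference_name: str
    species_tree: Path
    loci: Path
    out_dir: Path
    gene_tree: Path | None = None
    reference_labels: tuple[str, ...] = ("192a", "225a", "300c")
    p1_codon: int | None = None
    synteny_window: int = 7
    seed: int = 0


@dataclass
class RunManifest:
    command: str
    inputs: dict[str, str]  # path -> sha256
    parameters: dict
    seed: int
    version: str
    started: float = field(default_factory=time.time)
    finished: float | None = None
    outputs: dict[str, str] = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(
            {"inputs": self.inputs, "parameters": self.parameters,
             "outputs": self.outputs, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {"command": self.command, "inputs": self.inputs, "parameters": self.parameters,
             "seed": self.seed, "version": self.version, "started": self.started,
             "finished": self.finished, "outputs": self.outputs, "manifest_hash": self.hash()},
            indent=1, sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _paralog_of(gene_id: str) -> str:
    return gene_id.split("@", 1)[0]


def _species_of(gene_id: str) -> str:
    return gene_id.split("@", 1)[1] if "@" in gene_id else ""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute map-introns -> compare-arch -> infer-events -> synteny -> features.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        str(p): _sha256(p)
        for p in [config.gff3, config.genomes, config.alignment, config.species_tree, config.loci]
        + ([config.gene_tree] if config.gene_tree else [])
    }
    manifest = RunManifest(
        command="run",
        inputs=inputs,
        parameters={
            "reference_name": config.reference_name,
            "reference_labels": list(config.reference_labels),
            "p1_codon": config.p1_codon,
            "synteny_window": config.synteny_window,
        },
        seed=config.seed,
        version=__version__,
    )
    summary: dict = {"stages": {}}

    def record(name: str, path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    # -- stage 1: map-introns ----------------------------------------------
    stage = "map-introns"
    try:
        models = read_gff3(config.gff3)
        genomes = read_fasta(config.genomes)
        aln = read_alignment(config.alignment, config.reference_name)
        labels_by_gene: dict[str, list[IntronLabel]] = {}
        rows = []
        from .gene_models import introns_of
        for model in models:
            cds = model.cds_sequence(genomes[model.seq_id])
            labels = label_introns(model, aln, cds=cds)
            labels_by_gene[model.gene_id] = labels
            for rec, lab in zip(introns_of(model), labels):
                rows.append({"gene_id": model.gene_id, "intron_index": rec.index,
                             "coding_offset": rec.coding_offset, "ref_label": str(lab),
                             "mappable": lab.mappable, "intron_length": rec.length})
            log.info("map-introns gene=%s introns=%d", model.gene_id, len(labels))
        intron_tsv = out / "intron_labels.tsv"
        pd.DataFrame(rows, columns=["gene_id", "intron_index", "coding_offset",
                                    "ref_label", "mappable", "intron_length"]
                     ).to_csv(intron_tsv, sep="\t", index=False)
        record(stage, intron_tsv)
        summary["stages"][stage] = {"genes": len(models), "output": intron_tsv.name}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 2: compare-arch ---------------------------------------------
    stage = "compare-arch"
    try:
        profiles = [architecture.profile(m, labels_by_gene[m.gene_id]) for m in models]
        ref_labels = {IntronLabel.parse(t) for t in config.reference_labels}
        matrix_tsv = out / "gainloss_matrix.tsv"
        if profiles:
            matrix = architecture.compare(profiles, ref_labels)
            matrix.table.to_csv(matrix_tsv, sep="\t")
        else:
            matrix_tsv.write_text("")
        sizes_tsv = out / "size_table.tsv"
        architecture.size_table(profiles).to_csv(sizes_tsv, sep="\t")
        record(stage, matrix_tsv)
        record(stage, sizes_tsv)
        patterns = {p.gene_id: p.pattern for p in profiles}
        for gid, pat in patterns.items():
            log.info("compare-arch gene=%s pattern=%s", gid, pat)
        summary["stages"][stage] = {"patterns": patterns}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 3: infer-events ---------------------------------------------
    stage = "infer-events"
    try:
        sp_tree = read_tree(config.species_tree)
        try:
            ages = phylo.node_ages(sp_tree)
        except IntroscapeError:
            ages = None
        events = []
        # intron-gain characters per paralog
        by_paralog: dict[str, list] = {}
        for p in profiles:
            by_paralog.setdefault(_paralog_of(p.gene_id), []).append(p)
        for paralog, plist in sorted(by_paralog.items()):
            novel = set()
            for p in plist:
                novel |= {l for l in p.label_set if l not in ref_labels}
            for label in sorted(novel, key=lambda l: (l.ref_codon, l.phase_letter)):
                presence: dict[str, int | None] = {}
                for p in plist:
                    sp = _species_of(p.gene_id)
                    if label in p.label_set:
                        presence[sp] = 1
                    elif p.partial:
                        presence[sp] = None
                    else:
                        presence[sp] = 0
                result = phylo.dollo_events(sp_tree, presence, character=f"{paralog}:{label}")
                interval = (phylo.date_event(sp_tree, result.gain_clade)
                            if ages is not None and result.gain_clade else None)
                events.append({
                    "character": result.character,
                    "type": "intron_gain",
                    "gain_clade": sorted(result.gain_clade) if result.gain_clade else None,
                    "loss_clades": [sorted(c) for c in result.loss_clades],
                    "age_interval": list(interval) if interval else None,
                    "rendered": phylo.format_interval(interval) if interval else None,
                })
                log.info("infer-events character=%s losses=%d", result.character, result.n_losses)
        if config.gene_tree is not None:
            gtree = read_tree(config.gene_tree)
            for clade in sorted(phylo.duplication_nodes(gtree), key=lambda c: (len(c), sorted(c))):
                species_clade = frozenset(phylo.leaf_species(l) for l in clade)
                interval = None
                if ages is not None:
                    mrca = sp_tree.mrca(taxon_labels=sorted(species_clade))
                    node_clade = frozenset(l.taxon.label for l in mrca.leaf_iter())
                    interval = phylo.date_event(sp_tree, node_clade)
                events.append({
                    "character": "duplication:" + "|".join(sorted(clade)[:3]) + "...",
                    "type": "duplication",
                    "gain_clade": sorted(species_clade),
                    "loss_clades": [],
                    "age_interval": list(interval) if interval else None,
                    "rendered": phylo.format_interval(interval) if interval else None,
                })
        events_json = out / "events.json"
        events_json.write_text(json.dumps(events, indent=1))
        record(stage, events_json)
        summary["stages"][stage] = {"n_events": len(events)}
        summary["events"] = events
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 4: synteny ---------------------------------------------------
    stage = "synteny"
    try:
        loci = synteny.read_loci_tsv(config.loci)
        grouped: dict[str, list] = {}
        for locus in loci:
            grouped.setdefault(_paralog_of(locus.focal_gene), []).append(locus)
            log.info("synteny locus species=%s focal=%s", locus.species, locus.focal_gene)
        classified = synteny.classify_copy_loci(grouped, window=config.synteny_window)
        synteny_json = out / "loci_classification.json"
        synteny_json.write_text(json.dumps(classified, indent=1, sort_keys=True))
        record(stage, synteny_json)
        summary["stages"][stage] = {"paralog_sets": sorted(grouped)}
        summary["loci"] = classified
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage 5: features ---------------------------------------------------
    stage = "features"
    try:
        cons_tsv = out / "conservation.tsv"
        if len(aln.rows) >= 2:
            profile_cols = sequence_features.conservation_profile(aln)
            pd.DataFrame({
                "column": range(1, aln.n_columns + 1),
                "modal_residue": profile_cols.modal_residues,
                "modal_pct": [round(f, 2) for f in profile_cols.modal_fractions],
                "bin": profile_cols.bins,
            }).to_csv(cons_tsv, sep="\t", index=False)
            bin_totals = profile_cols.bin_totals
        else:
            cons_tsv.write_text("")
            bin_totals = {}
        record(stage, cons_tsv)
        features: dict[str, dict] = {}
        if config.p1_codon is not None:
            for name, ann in sequence_features.rcl_annotate(aln, config.p1_codon).items():
                features[name] = {
                    "rcl": ann.rcl, "hinge": ann.hinge,
                    "inhibitory_call": ann.inhibitory_call,
                    "er_retention": ann.er_retention,
                    "gaps_at_p5_p6": ann.gaps_at_p5_p6,
                }
        else:
            for name in aln.names:
                features[name] = {"er_retention": sequence_features.er_retention(aln.degapped(name))}
        feat_json = out / "features.json"
        feat_json.write_text(json.dumps(features, indent=1, sort_keys=True))
        record(stage, feat_json)
        summary["stages"][stage] = {"bin_totals": bin_totals}
        summary["features"] = features
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    summary["manifest_hash"] = manifest.hash()
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
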