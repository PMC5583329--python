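"""Architecture profiles, gain/loss matrices, and structural edits."""

import pytest

from introscape.architecture import (
    apply_codon_indel,
    compare,
    insert_intron,
    profile,
    size_table,
)
from introscape.errors import DomainError, InputError
from introscape.gene_models import read_gff3, read_fasta
from introscape.intron_numbering import IntronLabel, label_introns

from conftest import identity_alignment, make_model

REF_SET = {IntronLabel(192, "a"), IntronLabel(225, "a"), IntronLabel(300, "c")}


def _labelled_profile(exon_lengths, gene_id="gene1", partial=False):
    protein = "A" * (sum(exon_lengths) // 3)
    aln = identity_alignment({"REF": protein, gene_id: protein}, "REF")
    model = make_model(exon_lengths, [10] * (len(exon_lengths) - 1),
                       gene_id=gene_id, partial=partial)
    return profile(model, label_introns(model, aln))


class TestProfile:
    @pytest.mark.parametrize("exons,pattern", [
        ([574, 99, 227, 303], "4e/3i"),
        ([107, 198, 269, 99, 227, 303], "6e/5i"),
        ([1203], "1e/0i"),
    ])
    def test_pattern_string(self, exons, pattern):
        assert _labelled_profile(exons).pattern == pattern

    def test_sizes_in_transcription_order(self):
        p = _labelled_profile([574, 99, 227, 303])
        assert p.exon_sizes == (574, 99, 227, 303)
        assert p.intron_sizes == (10, 10, 10)


class TestCompare:
    def test_fish_set1_gains(self):
        p = _labelled_profile([107, 198, 269, 99, 227, 303])
        m = compare([p], REF_SET)
        assert m.gains["gene1"] == {IntronLabel(36, "b"), IntronLabel(102, "b")}
        assert m.losses["gene1"] == frozenset()

    def test_tetrapod_profile_neutral(self):
        p = _labelled_profile([574, 99, 227, 303])
        m = compare([p], REF_SET)
        assert m.gains["gene1"] == frozenset()
        assert m.losses["gene1"] == frozenset()

    def test_partial_gene_yields_unknown_not_loss(self):
        # missing the first ancestral intron, but flagged partial
        p = _labelled_profile([673, 227, 303], partial=True)
        m = compare([p], REF_SET)
        assert m.losses["gene1"] == frozenset()
        assert IntronLabel(192, "a") in m.unknown["gene1"]
        assert m.table.loc["gene1", "192a"] == "U"

    def test_complete_gene_missing_ancestral_is_loss(self):
        p = _labelled_profile([673, 227, 303])
        m = compare([p], REF_SET)
        assert m.losses["gene1"] == {IntronLabel(192, "a")}

    def test_duplicate_gene_ids_rejected(self):
        p = _labelled_profile([574, 99, 227, 303])
        with pytest.raises(InputError):
            compare([p, p], REF_SET)

    def test_permutation_invariant_and_idempotent(self):
        a = _labelled_profile([574, 99, 227, 303], gene_id="a")
        b = _labelled_profile([107, 198, 269, 99, 227, 303], gene_id="b")
        m1 = compare([a, b], REF_SET)
        m2 = compare([b, a], REF_SET)
        assert m1.gains == m2.gains and m1.losses == m2.losses
        assert sorted(m1.table.columns) == sorted(m2.table.columns)
        m3 = compare([a, b], REF_SET)
        assert m1.table.sort_index().equals(m3.table.sort_index())

    def test_recovers_simulated_gain_columns(self, sim, sim_dir):
        """Truth-log agreement: novel columns are exactly the scripted gains."""
        models = read_gff3(sim_dir / "genes.gff3")
        genomes = read_fasta(sim_dir / "genomes.fna")
        set1 = [m for m in models if m.gene_id.startswith("HSP47_1@")]
        profiles = []
        for m in set1:
            labels = label_introns(m, sim.alignment, cds=m.cds_sequence(genomes[m.seq_id]))
            profiles.append(profile(m, labels))
        matrix = compare(profiles, REF_SET)
        assert {str(l) for l in matrix.novel_labels} == {"36b", "102b"}
        gained_species = {g.split("@")[1] for g, s in matrix.gains.items() if s}
        truth_gain_species = set()
        for ev in sim.truth["events"]:
            if ev["type"] == "intron_gain":
                truth_gain_species |= set(ev["branch"])
        assert gained_species == truth_gain_species


class TestInsertIntron:
    def test_two_insertions_make_6e5i(self):
        model = make_model([574, 99, 227, 303], [120, 90, 80])
        edited = insert_intron(insert_intron(model, 107, 50), 305, 60)
        assert edited.n_exons == 6 and edited.n_introns == 5
        assert edited.exon_lengths == (107, 198, 269, 99, 227, 303)

    def test_cds_sequence_preserved(self):
        import numpy as np
        rng = np.random.default_rng(7)
        model = make_model([30, 21], [12], strand="+", start=10)
        hi = max(e for _, e in model.cds_exons)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, hi + 20))
        before = model.cds_sequence(genome)
        edited = insert_intron(model, 13, 9)
        # physically insert the 9 nt intron at the genomic split point
        cut = model.cds_exons[0][0] + 13
        edited_genome = genome[:cut] + "GTTTTTTAG" + genome[cut:]
        assert edited.exon_lengths == (13, 17, 21)
        assert edited.cds_sequence(edited_genome) == before

    def test_minus_strand_split_lengths(self):
        model = make_model([30, 21], [12], strand="-", start=10)
        edited = insert_intron(model, 13, 9)
        assert edited.exon_lengths == (13, 17, 21)
        assert [edited.intron_genomic_length(i) for i in range(2)] == [9, 12]

    def test_offset_at_junction_rejected(self):
        model = make_model([574, 99, 227, 303], [120, 90, 80])
        for bad in (0, 574, 673, 900, 1203):
            with pytest.raises(DomainError):
                insert_intron(model, bad, 50)

    def test_insertion_profile_is_reversible(self):
        model = make_model([574, 99, 227, 303], [120, 90, 80])
        edited = insert_intron(model, 107, 50)
        # conceptual removal: merging the two flanking exons restores lengths
        merged = (edited.exon_lengths[0] + edited.exon_lengths[1],) + edited.exon_lengths[2:]
        assert merged == model.exon_lengths


class TestCodonIndel:
    def test_one_codon_insertion_303_to_306(self):
        model = make_model([574, 99, 227, 303], [120, 90, 80])
        edited = apply_codon_indel(model, 3, +1)
        assert edited.exon_lengths == (574, 99, 227, 306)
        assert edited.cds_length % 3 == 0

    def test_two_codon_deletion_99_to_93(self):
        model = make_model([574, 99, 227, 303], [120, 90, 80])
        edited = apply_codon_indel(model, 1, -2)
        assert edited.exon_lengths == (574, 93, 227, 303)
        assert edited.cds_length % 3 == 0

    def test_zero_codons_is_identity(self):
        model = make_model([574, 99, 227, 303], [120, 90, 80])
        assert apply_codon_indel(model, 1, 0) is model

    def test_overlarge_deletion_rejected(self):
        model = make_model([574, 99, 227, 303], [120, 90, 80])
        with pytest.raises(DomainError):
            apply_codon_indel(model, 1, -33)

    def test_minus_strand_intron_lengths_unchanged(self):
        from introscape.gene_models import introns_of
        model = make_model([574, 99, 227, 303], [120, 90, 80], strand="-")
        edited = apply_codon_indel(model, 1, -2)
        assert [r.length for r in introns_of(edited)] == [120, 90, 80]


class TestSizeTable:
    def test_ranges(self):
        a = _labelled_profile([574, 99, 227, 303], gene_id="a")
        b = _labelled_profile([600, 99, 227, 303], gene_id="b")
        table = size_table([a, b])
        assert table.loc["min", "exon_2"] == 99
        assert table.loc["max", "exon_2"] == 99
        assert table.loc["min", "exon_1"] == 574
        assert table.loc["max", "exon_1"] == 600

    def test_empty_input(self):
        assert size_table([]).empty

    def test_missing_positions_blank(self):
        a = _labelled_profile([574, 99, 227, 303], gene_id="a")
        b = _labelled_profile([1203], gene_id="b")
        table = size_table([a, b])
        import pandas as pd
        assert pd.isna(table.loc["b", "exon_2"])
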