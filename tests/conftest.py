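import pytest

from introscape.gene_models import GeneModel, MultipleAlignment
from introscape.synthetic_data import default_config, simulate


@pytest.fixture(scope="session")
def sim():
    """One simulated history under the default study scenario (seed 1)."""
    return simulate(default_config(seed=1))


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    simulate(default_config(seed=1), out)
    return out


def make_model(exon_lengths, intron_lengths, gene_id="g", strand="+", start=100, **kw):
    """Build a GeneModel from coding exon lengths and intron lengths."""
    assert len(intron_lengths) == len(exon_lengths) - 1
    exons = []
    pos = start
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    if strand == "-":
        total = pos + start
        exons = [(total - e, total - s) for s, e in exons]
    return GeneModel(gene_id=gene_id, species=kw.pop("species", "sp"), seq_id=kw.pop("seq_id", "chr1"),
                     strand=strand, cds_exons=tuple(exons), **kw)


def identity_alignment(seqs: dict[str, str], reference_name: str) -> MultipleAlignment:
    return MultipleAlignment(tuple(seqs), tuple(seqs.values()), reference_name)


@pytest.fixture
def collinear_gene_aln():
    """A 400-codon gene identical to the reference: projection is the identity."""
    protein = ("ACDEFGHIKLMNPQRSTVWY" * 20)
    seqs = {"REF": protein, "gene1": protein}
    return identity_alignment(seqs, "REF")
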