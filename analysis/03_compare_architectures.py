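#!/usr/bin/env python
"""Compare labelled architectures against the ancestral 192a/225a/300c set.

Writes the presence/absence matrix and the exon/intron size table under
results/, and prints each paralog set's architecture pattern — the expected
picture is 4e/3i everywhere except euteleost set-I genes at 6e/5i.
"""

from pathlib import Path

from introscape.architecture import compare, profile, size_table
from introscape.gene_models import read_alignment, read_fasta, read_gff3
from introscape.intron_numbering import IntronLabel, label_introns

ROOT = Path(__file__).resolve().parent.parent
FIXTURES = ROOT / "results" / "fixtures"
ANCESTRAL = {IntronLabel.parse(t) for t in ("192a", "225a", "300c")}


def main() -> None:
    models = read_gff3(FIXTURES / "genes.gff3")
    genomes = read_fasta(FIXTURES / "genomes.fna")
    aln = read_alignment(FIXTURES / "alignment.afa", "REF_ancestor")
    profiles = []
    for m in models:
        labels = label_introns(m, aln, cds=m.cds_sequence(genomes[m.seq_id]))
        profiles.append(profile(m, labels))
    matrix = compare(profiles, ANCESTRAL)
    matrix.table.to_csv(ROOT / "results" / "gainloss_matrix.tsv", sep="\t")
    size_table(profiles).to_csv(ROOT / "results" / "size_table.tsv", sep="\t")

    by_pattern: dict[str, list[str]] = {}
    for p in profiles:
        by_pattern.setdefault(p.pattern, []).append(p.gene_id)
    for pattern in sorted(by_pattern):
        print(f"{pattern}: {len(by_pattern[pattern])} genes")
    gained = sorted(g for g, s in matrix.gains.items() if s)
    print(f"novel labels {sorted(str(l) for l in matrix.novel_labels)} "
          f"confined to {len(gained)} genes:")
    for g in gained:
        print(f"  {g}")
    print(f"matrix -> {ROOT / 'results' / 'gainloss_matrix.tsv'}")


if __name__ == "__main__":
    main()
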