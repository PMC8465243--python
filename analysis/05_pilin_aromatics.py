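#!/usr/bin/env python
"""Pilin maturation and aromatic-residue content.

Scores the packaged Geobacter sulfurreducens PCA PilA reference (the
canonical conductive pilin: 9.83-9.84% aromatics on the 61-residue
mature peptide) and the PilA homolog planted in the synthetic genome.
Aromatic content of the mature pilin is the standard sequence proxy for
pilus conductivity.  Writes results/pilin_aromatics.tsv.
"""

from pathlib import Path

from eetcensus import packaged_data, seqio
from eetcensus.pilin import pilin_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    entries = list(seqio.read_fasta(packaged_data("pca_pila.faa")))
    census_pilin = RESULTS / "census" / "pilin.tsv"
    rows = ["locus_tag\tbasis\tmature_start\taromatic_percent"]
    for tag, seq in entries:
        rep = pilin_report(tag, seq)
        rows.append(f"{rep.locus_tag}\t{rep.basis}\t{rep.mature_start}\t"
                    f"{rep.aromatic_percent:.2f}")
        print(f"{tag}: cleaved at {rep.mature_start}, "
              f"mature {len(seq) - rep.mature_start} aa, "
              f"aromatics {rep.aromatic_percent:.2f}% ({rep.basis})")
    (RESULTS / "pilin_aromatics.tsv").write_text("\n".join(rows) + "\n")
    if census_pilin.exists():
        print(census_pilin.read_text().rstrip())
    else:
        print("(run scripts 01+03 to score the planted genome pilin too)")


if __name__ == "__main__":
    main()
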