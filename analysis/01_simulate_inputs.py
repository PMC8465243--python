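#!/usr/bin/env python
"""Build the synthetic study inputs for the census analysis.

Generates, with fixed seeds, a genome that mirrors the study organism's
headline parameters — 63.1% G+C, four rRNA (rrn) operons, a maximal
c-type cytochrome carrying 53 heme-binding motifs — plus reference
cytochrome/proteome sets, a conserved-domain hit table, a subcellular
localization table, and a type-IV-pilus exemplar set anchored on the
packaged Geobacter sulfurreducens PCA PilA sequence.  Everything is
written under results/inputs/ together with truth.json so downstream
scripts can check what they recover.
"""

import json
from pathlib import Path

import numpy as np

from eetcensus import packaged_data, seqio, synth

RESULTS = Path(__file__).resolve().parent.parent / "results"
INPUTS = RESULTS / "inputs"
SEED = 1953


def mutate_outside(seq, protected, fraction, seed, alphabet):
    rng = np.random.default_rng(seed)
    free = [i for i in range(len(seq)) if i not in protected]
    rng.shuffle(free)
    chars = list(seq)
    for p in free[: int(fraction * len(seq))]:
        options = [c for c in alphabet if c != chars[p]]
        chars[p] = options[rng.integers(0, len(options))]
    return "".join(chars)


def main():
    INPUTS.mkdir(parents=True, exist_ok=True)

    refs, ref_truths = [], []
    for i in range(3):
        s, t = synth.gen_protein_with_motifs(6, 240, SEED + i)
        refs.append((f"REFC_{i}", s))
        ref_truths.append(t)

    planted = []
    for i in range(6):
        base = refs[i % 3][1]
        protected = {p for s0, n in ref_truths[i % 3]
                     for p in range(s0, s0 + n + 3)}
        planted.append((f"CYT_{i}", mutate_outside(
            base, protected, 0.30, SEED + 100 + i, synth.MOTIF_FREE_POOL)))

    rng = np.random.default_rng(SEED + 200)
    decoys = [(f"DEC_{i}",
               "".join(rng.choice(list(synth.MOTIF_FREE_POOL), 200)))
              for i in range(6)]

    big, _ = synth.gen_protein_with_motifs(53, 600, SEED + 300)

    [(_, pca_pila)] = seqio.read_fasta(packaged_data("pca_pila.faa"))
    pila_homolog = mutate_outside(pca_pila, set(range(0, 12)), 0.20,
                                  SEED + 400, synth.AMINO_ACIDS)

    proteins = planted + decoys + [("BIGC", big), ("PILA_1", pila_homolog)]
    record, truth = synth.gen_genome(63.1, 4, len(proteins), SEED + 500,
                                     proteins=proteins)
    seqio.write_genome_record(record, INPUTS / "genome.gbk")
    seqio.write_fasta(refs, INPUTS / "reference_cytochromes.faa")
    seqio.write_fasta(refs, INPUTS / "reference_proteome.faa")

    pilt = "M" + "KLVADEGIRTS" * 12
    t4p = [("PilA|PCA_PilA", pca_pila), ("PilT|PilT_ref", pilt)]
    seqio.write_fasta(t4p, INPUTS / "t4p_reference.faa")

    (INPUTS / "domain_hits.tsv").write_text(
        "locus_tag\taccession\tevalue\nBIGC\tPF00034\t1e-06\n")
    (INPUTS / "localization.tsv").write_text(
        "locus_tag\tcompartment\n" + "".join(
            f"{tag}\t{where}\n" for tag, where in
            [("CYT_0", "PP"), ("CYT_1", "PP"), ("CYT_2", "EX"),
             ("CYT_3", "CM"), ("CYT_4", "PP"), ("BIGC", "EX")]))

    truth_out = {"seed": SEED, "gc_percent": 63.1, "n_rrn_operons": 4,
                 "planted_cytochromes": [t for t, _ in planted] + ["BIGC"],
                 "max_hemes": 53, "decoys": [t for t, _ in decoys],
                 "pilin_locus": "PILA_1"}
    (INPUTS / "truth.json").write_text(json.dumps(truth_out, indent=2) + "\n")

    print(f"genome: {len(record.sequence):,} bp, "
          f"{len(proteins)} CDS, 4 rrn operons -> {INPUTS}/genome.gbk")
    print(f"planted: {len(planted)} cytochromes (+1 with 53 hemes), "
          f"{len(decoys)} decoys, 1 PilA homolog")


if __name__ == "__main__":
    main()
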