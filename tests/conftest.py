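import numpy as np
import pytest

from eetcensus import seqio, synth

# minimal handwritten GenBank record: 1 CDS (3..11) + 1 16S rRNA (21..50)
MINI_GENBANK = """\
LOCUS       TESTREC                   60 bp    DNA     circular BCT 01-JAN-2000
DEFINITION  synthetic two-feature test record.
ACCESSION   TESTREC
VERSION     TESTREC.1
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     source          1..60
     CDS             3..11
                     /locus_tag="CDS_0001"
                     /product="test protein"
     rRNA            complement(21..50)
                     /locus_tag="RRNA_0001"
                     /product="16S ribosomal RNA"
ORIGIN
        1 aaatggctta acccgggttt aaacccgggt ttaaacccgg gtttaaaccc gggtttaaac
//
"""


@pytest.fixture
def mini_genbank(tmp_path):
    path = tmp_path / "mini.gbk"
    path.write_text(MINI_GENBANK)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20210914)


@pytest.fixture(scope="session")
def census_fixture(tmp_path_factory):
    """Synthetic census inputs with full ground truth.

    Three reference cytochromes; six planted cytochromes derived from
    them by 30% point mutation outside the motifs (plus one 53-motif
    maximal protein also derived from a reference); six motif-free
    decoys; a genome at 63.1% G+C with four rRNA operons.
    """
    from oracles import mutate_preserving_motifs

    root = tmp_path_factory.mktemp("census")
    refs = []
    for i in range(3):
        s, _ = synth.gen_protein_with_motifs(6, 240, 100 + i)
        refs.append((f"REFC_{i}", s))
    planted = []
    for i in range(6):
        base, truth = synth.gen_protein_with_motifs(6, 240, 100 + i % 3)
        planted.append((f"CYT_{i}",
                        mutate_preserving_motifs(base, truth, 0.30, 300 + i)))
    decoys = []
    for i in range(6):
        r = np.random.default_rng(400 + i)
        decoys.append((f"DEC_{i}",
                       "".join(r.choice(list(synth.MOTIF_FREE_POOL), 200))))
    # maximal multiheme protein: 53 planted motifs, called via the
    # domain-evidence branch (domain_hits table below)
    big, _ = synth.gen_protein_with_motifs(53, 600, 55)
    proteins = planted + decoys + [("BIGC", big)]
    record, truth = synth.gen_genome(63.1, 4, len(proteins), 12,
                                     proteins=proteins)
    genome = root / "genome.gbk"
    seqio.write_genome_record(record, genome)
    ref_faa = root / "ref_cytochromes.faa"
    seqio.write_fasta(refs, ref_faa)
    refprot = root / "ref_proteome.faa"
    seqio.write_fasta(refs, refprot)
    domains = root / "domain_hits.tsv"
    domains.write_text("locus_tag\taccession\tevalue\nBIGC\tPF00034\t1e-06\n")
    localization = root / "localization.tsv"
    loc_rows = ["locus_tag\tcompartment", "CYT_0\tPP", "CYT_1\tPP",
                "CYT_2\tEX", "CYT_3\tCM", "BIGC\tEX"]
    localization.write_text("\n".join(loc_rows) + "\n")
    return {"root": root, "genome": genome, "record": record,
            "truth": truth, "refs": refs, "ref_faa": ref_faa,
            "refprot": refprot, "domains": domains,
            "localization": localization, "planted": planted,
            "decoys": decoys, "big": ("BIGC", big)}
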