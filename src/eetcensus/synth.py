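"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the census has a generator here that emulates
its input with planted, exactly known truth: proteins with a planted
number of heme-binding motifs on a motif-free background, homolog pairs
tuned to a target alignment identity, annotated genome records with set
G+C composition and rRNA operon count, and multiple sequence alignments
evolved on a known tree under Jukes-Cantor.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; rerunning with the same arguments is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import homology
from .seqio import Feature, GenomeRecord, reverse_complement

# 18 residues: every amino acid except C and H, so no accidental
# C(X)nCH motif can form in background sequence.
MOTIF_FREE_POOL = "ADEFGIKLMNPQRSTVWY"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# NCBI translation table 11 codons per amino acid (representative set).
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOP = "TAA"


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic dataset."""

    seed: int
    kind: str  # protein_motifs | homolog_family | genome | msa_on_tree
    parameters: dict = field(default_factory=dict)


def gen_protein_with_motifs(k: int, length: int, seed: int
                            ) -> tuple[str, list[tuple[int, int]]]:
    """Protein with exactly ``k`` planted C(X)nCH motifs.

    Background residues are drawn from a C/H-free pool, so the planted
    motifs are the only heme-binding sites.  Returns the sequence and the
    truth list of (start, n) planted sites.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if length < 6 * k:
        raise ValueError(f"length {length} too small for {k} motifs")
    rng = np.random.default_rng(seed)
    ns = rng.integers(2, 5, size=k)
    if int(np.sum(ns + 3)) > length:
        ns = np.full(k, 2)  # shortest motifs still fit under length >= 6k
    motif_total = int(np.sum(ns + 3)) if k else 0
    n_bg = length - motif_total
    # split background into k+1 gaps
    cuts = np.sort(rng.integers(0, n_bg + 1, size=k)) if k else np.array([], int)
    gaps = np.diff(np.concatenate([[0], cuts, [n_bg]]))
    pool = np.array(list(MOTIF_FREE_POOL))
    parts: list[str] = []
    truth: list[tuple[int, int]] = []
    pos = 0
    for idx in range(k + 1):
        g = int(gaps[idx])
        parts.append("".join(rng.choice(pool, size=g)))
        pos += g
        if idx < k:
            n = int(ns[idx])
            spacer = "".join(rng.choice(pool, size=n))
            parts.append(f"C{spacer}CH")
            truth.append((pos, n))
            pos += n + 3
    return "".join(parts), truth


def gen_homolog_pair(length: int, target_identity: float, seed: int,
                     indel_fraction: float = 0.02,
                     tolerance: float = 2.0, max_rounds: int = 40
                     ) -> tuple[str, str, float]:
    """Protein pair whose local-alignment identity hits a target.

    ``b`` is derived from ``a`` by point substitutions (plus a small
    fixed fraction of single-residue indels, <= 5%) calibrated against
    ``homology.align_local`` until realized identity is within
    ``tolerance`` points of ``target_identity``.
    """
    if not (0 < target_identity <= 100):
        raise ValueError("target_identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    a = "".join(rng.choice(aa, size=length))
    if target_identity == 100:
        return a, a, 100.0

    n_indels = int(round(indel_fraction * length)) if target_identity < 98 else 0

    def build(n_subs: int) -> str:
        r = np.random.default_rng(seed + 1)  # fixed per pair: monotone in n_subs
        chars = list(a)
        pos = r.permutation(length)[:n_subs]
        for p in pos:
            choices = [c for c in AMINO_ACIDS if c != chars[p]]
            chars[p] = choices[r.integers(0, len(choices))]
        for _ in range(n_indels):
            q = int(r.integers(0, len(chars)))
            if r.integers(0, 2):
                chars.insert(q, str(r.choice(aa)))
            else:
                del chars[q]
        return "".join(chars)

    def measure(b: str) -> float:
        return homology.align_local(a, b).identity_percent

    lo, hi = 0, length  # substitutions: identity decreases with n_subs
    n = int(round(length * (1 - target_identity / 100)))
    best: Optional[tuple[float, str, float]] = None
    for _ in range(max_rounds):
        b = build(n)
        ident = measure(b)
        err = abs(ident - target_identity)
        if best is None or err < best[0]:
            best = (err, b, ident)
        if err <= tolerance:
            break
        if ident > target_identity:
            lo = n + 1
        else:
            hi = n - 1
        if lo > hi:
            break
        n = (lo + hi) // 2
    err, b, ident = best
    if err > tolerance:
        raise ValueError(
            f"could not reach identity {target_identity} +/- {tolerance} "
            f"(best realized {ident:.1f})")
    return a, b, ident


def reverse_translate(protein: str, gc_target: float, rng: np.random.Generator
                      ) -> str:
    """Encode a protein with codons greedily balanced toward a GC target."""
    f = gc_target / 100.0
    gc_so_far = 0
    total = 0
    codons = []
    for aa in protein:
        opts = _CODONS[aa]
        deficits = []
        for c in opts:
            gcn = c.count("G") + c.count("C")
            deficits.append(abs((gc_so_far + gcn) / (total + 3) - f))
        jmin = min(range(len(opts)), key=lambda i: (deficits[i], opts[i]))
        # random tie-break among near-optimal codons
        near = [i for i in range(len(opts)) if deficits[i] - deficits[jmin] < 1e-9]
        j = int(near[rng.integers(0, len(near))])
        codons.append(opts[j])
        gc_so_far += opts[j].count("G") + opts[j].count("C")
        total += 3
    return "".join(codons) + _STOP


def gen_genome(gc_percent: float, n_rrn_operons: int, n_cds: int, seed: int,
               length: Optional[int] = None,
               proteins: Optional[Sequence[tuple[str, str]]] = None,
               cds_len: int = 120, topology: str = "circular"
               ) -> tuple[GenomeRecord, dict]:
    """Annotated genome with set composition and planted features.

    rRNA operons are planted as 16S+23S+5S feature triples; CDS features
    carry valid translations (optionally of caller-supplied ``proteins``,
    e.g. motif-planted cytochromes).  Overall G+C hits ``gc_percent``
    within +/-0.1 by exact composition accounting.  Returns the record
    and a truth dict.
    """
    if not (0 < gc_percent < 100):
        raise ValueError("gc_percent must be in (0, 100)")
    if n_rrn_operons < 0 or n_cds < 0:
        raise ValueError("feature counts must be >= 0")
    rng = np.random.default_rng(seed)
    if proteins is None:
        aa = np.array(list(MOTIF_FREE_POOL))
        proteins = [(f"SYN_{i + 1:05d}", "".join(rng.choice(aa, size=cds_len)))
                    for i in range(n_cds)]
    else:
        proteins = list(proteins)
        if len(proteins) != n_cds:
            raise ValueError("len(proteins) must equal n_cds")
    cds_nts = [reverse_translate(p, gc_percent, rng) for _, p in proteins]
    rrn_lens = [1500, 2800, 120]  # 16S, 23S, 5S
    feature_nt = sum(len(x) for x in cds_nts) + n_rrn_operons * sum(rrn_lens)
    n_slots = n_cds + 3 * n_rrn_operons + 1
    if length is None:
        length = int(feature_nt * 1.25) + 200
    gap_total = length - feature_nt
    if gap_total < n_slots - 1:
        raise ValueError(
            f"requested features need {feature_nt} bp but length is {length}")

    # exact background composition so overall GC lands on target
    target_gc_bases = int(round(gc_percent / 100.0 * length))
    cds_gc = sum(s.count("G") + s.count("C") for s in cds_nts)
    bg_total = length - sum(len(x) for x in cds_nts)
    bg_gc = min(max(target_gc_bases - cds_gc, 0), bg_total)
    g = bg_gc // 2
    c = bg_gc - g
    at = bg_total - bg_gc
    a = at // 2
    t = at - a
    bg = np.array(list("G" * g + "C" * c + "A" * a + "T" * t))
    rng.shuffle(bg)
    bg = "".join(bg)

    # lay out: [gap][feature][gap]...[gap]
    cuts = np.sort(rng.integers(0, gap_total + 1, size=n_slots - 1))
    gaps = np.diff(np.concatenate([[0], cuts, [gap_total]]))
    blocks: list[tuple[str, Optional[dict]]] = []
    fi = 0
    for ci, nt in enumerate(cds_nts):
        strand = "+" if rng.integers(0, 2) else "-"
        blocks.append((nt if strand == "+" else reverse_complement(nt),
                       {"ftype": "CDS", "tag": proteins[ci][0],
                        "strand": strand, "translation": proteins[ci][1],
                        "product": "hypothetical protein"}))
    for op in range(n_rrn_operons):
        for cls, ln in zip(("16S", "23S", "5S"), rrn_lens):
            blocks.append((None, {"ftype": "rRNA", "ln": ln,
                                  "tag": f"SYNR_{op + 1:02d}_{cls}",
                                  "strand": "+", "rrna_class": cls,
                                  "product": f"{cls} ribosomal RNA"}))
    order = rng.permutation(len(blocks))
    seq_parts: list[str] = []
    features: list[Feature] = []
    bg_pos = 0
    pos = 0
    truth_features = []
    for slot, bi in enumerate(order):
        gp = int(gaps[slot])
        seq_parts.append(bg[bg_pos:bg_pos + gp])
        bg_pos += gp
        pos += gp
        nt, meta = blocks[bi]
        if nt is None:  # rRNA body comes from background material
            ln = meta["ln"]
            nt = bg[bg_pos:bg_pos + ln]
            bg_pos += ln
        seq_parts.append(nt)
        feat = Feature(meta["tag"], meta["ftype"], pos, pos + len(nt),
                       meta["strand"], meta.get("product", ""),
                       meta.get("translation", ""),
                       meta.get("rrna_class"))
        features.append(feat)
        truth_features.append((meta["tag"], meta["ftype"], pos, pos + len(nt)))
        pos += len(nt)
    seq_parts.append(bg[bg_pos:])
    sequence = "".join(seq_parts)
    assert len(sequence) == length
    record = GenomeRecord(f"synth_genome_seed{seed}", sequence, topology,
                          sorted(features, key=lambda f: f.start))
    truth = {"gc_percent": gc_percent, "n_rrn_operons": n_rrn_operons,
             "n_cds": n_cds, "proteins": list(proteins),
             "features": sorted(truth_features, key=lambda x: x[2])}
    return record, truth


def gen_msa_on_tree(tree, n_sites: int, site_rate: float, seed: int
                    ) -> list[tuple[str, str]]:
    """Alignment evolved on a tree under Jukes-Cantor.

    ``tree`` is a newick string (or a phylo Tree); branch lengths are in
    expected substitutions per site before scaling by ``site_rate``.
    Columns evolve independently; the root sequence is i.i.d. uniform.
    """
    import io

    from Bio import Phylo

    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if hasattr(tree, "newick"):
        tree = tree.newick()
    phylo_tree = Phylo.read(io.StringIO(tree), "newick")
    rng = np.random.default_rng(seed)
    nt = np.array(list(NUCLEOTIDES))
    root_seq = rng.integers(0, 4, size=n_sites)
    out: list[tuple[str, str]] = []

    def evolve(parent_states: np.ndarray, clade) -> None:
        t = float(clade.branch_length or 0.0) * site_rate
        if t < 0:
            raise ValueError("negative branch length")
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        states = parent_states.copy()
        hit = rng.random(n_sites) < p_change
        if hit.any():
            # jump to one of the three other states
            shift = rng.integers(1, 4, size=int(hit.sum()))
            states[hit] = (states[hit] + shift) % 4
        if clade.clades:
            for child in clade.clades:
                evolve(states, child)
        else:
            out.append((clade.name, "".join(nt[states])))

    root = phylo_tree.root
    for child in root.clades:
        evolve(root_seq, child)
    if not root.clades:
        out.append((root.name, "".join(nt[root_seq])))
    return out


def generate(spec: SyntheticSpec):
    """Dispatch a SyntheticSpec to its generator."""
    p = dict(spec.parameters)
    if spec.kind == "protein_motifs":
        return gen_protein_with_motifs(p["k"], p["length"], spec.seed)
    if spec.kind == "homolog_family":
        return gen_homolog_pair(p["length"], p["target_identity"], spec.seed)
    if spec.kind == "genome":
        return gen_genome(p["gc"], p["n_rrn"], p["n_cds"], spec.seed,
                          length=p.get("length"))
    if spec.kind == "msa_on_tree":
        return gen_msa_on_tree(p["tree"], p["n_sites"], p["site_rate"],
                               spec.seed)
    raise ValueError(f"unknown synthetic kind {spec.kind!r}")
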