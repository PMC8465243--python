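"""Pairwise protein alignment, E-values, reciprocal best hits and
closest-homolog tables.

Alignment is exact local Smith-Waterman with affine gaps (BLOSUM62,
gap open 11, gap extend 1 in BLAST conventions) rather than a heuristic
seeded search: deterministic and exact at desk scale.  Identity is
computed over alignment columns including gap columns; coverage is the
aligned span of the named sequence over its full length.  Both
definitions are recorded in output metadata because conventions differ
between tools.

E-values follow Karlin-Altschul statistics, E = K*m*n*exp(-lambda*S),
with gapped-BLOSUM62 constants (K=0.041, lambda=0.267) as configurable
defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

IDENTITY_DEFINITION = "identical columns / alignment columns (gaps in denominator)"
COVERAGE_DEFINITION = "aligned span on the named sequence / its length"

KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267


@dataclass
class AlignmentResult:
    query: str
    subject: str
    score: float
    identity_percent: float
    query_coverage_percent: float
    subject_coverage_percent: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: Optional[float] = None


@dataclass
class BBHPair:
    locus_a: str
    locus_b: str
    identity_percent: float
    coverage_a: float
    coverage_b: float


@dataclass
class HomologyAssignment:
    locus_tag: str
    closest_reference: Optional[tuple[str, str]]  # (proteome_id, locus_tag)
    best_identity_percent: float
    unique: bool


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length k costs open + k*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    s = seq.rstrip("*").upper()
    return "".join(c if c in alphabet else "X" for c in s)


def align_local(a: str, b: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1,
                query_name: str = "query", subject_name: str = "subject"
                ) -> AlignmentResult:
    """Optimal local alignment of query ``a`` against subject ``b``."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    sa, sb = _sanitize(a, alphabet), _sanitize(b, alphabet)
    alignments = aligner.align(sa, sb)
    if alignments.score <= 0:
        return AlignmentResult(query_name, subject_name, 0.0, 0.0, 0.0, 0.0,
                               (0, 0), (0, 0))
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qseg, sseg = aln.aligned
    qspan = (int(qseg[0][0]), int(qseg[-1][1]))
    sspan = (int(sseg[0][0]), int(sseg[-1][1]))
    return AlignmentResult(
        query_name, subject_name, float(alignments.score), identity,
        100.0 * (qspan[1] - qspan[0]) / len(sa),
        100.0 * (sspan[1] - sspan[0]) / len(sb),
        qspan, sspan)


def estimate_evalue(score: float, query_len: int, db_len: int,
                    K: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    """Expected number of chance alignments scoring >= score."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    return K * query_len * db_len * math.exp(-lam * score)


def _result_key(r: AlignmentResult) -> tuple:
    # best hit: highest score, then highest identity, then smallest tag
    return (-r.score, -r.identity_percent, r.subject)


def _all_pairs(proteome_a: Sequence[tuple[str, str]],
               proteome_b: Sequence[tuple[str, str]],
               **kw) -> dict[tuple[str, str], AlignmentResult]:
    out = {}
    for ta, sa in proteome_a:
        for tb, sb in proteome_b:
            out[(ta, tb)] = align_local(sa, sb, query_name=ta,
                                        subject_name=tb, **kw)
    return out


def bidirectional_best_hits(proteome_a: Sequence[tuple[str, str]],
                            proteome_b: Sequence[tuple[str, str]],
                            min_identity: float = 40.0,
                            min_coverage: float = 80.0,
                            **kw) -> list[BBHPair]:
    """Reciprocal best hits surviving identity and coverage thresholds.

    A pair is kept iff each member is the other's best-scoring hit, the
    alignment identity is >= ``min_identity`` and coverage is >=
    ``min_coverage`` in the query direction of each member.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    for prot in (proteome_a, proteome_b):
        tags = [t for t, _ in prot]
        if len(tags) != len(set(tags)):
            raise ValueError("locus_tags must be unique within a proteome")
    results = _all_pairs(proteome_a, proteome_b, **kw)
    best_ab = {}
    for ta, _ in proteome_a:
        cands = [results[(ta, tb)] for tb, _ in proteome_b]
        best_ab[ta] = min(cands, key=_result_key)
    best_ba = {}
    for tb, _ in proteome_b:
        cands = [results[(ta, tb)] for ta, _ in proteome_a]
        # same DP result serves both directions (score matrix symmetric)
        best_ba[tb] = min(cands, key=lambda r: (-r.score, -r.identity_percent,
                                                r.query))
    pairs = []
    for ta, ra in sorted(best_ab.items()):
        tb = ra.subject
        if best_ba[tb].query != ta:
            continue
        if ra.score <= 0 or ra.identity_percent < min_identity:
            continue
        if ra.query_coverage_percent < min_coverage or \
                ra.subject_coverage_percent < min_coverage:
            continue
        pairs.append(BBHPair(ta, tb, ra.identity_percent,
                             ra.query_coverage_percent,
                             ra.subject_coverage_percent))
    return pairs


def assign_homology(focal: Sequence[tuple[str, str]],
                    references: Sequence[tuple[str, Sequence[tuple[str, str]]]],
                    uniqueness_threshold: float = 40.0,
                    evalue_cutoff: float = 1e-5,
                    **kw) -> list[HomologyAssignment]:
    """Closest reference homolog per focal protein; uniqueness calling.

    The closest homolog is the best-scoring significant hit over ALL
    reference proteomes; only alignments with E-value below
    ``evalue_cutoff`` count as hits, so short spurious local fragments
    (which routinely reach 40-50% identity between unrelated proteins)
    cannot mask a genuinely unique gene.  A focal protein is unique when
    it has no significant hit or its best hit's identity falls below
    ``uniqueness_threshold``.  Self-hits (same locus_tag) are excluded so
    a proteome can be screened against a set containing itself.
    """
    if not references:
        raise ValueError("at least one reference proteome required")
    db_len = sum(len(s) for _, ref in references for _, s in ref)
    out = []
    for tag, seq in sorted(focal):
        best: Optional[tuple[tuple, float, str, str]] = None
        for prot_id, ref in references:
            for rtag, rseq in ref:
                if rtag == tag:
                    continue
                r = align_local(seq, rseq, query_name=tag, subject_name=rtag,
                                **kw)
                if r.score <= 0:
                    continue
                if estimate_evalue(r.score, len(seq), db_len) >= evalue_cutoff:
                    continue
                key = (-r.score, -r.identity_percent, prot_id, rtag)
                if best is None or key < best[0]:
                    best = (key, r.identity_percent, prot_id, rtag)
        if best is None:
            out.append(HomologyAssignment(tag, None, 0.0, True))
        else:
            _, ident, pid, rtag = best
            out.append(HomologyAssignment(tag, (pid, rtag), ident,
                                          ident < uniqueness_threshold))
    return out


def detect_t4p(proteome: Sequence[tuple[str, str]],
               t4p_reference: Mapping[str, Sequence[tuple[str, str]]],
               min_identity: float = 40.0, min_coverage: float = 80.0,
               **kw) -> dict[str, list[tuple[str, float]]]:
    """Map type-IV-pilus gene names onto a proteome.

    ``t4p_reference`` maps a gene name (PilA, PilT, ...) to one or more
    exemplar sequences.  Each proteome locus is assigned to the gene name
    of its best-scoring exemplar when that hit passes the reciprocal-best
    thresholds (identity and coverage in both directions), so paralog
    expansions (e.g. several retraction ATPase PilT copies) all map to
    the same name.  Names with no qualifying locus are reported absent
    (empty list).
    """
    if not t4p_reference:
        raise ValueError("empty T4P reference set")
    exemplars = []  # (gene_name, tag, seq)
    for name, entries in t4p_reference.items():
        for etag, eseq in entries:
            exemplars.append((name, etag, eseq))
    table: dict[str, list[tuple[str, float]]] = {n: [] for n in t4p_reference}
    for tag, seq in proteome:
        best = None
        for name, etag, eseq in exemplars:
            r = align_local(seq, eseq, query_name=tag, subject_name=etag, **kw)
            key = (-r.score, -r.identity_percent, etag)
            if best is None or key < best[0]:
                best = (key, name, r)
        _, name, r = best
        if r.score <= 0 or r.identity_percent < min_identity:
            continue
        if r.query_coverage_percent < min_coverage or \
                r.subject_coverage_percent < min_coverage:
            continue
        table[name].append((tag, r.identity_percent))
    for name in table:
        table[name].sort(key=lambda x: (-x[1], x[0]))
    return table
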