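"""Putative c-type cytochrome census.

c-type cytochromes bind heme covalently at C(X)nCH motifs (cysteine, n
spacer residues, cysteine, histidine; n = 2-4 here).  Candidate proteins
are first screened for at least one such motif, then accepted when either
an externally supplied conserved-domain hit (e-value below ``domain_e``)
or a pairwise alignment against a reference cytochrome set (e-value below
``aln_e``) supports the call.  The motif screen is a mandatory first gate:
a domain hit without a heme motif is never called.

Motif scanning is greedy left-to-right: at each cysteine the shortest
valid spacer length is taken and scanning resumes after the matched
histidine, so reported hits are non-overlapping.  The residue symbol X
(unknown amino acid) may sit in the spacer but never serves as the motif's
cysteines or histidine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import homology

VALID_COMPARTMENTS = {"CM", "PP", "EX", "CY", "unknown"}


@dataclass
class HemeMotifHit:
    """One matched C(X)nCH site; ``start`` indexes the first cysteine."""

    start: int
    n: int
    motif_text: str
    locus_tag: str = ""


@dataclass
class CytochromeCall:
    locus_tag: str
    n_hemes: int
    evidence: str  # domain | alignment | both
    best_domain_evalue: Optional[float] = None
    best_alignment_evalue: Optional[float] = None
    localization: str = "unknown"


@dataclass
class CensusReport:
    n_called: int
    heme_min: int
    heme_max: int
    localization_counts: dict[str, int]
    calls: list[CytochromeCall] = field(default_factory=list)


def scan_heme_motifs(protein: str, n_min: int = 2, n_max: int = 4,
                     locus_tag: str = "") -> list[HemeMotifHit]:
    """Greedy non-overlapping scan for C(X)nCH heme-binding motifs."""
    if not protein:
        return []
    seq = protein.rstrip("*").upper()
    if "*" in seq:
        warnings.warn(f"internal stop codon in {locus_tag or 'protein'}; "
                      "no motifs reported", stacklevel=2)
        return []
    hits: list[HemeMotifHit] = []
    i, L = 0, len(seq)
    while i < L:
        if seq[i] == "C":
            matched = False
            for n in range(n_min, n_max + 1):
                j = i + n + 1  # second cysteine
                if j + 1 < L and seq[j] == "C" and seq[j + 1] == "H":
                    hits.append(HemeMotifHit(i, n, seq[i:j + 2], locus_tag))
                    i = j + 2  # resume after the matched histidine
                    matched = True
                    break
            if matched:
                continue
        i += 1
    return hits


def classify_cytochromes(
    proteome: Sequence[tuple[str, str]],
    domain_hits: Mapping[str, float] | None = None,
    reference_cytochromes: Sequence[tuple[str, str]] | None = None,
    domain_e: float = 0.01,
    aln_e: float = 1e-10,
    n_min: int = 2,
    n_max: int = 4,
) -> list[CytochromeCall]:
    """Call putative c-type cytochromes in a proteome.

    ``domain_hits`` maps locus_tag to the minimum e-value of any
    cytochrome-family conserved-domain hit (produced externally).
    ``reference_cytochromes`` is the (name, sequence) set used for the
    pairwise-alignment evidence branch.
    """
    domain_hits = dict(domain_hits or {})
    refs = list(reference_cytochromes or [])
    tags = {t for t, _ in proteome}
    missing = set(domain_hits) - tags
    if missing:
        raise ValueError(
            f"domain_hits references loci absent from the proteome: "
            f"{sorted(missing)[:5]}")
    db_len = sum(len(s) for _, s in refs)
    calls: list[CytochromeCall] = []
    for tag, seq in proteome:
        hits = scan_heme_motifs(seq, n_min, n_max, tag)
        if not hits:
            continue
        dom_e = domain_hits.get(tag)
        domain_ok = dom_e is not None and dom_e < domain_e
        best_aln_e: Optional[float] = None
        if refs:
            for _, ref in refs:
                res = homology.align_local(seq, ref)
                e = homology.estimate_evalue(res.score, len(seq), db_len)
                if best_aln_e is None or e < best_aln_e:
                    best_aln_e = e
        aln_ok = best_aln_e is not None and best_aln_e < aln_e
        if not (domain_ok or aln_ok):
            continue
        evidence = "both" if (domain_ok and aln_ok) else \
            ("domain" if domain_ok else "alignment")
        calls.append(CytochromeCall(tag, len(hits), evidence, dom_e, best_aln_e))
    return calls


def summarize_census(calls: Sequence[CytochromeCall],
                     localization_table: Mapping[str, str] | None = None
                     ) -> CensusReport:
    """Attach subcellular localizations and summarise the census.

    Compartment labels follow the convention CM (cytoplasmic membrane),
    PP (periplasm), EX (extracellular), CY (cytoplasm).
    """
    loc = dict(localization_table or {})
    bad = {v for v in loc.values()} - VALID_COMPARTMENTS
    if bad:
        raise ValueError(f"unknown localization labels: {sorted(bad)}")
    out_calls = []
    counts: dict[str, int] = {}
    for c in calls:
        where = loc.get(c.locus_tag, "unknown")
        out_calls.append(CytochromeCall(c.locus_tag, c.n_hemes, c.evidence,
                                        c.best_domain_evalue,
                                        c.best_alignment_evalue, where))
        counts[where] = counts.get(where, 0) + 1
    if out_calls:
        hemes = [c.n_hemes for c in out_calls]
        return CensusReport(len(out_calls), min(hemes), max(hemes), counts,
                            out_calls)
    return CensusReport(0, 0, 0, {}, [])


def census_frame(report: CensusReport):
    """Per-protein call table as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [{"locus_tag": c.locus_tag, "n_hemes": c.n_hemes,
             "evidence": c.evidence,
             "domain_evalue": c.best_domain_evalue,
             "alignment_evalue": c.best_alignment_evalue,
             "localization": c.localization}
            for c in sorted(report.calls, key=lambda c: c.locus_tag)]
    return pd.DataFrame(rows, columns=["locus_tag", "n_hemes", "evidence",
                                       "domain_evalue", "alignment_evalue",
                                       "localization"])
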