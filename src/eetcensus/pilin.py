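"""Type IV pilin maturation and aromatic-residue content.

Major pilins (PilA) are exported as preproteins with a short, positively
charged class-III signal peptide that the prepilin peptidase cleaves
after an invariant glycine; the mature pilin starts at the hydrophobic
residue (canonically phenylalanine) that follows.  The fraction of
aromatic residues (F, W, Y) in the mature peptide is a widely used proxy
for pilus conductivity: aromatic side chains stack along the filament and
carry electrons in conductive pili.

Histidine is excluded from the aromatic set: on the Geobacter
sulfurreducens PCA PilA mature 61-mer, F/W/Y gives 6/61 = 9.84%, the
accepted literature value, whereas including H does not.  The set is
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

DEFAULT_AROMATICS = "FWY"
HYDROPHOBIC_AFTER_CLEAVAGE = set("FMLI")
LEADER_SEARCH_WINDOW = 40


@dataclass
class PilinReport:
    locus_tag: str
    mature_start: Optional[int]
    aromatic_percent: float
    aromatic_residues_counted: str
    basis: str  # "mature" | "full_length"


def find_mature_pilin_start(seq: str,
                            window: int = LEADER_SEARCH_WINDOW) -> Optional[int]:
    """Position just after the prepilin-peptidase cleavage glycine.

    Scans the first ``window`` residues for the G|[FMLI] consensus and
    takes the first qualifying glycine — prepilin leaders are short and
    strictly N-terminal, so the first consensus site is the cleavage
    site.  Returns None when no site is found; callers then fall back to
    full-length content.
    """
    if len(seq) < 10:
        raise ValueError("sequence too short to be a pilin preprotein")
    s = seq.upper()
    limit = min(window, len(s) - 1)
    for i in range(limit):
        if s[i] == "G" and s[i + 1] in HYDROPHOBIC_AFTER_CLEAVAGE:
            return i + 1
    return None


def aromatic_fraction(seq: str, start: int = 0,
                      aromatics: str = DEFAULT_AROMATICS) -> float:
    """Percent aromatic residues in ``seq[start:]``."""
    if start >= len(seq):
        raise ValueError("start beyond sequence end")
    s = seq.upper()[start:]
    if not s:
        raise ValueError("empty effective sequence")
    return 100.0 * sum(s.count(a) for a in aromatics.upper()) / len(s)


def pilin_report(locus_tag: str, seq: str,
                 aromatics: str = DEFAULT_AROMATICS,
                 cleave: bool = True) -> PilinReport:
    """Aromatic content of a pilin, on the mature peptide when the
    cleavage site is detectable, otherwise full-length with a warning."""
    start = find_mature_pilin_start(seq) if cleave else None
    if start is not None:
        return PilinReport(locus_tag, start,
                           aromatic_fraction(seq, start, aromatics),
                           aromatics, "mature")
    if cleave:
        warnings.warn(f"{locus_tag}: no prepilin cleavage site detected; "
                      "reporting full-length aromatic content", stacklevel=2)
    return PilinReport(locus_tag, None, aromatic_fraction(seq, 0, aromatics),
                       aromatics, "full_length")
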