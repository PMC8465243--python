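"""eetcensus: genome mining for extracellular-electron-transfer machinery.

A census pipeline for electrogenic bacteria: c-type cytochrome detection
via C(X)nCH heme-motif screening with a two-branch evidence rule,
reciprocal-best-hit homology mapping, type IV pilin aromatic-content
scoring, genome feature statistics, and 16S rRNA neighbor-joining
phylogeny — with seeded synthetic-data generators so every stage is
testable with known ground truth.
"""

__version__ = "0.1.0"

from importlib import resources


def packaged_data(name: str):
    """Path-like handle to a data file shipped with the package."""
    return resources.files("eetcensus.data").joinpath(name)
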