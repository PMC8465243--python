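"""Genome record I/O and genome-level statistics.

Reads annotated bacterial replicons from GenBank flat files or FASTA+GFF3,
normalises coordinates to 0-based half-open, and computes the descriptive
statistics used throughout the census: length, G+C content, feature counts
per type, 16S rRNA copy number and windowed G+C skew.

All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention is converted on read and restored on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

FeatureType = Literal["CDS", "tRNA", "rRNA", "tmRNA", "other"]
RrnaClass = Optional[Literal["5S", "16S", "23S"]]

_KNOWN_FTYPES = {"CDS", "tRNA", "rRNA", "tmRNA"}
_SKIPPED_GENBANK_TYPES = {"source", "gene"}

_COMPLEMENT = str.maketrans("ACGTNacgtnRYKMSWBDHVrykmswbdhv",
                            "TGCANtgcanYRMKSWVHDByrmkswvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A feature interval falls outside the replicon."""


class GenomeParseError(ValueError):
    """The input file could not be parsed in the named format."""


@dataclass
class Feature:
    """A located, typed genome feature.

    ``start``/``end`` are 0-based half-open on the forward strand.  A
    feature spanning the origin of a circular replicon carries
    ``wraps=True`` and ``end`` > replicon length; its sequence is spliced
    on extraction.
    """

    locus_tag: str
    ftype: FeatureType
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    translation: str = ""
    rrna_class: RrnaClass = None
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(
                f"feature {self.locus_tag}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.locus_tag}: bad strand {self.strand!r}")
        if self.rrna_class is not None and self.ftype != "rRNA":
            raise ValueError(
                f"feature {self.locus_tag}: rrna_class set on non-rRNA feature")

    def extract(self, sequence: str) -> str:
        """Spliced, strand-corrected nucleotide sequence of this feature."""
        if self.wraps:
            n = len(sequence)
            sub = sequence[self.start:] + sequence[: self.end - n]
        else:
            sub = sequence[self.start:self.end]
        return reverse_complement(sub) if self.strand == "-" else sub


def infer_rrna_class(product: str) -> RrnaClass:
    # GenBank has no structured rRNA-class field; the product string does.
    low = product.lower()
    for cls in ("16S", "23S", "5S"):
        if cls.lower() in low:
            return cls  # type: ignore[return-value]
    return None


@dataclass
class GenomeRecord:
    """An annotated replicon: sequence plus located features."""

    identifier: str
    sequence: str
    topology: Literal["linear", "circular"] = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise ValueError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)
            if f.wraps:
                if self.topology != "circular":
                    raise CoordinateError(
                        f"feature {f.locus_tag} wraps the origin of a linear replicon")
                if not (f.start < n < f.end <= 2 * n):
                    raise CoordinateError(
                        f"feature {f.locus_tag}: bad wrapped interval "
                        f"[{f.start},{f.end}) on length {n}")
            elif not (0 <= f.start < f.end <= n):
                raise CoordinateError(
                    f"feature {f.locus_tag}: interval [{f.start},{f.end}) "
                    f"outside [0,{n})")

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_translations(self, table: int = 11) -> list[tuple[str, str]]:
        """(locus_tag, protein) for every CDS, translating where needed."""
        out = []
        for f in self.features:
            if f.ftype != "CDS":
                continue
            prot = f.translation or _translate_cds(f.extract(self.sequence), table)
            out.append((f.locus_tag, prot))
        return out


def _translate_cds(nt: str, table: int = 11) -> str:
    prot = str(Seq(nt[: len(nt) - len(nt) % 3]).translate(table=table))
    return prot.rstrip("*")


@dataclass
class GenomeStats:
    length_bp: int
    gc_percent: float
    counts: dict[str, int]
    n_16s: int


def read_genome_record(path: str | Path, fmt: str = "genbank",
                       gff3: str | Path | None = None) -> GenomeRecord:
    """Read one annotated replicon.

    ``fmt`` is ``"genbank"`` or ``"fasta+gff3"``; the latter takes the FASTA
    in ``path`` and the annotation in ``gff3``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "genbank":
        return _read_genbank(path)
    if fmt == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires the gff3= path")
        return _read_fasta_gff3(path, Path(gff3))
    raise ValueError(f"unknown format {fmt!r}")


def _read_genbank(path: Path) -> GenomeRecord:
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise GenomeParseError(f"{path}: not a parseable GenBank file: {exc}") from exc
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    seq = str(rec.seq).upper()
    features: list[Feature] = []
    auto = 0
    for sf in rec.features:
        if sf.type in _SKIPPED_GENBANK_TYPES:
            continue
        ftype = sf.type if sf.type in _KNOWN_FTYPES else "other"
        quals = sf.qualifiers
        tag = quals.get("locus_tag", [None])[0]
        if tag is None:
            auto += 1
            tag = f"feat_{auto:05d}"
        product = quals.get("product", [""])[0]
        strand = "-" if sf.location.strand == -1 else "+"
        start = int(sf.location.start)  # Biopython already 0-based half-open
        end = int(sf.location.end)
        wraps = False
        parts = getattr(sf.location, "parts", [sf.location])
        if len(parts) > 1 and topology == "circular":
            p0, p1 = parts[0], parts[-1]
            if int(p0.end) == len(seq) and int(p1.start) == 0:
                start, end, wraps = int(p0.start), len(seq) + int(p1.end), True
        translation = quals.get("translation", [""])[0]
        feat = Feature(tag, ftype, start, end, strand, product, translation,
                       infer_rrna_class(product) if ftype == "rRNA" else None,
                       wraps)
        if ftype == "CDS" and not feat.translation:
            feat.translation = _translate_cds(feat.extract(seq))
        features.append(feat)
    return GenomeRecord(rec.id or path.stem, seq, topology, features)


def _read_fasta_gff3(fasta: Path, gff3: Path) -> GenomeRecord:
    import gffutils

    try:
        rec = next(SeqIO.parse(str(fasta), "fasta"))
    except (StopIteration, ValueError) as exc:
        raise GenomeParseError(f"{fasta}: not a parseable FASTA: {exc}") from exc
    seq = str(rec.seq).upper()
    try:
        db = gffutils.create_db(str(gff3), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:  # gffutils raises bare Exceptions on bad input
        raise GenomeParseError(f"{gff3}: not parseable GFF3: {exc}") from exc
    features: list[Feature] = []
    auto = 0
    for gf in db.all_features():
        if gf.featuretype not in _KNOWN_FTYPES:
            continue
        tag = (gf.attributes.get("locus_tag") or gf.attributes.get("ID") or [None])[0]
        if tag is None:
            auto += 1
            tag = f"feat_{auto:05d}"
        product = (gf.attributes.get("product") or [""])[0]
        ftype = gf.featuretype
        feat = Feature(tag, ftype, gf.start - 1, gf.end,  # GFF3 is 1-based inclusive
                       "-" if gf.strand == "-" else "+", product, "",
                       infer_rrna_class(product) if ftype == "rRNA" else None)
        if ftype == "CDS":
            feat.translation = _translate_cds(feat.extract(seq))
        features.append(feat)
    return GenomeRecord(rec.id or fasta.stem, seq, "linear", features)


def write_genome_record(record: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trip safe)."""
    seq_features = []
    n = len(record.sequence)
    for f in record.features:
        if f.wraps:
            from Bio.SeqFeature import CompoundLocation
            strand = -1 if f.strand == "-" else 1
            loc = CompoundLocation([FeatureLocation(f.start, n, strand),
                                    FeatureLocation(0, f.end - n, strand)])
        else:
            loc = FeatureLocation(f.start, f.end, -1 if f.strand == "-" else 1)
        quals = {"locus_tag": [f.locus_tag]}
        if f.product:
            quals["product"] = [f.product]
        if f.ftype == "CDS" and f.translation:
            quals["translation"] = [f.translation]
        seq_features.append(SeqFeature(loc, type=f.ftype, qualifiers=quals))
    rec = SeqRecord(Seq(record.sequence), id=record.identifier,
                    name=record.identifier[:16], description="",
                    features=seq_features,
                    annotations={"molecule_type": "DNA",
                                 "topology": record.topology})
    SeqIO.write(rec, str(path), "genbank")


def genome_stats(record: GenomeRecord) -> GenomeStats:
    """Length, G+C%, per-type feature counts and 16S copy number.

    G+C is computed over unambiguous bases only (N and other ambiguity
    codes excluded from the denominator).
    """
    seq = record.sequence
    g, c = seq.count("G"), seq.count("C")
    a, t = seq.count("A"), seq.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("G+C content undefined: no unambiguous bases")
    counts: dict[str, int] = {k: 0 for k in ("CDS", "tRNA", "rRNA", "tmRNA", "other")}
    n_16s = 0
    for f in record.features:
        counts[f.ftype] += 1
        if f.ftype == "rRNA" and f.rrna_class == "16S":
            n_16s += 1
    return GenomeStats(len(seq), 100.0 * (g + c) / denom, counts, n_16s)


def gc_skew(record: GenomeRecord, window: int, step: int
            ) -> list[tuple[int, float, bool]]:
    """Windowed (G-C)/(G+C); windows wrap on circular replicons.

    Returns (window midpoint, skew, defined) triples; a window with no G or
    C reports skew 0.0 with defined=False.
    """
    n = len(record.sequence)
    if not (0 < window <= n):
        raise ValueError(f"window must be in (0, {n}]")
    if step <= 0:
        raise ValueError("step must be positive")
    seq = record.sequence
    out = []
    starts = range(0, n, step) if record.topology == "circular" \
        else range(0, n - window + 1, step)
    for s in starts:
        if s + window <= n:
            win = seq[s:s + window]
        else:  # circular wrap
            win = seq[s:] + seq[: s + window - n]
        g, c = win.count("G"), win.count("C")
        mid = (s + window // 2) % n
        if g + c == 0:
            out.append((mid, 0.0, False))
        else:
            out.append((mid, (g - c) / (g + c), True))
    return out


def extract_16s(record: GenomeRecord) -> list[tuple[str, str]]:
    """All 16S rRNA sequences, spliced and strand-corrected.

    Ordered by start coordinate and labelled rrn1..rrnN, mirroring the
    operon naming convention for ribosomal RNA clusters.
    """
    feats = sorted((f for f in record.features
                    if f.ftype == "rRNA" and f.rrna_class == "16S"),
                   key=lambda f: f.start)
    return [(f"rrn{i}", f.extract(record.sequence))
            for i, f in enumerate(feats, start=1)]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in entries]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
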