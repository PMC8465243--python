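"""End-to-end census orchestration.

Runs genome -> stats -> proteome -> cytochrome census -> homology /
uniqueness -> T4P detection -> pilin aromatics, writing diff-able TSV/JSON
outputs.  Reruns on identical inputs are byte-identical: every output
carries the configuration hash and tool version, and wall-clock timings
go to stderr only, never into result files.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, cytochromes, homology, pilin, seqio

PILIN_GENE_NAMES = {"PilA", "PilE", "PilV", "PilW", "PilY"}


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    genome: str
    genome_format: str = "genbank"
    gff3: Optional[str] = None
    reference_proteomes: dict[str, str] = field(default_factory=dict)
    reference_cytochromes: Optional[str] = None
    t4p_reference: Optional[str] = None  # FASTA; gene name = id prefix before '|'
    domain_hits: Optional[str] = None  # TSV: locus_tag, accession, evalue
    localization: Optional[str] = None  # TSV: locus_tag, compartment
    min_identity: float = 40.0
    min_coverage: float = 80.0
    uniqueness_threshold: float = 40.0
    domain_e: float = 0.01
    aln_e: float = 1e-10
    heme_n_min: int = 2
    heme_n_max: int = 4
    outdir: str = "census_out"
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.min_identity <= 100 and 0 <= self.min_coverage <= 100):
            raise ConfigurationError("identity/coverage thresholds must be 0-100")
        if not (1 <= self.heme_n_min <= self.heme_n_max):
            raise ConfigurationError("invalid heme spacer range")
        if self.domain_e <= 0 or self.aln_e <= 0:
            raise ConfigurationError("e-value cutoffs must be positive")
        for label, p in self._input_paths():
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"missing input {label}: {p}")
        if self.reference_cytochromes is None and self.domain_hits is None:
            raise ConfigurationError(
                "need a reference cytochrome set and/or a domain-hit table")

    def _input_paths(self):
        yield "genome", self.genome
        yield "gff3", self.gff3
        for name, p in self.reference_proteomes.items():
            yield f"reference_proteome[{name}]", p
        yield "reference_cytochromes", self.reference_cytochromes
        yield "t4p_reference", self.t4p_reference
        yield "domain_hits", self.domain_hits
        yield "localization", self.localization

    def config_hash(self) -> str:
        # hash covers scientific inputs and thresholds, not output location
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _stamp(cfg: PipelineConfig) -> str:
    return f"# eetcensus {__version__} config={cfg.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
               float_format: str = "%.4g") -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def _read_domain_hits(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    tag_col = cols.get("locus_tag", df.columns[0])
    e_col = cols.get("evalue", df.columns[-1])
    return df.groupby(tag_col)[e_col].min().to_dict()


def _read_localization(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _read_t4p_reference(path: str) -> dict[str, list[tuple[str, str]]]:
    # FASTA ids of the form "GeneName|exemplar_tag"
    table: dict[str, list[tuple[str, str]]] = {}
    for name, seq in seqio.read_fasta(path):
        gene, _, tag = name.partition("|")
        table.setdefault(gene, []).append((tag or name, seq))
    return table


def run_census(config: PipelineConfig) -> dict[str, Path]:
    """Run the full census; returns paths of the outputs written."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"eetcensus {__version__}",
                            f"config {config.config_hash()}"]

    def stage(name):
        t0 = time.perf_counter()

        def done(msg: str) -> None:
            dt = time.perf_counter() - t0
            print(f"[{name}] {msg} ({dt:.2f}s)", file=sys.stderr)
            log_lines.append(f"{name}: {msg}")

        return done

    done = stage("genome")
    record = seqio.read_genome_record(config.genome, config.genome_format,
                                      gff3=config.gff3)
    stats = seqio.genome_stats(record)
    stats_path = outdir / "stats.json"
    with open(stats_path, "w") as fh:
        json.dump({"tool_version": __version__,
                   "config_hash": config.config_hash(),
                   "identifier": record.identifier,
                   "length_bp": stats.length_bp,
                   "gc_percent": round(stats.gc_percent, 2),
                   "counts": stats.counts, "n_16s": stats.n_16s},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    done(f"{stats.length_bp} bp, {stats.counts['CDS']} CDS")

    proteome = record.cds_translations()

    done = stage("cytochromes")
    domain_hits = _read_domain_hits(config.domain_hits) if config.domain_hits else {}
    refs = seqio.read_fasta(config.reference_cytochromes) \
        if config.reference_cytochromes else []
    calls = cytochromes.classify_cytochromes(
        proteome, domain_hits, refs, config.domain_e, config.aln_e,
        config.heme_n_min, config.heme_n_max)
    loc = _read_localization(config.localization) if config.localization else {}
    report = cytochromes.summarize_census(calls, loc)
    cyt_path = outdir / "cytochromes.tsv"
    _write_tsv(cytochromes.census_frame(report), cyt_path, config)
    done(f"{report.n_called} called, hemes {report.heme_min}-{report.heme_max}")

    done = stage("homology")
    called = {c.locus_tag for c in calls}
    focal = [(t, s) for t, s in proteome if t in called]
    references = [(name, seqio.read_fasta(path))
                  for name, path in sorted(config.reference_proteomes.items())]
    if references and focal:
        assignments = homology.assign_homology(
            focal, references, config.uniqueness_threshold)
    else:
        assignments = []
    hom_df = pd.DataFrame(
        [{"locus_tag": a.locus_tag,
          "closest_proteome": a.closest_reference[0] if a.closest_reference else "",
          "closest_locus": a.closest_reference[1] if a.closest_reference else "",
          "best_identity_percent": a.best_identity_percent,
          "unique": a.unique}
         for a in assignments],
        columns=["locus_tag", "closest_proteome", "closest_locus",
                 "best_identity_percent", "unique"])
    _write_tsv(hom_df, outdir / "homology.tsv", config)
    uniq_df = hom_df[hom_df["unique"] == True]  # noqa: E712
    _write_tsv(uniq_df, outdir / "unique_genes.tsv", config)
    done(f"{len(assignments)} assignments, {len(uniq_df)} unique")

    done = stage("t4p")
    pilin_rows = []
    t4p_rows = []
    if config.t4p_reference:
        t4p_ref = _read_t4p_reference(config.t4p_reference)
        t4p = homology.detect_t4p(proteome, t4p_ref, config.min_identity,
                                  config.min_coverage)
        seqs = dict(proteome)
        for gene in sorted(t4p):
            for tag, ident in t4p[gene]:
                t4p_rows.append({"gene": gene, "locus_tag": tag,
                                 "identity_percent": ident})
                if gene in PILIN_GENE_NAMES:
                    rep = pilin.pilin_report(tag, seqs[tag])
                    pilin_rows.append({
                        "locus_tag": tag, "gene": gene, "basis": rep.basis,
                        "mature_start": rep.mature_start,
                        "aromatic_percent": round(rep.aromatic_percent, 2)})
    _write_tsv(pd.DataFrame(t4p_rows, columns=["gene", "locus_tag",
                                               "identity_percent"]),
               outdir / "t4p.tsv", config)
    _write_tsv(pd.DataFrame(pilin_rows, columns=["locus_tag", "gene", "basis",
                                                 "mature_start",
                                                 "aromatic_percent"]),
               outdir / "pilin.tsv", config)
    done(f"{len(t4p_rows)} T4P loci, {len(pilin_rows)} pilins scored")

    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    return {"stats": stats_path, "cytochromes": cyt_path,
            "homology": outdir / "homology.tsv",
            "unique_genes": outdir / "unique_genes.tsv",
            "t4p": outdir / "t4p.tsv", "pilin": outdir / "pilin.tsv",
            "log": log_path}
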