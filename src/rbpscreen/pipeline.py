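"""End-to-end driver: scans -> quantification -> hits -> interaction matrix.

The driver consumes a manifest of scans (one per RNA incubation, each tagged
with its locus and strand, optionally with replicate tags), quantifies each
array independently (no between-array normalisation — every array is
filtered against its own global signal distribution), applies the dual
Z-score/fold filter, subtracts antisense hits per locus, and assembles the
sense-specific binary interaction matrix with clustering order, the
common-binder ranking, and replicate QC (concordance r² and hit-set overlap
significance) where replicates are present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .array_io import DEFAULT_CONTROL_PATTERNS, ArrayScan, read_gpr
from .errors import ConfigError
from .hit_calling import (
    HitTable,
    InteractionMatrix,
    build_matrix,
    call_hits,
    cluster_matrix,
    common_binders,
)
from .quantify import quantify_scan, write_stats_tsv
from .stats_enrich import (
    AnnotationMap,
    enrichment_to_frame,
    overlap_significance,
    replicate_concordance,
    term_enrichment,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanEntry:
    """One manifest line: where a scan lives and what it probed."""

    rna_id: str
    strand: str
    path: str
    replicate: int = 0


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    manifest: list[ScanEntry]
    z_min: float = 3.0
    fold_min: float = 2.5
    min_frac: float = 0.75
    control_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_CONTROL_PATTERNS))
    annotations: dict[str, str] = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sense_loci = {e.rna_id for e in self.manifest if e.strand == "sense"}
        for e in self.manifest:
            if e.strand not in ("sense", "antisense"):
                raise ConfigError(f"manifest strand {e.strand!r} invalid for {e.rna_id!r}")
            if e.rna_id not in sense_loci:
                raise ConfigError(f"locus {e.rna_id!r} has antisense but no sense scan")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        manifest = [ScanEntry(**e) for e in raw.pop("manifest")]
        return cls(manifest=manifest, **raw)


@dataclass
class PipelineResult:
    """All products of one run."""

    matrix: InteractionMatrix
    hit_tables: dict[tuple[str, str], HitTable]
    sense_specific_tables: dict[str, HitTable]
    common: pd.DataFrame
    stats: dict[tuple[str, str], pd.DataFrame]
    replicate_qc: dict[tuple[str, str], dict]
    enrichment: dict[str, pd.DataFrame]
    summary: dict


def analyze_scans(
    scans: Sequence[ArrayScan],
    z_min: float = 3.0,
    fold_min: float = 2.5,
    min_frac: float = 0.75,
    annotations: dict[str, AnnotationMap] | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on already-parsed scans.

    When several scans share a (locus, strand), the first is analysed and
    the rest are treated as technical replicates: each contributes a
    concordance r² and a hit-overlap Fisher p against the first. Loci
    without an antisense scan fall back to their raw sense hits, with a
    warning, since no specificity subtraction is possible.
    """
    from .hit_calling import sense_specific as _sense_specific

    primaries: dict[tuple[str, str], ArrayScan] = {}
    replicate_qc: dict[tuple[str, str], dict] = {}
    for scan in scans:
        if scan.strand is None:
            raise ConfigError(f"scan {scan.scan_id!r} has no strand assigned")
        key = (scan.rna_id, scan.strand)
        if key not in primaries:
            primaries[key] = scan
        else:
            first = primaries[key]
            r, r2 = replicate_concordance(first, scan)
            qa = quantify_scan(first)
            qb = quantify_scan(scan)
            hits_a = call_hits(qa, z_min, fold_min, *key).hits
            hits_b = call_hits(qb, z_min, fold_min, *key).hits
            shared = len(qa.index.intersection(qb.index))
            p = overlap_significance(hits_a, hits_b, shared)
            replicate_qc[key] = {
                "scan_a": first.scan_id, "scan_b": scan.scan_id,
                "r": r, "r_squared": r2,
                "overlap": len(hits_a & hits_b),
                "hits_a": len(hits_a), "hits_b": len(hits_b),
                "universe": shared, "overlap_p": p,
            }

    stats: dict[tuple[str, str], pd.DataFrame] = {}
    hit_tables: dict[tuple[str, str], HitTable] = {}
    for (rna, strand), scan in primaries.items():
        table = quantify_scan(scan)
        stats[(rna, strand)] = table
        hit_tables[(rna, strand)] = call_hits(table, z_min, fold_min, rna, strand)

    loci = [rna for rna, strand in primaries if strand == "sense"]
    sense_tables: dict[str, HitTable] = {}
    for rna in loci:
        sense = hit_tables[(rna, "sense")]
        anti = hit_tables.get((rna, "antisense"))
        if anti is None:
            logger.warning("locus %s: no antisense scan; using raw sense hits", rna)
            sense_tables[rna] = sense
        else:
            sense_tables[rna] = _sense_specific(sense, anti)

    matrix = cluster_matrix(build_matrix([sense_tables[r] for r in loci])) \
        if any(len(t) for t in sense_tables.values()) \
        else build_matrix([sense_tables[r] for r in loci])
    common = common_binders(list(hit_tables.values()), min_frac=min_frac)

    enrichment: dict[str, pd.DataFrame] = {}
    if annotations:
        universe = frozenset().union(*(set(s.index) for s in stats.values()))
        any_binders = frozenset().union(*(t.hits for t in hit_tables.values()))
        for namespace, ann in annotations.items():
            res = term_enrichment(any_binders, universe, ann)
            enrichment[namespace] = enrichment_to_frame(res)

    n_tested = len(next(iter(stats.values()))) if stats else 0
    summary = {
        "version": __version__,
        "seed": seed,
        "thresholds": {"z_min": z_min, "fold_min": fold_min, "min_frac": min_frac},
        "n_scans": len(primaries),
        "n_loci": len(loci),
        "proteins_tested": n_tested,
        "hits_per_scan": {f"{r}/{s}": len(t) for (r, s), t in hit_tables.items()},
        "any_rna_binders": len(frozenset().union(*(t.hits for t in hit_tables.values()))) if hit_tables else 0,
        "sense_specific_interactions": matrix.n_interactions,
        "sense_specific_proteins": len(matrix.proteins),
        "common_binders": len(common),
        "replicate_qc": {f"{r}/{s}": qc for (r, s), qc in replicate_qc.items()},
    }
    return PipelineResult(
        matrix=matrix,
        hit_tables=hit_tables,
        sense_specific_tables=sense_tables,
        common=common,
        stats=stats,
        replicate_qc=replicate_qc,
        enrichment=enrichment,
        summary=summary,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Load every manifest scan, run the analysis, write all outputs."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    scans = []
    for entry in cfg.manifest:
        path = Path(entry.path)
        if not path.exists():
            raise FileNotFoundError(f"manifest scan not readable: {path}")
        scan = read_gpr(path, control_patterns=cfg.control_patterns)
        scan.rna_id = entry.rna_id
        scan.strand = entry.strand
        scans.append(scan)
    annotations = {
        ns: AnnotationMap.from_tsv(p, namespace=ns)
        for ns, p in cfg.annotations.items()
    }
    result = analyze_scans(
        scans, z_min=cfg.z_min, fold_min=cfg.fold_min, min_frac=cfg.min_frac,
        annotations=annotations or None, seed=cfg.seed,
    )
    if cfg.outdir:
        write_outputs(result, cfg.outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write TSV/JSON products of a run into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (rna, strand), table in result.stats.items():
        write_stats_tsv(table, out / f"stats_{rna}_{strand}.tsv")
    for (rna, strand), ht in result.hit_tables.items():
        ht.stats.to_csv(out / f"hits_{rna}_{strand}.tsv", sep="\t",
                        index_label="protein_id", float_format="%.10g")
    result.matrix.to_tsv(out / "interaction_matrix.tsv")
    result.matrix.ordered().to_csv(out / "interaction_matrix_clustered.tsv",
                                   sep="\t", index_label="protein_id")
    result.common.to_csv(out / "common_binders.tsv", sep="\t",
                         index_label="protein_id", float_format="%.10g")
    for namespace, frame in result.enrichment.items():
        frame.to_csv(out / f"enrichment_{namespace}.tsv", sep="\t",
                     index=False, float_format="%.10g")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2,
                                                 sort_keys=True) + "\n")


def report_summary(result: PipelineResult, path: str | Path | None = None) -> dict:
    """Machine-readable run summary; optionally written as JSON."""
    if path is not None:
        Path(path).write_text(json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    return result.summary
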