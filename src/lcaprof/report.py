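"""End-to-end pipeline orchestration and matrix/summary export.

Exported matrices mirror the customary supplementary-table layout:
column 1 holds the enzyme (EC) identifier, subsequent columns the
taxonomic divisions, and rows are ordered numerically on the four EC
fields (2.4.2.14 before 2.7.6.1).  Values are written at full precision
so write-then-read is the identity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import pathway as pw
from .distribution import (
    AverageMatrix,
    build_presence,
    clade_average,
    classify,
    ec_presence,
    genus_average,
    infer_lca,
)
from .hits import FilterConfig, read_catalogue, read_hits, filter_hits
from .simulate import read_manifest
from .taxonomy import Taxonomy, filter_genomes, read_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_matrix", "read_matrix", "ec_sort_key"]


def ec_sort_key(ec: str) -> tuple:
    """Numeric ordering on the four dotted EC fields; non-numeric fields
    (preliminary 'n'-prefixed or '-') sort after numeric ones."""
    key = []
    for part in ec.split("."):
        try:
            key.append((0, int(part)))
        except ValueError:
            key.append((1, part))
    return tuple(key)


def write_matrix(a: AverageMatrix, path: str | Path) -> None:
    """Export an average matrix: one row per enzyme (EC-numeric order),
    one column per taxonomic division, full-precision values."""
    if a.values.empty:
        raise ValueError("refusing to write an empty matrix")
    t = a.values.T  # enzymes in rows, divisions in columns
    order = sorted(t.index, key=ec_sort_key)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("enzyme\t" + "\t".join(str(c) for c in t.columns) + "\n")
        for enzyme in order:
            vals = "\t".join(repr(float(v)) for v in t.loc[enzyme])
            fh.write(f"{enzyme}\t{vals}\n")


def read_matrix(path: str | Path, level: str) -> AverageMatrix:
    """Inverse of :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AverageMatrix(values=df.T, level=level)


@dataclass
class RunConfig:
    """Paths and switches for one pipeline run."""

    hits_manifest: Path
    taxonomy: Path
    catalogue: Path
    outdir: Path
    pathways: tuple[Path, ...] = ()
    filter: FilterConfig = field(default_factory=FilterConfig)
    ec_level: bool = True  # resolve subunit/analog groups before LCA calls


def run_pipeline(cfg: RunConfig) -> dict:
    """Run hit filtering -> presence -> averaging -> classification ->
    LCA attribution (-> pathway annotation), writing all artifacts.

    Returns the machine-readable run log (also written to
    ``run_log.json``): thresholds used and record counts in/out at every
    stage.  Reruns on identical inputs produce byte-identical artifacts.
    """
    for name in ("hits_manifest", "taxonomy", "catalogue"):
        p = Path(getattr(cfg, name))
        if not p.is_file():
            raise FileNotFoundError(f"{name} file not found: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "thresholds": {
            "evalue_max": cfg.filter.evalue_max,
            "coverage_min": cfg.filter.coverage_min,
            "min_genes": cfg.filter.min_genes,
            "wide_fraction": cfg.filter.wide_fraction,
            "presence_cutoff": cfg.filter.presence_cutoff,
            "sparse_fraction": cfg.filter.sparse_fraction,
            "exclusive_best_hit": cfg.filter.exclusive_best_hit,
        },
        "stages": {},
    }

    catalogue = read_catalogue(cfg.catalogue)
    tax_all = read_taxonomy(cfg.taxonomy)
    tax = filter_genomes(tax_all, cfg.filter)
    log["stages"]["genome_filter"] = {
        "genomes_in": len(tax_all),
        "genomes_out": len(tax),
    }

    hits = []
    for genome_id, hit_path in read_manifest(cfg.hits_manifest):
        hits.extend(read_hits(hit_path, genome_id=genome_id))
    kept = filter_hits(
        [h for h in hits if h.genome_id in tax], catalogue, cfg.filter
    )
    log["stages"]["hit_filter"] = {"hits_in": len(hits), "hits_out": len(kept)}
    with (outdir / "filtered_hits.tsv").open("w") as fh:
        fh.write(
            "genome_id\tquery_id\tprofile_id\tevalue\tbitscore\t"
            "profile_start\tprofile_end\n"
        )
        for h in kept:
            fh.write(
                f"{h.genome_id}\t{h.query_id}\t{h.profile_id}\t{h.evalue!r}\t"
                f"{h.bitscore!r}\t{h.profile_start}\t{h.profile_end}\n"
            )

    m = build_presence(kept, tax, catalogue)
    m.to_csv(outdir / "presence_profile.tsv", sep="\t")
    m_ec = ec_presence(m, catalogue)
    m_ec.to_csv(outdir / "presence_ec.tsv", sep="\t")
    log["stages"]["presence"] = {
        "genomes": int(m.shape[0]),
        "profiles": int(m.shape[1]),
        "ecs": int(m_ec.shape[1]),
    }

    level_matrix = m_ec if cfg.ec_level else m
    g = genus_average(level_matrix, tax)
    c = clade_average(g, tax)
    write_matrix(g, outdir / "genus_average.tsv")
    write_matrix(c, outdir / "clade_average.tsv")

    summary = classify(c, tax, cfg.filter)
    summary.table.to_csv(outdir / "distribution_summary.tsv", sep="\t", index=False)
    verdicts = infer_lca(summary)
    verdicts.to_frame().to_csv(outdir / "lca_verdicts.tsv", sep="\t")
    log["stages"]["classification"] = {
        "enzymes": len(verdicts),
        "lca_attributed": int(verdicts.sum()),
    }

    verdict_map = {str(k): bool(v) for k, v in verdicts.items()}
    for p in cfg.pathways:
        p = Path(p)
        graph = pw.annotate_steps(pw.read_pathway(p), verdict_map)
        (outdir / f"{p.stem}.annotated.json").write_text(pw.to_json(graph))
        (outdir / f"{p.stem}.annotated.dot").write_text(pw.to_dot(graph))
        log["stages"].setdefault("pathways", {})[p.stem] = {
            label: sum(1 for s in graph.steps.values() if s.ancestry == label)
            for label in pw.ANCESTRY_LABELS
        }

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log
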