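"""Domain → clade → genus → genome hierarchy and the genome-inclusion rule.

The hierarchy has exactly four levels.  The top level is one of the three
cellular domains (Bacteria, Archaea, Eukarya); *clades* are the
intermediate taxonomic divisions (JGI-IMG-style categories) whose count
per domain forms the denominator of the wide-distribution rule; genera
group the sampled genomes.

Genomes flagged as obligate parasites, or with fewer than ``min_genes``
genes, are excluded before any distribution statistic is computed — a
guard against the massive gene loss of reduced genomes masquerading as
ancestral absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .hits import FilterConfig

logger = logging.getLogger(__name__)

__all__ = ["DOMAINS", "GenomeRecord", "Taxonomy", "read_taxonomy", "filter_genomes"]

DOMAINS = ("Bacteria", "Archaea", "Eukarya")


@dataclass(frozen=True, slots=True)
class GenomeRecord:
    genome_id: str
    domain: str
    clade: str
    genus: str
    gene_count: int
    obligate_parasite: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"genome {self.genome_id!r}: unknown domain {self.domain!r} "
                f"(expected one of {DOMAINS})"
            )
        if self.gene_count < 0:
            raise ValueError(f"genome {self.genome_id!r}: negative gene_count")


class Taxonomy:
    """Immutable collection of genome records with derived level indices."""

    def __init__(self, records: Iterable[GenomeRecord]):
        self._records: dict[str, GenomeRecord] = {}
        for rec in records:
            if rec.genome_id in self._records:
                raise ValueError(f"duplicate genome_id {rec.genome_id!r}")
            self._records[rec.genome_id] = rec
        # build and validate the nesting: genus -> one clade -> one domain
        self.genus_to_clade: dict[str, str] = {}
        self.clade_to_domain: dict[str, str] = {}
        self.genus_genomes: dict[str, list[str]] = {}
        self.clade_genera: dict[str, list[str]] = {}
        self.domain_clades: dict[str, list[str]] = {d: [] for d in DOMAINS}
        for rec in self._records.values():
            prev = self.genus_to_clade.setdefault(rec.genus, rec.clade)
            if prev != rec.clade:
                raise ValueError(
                    f"genus {rec.genus!r} assigned to clades "
                    f"{prev!r} and {rec.clade!r}"
                )
            prev_d = self.clade_to_domain.setdefault(rec.clade, rec.domain)
            if prev_d != rec.domain:
                raise ValueError(
                    f"clade {rec.clade!r} assigned to domains "
                    f"{prev_d!r} and {rec.domain!r}"
                )
            self.genus_genomes.setdefault(rec.genus, []).append(rec.genome_id)
        for genus, clade in self.genus_to_clade.items():
            self.clade_genera.setdefault(clade, []).append(genus)
        for clade, domain in self.clade_to_domain.items():
            self.domain_clades[domain].append(clade)
        for index in (self.genus_genomes, self.clade_genera, self.domain_clades):
            for key in index:
                index[key].sort()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._records

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._records[genome_id]

    def __iter__(self):
        return iter(self._records.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return self._records == other._records

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self._records)

    @property
    def records(self) -> list[GenomeRecord]:
        return [self._records[g] for g in self.genome_ids]

    def domains(self) -> list[str]:
        return [d for d in DOMAINS if self.domain_clades[d]]


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a taxonomy TSV (genome_id, domain, clade, genus, gene_count,
    obligate_parasite) into a validated :class:`Taxonomy`."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"taxonomy table not found: {path}")
    records: list[GenomeRecord] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "genome_id",
            "domain",
            "clade",
            "genus",
            "gene_count",
            "obligate_parasite",
        ]
        if [h.lstrip("#") for h in header] != expected:
            raise ValueError(f"{path}: header {header} != expected {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            flag = parts[5].strip().lower()
            if flag not in ("0", "1", "true", "false"):
                raise ValueError(
                    f"{path}: line {lineno}: obligate_parasite must be "
                    f"boolean-like, got {parts[5]!r}"
                )
            records.append(
                GenomeRecord(
                    genome_id=parts[0],
                    domain=parts[1],
                    clade=parts[2],
                    genus=parts[3],
                    gene_count=int(parts[4]),
                    obligate_parasite=flag in ("1", "true"),
                )
            )
    return Taxonomy(records)


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "genome_id\tdomain\tclade\tgenus\tgene_count\tobligate_parasite\n"
        )
        for rec in tax.records:
            fh.write(
                f"{rec.genome_id}\t{rec.domain}\t{rec.clade}\t{rec.genus}\t"
                f"{rec.gene_count}\t{int(rec.obligate_parasite)}\n"
            )


def filter_genomes(tax: Taxonomy, config: FilterConfig | None = None) -> Taxonomy:
    """Drop obligate parasites and reduced genomes (< ``min_genes`` genes).

    Genera and clades left empty are pruned from all downstream
    denominators.  Idempotent; counts removed per reason are logged.
    """
    if config is None:
        config = FilterConfig()
    kept: list[GenomeRecord] = []
    n_parasite = n_reduced = 0
    for rec in tax:
        if rec.obligate_parasite:
            n_parasite += 1
            continue
        if rec.gene_count < config.min_genes:
            n_reduced += 1
            continue
        kept.append(rec)
    logger.info(
        "genome filter: kept %d of %d (removed %d obligate parasites, "
        "%d reduced genomes with < %d genes)",
        len(kept), len(tax), n_parasite, n_reduced, config.min_genes,
    )
    if not kept:
        logger.warning("genome filter removed every genome")
    return Taxonomy(kept)
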