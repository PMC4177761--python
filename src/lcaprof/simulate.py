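"""Synthetic genome scans with known ground truth.

The generator emulates the statistical structure the distribution
analysis assumes: a balanced three-domain taxonomy
(clades × genera × genomes), binary enzyme presence produced by
ancestral presence with per-lineage loss, domain-restricted innovation,
horizontal-transfer noise, and parasite genome reduction.  It then
inverts the annotation stage, emitting BLAST-tabular hit files whose
E-values and profile coverages straddle the significance thresholds, so
the whole pipeline — parsing, filtering, binarization, averaging,
classification, LCA attribution — can be exercised end to end against a
known answer.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``ScenarioConfig.seed``; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .hits import FilterConfig, ProfileDef
from .taxonomy import DOMAINS, GenomeRecord, Taxonomy

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "simulate_taxonomy",
    "simulate_evolution",
    "emit_hits",
    "default_catalogue",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic evolutionary scenario.

    loss_prob:
        per-genome probability that an ancestral enzyme was lost.
    genus_loss_prob:
        optional lineage-correlated loss: whole genera lose the enzyme
        with this probability before genome-level loss is applied —
        clustered loss is the realistic stressor for the clade rule.
    domain_gains:
        enzyme -> (domain, gain probability); the enzyme arises only in
        genomes of that domain, never ancestrally.
    hgt_rate:
        per-cell probability that an absent enzyme is acquired
        horizontally (uniform noise).
    parasite_fraction:
        fraction of genomes flagged obligate parasites; those genomes
        also draw a reduced gene count (< 1000 genes).
    decoy_prob:
        probability that an absent genome × profile cell emits a decoy
        hit failing at least one significance threshold.
    """

    n_clades_per_domain: int = 4
    n_genera_per_clade: int = 3
    n_genomes_per_genus: int = 3
    ancestral_enzymes: tuple[str, ...] = ()
    loss_prob: float = 0.1
    genus_loss_prob: float = 0.0
    domain_gains: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    hgt_rate: float = 0.0
    parasite_fraction: float = 0.0
    decoy_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "loss_prob",
            "genus_loss_prob",
            "hgt_rate",
            "parasite_fraction",
            "decoy_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_clades_per_domain",
            "n_genera_per_clade",
            "n_genomes_per_genus",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        overlap = set(self.ancestral_enzymes) & set(self.domain_gains)
        if overlap:
            raise ValueError(
                f"enzymes listed both ancestral and domain-gain: {sorted(overlap)}"
            )
        for enz, (domain, prob) in self.domain_gains.items():
            if domain not in DOMAINS:
                raise ValueError(f"domain_gains[{enz!r}]: unknown domain {domain!r}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"domain_gains[{enz!r}]: probability {prob}")

    @property
    def enzymes(self) -> list[str]:
        return sorted(set(self.ancestral_enzymes) | set(self.domain_gains))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for scoring recovery."""

    truly_ancestral: pd.Series  # bool per enzyme
    pre_noise_presence: pd.DataFrame  # genome × enzyme before HGT


def _rng(cfg: ScenarioConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def simulate_taxonomy(cfg: ScenarioConfig) -> Taxonomy:
    """Balanced domain/clade/genus/genome hierarchy with deterministic ids.

    ``parasite_fraction`` of genomes (chosen at random) are flagged
    obligate parasites with gene counts below 1000; the rest draw gene
    counts in [1500, 6000].
    """
    rng = _rng(cfg, 1)
    records: list[GenomeRecord] = []
    ids: list[tuple[str, str, str, str]] = []
    for domain in DOMAINS:
        dcode = domain[:3].lower()
        for c in range(cfg.n_clades_per_domain):
            clade = f"{dcode}_c{c + 1:02d}"
            for g in range(cfg.n_genera_per_clade):
                genus = f"{clade}_g{g + 1:02d}"
                for s in range(cfg.n_genomes_per_genus):
                    genome = f"{genus}_s{s + 1:02d}"
                    ids.append((genome, domain, clade, genus))
    n = len(ids)
    n_parasites = int(round(cfg.parasite_fraction * n))
    parasite_idx = set(
        rng.choice(n, size=n_parasites, replace=False).tolist()
    ) if n_parasites else set()
    gene_counts = rng.integers(1500, 6001, size=n)
    reduced_counts = rng.integers(400, 1000, size=n)
    for i, (genome, domain, clade, genus) in enumerate(ids):
        parasite = i in parasite_idx
        records.append(
            GenomeRecord(
                genome_id=genome,
                domain=domain,
                clade=clade,
                genus=genus,
                gene_count=int(reduced_counts[i] if parasite else gene_counts[i]),
                obligate_parasite=parasite,
            )
        )
    return Taxonomy(records)


def simulate_evolution(
    tax: Taxonomy, cfg: ScenarioConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Evolve presence/absence over the taxonomy.

    Ancestral enzymes start present everywhere and are lost per genome
    with ``loss_prob`` (optionally whole genera first with
    ``genus_loss_prob``); domain-gain enzymes appear only within their
    domain with the stated probability; HGT then flips absent cells on
    with ``hgt_rate``.
    """
    rng = _rng(cfg, 2)
    genomes = tax.genome_ids
    enzymes = cfg.enzymes
    n_g, n_e = len(genomes), len(enzymes)
    presence = np.zeros((n_g, n_e), dtype=np.int8)
    domain_of = np.array([tax[g].domain for g in genomes])
    genus_of = np.array([tax[g].genus for g in genomes])
    genera = sorted(set(genus_of))
    for j, enz in enumerate(enzymes):
        if enz in cfg.domain_gains:
            domain, prob = cfg.domain_gains[enz]
            in_domain = domain_of == domain
            gained = rng.random(n_g) < prob
            presence[in_domain & gained, j] = 1
        else:
            keep = np.ones(n_g, dtype=bool)
            if cfg.genus_loss_prob > 0:
                lost_genera = {
                    gn
                    for gn in genera
                    if rng.random() < cfg.genus_loss_prob
                }
                keep &= ~np.isin(genus_of, list(lost_genera))
            keep &= rng.random(n_g) >= cfg.loss_prob
            presence[keep, j] = 1
    pre_noise = pd.DataFrame(
        presence.copy(),
        index=pd.Index(genomes, name="genome_id"),
        columns=pd.Index(enzymes, name="profile_id"),
    )
    if cfg.hgt_rate > 0:
        hgt = (presence == 0) & (rng.random((n_g, n_e)) < cfg.hgt_rate)
        presence[hgt] = 1
    matrix = pd.DataFrame(
        presence,
        index=pre_noise.index.copy(),
        columns=pre_noise.columns.copy(),
    )
    truly = pd.Series(
        {e: e in set(cfg.ancestral_enzymes) for e in enzymes}, dtype=bool
    )
    truly.index.name = "enzyme"
    return matrix, GroundTruth(truly_ancestral=truly, pre_noise_presence=pre_noise)


def default_catalogue(
    enzymes: list[str], profile_length: int = 400
) -> dict[str, ProfileDef]:
    """One single-role profile per enzyme id (profile == enzyme)."""
    return {
        e: ProfileDef(
            profile_id=e,
            ec_number=e if e.count(".") == 3 else f"9.9.9.{i + 1}",
            role="single",
            profile_length=profile_length,
        )
        for i, e in enumerate(enzymes)
    }


def _min_passing_span(length: int, coverage_min: float) -> int:
    """Smallest integer span whose float coverage span/length passes."""
    s = min(length, max(1, math.ceil(coverage_min * length)))
    while s <= length and s / length < coverage_min:
        s += 1
    while s > 1 and (s - 1) / length >= coverage_min:
        s -= 1
    return s


def _sample_true_hit(
    rng: np.random.Generator, length: int, config: FilterConfig
) -> tuple[int, int, float]:
    """Aligned span and E-value guaranteed to pass both thresholds."""
    min_span = _min_passing_span(length, config.coverage_min)
    span = int(rng.integers(min_span, length + 1))
    start = int(rng.integers(1, length - span + 2))
    evalue = 10.0 ** rng.uniform(-40.0, math.log10(config.evalue_max))
    evalue = min(evalue, config.evalue_max)
    return start, start + span - 1, evalue


def _sample_decoy_hit(
    rng: np.random.Generator, length: int, config: FilterConfig
) -> tuple[int, int, float]:
    """A hit failing at least one threshold (straddling the boundary)."""
    min_span = _min_passing_span(length, config.coverage_min)
    lo = max(1, math.ceil(0.30 * length))
    if rng.random() < 0.5 and lo < min_span:
        # good E-value, short alignment: coverage in [~0.30, coverage_min)
        span = int(rng.integers(lo, min_span))
        evalue = 10.0 ** rng.uniform(-40.0, math.log10(config.evalue_max))
        evalue = min(evalue, config.evalue_max)
    else:
        # good coverage, E-value just above threshold: (evalue_max, 1e-6]
        span = int(rng.integers(min_span, length + 1))
        log_max = math.log10(config.evalue_max)
        evalue = 10.0 ** rng.uniform(log_max + 0.05, -6.0)
    start = int(rng.integers(1, length - span + 2))
    return start, start + span - 1, evalue


def emit_hits(
    m: pd.DataFrame,
    catalogue: Mapping[str, ProfileDef],
    cfg: ScenarioConfig,
    outdir: str | Path,
    config: FilterConfig | None = None,
) -> Path:
    """Write per-genome BLAST-tabular hit files inverting ``m``.

    Every present cell emits at least one hit passing both thresholds;
    absent cells emit a decoy failing at least one with probability
    ``cfg.decoy_prob``.  Filtering and re-binarizing the emitted files
    reproduces ``m`` exactly.  Returns the manifest path
    (genome_id <tab> file path, one row per genome).
    """
    if config is None:
        config = FilterConfig()
    rng = _rng(cfg, 3)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with manifest.open("w") as mf:
        mf.write("genome_id\tpath\n")
        for genome in m.index:
            fname = outdir / f"{genome}.hits.tsv"
            with fname.open("w") as fh:
                q = 0
                for profile_id in m.columns:
                    pdef = catalogue[profile_id]
                    length = pdef.profile_length
                    present = bool(m.at[genome, profile_id])
                    if present:
                        start, end, evalue = _sample_true_hit(rng, length, config)
                    elif rng.random() < cfg.decoy_prob:
                        start, end, evalue = _sample_decoy_hit(rng, length, config)
                    else:
                        continue
                    q += 1
                    span = end - start + 1
                    ident = round(float(rng.uniform(25.0, 95.0)), 1)
                    bitscore = round(float(rng.uniform(50.0, 900.0)), 1)
                    fh.write(
                        f"{genome}_q{q:04d}\t{profile_id}\t{ident}\t{span}\t"
                        f"{int(span * 0.2)}\t1\t1\t{span}\t{start}\t{end}\t"
                        f"{evalue:.3e}\t{bitscore}\n"
                    )
            mf.write(f"{genome}\t{fname.name}\n")
    return manifest


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Parse a manifest TSV into (genome_id, absolute hit-file path) pairs."""
    path = Path(path)
    out: list[tuple[str, Path]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.lstrip("#") for h in header] != ["genome_id", "path"]:
            raise ValueError(f"{path}: bad manifest header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            genome_id, rel = line.split("\t")
            out.append((genome_id, path.parent / rel))
    return out
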