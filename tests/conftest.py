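from __future__ import annotations

from fractions import Fraction

import pandas as pd
import pytest

from lcaprof.hits import FilterConfig, ProfileDef, ProfileHit
from lcaprof.taxonomy import GenomeRecord, Taxonomy


def make_hit(
    genome="g1",
    query="q1",
    profile="P1",
    evalue=1e-20,
    bitscore=100.0,
    profile_start=1,
    profile_end=100,
    query_start=1,
    query_end=100,
    percent_identity=50.0,
    align_length=None,
) -> ProfileHit:
    if align_length is None:
        align_length = profile_end - profile_start + 1
    return ProfileHit(
        genome_id=genome,
        query_id=query,
        profile_id=profile,
        percent_identity=percent_identity,
        align_length=align_length,
        profile_start=profile_start,
        profile_end=profile_end,
        query_start=query_start,
        query_end=query_end,
        evalue=evalue,
        bitscore=bitscore,
    )


@pytest.fixture
def small_catalogue() -> dict[str, ProfileDef]:
    """Two singles, one subunit pair (AND) and one analog pair (OR)."""
    defs = [
        ProfileDef("P1", "1.1.1.1", "single", "", "sfA", 100),
        ProfileDef("P2", "2.2.2.2", "single", "", "sfB", 200),
        ProfileDef("SU1a", "6.3.5.3", "subunit", "S1", "sfC", 150),
        ProfileDef("SU1b", "6.3.5.3", "subunit", "S1", "sfD", 300),
        ProfileDef("AN1a", "2.1.2.2", "analog", "AN1", "sfE", 120),
        ProfileDef("AN1b", "2.1.2.2", "analog", "AN1", "sfF", 240),
    ]
    return {d.profile_id: d for d in defs}


def build_taxonomy(shape: dict[str, dict[str, dict[str, int]]]) -> Taxonomy:
    """shape: domain -> clade -> genus -> number of genomes."""
    records = []
    for domain, clades in shape.items():
        for clade, genera in clades.items():
            for genus, n in genera.items():
                for i in range(n):
                    records.append(
                        GenomeRecord(
                            genome_id=f"{genus}_s{i + 1}",
                            domain=domain,
                            clade=clade,
                            genus=genus,
                            gene_count=2000,
                        )
                    )
    return Taxonomy(records)


@pytest.fixture
def small_taxonomy() -> Taxonomy:
    return build_taxonomy(
        {
            "Bacteria": {"bc1": {"bg1": 3, "bg2": 1}, "bc2": {"bg3": 2}},
            "Archaea": {"ac1": {"ag1": 2}},
            "Eukarya": {"ec1": {"eg1": 1}},
        }
    )


def nested_mean_oracle(
    presence: pd.DataFrame, tax: Taxonomy
) -> dict[tuple[str, str], Fraction]:
    """Brute-force two-step average: (clade, enzyme) -> exact Fraction.

    Independent of the pipeline: enumerates genomes per genus and genera
    per clade directly from the records.
    """
    out: dict[tuple[str, str], Fraction] = {}
    clades = {rec.clade for rec in tax}
    for clade in clades:
        genera = sorted({r.genus for r in tax if r.clade == clade})
        for enzyme in presence.columns:
            genus_means = []
            for genus in genera:
                genomes = sorted(
                    r.genome_id for r in tax if r.genus == genus
                )
                genomes = [g for g in genomes if g in presence.index]
                if not genomes:
                    continue
                vals = [Fraction(int(presence.at[g, enzyme])) for g in genomes]
                genus_means.append(sum(vals) / len(vals))
            out[(clade, enzyme)] = sum(genus_means) / len(genus_means)
    return out


@pytest.fixture
def default_config() -> FilterConfig:
    return FilterConfig()
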