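"""Presence/absence matrices, two-step taxonomic averaging, and LCA calls.

The central statistic is a *normalized* taxonomic distribution: raw
genome-level presence/absence is averaged per genus, the genus values are
averaged per clade, and an enzyme's spread within a cellular domain is
the fraction of the domain's clades that contain it.  The two-step mean
gives each genus unit weight regardless of how many genomes were
sequenced for it, removing genome-sampling redundancy (one heavily
sequenced genus cannot dominate its clade).

An enzyme *widely distributed* in a domain is one present in strictly
more than half of that domain's clades; an enzyme widely distributed in
all three cellular domains is attributed to the last common ancestor
(LCA) of Bacteria, Archaea and Eukarya.

Enzymes are identified by EC number.  One EC may be served by several
profiles: subunits of a complex (all required), analogous non-homologous
families or paralogs (any one suffices).  :func:`ec_presence` resolves
profile-level presence to EC-level presence under those semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .hits import FilterConfig, ProfileDef, ProfileHit
from .taxonomy import DOMAINS, Taxonomy

__all__ = [
    "AverageMatrix",
    "DistributionSummary",
    "build_presence",
    "genus_average",
    "clade_average",
    "classify",
    "infer_lca",
    "ec_presence",
]


@dataclass(frozen=True)
class AverageMatrix:
    """Real-valued averages in [0, 1] at genus or clade level.

    ``values`` is enzymes/profiles in columns, taxa in rows.  With
    ``exact=True`` upstream, cells hold :class:`fractions.Fraction`
    instead of floats and all identities are exact.
    """

    values: pd.DataFrame
    level: str  # "genus" | "clade"

    def __post_init__(self) -> None:
        if self.level not in ("genus", "clade"):
            raise ValueError(f"unknown level {self.level!r}")
        vals = self.values.to_numpy()
        if vals.size and ((vals < 0).any() or (vals > 1).any()):
            raise ValueError("average values must lie in [0, 1]")


@dataclass(frozen=True)
class DistributionSummary:
    """Per-(enzyme, domain) clade fractions and distribution classes.

    ``table`` columns: enzyme, domain, n_clades_present, n_clades,
    clade_fraction, dist_class.  ``dist_class`` is one of ``widely``,
    ``partially``, ``sparsely``, ``absent``.
    """

    table: pd.DataFrame

    def fraction(self, enzyme: str, domain: str):
        row = self.table[
            (self.table["enzyme"] == enzyme) & (self.table["domain"] == domain)
        ]
        if row.empty:
            raise KeyError((enzyme, domain))
        return row["clade_fraction"].iloc[0]

    def dist_class(self, enzyme: str, domain: str) -> str:
        row = self.table[
            (self.table["enzyme"] == enzyme) & (self.table["domain"] == domain)
        ]
        if row.empty:
            raise KeyError((enzyme, domain))
        return row["dist_class"].iloc[0]

    @property
    def enzymes(self) -> list[str]:
        return sorted(self.table["enzyme"].unique())


def build_presence(
    filtered_hits: Iterable[ProfileHit],
    tax: Taxonomy,
    catalogue: Mapping[str, ProfileDef],
) -> pd.DataFrame:
    """Binary genome × profile matrix: 1 iff >= 1 retained hit.

    Rows cover *every* genome in ``tax`` (all-zero rows for genomes
    without hits); columns cover every profile in the catalogue.
    """
    genomes = tax.genome_ids
    profiles = sorted(catalogue)
    m = pd.DataFrame(
        np.zeros((len(genomes), len(profiles)), dtype=np.int8),
        index=pd.Index(genomes, name="genome_id"),
        columns=pd.Index(profiles, name="profile_id"),
    )
    for hit in filtered_hits:
        if hit.genome_id not in tax:
            raise KeyError(
                f"hit from genome {hit.genome_id!r} absent from the taxonomy"
            )
        if hit.profile_id not in catalogue:
            raise KeyError(f"hit to unknown profile {hit.profile_id!r}")
        m.at[hit.genome_id, hit.profile_id] = 1
    return m


def _group_mean(
    m: pd.DataFrame, groups: Mapping[str, list[str]], exact: bool
) -> pd.DataFrame:
    keys = sorted(groups)
    if exact:
        data = {}
        for key in keys:
            members = m.loc[groups[key]]
            n = len(members)
            data[key] = [
                sum(Fraction(v) for v in members[col]) / n for col in m.columns
            ]
        out = pd.DataFrame.from_dict(
            data, orient="index", columns=m.columns, dtype=object
        )
    else:
        out = pd.DataFrame(
            {key: m.loc[groups[key]].mean(axis=0) for key in keys}
        ).T
        out.columns = m.columns
    out.index.name = None
    return out


def genus_average(
    m: pd.DataFrame, tax: Taxonomy, exact: bool = False
) -> AverageMatrix:
    """First normalization step: unweighted mean presence per genus."""
    unknown = set(m.index) - set(tax.genome_ids)
    if unknown:
        raise KeyError(f"matrix rows not in taxonomy: {sorted(unknown)}")
    groups = {
        genus: [g for g in genomes if g in m.index]
        for genus, genomes in tax.genus_genomes.items()
    }
    groups = {k: v for k, v in groups.items() if v}
    values = _group_mean(m, groups, exact)
    values.index.name = "genus"
    return AverageMatrix(values=values, level="genus")


def clade_average(g: AverageMatrix, tax: Taxonomy, exact: bool = False) -> AverageMatrix:
    """Second step: unweighted mean of genus averages per clade.

    Each genus carries weight 1 regardless of its genome count, so a
    clade of genera with 9 and 1 genomes and genus values 1.0 and 0.0
    averages to 0.5, not 0.9.
    """
    if g.level != "genus":
        raise ValueError("clade_average expects a genus-level matrix")
    groups = {
        clade: [gn for gn in genera if gn in g.values.index]
        for clade, genera in tax.clade_genera.items()
    }
    groups = {k: v for k, v in groups.items() if v}
    values = _group_mean(g.values, groups, exact)
    values.index.name = "clade"
    return AverageMatrix(values=values, level="clade")


def _class_of(fraction, config: FilterConfig) -> str:
    if fraction == 0:
        return "absent"
    if fraction > config.wide_fraction:
        return "widely"
    if fraction <= config.sparse_fraction:
        return "sparsely"
    return "partially"


def classify(
    c: AverageMatrix, tax: Taxonomy, config: FilterConfig | None = None
) -> DistributionSummary:
    """Per-domain distribution class from clade-level averages.

    A clade contains an enzyme when its average exceeds
    ``presence_cutoff`` (default 0: any retained member genus suffices);
    the enzyme is *widely* distributed in a domain when the fraction of
    containing clades strictly exceeds ``wide_fraction``.
    """
    if c.level != "clade":
        raise ValueError("classify expects a clade-level matrix")
    if config is None:
        config = FilterConfig()
    rows = []
    for domain in tax.domains():
        clades = [cl for cl in tax.domain_clades[domain] if cl in c.values.index]
        if not clades:
            raise ValueError(
                f"domain {domain!r} has no clades left after filtering"
            )
        sub = c.values.loc[clades]
        for enzyme in c.values.columns:
            present = int(sum(1 for v in sub[enzyme] if v > config.presence_cutoff))
            frac = Fraction(present, len(clades))
            rows.append(
                {
                    "enzyme": enzyme,
                    "domain": domain,
                    "n_clades_present": present,
                    "n_clades": len(clades),
                    "clade_fraction": float(frac),
                    "dist_class": _class_of(frac, config),
                }
            )
    return DistributionSummary(table=pd.DataFrame(rows))


def infer_lca(summary: DistributionSummary) -> pd.Series:
    """LCA verdict per enzyme: widely distributed in all three domains.

    Raises when an enzyme lacks a classification for any of the three
    cellular domains — an LCA call is only meaningful across all three.
    """
    verdicts = {}
    t = summary.table
    for enzyme in summary.enzymes:
        sub = t[t["enzyme"] == enzyme]
        classes = dict(zip(sub["domain"], sub["dist_class"]))
        missing = [d for d in DOMAINS if d not in classes]
        if missing:
            raise ValueError(
                f"enzyme {enzyme!r} has no classification for domain(s) "
                f"{missing}; all of {DOMAINS} are required"
            )
        verdicts[enzyme] = all(classes[d] == "widely" for d in DOMAINS)
    s = pd.Series(verdicts, dtype=bool).sort_index()
    s.index.name = "enzyme"
    s.name = "lca_verdict"
    return s


def ec_presence(
    m: pd.DataFrame, catalogue: Mapping[str, ProfileDef]
) -> pd.DataFrame:
    """Collapse a genome × profile matrix to genome × EC.

    Subunit groups require *all* member profiles (a complex is functional
    only when complete); analog/paralog groups and singles require *any*
    member.  An EC is present when any of its contributing groups is.
    """
    by_ec: dict[str, list[ProfileDef]] = {}
    for p in catalogue.values():
        by_ec.setdefault(p.ec_number, []).append(p)
    cols = {}
    for ec in sorted(by_ec):
        members = by_ec[ec]
        if not members:
            raise ValueError(f"EC {ec} has no profiles")
        contributions = []
        subunit_groups: dict[str, list[ProfileDef]] = {}
        for p in members:
            if p.profile_id not in m.columns:
                raise KeyError(
                    f"profile {p.profile_id!r} missing from presence matrix"
                )
            if p.role == "subunit":
                subunit_groups.setdefault(p.group_id, []).append(p)
            else:
                contributions.append(m[p.profile_id].to_numpy(dtype=bool))
        for group in subunit_groups.values():
            stack = np.column_stack(
                [m[p.profile_id].to_numpy(dtype=bool) for p in group]
            )
            contributions.append(stack.all(axis=1))
        cols[ec] = np.column_stack(contributions).any(axis=1).astype(np.int8)
    out = pd.DataFrame(cols, index=m.index)
    out.columns.name = "ec_number"
    return out
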