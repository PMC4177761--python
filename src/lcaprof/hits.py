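"""Profile-search hit tables: parsing, coverage, and best-hit filtering.

Hits come from an RPS-BLAST-style search of proteomes against a library of
enzyme-family profiles (PSSMs), written in the standard 12-column BLAST
tabular layout (``-outfmt 6``) with the *subject* being a profile.  An
optional 13th column carries the genome identifier; otherwise the genome is
supplied per file (via a manifest).

Filtering follows the conventional annotation criteria for this kind of
scan: a hit is significant when its expectation value is at most
``evalue_max`` (default 1e-10) and its alignment covers at least
``coverage_min`` (default 55%) of the *profile* length; among surviving
hits only the best one per (genome, query, profile) is kept — or per
(genome, query) in exclusive mode, where each protein is assigned to a
single profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileHit",
    "ProfileDef",
    "FilterConfig",
    "read_hits",
    "read_catalogue",
    "profile_coverage",
    "filter_hits",
]

#: column order of BLAST tabular output ("-outfmt 6")
BLAST6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

VALID_ROLES = frozenset({"single", "subunit", "analog", "paralog"})


@dataclass(frozen=True, slots=True)
class ProfileHit:
    """A single alignment of a query protein against an enzyme profile."""

    genome_id: str
    query_id: str
    profile_id: str
    percent_identity: float
    align_length: int
    profile_start: int  # 1-based inclusive, on the profile
    profile_end: int
    query_start: int
    query_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.profile_start > self.profile_end:
            raise ValueError(
                f"profile_start {self.profile_start} > profile_end "
                f"{self.profile_end} for query {self.query_id!r}"
            )
        if self.query_start > self.query_end:
            raise ValueError(
                f"query_start {self.query_start} > query_end "
                f"{self.query_end} for query {self.query_id!r}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue!r}")
        if self.align_length < 1:
            raise ValueError(f"align_length {self.align_length} < 1")


@dataclass(frozen=True, slots=True)
class ProfileDef:
    """Identity of one enzyme profile in the catalogue.

    ``role`` partitions profiles into four kinds: ``single`` (the only
    family for its EC), ``subunit`` (one component of a complex; the EC is
    achieved only when *all* members of its ``group_id`` are present),
    ``analog`` (a non-homologous family catalysing the same EC; *any*
    member suffices) and ``paralog`` (related families sharing an EC; any
    member suffices).
    """

    profile_id: str
    ec_number: str
    role: str
    group_id: str = ""
    superfamily: str = ""
    profile_length: int = 1

    def __post_init__(self) -> None:
        if self.profile_length < 1:
            raise ValueError(
                f"profile {self.profile_id!r}: profile_length must be >= 1"
            )
        fields = self.ec_number.split(".")
        if len(fields) != 4 or not all(fields):
            raise ValueError(
                f"profile {self.profile_id!r}: EC number {self.ec_number!r} "
                "must have 4 dot-separated fields"
            )
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"profile {self.profile_id!r}: unknown role {self.role!r}"
            )
        if self.role in ("subunit", "analog", "paralog") and not self.group_id:
            raise ValueError(
                f"profile {self.profile_id!r}: role {self.role!r} requires a group_id"
            )


@dataclass(frozen=True, slots=True)
class FilterConfig:
    """Thresholds applied across the pipeline.

    evalue_max:
        maximum expectation value for a significant hit (inclusive).
    coverage_min:
        minimum aligned fraction of the profile (inclusive).
    min_genes:
        genomes with fewer genes are treated as reduced and excluded.
    wide_fraction:
        an enzyme is *widely* distributed in a domain when present in
        strictly more than this fraction of the domain's clades.
    presence_cutoff:
        a clade counts as containing an enzyme when its clade-level
        average exceeds this value (default 0: any member genus suffices).
    sparse_fraction:
        clade fractions in (0, sparse_fraction] are labelled *sparsely*;
        between that and wide_fraction, *partially*.  A reporting
        convention — no inference depends on the sparse/partial boundary.
    """

    evalue_max: float = 1e-10
    coverage_min: float = 0.55
    min_genes: int = 1000
    wide_fraction: float = 0.5
    presence_cutoff: float = 0.0
    sparse_fraction: float = 0.1
    exclusive_best_hit: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_min <= 1.0:
            raise ValueError("coverage_min must lie in [0, 1]")
        if not 0.0 <= self.presence_cutoff < 1.0:
            raise ValueError("presence_cutoff must lie in [0, 1)")
        if not 0.0 <= self.sparse_fraction <= self.wide_fraction <= 1.0:
            raise ValueError("need 0 <= sparse_fraction <= wide_fraction <= 1")
        if self.evalue_max < 0:
            raise ValueError("evalue_max must be non-negative")
        if self.min_genes < 0:
            raise ValueError("min_genes must be non-negative")


class MalformedRowError(ValueError):
    """Raised (or collected) for rows that violate the tabular contract."""


def _parse_row(
    parts: Sequence[str], lineno: int, genome_id: str | None
) -> ProfileHit:
    if len(parts) == 13:
        row_genome = parts[12]
    elif len(parts) == 12:
        if genome_id is None:
            raise MalformedRowError(
                f"line {lineno}: 12-column row but no genome_id supplied"
            )
        row_genome = genome_id
    else:
        raise MalformedRowError(
            f"line {lineno}: expected 12 or 13 tab-separated columns, "
            f"got {len(parts)}"
        )
    try:
        hit = ProfileHit(
            genome_id=row_genome,
            query_id=parts[0],
            profile_id=parts[1],
            percent_identity=float(parts[2]),
            align_length=int(parts[3]),
            query_start=int(parts[6]),
            query_end=int(parts[7]),
            profile_start=int(parts[8]),
            profile_end=int(parts[9]),
            evalue=float(parts[10]),
            bitscore=float(parts[11]),
        )
    except ValueError as exc:
        raise MalformedRowError(f"line {lineno}: {exc}") from exc
    if not math.isfinite(hit.evalue):
        raise MalformedRowError(f"line {lineno}: non-finite E-value")
    return hit


def read_hits(
    path: str | Path,
    genome_id: str | None = None,
    strict: bool = False,
) -> list[ProfileHit]:
    """Read a BLAST-tabular hit file into :class:`ProfileHit` records.

    Rows appear in file order.  Malformed rows (wrong column count,
    non-numeric scores, reversed coordinates) are rejected with a logged
    diagnostic naming the line number, or raise when ``strict`` is true.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"hit table not found: {path}")
    hits: list[ProfileHit] = []
    bad = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                hits.append(_parse_row(parts, lineno, genome_id))
            except MalformedRowError as exc:
                if strict:
                    raise
                bad += 1
                logger.warning("%s: rejected row — %s", path.name, exc)
    if not hits:
        logger.warning("%s: no hits parsed (%d rejected rows)", path.name, bad)
    return hits


def read_catalogue(path: str | Path) -> dict[str, ProfileDef]:
    """Read the profile catalogue TSV into a ``profile_id -> ProfileDef`` map.

    Expected columns: profile_id, ec_number, role, group_id, superfamily,
    profile_length.  Every subunit/analog/paralog group must contain at
    least two profiles.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"profile catalogue not found: {path}")
    defs: dict[str, ProfileDef] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "profile_id",
            "ec_number",
            "role",
            "group_id",
            "superfamily",
            "profile_length",
        ]
        if [h.lstrip("#") for h in header] != expected:
            raise ValueError(
                f"{path}: catalogue header {header} != expected {expected}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            pd_ = ProfileDef(
                profile_id=parts[0],
                ec_number=parts[1],
                role=parts[2],
                group_id=parts[3],
                superfamily=parts[4],
                profile_length=int(parts[5]),
            )
            if pd_.profile_id in defs:
                raise ValueError(
                    f"{path}: duplicate profile_id {pd_.profile_id!r}"
                )
            defs[pd_.profile_id] = pd_
    _check_groups(defs.values())
    return defs


def _check_groups(catalogue: Iterable[ProfileDef]) -> None:
    from collections import Counter

    counts: Counter[tuple[str, str]] = Counter()
    for p in catalogue:
        if p.role in ("subunit", "analog", "paralog"):
            counts[(p.role, p.group_id)] += 1
    lonely = [k for k, n in counts.items() if n < 2]
    if lonely:
        raise ValueError(
            "groups with fewer than 2 member profiles: "
            + ", ".join(f"{role}:{gid}" for role, gid in sorted(lonely))
        )


def profile_coverage(hit: ProfileHit, profile_length: int) -> float:
    """Fraction of the profile covered by the hit's aligned span.

    The span is 1-based inclusive, so a hit spanning 23..77 of a
    100-residue profile covers (77 - 23 + 1)/100 = 0.55.
    """
    if hit.profile_end > profile_length:
        raise ValueError(
            f"hit on profile {hit.profile_id!r} ends at {hit.profile_end} "
            f"beyond profile length {profile_length}"
        )
    return (hit.profile_end - hit.profile_start + 1) / profile_length


def _best_hit_key(hit: ProfileHit) -> tuple:
    # lower evalue wins; ties -> higher bitscore, lower profile_start,
    # then lexicographic profile_id so output is order-independent
    return (hit.evalue, -hit.bitscore, hit.profile_start, hit.profile_id)


def filter_hits(
    hits: Iterable[ProfileHit],
    catalogue: Mapping[str, ProfileDef],
    config: FilterConfig | None = None,
) -> list[ProfileHit]:
    """Apply significance thresholds and best-hit selection.

    Retains hits with ``evalue <= evalue_max`` *and* profile coverage
    ``>= coverage_min`` (both inclusive), then keeps the single best
    survivor per (genome, query, profile) — or per (genome, query) when
    ``config.exclusive_best_hit`` is set, so each protein maps to exactly
    one profile.  Output order is deterministic (sorted by genome, query,
    profile).
    """
    if config is None:
        config = FilterConfig()
    best: dict[tuple, ProfileHit] = {}
    for hit in hits:
        pdef = catalogue.get(hit.profile_id)
        if pdef is None:
            raise KeyError(
                f"hit references unknown profile {hit.profile_id!r}"
            )
        if hit.evalue > config.evalue_max:
            continue
        if profile_coverage(hit, pdef.profile_length) < config.coverage_min:
            continue
        if config.exclusive_best_hit:
            key = (hit.genome_id, hit.query_id)
        else:
            key = (hit.genome_id, hit.query_id, hit.profile_id)
        incumbent = best.get(key)
        if incumbent is None or _best_hit_key(hit) < _best_hit_key(incumbent):
            best[key] = hit
    return [
        best[k]
        for k in sorted(
            best, key=lambda k: (k[0], k[1], best[k].profile_id)
        )
    ]
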