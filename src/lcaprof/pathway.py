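"""Reaction graphs for nucleotide metabolism and route-ancestry queries.

A pathway is a directed metabolite graph whose edges are enzymatic steps.
Each step carries a set of alternative EC numbers — any one of which
catalyses the reaction — plus free-form tags (``folate_dependent``,
``archaea_specific``, ``salvage``, ``de_novo``, ``nonenzymatic`` ...).

Projecting per-EC LCA verdicts onto steps gives each step an ancestry
label: ``lca`` when any alternative EC is LCA-attributed, ``non_lca``
when every resolvable alternative is not, and ``undetermined`` when no
alternative is true and at least one is unresolved (no verdict) or the
step is non-enzymatic.  A route is ancestrally complete when a directed
path from source to target exists using only steps of the required
label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "PathwayStep",
    "PathwayGraph",
    "read_pathway",
    "write_pathway",
    "annotate_steps",
    "route_complete",
]

ANCESTRY_LABELS = ("lca", "non_lca", "undetermined")


def _check_ec(ec: str) -> str:
    parts = ec.split(".")
    if len(parts) != 4 or not all(parts):
        raise ValueError(f"EC number {ec!r} must have 4 dot-separated fields")
    return ec


@dataclass(frozen=True)
class PathwayStep:
    """One enzymatic step: substrates -> products via alternative ECs."""

    step_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    ec_alternatives: frozenset[str]
    reversible: bool = False
    tags: frozenset[str] = frozenset()
    ancestry: str = "undetermined"

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(f"step {self.step_id!r}: empty substrates/products")
        if set(self.substrates) == set(self.products):
            raise ValueError(
                f"step {self.step_id!r}: substrates equal products"
            )
        if not self.ec_alternatives and "nonenzymatic" not in self.tags:
            raise ValueError(
                f"step {self.step_id!r}: enzymatic step needs >= 1 EC"
            )
        for ec in self.ec_alternatives:
            _check_ec(ec)
        if self.ancestry not in ANCESTRY_LABELS:
            raise ValueError(f"step {self.step_id!r}: ancestry {self.ancestry!r}")


class PathwayGraph:
    """Collection of steps over a shared metabolite namespace."""

    def __init__(self, steps: Iterable[PathwayStep]):
        self.steps: dict[str, PathwayStep] = {}
        for step in steps:
            if step.step_id in self.steps:
                raise ValueError(f"duplicate step_id {step.step_id!r}")
            self.steps[step.step_id] = step

    @property
    def metabolites(self) -> list[str]:
        mets: set[str] = set()
        for step in self.steps.values():
            mets.update(step.substrates)
            mets.update(step.products)
        return sorted(mets)

    @property
    def ecs(self) -> list[str]:
        out: set[str] = set()
        for step in self.steps.values():
            out.update(step.ec_alternatives)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.steps)

    def __getitem__(self, step_id: str) -> PathwayStep:
        return self.steps[step_id]

    def to_nx(self, require: str | None = None) -> nx.MultiDiGraph:
        """Metabolite graph; with ``require``, only steps of that ancestry."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.metabolites)
        for step in self.steps.values():
            if require is not None and step.ancestry != require:
                continue
            for s in step.substrates:
                for p in step.products:
                    g.add_edge(s, p, key=step.step_id, step_id=step.step_id)
                    if step.reversible:
                        g.add_edge(p, s, key=step.step_id, step_id=step.step_id)
        return g


def read_pathway(path: str | Path) -> PathwayGraph:
    """Read a pathway TSV (step_id, substrates, products, ec_list,
    reversible, tags; list fields comma-joined, '-' for empty)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"pathway file not found: {path}")
    steps: list[PathwayStep] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["step_id", "substrates", "products", "ec_list", "reversible", "tags"]
        if [h.lstrip("#") for h in header] != expected:
            raise ValueError(f"{path}: header {header} != expected {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")

            def split(fieldval: str) -> tuple[str, ...]:
                return tuple(x for x in fieldval.split(",") if x and x != "-")

            steps.append(
                PathwayStep(
                    step_id=parts[0],
                    substrates=split(parts[1]),
                    products=split(parts[2]),
                    ec_alternatives=frozenset(split(parts[3])),
                    reversible=parts[4].strip() in ("1", "true", "True"),
                    tags=frozenset(split(parts[5])),
                )
            )
    return PathwayGraph(steps)


def write_pathway(g: PathwayGraph, path: str | Path) -> None:
    """Inverse of :func:`read_pathway` (ancestry labels are not stored
    in the TSV; use :func:`to_json` for annotated exports)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("step_id\tsubstrates\tproducts\tec_list\treversible\ttags\n")
        for step_id in sorted(g.steps):
            s = g.steps[step_id]
            fh.write(
                "\t".join(
                    [
                        s.step_id,
                        ",".join(s.substrates),
                        ",".join(s.products),
                        ",".join(sorted(s.ec_alternatives)) or "-",
                        str(int(s.reversible)),
                        ",".join(sorted(s.tags)) or "-",
                    ]
                )
                + "\n"
            )


def annotate_steps(
    g: PathwayGraph, verdicts: Mapping[str, bool]
) -> PathwayGraph:
    """Label each step's ancestry from per-EC LCA verdicts.

    ``lca`` — any alternative EC has a true verdict (the reaction was
    available to the LCA if any catalysing family was); ``non_lca`` — all
    alternatives resolve and none is true; ``undetermined`` — no true
    alternative and >= 1 EC without a verdict, or a non-enzymatic step.
    """
    out: list[PathwayStep] = []
    for step in g.steps.values():
        if not step.ec_alternatives:
            out.append(replace(step, ancestry="undetermined"))
            continue
        resolved = [verdicts[ec] for ec in step.ec_alternatives if ec in verdicts]
        n_unresolved = len(step.ec_alternatives) - len(resolved)
        if any(resolved):
            ancestry = "lca"
        elif n_unresolved:
            ancestry = "undetermined"
        else:
            ancestry = "non_lca"
        out.append(replace(step, ancestry=ancestry))
    return PathwayGraph(out)


def route_complete(
    g: PathwayGraph,
    source: str,
    target: str,
    require: str = "lca",
) -> tuple[bool, list[str] | None]:
    """Is there a directed route from ``source`` to ``target`` using only
    steps whose ancestry equals ``require``?

    Returns ``(ok, witness)`` where the witness is an alternating
    metabolite/step-id path (metabolite, step, metabolite, ...) for one
    shortest route, or ``None``.
    """
    mets = set(g.metabolites)
    for m in (source, target):
        if m not in mets:
            raise KeyError(f"unknown metabolite {m!r}")
    if require not in ANCESTRY_LABELS:
        raise ValueError(f"unknown ancestry label {require!r}")
    sub = g.to_nx(require=require)
    try:
        nodes = nx.shortest_path(sub, source, target)
    except nx.NetworkXNoPath:
        return False, None
    witness: list[str] = [nodes[0]]
    for a, b in zip(nodes, nodes[1:]):
        step_id = next(iter(sub[a][b]))
        witness.extend([step_id, b])
    return True, witness


def to_json(g: PathwayGraph) -> str:
    """Annotated graph as a JSON document (steps with ancestry labels)."""
    doc = {
        "metabolites": g.metabolites,
        "steps": [
            {
                "step_id": s.step_id,
                "substrates": list(s.substrates),
                "products": list(s.products),
                "ec_alternatives": sorted(s.ec_alternatives),
                "reversible": s.reversible,
                "tags": sorted(s.tags),
                "ancestry": s.ancestry,
            }
            for s in (g.steps[k] for k in sorted(g.steps))
        ],
    }
    return json.dumps(doc, indent=2)


def to_dot(g: PathwayGraph) -> str:
    """GraphViz DOT export; LCA steps red, non-LCA blue, undetermined grey."""
    color = {"lca": "red", "non_lca": "blue", "undetermined": "grey"}
    lines = ["digraph pathway {"]
    for m in g.metabolites:
        lines.append(f'  "{m}" [shape=ellipse];')
    for step_id in sorted(g.steps):
        s = g.steps[step_id]
        label = step_id + "\\n" + ",".join(sorted(s.ec_alternatives))
        for a in s.substrates:
            for b in s.products:
                lines.append(
                    f'  "{a}" -> "{b}" [label="{label}", '
                    f'color={color[s.ancestry]}];'
                )
    lines.append("}")
    return "\n".join(lines)
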