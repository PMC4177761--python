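"""Packaged reference data for nucleotide metabolism.

The package ships small curated TSVs:

* ``purine_enzymes.synthetic.tsv`` / ``pyrimidine_enzymes.synthetic.tsv`` —
  the enzyme inventories of purine and pyrimidine metabolism (120
  distinct EC numbers across the two maps).  These are synthetic
  reconstructions assembled from standard purine/pyrimidine pathway
  knowledge, not a copy of any external database dump.
* ``profile_catalogue.synthetic.tsv`` — a synthetic profile catalogue:
  151 enzyme profiles covering the 120 ECs, with subunit, analog and
  paralog groupings for the multi-profile steps (e.g. PurQ + PurL
  subunits of EC 6.3.5.3; PurN / PurT analogs of EC 2.1.2.2).
* ``pathway_*.tsv`` — reaction graphs of the de novo purine route to
  IMP, the de novo pyrimidine route to UMP, and pyrimidine metabolism
  from UMP onward.
* ``purine_denovo_classes.synthetic.tsv`` — per-domain distribution
  classes for the de novo purine enzymes, a synthetic stand-in encoding
  qualitative distribution statements for demonstration and testing.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .hits import ProfileDef, read_catalogue
from .pathway import PathwayGraph, read_pathway
from .taxonomy import DOMAINS

__all__ = [
    "data_path",
    "load_enzyme_inventory",
    "load_catalogue",
    "load_pathway",
    "load_distribution_classes",
    "lca_from_classes",
]

PATHWAY_FILES = {
    "purine_de_novo": "pathway_purine_de_novo.tsv",
    "pyrimidine_de_novo": "pathway_pyrimidine_de_novo.tsv",
    "pyrimidine_from_ump": "pathway_pyrimidine_from_ump.tsv",
}


def data_path(name: str) -> Path:
    p = resources.files("lcaprof.data") / name
    with resources.as_file(p) as path:
        return Path(path)


def load_enzyme_inventory(which: str = "all") -> pd.DataFrame:
    """Enzyme inventory (columns ec_number, name, pathway).

    ``which`` is ``purine``, ``pyrimidine`` or ``all`` (concatenated;
    ECs shared between the two maps appear once per map).
    """
    frames = []
    if which in ("purine", "all"):
        frames.append(pd.read_csv(data_path("purine_enzymes.synthetic.tsv"), sep="\t"))
    if which in ("pyrimidine", "all"):
        frames.append(
            pd.read_csv(data_path("pyrimidine_enzymes.synthetic.tsv"), sep="\t")
        )
    if not frames:
        raise ValueError(f"unknown inventory {which!r}")
    return pd.concat(frames, ignore_index=True)


def load_catalogue() -> dict[str, ProfileDef]:
    """The packaged 151-profile catalogue."""
    return read_catalogue(data_path("profile_catalogue.synthetic.tsv"))


def load_pathway(name: str) -> PathwayGraph:
    if name not in PATHWAY_FILES:
        raise KeyError(
            f"unknown pathway {name!r}; available: {sorted(PATHWAY_FILES)}"
        )
    return read_pathway(data_path(PATHWAY_FILES[name]))


def load_distribution_classes(
    name: str = "purine_denovo_classes.synthetic.tsv",
) -> pd.DataFrame:
    """Per-domain distribution classes (ec_number, Bacteria, Archaea,
    Eukarya), each cell one of widely/partially/sparsely/absent."""
    df = pd.read_csv(data_path(name), sep="\t")
    expected = ["ec_number", *DOMAINS]
    if list(df.columns) != expected:
        raise ValueError(f"{name}: columns {list(df.columns)} != {expected}")
    return df


def lca_from_classes(classes: pd.DataFrame) -> dict[str, bool]:
    """Apply the LCA rule to a distribution-class table: an enzyme is
    LCA-attributed iff classed *widely* in all three domains."""
    return {
        row["ec_number"]: all(row[d] == "widely" for d in DOMAINS)
        for _, row in classes.iterrows()
    }
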