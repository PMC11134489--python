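"""CSV reading and writing for reactions and site datasets.

The reaction table has columns ``rxn_smiles`` (required, in the
``reactants>agents>products`` dialect), ``yield`` and ``id`` (optional).
The site table carries one enumerated candidate site per row.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .chem_core import Molecule, ParseError, ReactionRecord, parse_reaction
from .site_enum import SiteDataset, SiteInstance

SITE_COLUMNS = ["substrate", "site_atom", "site_reaction", "label", "yield"]


def read_reactions(path: str | Path) -> list[ReactionRecord | str]:
    """Read a reaction CSV; unparseable rows are passed through as raw
    strings so curation can count them as validity drops."""
    df = pd.read_csv(path)
    if "rxn_smiles" not in df.columns:
        raise ValueError(f"{path}: missing required column 'rxn_smiles'")
    out: list[ReactionRecord | str] = []
    for i, row in df.iterrows():
        yld = row.get("yield")
        if yld is not None and (isinstance(yld, float) and math.isnan(yld)):
            yld = None
        source_id = str(row["id"]) if "id" in df.columns else str(i)
        try:
            out.append(
                parse_reaction(
                    str(row["rxn_smiles"]),
                    yield_percent=float(yld) if yld is not None else None,
                    source_id=source_id,
                )
            )
        except (ParseError, ValueError):
            out.append(str(row["rxn_smiles"]))
    return out


def write_reactions(records: list[ReactionRecord], path: str | Path) -> None:
    rows = [
        {
            "rxn_smiles": r.to_reaction_smiles(),
            "yield": r.yield_percent,
            "id": r.source_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["rxn_smiles", "yield", "id"]).to_csv(path, index=False)


def write_sites(dataset: SiteDataset, path: str | Path) -> None:
    rows = [
        {
            "substrate": inst.substrate.smiles,
            "site_atom": inst.site_atom,
            "site_reaction": inst.site_reaction,
            "label": inst.label,
            "yield": inst.yield_label,
        }
        for inst in dataset.instances
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False)


def read_sites(path: str | Path) -> SiteDataset:
    df = pd.read_csv(path)
    missing = [c for c in ("substrate", "site_atom", "site_reaction") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing site columns {missing}")
    instances = []
    for _, row in df.iterrows():
        product = row["site_reaction"].split(">>")[1]
        label = row.get("label")
        yld = row.get("yield")
        instances.append(
            SiteInstance(
                substrate=Molecule.from_smiles(row["substrate"]),
                site_atom=int(row["site_atom"]),
                symmetry_class=-1,
                site_product=Molecule.from_smiles(product),
                label=None if pd.isna(label) else int(label),
                yield_label=None if pd.isna(yld) else float(yld),
            )
        )
    return SiteDataset(instances=instances)
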