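"""Filtering funnel that turns raw candidate reactions into a clean
aromatic C-H borylation dataset.

Stages, in order: a naive C-H / C-B screen, product fragmentation along
C-B bonds with reactant matching (this is what rejects Miyaura-type
C-X -> C-B borylations), SMILES validity, optional yield presence, and
the iridium-catalyzed aromatic-site requirement. Each retained record
carries the matched site atom id in the substrate's canonical ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import rdmolops

from .chem_core import Molecule, ReactionRecord

STAGES = (
    "input",
    "naive_CH_CB_pass",
    "fragment_match_pass",
    "valid_species_pass",
    "with_yield",
    "ir_aromatic_pass",
    "deduplicated",
)


@dataclass
class CurationReport:
    """Per-stage survivor counts (the filtering funnel)."""

    counts: dict[str, int] = field(default_factory=dict)
    dropped_ids: dict[str, list[str]] = field(default_factory=dict)

    def record_drop(self, stage: str, source_id: str) -> None:
        self.dropped_ids.setdefault(stage, []).append(source_id)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass
class CurationConfig:
    require_yield: bool = False
    require_ir: bool = True


def _has_CH(mol: Molecule) -> bool:
    return any(
        a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1 for a in mol.mol.GetAtoms()
    )


def _has_CB_bond(mol: Molecule) -> bool:
    for bond in mol.mol.GetBonds():
        symbols = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
        if symbols == {"C", "B"}:
            return True
    return False


def naive_filter(record: ReactionRecord) -> bool:
    """C-H bond in the substrate and C-B bond in some product."""
    return _has_CH(record.substrate) and any(_has_CB_bond(p) for p in record.products)


def fragment_match(reactant: Molecule, product: Molecule) -> int | None:
    """Fragment the product along C-B bonds and match against the reactant.

    For each C-B bond in canonical bond order: delete the bond, discard
    the boron-containing fragment whole (Bpin, Bneop, catecholboronate -
    the boron group's identity is not restricted), cap the carbon with
    one hydrogen, canonicalize. If the capped fragment equals the
    reactant, return that carbon's atom id mapped onto the reactant's
    canonical ordering. First match wins; None if no cleavage matches.

    This restores the C-H bond that borylation replaced, so genuine C-H
    borylations round-trip while aryl-halide (Miyaura) borylations fail:
    their capped fragment lacks the halide.

    Raises
    ------
    ValueError
        If the product has no C-B bond.
    """
    if not _has_CB_bond(product):
        raise ValueError(f"product {product.smiles} has no C-B bond")
    pmol = product.mol
    for bond in pmol.GetBonds():
        a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
        if {a1.GetSymbol(), a2.GetSymbol()} != {"C", "B"}:
            continue
        carbon = a1 if a1.GetSymbol() == "C" else a2
        boron = a2 if a1.GetSymbol() == "C" else a1
        rw = Chem.RWMol(pmol)
        rw.RemoveBond(a1.GetIdx(), a2.GetIdx())
        frags = rdmolops.GetMolFrags(rw.GetMol())
        carbon_frag = next(f for f in frags if carbon.GetIdx() in f)
        if boron.GetIdx() in carbon_frag:
            continue  # ring C-B bond: cleavage does not detach the boron group
        keep = set(carbon_frag)
        sub = Chem.RWMol(rw)
        for idx in sorted(range(sub.GetNumAtoms()), reverse=True):
            if idx not in keep:
                sub.RemoveAtom(idx)
        new_cidx = sum(1 for i in carbon_frag if i < carbon.GetIdx())
        frag_mol = sub.GetMol()
        capped = frag_mol.GetAtomWithIdx(new_cidx)
        # cap with exactly one hydrogen; charges and isotopes are untouched
        if capped.GetNoImplicit() or capped.GetNumExplicitHs() > 0:
            capped.SetNumExplicitHs(capped.GetNumExplicitHs() + 1)
        try:
            Chem.SanitizeMol(frag_mol)
        except Exception:
            continue
        smi = Chem.MolToSmiles(frag_mol)
        if smi == reactant.smiles:
            order_prop = frag_mol.GetProp("_smilesAtomOutputOrder")
            order = [int(t) for t in order_prop.strip("[]").split(",") if t]
            return order.index(new_cidx)
    return None


def _contains_iridium(record: ReactionRecord) -> bool:
    return any(m.contains_element("Ir") for m in record.agents)


def iridium_aromatic_filter(record: ReactionRecord, site: int) -> bool:
    """Iridium in the agents and an aromatic matched site carbon."""
    if not _contains_iridium(record):
        return False
    atom = record.substrate.mol.GetAtomWithIdx(site)
    return atom.GetIsAromatic()


def curate(
    records: list[ReactionRecord | str],
    config: CurationConfig | None = None,
) -> tuple[list[ReactionRecord], CurationReport]:
    """Apply the full funnel; retained records carry ``site_atom``.

    Accepts parsed records or raw reaction SMILES strings; strings that
    fail to parse are counted as validity-stage drops. Output is
    deduplicated by canonical (substrate, product) pair, agents ignored,
    and is independent of input order up to ordering.
    """
    config = config or CurationConfig()
    report = CurationReport()
    parsed: list[ReactionRecord] = []
    n_input = len(records)
    parse_failures = 0
    for i, rec in enumerate(records):
        if isinstance(rec, str):
            from .chem_core import parse_reaction

            try:
                rec = parse_reaction(rec, source_id=str(i))
            except Exception:
                parse_failures += 1
                report.record_drop("valid_species_pass", str(i))
                continue
        parsed.append(rec)

    report.counts["input"] = n_input

    stage1: list[ReactionRecord] = []
    for r in parsed:
        if naive_filter(r):
            stage1.append(r)
        else:
            report.record_drop("naive_CH_CB_pass", r.source_id)
    report.counts["naive_CH_CB_pass"] = len(stage1)

    stage2: list[ReactionRecord] = []
    for r in stage1:
        site = None
        for product in r.products:
            if not _has_CB_bond(product):
                continue
            site = fragment_match(r.substrate, product)
            if site is not None:
                break
        if site is None:
            report.record_drop("fragment_match_pass", r.source_id)
        else:
            stage2.append(replace(r, site_atom=site))
    report.counts["fragment_match_pass"] = len(stage2)

    # Validity: parse failures were already dropped before this point;
    # everything reaching here re-parsed through canonical SMILES.
    report.counts["valid_species_pass"] = len(stage2)

    stage3 = stage2
    if config.require_yield:
        stage3 = [r for r in stage2 if r.yield_percent is not None]
        for r in stage2:
            if r.yield_percent is None:
                report.record_drop("with_yield", r.source_id)
    report.counts["with_yield"] = len(stage3)

    stage4 = stage3
    if config.require_ir:
        stage4 = []
        for r in stage3:
            if iridium_aromatic_filter(r, r.site_atom):
                stage4.append(r)
            else:
                report.record_drop("ir_aromatic_pass", r.source_id)
    report.counts["ir_aromatic_pass"] = len(stage4)

    seen: set[tuple[str, str]] = set()
    out: list[ReactionRecord] = []
    for r in sorted(stage4, key=lambda r: (r.substrate.smiles, r.products[0].smiles)):
        key = (r.substrate.smiles, ".".join(sorted(p.smiles for p in r.products)))
        if key in seen:
            report.record_drop("deduplicated", r.source_id)
            continue
        seen.add(key)
        out.append(r)
    report.counts["deduplicated"] = len(out)
    return out, report
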