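"""Candidate-site enumeration for monoborylation.

A substrate with k symmetry-distinct eligible carbons gives k candidate
site reactions ``substrate>>site_product``, one per unique product: the
ensemble of hypothetical monoborylations that the classifier scores.
Sites are deduplicated by graph-automorphism symmetry class because
substitution at equivalent positions yields the same product molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median

from rdkit import Chem

from .chem_core import Molecule

#: Pinacol boronate attachment fragment; atom 0 is the boron.
BPIN_FRAGMENT = "B1OC(C)(C)C(C)(C)O1"

MODES = ("aromatic_CH", "nonquaternary_C")


@dataclass
class SiteInstance:
    """One candidate borylation site of a substrate."""

    substrate: Molecule
    site_atom: int
    symmetry_class: int
    site_product: Molecule
    label: int | None = None
    yield_label: float | None = None

    @property
    def site_reaction(self) -> str:
        return f"{self.substrate.smiles}>>{self.site_product.smiles}"


@dataclass
class SiteDataset:
    """Site instances grouped by substrate canonical SMILES."""

    instances: list[SiteInstance]

    @property
    def grouping(self) -> dict[str, list[SiteInstance]]:
        groups: dict[str, list[SiteInstance]] = {}
        for inst in self.instances:
            groups.setdefault(inst.substrate.smiles, []).append(inst)
        return groups

    def median_site_count(self) -> float:
        """Median number of candidate site classes per substrate."""
        sizes = [len(v) for v in self.grouping.values()]
        return median(sizes) if sizes else float("nan")


def symmetry_classes(mol: Molecule) -> dict[int, int]:
    """Map each atom id to its graph-automorphism symmetry class.

    Classes come from RDKit's canonical ranking without tie-breaking:
    two atoms share a rank iff they are interchangeable under the
    molecular graph's automorphisms. Classes are renumbered to
    contiguous integers from 0 in order of lowest member atom id.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol.mol, breakTies=False))
    mapping: dict[int, int] = {}
    out: dict[int, int] = {}
    for atom_id, rank in enumerate(ranks):
        if rank not in mapping:
            mapping[rank] = len(mapping)
        out[atom_id] = mapping[rank]
    return out


def attach_boron(substrate: Molecule, site_atom: int) -> Molecule:
    """Replace one H on ``site_atom`` with a pinacol boronate group.

    Raises
    ------
    ValueError
        If the site atom is not a carbon or bears no hydrogen.
    """
    mol = substrate.mol
    if site_atom < 0 or site_atom >= mol.GetNumAtoms():
        raise ValueError(f"atom id {site_atom} out of range for {substrate.smiles}")
    atom = mol.GetAtomWithIdx(site_atom)
    if atom.GetSymbol() != "C":
        raise ValueError(f"site atom {site_atom} of {substrate.smiles} is not carbon")
    if atom.GetTotalNumHs() < 1:
        raise ValueError(f"site atom {site_atom} of {substrate.smiles} bears no hydrogen")

    bpin = Chem.MolFromSmiles(BPIN_FRAGMENT)
    combo = Chem.RWMol(Chem.CombineMols(mol, bpin))
    boron_idx = mol.GetNumAtoms()
    target = combo.GetAtomWithIdx(site_atom)
    # Explicit H bookkeeping: implicit counts re-derive on sanitization,
    # explicit ones must be decremented by hand.
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    combo.AddBond(site_atom, boron_idx, Chem.BondType.SINGLE)
    product = combo.GetMol()
    Chem.SanitizeMol(product)
    return Molecule.from_smiles(Chem.MolToSmiles(product))


def _eligible(atom: Chem.Atom, mode: str) -> bool:
    if atom.GetSymbol() != "C" or atom.GetTotalNumHs() < 1:
        return False
    if mode == "aromatic_CH":
        return atom.GetIsAromatic()
    return True


def enumerate_sites(substrate: Molecule, mode: str = "aromatic_CH") -> list[SiteInstance]:
    """One SiteInstance per symmetry class of eligible carbons.

    ``aromatic_CH`` restricts to aromatic C-H positions (the undirected
    iridium-catalyzed reaction); ``nonquaternary_C`` admits any carbon
    bearing a hydrogen. The class representative is the lowest canonical
    atom id; labels are left unset. Empty list if nothing is eligible.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    classes = symmetry_classes(substrate)
    seen: set[int] = set()
    out: list[SiteInstance] = []
    for atom in substrate.mol.GetAtoms():
        if not _eligible(atom, mode):
            continue
        cls = classes[atom.GetIdx()]
        if cls in seen:
            continue
        seen.add(cls)
        out.append(
            SiteInstance(
                substrate=substrate,
                site_atom=atom.GetIdx(),
                symmetry_class=cls,
                site_product=attach_boron(substrate, atom.GetIdx()),
            )
        )
    return out


def build_site_dataset(
    records,
    mode: str = "aromatic_CH",
) -> tuple[SiteDataset, dict[str, list[Molecule]]]:
    """Group curated reactions by substrate and label the enumerated sites.

    Each substrate's candidate sites are enumerated once; experimental
    products (with their yields) from all of the substrate's records
    label them. Returns the labeled dataset plus, per substrate, any
    experimental products that no enumerated site explains.
    """
    by_substrate: dict[str, list] = {}
    for r in records:
        by_substrate.setdefault(r.substrate.smiles, []).append(r)
    instances: list[SiteInstance] = []
    warnings: dict[str, list[Molecule]] = {}
    for smi, recs in by_substrate.items():
        substrate = recs[0].substrate
        sites = enumerate_sites(substrate, mode)
        experimental = [
            (p, r.yield_percent) for r in recs for p in r.products
        ]
        labeled, warned = label_sites(sites, experimental)
        instances.extend(labeled)
        if warned:
            warnings[smi] = warned
    return SiteDataset(instances=instances), warnings


def label_sites(
    instances: list[SiteInstance],
    experimental: list[tuple[Molecule, float | None]],
) -> tuple[list[SiteInstance], list[Molecule]]:
    """Label enumerated sites against experimental products.

    A site gets label 1 iff its product canonically equals one of the
    experimental products (mixtures label several sites 1); its yield
    label is copied from the matching product. Experimental products no
    enumerated site can explain are returned as warnings.
    """
    substrates = {inst.substrate.smiles for inst in instances}
    if len(substrates) > 1:
        raise ValueError("label_sites expects instances of a single substrate")
    by_product = {inst.site_product.smiles: inst for inst in instances}
    labeled = [replace(inst, label=0, yield_label=None) for inst in instances]
    index = {inst.site_product.smiles: i for i, inst in enumerate(labeled)}
    warnings: list[Molecule] = []
    for product, yld in experimental:
        key = product.smiles
        if key in by_product:
            i = index[key]
            labeled[i] = replace(labeled[i], label=1, yield_label=yld)
        else:
            warnings.append(product)
    return labeled, warnings
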