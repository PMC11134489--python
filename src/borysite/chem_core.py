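"""Molecule and reaction parsing shared by the whole pipeline.

All structure handling goes through RDKit with its default aromaticity
perception (the RDKit aromaticity model; see :data:`AROMATICITY_MODEL`).
Atom identifiers used throughout the package are indices into the
*canonical* atom ordering: a :class:`Molecule` always re-parses its own
canonical SMILES, so atom index ``i`` means the same atom regardless of
how the input SMILES was written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property, lru_cache

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Aromaticity perception used everywhere, recorded for reproducibility.
AROMATICITY_MODEL = "rdkit-default"


class ParseError(ValueError):
    """Raised when a SMILES or reaction SMILES cannot be parsed."""


@lru_cache(maxsize=200000)
def canonicalize(smiles: str) -> str:
    """Return the unique RDKit canonical SMILES for ``smiles``.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.

    Raises
    ------
    ParseError
        If the string is empty or does not parse to a valid molecule.
    """
    if not smiles or not isinstance(smiles, str):
        raise ParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A molecule held in canonical form.

    ``smiles`` is always the canonical SMILES; the underlying RDKit mol
    is parsed from it, so its atom indices are canonical atom ids.
    """

    smiles: str

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        return cls(canonicalize(smiles))

    @cached_property
    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - smiles is canonical by construction
            raise ParseError(f"unparseable SMILES: {self.smiles!r}")
        return m

    @property
    def atom_count(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def aromatic_ring_count(self) -> int:
        return count_aromatic_rings(self)

    def contains_element(self, symbol: str) -> bool:
        return any(a.GetSymbol() == symbol for a in self.mol.GetAtoms())

    def __str__(self) -> str:
        return self.smiles


@dataclass
class ReactionRecord:
    """One reaction: substrate(s) > agents > product(s), optional yield."""

    reactants: list[Molecule]
    agents: list[Molecule]
    products: list[Molecule]
    yield_percent: float | None = None
    source_id: str = ""
    site_atom: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError("a reaction needs at least one product")
        if self.yield_percent is not None and not 0 <= self.yield_percent <= 100:
            raise ValueError(f"yield {self.yield_percent} outside [0, 100]")

    @property
    def substrate(self) -> Molecule:
        """The borylation substrate.

        With several reactant-field molecules, the substrate is the one
        with the most heavy atoms among those not containing boron
        (boron reagents such as B2pin2 are co-reactants, not substrates).
        """
        candidates = [m for m in self.reactants if not m.contains_element("B")]
        if not candidates:
            candidates = self.reactants
        return max(candidates, key=lambda m: m.atom_count)

    def to_reaction_smiles(self) -> str:
        return ">".join(
            ".".join(m.smiles for m in part)
            for part in (self.reactants, self.agents, self.products)
        )


def parse_reaction(
    rxn_smiles: str,
    yield_percent: float | None = None,
    source_id: str = "",
) -> ReactionRecord:
    """Parse a ``reactants>agents>products`` reaction SMILES.

    Components are '.'-separated within each field and canonicalized.
    An empty agents field yields an empty agent list.

    Raises
    ------
    ParseError
        If the string does not have exactly two ``>`` separators, if the
        reactant or product field is empty, or if any component fails to
        parse.
    """
    parts = rxn_smiles.split(">")
    if len(parts) != 3:
        raise ParseError(
            f"reaction SMILES needs exactly two '>' separators: {rxn_smiles!r}"
        )
    raw_reactants, raw_agents, raw_products = parts
    if not raw_reactants or not raw_products:
        raise ParseError(f"reactant and product fields must be nonempty: {rxn_smiles!r}")

    def _field(raw: str) -> list[Molecule]:
        if not raw:
            return []
        return [Molecule.from_smiles(tok) for tok in raw.split(".")]

    return ReactionRecord(
        reactants=_field(raw_reactants),
        agents=_field(raw_agents),
        products=_field(raw_products),
        yield_percent=yield_percent,
        source_id=source_id,
    )


def count_aromatic_rings(mol: Molecule) -> int:
    """Number of SSSR rings whose atoms are all aromatic.

    This is the ring count behind the one-ring / several-rings dataset
    split (benzene 1, biphenyl and naphthalene 2, ...).
    """
    m = mol.mol
    count = 0
    for ring in Chem.GetSymmSSSR(m):
        if all(m.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            count += 1
    return count


def ring_is_heterocyclic(mol: Molecule, atom_id: int) -> bool:
    """True iff some smallest ring through ``atom_id`` has a non-carbon atom.

    Raises
    ------
    ValueError
        If the atom is not an aromatic ring atom.
    """
    m = mol.mol
    if atom_id < 0 or atom_id >= m.GetNumAtoms():
        raise ValueError(f"atom id {atom_id} out of range for {mol.smiles}")
    atom = m.GetAtomWithIdx(atom_id)
    if not (atom.GetIsAromatic() and atom.IsInRing()):
        raise ValueError(f"atom {atom_id} of {mol.smiles} is not in an aromatic ring")
    for ring in Chem.GetSymmSSSR(m):
        if atom_id in ring:
            if any(m.GetAtomWithIdx(i).GetSymbol() != "C" for i in ring):
                return True
    return False
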