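"""Parsing, validation and serialization of atom-mapped reactions and condition tables.

Reactions arrive as reaction SMILES, one per line, in the daylight
``reactants>agents>products`` dialect with ``:n`` atom-map annotations.
Conditions arrive as a CSV aligned row-by-row with the reaction file.

Conventions enforced here:

* explicit hydrogens are removed after parsing (H2 as an agent is kept as a
  reagent entry but contributes no heavy atoms);
* stereochemistry annotations are parsed and discarded;
* aromatic bonds written in lowercase SMILES are honored as given — no
  re-aromatization is attempted (input contract);
* a reactant molecule none of whose atoms map into a product is transferred
  to the reagents list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: bond order symbols used throughout: 1, 2, 3 and "a" for aromatic
BondOrder = Union[int, str]

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "a",
}
_ORDER_RDKIT = {v: k for k, v in _RDKIT_ORDER.items()}


class ReactionParseError(ValueError):
    """Malformed reaction SMILES or violated mapping invariant."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element symbol, formal charge, optional atom-map number."""

    element: str
    formal_charge: int = 0
    map_number: int | None = None


@dataclass
class MolecularGraph:
    """A molecule as an explicit graph over heavy atoms.

    ``bonds`` holds ``(i, j, order)`` with ``i < j`` atom indices and order
    in {1, 2, 3, "a"}.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, BondOrder]] = field(default_factory=list)

    def map_numbers(self) -> set[int]:
        return {a.map_number for a in self.atoms if a.map_number is not None}


@dataclass
class MappedReaction:
    """Reactants, products and reagents of one atom-mapped reaction.

    Invariants: every product atom's map number occurs among reactant atoms;
    every reactant graph has at least one atom mapped into a product.
    """

    reactants: list[MolecularGraph]
    products: list[MolecularGraph]
    reagents: list[MolecularGraph] = field(default_factory=list)


@dataclass
class ConditionRecord:
    """Raw experimental conditions for one reaction.

    Temperature (°C) and pressure (atm) may be numbers, range strings or
    synonym tokens ("rt", "atmospheric pressure"); they are normalized
    downstream.  Exactly one catalyst name per record.
    """

    temperature: float | str
    pressure: float | str
    catalyst: str
    acid: bool = False
    base: bool = False
    poison: bool = False


def _mol_to_graph(mol: Chem.Mol) -> MolecularGraph:
    atoms = []
    for a in mol.GetAtoms():
        m = a.GetAtomMapNum()
        atoms.append(Atom(a.GetSymbol(), a.GetFormalCharge(), m if m > 0 else None))
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        order = _RDKIT_ORDER.get(b.GetBondType())
        if order is None:
            raise ReactionParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append((i, j, order))
    return MolecularGraph(atoms, sorted(bonds))


def _parse_side(smiles: str, side: str) -> list[MolecularGraph]:
    """Parse one dot-separated side of a reaction SMILES into graphs."""
    if not smiles:
        return []
    graphs = []
    for token in smiles.split("."):
        mol = Chem.MolFromSmiles(token)
        if mol is None:
            raise ReactionParseError(f"malformed SMILES {token!r} in {side}")
        Chem.RemoveStereochemistry(mol)
        # drop explicit hydrogens; H2 itself collapses to an empty graph and
        # is recorded as a zero-atom reagent placeholder below
        mol = Chem.RemoveHs(mol)
        graphs.append(_mol_to_graph(mol))
    return graphs


def _check_unique_maps(graphs: Sequence[MolecularGraph], side: str) -> None:
    seen: set[int] = set()
    for g in graphs:
        for a in g.atoms:
            if a.map_number is None:
                continue
            if a.map_number in seen:
                raise ReactionParseError(
                    f"duplicate atom-map number {a.map_number} on {side} side"
                )
            seen.add(a.map_number)


def parse_reaction_smiles(line: str) -> MappedReaction:
    """Parse one atom-mapped reaction SMILES line into a :class:`MappedReaction`.

    Species in the agents slot become reagents.  Reactant molecules with no
    atom mapped into any product are moved to the reagents list; product map
    numbers must all originate from reactant atoms.
    """
    line = line.strip()
    parts = line.split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"expected 'reactants>agents>products', got {line!r}"
        )
    reactants = _parse_side(parts[0], "reactant")
    reagents = _parse_side(parts[1], "agent")
    products = _parse_side(parts[2], "product")
    if not products:
        raise ReactionParseError("reaction has no products")

    _check_unique_maps(reactants, "reactant")
    _check_unique_maps(products, "product")

    product_maps: set[int] = set()
    for g in products:
        product_maps |= g.map_numbers()
    # unmapped-reactant rule: no atom mapped into a product -> reagent
    kept, moved = [], []
    for g in reactants:
        (kept if g.map_numbers() & product_maps else moved).append(g)
    reagents = reagents + moved
    if not kept:
        raise ReactionParseError("no reactant atom is mapped into any product")

    reactant_maps: set[int] = set()
    for g in kept:
        reactant_maps |= g.map_numbers()
    orphan = product_maps - reactant_maps
    if orphan:
        raise ReactionParseError(
            f"product map numbers {sorted(orphan)} missing from reactants"
        )
    return MappedReaction(kept, products, reagents)


def _graph_to_mol(graph: MolecularGraph) -> Chem.Mol:
    em = Chem.RWMol()
    for a in graph.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        if a.map_number is not None:
            ra.SetAtomMapNum(a.map_number)
        em.AddAtom(ra)
    for i, j, order in graph.bonds:
        em.AddBond(i, j, _ORDER_RDKIT[order])
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def serialize_reaction(rxn: MappedReaction) -> str:
    """Render a MappedReaction back to a reaction SMILES line."""

    def side(graphs: Sequence[MolecularGraph]) -> str:
        return ".".join(Chem.MolToSmiles(_graph_to_mol(g)) for g in graphs)

    return f"{side(rxn.reactants)}>{side(rxn.reagents)}>{side(rxn.products)}"


def read_reaction_file(path: str | Path) -> list[MappedReaction]:
    """Parse a reaction file: one atom-mapped reaction SMILES per line."""
    out = []
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            out.append(parse_reaction_smiles(line))
        except ReactionParseError as e:
            raise ReactionParseError(f"{path}:{n}: {e}") from e
    return out


_CONDITION_COLUMNS = ["temperature", "pressure", "catalyst", "acid", "base", "poison"]
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


def _parse_bool(token: str, column: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {token!r} in column {column!r}")


def _parse_value(token: str) -> float | str:
    """Numeric if it parses; otherwise the raw token (synonym or range)."""
    try:
        return float(token)
    except ValueError:
        return token.strip()


def read_condition_table(path: str | Path, n_reactions: int | None = None) -> list[ConditionRecord]:
    """Read the aligned condition CSV.

    Columns must be exactly ``temperature,pressure,catalyst,acid,base,poison``.
    If ``n_reactions`` is given, the row count must match it.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or sorted(reader.fieldnames) != sorted(_CONDITION_COLUMNS):
            raise ValueError(
                f"condition table columns must be {_CONDITION_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            records.append(
                ConditionRecord(
                    temperature=_parse_value(row["temperature"]),
                    pressure=_parse_value(row["pressure"]),
                    catalyst=row["catalyst"].strip(),
                    acid=_parse_bool(row["acid"], "acid"),
                    base=_parse_bool(row["base"], "base"),
                    poison=_parse_bool(row["poison"], "poison"),
                )
            )
    if n_reactions is not None and len(records) != n_reactions:
        raise ValueError(
            f"condition table has {len(records)} rows but {n_reactions} reactions"
        )
    return records


def write_condition_table(path: str | Path, records: Sequence[ConditionRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CONDITION_COLUMNS)
        for r in records:
            writer.writerow(
                [r.temperature, r.pressure, r.catalyst,
                 int(r.acid), int(r.base), int(r.poison)]
            )
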