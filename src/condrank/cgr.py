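"""Condensed Graph of Reaction (CGR).

A CGR superposes the mapped reactant and product graphs of a reaction into a
single pseudomolecule.  Each bond carries a pair of orders ``(before, after)``
with 0 meaning "absent"; bonds whose two orders differ are *dynamic* — they
encode bond breaking, formation, or an order change (e.g. the 2→1 change of a
hydrogenated alkene).  Atoms present only on the reactant side (leaving
groups, e.g. the oxygens of a reduced nitro group) are retained with their
bonds as order→0 dynamic bonds, because broken-bond information is chemically
essential for hydrogenolysis chemistry.  Formal charges are likewise kept as
a per-atom ``(reactant, product)`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .reactions import BondOrder, MappedReaction, MolecularGraph


class MappingInconsistencyError(ValueError):
    """The same atom-map number refers to different elements on the two sides."""


#: (reactant_order, product_order); 0 = bond absent on that side
DynamicBondLabel = tuple[BondOrder | int, BondOrder | int]


@dataclass(frozen=True)
class CGRAtom:
    element: str
    reactant_charge: int
    product_charge: int
    map_number: int | None = None

    @property
    def dynamic_charge(self) -> bool:
        return self.reactant_charge != self.product_charge


@dataclass
class CGR:
    """Superposed reaction graph: atoms plus (i, j, (order_before, order_after))."""

    atoms: list[CGRAtom] = field(default_factory=list)
    bonds: list[tuple[int, int, DynamicBondLabel]] = field(default_factory=list)

    def adjacency(self) -> dict[int, list[tuple[int, DynamicBondLabel]]]:
        adj: dict[int, list[tuple[int, DynamicBondLabel]]] = {
            i: [] for i in range(len(self.atoms))
        }
        for i, j, label in self.bonds:
            adj[i].append((j, label))
            adj[j].append((i, label))
        return adj


def _collect_side(
    graphs: list[MolecularGraph],
) -> tuple[dict[int, tuple[str, int]], list[tuple[str, int]], dict[tuple, BondOrder]]:
    """Atoms by map number, unmapped atoms, and bonds keyed by endpoint ids.

    Endpoint ids are ``("m", map_number)`` for mapped atoms and
    ``("u", side_serial)`` for unmapped ones.
    """
    mapped: dict[int, tuple[str, int]] = {}
    unmapped: list[tuple[str, int]] = []
    bonds: dict[tuple, BondOrder] = {}
    serial = 0
    for g in graphs:
        local_ids = []
        for a in g.atoms:
            if a.map_number is not None:
                mapped[a.map_number] = (a.element, a.formal_charge)
                local_ids.append(("m", a.map_number))
            else:
                unmapped.append((a.element, a.formal_charge))
                local_ids.append(("u", serial))
                serial += 1
        for i, j, order in g.bonds:
            key = tuple(sorted((local_ids[i], local_ids[j])))
            bonds[key] = order
    return mapped, unmapped, bonds


def build_cgr(rxn: MappedReaction) -> CGR:
    """Superpose reactants and products by atom-map number.

    Raises :class:`MappingInconsistencyError` when one map number carries
    different element symbols on the two sides.
    """
    r_mapped, r_unmapped, r_bonds = _collect_side(rxn.reactants)
    p_mapped, p_unmapped, p_bonds = _collect_side(rxn.products)
    if p_unmapped:
        raise MappingInconsistencyError("products contain unmapped atoms")

    for m, (el, _) in p_mapped.items():
        if m in r_mapped and r_mapped[m][0] != el:
            raise MappingInconsistencyError(
                f"map number {m} is {r_mapped[m][0]} in reactants but {el} in products"
            )

    atoms: list[CGRAtom] = []
    index: dict[tuple, int] = {}
    # mapped atoms in ascending map-number order (deterministic)
    for m in sorted(set(r_mapped) | set(p_mapped)):
        rc = r_mapped[m][1] if m in r_mapped else p_mapped[m][1]
        pc = p_mapped[m][1] if m in p_mapped else r_mapped[m][1]
        el = r_mapped[m][0] if m in r_mapped else p_mapped[m][0]
        index[("m", m)] = len(atoms)
        atoms.append(CGRAtom(el, rc, pc, map_number=m))
    # reactant-only unmapped atoms (leaving groups without maps)
    for k, (el, ch) in enumerate(r_unmapped):
        index[("u", k)] = len(atoms)
        atoms.append(CGRAtom(el, ch, ch))

    bonds = []
    for key in sorted(set(r_bonds) | set(p_bonds)):
        a, b = key
        if a not in index or b not in index:
            continue  # bond touching an atom we did not keep (cannot happen today)
        label = (r_bonds.get(key, 0), p_bonds.get(key, 0))
        i, j = index[a], index[b]
        if i > j:
            i, j = j, i
        bonds.append((i, j, label))
    return CGR(atoms, sorted(bonds))


def dynamic_bond_count(cgr: CGR) -> int:
    """Number of bonds whose reactant-side and product-side orders differ."""
    return sum(1 for _, _, (r, p) in cgr.bonds if r != p)


def reactant_projection(cgr: CGR) -> list[tuple[int, int, BondOrder]]:
    """Bonds present on the reactant side (order > 0), as (i, j, order)."""
    return [(i, j, r) for i, j, (r, _) in cgr.bonds if r != 0]


def product_projection(cgr: CGR) -> list[tuple[int, int, BondOrder]]:
    return [(i, j, p) for i, j, (_, p) in cgr.bonds if p != 0]


def to_networkx(cgr: CGR) -> nx.Graph:
    g = nx.Graph()
    for i, a in enumerate(cgr.atoms):
        g.add_node(i, label=f"{a.element}{a.reactant_charge}>{a.product_charge}")
    for i, j, (r, p) in cgr.bonds:
        g.add_edge(i, j, label=f"{r}>{p}")
    return g


def transformation_key(cgr: CGR) -> str:
    """Canonical, atom-order-invariant string identifying the transformation.

    Weisfeiler–Lehman graph hash over element/charge node labels and
    (before, after) edge labels; isomorphic CGRs share a key, so reactions of
    the same transformation can be grouped regardless of atom numbering.
    """
    return nx.weisfeiler_lehman_graph_hash(
        to_networkx(cgr), node_attr="label", edge_attr="label", iterations=4
    )


def dump(cgr: CGR) -> str:
    """Human-readable adjacency dump, one bond per line: ``C1-C2 [2>1]``."""
    lines = []
    for i, j, (r, p) in cgr.bonds:
        ai, aj = cgr.atoms[i], cgr.atoms[j]
        lines.append(f"{ai.element}{i}-{aj.element}{j} [{r}>{p}]")
    return "\n".join(lines)
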