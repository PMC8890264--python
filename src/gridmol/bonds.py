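"""Bond inference: from typed atoms to a valid molecule.

Given a set of typed atoms (element, aromaticity, H-bond roles, formal charge
and 3D coordinates — typically the output of atom fitting), a deterministic
sequence of rules constructs bonds, bond orders, hydrogens and charges:

1. *Connect*: propose a bond between atoms closer than the sum of their
   covalent radii plus a tolerance (and farther than a 0.4 Å clash floor).
2. *Prune*: while an atom carries more bonds than its maximum valence, its
   longest bond is removed.
3. *Aromatic rings*: rings of allowed size (5, 6) whose atoms are all
   aromatic-typed become aromatic; a Kekulé structure is found by maximum
   matching over ring atoms that can accept a double bond (carbons, and
   2-coordinate non-donor nitrogens — donor-flagged or 3-coordinate N, and
   O/S, contribute a lone pair instead).
4. *Order raising*: remaining bonds are upgraded to double/triple, shortest
   first, when the observed length is short relative to the covalent-radius
   sum (<= 0.93x for double, <= 0.82x for triple) and free valence permits.
5. *Charges* come from the type vectors' charge block, never re-perceived.
6. *Hydrogens*: implicit counts fill the smallest admissible valence that
   accommodates the bond-order sum; donor-typed atoms must keep >= 1 H.

Covalent radii are the Cordero 2008 consensus values.  Validity requires a
single connected fragment and a successful RDKit sanitization of the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .atom_types import TypedStruct, untype

__all__ = ["BondRules", "Bond", "InferredMolecule", "connect_atoms",
           "assign_bond_orders", "add_hydrogens", "make_molecule"]

# Cordero et al. 2008 single-bond covalent radii (Å); C is the sp3 value,
# Fe the low-spin value.
COVALENT_RADII = {
    "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Fe": 1.32,
    "Na": 1.66, "Mg": 1.41, "K": 2.03, "Ca": 1.76, "Zn": 1.22,
}

# Admissible total valences (bond-order sum + implicit H) per neutral element.
VALENCES = {
    "B": (3,), "C": (4,), "N": (3,), "O": (2,), "F": (1,),
    "P": (3, 5), "S": (2, 4, 6), "Cl": (1,), "Br": (1,), "I": (1,),
    "Fe": (2, 3, 6), "Na": (1,), "Mg": (2,), "K": (1,), "Ca": (2,), "Zn": (2,),
}


def allowed_valences(element: str, charge: int = 0):
    """Charge-adjusted admissible valences (nonpositive entries dropped)."""
    base = VALENCES[element]
    if charge == 0:
        return base
    if element in ("N", "P", "O", "S"):
        adj = tuple(v + charge for v in base)
    elif element == "B":
        adj = tuple(v - charge for v in base)
    elif element == "C":
        adj = tuple(v - abs(charge) for v in base)
    else:
        adj = base
    return tuple(v for v in adj if v > 0) or (1,)


@dataclass(frozen=True)
class BondRules:
    covalent_radii: dict = field(default_factory=lambda: dict(COVALENT_RADII))
    bond_tolerance: float = 0.45
    clash_floor: float = 0.4
    valences: dict = field(default_factory=lambda: dict(VALENCES))
    aromatic_ring_sizes: frozenset = frozenset({5, 6})
    double_ratio: float = 0.93
    triple_ratio: float = 0.82

    def max_valence(self, element: str, charge: int = 0) -> int:
        return max(allowed_valences(element, charge))


@dataclass
class Bond:
    i: int
    j: int
    order: int = 1
    aromatic: bool = False


@dataclass
class InferredMolecule:
    """Atoms + bonds + hydrogens + charges with a validity verdict."""

    elements: list
    coordinates: np.ndarray
    charges: list
    aromatic_atoms: list
    donor_atoms: list
    acceptor_atoms: list
    bonds: list
    implicit_h: list = field(default_factory=list)
    valid: bool = True
    failure_reason: str | None = None

    def mark_invalid(self, reason: str):
        self.valid = False
        if self.failure_reason is None:
            self.failure_reason = reason

    def bond_order_sum(self, i: int) -> int:
        return sum(b.order for b in self.bonds if i in (b.i, b.j))

    def to_rdkit(self, with_conformer: bool = True) -> Chem.Mol:
        """Kekulé RDKit molecule with explicit H counts; not sanitized."""
        rw = Chem.RWMol()
        for k, el in enumerate(self.elements):
            a = Chem.Atom(el)
            a.SetFormalCharge(int(self.charges[k]))
            if self.implicit_h:
                a.SetNumExplicitHs(int(self.implicit_h[k]))
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for b in self.bonds:
            rw.AddBond(b.i, b.j, order_map[b.order])
        mol = rw.GetMol()
        if with_conformer and len(self.elements):
            conf = Chem.Conformer(len(self.elements))
            for k, xyz in enumerate(np.atleast_2d(self.coordinates)):
                conf.SetAtomPosition(k, Point3D(*map(float, xyz)))
            mol.AddConformer(conf)
        return mol

    def canonical_smiles(self) -> str | None:
        try:
            mol = self.to_rdkit(with_conformer=False)
            Chem.SanitizeMol(mol)
            return Chem.MolToSmiles(mol)
        except Exception:
            return None


def _decode(struct: TypedStruct):
    rows = [untype(a.type_vector, struct.scheme) for a in struct.atoms]
    elements = [r[0] for r in rows]
    aromatic = [r[1] for r in rows]
    acceptor = [r[2] for r in rows]
    donor = [r[3] for r in rows]
    charge = [r[4] for r in rows]
    return elements, aromatic, acceptor, donor, charge


def connect_atoms(struct: TypedStruct, rules: BondRules = BondRules()):
    """Distance-based bond proposal with valence-count pruning.

    Returns a list of :class:`Bond` (all order 1).  A bond is proposed iff the
    interatomic distance lies in (clash_floor, r_i + r_j + tolerance]; atoms
    exceeding their maximum valence in bond count lose their longest bonds.
    """
    if len(struct) == 0:
        return []
    elements, _, _, _, charges = _decode(struct)
    coords = struct.coordinates
    n = len(elements)
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    proposed = []
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = rules.covalent_radii[elements[i]] + rules.covalent_radii[elements[j]] + rules.bond_tolerance
            if rules.clash_floor < dist[i, j] <= cutoff:
                proposed.append((dist[i, j], i, j))
    proposed.sort()
    counts = [0] * n
    kept = []
    for d, i, j in proposed:
        kept.append((d, i, j))
        counts[i] += 1
        counts[j] += 1
    # prune longest bonds of over-valent atoms
    changed = True
    while changed:
        changed = False
        for a in range(n):
            cap = rules.max_valence(elements[a], charges[a])
            if counts[a] > cap:
                for d, i, j in reversed(kept):
                    if a in (i, j):
                        kept.remove((d, i, j))
                        counts[i] -= 1
                        counts[j] -= 1
                        changed = True
                        break
    return [Bond(i, j) for _, i, j in kept]


def assign_bond_orders(struct: TypedStruct, bonds: list, rules: BondRules = BondRules()) -> InferredMolecule:
    """Aromatic-ring kekulization plus length-based order raising."""
    elements, aromatic, acceptor, donor, charges = _decode(struct)
    coords = struct.coordinates
    mol = InferredMolecule(
        elements=elements, coordinates=coords, charges=charges,
        aromatic_atoms=aromatic, donor_atoms=donor, acceptor_atoms=acceptor,
        bonds=[Bond(b.i, b.j) for b in bonds],
    )
    if not bonds:
        return mol
    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    bond_by_pair = {}
    for b in mol.bonds:
        g.add_edge(b.i, b.j)
        bond_by_pair[frozenset((b.i, b.j))] = b

    # aromatic rings of allowed size with all-aromatic-typed atoms
    ring_atoms = set()
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) in rules.aromatic_ring_sizes and all(aromatic[a] for a in cycle):
            sub = g.subgraph(cycle)
            for u, v in sub.edges():
                bond_by_pair[frozenset((u, v))].aromatic = True
            ring_atoms.update(cycle)

    # kekulize: maximum matching over ring atoms able to take a double bond
    def eligible(a: int) -> bool:
        el = elements[a]
        if el == "C":
            return True
        if el in ("N", "P"):
            return g.degree(a) == 2 and not donor[a]
        return False  # O, S and the rest contribute a lone pair

    arom_edges = [(b.i, b.j) for b in mol.bonds if b.aromatic and eligible(b.i) and eligible(b.j)]
    need = {a for a in ring_atoms if eligible(a)}
    if need:
        kg = nx.Graph(arom_edges)
        matching = nx.max_weight_matching(kg, maxcardinality=True)
        matched = {a for pair in matching for a in pair}
        if need - matched:
            mol.mark_invalid("kekulization/aromaticity failure")
        for u, v in matching:
            bond_by_pair[frozenset((u, v))].order = 2

    # raise remaining bond orders by length, shortest first, within free valence
    def free_valence(a: int) -> int:
        return rules.max_valence(elements[a], charges[a]) - mol.bond_order_sum(a)

    nonring = [b for b in mol.bonds if not b.aromatic]
    nonring.sort(key=lambda b: np.linalg.norm(coords[b.i] - coords[b.j]))
    for b in nonring:
        d = float(np.linalg.norm(coords[b.i] - coords[b.j]))
        ref = rules.covalent_radii[elements[b.i]] + rules.covalent_radii[elements[b.j]]
        want = 3 if d <= rules.triple_ratio * ref else 2 if d <= rules.double_ratio * ref else 1
        raise_by = min(want - b.order, free_valence(b.i), free_valence(b.j))
        if raise_by > 0:
            b.order += raise_by
    return mol


def add_hydrogens(mol: InferredMolecule, rules: BondRules = BondRules()) -> InferredMolecule:
    """Implicit hydrogens fill the smallest admissible valence per atom."""
    mol.implicit_h = []
    for a, el in enumerate(mol.elements):
        vsum = mol.bond_order_sum(a)
        options = [v for v in allowed_valences(el, mol.charges[a]) if v >= vsum]
        if not options:
            mol.mark_invalid("valence exceeded")
            mol.implicit_h.append(0)
            continue
        h = options[0] - vsum
        if mol.donor_atoms[a] and h == 0:
            bigger = [v for v in allowed_valences(el, mol.charges[a]) if v > vsum]
            if bigger:
                h = bigger[0] - vsum
            else:
                mol.mark_invalid("donor without H")
        mol.implicit_h.append(h)
    return mol


def make_molecule(struct: TypedStruct, rules: BondRules = BondRules()) -> InferredMolecule:
    """Full inference pipeline: connect -> orders -> charges -> H -> sanity."""
    if len(struct) == 0:
        out = InferredMolecule([], np.zeros((0, 3)), [], [], [], [], [])
        out.mark_invalid("no atoms")
        return out
    bonds = connect_atoms(struct, rules)
    mol = assign_bond_orders(struct, bonds, rules)
    mol = add_hydrogens(mol, rules)
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.elements)))
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    if nx.number_connected_components(g) != 1:
        mol.mark_invalid("multiple fragments")
    if mol.valid:
        try:
            rd = mol.to_rdkit(with_conformer=False)
            Chem.SanitizeMol(rd)
        except Exception as exc:  # valence/kekulization problems surface here
            mol.mark_invalid(f"sanitization failure: {exc}")
    return mol
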