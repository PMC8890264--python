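"""Property-based atom typing.

Heavy atoms are mapped to fixed-length type vectors formed by concatenating
one-hot / indicator blocks for a small set of atomic properties: element,
aromaticity, hydrogen-bond acceptor and donor roles, and formal charge.
Hydrogens are never typed; they are recovered downstream by bond inference.

Two 18-channel schemes are provided, one per structural role:

=================  ====================================  ===========
property           values (ligand / receptor)            num. values
=================  ====================================  ===========
element            B C N O F P S Cl Br I Fe  (ligand)    11
                   C N O Na Mg P S Cl K Ca Zn (receptor) 11
aromatic           false, true                           2
H-bond acceptor    true                                  1
H-bond donor       true                                  1
formal charge      -1, 0, +1                             3
=================  ====================================  ===========

Properties are concatenated in the table's row order; within a property,
values in listed order. Donor/acceptor roles follow the common SMARTS-based
definitions shipped with RDKit's Lipinski descriptors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "AtomProperty",
    "TypeScheme",
    "TypedAtom",
    "TypedStruct",
    "LIGAND_ELEMENTS",
    "RECEPTOR_ELEMENTS",
    "default_scheme",
    "type_atom",
    "type_molecule",
    "untype",
    "scheme_to_json",
    "scheme_from_json",
]

LIGAND_ELEMENTS = ("B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "Fe")
RECEPTOR_ELEMENTS = ("C", "N", "O", "Na", "Mg", "P", "S", "Cl", "K", "Ca", "Zn")

# RDKit Lipinski-style H-bond role definitions, pinned here so behaviour
# does not drift with toolkit versions.
_DONOR_SMARTS = "[$([N;!H0;v3,v4&+1]),$([O,S;!H0;+0]),n&H1&+0]"
_ACCEPTOR_SMARTS = (
    "[$([O,S;!H0;v2;!$(*-*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),"
    "$([N;v3;!$(N-*=[O,N,P,S])]),n&H0&+0,$([o,s;+0;!$([o,s]:n);!$([o,s]:c:n)])]"
)


class TypingError(ValueError):
    """Raised when an atom or vector cannot be expressed in a scheme."""


@dataclass(frozen=True)
class AtomProperty:
    """One atomic property and its ordered admissible values."""

    name: str
    values: tuple

    def __post_init__(self):
        if len(self.values) < 1:
            raise ValueError(f"property {self.name!r} has no values")
        if len(set(self.values)) != len(self.values):
            raise ValueError(f"property {self.name!r} has duplicate values")

    @property
    def width(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TypeScheme:
    """Ordered list of atomic properties defining the channel layout."""

    role: str
    properties: tuple

    @property
    def total_width(self) -> int:
        return sum(p.width for p in self.properties)

    @property
    def elements(self) -> tuple:
        return self.get_property("element").values

    def get_property(self, name: str) -> AtomProperty:
        for p in self.properties:
            if p.name == name:
                return p
        raise KeyError(name)

    def block_slice(self, name: str) -> slice:
        """Channel index range of one property block."""
        start = 0
        for p in self.properties:
            if p.name == name:
                return slice(start, start + p.width)
            start += p.width
        raise KeyError(name)

    def channel_labels(self) -> list:
        return [f"{p.name}:{v}" for p in self.properties for v in p.values]

    def has_property(self, name: str) -> bool:
        return any(p.name == name for p in self.properties)

    @property
    def n_element_channels(self) -> int:
        return self.get_property("element").width


@dataclass
class TypedAtom:
    """A heavy atom as a 3D coordinate plus a type vector."""

    coordinate: np.ndarray
    type_vector: np.ndarray

    def __post_init__(self):
        self.coordinate = np.asarray(self.coordinate, dtype=float).reshape(3)
        self.type_vector = np.asarray(self.type_vector, dtype=float)


@dataclass
class TypedStruct:
    """A set of typed atoms — the atomistic twin of a density grid."""

    atoms: list
    scheme: TypeScheme

    def __post_init__(self):
        for a in self.atoms:
            if a.type_vector.shape != (self.scheme.total_width,):
                raise TypingError(
                    f"type vector length {a.type_vector.shape} does not match "
                    f"scheme width {self.scheme.total_width}"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coordinate for a in self.atoms])

    @property
    def type_vectors(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, self.scheme.total_width))
        return np.array([a.type_vector for a in self.atoms])

    @property
    def centroid(self) -> np.ndarray:
        return self.coordinates.mean(axis=0)


def default_scheme(role: str) -> TypeScheme:
    """Default 18-channel scheme for ``role`` in {"ligand", "receptor"}."""
    if role == "ligand":
        elements = LIGAND_ELEMENTS
    elif role == "receptor":
        elements = RECEPTOR_ELEMENTS
    else:
        raise TypingError(f"unknown role {role!r}; expected 'ligand' or 'receptor'")
    return TypeScheme(
        role=role,
        properties=(
            AtomProperty("element", elements),
            AtomProperty("aromatic", (False, True)),
            AtomProperty("acceptor", (True,)),
            AtomProperty("donor", (True,)),
            AtomProperty("charge", (-1, 0, 1)),
        ),
    )


def type_atom(element, aromatic, acceptor, donor, charge, scheme: TypeScheme) -> np.ndarray:
    """Concatenated one-hot/indicator vector for one atom's properties."""
    vec = np.zeros(scheme.total_width)
    elem_prop = scheme.get_property("element")
    if element not in elem_prop.values:
        raise TypingError(f"unsupported element {element!r} for role {scheme.role!r}")
    vec[scheme.block_slice("element").start + elem_prop.values.index(element)] = 1.0
    if scheme.has_property("charge"):
        charge_prop = scheme.get_property("charge")
        if charge not in charge_prop.values:
            raise TypingError(f"formal charge {charge} outside range {charge_prop.values}")
        vec[scheme.block_slice("charge").start + charge_prop.values.index(charge)] = 1.0
    if scheme.has_property("aromatic"):
        vec[scheme.block_slice("aromatic").start + int(bool(aromatic))] = 1.0
    if acceptor and scheme.has_property("acceptor"):
        vec[scheme.block_slice("acceptor")] = 1.0
    if donor and scheme.has_property("donor"):
        vec[scheme.block_slice("donor")] = 1.0
    return vec


def untype(type_vector: np.ndarray, scheme: TypeScheme):
    """Invert :func:`type_atom`: argmax within one-hot blocks, 0.5 threshold on
    indicator blocks. Exact left-inverse on valid vectors."""
    v = np.asarray(type_vector, dtype=float)
    if v.shape != (scheme.total_width,):
        raise TypingError("type vector length does not match scheme")
    eb = v[scheme.block_slice("element")]
    if not np.any(eb > 0):
        raise TypingError("untypable density: all-zero element block")
    element = scheme.get_property("element").values[int(np.argmax(eb))]
    aromatic = acceptor = donor = False
    charge = 0
    if scheme.has_property("aromatic"):
        ab = v[scheme.block_slice("aromatic")]
        aromatic = bool(np.argmax(ab)) if np.any(ab > 0) else False
    if scheme.has_property("acceptor"):
        acceptor = bool(v[scheme.block_slice("acceptor")][0] >= 0.5)
    if scheme.has_property("donor"):
        donor = bool(v[scheme.block_slice("donor")][0] >= 0.5)
    if scheme.has_property("charge"):
        cb = v[scheme.block_slice("charge")]
        charge = scheme.get_property("charge").values[int(np.argmax(cb))] if np.any(cb >= 0.5) else 0
    return element, aromatic, acceptor, donor, charge


def _perceive_roles(mol: Chem.Mol):
    donor_q = Chem.MolFromSmarts(_DONOR_SMARTS)
    acceptor_q = Chem.MolFromSmarts(_ACCEPTOR_SMARTS)
    donors = {i for (i,) in mol.GetSubstructMatches(donor_q)}
    acceptors = {i for (i,) in mol.GetSubstructMatches(acceptor_q)}
    return donors, acceptors


def type_molecule(mol: Chem.Mol, scheme: TypeScheme, conf_id: int = -1) -> TypedStruct:
    """Type every heavy atom of an RDKit molecule with 3D coordinates.

    Aromaticity, H-bond roles and formal charges are taken from the molecule's
    RDKit perception; hydrogens are excluded.
    """
    if mol.GetNumConformers() == 0:
        raise TypingError("molecule has no 3D coordinates")
    conf = mol.GetConformer(conf_id)
    donors, acceptors = _perceive_roles(mol)
    elements = scheme.get_property("element").values
    bad = [
        f"{a.GetSymbol()}#{a.GetIdx()}"
        for a in mol.GetAtoms()
        if a.GetAtomicNum() > 1 and a.GetSymbol() not in elements
    ]
    if bad:
        raise TypingError(f"unsupported elements for role {scheme.role!r}: {bad}")
    atoms = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() <= 1:
            continue
        pos = conf.GetAtomPosition(a.GetIdx())
        vec = type_atom(
            a.GetSymbol(),
            a.GetIsAromatic(),
            a.GetIdx() in acceptors,
            a.GetIdx() in donors,
            int(np.clip(a.GetFormalCharge(), -1, 1)),
            scheme,
        )
        atoms.append(TypedAtom(np.array([pos.x, pos.y, pos.z]), vec))
    return TypedStruct(atoms=atoms, scheme=scheme)


def scheme_to_json(scheme: TypeScheme) -> str:
    return json.dumps(
        {
            "role": scheme.role,
            "properties": [
                {"name": p.name, "values": list(p.values)} for p in scheme.properties
            ],
        },
        indent=2,
    )


def scheme_from_json(text: str) -> TypeScheme:
    d = json.loads(text)
    return TypeScheme(
        role=d["role"],
        properties=tuple(
            AtomProperty(p["name"], tuple(p["values"])) for p in d["properties"]
        ),
    )
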