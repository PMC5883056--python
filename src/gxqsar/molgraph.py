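"""Hydrogen-suppressed molecular graphs from SMILES.

The graph is the substrate for every 2D descriptor in the package: each heavy
atom carries the counts the electrotopological-state (E-state) machinery needs
(sigma degree, attached hydrogens, valence electrons, principal quantum
number), bonds carry discrete Kekulé orders, and an all-pairs topological
distance matrix (shortest path in bonds) is attached to the graph.

Conventions
-----------
* Hydrogens are suppressed: they exist only as per-atom ``attached_h`` counts.
  (MMFF94 typing expands hydrogens internally, see :func:`mmff_numeric_types`.)
* Aromatic systems are Kekulized deterministically; E-state atom typing and
  ``double_bond_count`` are read off the Kekulé structure, while the
  ``aromatic`` flag records the perceived aromaticity.
* Atom indices are 0-based everywhere inside the library.
* Multi-fragment inputs are accepted; cross-fragment distances are infinite
  and the fragment count is recorded so downstream descriptors can ignore
  cross-fragment pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

from .errors import SmilesParseError, VocabularyError

RDLogger.DisableLog("rdApp.*")

_PERIODIC_TABLE = Chem.GetPeriodicTable()

# bond-symbol ordering used by systematic E-state labels (tsC, dsCH, ssssC ...)
_BOND_SYMBOL = {3: "t", 2: "d", 1: "s"}
_BOND_SORT = {"t": 0, "d": 1, "s": 2}


def principal_quantum_number(atomic_num: int) -> int:
    """Row of the periodic table (2 for C/N/O/F, 3 for Si-Cl, ...)."""
    for n, upper in ((1, 2), (2, 10), (3, 18), (4, 36), (5, 54), (6, 86)):
        if atomic_num <= upper:
            return n
    return 7


@dataclass(frozen=True)
class AtomRecord:
    """Per-atom bookkeeping for a heavy atom."""

    element: str
    formal_charge: int
    attached_h: int
    sigma_degree: int          # count of heavy-atom neighbours (delta)
    valence_electrons: int     # Zv
    principal_quantum_number: int
    double_bond_count: int     # Kekulé double bonds at this atom
    aromatic: bool


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph with topological distances.

    ``bonds`` holds ``(i, j, order)`` triples with Kekulé orders in
    ``{1, 2, 3}``; ``distance`` is the symmetric shortest-path matrix in bond
    counts with ``inf`` between fragments.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]]
    distance: np.ndarray
    source_smiles: str = ""
    n_fragments: int = 1
    rdkit_mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def canonical_smiles(self) -> str:
        if self.rdkit_mol is None:
            raise ValueError("graph was built without an RDKit molecule")
        return Chem.MolToSmiles(self.rdkit_mol)


def _distance_from_bonds(n: int, bonds: Sequence[tuple[int, int, int]]) -> np.ndarray:
    """All-pairs shortest path by breadth-first search from every atom."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b, _ in bonds:
        adj[a].append(b)
        adj[b].append(a)
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0.0
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if not np.isfinite(dist[src, v]):
                        dist[src, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def from_rdkit(mol: Chem.Mol, source_smiles: str = "") -> MolecularGraph:
    """Build a :class:`MolecularGraph` from a sanitized RDKit molecule."""
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    double_counts = [0] * mol.GetNumAtoms()
    bonds: list[tuple[int, int, int]] = []
    for bond in kek.GetBonds():
        order = int(round(bond.GetBondTypeAsDouble()))
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds.append((i, j, order))
        if order == 2:
            double_counts[i] += 1
            double_counts[j] += 1

    atoms = []
    for atom in mol.GetAtoms():
        atoms.append(
            AtomRecord(
                element=atom.GetSymbol(),
                formal_charge=atom.GetFormalCharge(),
                attached_h=atom.GetTotalNumHs(),
                sigma_degree=atom.GetDegree(),
                valence_electrons=_PERIODIC_TABLE.GetNOuterElecs(atom.GetAtomicNum()),
                principal_quantum_number=principal_quantum_number(atom.GetAtomicNum()),
                double_bond_count=double_counts[atom.GetIdx()],
                aromatic=atom.GetIsAromatic(),
            )
        )

    n = mol.GetNumAtoms()
    if n:
        dist = np.asarray(rdmolops.GetDistanceMatrix(mol), dtype=float).copy()
        dist[dist > 1e7] = np.inf
    else:
        dist = np.zeros((0, 0))
    frags = len(rdmolops.GetMolFrags(mol)) if n else 0
    return MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        distance=dist,
        source_smiles=source_smiles,
        n_fragments=frags,
        rdkit_mol=mol,
    )


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Raises
    ------
    SmilesParseError
        If the string is empty, syntactically invalid, or chemically
        unsanitizable (the message names the offending atom where RDKit
        can identify it).
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES syntax: {smiles!r}")
    problems = Chem.DetectChemistryProblems(mol)
    if problems:
        detail = "; ".join(p.Message() for p in problems)
        raise SmilesParseError(f"cannot sanitize {smiles!r}: {detail}")
    Chem.SanitizeMol(mol)
    return from_rdkit(mol, source_smiles=smiles)


def from_atoms_bonds(
    elements: Sequence[str],
    bonds: Sequence[tuple[int, int, int]],
    attached_h: Optional[Sequence[int]] = None,
    formal_charge: Optional[Sequence[int]] = None,
) -> MolecularGraph:
    """Assemble a graph directly from atoms and bonds (no SMILES round trip).

    Used for synthetic/random graphs in property testing; hydrogen counts
    default to filling standard valence where possible, else zero.
    """
    n = len(elements)
    degree = [0] * n
    double = [0] * n
    for a, b, order in bonds:
        if not (0 <= a < n and 0 <= b < n) or a == b:
            raise ValueError(f"invalid bond ({a}, {b})")
        degree[a] += 1
        degree[b] += 1
        if order == 2:
            double[a] += 1
            double[b] += 1
    bond_order_sum = [0] * n
    for a, b, order in bonds:
        bond_order_sum[a] += order
        bond_order_sum[b] += order
    atoms = []
    for i, el in enumerate(elements):
        num = _PERIODIC_TABLE.GetAtomicNumber(el)
        charge = formal_charge[i] if formal_charge is not None else 0
        if attached_h is not None:
            h = attached_h[i]
        else:
            default_val = _PERIODIC_TABLE.GetDefaultValence(num)
            h = max(default_val - bond_order_sum[i], 0) if default_val > 0 else 0
        atoms.append(
            AtomRecord(
                element=el,
                formal_charge=charge,
                attached_h=h,
                sigma_degree=degree[i],
                valence_electrons=_PERIODIC_TABLE.GetNOuterElecs(num),
                principal_quantum_number=principal_quantum_number(num),
                double_bond_count=double[i],
                aromatic=False,
            )
        )
    dist = _distance_from_bonds(n, bonds)
    # fragment count = number of connected components
    comp = 0
    seen = [False] * n
    for i in range(n):
        if not seen[i]:
            comp += 1
            for j in range(n):
                if np.isfinite(dist[i, j]):
                    seen[j] = True
    return MolecularGraph(
        atoms=atoms, bonds=list(bonds), distance=dist, n_fragments=comp
    )


def estate_atom_type(graph: MolecularGraph, atom_index: int) -> str:
    """Systematic E-state atom-type label (e.g. ``dsCH``, ``ssssC``).

    The label concatenates the Kekulé bond symbols at the atom (``t`` before
    ``d`` before ``s``), the element symbol, and the attached-hydrogen suffix.
    An isolated heavy atom gets just ``element + H-suffix`` (e.g. ``CH4``).
    """
    if not 0 <= atom_index < graph.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    symbols = []
    for a, b, order in graph.bonds:
        if atom_index in (a, b):
            symbols.append(_BOND_SYMBOL[order])
    symbols.sort(key=_BOND_SORT.__getitem__)
    atom = graph.atoms[atom_index]
    h = atom.attached_h
    suffix = "" if h == 0 else ("H" if h == 1 else f"H{h}")
    return "".join(symbols) + atom.element + suffix


def _load_mmff_symbol_table() -> dict[int, str]:
    text = resources.files("gxqsar.data").joinpath("mmff94_symbolic_types.json").read_text()
    return {int(k): v for k, v in json.loads(text).items()}


_MMFF_SYMBOLS: Optional[dict[int, str]] = None

UNTYPED = "untyped"


def mmff_symbol_table() -> dict[int, str]:
    """Numeric MMFF94 type -> symbolic label table (shipped as data)."""
    global _MMFF_SYMBOLS
    if _MMFF_SYMBOLS is None:
        _MMFF_SYMBOLS = _load_mmff_symbol_table()
    return _MMFF_SYMBOLS


def mmff_numeric_types(graph: MolecularGraph) -> list[int]:
    """MMFF94 numeric atom types over the hydrogen-expanded molecule.

    Heavy atoms come first in input order, then the added hydrogens. Atoms the
    MMFF94 parameterization cannot type yield 0 (mapped to ``untyped`` by
    :func:`mmff_symbolic_type`).
    """
    if graph.rdkit_mol is None:
        raise ValueError("MMFF typing requires an RDKit-backed graph")
    from rdkit.Chem import AllChem

    molh = Chem.AddHs(graph.rdkit_mol)
    props = AllChem.MMFFGetMoleculeProperties(molh)
    if props is None:
        return [0] * molh.GetNumAtoms()
    return [props.GetMMFFAtomType(i) for i in range(molh.GetNumAtoms())]


def mmff_symbolic_type(graph: MolecularGraph, atom_index: int) -> str:
    """MMFF94 symbolic type of a heavy atom; ``untyped`` when unparameterized."""
    if not 0 <= atom_index < graph.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    numeric = mmff_numeric_types(graph)[atom_index]
    if numeric == 0:
        return UNTYPED
    return mmff_symbol_table().get(numeric, f"MMFF_{numeric}")


def read_smiles_file(path) -> list[tuple[str, MolecularGraph]]:
    """Read a one-SMILES-per-line file; optional whitespace-separated name."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            out.append((name, parse_smiles(smiles)))
    return out


def read_sdf(path) -> list[tuple[str, MolecularGraph]]:
    """Read structures from an SDF (V2000) file; 3D coordinates are ignored."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise SmilesParseError(f"unreadable record {i + 1} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
        out.append((name or f"mol{i + 1}", from_rdkit(mol, Chem.MolToSmiles(mol))))
    return out
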