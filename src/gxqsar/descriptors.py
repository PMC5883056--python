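"""2D descriptor calculators: E-state indices, topological pair counts,
atom-type counts, the carbon electronegativity spread, and rule-of-five
properties.

The electrotopological state of atom *i* follows the standard Kier–Hall
formulation::

    delta_v_i = Zv - h                    (second-row atoms)
              = (Zv - h) / (Z - Zv - 1)   (higher rows)
    I_i  = ((2 / N)^2 * delta_v_i + 1) / delta_i
    dI_i = sum_j (I_i - I_j) / (d_ij + 1)^2
    S_i  = I_i + dI_i

with ``delta`` the heavy-atom degree, ``h`` the attached hydrogens, ``N`` the
principal quantum number and ``d_ij`` the topological (bond-count) distance.
Group indices such as ``SdsCHE-index`` sum ``S`` over atoms of the named
bonding environment; ``SssssCcount`` and the ``T_x_y_d`` pair descriptors are
pure counts. ``DeltaEpsilonC`` is the spread (max - min) of the Kier–Hall
relative electronegativity ``eps = (delta_v - delta) / N^2`` over carbon
atoms.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, Lipinski

from . import __version__ as _version
from .errors import VocabularyError
from .molgraph import MolecularGraph, estate_atom_type, mmff_numeric_types

_PT = Chem.GetPeriodicTable()


@dataclass
class AtomEState:
    """Per-atom E-state quantities for one molecule.

    ``undefined`` lists atoms whose intrinsic state is undefined (isolated
    heavy atoms with degree 0 under the default policy); their entries are
    NaN and they are excluded from the pairwise perturbation sums.
    """

    delta: np.ndarray
    delta_v: np.ndarray
    principal_quantum_number: np.ndarray
    intrinsic_state: np.ndarray
    perturbation: np.ndarray
    estate: np.ndarray          # S = I + dI
    electronegativity: np.ndarray
    undefined: list[int] = field(default_factory=list)


def estate_values(graph: MolecularGraph, isolated_policy: str = "flag") -> AtomEState:
    """Compute Kier–Hall E-state values for every heavy atom.

    ``isolated_policy`` controls degree-0 atoms: ``"flag"`` (default) marks
    them undefined; ``"unit-delta"`` evaluates I with delta treated as 1.
    """
    if graph.n_atoms < 1:
        raise ValueError("empty graph")
    n = graph.n_atoms
    delta = np.array([a.sigma_degree for a in graph.atoms], dtype=float)
    pqn = np.array([a.principal_quantum_number for a in graph.atoms], dtype=float)
    delta_v = np.empty(n)
    for i, a in enumerate(graph.atoms):
        z = _PT.GetAtomicNumber(a.element)
        zv = a.valence_electrons
        raw = zv - a.attached_h
        delta_v[i] = raw if a.principal_quantum_number <= 2 else raw / (z - zv - 1)

    undefined = [i for i in range(n) if delta[i] == 0]
    eff_delta = delta.copy()
    if isolated_policy == "unit-delta":
        eff_delta[eff_delta == 0] = 1.0
        undefined = []
    elif isolated_policy != "flag":
        raise ValueError(f"unknown isolated_policy {isolated_policy!r}")

    intrinsic = np.full(n, np.nan)
    ok = eff_delta > 0
    intrinsic[ok] = ((2.0 / pqn[ok]) ** 2 * delta_v[ok] + 1.0) / eff_delta[ok]

    perturb = np.full(n, np.nan)
    damp = (graph.distance + 1.0) ** 2
    defined = np.where(ok)[0]
    for i in defined:
        terms = 0.0
        for j in defined:
            if i == j or not np.isfinite(graph.distance[i, j]):
                continue
            terms += (intrinsic[i] - intrinsic[j]) / damp[i, j]
        perturb[i] = terms

    eps = (delta_v - delta) / pqn**2
    return AtomEState(
        delta=delta,
        delta_v=delta_v,
        principal_quantum_number=pqn.astype(int),
        intrinsic_state=intrinsic,
        perturbation=perturb,
        estate=intrinsic + perturb,
        electronegativity=eps,
        undefined=undefined,
    )


def estate_group_index(graph: MolecularGraph, type_label: str) -> float:
    """Sum of atom-level S over atoms of the given E-state type (0.0 if none)."""
    values = estate_values(graph)
    total = 0.0
    for i in range(graph.n_atoms):
        if estate_atom_type(graph, i) == type_label:
            total += values.estate[i]
    return total


_ESTATE_LABEL_RE = re.compile(r"^[tds]*[A-Z][a-z]?(H\d?)?$")
_MMFF_LABEL_RE = re.compile(r"^MMFF_(\d+)$")


def atom_type_count(graph: MolecularGraph, type_label: str) -> int:
    """Count atoms carrying an E-state label (``ssssC``) or an MMFF numeric
    type (``MMFF_29``; counted over the hydrogen-expanded molecule)."""
    m = _MMFF_LABEL_RE.match(type_label)
    if m:
        wanted = int(m.group(1))
        return sum(1 for t in mmff_numeric_types(graph) if t == wanted)
    if not _ESTATE_LABEL_RE.match(type_label):
        raise VocabularyError(type_label, ["<estate label e.g. ssssC/dsCH>", "MMFF_<n>"])
    return sum(
        1 for i in range(graph.n_atoms) if estate_atom_type(graph, i) == type_label
    )


def _pair_class_mask(graph: MolecularGraph, cls: str) -> np.ndarray:
    if cls == "T":
        return np.ones(graph.n_atoms, dtype=bool)
    if cls == "2":
        return np.array([a.double_bond_count > 0 for a in graph.atoms])
    if re.fullmatch(r"[A-Z][a-z]?", cls):
        return np.array([a.element == cls for a in graph.atoms])
    raise VocabularyError(cls, ["T", "2", "<element symbol>"])


def tpair_count(graph: MolecularGraph, class_a: str, class_b: str, d: int) -> int:
    """Count unordered heavy-atom pairs of the two classes at exact topological
    distance ``d`` (cross-fragment pairs, at infinite distance, never count).

    Classes: ``T`` = any heavy atom; an element symbol; ``2`` = atom bearing
    at least one (Kekulé) double bond.
    """
    if d < 1:
        raise ValueError(f"pair distance must be >= 1, got {d}")
    mask_a = _pair_class_mask(graph, class_a)
    mask_b = _pair_class_mask(graph, class_b)
    count = 0
    n = graph.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if graph.distance[i, j] == d and (
                (mask_a[i] and mask_b[j]) or (mask_b[i] and mask_a[j])
            ):
                count += 1
    return count


_HB_RULES: Optional[dict] = None


def hbond_acceptor_rules() -> dict:
    """The include/exclude SMARTS rule set behind H-AcceptorCount (data file)."""
    global _HB_RULES
    if _HB_RULES is None:
        text = resources.files("gxqsar.data").joinpath("hbond_acceptor_rules.json").read_text()
        _HB_RULES = json.loads(text)
    return _HB_RULES


def h_acceptor_count(graph: MolecularGraph) -> int:
    """Count N/O atoms with an available lone pair.

    The shipped rule set includes all N and O atoms, then excludes positively
    charged N/O, amide nitrogens and pyrrole-type (three-coordinate) aromatic
    nitrogens. Distinct from the Lipinski N+O count used by the rule of five.
    """
    if graph.rdkit_mol is None:
        raise ValueError("H-acceptor counting requires an RDKit-backed graph")
    rules = hbond_acceptor_rules()
    mol = graph.rdkit_mol
    included: set[int] = set()
    for smarts in rules["include"]:
        patt = Chem.MolFromSmarts(smarts)
        included.update(m[0] for m in mol.GetSubstructMatches(patt))
    for smarts in rules["exclude"]:
        patt = Chem.MolFromSmarts(smarts)
        included.difference_update(m[0] for m in mol.GetSubstructMatches(patt))
    return len(included)


def delta_epsilon_c(graph: MolecularGraph) -> float:
    """Spread (max - min) of Kier–Hall relative electronegativity over carbons.

    Returns 0.0 when the molecule has fewer than two carbon atoms.
    """
    carbons = [i for i, a in enumerate(graph.atoms) if a.element == "C"]
    if len(carbons) < 2:
        return 0.0
    eps = estate_values(graph).electronegativity[carbons]
    return float(eps.max() - eps.min())


def rule_of_five_properties(graph: MolecularGraph) -> dict:
    """Lipinski rule-of-five inputs: MW (average, g/mol, incl. hydrogens),
    logP (atom-contribution estimate, delegated to RDKit Crippen), HBD
    (N-H plus O-H hydrogen count) and HBA (N plus O atom count).

    A failed logP evaluation yields ``None`` so downstream filters can fail
    closed rather than silently passing the compound.
    """
    if graph.rdkit_mol is None:
        raise ValueError("rule-of-five properties require an RDKit-backed graph")
    mol = graph.rdkit_mol
    try:
        logp: Optional[float] = float(Crippen.MolLogP(mol))
    except Exception:
        logp = None
    return {
        "MW": float(RDDescriptors.MolWt(mol)),
        "logP": logp,
        "HBD": int(Lipinski.NHOHCount(mol)),
        "HBA": int(Lipinski.NOCount(mol)),
    }


@dataclass
class DescriptorVector:
    """Named descriptor values for one molecule, with calculator provenance."""

    values: dict[str, float]
    provenance: str = f"gxqsar-{_version}"

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


_T_PAIR_RE = re.compile(r"^T_([A-Za-z0-9]{1,2})_([A-Za-z0-9]{1,2})_(\d+)$")

_STATIC_CALCULATORS: dict[str, Callable[[MolecularGraph], float]] = {
    "DeltaEpsilonC": delta_epsilon_c,
    "MMFF_29": lambda g: atom_type_count(g, "MMFF_29"),
    "SssssCcount": lambda g: atom_type_count(g, "ssssC"),
    "SdsCHE-index": lambda g: estate_group_index(g, "dsCH"),
    "SdssCE-index": lambda g: estate_group_index(g, "dssC"),
    "SssssCE-index": lambda g: estate_group_index(g, "ssssC"),
    "H-AcceptorCount": h_acceptor_count,
    "MW": lambda g: rule_of_five_properties(g)["MW"],
    "logP": lambda g: rule_of_five_properties(g)["logP"],
    "HBD": lambda g: rule_of_five_properties(g)["HBD"],
    "HBA": lambda g: rule_of_five_properties(g)["HBA"],
}

#: Descriptor sets of the three frozen cell-line models plus the rule of five.
MODEL_DESCRIPTORS: dict[str, list[str]] = {
    "model1": ["DeltaEpsilonC", "MMFF_29", "SssssCcount", "T_2_2_1", "SdsCHE-index"],
    "model2": ["SdssCE-index", "T_2_2_2", "H-AcceptorCount", "SdsCHE-index", "T_O_O_3"],
    "model3": ["T_T_N_4", "T_O_O_3", "SssssCE-index"],
    "ro5": ["MW", "logP", "HBD", "HBA"],
}

_COUNT_DESCRIPTOR_RE = re.compile(r"^(T_.+|MMFF_\d+|SssssCcount|H-AcceptorCount|HBD|HBA)$")


def registered_names() -> list[str]:
    names = set(_STATIC_CALCULATORS)
    names.update(n for group in MODEL_DESCRIPTORS.values() for n in group)
    return sorted(names)


def resolve_descriptor(name: str) -> Callable[[MolecularGraph], float]:
    """Map a descriptor name to its calculator; T_x_y_d names are parsed
    dynamically. Unknown names raise a vocabulary error listing known names."""
    if name in _STATIC_CALCULATORS:
        return _STATIC_CALCULATORS[name]
    m = _T_PAIR_RE.match(name)
    if m:
        a, b, d = m.group(1), m.group(2), int(m.group(3))
        return lambda g: tpair_count(g, a, b, d)
    raise VocabularyError(name, registered_names() + ["T_<class>_<class>_<d>"])


def descriptor_vector(graph: MolecularGraph, descriptor_names: Sequence[str]) -> DescriptorVector:
    """Compute the requested descriptors for one molecule, in request order."""
    calculators = [(n, resolve_descriptor(n)) for n in descriptor_names]
    values: dict[str, float] = {}
    for name, calc in calculators:
        v = calc(graph)
        if v is not None and _COUNT_DESCRIPTOR_RE.match(name):
            v = int(v)
        values[name] = v
    return DescriptorVector(values=values)


def expand_descriptor_request(request: str) -> list[str]:
    """Resolve a CLI-style request (``model1|model2|model3|ro5`` or a
    comma-separated name list) into explicit descriptor names."""
    names: list[str] = []
    for token in request.split(","):
        token = token.strip()
        if token in MODEL_DESCRIPTORS:
            names.extend(n for n in MODEL_DESCRIPTORS[token] if n not in names)
        elif token:
            resolve_descriptor(token)  # validate
            if token not in names:
                names.append(token)
    return names
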