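"""Independent brute-force oracles for the descriptor engine and statistics.

Everything here is deliberately plain and loop-based, and is never imported
by the library: the engine and the oracle cannot share bugs. RDKit is used
only to read SMILES into an atom/bond list; all distances, E-state values,
pair counts and regression statistics are recomputed from first principles.

Running this module as a script regenerates the frozen fixture table
(src/gxqsar/data/fixture_molecules.json) from the oracle implementations.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

# ---------------------------------------------------------------------------
# molecular structure, independent of the library's MolecularGraph
# ---------------------------------------------------------------------------


def mol_tables(smiles):
    """(elements, charges, h_counts, bonds[(i,j,order)], aromatic_flags)."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    hs = [a.GetTotalNumHs() for a in mol.GetAtoms()]
    bonds = []
    for b in kek.GetBonds():
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble())))
    return elements, charges, hs, bonds, mol


def floyd_warshall(n, bonds):
    dist = [[float("inf")] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0.0
    for a, b, _ in bonds:
        dist[a][b] = 1.0
        dist[b][a] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


_ZV = {"C": 4, "N": 5, "O": 6, "F": 7, "S": 6, "Cl": 7, "P": 5, "Br": 7, "I": 7}
_Z = {"C": 6, "N": 7, "O": 8, "F": 9, "S": 16, "Cl": 17, "P": 15, "Br": 35, "I": 53}
_PQN = {"C": 2, "N": 2, "O": 2, "F": 2, "S": 3, "Cl": 3, "P": 3, "Br": 4, "I": 5}


def estate_oracle(smiles):
    """Per-atom (I, dI, S, eps) by direct double loops over ordered pairs."""
    elements, _, hs, bonds, _ = mol_tables(smiles)
    n = len(elements)
    dist = floyd_warshall(n, bonds)
    degree = [0] * n
    for a, b, _ in bonds:
        degree[a] += 1
        degree[b] += 1
    I = [None] * n
    eps = [None] * n
    for i, el in enumerate(elements):
        zv, z, pqn = _ZV[el], _Z[el], _PQN[el]
        dv = (zv - hs[i]) if pqn == 2 else (zv - hs[i]) / (z - zv - 1)
        eps[i] = (dv - degree[i]) / pqn**2
        if degree[i] > 0:
            I[i] = ((2.0 / pqn) ** 2 * dv + 1.0) / degree[i]
    dI = [None] * n
    for i in range(n):
        if I[i] is None:
            continue
        acc = 0.0
        for j in range(n):
            if i == j or I[j] is None or dist[i][j] == float("inf"):
                continue
            acc += (I[i] - I[j]) / (dist[i][j] + 1.0) ** 2
        dI[i] = acc
    S = [None if I[i] is None else I[i] + dI[i] for i in range(n)]
    return I, dI, S, eps


def estate_type_oracle(smiles):
    """Systematic E-state labels from Kekulé bond orders (t < d < s order)."""
    elements, _, hs, bonds, _ = mol_tables(smiles)
    n = len(elements)
    labels = []
    order_key = {"t": 0, "d": 1, "s": 2}
    sym = {1: "s", 2: "d", 3: "t"}
    for i in range(n):
        syms = sorted(
            (sym[o] for a, b, o in bonds if i in (a, b)), key=order_key.__getitem__
        )
        h = hs[i]
        suffix = "" if h == 0 else ("H" if h == 1 else f"H{h}")
        labels.append("".join(syms) + elements[i] + suffix)
    return labels


def group_index_oracle(smiles, label):
    _, _, S, _ = estate_oracle(smiles)
    types = estate_type_oracle(smiles)
    return sum(s for s, t in zip(S, types) if t == label and s is not None)


def type_count_oracle(smiles, label):
    return sum(1 for t in estate_type_oracle(smiles) if t == label)


def tpair_oracle(smiles, cls_a, cls_b, d):
    """Exhaustive double loop over the distance matrix."""
    elements, _, _, bonds, _ = mol_tables(smiles)
    n = len(elements)
    dist = floyd_warshall(n, bonds)
    has_double = [False] * n
    for a, b, o in bonds:
        if o == 2:
            has_double[a] = True
            has_double[b] = True

    def in_class(i, cls):
        if cls == "T":
            return True
        if cls == "2":
            return has_double[i]
        return elements[i] == cls

    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i][j] != d:
                continue
            if (in_class(i, cls_a) and in_class(j, cls_b)) or (
                in_class(i, cls_b) and in_class(j, cls_a)
            ):
                count += 1
    return count


def delta_epsilon_c_oracle(smiles):
    elements, *_ = mol_tables(smiles)
    _, _, _, eps = estate_oracle(smiles)
    carbon_eps = [e for e, el in zip(eps, elements) if el == "C"]
    if len(carbon_eps) < 2:
        return 0.0
    return max(carbon_eps) - min(carbon_eps)


def h_acceptor_oracle(smiles):
    """N/O with lone pair: exclude +charged N/O, amide N, 3-coordinate
    aromatic N (pyrrole-type). Written against atom tables, not SMARTS."""
    elements, charges, hs, bonds, mol = mol_tables(smiles)
    n = len(elements)
    neighbors = [[] for _ in range(n)]
    order_at = {}
    for a, b, o in bonds:
        neighbors[a].append(b)
        neighbors[b].append(a)
        order_at[(a, b)] = o
        order_at[(b, a)] = o
    aromatic = [mol.GetAtomWithIdx(i).GetIsAromatic() for i in range(n)]
    count = 0
    for i in range(n):
        if elements[i] not in ("N", "O") or charges[i] > 0:
            continue
        if elements[i] == "N":
            # amide: N single-bonded to a carbon that is double-bonded to O
            is_amide = False
            for j in neighbors[i]:
                if elements[j] == "C" and order_at[(i, j)] == 1:
                    for k in neighbors[j]:
                        if k != i and elements[k] == "O" and order_at[(j, k)] == 2:
                            is_amide = True
            if is_amide:
                continue
            if aromatic[i] and len(neighbors[i]) + hs[i] == 3:
                continue  # pyrrole-type
        count += 1
    return count


_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


def mw_oracle(smiles):
    elements, _, hs, _, _ = mol_tables(smiles)
    return sum(_ATOMIC_MASS[e] for e in elements) + sum(hs) * _ATOMIC_MASS["H"]


def hbd_hba_oracle(smiles):
    """Lipinski convention: HBD = N-H + O-H hydrogen count, HBA = N + O."""
    elements, _, hs, _, _ = mol_tables(smiles)
    hbd = sum(h for e, h in zip(elements, hs) if e in ("N", "O"))
    hba = sum(1 for e in elements if e in ("N", "O"))
    return hbd, hba


def mmff29_oracle(smiles):
    """Hydrogens on enolic/phenolic oxygens: H on an O that is single-bonded
    to a carbon which carries a C=C double bond (aromatic rings Kekulized),
    and is not a carboxylic acid oxygen."""
    elements, _, hs, bonds, _ = mol_tables(smiles)
    n = len(elements)
    neighbors = [[] for _ in range(n)]
    order_at = {}
    for a, b, o in bonds:
        neighbors[a].append(b)
        neighbors[b].append(a)
        order_at[(a, b)] = o
        order_at[(b, a)] = o
    count = 0
    for i in range(n):
        if elements[i] != "O" or hs[i] == 0:
            continue
        for j in neighbors[i]:
            if elements[j] != "C" or order_at[(i, j)] != 1:
                continue
            # carboxylic: carbon double-bonded to another O -> type HOCO, not 29
            double_to_o = any(
                elements[k] == "O" and order_at[(j, k)] == 2 for k in neighbors[j] if k != i
            )
            double_to_c = any(
                elements[k] == "C" and order_at[(j, k)] == 2 for k in neighbors[j]
            )
            if double_to_c and not double_to_o:
                count += hs[i]
    return count


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------


def normal_equations_fit(X, y):
    """OLS by explicit normal equations (intercept first)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def explicit_loo_q2(X, y):
    """Leave-one-out q² by n explicit refits."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta = normal_equations_fit(X[mask], y[mask])
        pred = beta[0] + X[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - press / sst, press


def rm2_oracle(obs, pred):
    """Spreadsheet-style rm² arithmetic for both axis orders."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)

    def one(x, y):
        xm, ym = x.mean(), y.mean()
        r = ((x - xm) * (y - ym)).sum() / np.sqrt(
            ((x - xm) ** 2).sum() * ((y - ym) ** 2).sum()
        )
        r2 = r**2
        k = (x * y).sum() / (x * x).sum()
        r02 = 1.0 - ((y - k * x) ** 2).sum() / ((y - ym) ** 2).sum()
        return r2 * (1.0 - np.sqrt(abs(r2 - r02)))

    fwd = one(pred, obs)
    rev = one(obs, pred)
    return {"rm2": fwd, "rm2_reverse": rev, "rm2_avg": (fwd + rev) / 2, "rm2_delta": abs(fwd - rev)}


# ---------------------------------------------------------------------------
# fixture molecule set
# ---------------------------------------------------------------------------

FIXTURE_SMILES = [
    ("methane", "C"),
    ("ethane", "CC"),
    ("ethene", "C=C"),
    ("propene", "C=CC"),
    ("butadiene", "C=CC=C"),
    ("isoprene", "C=C(C)C=C"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("catechol", "Oc1ccccc1O"),
    ("ethanol", "CCO"),
    ("glycol", "OCCO"),
    ("glycerol", "OCC(O)CO"),
    ("acetone", "CC(C)=O"),
    ("acetamide", "CC(=O)N"),
    ("acetic_acid", "CC(=O)O"),
    ("glycine", "NCC(=O)O"),
    ("pyridine", "c1ccncc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("aniline", "Nc1ccccc1"),
    ("neopentane", "CC(C)(C)C"),
    ("tbutylbenzene", "CC(C)(C)c1ccccc1"),
    ("acrolein", "C=CC=O"),
    ("diethyl_ether", "CCOCC"),
    ("xanthone", "O=C1c2ccccc2Oc2ccccc21"),
    ("caged_xanthone_core", "CC1(C)OC2=CC3=C(C(=O)C4=CC=CC=C4O3)C(=O)C2=C1"),
]

MODEL_DESCRIPTOR_NAMES = [
    "DeltaEpsilonC",
    "MMFF_29",
    "SssssCcount",
    "T_2_2_1",
    "SdsCHE-index",
    "SdssCE-index",
    "T_2_2_2",
    "H-AcceptorCount",
    "T_O_O_3",
    "T_T_N_4",
    "SssssCE-index",
    "MW",
    "HBD",
    "HBA",
]


def oracle_descriptor_row(smiles):
    row = {
        "DeltaEpsilonC": delta_epsilon_c_oracle(smiles),
        "MMFF_29": mmff29_oracle(smiles),
        "SssssCcount": type_count_oracle(smiles, "ssssC"),
        "T_2_2_1": tpair_oracle(smiles, "2", "2", 1),
        "SdsCHE-index": group_index_oracle(smiles, "dsCH"),
        "SdssCE-index": group_index_oracle(smiles, "dssC"),
        "T_2_2_2": tpair_oracle(smiles, "2", "2", 2),
        "H-AcceptorCount": h_acceptor_oracle(smiles),
        "T_O_O_3": tpair_oracle(smiles, "O", "O", 3),
        "T_T_N_4": tpair_oracle(smiles, "T", "N", 4),
        "SssssCE-index": group_index_oracle(smiles, "ssssC"),
        "MW": mw_oracle(smiles),
    }
    hbd, hba = hbd_hba_oracle(smiles)
    row["HBD"], row["HBA"] = hbd, hba
    return row


def build_fixture_table():
    return [
        {"name": name, "smiles": smiles, "descriptors": oracle_descriptor_row(smiles)}
        for name, smiles in FIXTURE_SMILES
    ]


if __name__ == "__main__":
    import json
    import pathlib

    out = pathlib.Path(__file__).resolve().parents[1] / "src/gxqsar/data/fixture_molecules.json"
    table = build_fixture_table()
    out.write_text(json.dumps(table, indent=1))
    print(f"wrote {len(table)} fixture molecules to {out}")
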