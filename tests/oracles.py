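"""Independent reference implementations used only as test oracles.

Deliberately naive and separate from the package's code paths:

* ``mw_oracle`` — molecular weight as an explicit atomic-weight sum.
* ``tpsa_oracle`` — Ertl's N/O fragment-contribution table, looked up from
  raw atom environments (element, charge, H count, aromaticity, bond-order
  profile, 3-ring membership).
* ``mces_bond_count`` — brute-force maximum common (connected) edge
  subgraph by enumerating connected edge subsets of the smaller graph and
  testing monomorphic embedding in the other.
* ``has_subgraph`` — VF2 substructure check independent of RDKit matching.
"""

from __future__ import annotations

import itertools

import networkx as nx
from rdkit import Chem

# CIAAW standard atomic weights (conventional values)
ATOMIC_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                  "F": 18.998, "S": 32.067, "Cl": 35.453, "Br": 79.904}


def mw_oracle(mol: Chem.Mol) -> float:
    total = 0.0
    for atom in mol.GetAtoms():
        total += ATOMIC_WEIGHTS[atom.GetSymbol()]
        total += atom.GetTotalNumHs() * ATOMIC_WEIGHTS["H"]
    return total


# ---------------------------------------------------------------------------
# Ertl TPSA


def tpsa_oracle(mol: Chem.Mol) -> float:
    total = 0.0
    ri = mol.GetRingInfo()
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z not in (7, 8):
            continue
        nH = atom.GetTotalNumHs()
        chg = atom.GetFormalCharge()
        arom = atom.GetIsAromatic()
        in3 = ri.IsAtomInRingOfSize(atom.GetIdx(), 3)
        s = d = t = a = 0
        for b in atom.GetBonds():
            bt = b.GetBondType()
            if bt == Chem.BondType.AROMATIC:
                a += 1
            elif bt == Chem.BondType.SINGLE:
                s += 1
            elif bt == Chem.BondType.DOUBLE:
                d += 1
            elif bt == Chem.BondType.TRIPLE:
                t += 1
        contrib = _ertl(z, chg, nH, arom, s, d, t, a, in3)
        if contrib is None:
            raise KeyError(
                f"no Ertl contribution for Z={z} charge={chg} H={nH} "
                f"aromatic={arom} bonds(s/d/t/a)={s}/{d}/{t}/{a}")
        total += contrib
    return total


def _ertl(z, chg, nH, arom, ns, nd, nt, na, in3):
    """Contribution lookup; ``ns`` counts heavy-atom single bonds."""
    if z == 7:
        if arom:
            if chg == 0:
                if nH == 0 and na == 2 and ns == 0 and nd == 0:
                    return 12.89
                if nH == 0 and na == 3:
                    return 4.41
                if nH == 0 and na == 2 and ns == 1:
                    return 4.93
                if nH == 0 and na == 2 and nd == 1:
                    return 8.39
                if nH == 1 and na == 2:
                    return 15.79
            if chg == 1:
                if nH == 0 and na == 3:
                    return 4.10
                if nH == 0 and na == 2 and ns == 1:
                    return 3.88
                if nH == 1 and na == 2:
                    return 14.14
            return None
        if chg == 0:
            if nH == 0:
                if ns == 3:
                    return 21.94 if in3 else 3.24
                if ns == 1 and nd == 1:
                    return 12.36
                if nt == 1 and ns == 0:
                    return 23.79
                if ns == 1 and nd == 2:
                    return 11.68
                if nd == 1 and nt == 1:
                    return 13.60
            if nH == 1:
                if ns == 2:
                    return 21.94 if in3 else 12.03
                if nd == 1:
                    return 23.85
            if nH == 2 and ns == 1:
                return 26.02
        if chg == 1:
            if nH == 0:
                if ns == 4:
                    return 0.00
                if ns == 2 and nd == 1:
                    return 3.01
                if ns == 1 and nt == 1:
                    return 4.36
            if nH == 1:
                if ns == 3:
                    return 4.44
                if ns == 1 and nd == 1:
                    return 13.97
            if nH == 2:
                if ns == 2:
                    return 16.61
                if nd == 1:
                    return 25.59
            if nH == 3 and ns == 1:
                return 27.64
        return None
    if arom:
        if chg == 0 and nH == 0 and na == 2:
            return 13.14
        return None
    if chg == 0:
        if nH == 0:
            if ns == 2:
                return 12.53 if in3 else 9.23
            if nd == 1:
                return 17.07
        if nH == 1 and ns == 1:
            return 20.23
    if chg == -1 and nH == 0 and ns == 1:
        return 23.06
    return None


# ---------------------------------------------------------------------------
# graph tools


def to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetAtomicNum(),
                   aromatic=atom.GetIsAromatic())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=str(bond.GetBondType()))
    return g


def _node_match(a, b):
    return a["element"] == b["element"] and a["aromatic"] == b["aromatic"]


def _edge_match(a, b):
    return a["order"] == b["order"]


def has_subgraph(target: Chem.Mol, query: Chem.Mol) -> bool:
    """True iff ``query`` embeds in ``target`` (element/aromaticity-exact
    atoms, order-exact bonds) — VF2 monomorphism, independent of RDKit."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        to_graph(target), to_graph(query),
        node_match=_node_match, edge_match=_edge_match)
    return gm.subgraph_is_monomorphic()


def mces_bond_count(mol_a: Chem.Mol, mol_b: Chem.Mol) -> int:
    """Bond count of the maximum common connected edge subgraph.

    Enumerates connected edge subsets of the graph with fewer bonds, from
    largest to smallest, and returns the first size that embeds in the
    other graph.  Exponential — only for graphs of about 12 heavy atoms.
    """
    ga, gb = to_graph(mol_a), to_graph(mol_b)
    if ga.number_of_edges() > gb.number_of_edges():
        ga, gb = gb, ga
    edges = list(ga.edges())
    for k in range(len(edges), 0, -1):
        for subset in itertools.combinations(edges, k):
            sub = ga.edge_subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = nx.algorithms.isomorphism.GraphMatcher(
                gb, sub, node_match=_node_match, edge_match=_edge_match)
            if gm.subgraph_is_monomorphic():
                return k
    return 0
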