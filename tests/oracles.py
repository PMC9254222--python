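"""Independent brute-force oracles used by the test suite.

Deliberately implemented on a different path from the package: atom
descriptors come straight from RDKit, shortest paths from Floyd-Warshall
(the package uses BFS), and pair enumeration is exhaustive.
"""

import itertools
from collections import Counter


def brute_force_pairs(smiles, max_dist=7):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    descs = []
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            pi = 1
        else:
            pi = sum(
                {Chem.BondType.DOUBLE: 1, Chem.BondType.TRIPLE: 2}.get(
                    b.GetBondType(), 0)
                for b in atom.GetBonds()
            )
        descs.append((atom.GetSymbol(), atom.GetDegree(), pi))
    n = mol.GetNumAtoms()
    INF = 10 ** 9
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        d[i][j] = d[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    counts = Counter()
    for i, j in itertools.combinations(range(n), 2):
        if 1 <= d[i][j] <= max_dist:
            a, b_ = sorted((descs[i], descs[j]))
            counts[(a, d[i][j], b_)] += 1
    return counts


def brute_force_tanimoto(smiles_a, smiles_b, max_dist=7):
    ca = brute_force_pairs(smiles_a, max_dist)
    cb = brute_force_pairs(smiles_b, max_dist)
    keys = set(ca) | set(cb)
    return sum(min(ca[k], cb[k]) for k in keys) / sum(
        max(ca[k], cb[k]) for k in keys)
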