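"""Structure-based grouping of chemicals by atom-pair similarity.

SMILES strings are parsed (via RDKit) into heavy-atom molecular graphs;
each molecule is summarized as a multiset of Carhart-style atom pairs
(atom descriptor, topological distance, atom descriptor), where the atom
descriptor is (element, heavy-atom degree, π-electron count).  Counted
Tanimoto similarity over these multisets yields a distance matrix that
feeds average-linkage hierarchical clustering and classical
(Torgerson) multidimensional scaling.

The descriptor, similarity, MDS and BFS shortest-path computations are
implemented here; only SMILES parsing is delegated to RDKit.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Atom descriptor: (element symbol, heavy-atom degree, π-electron count).
AtomDescriptor = tuple[str, int, int]
#: Canonical atom-pair key: (descriptor_a, distance, descriptor_b),
#: descriptor_a <= descriptor_b lexicographically.
PairKey = tuple[AtomDescriptor, int, AtomDescriptor]


class StructureError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph: per-atom descriptors plus an undirected bond list."""

    atoms: tuple[AtomDescriptor, ...]
    bonds: tuple[tuple[int, int], ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass(frozen=True)
class AtomPairProfile:
    """Multiset of canonical atom-pair keys for one molecule."""

    smiles: str
    counts: tuple[tuple[PairKey, int], ...]
    max_dist: int

    def as_counter(self) -> Counter:
        return Counter(dict(self.counts))

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`.

    Hydrogens are implicit (not vertices) and do not count toward degree.
    Aromatic atoms carry π-count 1 (the aromatic-bond convention); for
    non-aromatic atoms the π-count is the number of π electrons the atom
    contributes to double/triple bonds (1 per double, 2 per triple).
    """
    from rdkit import Chem
    from rdkit import RDLogger

    if not smiles or not smiles.strip():
        raise StructureError("empty SMILES string")
    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles!r}")

    descriptors: list[AtomDescriptor] = []
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            pi = 1
        else:
            pi = 0
            for bond in atom.GetBonds():
                order = bond.GetBondType()
                if order == Chem.BondType.DOUBLE:
                    pi += 1
                elif order == Chem.BondType.TRIPLE:
                    pi += 2
        descriptors.append((atom.GetSymbol(), atom.GetDegree(), pi))
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=tuple(descriptors), bonds=bonds)


def _bfs_distances(adj: list[list[int]], source: int) -> list[int]:
    dist = [-1] * len(adj)
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def atom_pair_profile(
    graph: MolecularGraph, max_dist: int = 7, smiles: str = ""
) -> AtomPairProfile:
    """Atom-pair multiset of a molecular graph.

    For every unordered heavy-atom pair whose shortest-path bond distance
    is within ``max_dist``, the canonical key (min descriptor, distance,
    max descriptor) is counted.  For a connected n-atom molecule with
    unbounded max_dist the total count is n(n−1)/2.
    """
    n = graph.n_atoms
    if n < 2:
        warnings.warn("single-atom molecule has an empty atom-pair profile")
        return AtomPairProfile(smiles=smiles, counts=(), max_dist=max_dist)
    adj = graph.adjacency()
    counts: Counter = Counter()
    for i in range(n):
        dist = _bfs_distances(adj, i)
        for j in range(i + 1, n):
            d = dist[j]
            if d < 1 or d > max_dist:
                continue
            a, b = sorted((graph.atoms[i], graph.atoms[j]))
            counts[(a, d, b)] += 1
    return AtomPairProfile(
        smiles=smiles,
        counts=tuple(sorted(counts.items())),
        max_dist=max_dist,
    )


def profile_from_smiles(smiles: str, max_dist: int = 7) -> AtomPairProfile:
    """Convenience: SMILES → graph → atom-pair profile."""
    return atom_pair_profile(smiles_to_graph(smiles), max_dist=max_dist,
                             smiles=smiles)


def tanimoto(a: AtomPairProfile, b: AtomPairProfile,
             counted: bool = True) -> float:
    """Tanimoto similarity between two atom-pair profiles, in [0, 1].

    The counted (multiset) form Σ min(a_k, b_k) / Σ max(a_k, b_k) is the
    default; ``counted=False`` uses the unique-key (binary) form.  Two
    empty profiles compare as 1 only when they come from the identical
    SMILES string.
    """
    if a.max_dist != b.max_dist:
        raise ValueError("profiles were built with different max_dist")
    ca, cb = a.as_counter(), b.as_counter()
    if not ca and not cb:
        warnings.warn("comparing two empty atom-pair profiles")
        return 1.0 if a.smiles == b.smiles else 0.0
    keys = set(ca) | set(cb)
    if counted:
        num = sum(min(ca[k], cb[k]) for k in keys)
        den = sum(max(ca[k], cb[k]) for k in keys)
    else:
        num = len(set(ca) & set(cb))
        den = len(keys)
    return num / den


def distance_matrix(
    profiles: Sequence[AtomPairProfile],
    labels: Sequence[str] | None = None,
    counted: bool = True,
) -> pd.DataFrame:
    """Symmetric 1 − Tanimoto distance matrix with a zero diagonal."""
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least two profiles")
    if labels is None:
        labels = [p.smiles or str(i) for i, p in enumerate(profiles)]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto(profiles[i], profiles[j],
                                               counted=counted)
    return pd.DataFrame(d, index=list(labels), columns=list(labels))


@dataclass
class ClusterResult:
    """Dendrogram plus flat labels and (optionally) a 2-D embedding."""

    linkage: np.ndarray
    labels: list[str]
    flat: pd.Series | None = None
    embedding: pd.DataFrame | None = None

    def cut(self, k: int | None = None, height: float | None = None) -> pd.Series:
        """Flat cluster assignment at k clusters or a merge height."""
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k or height")
        if k is not None:
            assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        else:
            assign = hierarchy.fcluster(self.linkage, t=height,
                                        criterion="distance")
        return pd.Series(assign, index=self.labels, name="cluster")


def hierarchical_cluster(
    dist: pd.DataFrame,
    linkage: str = "average",
    cut_k: int | None = None,
    cut_height: float | None = None,
) -> ClusterResult:
    """Agglomerative clustering of a chemical distance matrix.

    Labels are sorted before linkage so the result is invariant to input
    row order; ties in merge distance break deterministically by label
    order.
    """
    if dist.shape[0] < 2:
        raise ValueError("need at least two chemicals to cluster")
    order = sorted(range(len(dist)), key=lambda i: str(dist.index[i]))
    labels = [str(dist.index[i]) for i in order]
    d = dist.to_numpy()[np.ix_(order, order)]
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    result = ClusterResult(linkage=Z, labels=labels)
    if cut_k is not None or cut_height is not None:
        result.flat = result.cut(k=cut_k, height=cut_height)
    return result


def classical_mds(dist: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, B = −½ J D² J, and embeds
    on the top-k eigenvectors scaled by √eigenvalue (negative eigenvalues
    clipped to zero, as usual for non-Euclidean input).  Each coordinate
    axis is sign-fixed so its first nonzero loading is positive.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if k >= n:
        raise ValueError("embedding dimension must be below the point count")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    if lam.max() > 0:  # zero out numerically-null axes
        lam[lam < lam.max() * 1e-12] = 0.0
    coords = vecs[:, idx] * np.sqrt(lam)
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    labels = (list(dist.index) if isinstance(dist, pd.DataFrame)
              else list(range(n)))
    return pd.DataFrame(coords, index=labels,
                        columns=[f"mds_{i + 1}" for i in range(k)])


def cluster_chemicals(
    chemicals: pd.DataFrame,
    max_dist: int = 7,
    linkage: str = "average",
    cut_k: int | None = None,
    counted: bool = True,
    embed: bool = True,
) -> tuple[pd.DataFrame, ClusterResult]:
    """End-to-end: annotation table → distances → clusters (+ MDS).

    Chemicals without a SMILES are skipped with a warning.  Returns the
    distance matrix (chemical ids as labels) and the ClusterResult.
    """
    usable = chemicals[chemicals["smiles"].notna()]
    skipped = len(chemicals) - len(usable)
    if skipped:
        logger.warning("skipping %d chemicals without SMILES", skipped)
    profiles = [profile_from_smiles(s, max_dist=max_dist)
                for s in usable["smiles"]]
    dist = distance_matrix(profiles, labels=usable["chemical_id"].tolist(),
                           counted=counted)
    result = hierarchical_cluster(dist, linkage=linkage, cut_k=cut_k)
    if embed and dist.shape[0] > 2:
        result.embedding = classical_mds(dist.loc[result.labels,
                                                  result.labels], k=2)
    return dist, result
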