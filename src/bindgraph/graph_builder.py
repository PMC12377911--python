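"""Residue proximity graphs and the random-topology ablation baseline.

Nodes are residues; an undirected edge connects residues whose alpha-carbon
distance is strictly below the cutoff (4, 6, 8 and 10 Angstrom are the
cutoffs explored here). The random baseline replaces the edge set with edges
sampled uniformly from residue pairs *not* connected in the original graph,
isolating the value of the true contact topology from mere message passing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures_io import ProteinChain

__all__ = [
    "ResidueGraph",
    "GraphConfig",
    "DEFAULT_CUTOFFS",
    "build_residue_graph",
    "build_random_graph",
    "save_graph",
    "load_graph",
]

DEFAULT_CUTOFFS = (4.0, 6.0, 8.0, 10.0)


@dataclass
class GraphConfig:
    cutoffs: tuple = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        cs = tuple(float(c) for c in self.cutoffs)
        if any(c <= 0 for c in cs) or list(cs) != sorted(set(cs)):
            raise ValueError("cutoffs must be positive and strictly increasing")
        self.cutoffs = cs


@dataclass
class ResidueGraph:
    """Undirected residue graph with optional node features and labels.

    ``edges`` is an (E, 2) integer array with i < j per row, no duplicates,
    no self-pairs. ``cutoff`` is the Angstrom threshold used, or the string
    ``"random"`` for the ablation baseline.
    """

    chain_ref: str
    n_nodes: int
    edges: np.ndarray
    cutoff: float | str
    features: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if e.size:
            e = np.sort(e, axis=1)
            if (e[:, 0] == e[:, 1]).any():
                raise ValueError("self-pairs are not allowed")
            if e.min() < 0 or e.max() >= self.n_nodes:
                raise ValueError("edge index out of range")
            e = np.unique(e, axis=0)
        self.edges = e
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != self.n_nodes:
                raise ValueError("feature rows must match node count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.n_nodes,):
                raise ValueError("labels length must match node count")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def edge_set(self) -> set:
        return {(int(i), int(j)) for i, j in self.edges}

    def adjacency(self, self_loops: bool = False) -> np.ndarray:
        """Dense boolean adjacency (symmetric)."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        if self.edges.size:
            a[self.edges[:, 0], self.edges[:, 1]] = True
            a[self.edges[:, 1], self.edges[:, 0]] = True
        if self_loops:
            np.fill_diagonal(a, True)
        return a


def build_residue_graph(chain: ProteinChain, cutoff: float) -> ResidueGraph:
    """Connect residue pairs with CA distance strictly less than ``cutoff``."""
    if len(chain) < 1:
        raise ValueError("chain must have at least one residue")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = squareform(pdist(chain.ca_coords))
    ii, jj = np.where(np.triu(d < cutoff, k=1))
    return ResidueGraph(
        chain_ref=chain.chain_id,
        n_nodes=len(chain),
        edges=np.column_stack([ii, jj]),
        cutoff=float(cutoff),
        labels=chain.labels,
    )


def build_random_graph(
    graph: ResidueGraph, n_edges: int | str = "match", seed: int = 0
) -> ResidueGraph:
    """Random-topology baseline: same nodes, edges disjoint from the original.

    Edges are drawn uniformly without replacement from the unordered node
    pairs absent from ``graph``; ``n_edges="match"`` targets the original
    edge count so that only topology, not density, differs. Deterministic
    for a fixed seed.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    ii, jj = np.triu_indices(n, k=1)
    adj = graph.adjacency()
    admissible = ~adj[ii, jj]
    pool = np.flatnonzero(admissible)
    target = graph.n_edges if n_edges == "match" else int(n_edges)
    if target > pool.size:
        warnings.warn(
            f"requested {target} random edges but only {pool.size} admissible "
            f"pairs remain; truncating"
        )
        target = pool.size
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=target, replace=False) if target else np.empty(0, int)
    edges = np.column_stack([ii[chosen], jj[chosen]])
    return ResidueGraph(
        chain_ref=graph.chain_ref,
        n_nodes=n,
        edges=edges,
        cutoff="random",
        features=graph.features,
        labels=graph.labels,
    )


def save_graph(graph: ResidueGraph, edge_path, meta_path) -> None:
    """Edge-list TSV plus a JSON sidecar (chain id, cutoff, node count)."""
    with open(edge_path, "w") as fh:
        fh.write("i\tj\n")
        for i, j in graph.edges:
            fh.write(f"{i}\t{j}\n")
    with open(meta_path, "w") as fh:
        json.dump(
            {"chain_id": graph.chain_ref, "cutoff": graph.cutoff, "n_nodes": graph.n_nodes},
            fh,
        )


def load_graph(edge_path, meta_path) -> ResidueGraph:
    with open(meta_path) as fh:
        meta = json.load(fh)
    edges = []
    with open(edge_path) as fh:
        fh.readline()
        for line in fh:
            i, j = line.split("\t")
            edges.append((int(i), int(j)))
    return ResidueGraph(
        chain_ref=meta["chain_id"],
        n_nodes=int(meta["n_nodes"]),
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
        cutoff=meta["cutoff"],
    )
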