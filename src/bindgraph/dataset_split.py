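"""Leakage-controlled train/validation/test splits.

Benchmark results on protein-ligand data are inflated when similar proteins
or similar ligands appear on both sides of a split. The procedure here
removes both routes:

1. cluster sequences so that any pair above 40% global-alignment identity
   shares a cluster, and assign *whole clusters* to splits;
2. cluster ligands by ECFP4 (Morgan radius 2, 1024 bits) Tanimoto
   similarity with single-linkage hierarchical clustering cut at 40%
   similarity;
3. purge: drop validation/test chains whose ligand cluster occurs in the
   training set, then test chains whose ligand cluster occurs in
   validation;
4. audit: exhaustively recompute cross-split maxima of sequence identity
   and ligand Tanimoto; the assignment passes iff both are <= 0.40.

Single linkage is chosen deliberately: it guarantees that no cross-cluster
pair exceeds the similarity cutoff, which is exactly the property the audit
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

__all__ = [
    "SplitAssignment", "sequence_identity", "cluster_sequences",
    "cluster_ligands", "assign_splits", "audit_leakage", "build_split",
]

RDLogger.DisableLog("rdApp.*")

SPLITS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Cluster-aware split membership with a leakage audit."""

    membership: dict[str, str]  # chain_id -> train|val|test
    seq_clusters: dict[str, int]
    ligand_clusters: dict[str, int]
    n_purged: int = 0
    audit: dict | None = field(default=None)

    def split(self, name: str) -> list[str]:
        return [c for c, s in self.membership.items() if s == name]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def sequence_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment length (gap columns
    count toward the length)."""
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = aligner or _aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_sequences(
    sequences: dict[str, str], identity_cutoff: float = 0.40, backend=None
) -> dict[str, int]:
    """Cluster chains so any pair with identity > cutoff shares a cluster.

    The built-in backend computes all pairwise global-alignment identities
    and takes connected components of the ``identity > cutoff`` graph (the
    transitive closure the contract requires). ``backend`` may substitute an
    external clustering tool: a callable (sequences, cutoff) -> chain_id ->
    cluster_id with the same contract.
    """
    if not sequences:
        raise ValueError("no sequences")
    if not 0 < identity_cutoff < 1:
        raise ValueError("identity cutoff must be in (0, 1)")
    if backend is not None:
        return backend(sequences, identity_cutoff)
    ids = list(sequences)
    n = len(ids)
    aligner = _aligner()
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(sequences[ids[i]], sequences[ids[j]], aligner) > identity_cutoff:
                adj[i, j] = adj[j, i] = True
    _, labels = connected_components(adj, directed=False)
    return {cid: int(lab) for cid, lab in zip(ids, labels)}


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def ligand_fingerprint(smiles: str):
    """ECFP4-style Morgan fingerprint (radius 2, 1024 bits); None for
    unparseable SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return _MORGAN.GetFingerprint(mol)


def cluster_ligands(
    smiles: dict[str, str], similarity_cutoff: float = 0.40
) -> tuple[dict[str, int], list[str]]:
    """Single-linkage hierarchical clustering of ligands on Tanimoto
    similarity, cut at distance 1 - cutoff.

    Returns (ligand_id -> cluster_id, list of excluded unparseable ids).
    """
    fps, excluded = {}, []
    for lid, smi in smiles.items():
        fp = ligand_fingerprint(smi)
        if fp is None:
            excluded.append(lid)
        else:
            fps[lid] = fp
    if excluded:
        warnings.warn(f"excluded {len(excluded)} unparseable SMILES: {excluded}")
    ids = list(fps)
    if not ids:
        raise ValueError("no parseable SMILES")
    if len(ids) == 1:
        return {ids[0]: 0}, excluded
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = TanimotoSimilarity(fps[ids[i]], fps[ids[j]])
            dist[i, j] = dist[j, i] = 1.0 - sim
    z = linkage(squareform(dist, checks=False), method="single")
    labels = fcluster(z, t=1.0 - similarity_cutoff, criterion="distance")
    return {lid: int(lab) for lid, lab in zip(ids, labels)}, excluded


def assign_splits(
    seq_clusters: dict[str, int],
    ligand_map: dict[str, str],
    ligand_clusters: dict[str, int],
    fractions: tuple = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly assign whole sequence clusters to train/val/test, then purge
    ligand-cluster leakage.

    Purge order follows the protocol: first drop val/test chains whose
    ligand cluster occurs in train, then test chains whose ligand cluster
    occurs in val. Deterministic for a fixed seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    rng = np.random.default_rng(seed)
    clusters = sorted(set(seq_clusters.values()))
    rng.shuffle(clusters)
    by_cluster: dict[int, list[str]] = {}
    for cid, cl in seq_clusters.items():
        by_cluster.setdefault(cl, []).append(cid)
    n_total = len(seq_clusters)
    targets = {"train": fractions[0] * n_total, "val": fractions[1] * n_total}
    membership: dict[str, str] = {}
    assigned = {"train": 0, "val": 0}
    for cl in clusters:
        members = by_cluster[cl]
        if assigned["train"] < targets["train"]:
            dest = "train"
        elif assigned["val"] < targets["val"]:
            dest = "val"
        else:
            dest = "test"
        for cid in members:
            membership[cid] = dest
        if dest in assigned:
            assigned[dest] += len(members)

    def lig_cluster(cid: str) -> int | None:
        return ligand_clusters.get(ligand_map.get(cid))

    n_purged = 0
    train_lc = {lig_cluster(c) for c, s in membership.items() if s == "train"} - {None}
    for cid in [c for c, s in membership.items() if s in ("val", "test")]:
        if lig_cluster(cid) in train_lc:
            del membership[cid]
            n_purged += 1
    val_lc = {lig_cluster(c) for c, s in membership.items() if s == "val"} - {None}
    for cid in [c for c, s in membership.items() if s == "test"]:
        if lig_cluster(cid) in val_lc:
            del membership[cid]
            n_purged += 1
    if not membership or not any(s == "train" for s in membership.values()):
        raise ValueError("empty training split after purge; try another seed")
    return SplitAssignment(
        membership=membership,
        seq_clusters=dict(seq_clusters),
        ligand_clusters=dict(ligand_clusters),
        n_purged=n_purged,
    )


def audit_leakage(
    assignment: SplitAssignment,
    sequences: dict[str, str],
    smiles: dict[str, str],
    ligand_map: dict[str, str],
    cutoff: float = 0.40,
) -> dict:
    """Exhaustive cross-split leakage audit.

    Recomputes the maximum sequence identity and maximum ligand Tanimoto
    over every cross-split pair; PASS iff both maxima are <= ``cutoff``.
    The worst pairs are named so a failure is actionable.
    """
    member = assignment.membership
    ids = list(member)
    aligner = _aligner()
    max_seq, seq_pair = 0.0, None
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if member[a] == member[b]:
                continue
            ident = sequence_identity(sequences[a], sequences[b], aligner)
            if ident > max_seq:
                max_seq, seq_pair = ident, (a, b)
    fps = {}
    for cid in ids:
        lid = ligand_map.get(cid)
        if lid is not None and lid not in fps:
            fp = ligand_fingerprint(smiles[lid])
            if fp is not None:
                fps[lid] = fp
    max_tan, tan_pair = 0.0, None
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if member[a] == member[b]:
                continue
            la, lb = ligand_map.get(a), ligand_map.get(b)
            if la in fps and lb in fps:
                sim = TanimotoSimilarity(fps[la], fps[lb])
                if sim > max_tan:
                    max_tan, tan_pair = sim, (la, lb)
    audit = {
        "max_cross_split_seq_identity": max_seq,
        "max_cross_split_ligand_tanimoto": max_tan,
        "worst_sequence_pair": seq_pair,
        "worst_ligand_pair": tan_pair,
        "n_purged": assignment.n_purged,
        "pass": max_seq <= cutoff and max_tan <= cutoff,
    }
    assignment.audit = audit
    return audit


def build_split(
    sequences: dict[str, str],
    ligand_map: dict[str, str],
    smiles: dict[str, str],
    fractions: tuple = (0.7, 0.15, 0.15),
    seed: int = 0,
    replicates: int = 1,
    cutoff: float = 0.40,
) -> list[SplitAssignment]:
    """End-to-end pipeline: cluster, assign, purge, audit.

    ``replicates`` produces that many independently seeded assignments
    (seed, seed+1, ...), the way repeated-split benchmarking is done.
    """
    seq_clusters = cluster_sequences(sequences, cutoff)
    ligand_clusters, _ = cluster_ligands(smiles, cutoff)
    out = []
    for r in range(replicates):
        asg = assign_splits(seq_clusters, ligand_map, ligand_clusters,
                            fractions, seed=seed + r)
        audit_leakage(asg, sequences, smiles, ligand_map, cutoff)
        out.append(asg)
    return out
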