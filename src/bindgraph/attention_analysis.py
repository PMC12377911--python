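"""Inspection of graph-attention coefficients.

For a chosen residue (typically a binding residue), the attention the model
pays to each spatial neighbor is extracted per head, averaged across heads,
and normalized into relative contributions. A PyMOL coloring script renders
the picture the way the interpretability figures do: the center residue
yellow, neighbors on a green (highest attention) to red (lowest attention)
gradient, low-attention neighbors transparent.

The self-connection's coefficient is reported separately rather than folded
into the neighbor ranking, where it would otherwise dominate silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_builder import ResidueGraph
from .gnn_models import BindingClassifier
from .structures_io import ProteinChain

__all__ = ["AttentionProfile", "extract_attention", "rank_neighbors",
           "emit_coloring_script", "write_attention_tsv"]


@dataclass
class AttentionProfile:
    """Attention of one center residue over its in-neighborhood.

    ``nodes`` lists the attended node indices (self first, then neighbors in
    index order); ``per_head`` is an (n_heads, len(nodes)) matrix whose rows
    each sum to 1 (softmax normalization over the in-neighborhood including
    the self-connection). ``neighbor_attention`` and
    ``relative_contribution`` cover neighbors only; the latter sums to 1
    whenever there is at least one neighbor.
    """

    center_node: int
    nodes: list[int]
    per_head: np.ndarray
    self_attention: float
    neighbor_attention: dict[int, float]
    relative_contribution: dict[int, float]


def extract_attention(model: BindingClassifier, graph: ResidueGraph,
                      node: int, layer: int = 0) -> AttentionProfile:
    """Head-wise and head-averaged attention of ``node`` in ``layer``.

    Runs one deterministic evaluation-mode forward pass, reads the layer's
    captured (L, L) per-head attention matrices and slices the center
    node's row over its in-neighborhood (self-connection included).
    """
    if model.spec.arch != "gat":
        raise ValueError(f"attention extraction requires a GAT model, got {model.spec.arch!r}")
    if not 0 <= node < graph.n_nodes:
        raise IndexError(f"node {node} out of range for {graph.n_nodes} nodes")
    model.predict_proba(graph)  # eval-mode pass; layers capture attention
    heads = model.layers[layer].last_attention
    mask_row = graph.adjacency(self_loops=True)[node]
    neighbors = [int(i) for i in np.flatnonzero(mask_row) if i != node]
    nodes = [node] + neighbors
    per_head = np.vstack([A[node, nodes] for A in heads])
    avg = per_head.mean(axis=0)  # arithmetic mean across heads
    self_att = float(avg[0])
    neighbor_att = {n: float(a) for n, a in zip(neighbors, avg[1:])}
    total = sum(neighbor_att.values())
    rel = ({n: a / total for n, a in neighbor_att.items()} if total > 0
           else {n: 0.0 for n in neighbor_att})
    return AttentionProfile(
        center_node=node,
        nodes=nodes,
        per_head=per_head,
        self_attention=self_att,
        neighbor_attention=neighbor_att,
        relative_contribution=rel,
    )


def rank_neighbors(profile: AttentionProfile) -> list[tuple[int, float]]:
    """Neighbors in descending head-averaged attention order; ties broken
    deterministically by node index."""
    return sorted(
        profile.relative_contribution.items(),
        key=lambda kv: (-profile.neighbor_attention[kv[0]], kv[0]),
    )


def _gradient_color(t: float) -> tuple[float, float, float]:
    """Linear green (t=1, highest attention) -> red (t=0, lowest)."""
    return (1.0 - t, t, 0.0)


def emit_coloring_script(
    profile: AttentionProfile,
    chain: ProteinChain,
    transparency_quantile: float = 0.25,
) -> str:
    """PyMOL command script visualizing one attention profile.

    The center residue is colored yellow; neighbors get a green-to-red
    gradient by relative contribution (green = highest). Neighbors in the
    lowest ``transparency_quantile`` of contributions are set half
    transparent. Deterministic: same profile, same bytes.
    """
    resnums = chain.residue_numbers or list(range(1, len(chain) + 1))
    for idx in profile.nodes:
        if not 0 <= idx < len(chain):
            raise IndexError(f"profile node {idx} not in chain of length {len(chain)}")
    ranked = rank_neighbors(profile)
    lines = [
        "# attention profile coloring",
        f"# center residue index {profile.center_node} "
        f"(self-attention {profile.self_attention:.4f})",
        "hide everything",
        "show cartoon",
        f"show sticks, resi {resnums[profile.center_node]}",
        f"color yellow, resi {resnums[profile.center_node]}",
    ]
    if ranked:
        contribs = np.array([c for _, c in ranked])
        lo, hi = contribs.min(), contribs.max()
        span = hi - lo if hi > lo else 1.0
        cut = float(np.quantile(contribs, transparency_quantile))
        for j, (nbr, contrib) in enumerate(ranked):
            t = (contrib - lo) / span
            r, g, b = _gradient_color(t)
            resi = resnums[nbr]
            lines.append(f"show sticks, resi {resi}")
            lines.append(f"set_color att_{j}, [{r:.3f}, {g:.3f}, {b:.3f}]")
            lines.append(f"color att_{j}, resi {resi}")
            if contrib <= cut:
                lines.append(f"set stick_transparency, 0.5, resi {resi}")
                lines.append(f"set cartoon_transparency, 0.5, resi {resi}")
    return "\n".join(lines) + "\n"


def write_attention_tsv(profile: AttentionProfile, chain: ProteinChain, path) -> None:
    """TSV of (neighbor residue number, head-averaged attention, relative
    contribution), in ranked order."""
    resnums = chain.residue_numbers or list(range(1, len(chain) + 1))
    with open(path, "w") as fh:
        fh.write("neighbor_residue\taveraged_attention\trelative_contribution\n")
        for nbr, contrib in rank_neighbors(profile):
            fh.write(f"{resnums[nbr]}\t{profile.neighbor_attention[nbr]:.6f}"
                     f"\t{contrib:.6f}\n")
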