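"""Per-residue node features.

Two sources are supported, mirroring the two regimes the classifiers are
compared under:

* **context-independent physicochemical property vectors** — every residue
  of the same amino-acid type gets the identical 566-dimensional vector,
  z-scored per property over the 20-letter alphabet.  Because these carry
  no sequential context, any benefit a graph model shows over a sequence
  baseline on them is attributable to structure.
* **external embeddings** — per-residue matrices computed elsewhere by a
  protein language model and loaded from an array archive or TSV; this
  package consumes them, it never runs a language model.

The bundled property table is a *synthetic* stand-in generated
deterministically in code (see :func:`synthetic_property_table`): it
reproduces the contract of a 566-property amino-acid index collection
(dimensionality, occasional missing values, constant properties) without
shipping the external database itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .structures_io import AA_ALPHABET, ProteinChain

__all__ = [
    "FeatureMatrix",
    "N_PROPERTIES",
    "synthetic_property_table",
    "load_property_table",
    "normalize_property_table",
    "aaindex_features",
    "load_embeddings",
    "save_embeddings",
    "attach_features",
]

#: number of per-amino-acid properties in the bundled table
N_PROPERTIES = 566

_TABLE_SEED = 56_620  # fixed: the table is part of the package contract


@lru_cache(maxsize=1)
def synthetic_property_table() -> pd.DataFrame:
    """Deterministic synthetic amino-acid property table (566 x 20).

    Rows are properties, columns the 20 standard one-letter codes. A small
    number of entries are missing (NaN) and two properties are constant,
    so the normalization pipeline's imputation and constant-column handling
    are exercised by realistic table pathology. Synthetic stand-in for an
    external physicochemical index database; values have no biochemical
    meaning.
    """
    rng = np.random.default_rng(_TABLE_SEED)
    loc = rng.normal(0.0, 5.0, size=(N_PROPERTIES, 1))
    scale = rng.lognormal(0.0, 1.0, size=(N_PROPERTIES, 1))
    values = loc + scale * rng.normal(size=(N_PROPERTIES, 20))
    # a handful of properties miss a few amino acids, as real indices do
    for prop in rng.choice(N_PROPERTIES, size=8, replace=False):
        k = rng.integers(1, 4)
        values[prop, rng.choice(20, size=k, replace=False)] = np.nan
    values[13, :] = 1.0  # constant properties survive in curated collections
    values[404, :] = -2.5
    return pd.DataFrame(values, columns=list(AA_ALPHABET))


def load_property_table(path) -> pd.DataFrame:
    """Load a property table from TSV (rows = properties, columns = residues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(AA_ALPHABET) - set(df.columns)
    if missing:
        raise ValueError(f"property table lacks columns for {sorted(missing)}")
    return df[list(AA_ALPHABET)].astype(float)


def normalize_property_table(table: pd.DataFrame) -> pd.DataFrame:
    """Impute missing entries with the property mean, then z-score each
    property across the 20 standard amino acids (population sd).

    Properties constant over the alphabet become all-zero rows.
    """
    v = table.to_numpy(dtype=float)
    row_mean = np.nanmean(v, axis=1, keepdims=True)
    v = np.where(np.isnan(v), row_mean, v)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=table.index, columns=table.columns)


@dataclass
class FeatureMatrix:
    """L x D node feature matrix for one chain."""

    chain_ref: str
    values: np.ndarray
    source: str  # "aaindex" | "external_embedding"
    dim: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")
        if self.dim != self.values.shape[1]:
            raise ValueError("dim does not match matrix width")
        if self.source == "aaindex" and self.dim != N_PROPERTIES:
            raise ValueError(f"aaindex features must be {N_PROPERTIES}-dimensional")


def aaindex_features(
    sequence: str, table: pd.DataFrame | None = None, chain_ref: str = ""
) -> FeatureMatrix:
    """Context-independent property features: row i depends only on letter i.

    ``'X'`` (nonstandard residue) receives the all-amino-acid mean, which is
    the zero vector after z-scoring.
    """
    if not sequence:
        raise ValueError("empty sequence")
    z = normalize_property_table(table if table is not None else synthetic_property_table())
    lut = {aa: z[aa].to_numpy() for aa in AA_ALPHABET}
    lut["X"] = np.zeros(len(z))
    rows = np.vstack([lut[aa] for aa in sequence])
    return FeatureMatrix(chain_ref=chain_ref, values=rows, source="aaindex", dim=rows.shape[1])


def load_embeddings(file, chain: ProteinChain) -> FeatureMatrix:
    """Load an externally computed per-residue embedding matrix for ``chain``.

    ``file`` is either an NPZ archive keyed by chain id, or a plain TSV
    holding one matrix. The row count must equal the chain length; a
    mismatch is an error naming both lengths (embedding/structure length
    disagreements are a classic failure mode of this pipeline).
    """
    path = str(file)
    if path.endswith(".npz"):
        with np.load(path) as arc:
            if chain.chain_id not in arc:
                raise KeyError(
                    f"chain {chain.chain_id!r} not in archive; keys: {sorted(arc.keys())}"
                )
            mat = np.asarray(arc[chain.chain_id], dtype=float)
    else:
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    if mat.ndim != 2:
        raise ValueError("embedding container must hold a 2-D matrix")
    if mat.shape[0] != len(chain):
        raise ValueError(
            f"embedding has {mat.shape[0]} rows but chain {chain.chain_id!r} "
            f"has {len(chain)} residues"
        )
    return FeatureMatrix(
        chain_ref=chain.chain_id, values=mat, source="external_embedding", dim=mat.shape[1]
    )


def save_embeddings(matrices: dict[str, np.ndarray], path) -> None:
    """Write per-chain embedding matrices to an NPZ archive keyed by chain id."""
    np.savez(path, **{k: np.asarray(v, dtype=float) for k, v in matrices.items()})


def attach_features(graph, features: FeatureMatrix):
    """Attach a feature matrix to a residue graph (rows follow residue index)."""
    if features.values.shape[0] != graph.n_nodes:
        raise ValueError(
            f"feature rows ({features.values.shape[0]}) != graph nodes ({graph.n_nodes})"
        )
    graph.features = features.values
    return graph
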