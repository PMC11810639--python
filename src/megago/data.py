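"""Per-protein graph container and its on-disk bundle.

A :class:`ProteinGraph` holds everything the model consumes for one chain:
the sequence (for one-hot encoding), the directed edge list derived from
the Cα contact map, a precomputed per-residue embedding matrix, and an
optional label row.  Serialization is an ``.npz`` of the arrays plus a JSON
sidecar with human-readable metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dhgnn import _mean_pool_matrix
from .structures_io import (EdgeList, LengthClass, ProteinChain,
                            build_contact_map, classify_length,
                            contact_map_to_edge_list)


@dataclass
class ProteinGraph:
    protein_id: str
    sequence: str
    edges: EdgeList
    embedding: np.ndarray  # N×f2
    labels: np.ndarray | None = None  # length-m binary row
    length_class: LengthClass = LengthClass.NORMAL
    _pool: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def pool_matrix(self) -> np.ndarray:
        """Cached full-neighborhood mean-pooling matrix."""
        if self._pool is None:
            self._pool = _mean_pool_matrix(self.edges, "all", None)
        return self._pool


def build_graph(chain: ProteinChain, embedder, protein_id: str | None = None,
                labels: np.ndarray | None = None,
                threshold: float = 10.0) -> ProteinGraph:
    cm = build_contact_map(chain, threshold=threshold)
    edges = contact_map_to_edge_list(cm)
    emb = embedder.embed(chain.sequence).matrix.data
    return ProteinGraph(protein_id=protein_id or chain.chain_id,
                        sequence=chain.sequence, edges=edges, embedding=emb,
                        labels=labels, length_class=classify_length(chain))


def save_graph(graph: ProteinGraph, path: str | Path) -> None:
    path = Path(path)
    arrays = {"edge_pairs": graph.edges.pairs, "embedding": graph.embedding}
    if graph.labels is not None:
        arrays["labels"] = np.asarray(graph.labels, dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    sidecar = {
        "protein_id": graph.protein_id,
        "sequence": graph.sequence,
        "n_residues": graph.n_residues,
        "m_edges": graph.edges.m_edges,
        "length_class": graph.length_class.value,
        "embedding_dim": int(graph.embedding.shape[1]),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_graph(path: str | Path) -> ProteinGraph:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        pairs = data["edge_pairs"]
        embedding = data["embedding"]
        labels = data["labels"] if "labels" in data else None
    seq = sidecar["sequence"]
    return ProteinGraph(
        protein_id=sidecar["protein_id"], sequence=seq,
        edges=EdgeList(pairs=pairs, n_nodes=len(seq)), embedding=embedding,
        labels=labels, length_class=LengthClass(sidecar["length_class"]))
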