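"""Structure, sequence and annotation I/O plus residue-graph construction.

A protein chain is reduced to its Cα trace; residues closer than a distance
threshold (default 10 Å, strict inequality) are connected, giving a symmetric
contact map that is flattened into a directed edge list for message passing.
Chains are stratified into three length classes: short (<100 residues),
normal (100–500) and long (>500).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CONTACT_THRESHOLD_A = 10.0

#: 3-letter → 1-letter residue codes; anything else maps to 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class LengthClass(str, Enum):
    SHORT = "short"
    NORMAL = "normal"
    LONG = "long"


class ChainSource(str, Enum):
    EXPERIMENTAL = "experimental"
    PREDICTED = "predicted"
    SYNTHETIC = "synthetic"


@dataclass
class ProteinChain:
    """A single chain reduced to sequence + Cα coordinates (Ångström)."""

    chain_id: str
    sequence: str
    ca_coords: np.ndarray  # N×3 float
    source: ChainSource = ChainSource.EXPERIMENTAL
    n_ca_missing: int = 0  # residues dropped for lacking a Cα atom

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=np.float64)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be N×3")
        if len(self.sequence) != self.ca_coords.shape[0]:
            raise ValueError("sequence length must equal number of Cα rows")
        if len(self.sequence) < 1:
            raise ValueError("chain must contain at least one residue")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite Cα coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass
class ContactMap:
    """Symmetric boolean residue-contact relation with an empty diagonal."""

    adjacency: np.ndarray  # N×N bool

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("adjacency diagonal must be empty")
        self.adjacency = a

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class EdgeList:
    """Directed 2×M edge index over 0-based node indices."""

    pairs: np.ndarray  # 2×M int
    n_nodes: int

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=np.int64).reshape(2, -1)
        if p.size and (p.min() < 0 or p.max() >= self.n_nodes):
            raise ValueError("edge index out of range")
        if p.size and np.any(p[0] == p[1]):
            raise ValueError("self-loops are not allowed")
        self.pairs = p

    @property
    def m_edges(self) -> int:
        return self.pairs.shape[1]

    def neighbors(self, node: int) -> np.ndarray:
        """Targets of edges leaving `node` (sorted, unique)."""
        return np.unique(self.pairs[1, self.pairs[0] == node])


@dataclass
class AnnotationSet:
    """Binary protein × term annotation matrix for one GO namespace."""

    namespace: str  # "BP" | "MF" | "CC"
    protein_ids: list[str]
    term_ids: list[str]
    matrix: np.ndarray  # n×m uint8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.shape != (len(self.protein_ids), len(self.term_ids)):
            raise ValueError("matrix shape must be n_proteins × n_terms")
        if len(set(self.term_ids)) != len(self.term_ids):
            raise ValueError("duplicate term ids")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)


# ---------------------------------------------------------------------------
# structure reading / writing


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolved in favor of altloc 'A'."""
    def key(a: gemmi.Atom):
        return (a.occ, a.altloc in ("", "A", "\0"))
    return max(atoms, key=key)


def read_chain(path: str | Path, chain_id: str) -> ProteinChain:
    """Read one chain from a PDB or mmCIF file as a Cα trace.

    Residues without a Cα atom are dropped; the drop count is logged and
    stored on the returned chain.  Only the first model is considered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"no models in {path}")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [c.name for c in model]
        raise KeyError(f"chain {chain_id!r} not in {path} (have {available})")
    seq: list[str] = []
    coords: list[list[float]] = []
    skipped = 0
    for residue in chain:
        cas = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
        if not cas:
            skipped += 1
            continue
        atom = _pick_altloc(cas)
        seq.append(THREE_TO_ONE.get(residue.name.upper(), "X"))
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not seq:
        raise ValueError(f"chain {chain_id!r} in {path} has no residues with Cα")
    if skipped:
        logger.info("chain %s in %s: dropped %d residue(s) without Cα",
                    chain_id, path.name, skipped)
    return ProteinChain(chain_id=chain_id, sequence="".join(seq),
                        ca_coords=np.array(coords), n_ca_missing=skipped)


def write_chain(chain: ProteinChain, path: str | Path) -> None:
    """Write a chain as a Cα-only PDB file."""
    lines = []
    cid = (chain.chain_id or "A")[0]
    for i, (aa, xyz) in enumerate(zip(chain.sequence, chain.ca_coords), start=1):
        res3 = ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} {cid}{i:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"           C  ")
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# graph construction


def build_contact_map(chain: ProteinChain,
                      threshold: float = CONTACT_THRESHOLD_A) -> ContactMap:
    """Cα–Cα contacts: pairs strictly closer than `threshold` Å."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    coords = chain.ca_coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    adjacency = dist < threshold
    np.fill_diagonal(adjacency, False)
    return ContactMap(adjacency=adjacency)


def contact_map_to_edge_list(cm: ContactMap) -> EdgeList:
    """Flatten a contact map into a directed 2×M edge index.

    Both directions of each contact are emitted; edges are ordered ascending
    by source then target, so the output is deterministic.
    """
    src, dst = np.nonzero(cm.adjacency)  # row-major order: sorted (src, dst)
    return EdgeList(pairs=np.vstack([src, dst]), n_nodes=cm.n_residues)


def edge_list_to_adjacency(edges: EdgeList) -> np.ndarray:
    adj = np.zeros((edges.n_nodes, edges.n_nodes), dtype=bool)
    adj[edges.pairs[0], edges.pairs[1]] = True
    return adj


def classify_length(chain_or_n: ProteinChain | int) -> LengthClass:
    """Length stratum of a chain: short <100, normal 100–500, long >500."""
    n = chain_or_n if isinstance(chain_or_n, int) else chain_or_n.n_residues
    if n < 1:
        raise ValueError("empty chain")
    if n < 100:
        return LengthClass.SHORT
    if n <= 500:
        return LengthClass.NORMAL
    return LengthClass.LONG


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path, namespace: str,
                     term_ids: list[str] | None = None) -> AnnotationSet:
    """Read "protein_id<TAB>term;term;…" lines into a binary label matrix.

    The term vocabulary is inferred (sorted) unless supplied.  Proteins with
    an empty term field get an all-zero row.
    """
    path = Path(path)
    proteins: list[str] = []
    per_protein: list[list[str]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated "
                             f"fields, got {len(parts)}")
        pid, terms_field = parts
        if not pid:
            raise ValueError(f"{path}:{lineno}: empty protein id")
        if pid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        seen.add(pid)
        proteins.append(pid)
        per_protein.append([t for t in terms_field.split(";") if t])
    if term_ids is None:
        vocab = sorted({t for terms in per_protein for t in terms})
    else:
        vocab = list(term_ids)
    index = {t: j for j, t in enumerate(vocab)}
    matrix = np.zeros((len(proteins), len(vocab)), dtype=np.uint8)
    for i, terms in enumerate(per_protein):
        for t in terms:
            if t not in index:
                raise ValueError(f"{path}: term {t!r} not in supplied vocabulary")
            matrix[i, index[t]] = 1
    return AnnotationSet(namespace=namespace, protein_ids=proteins,
                         term_ids=vocab, matrix=matrix)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    lines = []
    for i, pid in enumerate(ann.protein_ids):
        terms = [ann.term_ids[j] for j in np.nonzero(ann.matrix[i])[0]]
        lines.append(f"{pid}\t{';'.join(terms)}")
    Path(path).write_text("\n".join(lines) + "\n")
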