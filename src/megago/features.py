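"""Node features: one-hot residue encoding, per-residue embedders, and the
adaptive augmentation-fusion (adaAF) block.

adaAF merges the low-dimensional one-hot encoding f1 with a high-dimensional
language-model embedding f2 into a common width F through two linear maps,
then sharpens the fused features in three steps:

1. individualization: ``V' = V − γ·(V − μ)/σ + η`` with per-feature batch
   statistics μ, σ over the node axis (σ floored at 1e-5);
2. attention reweighting: ``W = 2·ReLU(FC3(V'))`` and ``V'' = V' ⊙ W``;
3. blending: ``Pool(δ1·V'' + δ2·BN(V))`` with δ2 = 1 − δ1, BN a standard
   batch normalization with learned affine, and Pool an adaptive average
   pool along the feature axis (identity at the default output size F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm, Linear, Module
from .structures_io import ProteinChain
from .tensor import Tensor

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard residues; 'X' is column 20
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
F1_DIM = len(ALPHABET) + 1  # 21


@dataclass
class NodeFeatures:
    """An N×d per-residue feature matrix tagged with its provenance."""

    matrix: Tensor
    kind: str  # "one_hot" | "embedding" | "fused"

    def __post_init__(self) -> None:
        if not isinstance(self.matrix, Tensor):
            self.matrix = Tensor(self.matrix)
        if self.kind not in ("one_hot", "embedding", "fused"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "one_hot" and not np.allclose(
                self.matrix.data.sum(axis=1), 1.0):
            raise ValueError("one-hot rows must sum to 1")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def one_hot_encode(sequence: str) -> NodeFeatures:
    """Encode a residue string into an N×21 one-hot matrix ('X' → column 20)."""
    sequence = sequence.upper()
    mat = np.zeros((len(sequence), F1_DIM))
    for i, aa in enumerate(sequence):
        if aa == "X":
            mat[i, F1_DIM - 1] = 1.0
        elif aa in AA_INDEX:
            mat[i, AA_INDEX[aa]] = 1.0
        else:
            raise ValueError(f"unknown residue letter {aa!r} at position {i}")
    return NodeFeatures(matrix=Tensor(mat), kind="one_hot")


class MockEmbedder:
    """Deterministic stand-in for a protein language model.

    Each row is a standard-normal vector derived from (residue letter,
    position, seed), so marginals are zero-mean unit-variance by
    construction and outputs are bit-identical across calls.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.name = "mock"
        self.dim = dim
        self.seed = seed
        self.deterministic = True

    def embed(self, sequence: str) -> NodeFeatures:
        rows = np.empty((len(sequence), self.dim))
        for i, aa in enumerate(sequence.upper()):
            letter = AA_INDEX.get(aa, F1_DIM - 1)
            rng = np.random.Generator(np.random.Philox(
                key=np.uint64(self.seed), counter=[i, letter, 0, 0]))
            rows[i] = rng.standard_normal(self.dim)
        return NodeFeatures(matrix=Tensor(rows), kind="embedding")


def mock_embed(sequence: str, dim: int, seed: int) -> NodeFeatures:
    return MockEmbedder(dim=dim, seed=seed).embed(sequence)


def adaptive_avg_pool_features(x: Tensor, out_size: int) -> Tensor:
    """Adaptive average pooling along the feature axis to `out_size` columns.

    Output column j averages input columns [floor(j·d/out), ceil((j+1)·d/out));
    at out_size == d this is the identity.
    """
    d = x.shape[1]
    if out_size == d:
        return x
    cols = []
    for j in range(out_size):
        lo = (j * d) // out_size
        hi = -(-(j + 1) * d // out_size)  # ceil
        cols.append(x[:, lo:hi].mean(axis=1, keepdims=True))
    from .tensor import concat
    return concat(cols, axis=1)


class AdaAF(Module):
    """The adaptive augmentation-fusion block (parameters + forward pass)."""

    def __init__(self, f1: int = F1_DIM, f2: int = 1280, out_dim: int = 512,
                 delta1: float = 0.5, pool_out: int | None = None,
                 enabled: bool = True, seed: int = 0,
                 eps: float = 1e-5):
        if not 0.0 <= delta1 <= 1.0:
            raise ValueError("delta1 must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        self.fc1 = Linear(f1, out_dim, rng)
        self.fc2 = Linear(f2, out_dim, rng)
        self.fc3 = Linear(out_dim, out_dim, rng)
        self.gamma = Tensor(np.array(1.0), requires_grad=True)  # scale factor
        self.eta = Tensor(np.array(0.0), requires_grad=True)    # shift factor
        self.bn = BatchNorm(out_dim)
        self.delta1 = delta1
        self.pool_out = out_dim if pool_out is None else pool_out
        self.enabled = enabled
        self.eps = eps
        self.f1, self.f2, self.out_dim = f1, f2, out_dim
        self.training = True
        # running statistics for the individualization step at inference
        self.running_mean = np.zeros(out_dim)
        self.running_std = np.ones(out_dim)
        self.momentum = 0.1

    @property
    def delta2(self) -> float:
        return 1.0 - self.delta1

    def fuse_linear(self, v1: NodeFeatures, v2: NodeFeatures) -> NodeFeatures:
        """Plain two-projection fusion: FC1(one-hot) + FC2(embedding)."""
        if v1.n != v2.n:
            raise ValueError("one-hot and embedding row counts differ")
        if v1.dim != self.fc1.d_in or v2.dim != self.fc2.d_in:
            raise ValueError("feature dims do not match the fusion projections")
        fused = self.fc1(v1.matrix) + self.fc2(v2.matrix)
        return NodeFeatures(matrix=fused, kind="fused")

    def apply_individualize(self, vfuse: NodeFeatures) -> NodeFeatures:
        """``V' = V − γ·(V − μ)/σ + η`` with per-column μ, σ over nodes."""
        x = vfuse.matrix
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            std_data = np.maximum(np.sqrt(var.data), self.eps)
            std = Tensor(std_data)  # σ floored at ε; treated as a statistic
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_std = ((1 - self.momentum) * self.running_std
                                + self.momentum * std_data.ravel())
        elif self.training:  # single node: σ undefined, use ε floor
            mu = Tensor(x.data.mean(axis=0, keepdims=True))
            std = Tensor(np.full((1, x.shape[1]), self.eps))
        else:
            mu = Tensor(self.running_mean[None, :])
            std = Tensor(np.maximum(self.running_std, self.eps)[None, :])
        out = x - self.gamma * ((x - mu) / std) + self.eta
        return NodeFeatures(matrix=out, kind="fused")

    def augment_and_blend(self, vfuse: NodeFeatures,
                          vprime: NodeFeatures) -> NodeFeatures:
        """Attention reweighting of V' blended with BN(V), then pooled."""
        if vfuse.matrix.shape != vprime.matrix.shape:
            raise ValueError("shape mismatch between V_Fuse and V'_Fuse")
        w_fuse = self.fc3(vprime.matrix).relu() * 2.0
        v_doubleprime = vprime.matrix * w_fuse
        blended = (self.delta1 * v_doubleprime
                   + self.delta2 * self.bn(vfuse.matrix))
        pooled = adaptive_avg_pool_features(blended, self.pool_out)
        return NodeFeatures(matrix=pooled, kind="fused")

    def forward_from_features(self, v1: NodeFeatures,
                              v2: NodeFeatures) -> NodeFeatures:
        """fuse → individualize → augment-blend on precomputed encodings.

        With the block disabled (ablation) the output is the plain
        two-projection fusion.
        """
        vfuse = self.fuse_linear(v1, v2)
        if not self.enabled:
            return vfuse
        vprime = self.apply_individualize(vfuse)
        return self.augment_and_blend(vfuse, vprime)

    def forward(self, chain: ProteinChain, embedder) -> NodeFeatures:
        """Full pipeline: encode → fuse → individualize → augment-blend."""
        v1 = one_hot_encode(chain.sequence)
        v2 = embedder.embed(chain.sequence)
        return self.forward_from_features(v1, v2)

    __call__ = forward


def adaaf_forward(chain: ProteinChain, embedder, params: AdaAF) -> NodeFeatures:
    return params.forward(chain, embedder)
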