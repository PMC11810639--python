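"""Dependent hierarchical GraphSAGE (DH-GNN).

Three GraphSAGE towers process the same residue graph: a Main tower and two
extractors that are biased toward long (α) and short (β) chains by adding,
respectively subtracting, scaled uniform noise between layers during
training.  Between layers 2 and 3 an interactive adapter block (IAB) lets
the towers exchange per-node summaries weighted by cosine similarity; layer
3 consumes the concatenation of each tower's earlier states with the
exchanged summaries, so representations mix several levels of abstraction.

Each GraphSAGE layer aggregates (MLP transform + mean pool) over a sampled
neighbor set ``S(v)`` and applies
``h_v = ReLU(W_sage · concat(h_S(v), h_v))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .nn import FeatureConv1d, Linear, Module
from .structures_io import EdgeList
from .tensor import Tensor, concat, const_matmul

ROLE_MAIN, ROLE_ALPHA, ROLE_BETA = "main", "alpha", "beta"


@dataclass
class NoiseSpec:
    """Training-time uniform noise: +U·τ1 on the α tower, −U·τ2 on β."""

    tau1: float = 0.5
    tau2: float = 0.5
    active: bool = True

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class BranchState:
    """Per-layer node representations of one tower."""

    branch: str  # role name
    h_per_layer: list[Tensor] = field(default_factory=list)


@dataclass
class AdapterOutput:
    """Similarity vectors, path weights and the four exchanged summaries."""

    sim_ma: np.ndarray  # length-N cosine(h_main, h_alpha)
    sim_mb: np.ndarray
    path_weights: dict[str, np.ndarray]  # per pair: N×3 softmax over kernels
    adapted: dict[str, Tensor]  # keys: M<-a, M<-b, a<-M, b<-M


def sample_neighbors(edges: EdgeList, node: int, k: int | str,
                     rng: np.random.Generator) -> np.ndarray:
    """``S(v)``: all neighbors if |N(v)| ≤ k (or k == "all"), else a uniform
    sample of size k without replacement."""
    nbrs = edges.neighbors(node)
    if k == "all" or len(nbrs) <= int(k):
        return nbrs
    return rng.choice(nbrs, size=int(k), replace=False)


def _mean_pool_matrix(edges: EdgeList, k: int | str,
                      rng: np.random.Generator | None) -> sparse.csr_matrix:
    """Row-stochastic sparse N×N matrix averaging each node's (sampled)
    neighbors.  Isolated nodes get an all-zero row, i.e. a zero aggregate."""
    n = edges.n_nodes
    if k == "all":
        src, dst = edges.pairs
    else:
        if rng is None:
            raise ValueError("neighbor sampling requires an RNG")
        src_l, dst_l = [], []
        for v in range(n):
            s = sample_neighbors(edges, v, k, rng)
            src_l.extend([v] * len(s))
            dst_l.extend(s.tolist())
        src = np.array(src_l, dtype=np.int64)
        dst = np.array(dst_l, dtype=np.int64)
    deg = np.bincount(src, minlength=n).astype(float)
    vals = 1.0 / deg[src] if len(src) else np.zeros(0)
    return sparse.csr_matrix((vals, (src, dst)), shape=(n, n))


class SageLayer(Module):
    """One GraphSAGE layer: MLP + mean aggregation, then concat and ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 layer_index: int = 1, sample_size: int | str = "all"):
        self.mlp = Linear(d_in, d_in, rng)  # the per-neighbor transform
        self.w_sage = Linear(2 * d_in, d_out, rng)
        self.layer_index = layer_index
        self.sample_size = sample_size
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, h_prev: Tensor, edges: EdgeList,
                 rng: np.random.Generator | None = None,
                 pool=None) -> Tensor:
        if h_prev.shape[1] != self.d_in:
            raise ValueError(
                f"expected {self.d_in} input features, got {h_prev.shape[1]}")
        if pool is None:
            pool = _mean_pool_matrix(edges, self.sample_size, rng)
        transformed = self.mlp(h_prev).relu()
        aggregated = const_matmul(pool, transformed)
        return self.w_sage(concat([aggregated, h_prev], axis=1)).relu()


def sage_forward(h_prev: Tensor | np.ndarray, edges: EdgeList,
                 layer: SageLayer, rng: np.random.Generator | None = None) -> Tensor:
    if not isinstance(h_prev, Tensor):
        h_prev = Tensor(h_prev)
    return layer(h_prev, edges, rng=rng)


def inject_noise(h: Tensor, branch: str, spec: NoiseSpec,
                 rng: np.random.Generator) -> Tensor:
    """Add (α) or subtract (β) elementwise U[0,1)·τ during training."""
    if branch == ROLE_MAIN or not spec.active:
        return h
    if branch == ROLE_ALPHA:
        tau = spec.tau1
        sign = 1.0
    elif branch == ROLE_BETA:
        tau = spec.tau2
        sign = -1.0
    else:
        raise ValueError(f"unknown branch {branch!r}")
    if tau == 0.0:
        return h
    u = rng.random(h.shape)
    return h + Tensor(sign * tau * u)


def cosine_rows(a: Tensor, b: Tensor) -> tuple[Tensor, np.ndarray]:
    """Per-row cosine similarity; rows with zero norm get similarity 0.

    Returns the similarity as an N×1 tensor (gradient flows through both
    inputs) plus a detached copy for reporting.
    """
    num = (a * b).sum(axis=1, keepdims=True)
    na = (a ** 2).sum(axis=1, keepdims=True)
    nb = (b ** 2).sum(axis=1, keepdims=True)
    prod = (na * nb).sqrt()
    zero = prod.data == 0.0
    denom = prod + Tensor(zero.astype(float))  # 0/1 = 0 on zero-norm rows
    sim = num / denom
    return sim, sim.data.ravel().copy()


class IAB(Module):
    """Interactive adapter block for one (Main, extractor) pair.

    The pair's concatenated features pass through parallel depthwise
    convolutions at kernel sizes {1, 3, 5} along the feature axis, each path
    is projected into a compact latent space and scored, the three scores
    are softmax-normalized per node, and the weighted sum of the path
    feature maps — projected back to width d — is the adaptive weight matrix
    ``Weight_adapt``.  The Main tower receives ``sim ⊙ Weight_adapt``; the
    extractor receives ``(1 − |sim|) ⊙ Weight_adapt``.
    """

    KERNELS = (1, 3, 5)

    def __init__(self, dim: int, rng: np.random.Generator):
        latent = max(8, dim // 4)
        self.convs = [FeatureConv1d(k, rng) for k in self.KERNELS]
        self.latent_proj = Linear(2 * dim, latent, rng)
        self.attn = Linear(latent, 1, rng)
        self.out_proj = Linear(2 * dim, dim, rng)
        self.dim = dim

    def __call__(self, h_main: Tensor, h_other: Tensor
                 ) -> tuple[Tensor, Tensor, np.ndarray, np.ndarray]:
        """Returns (to_main, to_other, sim_values, path_weights)."""
        if h_main.shape != h_other.shape:
            raise ValueError("adapter inputs must share a shape")
        sim, sim_vals = cosine_rows(h_main, h_other)
        stacked = concat([h_main, h_other], axis=1)  # N×2d
        maps = [conv(stacked) for conv in self.convs]
        scores = concat(
            [self.attn(self.latent_proj(m).relu()) for m in maps], axis=1)
        weights = scores.softmax(axis=1)  # N×3, sums to 1 across paths
        weighted = None
        for p in range(len(maps)):
            term = maps[p] * weights[:, p:p + 1]
            weighted = term if weighted is None else weighted + term
        weight_adapt = self.out_proj(weighted)  # N×d
        to_main = sim * weight_adapt
        to_other = (1.0 - sim.abs()) * weight_adapt
        return to_main, to_other, sim_vals, weights.data.copy()


def iab_exchange(h_main: Tensor, h_alpha: Tensor, h_beta: Tensor,
                 iab_alpha: IAB, iab_beta: IAB) -> AdapterOutput:
    """Run both adapter pairs and collect the four exchanged summaries."""
    to_m_a, to_a, sim_ma, w_a = iab_alpha(h_main, h_alpha)
    to_m_b, to_b, sim_mb, w_b = iab_beta(h_main, h_beta)
    return AdapterOutput(
        sim_ma=sim_ma, sim_mb=sim_mb,
        path_weights={"Ma": w_a, "Mb": w_b},
        adapted={"M<-a": to_m_a, "M<-b": to_m_b, "a<-M": to_a, "b<-M": to_b})


def layer2_concat(h1_main: Tensor, h2_main: Tensor,
                  h1_a: Tensor, h2_a_noise: Tensor,
                  h1_b: Tensor, h2_b_noise: Tensor,
                  adapter: AdapterOutput) -> tuple[Tensor, Tensor, Tensor]:
    """Assemble the widened layer-3 inputs for (Main, α, β)."""
    main_in = concat([h1_main, h2_main,
                      adapter.adapted["M<-a"], adapter.adapted["M<-b"]], axis=1)
    a_in = concat([h1_a, h2_a_noise, adapter.adapted["a<-M"]], axis=1)
    b_in = concat([h1_b, h2_b_noise, adapter.adapted["b<-M"]], axis=1)
    return main_in, a_in, b_in


class DHGNN(Module):
    """The full tower stack.  Tower 0 is Main; towers 1–2 take configurable
    roles (alpha / beta / main), which is how the branch-subset presets are
    expressed.  With a single tower or adapters disabled, the exchanged
    summaries are zero and the widened layer-3 input shape is kept."""

    def __init__(self, in_dim: int, hidden: int,
                 roles: tuple[str, ...] = (ROLE_MAIN, ROLE_ALPHA, ROLE_BETA),
                 noise: NoiseSpec | None = None,
                 iab_enabled: bool = True,
                 sample_k: int | str = "all",
                 seed: int = 0):
        if len(roles) not in (1, 3) or roles[0] != ROLE_MAIN:
            raise ValueError("roles must be (main,) or (main, r1, r2)")
        rng = np.random.default_rng(seed)
        self.roles = tuple(roles)
        self.noise = noise or NoiseSpec()
        self.iab_enabled = iab_enabled and len(roles) == 3
        self.sample_k = sample_k
        self.hidden = hidden
        self.towers: list[list[SageLayer]] = []
        for t, _role in enumerate(self.roles):
            l3_in = 4 * hidden if t == 0 else 3 * hidden
            self.towers.append([
                SageLayer(in_dim, hidden, rng, 1, sample_k),
                SageLayer(hidden, hidden, rng, 2, sample_k),
                SageLayer(l3_in, hidden, rng, 3, sample_k),
            ])
        if self.iab_enabled:
            self.iabs = [IAB(hidden, rng), IAB(hidden, rng)]
        else:
            self.iabs = []
        self.training = True

    def parameters(self):  # towers is a list of lists; flatten explicitly
        out = []
        for tower in self.towers:
            for layer in tower:
                out.extend(layer.parameters())
        for iab in self.iabs:
            out.extend(iab.parameters())
        return out

    def state_arrays(self, prefix: str = ""):
        out = {}
        for t, tower in enumerate(self.towers):
            for l, layer in enumerate(tower):
                out.update(layer.state_arrays(f"{prefix}tower{t}.l{l}."))
        for i, iab in enumerate(self.iabs):
            out.update(iab.state_arrays(f"{prefix}iab{i}."))
        return out

    def load_state_arrays(self, state, prefix: str = ""):
        for t, tower in enumerate(self.towers):
            for l, layer in enumerate(tower):
                layer.load_state_arrays(state, f"{prefix}tower{t}.l{l}.")
        for i, iab in enumerate(self.iabs):
            iab.load_state_arrays(state, f"{prefix}iab{i}.")

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def forward(self, v: Tensor, edges: EdgeList,
                rng: np.random.Generator | None = None,
                pool=None
                ) -> tuple[list[BranchState], AdapterOutput | None]:
        if rng is None:
            rng = np.random.default_rng(0)
        if pool is None and self.sample_k == "all":
            pool = _mean_pool_matrix(edges, "all", None)
        spec = NoiseSpec(self.noise.tau1, self.noise.tau2,
                         active=self.noise.active and self.training)
        n = v.shape[0]
        h1s, h2s, h2ns = [], [], []
        for t, role in enumerate(self.roles):
            layers = self.towers[t]
            p = pool if self.sample_k == "all" else None
            h1 = layers[0](v, edges, rng=rng, pool=p)
            h1_next = inject_noise(h1, role, spec, rng)
            h2 = layers[1](h1_next, edges, rng=rng, pool=p)
            h2n = inject_noise(h2, role, spec, rng)
            h1s.append(h1)
            h2s.append(h2)
            h2ns.append(h2n)
        zeros = Tensor(np.zeros((n, self.hidden)))
        if self.iab_enabled:
            adapter = iab_exchange(h2ns[0], h2ns[1], h2ns[2],
                                   self.iabs[0], self.iabs[1])
        else:
            adapter = None
        states: list[BranchState] = []
        for t, role in enumerate(self.roles):
            layers = self.towers[t]
            p = pool if self.sample_k == "all" else None
            if t == 0:
                ex_a = adapter.adapted["M<-a"] if adapter else zeros
                ex_b = adapter.adapted["M<-b"] if adapter else zeros
                l3_in = concat([h1s[0], h2ns[0], ex_a, ex_b], axis=1)
            else:
                key = "a<-M" if t == 1 else "b<-M"
                ex = adapter.adapted[key] if adapter else zeros
                l3_in = concat([h1s[t], h2ns[t], ex], axis=1)
            h3 = layers[2](l3_in, edges, rng=rng, pool=p)
            states.append(BranchState(branch=role, h_per_layer=[h1s[t], h2s[t], h3]))
        return states, adapter

    __call__ = forward


def dhgnn_forward(v: Tensor | np.ndarray, edges: EdgeList, model: DHGNN,
                  rng: np.random.Generator | None = None):
    if not isinstance(v, Tensor):
        v = Tensor(v)
    return model(v, edges, rng=rng)
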