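"""The assembled network: adaAF features → DH-GNN towers → adaSAB heads."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adasab import AdaSABHead, PredictionHead, combine_predictions
from .config import RunConfig
from .data import ProteinGraph
from .dhgnn import DHGNN, BranchState, NoiseSpec
from .features import F1_DIM, AdaAF, NodeFeatures
from .nn import Module
from .tensor import Tensor


@dataclass
class ModelOutput:
    per_tower: list[PredictionHead]
    combined: Tensor  # 1×m probabilities
    states: list[BranchState]


class MegaGo(Module):
    """End-to-end model for one residue graph at a time."""

    def __init__(self, config: RunConfig, n_terms: int):
        self.config = config
        self.n_terms = n_terms
        self.adaaf = AdaAF(f1=F1_DIM, f2=config.f2_dim,
                           out_dim=config.feat_dim, delta1=config.delta1,
                           pool_out=config.pool_out,
                           enabled=config.adaaf_enabled, seed=config.seed)
        feat_out = config.pool_out or config.feat_dim
        self.dhgnn = DHGNN(
            in_dim=feat_out, hidden=config.hidden, roles=config.towers,
            noise=NoiseSpec(config.tau1, config.tau2,
                            active=config.noise_active),
            iab_enabled=config.iab_enabled, sample_k=config.sample_k,
            seed=config.seed + 1)
        head_rng = np.random.default_rng(config.seed + 2)
        self.heads = [
            AdaSABHead(config.hidden, n_terms, role, head_rng,
                       zeta=config.zeta, gating_enabled=config.zeta_gating)
            for role in config.towers]
        self.training = True

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.adaaf.set_training(flag)
        self.dhgnn.set_training(flag)

    def parameters(self):
        out = self.adaaf.parameters() + self.dhgnn.parameters()
        for head in self.heads:
            out.extend(head.parameters())
        return out

    def state_arrays(self, prefix: str = ""):
        out = self.adaaf.state_arrays(prefix + "adaaf.")
        out.update(self.dhgnn.state_arrays(prefix + "dhgnn."))
        for i, head in enumerate(self.heads):
            out.update(head.state_arrays(f"{prefix}head{i}."))
        return out

    def load_state_arrays(self, state, prefix: str = ""):
        self.adaaf.load_state_arrays(state, prefix + "adaaf.")
        self.dhgnn.load_state_arrays(state, prefix + "dhgnn.")
        for i, head in enumerate(self.heads):
            head.load_state_arrays(state, f"{prefix}head{i}.")

    def forward(self, graph: ProteinGraph,
                rng: np.random.Generator | None = None) -> ModelOutput:
        from .features import one_hot_encode
        v1 = one_hot_encode(graph.sequence)
        v2 = NodeFeatures(matrix=Tensor(graph.embedding), kind="embedding")
        fused = self.adaaf.forward_from_features(v1, v2)
        pool = graph.pool_matrix() if self.config.sample_k == "all" else None
        states, _adapter = self.dhgnn(fused.matrix, graph.edges, rng=rng,
                                      pool=pool)
        per_tower = [head(state.h_per_layer[-1])
                     for head, state in zip(self.heads, states)]
        combined = combine_predictions(per_tower, mode=self.config.fusion)
        return ModelOutput(per_tower=per_tower, combined=combined,
                           states=states)

    __call__ = forward
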