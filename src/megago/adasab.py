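"""Adaptive structural attention readout (adaSAB).

Each tower's final node representations receive a learned scalar attention
score per node; softmax over nodes turns scores into weights.  A length-
aware ζ-gate decides per node whether the value path uses the attended
value vector or the node's untouched input: the α tower (long-chain bias)
retains nodes whose logistic-squashed score falls below ζ, the β tower
retains the complement, and Main is ungated.  The attended value is added
to the query projection and layer-normalized; a mean‖max readout and a
sigmoid head produce per-term probabilities, and the final prediction is
the mean over active towers (configurable to Main-only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import LayerNorm, Linear, Module
from .tensor import Tensor, concat

__all__ = ["AttentionState", "PredictionHead", "AdaSABHead",
           "attention_scores", "zeta_gate", "attention_combine",
           "readout_and_predict", "combine_predictions"]


@dataclass
class AttentionState:
    q: Tensor
    v: Tensor
    scores: Tensor  # N×1 raw scores
    att_weight: Tensor  # N×1, softmax over nodes
    zeta: float


@dataclass
class PredictionHead:
    branch: str
    readout: Tensor  # 1×2d mean‖max graph vector
    logits: Tensor  # 1×m
    probs: Tensor  # 1×m, sigmoid(logits)


def attention_scores(h: Tensor, proj: Linear) -> Tensor:
    """Learned scalar structural-significance score per node (N×1)."""
    return proj(h)


def zeta_gate(scores: np.ndarray, branch: str, zeta: float) -> np.ndarray:
    """Boolean retention mask from logistic-squashed scores.

    α retains nodes with squashed score < ζ, β retains the complement
    (squashed ≥ ζ), Main retains nothing; the α and β masks partition the
    node set for any score vector.
    """
    if not 0.0 < zeta <= 1.0:
        raise ValueError("zeta must lie in (0, 1]")
    squashed = 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=float).ravel()))
    if branch == "alpha":
        return squashed < zeta
    if branch == "beta":
        return squashed >= zeta
    if branch == "main":
        return np.zeros(squashed.shape, dtype=bool)
    raise ValueError(f"unknown branch {branch!r}")


def attention_combine(h: Tensor, state: AttentionState,
                      gate: np.ndarray, ln: LayerNorm) -> Tensor:
    """``attWeight · V + Q`` with gated nodes keeping their input on the
    value path, then per-node layer normalization."""
    mask = Tensor(gate.astype(float).reshape(-1, 1))
    v_eff = state.v * (1.0 - mask) + h * mask
    combined = state.att_weight * v_eff + state.q
    return ln(combined)


class AdaSABHead(Module):
    """Attention readout + prediction head for one tower."""

    def __init__(self, dim: int, n_terms: int, branch: str,
                 rng: np.random.Generator, zeta: float = 0.5,
                 gating_enabled: bool = True):
        self.q_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.score_proj = Linear(dim, 1, rng)
        self.ln = LayerNorm(dim)
        self.head = Linear(2 * dim, n_terms, rng)
        self.branch = branch
        self.zeta = zeta
        self.gating_enabled = gating_enabled  # off → plain SAB (no ζ)
        self.dim, self.n_terms = dim, n_terms

    def __call__(self, h: Tensor) -> PredictionHead:
        scores = attention_scores(h, self.score_proj)
        att_weight = scores.softmax(axis=0)
        state = AttentionState(q=self.q_proj(h), v=self.v_proj(h),
                               scores=scores, att_weight=att_weight,
                               zeta=self.zeta)
        if self.gating_enabled:
            gate = zeta_gate(scores.data, self.branch, self.zeta)
        else:
            gate = np.zeros(h.shape[0], dtype=bool)
        combined = attention_combine(h, state, gate, self.ln)
        return readout_and_predict(combined, self.head, branch=self.branch)


def readout_and_predict(h: Tensor, head: Linear,
                        branch: str = "main") -> PredictionHead:
    """mean‖max graph readout, then a sigmoid multi-label head."""
    if head.d_out < 1:
        raise ValueError("need at least one output term")
    readout = concat([h.mean(axis=0, keepdims=True),
                      h.max(axis=0, keepdims=True)], axis=1)
    logits = head(readout)
    return PredictionHead(branch=branch, readout=readout, logits=logits,
                          probs=logits.sigmoid())


def combine_predictions(heads: list[PredictionHead],
                        mode: str = "mean") -> Tensor:
    """Inference-time fusion of tower probabilities."""
    if not heads:
        raise ValueError("no prediction heads supplied")
    if mode == "main_only":
        for head in heads:
            if head.branch == "main":
                return head.probs
        raise ValueError("no main head present")
    if mode != "mean":
        raise ValueError(f"unknown fusion mode {mode!r}")
    total = heads[0].probs
    for head in heads[1:]:
        total = total + head.probs
    return total * (1.0 / len(heads))
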