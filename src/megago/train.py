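"""Training, prediction and checkpointing.

Training minimizes the sum of per-tower weighted cross-entropies with
adaptive-moment gradient descent over seeded mini-batches of graphs, logs
per-epoch losses and validation Fmax/AUPR, and early-stops on validation
AUPR.  All randomness (split, shuffling, noise, neighbor sampling) derives
from the run seed, so two identical runs produce identical trajectories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .data import ProteinGraph
from .model import MegaGo
from .objective_metrics import (LabelWeights, aupr, fmax, label_weights,
                                total_loss, wce_loss)
from .tensor import Adam, Tensor, concat

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass
class TrainResult:
    model: MegaGo
    history: list[dict] = field(default_factory=list)
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)
    weights: LabelWeights | None = None


def split_train_val(graphs: list[ProteinGraph], val_fraction: float,
                    seed: int) -> tuple[list[ProteinGraph], list[ProteinGraph]]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(graphs))
    n_val = max(1, int(round(val_fraction * len(graphs)))) if val_fraction > 0 else 0
    val_idx = set(order[:n_val].tolist())
    train = [g for i, g in enumerate(graphs) if i not in val_idx]
    val = [g for i, g in enumerate(graphs) if i in val_idx]
    return train, val


def _batch_forward(model: MegaGo, batch: list[ProteinGraph],
                   rng: np.random.Generator) -> dict[str, Tensor]:
    """Stack per-graph tower probabilities into per-tower n_b×m matrices."""
    rows: dict[int, list[Tensor]] = {i: [] for i in range(len(model.heads))}
    for graph in batch:
        out = model(graph, rng=rng)
        for i, head in enumerate(out.per_tower):
            rows[i].append(head.probs)
    names = _tower_names(model.config.towers)
    return {names[i]: concat(rows[i], axis=0) for i in rows}


def _tower_names(roles: tuple[str, ...]) -> list[str]:
    """Unique loss-report keys: Main, alpha, beta (suffixed if repeated)."""
    pretty = {"main": "Main", "alpha": "alpha", "beta": "beta"}
    names, seen = [], {}
    for role in roles:
        base = pretty[role]
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}{seen[base]}")
    return names


def predict_probs(model: MegaGo, graphs: list[ProteinGraph],
                  seed: int = 0) -> np.ndarray:
    """Deterministic inference: noise off, running statistics, combined head."""
    model.set_training(False)
    rng = np.random.default_rng(seed)  # only used if sample_k != "all"
    probs = np.vstack([model(g, rng=rng).combined.data for g in graphs])
    model.set_training(True)
    return probs


def train_model(config: RunConfig, graphs: list[ProteinGraph],
                log_fn=None) -> TrainResult:
    """Seeded mini-batch training with early stopping on validation AUPR."""
    if any(g.labels is None for g in graphs):
        raise ValueError("all graphs need label rows for training")
    n_terms = len(graphs[0].labels)
    model = MegaGo(config, n_terms=n_terms)
    train_graphs, val_graphs = split_train_val(
        graphs, config.val_fraction, config.seed)
    y_train = np.vstack([g.labels for g in train_graphs])
    weights = label_weights(y_train)
    optimizer = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 10)
    names = _tower_names(config.towers)
    history: list[dict] = []
    best_aupr, best_state, patience_left = -np.inf, None, config.patience
    for epoch in range(config.epochs):
        model.set_training(True)
        order = rng.permutation(len(train_graphs))
        epoch_losses = {name: 0.0 for name in names}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_graphs[i] for i in order[start:start + config.batch_size]]
            y_batch = np.vstack([g.labels for g in batch])
            per_tower = _batch_forward(model, batch, rng)
            losses = {name: wce_loss(y_batch, probs, weights,
                                     normalization=config.loss_normalization)
                      for name, probs in per_tower.items()}
            total = None
            for loss in losses.values():
                total = loss if total is None else total + loss
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"{ {k: float(v.data) for k, v in losses.items()} }")
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            for name, loss in losses.items():
                epoch_losses[name] += float(loss.data)
            n_batches += 1
        mean_losses = {k: v / n_batches for k, v in epoch_losses.items()}
        report = total_loss(mean_losses,
                            normalization=config.loss_normalization)
        entry = {"epoch": epoch, "wce": mean_losses, "total": report.total}
        if val_graphs:
            y_val = np.vstack([g.labels for g in val_graphs])
            p_val = predict_probs(model, val_graphs, seed=config.seed)
            if y_val.sum() > 0:
                entry["val_aupr"] = aupr(y_val, p_val)
                entry["val_fmax"] = fmax(y_val, p_val)[0]
        history.append(entry)
        if log_fn:
            log_fn(entry)
        logger.info("epoch %d: total=%.5f %s", epoch, report.total,
                    {k: round(v, 5) for k, v in mean_losses.items()})
        val_score = entry.get("val_aupr")
        if val_score is not None:
            if val_score > best_aupr:
                best_aupr = val_score
                best_state = model.state_arrays()
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stop at epoch %d", epoch)
                    break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return TrainResult(model=model, history=history,
                       train_ids=[g.protein_id for g in train_graphs],
                       val_ids=[g.protein_id for g in val_graphs],
                       weights=weights)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: MegaGo, path: str | Path,
                    extra: dict | None = None) -> None:
    """Single-file .npz checkpoint with embedded config and version header."""
    header = {"version": CHECKPOINT_VERSION,
              "config": model.config.to_dict(),
              "config_hash": model.config.config_hash(),
              "n_terms": model.n_terms}
    if extra:
        header["extra"] = extra
    arrays = model.state_arrays()
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[MegaGo, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        state = {k: data[k] for k in data.files if k != "__header__"}
    config = RunConfig.from_dict(header["config"])
    model = MegaGo(config, n_terms=header["n_terms"])
    model.load_state_arrays(state)
    return model, header


# ---------------------------------------------------------------------------
# CAFA-style prediction TSV


def write_predictions(protein_ids: list[str], term_ids: list[str],
                      probs: np.ndarray, path: str | Path) -> None:
    """"protein<TAB>term<TAB>score" rows, sorted by descending score."""
    rows = []
    for i, pid in enumerate(protein_ids):
        for j, tid in enumerate(term_ids):
            rows.append((pid, tid, float(probs[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        for pid, tid, score in rows:
            fh.write(f"{pid}\t{tid}\t{score:.6f}\n")


def read_predictions(path: str | Path, protein_ids: list[str],
                     term_ids: list[str]) -> np.ndarray:
    """Pivot a prediction TSV back into an aligned score matrix."""
    pidx = {p: i for i, p in enumerate(protein_ids)}
    tidx = {t: j for j, t in enumerate(term_ids)}
    probs = np.zeros((len(protein_ids), len(term_ids)))
    matched = 0
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        pid, tid, score = raw.split("\t")
        if pid in pidx and tid in tidx:
            probs[pidx[pid], tidx[tid]] = float(score)
            matched += 1
    if matched == 0:
        raise ValueError("prediction and truth ID sets are disjoint")
    return probs
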