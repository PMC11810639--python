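"""End-to-end workflows behind the command-line interface.

Each ``cmd_*`` function is importable and CLI-independent; the ``megago``
commands are thin wrappers around them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import gemmi
import numpy as np

from .config import RunConfig
from .data import ProteinGraph, build_graph, load_graph, save_graph
from .features import MockEmbedder
from .objective_metrics import (EvalReport, evaluate, information_content,
                                read_ic_table)
from .structures_io import read_annotations, read_chain
from .train import (TrainResult, load_checkpoint, predict_probs,
                    read_predictions, save_checkpoint, train_model,
                    write_predictions)

logger = logging.getLogger(__name__)

DEFAULT_EMBED_SEED = 0


def first_chain_id(path: str | Path) -> str:
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0 or len(structure[0]) == 0:
        raise ValueError(f"no chains in {path}")
    return structure[0][0].name


def _collect_structures(structures_dir: str | Path) -> list[Path]:
    structures_dir = Path(structures_dir)
    files = sorted(p for p in structures_dir.iterdir()
                   if p.suffix.lower() in (".pdb", ".cif", ".mmcif"))
    if not files:
        raise FileNotFoundError(f"no structure files in {structures_dir}")
    return files


def cmd_build_graphs(structures_dir: str | Path,
                     annotations_path: str | Path | None,
                     out_dir: str | Path,
                     namespace: str = "MF",
                     f2_dim: int = 16,
                     embed_seed: int = DEFAULT_EMBED_SEED,
                     threshold: float = 10.0,
                     force: bool = False) -> dict:
    """Serialize one graph per chain plus a dataset index.

    Unreadable files are collected as failures and the run continues; the
    call raises only if every file fails.  Re-runs skip graphs whose output
    is newer than the input (idempotent cache).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    embedder = MockEmbedder(dim=f2_dim, seed=embed_seed)
    annotations = None
    if annotations_path is not None:
        annotations = read_annotations(annotations_path, namespace)
    pid_row = ({p: i for i, p in enumerate(annotations.protein_ids)}
               if annotations else {})
    entries, failures = [], []
    n_cached = 0
    for path in _collect_structures(structures_dir):
        pid = path.stem
        out_path = out_dir / f"{pid}.npz"
        try:
            if (not force and out_path.exists()
                    and out_path.stat().st_mtime >= path.stat().st_mtime):
                graph = load_graph(out_path)
                n_cached += 1
            else:
                chain = read_chain(path, first_chain_id(path))
                labels = (annotations.matrix[pid_row[pid]]
                          if pid in pid_row else None)
                graph = build_graph(chain, embedder, protein_id=pid,
                                    labels=labels, threshold=threshold)
                save_graph(graph, out_path)
            entries.append({"protein_id": pid, "file": out_path.name,
                            "n_residues": graph.n_residues,
                            "m_edges": graph.edges.m_edges,
                            "length_class": graph.length_class.value})
        except Exception as exc:  # tolerate per-file failures
            logger.warning("failed to build graph for %s: %s", path.name, exc)
            failures.append({"file": path.name, "error": str(exc)})
    if not entries:
        raise RuntimeError(f"all {len(failures)} structure files failed")
    index = {"namespace": namespace,
             "term_ids": annotations.term_ids if annotations else [],
             "f2_dim": f2_dim, "embed_seed": embed_seed,
             "threshold": threshold, "graphs": entries,
             "failures": failures, "n_cached": n_cached}
    (out_dir / "index.json").write_text(json.dumps(index, indent=1))
    return index


def load_graph_dir(graph_dir: str | Path) -> tuple[list[ProteinGraph], dict]:
    graph_dir = Path(graph_dir)
    index = json.loads((graph_dir / "index.json").read_text())
    graphs = [load_graph(graph_dir / e["file"]) for e in index["graphs"]]
    return graphs, index


def load_bundle(bundle_dir: str | Path, f2_dim: int = 16,
                embed_seed: int = DEFAULT_EMBED_SEED,
                threshold: float = 10.0,
                namespace: str = "MF") -> tuple[list[ProteinGraph], list[str]]:
    """Build graphs in memory straight from a synthetic-style bundle
    (structures/ + annotations.tsv)."""
    bundle_dir = Path(bundle_dir)
    annotations = read_annotations(bundle_dir / "annotations.tsv", namespace)
    embedder = MockEmbedder(dim=f2_dim, seed=embed_seed)
    graphs = []
    for i, pid in enumerate(annotations.protein_ids):
        chain = read_chain(bundle_dir / "structures" / f"{pid}.pdb", "A")
        graphs.append(build_graph(chain, embedder, protein_id=pid,
                                  labels=annotations.matrix[i],
                                  threshold=threshold))
    return graphs, annotations.term_ids


def cmd_train(config: RunConfig, data_dir: str | Path,
              checkpoint_path: str | Path,
              log_path: str | Path | None = None) -> TrainResult:
    """Train on a graph directory (from build-graphs) or a raw bundle."""
    data_dir = Path(data_dir)
    if (data_dir / "index.json").exists():
        graphs, index = load_graph_dir(data_dir)
        term_ids = index["term_ids"]
    else:
        graphs, term_ids = load_bundle(data_dir, f2_dim=config.f2_dim)
    graphs = [g for g in graphs if g.labels is not None]
    log_fh = open(log_path, "w") if log_path else None
    try:
        def log_fn(entry):
            logger.info("epoch %s", entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
        result = train_model(config, graphs, log_fn=log_fn)
    finally:
        if log_fh:
            log_fh.close()
    save_checkpoint(result.model, checkpoint_path,
                    extra={"term_ids": term_ids,
                           "val_ids": result.val_ids,
                           "history_tail": result.history[-1]})
    return result


def cmd_predict(checkpoint_path: str | Path, structures: str | Path,
                out_tsv: str | Path,
                embed_seed: int = DEFAULT_EMBED_SEED) -> np.ndarray:
    """Deterministic inference on a structure directory or graph directory."""
    model, header = load_checkpoint(checkpoint_path)
    term_ids = header.get("extra", {}).get("term_ids") or \
        [f"term_{j}" for j in range(model.n_terms)]
    structures = Path(structures)
    if (structures / "index.json").exists():
        graphs, index = load_graph_dir(structures)
        if index["f2_dim"] != model.config.f2_dim:
            raise ValueError(
                f"embedding width mismatch: graphs have f2_dim="
                f"{index['f2_dim']}, checkpoint expects "
                f"{model.config.f2_dim}")
    else:
        embedder = MockEmbedder(dim=model.config.f2_dim, seed=embed_seed)
        graphs = []
        for path in _collect_structures(structures):
            chain = read_chain(path, first_chain_id(path))
            graphs.append(build_graph(chain, embedder, protein_id=path.stem))
    probs = predict_probs(model, graphs, seed=model.config.seed)
    write_predictions([g.protein_id for g in graphs], term_ids, probs, out_tsv)
    return probs


def sweep_sensitivity(graphs, delta1_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
                      tau_grid=(0.3, 0.5, 0.7, 0.9, 1.5, 2.0),
                      base: RunConfig | None = None) -> list[dict]:
    """Simple sensitivity sweep over the blend ratio δ1 and noise scale τ.

    Trains one model per grid point (τ1 = τ2 = τ) and records the final
    validation AUPR.  Returns a list of {"delta1", "tau", "val_aupr"} rows.
    """
    from dataclasses import replace
    base = base or RunConfig()
    rows = []
    for delta1 in delta1_grid:
        for tau in tau_grid:
            cfg = replace(base, delta1=delta1, tau1=tau, tau2=tau)
            result = train_model(cfg, graphs)
            rows.append({"delta1": delta1, "tau": tau,
                         "val_aupr": result.history[-1].get("val_aupr")})
    return rows


def cmd_evaluate(truth_path: str | Path, pred_path: str | Path,
                 ic_path: str | Path | None = None,
                 manifest_path: str | Path | None = None,
                 namespace: str = "MF",
                 out_json: str | Path | None = None) -> EvalReport:
    """Overall and stratified Fmax/AUPR/Smin from truth + prediction TSVs."""
    truth = read_annotations(truth_path, namespace)
    probs = read_predictions(pred_path, truth.protein_ids, truth.term_ids)
    ic = None
    if ic_path is not None:
        table = read_ic_table(ic_path)
        order = {t: j for j, t in enumerate(table.terms)}
        missing = [t for t in truth.term_ids if t not in order]
        if missing:
            raise ValueError(f"IC table lacks terms: {missing[:5]}")
        idx = [order[t] for t in truth.term_ids]
        ic = information_content(table.p[idx], terms=list(truth.term_ids))
    lengths = None
    if manifest_path is not None:
        manifest = json.loads(Path(manifest_path).read_text())
        by_id = {r["protein_id"]: r["n_residues"] for r in manifest["proteins"]}
        lengths = [by_id[p] for p in truth.protein_ids]
    report = evaluate(truth.matrix, probs, ic=ic, lengths=lengths)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report.to_dict(), indent=1))
    return report
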