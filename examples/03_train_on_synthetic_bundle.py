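"""Train the full three-tower model on a small synthetic bundle.

Generates 24 proteins with a planted sequence→function signal, trains for
8 epochs on CPU, and prints the loss trajectory plus held-out metrics.
Expect the total loss to fall steeply and the validation AUPR to edge
above the label prevalence (the random-ranking baseline); at the study
scale (120 proteins, 30 epochs) the gap widens to 2–3×.
"""

import tempfile
from pathlib import Path

import numpy as np

from megago import RunConfig, aupr
from megago.pipeline import load_bundle
from megago.synthetic import SyntheticSpec, make_dataset
from megago.train import predict_probs, train_model

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    make_dataset(SyntheticSpec(n_proteins=24, m_terms=12, seed=5), bundle)
    graphs, _ = load_bundle(bundle, f2_dim=16)

    cfg = RunConfig(seed=1, epochs=8, batch_size=8, patience=100)
    result = train_model(cfg, graphs)

    for h in result.history:
        print(f"epoch {h['epoch']}: total loss {h['total']:.3f}  "
              f"val AUPR {h.get('val_aupr', float('nan')):.3f}")

    val = [g for g in graphs if g.protein_id in set(result.val_ids)]
    y = np.vstack([g.labels for g in val])
    probs = predict_probs(result.model, val, seed=1)
    print(f"\nheld-out micro-AUPR {aupr(y, probs):.3f} "
          f"vs prevalence {y.mean():.3f}")
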