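"""Weighted multi-label objective, term information content, and CAFA-style
evaluation metrics (Fmax, Smin, AUPR) with length-class / IC-band strata.

The loss is a weighted binary cross-entropy per tower, summed over active
towers.  Term weights counteract class imbalance:

    w_j = max(1, min(10, Σ_i N_i⁺ / (l · N_j⁺)))

with the sum running over all l labels; never-observed terms (N_j⁺ = 0) get
the upper clamp.  Information content of a term with training frequency P
is IC = −log2(P); evaluation can stratify terms into IC bands (<5, 5–10,
>10) and proteins into length classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .structures_io import LengthClass, classify_length
from .tensor import Tensor

DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)
EPS_CLIP = 1e-7


# ---------------------------------------------------------------------------
# label weights and loss


@dataclass
class LabelWeights:
    weights: np.ndarray  # length-l, each in [1, 10]
    positives: np.ndarray  # length-l counts

    @property
    def n_terms(self) -> int:
        return len(self.weights)


@dataclass
class LossReport:
    per_branch: dict[str, float]
    total: float
    normalization: str = "as_printed"


def label_weights(y_or_counts: np.ndarray) -> LabelWeights:
    """Clamped inverse-frequency weights per term.

    Accepts either a binary n×l matrix or a length-l positive-count vector.
    """
    arr = np.asarray(y_or_counts)
    counts = arr.sum(axis=0).astype(float) if arr.ndim == 2 else arr.astype(float)
    l = len(counts)
    if l < 1:
        raise ValueError("need at least one label")
    total = counts.sum()
    with np.errstate(divide="ignore"):
        raw = np.where(counts > 0, total / (l * np.maximum(counts, 1e-300)),
                       np.inf)
    weights = np.clip(raw, 1.0, 10.0)
    return LabelWeights(weights=weights, positives=counts)


def wce_loss(y: np.ndarray, yhat: Tensor | np.ndarray, w: LabelWeights,
             normalization: str = "as_printed") -> Tensor:
    """Weighted binary cross-entropy over an n×m prediction matrix.

    ``normalization="as_printed"`` divides by n²; ``"conventional"`` divides
    by n·m.  Probabilities are clipped to [ε, 1−ε] with ε = 1e-7.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(yhat, Tensor):
        yhat = Tensor(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs yhat {yhat.shape}")
    n, m = y.shape
    if normalization == "as_printed":
        z = float(n * n)
    elif normalization == "conventional":
        z = float(n * m)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    p = yhat.clip(EPS_CLIP, 1.0 - EPS_CLIP)
    wt = Tensor(w.weights[None, :])
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -(wt * ll).sum() * (1.0 / z)


def total_loss(per_branch: dict[str, Tensor | float],
               normalization: str = "as_printed") -> LossReport:
    """Plain sum of the active towers' WCE values (inactive contribute 0)."""
    vals = {k: (float(v.data) if isinstance(v, Tensor) else float(v))
            for k, v in per_branch.items()}
    return LossReport(per_branch=vals, total=float(sum(vals.values())),
                      normalization=normalization)


# ---------------------------------------------------------------------------
# information content


@dataclass
class ICTable:
    terms: list[str]
    p: np.ndarray  # per-term training relative frequency, in (0, 1]
    ic: np.ndarray  # −log2(p); +inf for never-observed terms
    has_zero_frequency: bool = False

    def band(self, j: int) -> str:
        return ic_band(self.ic[j])

    def by_term(self) -> dict[str, float]:
        return dict(zip(self.terms, self.ic))


def write_ic_table(table: ICTable, path) -> None:
    """TSV rows "term<TAB>p<TAB>ic"."""
    from pathlib import Path
    lines = [f"{t}\t{p:.10g}\t{ic:.10g}"
             for t, p, ic in zip(table.terms, table.p, table.ic)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ic_table(path) -> ICTable:
    from pathlib import Path
    terms, ps = [], []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        term, p, _ic = raw.split("\t")
        terms.append(term)
        ps.append(float(p))
    return information_content(np.array(ps), terms=terms)


def ic_band(ic: float) -> str:
    """Band a term by its IC: "<5", "5-10" (inclusive), ">10"."""
    if ic < 5:
        return "<5"
    if ic <= 10:
        return "5-10"
    return ">10"


def information_content(freqs: dict[str, float] | np.ndarray,
                        terms: list[str] | None = None) -> ICTable:
    """IC(go) = −log2(P(go)) from training-split term frequencies."""
    if isinstance(freqs, dict):
        terms = list(freqs.keys())
        p = np.array([freqs[t] for t in terms], dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
        terms = [f"term_{j}" for j in range(len(p))] if terms is None else terms
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        ic = -np.log2(p)
    return ICTable(terms=terms, p=p, ic=ic,
                   has_zero_frequency=bool(np.any(p == 0)))


# ---------------------------------------------------------------------------
# CAFA metrics


def _as_arrays(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=int)
    yhat = yhat.data if isinstance(yhat, Tensor) else np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat shapes differ")
    return y, yhat


def fmax(y: np.ndarray, yhat: np.ndarray,
         grid: np.ndarray = DEFAULT_GRID) -> tuple[float, float]:
    """Protein-centric Fmax over a threshold grid.

    At threshold t a term is predicted when its score ≥ t.  Precision is
    averaged over proteins with ≥1 predicted term; recall over proteins
    with ≥1 true term.  Returns (Fmax, argmax threshold).
    """
    y, yhat = _as_arrays(y, yhat)
    has_truth = y.sum(axis=1) > 0
    if not has_truth.any():
        raise ValueError("no protein has a true annotation")
    best, best_t = 0.0, float(grid[0])
    truth_counts = y.sum(axis=1)
    for t in grid:
        pred = yhat >= t
        npred = pred.sum(axis=1)
        tp = (pred & (y == 1)).sum(axis=1)
        covered = npred > 0
        if not covered.any():
            continue
        precision = float((tp[covered] / npred[covered]).mean())
        recall = float((tp[has_truth] / truth_counts[has_truth]).mean())
        if precision + recall == 0:
            continue
        f1 = 2 * precision * recall / (precision + recall)
        if f1 > best:
            best, best_t = f1, float(t)
    return best, best_t


def smin(y: np.ndarray, yhat: np.ndarray, ic: ICTable | np.ndarray,
         grid: np.ndarray = DEFAULT_GRID,
         normalized: bool = False) -> tuple[float, float]:
    """Semantic-distance minimum over thresholds.

    ru(t) = mean over proteins of Σ IC(false negatives), mi(t) likewise for
    false positives; S(t) = √(ru² + mi²).  With ``normalized`` the value is
    divided by S at the all-negative predictor (pure remaining uncertainty),
    mapping it onto [0, 1].  Returns (Smin, argmin threshold).
    """
    y, yhat = _as_arrays(y, yhat)
    icv = ic.ic if isinstance(ic, ICTable) else np.asarray(ic, float)
    if len(icv) != y.shape[1]:
        raise ValueError("need one IC value per term")
    if not (y.sum(axis=1) > 0).any():
        raise ValueError("no protein has a true annotation")
    best, best_t = np.inf, float(grid[0])
    for t in grid:
        pred = yhat >= t
        fn = (y == 1) & ~pred
        fp = (y == 0) & pred
        ru = float((fn * icv[None, :]).sum(axis=1).mean())
        mi = float((fp * icv[None, :]).sum(axis=1).mean())
        s = float(np.hypot(ru, mi))
        if s < best:
            best, best_t = s, float(t)
    if normalized:
        s0 = float((y * icv[None, :]).sum(axis=1).mean())
        best = best / s0 if s0 > 0 else 0.0
    return best, best_t


def aupr(y: np.ndarray, yhat: np.ndarray, averaging: str = "micro") -> float:
    """Area under the precision–recall curve.

    Micro pools all protein–term pairs (step-wise average precision, so a
    constant-score predictor scores exactly the positive prevalence); macro
    averages per-term AP over terms with ≥1 positive.
    """
    y, yhat = _as_arrays(y, yhat)
    if y.sum() == 0:
        raise ValueError("no positive pairs")
    if averaging == "micro":
        return float(average_precision_score(y.ravel(), yhat.ravel()))
    if averaging == "macro":
        keep = y.sum(axis=0) > 0
        return float(np.mean([average_precision_score(y[:, j], yhat[:, j])
                              for j in np.nonzero(keep)[0]]))
    raise ValueError(f"unknown averaging {averaging!r}")


# ---------------------------------------------------------------------------
# evaluation report and stratification


@dataclass
class EvalReport:
    fmax: float
    aupr: float
    smin: float
    smin_normalized: float | None = None
    fmax_threshold: float = 0.0
    smin_threshold: float = 0.0
    strata: dict[str, "EvalReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"fmax": self.fmax, "aupr": self.aupr, "smin": self.smin,
               "smin_normalized": self.smin_normalized,
               "fmax_threshold": self.fmax_threshold,
               "smin_threshold": self.smin_threshold}
        if self.strata:
            out["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return out


def evaluate(y: np.ndarray, yhat: np.ndarray,
             ic: ICTable | None = None,
             lengths: list[int] | None = None,
             grid: np.ndarray = DEFAULT_GRID,
             _stratify: bool = True) -> EvalReport:
    """Overall Fmax/AUPR/Smin, plus per-length-class and per-IC-band
    sub-reports when stratum information is given."""
    y, yhat = _as_arrays(y, yhat)
    f, ft = fmax(y, yhat, grid)
    a = aupr(y, yhat)
    if ic is not None:
        s, st = smin(y, yhat, ic, grid)
        sn, _ = smin(y, yhat, ic, grid, normalized=True)
    else:
        s, st, sn = float("nan"), 0.0, None
    report = EvalReport(fmax=f, aupr=a, smin=s, smin_normalized=sn,
                        fmax_threshold=ft, smin_threshold=st)
    if not _stratify:
        return report
    if lengths is not None:
        classes = np.array([classify_length(n).value for n in lengths])
        for cls in (LengthClass.SHORT, LengthClass.NORMAL, LengthClass.LONG):
            rows = classes == cls.value
            if rows.any() and y[rows].sum() > 0:
                report.strata[f"length:{cls.value}"] = evaluate(
                    y[rows], yhat[rows], ic=ic, grid=grid, _stratify=False)
    if ic is not None:
        bands = np.array([ic_band(v) for v in ic.ic])
        for band in ("<5", "5-10", ">10"):
            cols = bands == band
            if cols.any() and y[:, cols].sum() > 0:
                sub = ICTable(terms=[t for t, k in zip(ic.terms, cols) if k],
                              p=ic.p[cols], ic=ic.ic[cols])
                report.strata[f"ic:{band}"] = evaluate(
                    y[:, cols], yhat[:, cols], ic=sub, grid=grid,
                    _stratify=False)
    return report


def stratified_balance(items: list, seed: int = 0,
                       length_of=None) -> tuple[list, dict]:
    """Seeded downsampling to equal length-class counts.

    ``items`` is any list; ``length_of(item)`` must yield the chain length
    (default: ``item.n_residues`` or ``item[0].n_residues``).  Returns the
    balanced subset (original order preserved) and a before/after count
    report.  Raises if a class is empty.
    """
    if length_of is None:
        def length_of(item):
            obj = item[0] if isinstance(item, tuple) else item
            return obj.n_residues
    classes: dict[str, list[int]] = {c.value: [] for c in LengthClass}
    for i, item in enumerate(items):
        classes[classify_length(int(length_of(item))).value].append(i)
    empty = [c for c, idx in classes.items() if not idx]
    if empty:
        raise ValueError(f"empty length class(es): {empty}")
    k = min(len(idx) for idx in classes.values())
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for idx in classes.values():
        keep.update(rng.choice(idx, size=k, replace=False).tolist())
    report = {"before": {c: len(idx) for c, idx in classes.items()},
              "after": {c: k for c in classes}}
    return [items[i] for i in sorted(keep)], report
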