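"""Self-contained synthetic fixtures: chains with plausible Cα geometry,
controlled length-class mixtures, and multi-label annotations carrying a
planted, learnable signal at controlled per-term frequencies.

The geometry is a seeded self-avoiding random walk with consecutive-Cα
spacing 3.8 ± 0.05 Å and a 3.0 Å minimum non-consecutive separation, with a
weak pull toward the running centroid so chains are compact enough to have
long-range contacts at the 10 Å threshold.  Labels come from a logistic
model on observable sequence statistics (hydrophobic fraction, length
class), so the signal is learnable from one-hot features alone; per-term
frequencies are hit exactly by taking the top-scoring proteins under
Gumbel-perturbed logits (at signal strength 0 this degenerates to uniform
random label assignment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures_io import (AnnotationSet, ChainSource, LengthClass,
                            ProteinChain, classify_length, write_annotations,
                            write_chain, write_fasta)

STEP_MEAN_A = 3.8  # consecutive Cα spacing, Å
STEP_JITTER_A = 0.05
MIN_SEPARATION_A = 3.0  # non-consecutive clash distance, Å

HYDROPHOBIC = set("AVILMFWC")
#: sampling ranges (residues) per length class
LENGTH_RANGES = {"short": (30, 99), "normal": (100, 500), "long": (501, 800)}


def default_freq_spectrum(m_terms: int) -> np.ndarray:
    """Per-term target frequencies sliding geometrically from 0.5 to 2⁻⁶,
    spreading information content between 1 and 6 bits."""
    return np.geomspace(0.5, 2.0 ** -6, m_terms)


@dataclass
class SyntheticSpec:
    n_proteins: int = 60
    length_mix: dict[str, float] = field(
        default_factory=lambda: {"short": 1 / 3, "normal": 1 / 3, "long": 1 / 3})
    m_terms: int = 20
    freq_spectrum: np.ndarray | None = None
    signal_strength: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.length_mix.values()) - 1.0) > 1e-9:
            raise ValueError("length_mix proportions must sum to 1")
        if self.freq_spectrum is None:
            self.freq_spectrum = default_freq_spectrum(self.m_terms)
        self.freq_spectrum = np.asarray(self.freq_spectrum, dtype=float)
        if len(self.freq_spectrum) != self.m_terms:
            raise ValueError("freq_spectrum length must equal m_terms")
        if np.any(self.freq_spectrum <= 0) or np.any(self.freq_spectrum >= 1):
            raise ValueError("target frequencies must lie in (0, 1)")


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    """Composition varies between proteins: per-protein hydrophobic
    propensity is drawn from U(0.2, 0.6), giving the label model variance
    to plant signal on."""
    theta = rng.uniform(0.2, 0.6)
    hydro = sorted(HYDROPHOBIC)
    polar = sorted(set("ACDEFGHIKLMNPQRSTVWY") - HYDROPHOBIC)
    letters = [
        rng.choice(hydro) if rng.random() < theta else rng.choice(polar)
        for _ in range(n)]
    return "".join(letters)


def generate_chain(length: int, seed: int,
                   max_restarts: int = 20) -> ProteinChain:
    """Seeded self-avoiding walk with native-like Cα spacing."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    sequence = _random_sequence(length, rng)
    for _ in range(max_restarts):
        coords = _try_walk(length, rng)
        if coords is not None:
            return ProteinChain(chain_id="A", sequence=sequence,
                                ca_coords=coords, source=ChainSource.SYNTHETIC)
    raise RuntimeError(f"self-avoiding walk failed after {max_restarts} restarts")


def _try_walk(length: int, rng: np.random.Generator,
              max_tries_per_step: int = 60) -> np.ndarray | None:
    coords = np.zeros((length, 3))
    for i in range(1, length):
        placed = False
        for attempt in range(max_tries_per_step):
            direction = rng.normal(size=3)
            # weak centroid pull keeps the chain compact enough for
            # long-range contacts; it decays on retries so crowded regions
            # never trap the walk
            centroid = coords[:i].mean(axis=0)
            pull = centroid - coords[i - 1]
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                direction = direction + 0.35 * (0.5 ** attempt) * pull / norm
            direction /= np.linalg.norm(direction)
            step = rng.uniform(STEP_MEAN_A - STEP_JITTER_A,
                               STEP_MEAN_A + STEP_JITTER_A)
            cand = coords[i - 1] + step * direction
            if i >= 2:
                d = np.linalg.norm(coords[:i - 1] - cand, axis=1)
                if d.min() < MIN_SEPARATION_A:
                    continue
            coords[i] = cand
            placed = True
            break
        if not placed:
            return None
    return coords


def _sequence_statistics(chains: list[ProteinChain]) -> np.ndarray:
    """Per-protein covariates: standardized hydrophobic fraction and
    standardized log-length."""
    hydro = np.array([sum(aa in HYDROPHOBIC for aa in c.sequence) /
                      c.n_residues for c in chains])
    loglen = np.log(np.array([c.n_residues for c in chains], dtype=float))

    def z(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)
    return np.column_stack([z(hydro), z(loglen)])


def generate_labels(chains: list[ProteinChain],
                    spec: SyntheticSpec) -> AnnotationSet:
    """Plant a logistic signal linking sequence statistics to terms.

    Term j scores protein i as ``s·(c_j1·z_hydro + c_j2·z_loglen)`` plus
    Gumbel noise; the ``round(P_j·n)`` highest-scoring proteins (at least
    one) are annotated, which pins realized frequencies to the targets.
    """
    if spec.m_terms < 2:
        raise ValueError("need at least two terms")
    n = len(chains)
    rng = np.random.default_rng(spec.seed + 1)
    x = _sequence_statistics(chains)
    matrix = np.zeros((n, spec.m_terms), dtype=np.uint8)
    for j in range(spec.m_terms):
        # deterministic ±1 coefficient pattern varies the signal direction
        c1 = 1.0 if (j % 2 == 0) else -1.0
        c2 = 1.0 if (j // 2) % 2 == 0 else -1.0
        logits = spec.signal_strength * (c1 * x[:, 0] + c2 * x[:, 1])
        gumbel = -np.log(-np.log(rng.uniform(1e-12, 1.0, size=n)))
        k = max(1, int(round(spec.freq_spectrum[j] * n)))
        if k > n:
            raise ValueError(f"infeasible frequency target for term {j}")
        top = np.argsort(-(logits + gumbel))[:k]
        matrix[top, j] = 1
    protein_ids = [f"synth_{i:04d}" for i in range(n)]
    term_ids = [f"GO:{7000000 + j:07d}" for j in range(spec.m_terms)]
    return AnnotationSet(namespace="MF", protein_ids=protein_ids,
                         term_ids=term_ids, matrix=matrix)


def generate_chains(spec: SyntheticSpec) -> list[ProteinChain]:
    """Chains with the requested length-class mixture (largest-remainder
    apportioning of counts, seeded lengths within each class's range)."""
    rng = np.random.default_rng(spec.seed)
    counts = _apportion(spec.n_proteins, spec.length_mix)
    chains: list[ProteinChain] = []
    i = 0
    for cls, count in counts.items():
        lo, hi = LENGTH_RANGES[cls]
        for _ in range(count):
            n = int(rng.integers(lo, hi + 1))
            chain = generate_chain(n, seed=int(rng.integers(0, 2 ** 31)))
            chain.chain_id = "A"
            chains.append(chain)
            i += 1
    return chains


def _apportion(total: int, mix: dict[str, float]) -> dict[str, int]:
    raw = {c: total * p for c, p in mix.items()}
    base = {c: int(np.floor(v)) for c, v in raw.items()}
    rem = total - sum(base.values())
    order = sorted(mix, key=lambda c: raw[c] - base[c], reverse=True)
    for c in order[:rem]:
        base[c] += 1
    return {c: base[c] for c in ("short", "normal", "long") if base.get(c, 0) > 0}


def make_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict:
    """Write PDB chains, a FASTA, an annotation TSV and a manifest JSON.

    The bundle round-trips through the structure/annotation readers.
    Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    chains = generate_chains(spec)
    labels = generate_labels(chains, spec)
    sequences = {}
    records = []
    for pid, chain in zip(labels.protein_ids, chains):
        write_chain(chain, outdir / "structures" / f"{pid}.pdb")
        sequences[pid] = chain.sequence
        records.append({"protein_id": pid, "n_residues": chain.n_residues,
                        "length_class": classify_length(chain).value})
    write_fasta(sequences, outdir / "sequences.fasta")
    write_annotations(labels, outdir / "annotations.tsv")
    class_counts = {c.value: 0 for c in LengthClass}
    for r in records:
        class_counts[r["length_class"]] += 1
    manifest = {
        "n_proteins": spec.n_proteins,
        "m_terms": spec.m_terms,
        "seed": spec.seed,
        "signal_strength": spec.signal_strength,
        "freq_spectrum": spec.freq_spectrum.tolist(),
        "realized_frequencies": (labels.matrix.mean(axis=0)).tolist(),
        "class_counts": class_counts,
        "proteins": records,
        "namespace": labels.namespace,
        "term_ids": labels.term_ids,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
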