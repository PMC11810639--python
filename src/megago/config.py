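"""Run configuration, ablation presets, and YAML round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

#: preset name → config overrides; unicode aliases accepted at lookup.
PRESETS: dict[str, dict] = {
    # all three towers, noise, adapters, adaAF, ζ-gating
    "full": {},
    # only the Main branch, feature blocks kept: L reduces to WCE_Main
    "Mx3": {"towers": ("main",), "iab_enabled": False,
            "noise_active": False},
    # Main plus two long-biased extractors
    "ax2+M": {"towers": ("main", "alpha", "alpha")},
    # Main plus two short-biased extractors
    "bx2+M": {"towers": ("main", "beta", "beta")},
    # bare single tower: no adaptive fusion, plain SAB readout
    "H-GNN": {"towers": ("main",), "iab_enabled": False,
              "noise_active": False, "adaaf_enabled": False,
              "zeta_gating": False},
    # three independent towers with noise but no adapters
    "H-GNNx3": {"iab_enabled": False},
    # plain two-projection feature fusion
    "no_adaAF": {"adaaf_enabled": False},
    # plain structural attention: no ζ-gating
    "SAB": {"zeta_gating": False},
}

_ALIASES = {"M×3": "Mx3", "α×2+M": "ax2+M", "β×2+M": "bx2+M",
            "H-GNN×3": "H-GNNx3"}


@dataclass
class RunConfig:
    """Every knob of the pipeline, with desk-scale defaults."""

    seed: int = 0
    ablation: str = "full"
    # adaAF
    adaaf_enabled: bool = True
    f2_dim: int = 16          # embedder width (1280 for the real model)
    feat_dim: int = 16        # fused width F
    delta1: float = 0.5
    pool_out: int | None = None
    # DH-GNN
    hidden: int = 16
    sample_k: int | str = "all"
    tau1: float = 0.5
    tau2: float = 0.5
    iab_enabled: bool = True
    noise_active: bool = True
    towers: tuple[str, ...] = ("main", "alpha", "beta")
    # adaSAB
    zeta: float = 0.5
    zeta_gating: bool = True
    fusion: str = "mean"      # "mean" | "main_only"
    # objective
    loss_normalization: str = "as_printed"
    # training
    lr: float = 1e-3
    batch_size: int = 8
    epochs: int = 50
    patience: int = 10
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.towers = tuple(self.towers)

    # -- presets ----------------------------------------------------------

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        name = _ALIASES.get(name, name)
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        return cls(ablation=name, **{**PRESETS[name], **overrides})

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["towers"] = list(self.towers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "towers" in d:
            d["towers"] = tuple(d["towers"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)
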