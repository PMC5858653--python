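"""Synthetic CT data generators with known ground truth.

CT values are generated from the standard-curve relation read in the
generative direction: a gene with amplification efficiency ``E`` and
intercept ``b`` amplifying ``amount`` ng of template crosses threshold
at

    CT = b + m · log10(amount),   m = −1 / log10(E)

(perfect doubling, E = 2, gives m ≈ −3.3219).  Measurement error is
additive Gaussian on the CT scale.  Every generator is reproducible
from its integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CtTable

__all__ = [
    "GeneSpec",
    "GroupSpec",
    "GeneratorSpec",
    "generate_group_experiment",
    "generate_dilution_experiment",
    "spec_from_json",
]


@dataclass(frozen=True)
class GeneSpec:
    name: str
    efficiency: float = 2.0  # per-cycle amplification factor, > 1
    intercept: float = 30.0  # CT at 1 ng

    @property
    def slope(self) -> float:
        return -1.0 / np.log10(self.efficiency)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    amounts: Mapping[str, float]  # gene name -> true template amount (ng)


@dataclass
class GeneratorSpec:
    genes: list[GeneSpec]
    groups: list[GroupSpec] = field(default_factory=list)
    noise_sd: float = 0.0  # cycles
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("need at least one gene")
        for g in self.genes:
            if g.efficiency <= 1:
                raise ValueError(f"gene {g.name!r}: efficiency must exceed 1")
        for grp in self.groups:
            if grp.n < 1:
                raise ValueError(f"group {grp.label!r}: n must be >= 1")
            missing = [g.name for g in self.genes if g.name not in grp.amounts]
            if missing:
                raise ValueError(f"group {grp.label!r}: no amount for {missing}")
            if any(a <= 0 for a in grp.amounts.values()):
                raise ValueError(f"group {grp.label!r}: amounts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _noisy_ct(gene: GeneSpec, amount: float, n: int, sd: float, rng) -> np.ndarray:
    det = gene.intercept + gene.slope * np.log10(amount)
    return det + rng.normal(0.0, sd, size=n) if sd > 0 else np.full(n, det)


def generate_group_experiment(spec: GeneratorSpec) -> CtTable:
    """Control-vs-condition CT table with per-row group labels."""
    if not spec.groups:
        raise ValueError("spec has no groups")
    rng = np.random.default_rng(spec.seed)
    cols = {g.name: [] for g in spec.genes}
    labels = []
    for grp in spec.groups:
        labels += [grp.label] * grp.n
        for g in spec.genes:
            cols[g.name].append(_noisy_ct(g, grp.amounts[g.name], grp.n, spec.noise_sd, rng))
    df = pd.DataFrame({name: np.concatenate(parts) for name, parts in cols.items()})
    return CtTable(df, group=np.array(labels, dtype=object))


def generate_dilution_experiment(
    spec: GeneratorSpec,
    amounts: Sequence[float],
    replicates: int = 3,
    constrain_means: bool = True,
) -> CtTable:
    """Serial-dilution CT table with per-row input amounts.

    ``constrain_means=True`` recentres the noise within each
    (gene, dilution) cell so every per-dilution replicate mean equals
    its noiseless value exactly; the between-replicate scatter is kept.
    """
    amounts = np.asarray(amounts, dtype=float)
    if amounts.size < 2 or np.any(amounts <= 0):
        raise ValueError("need >= 2 positive dilution levels")
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for g in spec.genes:
        parts = []
        for a in amounts:
            ct = _noisy_ct(g, a, replicates, spec.noise_sd, rng)
            if constrain_means and replicates > 1:
                det = g.intercept + g.slope * np.log10(a)
                ct = ct - ct.mean() + det
            parts.append(ct)
        cols[g.name] = np.concatenate(parts)
    df = pd.DataFrame(cols)
    return CtTable(df, amount=np.repeat(amounts, replicates))


def spec_from_json(source) -> GeneratorSpec:
    """Build a GeneratorSpec from a JSON file/stream/string.

    Expected keys: ``genes`` (list of {name, efficiency, intercept}),
    optional ``groups`` (list of {label, n, amounts}), ``noise_sd``,
    ``seed``.
    """
    if hasattr(source, "read"):
        cfg = json.load(source)
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        cfg = json.loads(source)
    else:
        with open(source) as fh:
            cfg = json.load(fh)
    genes = [GeneSpec(g["name"], g.get("efficiency", 2.0), g.get("intercept", 30.0))
             for g in cfg["genes"]]
    groups = [GroupSpec(g["label"], int(g["n"]), g["amounts"])
              for g in cfg.get("groups", [])]
    return GeneratorSpec(genes, groups, float(cfg.get("noise_sd", 0.0)),
                         int(cfg.get("seed", 0)))
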