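"""Synthetic compositional count data with planted log-ratio signal.

The generator emulates the statistical structure that high-throughput
sequencing (HTS) data are assumed to have: per-sample latent log-abundances,
an outcome that depends on the latent composition *only through log-ratios*
(so the generative law is scale-invariant by construction), and observed
counts drawn multinomially at an arbitrary, sample-specific sequencing
depth -- making the totals explicitly uninformative.

Generative steps for sample i:

1. z_i = base_log_abundance + dispersion * N(0, I_p)
2. logit_i = alpha* + sum_k beta*_k * R(exp(z_i); J+_k, J-_k)
3. y_i ~ Bernoulli(sigmoid(logit_i))
4. depth_i ~ Uniform{depth_min, ..., depth_max};
   counts_i ~ Multinomial(depth_i, softmax(z_i))
5. optional zero-inflation drops entries to 0 independently

Ground truth (planted partitions and coefficients) is kept alongside the
data so recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import expit, softmax

from .data import BalancePartition, CompositionMatrix
from .ratios import exact_ratio


class PlantedRatio(NamedTuple):
    """One planted signal: which log-ratio drives the outcome and how strongly."""

    partition: BalancePartition
    beta_star: float
    ratio_type: str = "balance"


def default_planted() -> list[PlantedRatio]:
    return [PlantedRatio(BalancePartition((0, 1), (2,)), 4.0, "balance")]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults: n=1000 samples, p=100 features, one planted balance
    {1,2}/{3} with slope beta*=4 and intercept alpha*=0, unit log-normal
    dispersion, sequencing depths uniform in [5000, 50000], no
    zero-inflation.
    """

    n: int = 1000
    p: int = 100
    planted: list[PlantedRatio] = field(default_factory=default_planted)
    alpha_star: float = 0.0
    base_log_abundance: np.ndarray | None = None
    dispersion: float = 1.0
    sequencing_depth_range: tuple[int, int] = (5000, 50000)
    zero_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 2:
            raise ValueError("need n >= 1 and p >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.sequencing_depth_range
        if lo < 1 or hi < lo:
            raise ValueError("sequencing_depth_range must be positive with min <= max")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")
        for planted in self.planted:
            planted.partition.require_valid()
            planted.partition.require_within(self.p)


@dataclass
class SimulatedDataset:
    counts: np.ndarray
    x: CompositionMatrix
    y: np.ndarray
    truth: SimulationConfig


def true_ratio_score(config: SimulationConfig, latent: np.ndarray) -> np.ndarray:
    """Logit of P(y=1) under the generative law, given latent abundances."""
    logits = np.full(latent.shape[0], float(config.alpha_star))
    for part, beta_star, ratio_type in config.planted:
        logits += beta_star * exact_ratio(latent, part, ratio_type)
    return logits


def simulate(config: SimulationConfig, pseudocount: float = 1.0) -> SimulatedDataset:
    """Draw one dataset; deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)
    base = (
        np.zeros(config.p)
        if config.base_log_abundance is None
        else np.asarray(config.base_log_abundance, dtype=float)
    )
    if base.shape != (config.p,):
        raise ValueError("base_log_abundance must have length p")

    z = base + config.dispersion * rng.standard_normal((config.n, config.p))
    logits = true_ratio_score(config, np.exp(z))
    y = (rng.random(config.n) < expit(logits)).astype(int)

    lo, hi = config.sequencing_depth_range
    depths = rng.integers(lo, hi, size=config.n, endpoint=True)
    probs = softmax(z, axis=1)
    counts = np.empty((config.n, config.p), dtype=np.int64)
    for i in range(config.n):
        counts[i] = rng.multinomial(depths[i], probs[i])
    if config.zero_inflation > 0:
        counts[rng.random(counts.shape) < config.zero_inflation] = 0

    x = apply_pseudocount(counts, pseudocount)
    return SimulatedDataset(counts=counts, x=x, y=y, truth=config)


def apply_pseudocount(counts, pseudocount: float,
                      feature_names: list[str] | None = None,
                      sample_ids: list[str] | None = None) -> CompositionMatrix:
    """Shift counts by a pseudocount and wrap as a CompositionMatrix.

    A pseudocount of 0 on an already strictly positive table is a
    passthrough; with zeros present the positivity check fails loudly.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    return CompositionMatrix(counts + pseudocount, feature_names, sample_ids)
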