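"""Synthetic multi-omics generator with known cluster and survival structure.

Emulates the statistical structure the downstream pipeline assumes: K latent
clusters, M omics blocks in which a fraction of features carry
cluster-specific mean shifts over Gaussian noise, and exponential survival
times whose scale differs by cluster (so the log-rank test has known power),
with uniform censoring. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ClinicalTable, OmicsBlock, OmicsDataset

__all__ = ["SimulationConfig", "simulate_multiomics"]

_DEFAULT_BLOCK_NAMES = ("cnv", "mrna", "mirna", "meth")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    cluster_separation is the magnitude of the per-cluster mean shift on
    each informative feature, in units of that block's noise SD = 1 scale;
    survival_scales are per-cluster exponential means (arbitrary time
    units, think months).
    """

    n_samples: int = 400
    n_clusters: int = 4
    block_widths: tuple[int, ...] = (200, 200, 50, 200)
    cluster_separation: float = 3.0
    informative_fraction: float | tuple[float, ...] = 0.2
    noise_sd: float | tuple[float, ...] = 1.0
    cluster_proportions: tuple[float, ...] | None = None
    survival_scales: tuple[float, ...] | None = None
    censor_rate: float = 0.2
    clinical_labels: bool = True
    seed: int = 2

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > self.n_samples:
            raise ValueError(f"K={self.n_clusters} exceeds n_samples={self.n_samples}")
        if any(w < 1 for w in self.block_widths):
            raise ValueError("all block widths must be >= 1")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, float)
            if len(p) != self.n_clusters or not np.isclose(p.sum(), 1.0):
                raise ValueError("cluster_proportions must have K entries summing to 1")
        if self.survival_scales is not None and len(self.survival_scales) != self.n_clusters:
            raise ValueError("survival_scales must have one entry per cluster")

    def per_block(self, value) -> np.ndarray:
        out = np.broadcast_to(np.asarray(value, float), (len(self.block_widths),))
        return out.copy()


def _cluster_means(rng: np.random.Generator, k: int, width: int, n_inform: int, sep: float) -> np.ndarray:
    """K x width mean matrix: informative columns get +/-sep shifts."""
    means = np.zeros((k, width))
    cols = rng.choice(width, size=n_inform, replace=False)
    signs = rng.choice([-1.0, 1.0], size=(k, n_inform))
    means[:, cols] = sep * signs
    return means


def simulate_multiomics(config: SimulationConfig) -> tuple[OmicsDataset, np.ndarray, ClinicalTable]:
    """Draw a seeded synthetic dataset.

    Returns the omics dataset, the true cluster assignment (0-based,
    length N), and a clinical table with cluster-linked survival and, when
    ``clinical_labels`` is on, one cluster-linked numeric covariate
    (``marker``), one cluster-linked categorical covariate (``grade``) and
    one independent categorical covariate (``batch``).
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_clusters

    props = (
        np.full(k, 1.0 / k)
        if config.cluster_proportions is None
        else np.asarray(config.cluster_proportions, float)
    )
    truth = rng.choice(k, size=n, p=props)

    inform = config.per_block(config.informative_fraction)
    noise = config.per_block(config.noise_sd)
    blocks = []
    for m, width in enumerate(config.block_widths):
        n_inform = int(round(inform[m] * width))
        means = _cluster_means(rng, k, width, n_inform, config.cluster_separation)
        values = means[truth] + rng.normal(0.0, noise[m], size=(n, width))
        name = _DEFAULT_BLOCK_NAMES[m] if m < len(_DEFAULT_BLOCK_NAMES) else f"omics{m + 1}"
        blocks.append(OmicsBlock(name, values, [f"{name}_f{j}" for j in range(width)]))

    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    dataset = OmicsDataset(blocks, sample_ids)

    scales = (
        np.geomspace(20.0, 80.0, k)
        if config.survival_scales is None
        else np.asarray(config.survival_scales, float)
    )
    t_true = rng.exponential(scales[truth])
    censored = rng.random(n) < config.censor_rate
    time = np.where(censored, rng.uniform(0.0, t_true), t_true)
    event = (~censored).astype(int)

    labels = pd.DataFrame()
    if config.clinical_labels:
        # grade follows the cluster with 15% label noise; batch is independent
        noisy = (truth + (rng.random(n) < 0.15).astype(int)) % k
        labels = pd.DataFrame(
            {
                "marker": 50.0 + 5.0 * truth + rng.normal(0.0, 2.0, n),
                "grade": [f"G{c + 1}" for c in noisy],
                "batch": rng.choice(["b1", "b2"], size=n),
            }
        )
    clinical = ClinicalTable(sample_ids, time, event, labels)
    return dataset, truth, clinical
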