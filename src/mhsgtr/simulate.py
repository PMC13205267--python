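"""Synthetic multi-omics benchmark data with planted cluster structure.

Emulates the kind of cohort the clustering pipeline targets: V views of
Gaussian features over a shared sample set in which a fraction of features
per view carries cluster-specific means, exponential survival times whose
hazard depends on the planted cluster, and clinical columns that are either
associated with the clusters (positive control) or independent of them
(negative control). Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, MultiOmicsDataset, OmicsMatrix, SurvivalTable

__all__ = ["SyntheticSpec", "generate_dataset", "generate_block_graph"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-cluster generator.

    ``separation`` is the between-cluster mean distance in units of the
    within-cluster standard deviation of an informative feature;
    ``informative_fraction`` is the per-view fraction of features carrying
    that signal. Survival times are exponential with per-cluster rates
    ``hazard_rates``; independent exponential censoring truncates a
    ``censor_rate`` fraction of follow-up in expectation.
    """

    n_samples: int = 150
    n_clusters: int = 3
    cluster_proportions: tuple[float, ...] | None = None
    view_dims: tuple[int, ...] = (200, 150, 100)
    separation: float = 3.0
    noise_sd: tuple[float, ...] | None = None
    informative_fraction: tuple[float, ...] | None = None
    hazard_rates: tuple[float, ...] | None = None
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        k = self.n_clusters
        if k < 2:
            raise ValueError("need at least 2 clusters")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / k] * k)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != k or np.any(props <= 0) or abs(props.sum() - 1) > 1e-8:
            raise ValueError("cluster_proportions must be a length-k simplex vector")
        if any(d <= 0 for d in self.view_dims):
            raise ValueError("view dimensions must be positive")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        V = len(self.view_dims)
        if self.noise_sd is None:
            self.noise_sd = tuple([1.0] * V)
        if self.informative_fraction is None:
            self.informative_fraction = tuple([0.3] * V)
        if self.hazard_rates is None:
            self.hazard_rates = tuple(1.0 * 0.5 ** j for j in range(k))
        if len(self.hazard_rates) != k or any(h <= 0 for h in self.hazard_rates):
            raise ValueError("hazard_rates must be k positive rates")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")


def generate_dataset(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, np.ndarray]:
    """Draw one multi-omics dataset; returns (dataset, true integer labels)."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_clusters
    labels = rng.choice(k, size=n, p=np.asarray(spec.cluster_proportions))
    sample_ids = [f"S{i:04d}" for i in range(n)]

    views: list[OmicsMatrix] = []
    for v, d in enumerate(spec.view_dims):
        sd = spec.noise_sd[v]
        n_info = int(round(spec.informative_fraction[v] * d))
        # cluster centroids: each informative feature carries cluster means
        # whose RMS pairwise difference equals separation * sd; the remaining
        # features are pure noise
        centers = np.zeros((k, d))
        if n_info > 0 and spec.separation > 0:
            raw = rng.standard_normal((k, n_info))
            raw -= raw.mean(axis=0)
            iu = np.triu_indices(k, 1)
            diff = raw[iu[0]] - raw[iu[1]]              # pairs x n_info
            rms = np.sqrt((diff ** 2).mean(axis=0))
            rms[rms == 0] = 1.0
            centers[:, :n_info] = raw * (spec.separation * sd / rms)
        X = centers[labels] + rng.standard_normal((n, d)) * sd
        views.append(OmicsMatrix(
            f"view{v + 1}", list(sample_ids),
            [f"v{v + 1}_f{j:04d}" for j in range(d)], X))

    rates = np.asarray(spec.hazard_rates)[labels]
    event_time = rng.exponential(1.0 / rates)
    if spec.censor_rate > 0:
        # censoring rate chosen so P(censor before event) ~= censor_rate
        c_rate = rates * spec.censor_rate / (1 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = SurvivalTable(list(sample_ids), time, event)

    # positive control: categorical column tilted by cluster; negative
    # control: independent uniform categorical
    levels = np.array(["A", "B", "C"])
    probs = np.full((k, 3), 0.15)
    for c in range(k):
        probs[c, c % 3] = 0.7
    assoc = np.array([rng.choice(levels, p=probs[c]) for c in labels])
    indep = rng.choice(levels, size=n)
    age = rng.normal(60, 10, size=n) + 5.0 * labels  # numeric, cluster-shifted
    cols = pd.DataFrame({"assoc_label": assoc, "indep_label": indep,
                         "age": age}, index=sample_ids)
    clinical = ClinicalTable(list(sample_ids), cols,
                             {"assoc_label": "categorical",
                              "indep_label": "categorical",
                              "age": "numeric"})
    return MultiOmicsDataset(views, survival, clinical), labels.astype(int)


def generate_block_graph(n_per_block: int, n_blocks: int, p_in: float,
                         p_out: float, seed: int = 0) -> np.ndarray:
    """Symmetric zero-diagonal stochastic-block-model adjacency matrix."""
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("require 0 <= p_out <= p_in <= 1")
    n = n_per_block * n_blocks
    rng = np.random.default_rng(seed)
    block = np.repeat(np.arange(n_blocks), n_per_block)
    p = np.where(block[:, None] == block[None, :], p_in, p_out)
    u = rng.random((n, n))
    upper = np.triu(u < p, k=1)
    adj = (upper | upper.T).astype(np.int64)
    return adj
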