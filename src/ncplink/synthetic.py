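"""Synthetic bipartite association networks with planted cluster signal.

The generator emulates the regime of the curated microbe-disease benchmark:
a sparse binary network of ~292 microbes by ~39 diseases with ~450
associations, an average disease degree near 11.5 and an average microbe
degree near 1.5 (diseases are the heavy-tailed side).  Microbes and diseases
are assigned uniformly to clusters; cells whose microbe cluster corresponds
to their disease cluster are sampled with an elevated probability, which
gives link prediction a recoverable signal.  Per-disease popularity weights
follow a Zipf-like law so the disease degree distribution is heavy-tailed.

The defaults below ARE the study conditions of this package's tests and
acceptance runs; they are fixed, not tuning knobs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import AssociationDataset
from .exceptions import ParameterError

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "planted_truth",
    "expected_density",
    "cluster_labels",
    "fixed_count_dataset",
]

logger = logging.getLogger(__name__)

_MAX_RESAMPLE = 32


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-cluster bipartite generator.

    Defaults give an expected density of about 0.0394 (~448 expected
    associations on the 292 x 39 grid, matching the benchmark's 450) with a
    4-cluster planted structure and Zipf skew 0.7 on disease popularity.
    """

    n_microbes: int = 292
    n_diseases: int = 39
    n_microbe_clusters: int = 4
    n_disease_clusters: int = 4
    intra_cluster_prob: float = 0.12
    inter_cluster_prob: float = 0.0125
    degree_skew: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_microbes, self.n_diseases) < 1:
            raise ParameterError("need at least one microbe and one disease")
        if not (1 <= self.n_microbe_clusters <= self.n_microbes):
            raise ParameterError("invalid n_microbe_clusters")
        if not (1 <= self.n_disease_clusters <= self.n_diseases):
            raise ParameterError("invalid n_disease_clusters")
        for name, p in (
            ("intra_cluster_prob", self.intra_cluster_prob),
            ("inter_cluster_prob", self.inter_cluster_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        if self.intra_cluster_prob < self.inter_cluster_prob:
            raise ParameterError(
                "intra_cluster_prob must be >= inter_cluster_prob "
                "(equality gives the signal-free null model)"
            )
        if self.degree_skew < 0:
            raise ParameterError("degree_skew must be nonnegative (0 = uniform popularity)")


def _zipf_weights(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-disease popularity weights: Zipf-like, mean 1, randomly assigned."""
    ranks = np.arange(1, cfg.n_diseases + 1, dtype=float)
    w = ranks ** (-cfg.degree_skew)
    w /= w.mean()
    return w[rng.permutation(cfg.n_diseases)]


def _draw_structure(cfg: SyntheticConfig, rng: np.random.Generator):
    """Cluster labels and popularity weights, in a fixed draw order."""
    m_labels = rng.integers(0, cfg.n_microbe_clusters, size=cfg.n_microbes)
    d_labels = rng.integers(0, cfg.n_disease_clusters, size=cfg.n_diseases)
    weights = _zipf_weights(cfg, rng)
    return m_labels, d_labels, weights


def _cell_probabilities(cfg: SyntheticConfig, m_labels, d_labels, weights) -> np.ndarray:
    # cluster correspondence: microbe cluster c maps to disease cluster c mod K_d
    match = (m_labels[:, None] % cfg.n_disease_clusters) == d_labels[None, :]
    base = np.where(match, cfg.intra_cluster_prob, cfg.inter_cluster_prob)
    probs = base * weights[None, :]
    if probs.max() > 1.0:
        raise ParameterError(
            "popularity weighting pushes a cell probability above 1; "
            "reduce intra_cluster_prob or degree_skew"
        )
    return probs


def cluster_labels(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Replay the generator's cluster assignment for ``cfg`` (same seed)."""
    m_labels, d_labels, _ = _draw_structure(cfg, np.random.default_rng(cfg.seed))
    return m_labels, d_labels


def expected_density(cfg: SyntheticConfig) -> float:
    """Closed-form expected edge density over random cluster assignments.

    Each microbe cluster corresponds to exactly one disease cluster, so a
    uniformly assigned pair matches with probability 1/n_disease_clusters;
    popularity weights have mean 1 and preserve the mixture.
    """
    f_intra = 1.0 / cfg.n_disease_clusters
    return f_intra * cfg.intra_cluster_prob + (1.0 - f_intra) * cfg.inter_cluster_prob


def _entity_names(cfg: SyntheticConfig) -> tuple[tuple[str, ...], tuple[str, ...]]:
    wm = len(str(cfg.n_microbes))
    wd = len(str(cfg.n_diseases))
    return (
        tuple(f"microbe_{i + 1:0{wm}d}" for i in range(cfg.n_microbes)),
        tuple(f"disease_{j + 1:0{wd}d}" for j in range(cfg.n_diseases)),
    )


def generate_dataset(cfg: SyntheticConfig) -> AssociationDataset:
    """Sample a planted-cluster bipartite network. Same seed, same dataset.

    Isolated entities (zero profiles) are retained.  If a draw produces no
    association at all, the draw is retried with an incremented seed offset
    (logged); the structure (labels, weights) stays that of ``cfg.seed``.
    """
    m_labels, d_labels, weights = _draw_structure(cfg, np.random.default_rng(cfg.seed))
    probs = _cell_probabilities(cfg, m_labels, d_labels, weights)
    for offset in range(_MAX_RESAMPLE):
        rng = np.random.default_rng(cfg.seed + offset)
        # burn the structure draws so edge randomness differs per offset
        _draw_structure(cfg, rng)
        md = (rng.random(probs.shape) < probs).astype(np.int8)
        if md.any():
            if offset:
                logger.warning("empty draw; resampled with seed offset %d", offset)
            names_m, names_d = _entity_names(cfg)
            return AssociationDataset(names_m, names_d, md)
    raise ParameterError("could not sample a non-empty network; probabilities too small")


def planted_truth(cfg: SyntheticConfig, ds: AssociationDataset) -> frozenset[tuple[str, str]]:
    """Name pairs of all cells generated with the intra-cluster probability.

    Used to check that projection scoring ranks held-out intra-cluster pairs
    above inter-cluster ones.
    """
    if (len(ds.microbe_names), len(ds.disease_names)) != (cfg.n_microbes, cfg.n_diseases):
        raise ParameterError("dataset shape does not match the config")
    m_labels, d_labels = cluster_labels(cfg)
    match = (m_labels[:, None] % cfg.n_disease_clusters) == d_labels[None, :]
    rows, cols = np.nonzero(match)
    return frozenset(
        (ds.microbe_names[i], ds.disease_names[j]) for i, j in zip(rows, cols)
    )


def fixed_count_dataset(
    n_microbes: int, n_diseases: int, n_associations: int, seed: int = 0
) -> AssociationDataset:
    """A network with an exact association count, pairs uniform at random.

    Useful for degree bookkeeping on a benchmark-shaped grid (e.g. exactly
    450 associations among 292 microbes and 39 diseases) and as a
    structure-free null.
    """
    n_cells = n_microbes * n_diseases
    if not 1 <= n_associations <= n_cells:
        raise ParameterError("n_associations must lie in [1, n_microbes * n_diseases]")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_associations, replace=False)
    md = np.zeros(n_cells, dtype=np.int8)
    md[flat] = 1
    cfg_names = SyntheticConfig(n_microbes=n_microbes, n_diseases=n_diseases,
                                n_microbe_clusters=1, n_disease_clusters=1)
    names_m, names_d = _entity_names(cfg_names)
    return AssociationDataset(names_m, names_d, md.reshape(n_microbes, n_diseases))
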