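"""Scikit-learn style estimator wrapping the full scoring pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import AssociationDataset
from .exceptions import ParameterError
from .fusion import DEFAULT_ALPHA, DEFAULT_BETA, FusionWeights, linear_fuse
from .ncp import (
    ScoreMatrix,
    combine_projections,
    disease_space_projection,
    microbe_space_projection,
)
from .ncp import rank_candidates as _rank_candidates
from .similarity import build_entity_similarities

__all__ = ["NetworkConsistencyProjection"]

_SIM_CHOICES = ("fused", "gip", "cosine")


class NetworkConsistencyProjection(BaseEstimator):
    """Bipartite link predictor: similarity fusion + network consistency projection.

    Fits on a binary microbe-disease association matrix (rows = microbes,
    columns = diseases).  Fitting builds GIP-kernel and cosine similarity
    matrices for each side from the interaction profiles, fuses each pair by
    a convex combination (``alpha`` on the disease side, ``beta`` on the
    microbe side), and scores every cell by network consistency projection.
    The estimator is transductive: scores are produced for the matrix it was
    fitted on.

    Parameters
    ----------
    alpha : float, default 0.3
        Disease-side weight on the GIP kernel, in (0, 1).
    beta : float, default 0.6
        Microbe-side weight on the GIP kernel, in (0, 1).
    lambda_prime : float, default 1.0
        Raw GIP bandwidth, normalised per side by the mean squared profile
        norm of the fitted matrix.
    microbe_similarity, disease_similarity : {"fused", "gip", "cosine"}
        Which similarity feeds the projection.  Single-similarity choices
        bypass fusion entirely (used by the ablation driver).
    norm : {"l2", "l1"}, default "l2"
        Vector norm used in the projection formulas.

    Attributes
    ----------
    dataset_ : AssociationDataset
        The fitted network (names synthesised if a bare array was passed).
    microbe_similarity_, disease_similarity_ : SimilarityMatrix
        The similarity matrices actually projected.
    score_matrix_ : ScoreMatrix
        Labelled scores for every pair.
    scores_ : ndarray of shape (n_microbes, n_diseases)
        The raw score array.

    Examples
    --------
    >>> import numpy as np
    >>> md = np.array([[1, 0], [0, 1]])
    >>> est = NetworkConsistencyProjection().fit(md)
    >>> est.scores_.shape
    (2, 2)
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        beta: float = DEFAULT_BETA,
        lambda_prime: float = 1.0,
        microbe_similarity: str = "fused",
        disease_similarity: str = "fused",
        norm: str = "l2",
    ):
        self.alpha = alpha
        self.beta = beta
        self.lambda_prime = lambda_prime
        self.microbe_similarity = microbe_similarity
        self.disease_similarity = disease_similarity
        self.norm = norm

    def _validate(self) -> None:
        FusionWeights(self.alpha, self.beta)  # range check
        if self.lambda_prime <= 0:
            raise ParameterError(f"lambda_prime must be positive, got {self.lambda_prime}")
        for name, choice in (
            ("microbe_similarity", self.microbe_similarity),
            ("disease_similarity", self.disease_similarity),
        ):
            if choice not in _SIM_CHOICES:
                raise ParameterError(f"{name} must be one of {_SIM_CHOICES}, got {choice!r}")

    @staticmethod
    def _as_dataset(X) -> AssociationDataset:
        if isinstance(X, AssociationDataset):
            return X
        md = np.asarray(X)
        if md.ndim != 2:
            raise ParameterError("X must be a 2-D binary association matrix")
        names_m = tuple(f"m{i}" for i in range(md.shape[0]))
        names_d = tuple(f"d{j}" for j in range(md.shape[1]))
        return AssociationDataset(names_m, names_d, md)

    def fit(self, X, y=None) -> "NetworkConsistencyProjection":
        """Build similarities from X and score every microbe-disease pair."""
        self._validate()
        ds = self._as_dataset(X)
        if ds.n_associations < 1:
            raise ParameterError("fit requires at least one known association")

        m_gip, m_cos = build_entity_similarities(ds, "microbe", self.lambda_prime)
        d_gip, d_cos = build_entity_similarities(ds, "disease", self.lambda_prime)

        pick = {"gip": lambda g, c, w: g, "cosine": lambda g, c, w: c,
                "fused": linear_fuse}
        MS = pick[self.microbe_similarity](m_gip, m_cos, self.beta)
        DS = pick[self.disease_similarity](d_gip, d_cos, self.alpha)

        ncpd = disease_space_projection(ds.MD, DS, norm=self.norm)
        ncpm = microbe_space_projection(ds.MD, MS, norm=self.norm)
        sm = combine_projections(
            ncpd, ncpm, DS, MS, norm=self.norm,
            params={"alpha": self.alpha, "beta": self.beta,
                    "lambda_prime": self.lambda_prime},
        )

        self.dataset_ = ds
        self.microbe_gip_, self.microbe_cosine_ = m_gip, m_cos
        self.disease_gip_, self.disease_cosine_ = d_gip, d_cos
        self.microbe_similarity_, self.disease_similarity_ = MS, DS
        self.score_matrix_ = sm
        self.scores_ = sm.scores
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit on X and return the score array."""
        return self.fit(X).scores_

    def predict(self, X=None) -> np.ndarray:
        """Return the fitted score array (transductive; X is ignored)."""
        if not hasattr(self, "scores_"):
            raise ParameterError("estimator is not fitted")
        return self.scores_

    def rank_candidates(self, disease: str, top_k: int = 10) -> list[tuple[str, float]]:
        """Top novel candidate microbes for one disease by descending score."""
        if not hasattr(self, "scores_"):
            raise ParameterError("estimator is not fitted")
        return _rank_candidates(self.score_matrix_, self.dataset_, disease, top_k)
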