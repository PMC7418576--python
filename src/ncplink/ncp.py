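"""Network consistency projection (NCP) scoring.

The association matrix MD is projected onto the disease similarity space and
onto the microbe similarity space, and the two projections are summed and
normalised by the similarity-vector norms:

    NCPD(i, j) = MD(i, :) . DS(:, j) / |MD(i, :)|
    NCPM(i, j) = MS(i, :) . MD(:, j) / |MD(:, j)|
    NCP(i, j)  = (NCPD(i, j) + NCPM(i, j)) / (|DS(:, j)| + |MS(i, :)|)

``|.|`` is the Euclidean norm (an L1 policy is provided for sensitivity
analysis), and 0/0 := 0 throughout: a microbe whose row is all zero — as
happens when leave-one-out masking removes a degree-1 microbe's only
association — still receives a finite score driven by the other space.

Scores are not probabilities: they are nonnegative, can exceed 1, and are
used purely for ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import AssociationDataset
from .exceptions import IncompatibilityError, ParameterError
from .fusion import FusionWeights
from .similarity import SimilarityMatrix

__all__ = [
    "ScoreMatrix",
    "disease_space_projection",
    "microbe_space_projection",
    "combine_projections",
    "predict",
    "rank_candidates",
]


def _vector_norms(m: np.ndarray, axis: int, norm: str = "l2") -> np.ndarray:
    if norm == "l2":
        return np.sqrt(np.sum(np.asarray(m, dtype=float) ** 2, axis=axis))
    if norm == "l1":
        return np.sum(np.abs(np.asarray(m, dtype=float)), axis=axis)
    raise ParameterError(f"norm must be 'l2' or 'l1', got {norm!r}")


def _safe_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


@dataclass(frozen=True)
class ScoreMatrix:
    """NCP association scores for every microbe-disease pair.

    Known associations keep their computed scores; they are excluded only
    when ranking novel candidates (:func:`rank_candidates`).
    """

    microbe_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    scores: np.ndarray = field(repr=False)
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "microbe_names", tuple(self.microbe_names))
        object.__setattr__(self, "disease_names", tuple(self.disease_names))
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.microbe_names), len(self.disease_names)):
            raise IncompatibilityError(
                f"scores shape {s.shape} does not match the name lists"
            )
        if not np.isfinite(s).all() or (s.size and s.min() < 0):
            raise IncompatibilityError("scores must be finite and nonnegative")
        s = s.copy()
        s.setflags(write=False)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "params", dict(self.params))

    def to_tsv(self, path) -> None:
        """Labelled TSV, diseases as columns, full precision."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(("",) + self.disease_names) + "\n")
            for name, row in zip(self.microbe_names, self.scores):
                fh.write(name + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def disease_space_projection(
    MD: np.ndarray, DS: SimilarityMatrix, norm: str = "l2"
) -> np.ndarray:
    """Project MD rows onto the disease similarity space.

    Entry (i, j) is ``MD(i,:) . DS(:,j) / |MD(i,:)|``; all-zero rows give 0.
    """
    md = np.asarray(MD, dtype=float)
    if DS.role != "disease" or DS.n != md.shape[1]:
        raise IncompatibilityError("DS must be a disease-role matrix matching MD columns")
    num = md @ DS.values
    row_norms = _vector_norms(md, axis=1, norm=norm)
    return _safe_divide(num, row_norms[:, None])


def microbe_space_projection(
    MD: np.ndarray, MS: SimilarityMatrix, norm: str = "l2"
) -> np.ndarray:
    """Project MD columns onto the microbe similarity space.

    Entry (i, j) is ``MS(i,:) . MD(:,j) / |MD(:,j)|``; all-zero columns give 0.
    """
    md = np.asarray(MD, dtype=float)
    if MS.role != "microbe" or MS.n != md.shape[0]:
        raise IncompatibilityError("MS must be a microbe-role matrix matching MD rows")
    num = MS.values @ md
    col_norms = _vector_norms(md, axis=0, norm=norm)
    return _safe_divide(num, col_norms[None, :])


def combine_projections(
    NCPD: np.ndarray,
    NCPM: np.ndarray,
    DS: SimilarityMatrix,
    MS: SimilarityMatrix,
    *,
    norm: str = "l2",
    params: Mapping[str, float] | None = None,
) -> ScoreMatrix:
    """Sum the two projections and normalise by the similarity-vector norms."""
    ncpd = np.asarray(NCPD, dtype=float)
    ncpm = np.asarray(NCPM, dtype=float)
    shape = (MS.n, DS.n)
    if ncpd.shape != shape or ncpm.shape != shape:
        raise IncompatibilityError(
            f"projection shapes {ncpd.shape}, {ncpm.shape} do not match ({MS.n}, {DS.n})"
        )
    ds_col_norms = _vector_norms(DS.values, axis=0, norm=norm)
    ms_row_norms = _vector_norms(MS.values, axis=1, norm=norm)
    den = ms_row_norms[:, None] + ds_col_norms[None, :]
    scores = _safe_divide(ncpd + ncpm, den)
    return ScoreMatrix(
        MS.entity_names, DS.entity_names, np.maximum(scores, 0.0), params=params or {}
    )


def predict(
    ds: AssociationDataset,
    weights: FusionWeights | None = None,
    lambda_prime: float = 1.0,
    *,
    microbe_similarity: str = "fused",
    disease_similarity: str = "fused",
    norm: str = "l2",
) -> ScoreMatrix:
    """Run the full pipeline: similarities -> linear fusion -> NCP scores.

    Thin functional wrapper over
    :class:`~ncplink.estimator.NetworkConsistencyProjection`.
    """
    from .estimator import NetworkConsistencyProjection

    weights = weights or FusionWeights()
    est = NetworkConsistencyProjection(
        alpha=weights.alpha,
        beta=weights.beta,
        lambda_prime=lambda_prime,
        microbe_similarity=microbe_similarity,
        disease_similarity=disease_similarity,
        norm=norm,
    )
    return est.fit(ds).score_matrix_


def rank_candidates(
    scores: ScoreMatrix,
    ds: AssociationDataset,
    disease: str,
    top_k: int = 10,
) -> list[tuple[str, float]]:
    """Top candidate microbes for one disease, known associations excluded.

    Sorted by descending score; ties broken by ascending microbe index.
    ``top_k`` larger than the candidate pool returns the full list.
    """
    if scores.microbe_names != ds.microbe_names or scores.disease_names != ds.disease_names:
        raise IncompatibilityError("score matrix does not match the dataset labels")
    j = ds.disease_index(disease)
    col = scores.scores[:, j]
    candidates = np.nonzero(ds.MD[:, j] == 0)[0]
    order = candidates[np.lexsort((candidates, -col[candidates]))]
    return [(ds.microbe_names[i], float(col[i])) for i in order[:top_k]]
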