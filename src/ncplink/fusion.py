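"""Linear network fusion of similarity matrices.

One entity role, two similarity views (GIP kernel and cosine), combined by
an elementwise convex combination:

    fused = w * gip + (1 - w) * cosine,      0 < w < 1

with weight ``alpha`` on the disease side and ``beta`` on the microbe side.
Endpoint weights 0 and 1 are rejected; single-similarity ablation runs pass
one matrix straight through instead of abusing a degenerate weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import IncompatibilityError, ParameterError
from .similarity import SimilarityMatrix

__all__ = ["FusionWeights", "linear_fuse"]

DEFAULT_ALPHA = 0.3
DEFAULT_BETA = 0.6


@dataclass(frozen=True)
class FusionWeights:
    """Convex-combination weights: ``alpha`` (diseases), ``beta`` (microbes).

    Defaults are the grid-search optimum on the benchmark network
    (alpha=0.3, beta=0.6); both must lie strictly inside (0, 1).
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        for name, w in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 < w < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1), got {w}")


def linear_fuse(
    gip: SimilarityMatrix, cosine: SimilarityMatrix, weight: float
) -> SimilarityMatrix:
    """Elementwise convex combination ``weight * gip + (1 - weight) * cosine``."""
    if not 0.0 < weight < 1.0:
        raise ParameterError(f"fusion weight must lie in (0, 1), got {weight}")
    if not gip.compatible_with(cosine):
        raise IncompatibilityError(
            "cannot fuse similarity matrices with different entity names or roles"
        )
    values = weight * gip.values + (1.0 - weight) * cosine.values
    return SimilarityMatrix(gip.entity_names, values, role=gip.role, method="fused")
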