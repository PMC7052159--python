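"""Multiplicative alpha/beta/gamma partitioning of dietary diversity.

A species' diet is treated as a system of N equally weighted subsystems (the
individuals).  Gamma diversity is the Hill number of the pooled (equal-weight
mean) profile; alpha is the corresponding within-subsystem effective number;
beta = gamma / alpha measures how many effectively distinct individual diets
the species contains (1 <= beta <= N).  The Jaccard-type turnover

    turnover = (1 - 1/beta) / (1 - 1/N)

normalises beta to [0, 1]: 0 when all individuals share one diet, 1 when
their diets are completely distinct.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .hill import DietProfile, hill_number

__all__ = [
    "PartitionResult",
    "partition",
    "jaccard_turnover",
    "alpha_diversity_per_species",
]


@dataclasses.dataclass
class PartitionResult:
    q: float
    n: int
    alpha: float
    gamma: float
    beta: float
    turnover: float | None = None
    species: str | None = None


def _profile_matrix(profiles: Sequence[DietProfile]) -> np.ndarray:
    """Align profiles on the union OTU set; rows are subsystems, rows sum to 1."""
    mat = pd.concat([pr.values for pr in profiles], axis=1).fillna(0.0)
    return mat.to_numpy(dtype=float).T


def _alpha(mat: np.ndarray, q: float) -> float:
    """Equal-weight Hill alpha of order q for row-normalised matrix ``mat``."""
    n = mat.shape[0]
    if q == 1:
        entropies = [
            -np.sum(row[row > 0] * np.log(row[row > 0])) for row in mat
        ]
        return float(math.exp(np.mean(entropies)))
    scaled = mat / n
    pos = scaled[scaled > 0]
    if q == 0:
        return float(pos.size) / n
    return float(np.sum(pos**q) ** (1.0 / (1.0 - q)) / n)


def partition(profiles: Sequence[DietProfile], q: float = 1.0) -> PartitionResult:
    """Partition gamma diversity into alpha and beta at order ``q``.

    Subsystems are weighted equally (w_j = 1/N); profiles over different OTU
    sets are aligned by union with zeros.
    """
    if q < 0:
        raise ValueError(f"order of diversity q must be >= 0 (got {q})")
    n = len(profiles)
    if n < 2:
        raise ValueError(f"partitioning needs at least 2 subsystems (got {n})")
    mat = _profile_matrix(profiles)
    gamma = hill_number(mat.mean(axis=0), q)
    alpha = _alpha(mat, q)
    beta = gamma / alpha
    result = PartitionResult(
        q=q,
        n=n,
        alpha=alpha,
        gamma=gamma,
        beta=beta,
        species=profiles[0].species,
    )
    result.turnover = jaccard_turnover(result)
    return result


def jaccard_turnover(result: PartitionResult) -> float:
    """Normalised prey turnover across subsystems: (1 - 1/beta) / (1 - 1/N)."""
    if result.n < 2:
        raise ValueError("turnover is undefined for a single subsystem")
    value = (1.0 - 1.0 / result.beta) / (1.0 - 1.0 / result.n)
    # beta can stray past its [1, N] bounds by floating-point rounding only
    return float(min(max(value, 0.0), 1.0))


def alpha_diversity_per_species(
    profiles: Sequence[DietProfile], q: float = 1.0
) -> float:
    """The alpha component alone ("individual niche breadth" of a species)."""
    if len(profiles) == 1:
        return hill_number(profiles[0], q)
    return _alpha(_profile_matrix(profiles), q)
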