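"""Neutral and phylogenetic Hill numbers and dietary niche-breadth metrics.

Hill numbers express diversity as an *effective number* of equally abundant
types.  For a relative-abundance vector ``p`` and order of diversity ``q``:

    qD = (sum_i p_i^q)^(1/(1-q))        for q != 1
    1D = exp(-sum_i p_i ln p_i)          (continuous limit at q = 1)

``q`` tunes the weight of rare versus abundant types: q=0 is richness, q=1 the
exponential of Shannon entropy, q=2 the inverse Simpson concentration.

The phylogenetic variant replaces types by branches of a rooted ultrametric or
non-ultrametric tree pruned to the profile support.  With branch lengths
``L_b``, branch abundances ``a_b`` (total relative abundance of the leaves
descending from branch ``b``) and mean depth ``T = sum_b L_b a_b``:

    qPD = [sum_b (L_b / T) a_b^q]^(1/(1-q))     for q != 1
    1PD = exp(-sum_b (L_b / T) a_b ln a_b)

which is the mean-phylogenetic-diversity ("effective number of equally
abundant, equally distinct lineages") formulation.

Dietary niche-breadth metrics built on these:

* ``dR``   — richness: neutral Hill number, q = 0
* ``dRE``  — richness + evenness: neutral Hill number, q = 1
* ``dRER`` — richness + evenness + regularity: phylogenetic Hill number, q = 1,
  evaluated over a set of posterior tree draws to propagate phylogenetic
  uncertainty (mean and standard error across draws are reported)
* ``levins`` — Levins' niche breadth, 1 / sum p_i^2, identical to q = 2
* ``trait_breadth`` — exp(Shannon) over behavioural trait categories
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DietProfile",
    "BreadthEstimate",
    "hill_number",
    "phylo_hill_number",
    "evenness_factor",
    "levins_index",
    "trait_breadth",
    "species_profile",
    "dietary_breadth",
]

_TOL = 1e-9


@dataclasses.dataclass
class DietProfile:
    """A relative-abundance (or relative-incidence) vector over OTUs.

    ``values`` is a pandas Series indexed by OTU id, non-negative, summing to
    one.  ``mode`` records whether the profile came from read abundances or
    presence/absence; ``level`` whether it describes one individual or a
    pooled species.  ``depth`` optionally carries the read total the profile
    was derived from (used for read-weighted species pooling).
    """

    values: pd.Series
    mode: str = "abundance"
    level: str = "individual"
    id: str | None = None
    species: str | None = None
    depth: float | None = None

    def __post_init__(self) -> None:
        v = pd.Series(self.values, dtype=float)
        if len(v) == 0 or not (v > 0).any():
            raise ValueError("diet profile must contain at least one positive entry")
        if (v < 0).any():
            raise ValueError("diet profile entries must be non-negative")
        if abs(float(v.sum()) - 1.0) > _TOL:
            raise ValueError(f"diet profile must sum to 1 (got {v.sum():.12g})")
        if self.mode not in ("abundance", "incidence"):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        self.values = v

    @classmethod
    def from_counts(
        cls,
        counts: pd.Series,
        mode: str = "abundance",
        **kwargs,
    ) -> "DietProfile":
        """Build a profile from raw non-negative counts.

        Abundance mode normalises the counts; incidence mode normalises the
        presence/absence indicator so the profile stays a valid ``p`` vector.
        """
        c = pd.Series(counts, dtype=float)
        c = c[c > 0]
        if c.empty:
            raise ValueError("cannot build a profile from an all-zero count vector")
        depth = float(c.sum())
        if mode == "incidence":
            v = pd.Series(1.0 / len(c), index=c.index)
        else:
            v = c / depth
        return cls(values=v, mode=mode, depth=depth, **kwargs)

    @property
    def support(self) -> pd.Index:
        return self.values.index[self.values > 0]


@dataclasses.dataclass
class BreadthEstimate:
    """A dietary niche-breadth estimate with tree-draw dispersion.

    ``se`` is the standard error across posterior tree draws (sample standard
    deviation / sqrt(n_draws)); it is 0 for tree-free metrics.  ``draws``
    keeps the per-tree values so downstream mixed models can use every draw.
    """

    metric: str
    mean: float
    se: float = 0.0
    n_draws: int = 1
    draws: np.ndarray | None = None
    species: str | None = None
    mode: str = "abundance"


def _as_prob(p) -> np.ndarray:
    """Coerce to a normalised positive probability vector, dropping zeros."""
    if isinstance(p, DietProfile):
        arr = p.values.to_numpy(dtype=float)
    else:
        arr = np.asarray(pd.Series(p).to_numpy(), dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("abundances must be finite and non-negative")
    arr = arr[arr > 0]
    total = arr.sum()
    if total <= 0:
        raise ValueError("abundance vector has no positive entries")
    return arr / total


def hill_number(p, q: float) -> float:
    """Effective number of OTUs of order ``q`` for profile ``p``.

    ``p`` may be a :class:`DietProfile`, a Series, or any abundance vector
    (counts are normalised).  Zero-abundance entries are ignored.
    """
    if q < 0:
        raise ValueError(f"order of diversity q must be >= 0 (got {q})")
    pr = _as_prob(p)
    if q == 1:
        return float(math.exp(-np.sum(pr * np.log(pr))))
    if q == 0:
        return float(pr.size)
    return float(np.sum(pr**q) ** (1.0 / (1.0 - q)))


def evenness_factor(p) -> float:
    """Hill-evenness: qD(1)/qD(0); 1 iff ``p`` is uniform on its support."""
    return hill_number(p, 1) / hill_number(p, 0)


def levins_index(p) -> float:
    """Levins' niche breadth 1 / sum p_i^2 (identical to the q = 2 Hill number)."""
    pr = _as_prob(p)
    return float(1.0 / np.sum(pr**2))


def trait_breadth(trait_profile) -> float:
    """Breadth of a behavioural niche axis: exp(Shannon) over category use."""
    return hill_number(trait_profile, 1)


# ---------------------------------------------------------------------------
# phylogenetic Hill numbers
# ---------------------------------------------------------------------------


def _profile_weights(p) -> dict[str, float]:
    if isinstance(p, DietProfile):
        s = p.values
    else:
        s = pd.Series(p, dtype=float)
    s = s[s > 0]
    if s.empty:
        raise ValueError("profile has no positive entries")
    return {str(k): float(v) for k, v in s.items()}


def _branch_terms(
    tree: dendropy.Tree, weights: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and abundances of the tree pruned to the profile support.

    Implemented without mutating the tree: a postorder pass accumulates the
    per-edge descendant abundance ``a``; edges with 0 < a < total are exactly
    the edges of the induced subtree rooted at the MRCA of the support
    (ancestors of the MRCA carry a == total, off-support edges a == 0), and
    degree-2 merges created by pruning are immaterial because every retained
    quantity is linear in branch length.
    """
    leaf_labels = {t.label for t in tree.taxon_namespace}
    missing = sorted(set(weights) - leaf_labels)
    if missing:
        raise ValueError(f"profile OTUs missing from tree leaves: {missing}")
    total = sum(weights.values())
    acc: dict[int, float] = {}
    lengths: list[float] = []
    abunds: list[float] = []
    eps = 1e-12 * total
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            a = weights.get(node.taxon.label if node.taxon else None, 0.0)
        else:
            a = sum(acc.pop(id(ch)) for ch in node.child_nodes())
        acc[id(node)] = a
        length = node.edge.length
        if length is not None and length > 0 and eps < a < total - eps:
            lengths.append(float(length))
            abunds.append(a / total)
    return np.asarray(lengths), np.asarray(abunds)


def phylo_hill_number(p, tree: dendropy.Tree, q: float) -> float:
    """Effective number of equally distinct lineages of order ``q``.

    The tree is (conceptually) pruned to the support of ``p`` before the mean
    depth T is computed, so the result describes the consumed assemblage
    rather than the reference tree.  Branch-length rescaling leaves the value
    unchanged (T normalisation).
    """
    if q < 0:
        raise ValueError(f"order of diversity q must be >= 0 (got {q})")
    weights = _profile_weights(p)
    if len(weights) == 1:
        # a single lineage: pruning leaves a point tree; one effective lineage
        if next(iter(weights)) not in {t.label for t in tree.taxon_namespace}:
            raise ValueError(
                f"profile OTUs missing from tree leaves: {sorted(weights)}"
            )
        return 1.0
    lengths, abunds = _branch_terms(tree, weights)
    tbar = float(np.sum(lengths * abunds))
    if tbar <= 0:
        raise ValueError("degenerate tree: mean depth T is zero after pruning")
    w = lengths / tbar
    if q == 1:
        return float(math.exp(-np.sum(w * abunds * np.log(abunds))))
    return float(np.sum(w * abunds**q) ** (1.0 / (1.0 - q)))


# ---------------------------------------------------------------------------
# species-level pooling and breadth metrics
# ---------------------------------------------------------------------------


def species_profile(
    profiles: Sequence[DietProfile], pool: str = "mean"
) -> DietProfile:
    """Pool individual profiles into one species-level profile.

    ``pool='mean'`` (default) averages the individual relative-abundance
    vectors with equal weight, which removes sequencing-depth differences
    between individuals; ``pool='reads'`` weights each individual by its read
    depth, equivalent to summing raw counts.
    """
    if not profiles:
        raise ValueError("need at least one individual profile")
    mode = profiles[0].mode
    mat = pd.concat([pr.values for pr in profiles], axis=1).fillna(0.0)
    if pool == "mean":
        pooled = mat.mean(axis=1)
    elif pool == "reads":
        depths = np.array([pr.depth for pr in profiles], dtype=float)
        if np.any(~np.isfinite(depths)) or np.any(depths <= 0):
            raise ValueError("pool='reads' requires positive depths on every profile")
        pooled = (mat * depths).sum(axis=1) / depths.sum()
    else:
        raise ValueError(f"unknown pooling rule {pool!r}")
    pooled = pooled / pooled.sum()
    return DietProfile(
        values=pooled[pooled > 0],
        mode=mode,
        level="species",
        species=profiles[0].species,
    )


def dietary_breadth(
    profiles: Sequence[DietProfile],
    metric: str,
    trees: Sequence[dendropy.Tree] | None = None,
    pool: str = "mean",
) -> BreadthEstimate:
    """Species-level dietary niche breadth (dR, dRE, dRER or levins).

    dRER is evaluated once per tree in ``trees`` and summarised by its mean
    and standard error across draws, propagating phylogenetic uncertainty.
    """
    pooled = species_profile(profiles, pool=pool)
    if metric == "dR":
        value = hill_number(pooled, 0)
    elif metric == "dRE":
        value = hill_number(pooled, 1)
    elif metric == "levins":
        value = levins_index(pooled)
    elif metric == "dRER":
        if not trees:
            raise ValueError("metric 'dRER' requires a tree set")
        draws = np.array([phylo_hill_number(pooled, t, 1) for t in trees])
        se = 0.0
        if draws.size > 1:
            se = float(draws.std(ddof=1) / math.sqrt(draws.size))
        return BreadthEstimate(
            metric="dRER",
            mean=float(draws.mean()),
            se=se,
            n_draws=int(draws.size),
            draws=draws,
            species=pooled.species,
            mode=pooled.mode,
        )
    else:
        raise ValueError(f"unknown breadth metric {metric!r}")
    return BreadthEstimate(
        metric=metric, mean=float(value), species=pooled.species, mode=pooled.mode
    )
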