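"""Quality control of replicated diet-metabarcoding OTU count tables.

Raw tables hold read counts per (OTU, sample, PCR replicate) together with
sample metadata (predator species, processing batch, primer set, blank flag).
The sequence-reliability chain applied here, in order:

1. blank removal — any OTU detected in an extraction or library blank is
   zeroed in all non-blank samples of the same processing batch (PCR blanks
   are monitored but not used for removal); blanks are then dropped;
2. replicate concordance — an OTU is kept in a sample only if it appears in
   at least ``min_replicates`` of its PCR replicates (default 2 of 3);
3. replicate collapse — surviving replicate counts are summed per sample,
   preserving integer depth semantics for the depth filter;
4. depth filter — samples with fewer than ``min_depth`` reads (default 5000)
   are removed;
5. relative-abundance filter — per sample, OTUs below ``min_fraction`` of the
   sample total (default 0.02%) are zeroed in a single pass (totals are not
   re-normalised between removals).

Every step appends its parameters to a provenance log.  Rarefaction curves
and a curvature index (area under the curve over its enclosing rectangle)
flag under-sequenced samples for reporting; the hard rule remains the depth
filter.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .hill import DietProfile

__all__ = [
    "ReplicateCountTable",
    "FilteredCountTable",
    "filter_replicate_concordance",
    "remove_blank_contaminants",
    "collapse_replicates",
    "filter_min_depth",
    "filter_rel_abundance",
    "run_qc",
    "rarefaction_curve",
    "curvature_index",
    "to_profiles",
]

META_COLUMNS = ("species", "batch", "primer", "is_blank", "blank_kind")
REMOVAL_BLANK_KINDS = ("extraction", "library")


@dataclasses.dataclass
class ReplicateCountTable:
    """OTU x (sample x replicate) read counts plus per-sample metadata.

    ``counts`` is a wide DataFrame indexed by otu_id with a two-level column
    MultiIndex (sample_id, replicate_id); ``meta`` is indexed by sample_id
    with columns species, batch, primer, is_blank, blank_kind.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    provenance: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.columns.nlevels != 2:
            raise ValueError("counts must have (sample_id, replicate_id) columns")
        self.counts.columns = self.counts.columns.set_names(
            ["sample_id", "replicate_id"]
        )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        missing_meta = set(self.counts.columns.get_level_values(0)) - set(
            self.meta.index
        )
        if missing_meta:
            raise ValueError(f"samples missing from metadata: {sorted(missing_meta)}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad_blanks = self.meta[
            self.meta["is_blank"] & (self.meta["blank_kind"] == "none")
        ]
        if len(bad_blanks):
            raise ValueError(
                f"blank samples without a blank_kind: {list(bad_blanks.index)}"
            )

    @property
    def samples(self) -> list:
        return list(self.counts.columns.get_level_values(0).unique())

    def replicates_of(self, sample_id) -> list:
        return list(self.counts[sample_id].columns)

    def _with(self, counts: pd.DataFrame, meta: pd.DataFrame, step: dict):
        return ReplicateCountTable(
            counts=counts, meta=meta, provenance=[*self.provenance, step]
        )


@dataclasses.dataclass
class FilteredCountTable:
    """OTU x sample counts after replicate collapse, with a provenance log."""

    counts: pd.DataFrame  # index otu_id, columns sample_id
    meta: pd.DataFrame
    provenance: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def _with(self, counts: pd.DataFrame, step: dict) -> "FilteredCountTable":
        meta = self.meta.loc[self.meta.index.intersection(counts.columns)]
        return FilteredCountTable(
            counts=counts, meta=meta, provenance=[*self.provenance, step]
        )


def filter_replicate_concordance(
    raw: ReplicateCountTable, min_replicates: int = 2
) -> ReplicateCountTable:
    """Zero OTUs not detected in >= ``min_replicates`` PCR replicates of a sample.

    Blank samples are exempt (their content feeds blank removal, not diet).
    """
    counts = raw.counts.copy()
    for sample in raw.samples:
        reps = raw.replicates_of(sample)
        if not 1 <= min_replicates <= len(reps):
            raise ValueError(
                f"min_replicates={min_replicates} invalid for sample {sample!r} "
                f"with {len(reps)} replicates"
            )
        if raw.meta.loc[sample, "is_blank"]:
            continue
        block = counts[sample]
        discordant = (block > 0).sum(axis=1) < min_replicates
        counts.loc[discordant, sample] = 0
    return raw._with(
        counts,
        raw.meta,
        {"step": "replicate_concordance", "min_replicates": min_replicates},
    )


def remove_blank_contaminants(raw: ReplicateCountTable) -> ReplicateCountTable:
    """Zero batch-matched blank OTUs in samples, then drop blank samples.

    Only extraction and library blanks drive removal; OTUs seen solely in PCR
    blanks are reported in the provenance log but left untouched.
    """
    counts = raw.counts.copy()
    meta = raw.meta
    blanks = meta[meta["is_blank"]]
    removed: dict = {}
    pcr_only: dict = {}
    for batch, batch_blanks in blanks.groupby("batch"):
        removal = batch_blanks[batch_blanks["blank_kind"].isin(REMOVAL_BLANK_KINDS)]
        blank_cols = [
            c for c in counts.columns if c[0] in set(removal.index)
        ]
        if blank_cols:
            contaminants = counts.index[(counts[blank_cols] > 0).any(axis=1)]
        else:
            contaminants = counts.index[:0]
        pcr_blanks = batch_blanks[~batch_blanks.index.isin(removal.index)]
        pcr_cols = [c for c in counts.columns if c[0] in set(pcr_blanks.index)]
        if pcr_cols:
            seen = counts.index[(counts[pcr_cols] > 0).any(axis=1)]
            pcr_only[batch] = sorted(set(seen) - set(contaminants))
        if len(contaminants):
            batch_samples = meta.index[
                (meta["batch"] == batch) & ~meta["is_blank"]
            ]
            cols = [c for c in counts.columns if c[0] in set(batch_samples)]
            counts.loc[contaminants, cols] = 0
            removed[batch] = sorted(contaminants)
    keep_cols = [c for c in counts.columns if not meta.loc[c[0], "is_blank"]]
    counts = counts[keep_cols]
    meta = meta[~meta["is_blank"]]
    return raw._with(
        counts,
        meta,
        {
            "step": "blank_removal",
            "removed_per_batch": removed,
            "pcr_blank_only_otus": pcr_only,
        },
    )


def collapse_replicates(filtered: ReplicateCountTable) -> FilteredCountTable:
    """Sum replicate counts per (OTU, sample); drop globally empty OTU rows."""
    counts = filtered.counts.T.groupby(level="sample_id").sum().T
    counts = counts.loc[counts.sum(axis=1) > 0]
    return FilteredCountTable(
        counts=counts,
        meta=filtered.meta.loc[filtered.meta.index.intersection(counts.columns)],
        provenance=[*filtered.provenance, {"step": "collapse_replicates",
                                           "rule": "sum"}],
    )


def filter_min_depth(
    table: FilteredCountTable, min_reads: int = 5000
) -> FilteredCountTable:
    """Remove samples with total reads strictly below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.sample_depths
    keep = depths.index[depths >= min_reads]
    if len(keep) == 0:
        raise ValueError(
            f"depth filter at {min_reads} reads removed every sample"
        )
    counts = table.counts[keep]
    counts = counts.loc[counts.sum(axis=1) > 0]
    return table._with(
        counts,
        {
            "step": "min_depth",
            "min_reads": min_reads,
            "dropped_samples": sorted(set(depths.index) - set(keep)),
        },
    )


def filter_rel_abundance(
    table: FilteredCountTable, min_fraction: float = 0.0002
) -> FilteredCountTable:
    """Zero per-sample OTUs whose share of the sample total is strictly below
    ``min_fraction`` (single pass: totals are not re-normalised), then drop
    globally empty OTU rows."""
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    frac = counts.div(totals.where(totals > 0, 1.0), axis=1)
    counts[frac < min_fraction] = 0
    counts = counts.loc[counts.sum(axis=1) > 0]
    return table._with(
        counts, {"step": "rel_abundance", "min_fraction": min_fraction}
    )


def run_qc(
    raw: ReplicateCountTable,
    min_replicates: int = 2,
    min_depth: int = 5000,
    min_fraction: float = 0.0002,
) -> FilteredCountTable:
    """The full sequence-reliability chain in its pinned order."""
    table = remove_blank_contaminants(raw)
    table = filter_replicate_concordance(table, min_replicates=min_replicates)
    collapsed = collapse_replicates(table)
    collapsed = filter_min_depth(collapsed, min_reads=min_depth)
    return filter_rel_abundance(collapsed, min_fraction=min_fraction)


# ---------------------------------------------------------------------------
# rarefaction diagnostics
# ---------------------------------------------------------------------------


def rarefaction_curve(
    sample_counts,
    step: int = 100,
    draws: int = 0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected OTU richness as a function of subsampling depth.

    With ``draws == 0`` the hypergeometric expectation is computed exactly
    (in log space for numerical stability); with ``draws > 0`` richness is
    averaged over that many random subsamples without replacement.
    Returns (depths, expected_richness); the curve ends at the observed depth,
    where expected richness equals observed richness.
    """
    if step <= 0:
        raise ValueError("step must be a positive integer")
    x = np.asarray(pd.Series(sample_counts).to_numpy(), dtype=float)
    x = x[x > 0]
    total = int(x.sum())
    if total <= 0:
        raise ValueError("sample has no reads")
    depths = np.arange(step, total + 1, step, dtype=int)
    if len(depths) == 0 or depths[-1] != total:
        depths = np.append(depths, total)
    if draws > 0:
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(x.size), x.astype(int))
        richness = np.empty(depths.size)
        for i, m in enumerate(depths):
            vals = [
                np.unique(rng.choice(pool, size=m, replace=False)).size
                for _ in range(draws)
            ]
            richness[i] = np.mean(vals)
    else:
        # E[S_m] = sum_i 1 - C(total - x_i, m) / C(total, m)
        richness = np.empty(depths.size)
        for i, m in enumerate(depths):
            rest = total - x
            with np.errstate(invalid="ignore"):
                logp = (
                    gammaln(rest + 1)
                    - gammaln(rest - m + 1)
                    - gammaln(total + 1)
                    + gammaln(total - m + 1)
                )
            absent = np.where(rest >= m, np.exp(logp), 0.0)
            richness[i] = np.sum(1.0 - absent)
    return depths, richness


def curvature_index(depths, richness) -> float:
    """Area under the rarefaction curve over its enclosing rectangle.

    1 for a fully saturated (flat) curve, 0.5 for a straight line from the
    origin; values below a reporting threshold flag under-sequenced samples.
    """
    d = np.asarray(depths, dtype=float)
    r = np.asarray(richness, dtype=float)
    if d.size < 2:
        raise ValueError("curve needs at least two points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("depths must be strictly increasing")
    width = d[-1] - d[0]
    height = r.max()
    if width <= 0 or height <= 0:
        raise ValueError("degenerate curve: zero-area enclosing rectangle")
    return float(np.trapezoid(r, d) / (width * height))


def to_profiles(
    table: FilteredCountTable, mode: str = "abundance"
) -> list[DietProfile]:
    """Per-individual diet profiles from the filtered table.

    Abundance mode divides counts by the sample total; incidence mode spreads
    equal mass over detected OTUs so the result remains a valid probability
    vector for every Hill computation.  Empty samples are excluded with a
    warning.
    """
    profiles = []
    for sample in table.counts.columns:
        col = table.counts[sample]
        if col.sum() <= 0:
            warnings.warn(f"sample {sample!r} is empty after filtering; excluded")
            continue
        species = (
            table.meta.loc[sample, "species"] if sample in table.meta.index else None
        )
        profiles.append(
            DietProfile.from_counts(col, mode=mode, id=str(sample), species=species)
        )
    if not profiles:
        raise ValueError("no non-empty samples to convert into profiles")
    return profiles
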