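"""Plain-text interchange: count tables, profiles, trees and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd

from .hill import DietProfile
from .qc import FilteredCountTable, ReplicateCountTable

__all__ = [
    "load_replicate_table",
    "write_filtered_table",
    "write_profiles",
    "read_profiles",
    "read_trees",
    "write_breadths",
    "write_partitions",
    "write_contrasts",
    "write_provenance",
]


def load_replicate_table(counts_path, meta_path) -> ReplicateCountTable:
    """Read a long-format counts TSV (otu_id, sample_id, replicate_id, count)
    and a metadata TSV (sample_id, species, batch, primer, is_blank,
    blank_kind) into a replicate count table."""
    long = pd.read_csv(counts_path, sep="\t")
    required = {"otu_id", "sample_id", "replicate_id", "count"}
    if not required.issubset(long.columns):
        raise ValueError(f"counts TSV must have columns {sorted(required)}")
    wide = long.pivot_table(
        index="otu_id",
        columns=["sample_id", "replicate_id"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    if meta["is_blank"].dtype == object:
        meta["is_blank"] = meta["is_blank"].astype(str).str.lower().isin(
            ("true", "1", "yes")
        )
    meta["blank_kind"] = meta["blank_kind"].fillna("none")
    return ReplicateCountTable(counts=wide, meta=meta)


def write_filtered_table(table: FilteredCountTable, path) -> None:
    table.counts.rename_axis("otu_id").to_csv(path, sep="\t")


def write_profiles(profiles, path) -> None:
    """Long-format profile TSV: sample_id, species, mode, otu_id, value."""
    rows = []
    for pr in profiles:
        for otu, value in pr.values.items():
            rows.append(
                {
                    "sample_id": pr.id,
                    "species": pr.species,
                    "mode": pr.mode,
                    "otu_id": otu,
                    "value": value,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list:
    long = pd.read_csv(path, sep="\t")
    profiles = []
    for (sample, species, mode), grp in long.groupby(
        ["sample_id", "species", "mode"], dropna=False
    ):
        values = grp.set_index("otu_id")["value"]
        profiles.append(
            DietProfile(
                values=values / values.sum(),
                mode=mode,
                id=str(sample),
                species=None if pd.isna(species) else species,
            )
        )
    return profiles


def read_trees(path) -> list:
    """Read one or more newick trees sharing a taxon namespace."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    return list(trees)


def write_breadths(estimates, path) -> None:
    rows = [
        {
            "species": b.species,
            "metric": b.metric,
            "mode": b.mode,
            "mean": b.mean,
            "se": b.se,
            "n_draws": b.n_draws,
        }
        for b in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_partitions(results, path) -> None:
    rows = [
        {
            "species": r.species,
            "q": r.q,
            "N": r.n,
            "alpha": r.alpha,
            "gamma": r.gamma,
            "beta": r.beta,
            "turnover": r.turnover,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def contrasts_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "model": r.model,
                "response": r.response,
                "predictor": r.predictor,
                "estimate": r.estimate,
                "stat": r.stat,
                "stat_name": r.stat_name,
                "df": ",".join(str(d) for d in r.df),
                "p": r.p,
                "r2": r.r2,
                "r2_marginal": r.r2_marginal,
                "r2_conditional": r.r2_conditional,
                "n": r.n,
                "significant": r.significant,
                "note": r.note,
            }
            for r in results
        ]
    )


def write_contrasts(results, path) -> None:
    contrasts_frame(results).to_csv(path, sep="\t", index=False)


def write_provenance(table, path) -> None:
    Path(path).write_text(json.dumps(table.provenance, indent=2, default=str))
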