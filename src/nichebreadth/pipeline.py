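"""End-to-end driver: QC → diversity → partitioning → spatial → association.

`species_records` turns a (possibly simulated) assemblage into one
:class:`~nichebreadth.association.SpeciesRecord` per species, averaging the
two primer datasets draw-wise; `analyze_assemblage` additionally runs the
standard contrast battery.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

from .association import (
    SpeciesRecord,
    average_primers,
    run_contrast_battery,
)
from .hill import dietary_breadth, trait_breadth
from .partition import alpha_diversity_per_species, partition
from .qc import run_qc, to_profiles
from .spatial import distribution_homogeneity, potential_range_size

__all__ = ["species_records", "analyze_assemblage"]


@dataclasses.dataclass
class QCSettings:
    min_replicates: int = 2
    min_depth: int = 5000
    min_fraction: float = 0.0002


def _primer_records(table, tree_set, qc: QCSettings, mode: str, q: float,
                    pool: str, primer: str) -> dict:
    """QC one primer dataset and compute per-species dietary metrics."""
    filtered = run_qc(
        table,
        min_replicates=qc.min_replicates,
        min_depth=qc.min_depth,
        min_fraction=qc.min_fraction,
    )
    profiles = to_profiles(filtered, mode=mode)
    by_species = defaultdict(list)
    for pr in profiles:
        by_species[pr.species].append(pr)
    records = {}
    for species, profs in by_species.items():
        drer = dietary_breadth(profs, "dRER", trees=tree_set, pool=pool)
        rec = SpeciesRecord(
            species=species,
            primer=primer,
            dR=dietary_breadth(profs, "dR", pool=pool).mean,
            dRE=dietary_breadth(profs, "dRE", pool=pool).mean,
            levins=dietary_breadth(profs, "levins", pool=pool).mean,
            dRER_draws=drer.draws,
        )
        if len(profs) >= 2:
            part = partition(profs, q=q)
            rec.turnover = part.turnover
            rec.alpha = part.alpha
        else:
            rec.alpha = alpha_diversity_per_species(profs, q=q)
        records[species] = rec
    return records


def species_records(
    assemblage,
    qc: QCSettings | None = None,
    mode: str = "abundance",
    q: float = 1.0,
    pool: str = "mean",
) -> list:
    """Per-species metric records from a simulated or loaded assemblage."""
    qc = qc or QCSettings()
    per_primer = {
        primer: _primer_records(
            table, assemblage.tree_set, qc, mode, q, pool, primer
        )
        for primer, table in assemblage.tables.items()
    }
    all_species = sorted(
        {sp for recs in per_primer.values() for sp in recs}
    )
    merged = []
    for sp in all_species:
        present = [recs[sp] for recs in per_primer.values() if sp in recs]
        rec = average_primers(present)
        if sp in assemblage.rasters:
            raster = assemblage.rasters[sp]
            rec.potential_range_cells = float(potential_range_size(raster))
            rec.homogeneity = float(distribution_homogeneity(raster))
        if assemblage.recognised_range is not None and sp in assemblage.recognised_range:
            rec.recognised_range_area = float(assemblage.recognised_range[sp])
        traits = assemblage.trait_profiles
        if traits is not None and sp in traits.index:
            row = traits.loc[sp]
            for axis in ("hunting", "habitat", "roosting"):
                cols = [c for c in traits.columns if c.startswith(axis)]
                if cols and row[cols].sum() > 0:
                    setattr(rec, f"{axis}_breadth", trait_breadth(row[cols]))
        merged.append(rec)
    return merged


def analyze_assemblage(assemblage, qc: QCSettings | None = None,
                       mode: str = "abundance", q: float = 1.0,
                       pool: str = "mean"):
    """Full pipeline; returns (species records, association results)."""
    records = species_records(assemblage, qc=qc, mode=mode, q=q, pool=pool)
    return records, run_contrast_battery(records)
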