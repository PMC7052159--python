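import dendropy
import numpy as np
import pandas as pd
import pytest

from nichebreadth import DietProfile


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def random_profiles(rng):
    """100 random Dirichlet profiles with support sizes up to 50."""
    profiles = []
    for _ in range(100):
        s = int(rng.integers(2, 51))
        p = rng.dirichlet(np.full(s, rng.uniform(0.2, 3.0)))
        profiles.append(p)
    return profiles


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


@pytest.fixture
def star_tree():
    return make_tree("(A:1,B:1,C:1,D:1,E:1):0;")


def build_table(cells, meta_rows, n_replicates=3):
    """Replicate count table from {(otu, sample): replicate counts} plus
    {sample: (species, batch, primer, is_blank, blank_kind)}."""
    from nichebreadth import ReplicateCountTable

    otus = sorted({otu for otu, _ in cells})
    samples = list(meta_rows)
    columns = pd.MultiIndex.from_tuples(
        [(s, r) for s in samples for r in range(1, n_replicates + 1)],
        names=["sample_id", "replicate_id"],
    )
    counts = pd.DataFrame(0, index=otus, columns=columns)
    for (otu, sample), reps in cells.items():
        for r, value in enumerate(reps, start=1):
            counts.loc[otu, (sample, r)] = value
    meta = pd.DataFrame.from_dict(
        meta_rows,
        orient="index",
        columns=["species", "batch", "primer", "is_blank", "blank_kind"],
    )
    meta.index.name = "sample_id"
    return ReplicateCountTable(counts=counts, meta=meta)


def make_planted_table():
    """Hand-built QC fixture with one planted failure mode per rule.

    * OTU_C: contaminant in the batch-B1 extraction blank — must vanish from
      B1 samples (S1) but survive in the B2 sample (S3);
    * OTU_D: 1-of-3 replicate artifact in S2 — removed by concordance;
    * OTU_E: 2 reads of 13,802 in S1 (0.014%) — removed by the 0.02% rule;
    * OTU_F: seen only in a PCR blank — monitored, never removed;
    * S_shallow: 4,000 reads — removed by the 5,000-read depth rule.
    """
    cells = {
        ("OTU_A", "S1"): (4000, 4000, 4000),
        ("OTU_B", "S1"): (600, 600, 600),
        ("OTU_C", "S1"): (100, 100, 100),
        ("OTU_E", "S1"): (1, 1, 0),
        ("OTU_A", "S2"): (3000, 3000, 3000),
        ("OTU_B", "S2"): (700, 700, 700),
        ("OTU_D", "S2"): (500, 0, 0),
        ("OTU_A", "S3"): (2000, 2000, 2000),
        ("OTU_B", "S3"): (400, 400, 400),
        ("OTU_C", "S3"): (100, 100, 100),
        ("OTU_F", "S3"): (200, 200, 200),
        ("OTU_A", "S_shallow"): (1500, 1500, 1000),
        ("OTU_C", "blank_B1_ext"): (50, 0, 0),
        ("OTU_F", "blank_B2_pcr"): (30, 0, 0),
    }
    meta = {
        "S1": ("bat1", "B1", "Zeale", False, "none"),
        "S2": ("bat1", "B1", "Zeale", False, "none"),
        "S3": ("bat2", "B2", "Zeale", False, "none"),
        "S_shallow": ("bat2", "B2", "Zeale", False, "none"),
        "blank_B1_ext": (None, "B1", "Zeale", True, "extraction"),
        "blank_B2_pcr": (None, "B2", "Zeale", True, "pcr"),
    }
    return build_table(cells, meta)


PLANTED_EXPECTED = pd.DataFrame(
    {
        "S1": {"OTU_A": 12000, "OTU_B": 1800, "OTU_C": 0, "OTU_F": 0},
        "S2": {"OTU_A": 9000, "OTU_B": 2100, "OTU_C": 0, "OTU_F": 0},
        "S3": {"OTU_A": 6000, "OTU_B": 1200, "OTU_C": 300, "OTU_F": 600},
    }
).rename_axis("otu_id")


def profile(values, index=None, **kwargs) -> DietProfile:
    values = np.asarray(values, dtype=float)
    if index is None:
        index = [f"OTU_{i + 1}" for i in range(values.size)]
    return DietProfile(values=pd.Series(values, index=index), **kwargs)
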