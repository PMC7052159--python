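"""Synthetic data generator for the full diet/spatial analysis pipeline.

Emulates the structure of a multi-species insectivore diet-metabarcoding
study: several predator species, tens of individuals each, three PCR
replicates per individual amplified with two primer sets, a sparse OTU table
with processing-batch blanks and planted contaminants, a set of posterior-like
prey trees, per-species habitat-suitability rasters, and species-level
behavioural trait profiles.

The dietary gradient across species is planted on *evenness* (per-species
Dirichlet concentration) and *regularity* (phylogenetic clustering of the
prey pool), while prey-pool size — hence richness — is held constant.  The
full-breadth metric dRER therefore varies across species while dR does not,
which is what lets a coupling between dRER and raster homogeneity be planted
without dragging richness along.

The spatial coupling is imposed on the raster *unevenness parameter*: the
target homogeneity of a species' raster is a linear function of its
standardised true dRER plus noise, and the lognormal spread of cell
suitabilities is chosen so a large raster realises that homogeneity in
expectation (for suitabilities ~ lognormal(0, s²), the evenness factor tends
to exp(-s²/2)).  Realised homogeneity inherits sampling noise, mimicking an
observational design.

All randomness flows from a single integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import random
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .hill import phylo_hill_number
from .qc import ReplicateCountTable
from .spatial import SuitabilityRaster, write_ascii_grid

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "Assemblage",
    "simulate_prey_tree",
    "perturb_tree_set",
    "simulate_species_diets",
    "simulate_reads",
    "simulate_raster",
    "simulate_assemblage",
    "write_assemblage",
]


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_species: int = 7
    n_individuals: int = 50
    n_replicates: int = 3
    n_otus: int = 2000
    primers: tuple = ("Zeale", "Epp")
    depth_mean: float = 20000.0  # per PCR replicate
    depth_dispersion: float = 5.0  # negative-binomial shape; larger = tighter
    dropout: float = 0.05  # per-replicate per-OTU detection failure
    n_contaminants: int = 5
    contaminant_reads_mean: float = 30.0  # per contaminated sample-replicate
    n_batches: int = 4
    shallow_fraction: float = 0.02  # samples forced under the depth filter
    shallow_depth: int = 3000
    pool_size: int = 200  # prey-pool size, constant across species
    alpha_range: tuple = (0.15, 2.0)  # Dirichlet concentration (evenness)
    clustering_range: tuple = (6.0, 0.0)  # phylogenetic clustering (regularity)
    turnover_range: tuple = (0.3, 0.7)  # individual diet turnover
    n_trees: int = 50
    tree_jitter_sd: float = 0.1
    raster_shape: tuple = (40, 40)
    range_fill: tuple = (0.4, 0.95)  # fraction of cells inside the range
    base_homogeneity: float = 0.55
    coupling_slope: float = 0.0  # homogeneity per SD of true dRER
    coupling_noise_sd: float = 0.03

    def validate(self) -> None:
        for name in ("n_species", "n_individuals", "n_replicates", "n_otus",
                     "n_trees", "pool_size", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("dropout", "shallow_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pool_size > self.n_otus:
            raise ValueError("prey-pool size cannot exceed the OTU universe")


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated data."""

    species: list
    prey_pools: dict  # species -> list of OTU ids
    species_profiles: dict  # species -> pd.Series (true mean profile)
    drer_draws: dict  # species -> np.ndarray over the tree set
    target_homogeneity: dict  # species -> planted target
    realised_homogeneity: dict  # species -> value realised by the raster
    contaminants: list  # planted contaminant OTU ids
    coupling_slope: float


@dataclasses.dataclass
class Assemblage:
    """Everything the pipeline consumes, plus the truth record."""

    config: SimulationConfig
    tree: dendropy.Tree
    tree_set: list
    tables: dict  # primer -> ReplicateCountTable
    rasters: dict  # species -> SuitabilityRaster
    trait_profiles: pd.DataFrame  # species x trait category columns
    recognised_range: pd.Series  # species -> external range area analogue
    truth: SimulationTruth


def _otu_label(i: int) -> str:
    return f"OTU_{i + 1}"


def simulate_prey_tree(n_otus: int, seed: int) -> dendropy.Tree:
    """A random coalescent prey tree with leaves OTU_1..OTU_n.

    Kingman coalescent waiting times guarantee strictly positive branch
    lengths for every tree size, including the two-leaf case.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs for a tree")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([_otu_label(i) for i in range(n_otus)])
    return treesim.pure_kingman_tree(taxon_namespace=taxa, pop_size=1, rng=rng)


def perturb_tree_set(
    tree: dendropy.Tree, n_trees: int, sd: float, seed: int
) -> list:
    """Posterior-like tree draws: lognormal branch-length jitter, fixed topology."""
    if sd < 0:
        raise ValueError("branch-length jitter sd must be >= 0")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_trees):
        clone = dendropy.Tree(tree)
        if sd > 0:
            for edge in clone.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(edge.length) * float(
                        rng.lognormal(0.0, sd)
                    )
        draws.append(clone)
    return draws


def _leaf_distances_from(tree: dendropy.Tree, focal) -> dict:
    """Patristic distance from a focal leaf to every leaf (graph BFS)."""
    dist = {id(focal): 0.0}
    stack = [focal]
    leaf_dist = {}
    while stack:
        node = stack.pop()
        d = dist[id(node)]
        if node.is_leaf():
            leaf_dist[node.taxon.label] = d
        neighbours = list(node.child_nodes())
        if node.parent_node is not None:
            neighbours.append(node.parent_node)
        for nb in neighbours:
            if id(nb) in dist:
                continue
            edge = node.edge if nb is node.parent_node else nb.edge
            length = edge.length or 0.0
            dist[id(nb)] = d + length
            stack.append(nb)
    return leaf_dist


def simulate_species_diets(
    config: SimulationConfig, tree: dendropy.Tree, rng: np.random.Generator
):
    """True per-individual diet profiles for every species.

    Per species: a prey pool is drawn from the tree leaves with clustering
    strength lambda (lambda=0: uniform; large lambda: concentrated around a
    focal clade, lowering regularity); a base profile ~ Dirichlet(alpha);
    individuals share each pool OTU with probability 1 - tau, otherwise the
    OTU belongs to a single random individual (tau=0: identical individuals,
    tau=1: disjoint diets).
    """
    config.validate()
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    labels = [leaf.taxon.label for leaf in leaves]
    n_sp = config.n_species
    alphas = np.linspace(*config.alpha_range, n_sp)
    lambdas = np.linspace(*config.clustering_range, n_sp)
    taus = np.linspace(*config.turnover_range, n_sp)
    pools: dict = {}
    bases: dict = {}
    individuals: dict = {}
    for s in range(n_sp):
        name = f"SP{s + 1}"
        lam = lambdas[s]
        if lam > 0:
            focal = leaves[rng.integers(len(leaves))]
            d = _leaf_distances_from(tree, focal)
            logw = -lam * np.array([d[lb] for lb in labels])
        else:
            logw = np.zeros(len(labels))
        # Gumbel top-k = weighted sampling without replacement
        keys = logw + rng.gumbel(size=len(labels))
        idx = np.argsort(keys)[::-1][: config.pool_size]
        pool = [labels[i] for i in sorted(idx)]
        base = rng.dirichlet(np.full(len(pool), alphas[s]))
        base = pd.Series(base, index=pool)
        base = base[base > 0]
        # individual membership: shared core vs single-owner OTUs
        tau = taus[s]
        owner = np.where(
            rng.random(len(base)) < tau,
            rng.integers(config.n_individuals, size=len(base)),
            -1,
        )
        profs = []
        for ind in range(config.n_individuals):
            mask = (owner == -1) | (owner == ind)
            sub = base[mask]
            if sub.empty:
                sub = base.iloc[[int(rng.integers(len(base)))]]
            profs.append(sub / sub.sum())
        pools[name] = list(base.index)
        bases[name] = base / base.sum()
        individuals[name] = profs
    return pools, bases, individuals


def _sample_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    shape = config.depth_dispersion
    p = shape / (shape + config.depth_mean)
    return int(rng.negative_binomial(shape, p)) + 1


def simulate_reads(
    individuals: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    primer: str,
    contaminants: list,
) -> ReplicateCountTable:
    """Replicated read counts with depth variation, dropout, blanks and
    planted contaminants (injected into blanks and same-batch samples)."""
    columns: dict = {}
    meta_rows: dict = {}
    sample_batch: dict = {}
    all_samples = []
    for species, profs in individuals.items():
        for ind, prof in enumerate(profs):
            sample = f"{species}_I{ind + 1}_{primer}"
            all_samples.append((sample, species, prof))
    n_shallow = int(np.floor(config.shallow_fraction * len(all_samples)))
    shallow = set(
        rng.choice(len(all_samples), size=n_shallow, replace=False).tolist()
    ) if n_shallow else set()
    for k, (sample, species, prof) in enumerate(all_samples):
        batch = f"B{k % config.n_batches + 1}"
        sample_batch[sample] = batch
        meta_rows[sample] = (species, batch, primer, False, "none")
        if k in shallow:
            # shallow in *collapsed* total: split the target across replicates
            total = int(rng.integers(1000, config.shallow_depth + 1))
            depth = max(1, total // config.n_replicates)
        else:
            depth = _sample_depth(config, rng)
        p = prof.to_numpy()
        for rep in range(1, config.n_replicates + 1):
            keep = rng.random(p.size) >= config.dropout
            if not keep.any():
                keep[int(rng.integers(p.size))] = True
            pr = np.where(keep, p, 0.0)
            pr = pr / pr.sum()
            reads = rng.multinomial(depth, pr)
            col = pd.Series(reads, index=prof.index)
            columns[(sample, rep)] = col[col > 0]
    # contamination: blanks per batch plus additive reads in batch samples
    batches = sorted({b for b in sample_batch.values()})
    contam_by_batch = {}
    if contaminants:
        for b_i, batch in enumerate(batches):
            picked = [
                contaminants[i]
                for i in range(len(contaminants))
                if rng.random() < 0.8
            ] or [contaminants[b_i % len(contaminants)]]
            contam_by_batch[batch] = picked
            for kind in ("extraction", "library", "pcr"):
                blank = f"blank_{batch}_{kind}_{primer}"
                meta_rows[blank] = (None, batch, primer, True, kind)
                for rep in range(1, config.n_replicates + 1):
                    reads = rng.poisson(
                        config.contaminant_reads_mean, size=len(picked)
                    ) + 1
                    columns[(blank, rep)] = pd.Series(reads, index=picked)
            for sample, batch_of in sample_batch.items():
                if batch_of != batch:
                    continue
                for rep in range(1, config.n_replicates + 1):
                    extra = rng.poisson(
                        config.contaminant_reads_mean, size=len(picked)
                    )
                    add = pd.Series(extra, index=picked)
                    add = add[add > 0]
                    if add.empty:
                        continue
                    columns[(sample, rep)] = (
                        columns[(sample, rep)].add(add, fill_value=0).astype(int)
                    )
    counts = pd.DataFrame(columns).fillna(0).astype(int)
    counts.columns = pd.MultiIndex.from_tuples(
        counts.columns, names=["sample_id", "replicate_id"]
    )
    counts = counts.sort_index(axis=1)
    meta = pd.DataFrame.from_dict(
        meta_rows,
        orient="index",
        columns=["species", "batch", "primer", "is_blank", "blank_kind"],
    )
    meta.index.name = "sample_id"
    return ReplicateCountTable(counts=counts, meta=meta)


def simulate_raster(
    shape, unevenness: float, seed_or_rng, fill: float = 1.0
) -> SuitabilityRaster:
    """Lognormal suitabilities rescaled to (0, 1]; unevenness 0 = uniform.

    ``fill`` is the fraction of cells inside the species' suitable range; the
    remaining cells get suitability 0 and fall below the s_min = 0 floor, so
    the potential range size varies across species.
    """
    if unevenness < 0:
        raise ValueError("unevenness must be >= 0")
    if not 0 < fill <= 1:
        raise ValueError("fill must lie in (0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if np.isscalar(shape):
        shape = (int(shape), 1)
    if unevenness == 0:
        values = np.ones(shape)
    else:
        values = rng.lognormal(0.0, unevenness, size=shape)
        values = values / values.max()
    if fill < 1:
        n = values.size
        n_out = n - max(1, int(round(fill * n)))
        if n_out > 0:
            out = rng.choice(n, size=n_out, replace=False)
            flat = values.ravel()
            flat[out] = 0.0
            values = flat.reshape(shape)
    return SuitabilityRaster(values=values, s_min=0.0)


def _trait_profiles(config, rng) -> pd.DataFrame:
    cats = (
        [f"hunting_{c}" for c in "ABCD"]
        + [f"habitat_{c}" for c in "ABCDE"]
        + [f"roosting_{c}" for c in "ABC"]
    )
    rows = {}
    for s in range(config.n_species):
        name = f"SP{s + 1}"
        row = np.concatenate(
            [rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(5)),
             rng.dirichlet(np.ones(3))]
        )
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=cats)


def simulate_assemblage(config: SimulationConfig) -> Assemblage:
    """Generate every pipeline input plus the ground-truth record."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_prey_tree(config.n_otus, seed=config.seed)
    tree_set = perturb_tree_set(
        tree, config.n_trees, config.tree_jitter_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    pools, bases, individuals = simulate_species_diets(config, tree, rng)
    species = list(pools)
    # contaminant OTUs: drawn from the universe outside every prey pool
    used = set().union(*pools.values())
    free = [
        _otu_label(i) for i in range(config.n_otus) if _otu_label(i) not in used
    ]
    contaminants = list(
        rng.choice(free, size=min(config.n_contaminants, len(free)),
                   replace=False)
    ) if free and config.n_contaminants else []
    tables = {
        primer: simulate_reads(
            individuals, config, rng, primer, contaminants
        )
        for primer in config.primers
    }
    # true species profiles and dRER draws
    species_profiles = {}
    drer = {}
    for name in species:
        mat = pd.concat(individuals[name], axis=1).fillna(0.0)
        prof = mat.mean(axis=1)
        prof = prof / prof.sum()
        species_profiles[name] = prof
        drer[name] = np.array(
            [phylo_hill_number(prof, t, 1) for t in tree_set]
        )
    means = np.array([drer[name].mean() for name in species])
    z = (means - means.mean()) / (means.std() if means.std() > 0 else 1.0)
    rasters = {}
    target_h = {}
    realised_h = {}
    from .spatial import distribution_homogeneity

    for name, zi in zip(species, z):
        h = config.base_homogeneity + config.coupling_slope * zi
        h += rng.normal(0.0, config.coupling_noise_sd)
        h = float(np.clip(h, 0.05, 0.995))
        sigma = float(np.sqrt(-2.0 * np.log(h)))
        fill = float(rng.uniform(*config.range_fill))
        raster = simulate_raster(config.raster_shape, sigma, rng, fill=fill)
        rasters[name] = raster
        target_h[name] = h
        realised_h[name] = distribution_homogeneity(raster)
    # recognised range: external cartography analogue, uncoupled noise
    recognised = pd.Series(
        {
            name: float(
                potential * rng.uniform(0.3, 1.0)
            )
            for name, potential in (
                (name, (rasters[name].values > rasters[name].s_min).sum())
                for name in species
            )
        }
    )
    truth = SimulationTruth(
        species=species,
        prey_pools=pools,
        species_profiles=species_profiles,
        drer_draws=drer,
        target_homogeneity=target_h,
        realised_homogeneity=realised_h,
        contaminants=contaminants,
        coupling_slope=config.coupling_slope,
    )
    return Assemblage(
        config=config,
        tree=tree,
        tree_set=tree_set,
        tables=tables,
        rasters=rasters,
        trait_profiles=_trait_profiles(config, rng),
        recognised_range=recognised,
        truth=truth,
    )


def write_assemblage(assemblage: Assemblage, outdir) -> None:
    """Write all generated inputs as plain-text files (TSV/newick/ASCII/JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for primer, table in assemblage.tables.items():
        long = (
            table.counts.stack(["sample_id", "replicate_id"], future_stack=True)
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "otu_id"})
        )
        long = long[long["count"] > 0]
        long.columns = ["otu_id", "sample_id", "replicate_id", "count"]
        long.to_csv(out / f"counts_{primer}.tsv", sep="\t", index=False)
        table.meta.to_csv(out / f"meta_{primer}.tsv", sep="\t")
    trees = dendropy.TreeList(assemblage.tree_set)
    trees.write(path=str(out / "trees.nwk"), schema="newick")
    assemblage.tree.write(path=str(out / "tree_main.nwk"), schema="newick")
    for name, raster in assemblage.rasters.items():
        write_ascii_grid(raster, out / f"raster_{name}.asc")
    assemblage.trait_profiles.to_csv(out / "traits.tsv", sep="\t")
    assemblage.recognised_range.rename("recognised_range_area").to_csv(
        out / "recognised_range.tsv", sep="\t"
    )
    truth = assemblage.truth
    payload = {
        "species": truth.species,
        "prey_pools": truth.prey_pools,
        "drer_draws": {k: v.tolist() for k, v in truth.drer_draws.items()},
        "target_homogeneity": truth.target_homogeneity,
        "realised_homogeneity": truth.realised_homogeneity,
        "contaminants": list(truth.contaminants),
        "coupling_slope": truth.coupling_slope,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
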