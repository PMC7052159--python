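# nichebreadth

Tools for asking how the **dietary niche breadth** of generalist predators
relates to the **shape of their geographic distribution**, using DNA
metabarcoding diet data and habitat-suitability rasters. The motivating
system is a community of insectivorous bats whose faecal samples were
amplified in replicated PCRs with two primer sets, but every stage is
generic: any replicated OTU-by-sample count table, any prey phylogeny, any
suitability raster.

## What it computes

**Diet QC.** Raw OTU × (sample × PCR replicate) read counts are filtered by
the standard sequence-reliability chain: batch-scoped removal of OTUs seen
in extraction/library blanks, a 2-of-3 replicate concordance rule, replicate
collapse, a 5,000-read minimum sample depth, and a per-sample 0.02% minimum
relative abundance. Rarefaction curves and a curvature index (area under the
curve over its enclosing rectangle) flag under-sequenced samples.

**Dietary breadth as Hill numbers.** For a diet profile *p* the Hill number
of order *q* is ᵠD = (Σᵢ pᵢᵠ)^(1/(1−q)), with the q→1 limit exp(−Σ pᵢ ln pᵢ).
Three nested breadth metrics follow:

* `dR` — richness, ⁰D;
* `dRE` — richness + evenness, ¹D;
* `dRER` — richness + evenness + regularity: the *phylogenetic* Hill number
  ¹PD on the prey tree pruned to the diet, computed from abundance-weighted
  branch lengths normalised by the mean depth T̄ = Σ Lᵦaᵦ. Phylogenetic
  uncertainty is propagated by evaluating ¹PD over a set of posterior tree
  draws (mean ± SE across draws). Levins' index 1/Σpᵢ² (= ²D) is included
  for comparability with the older literature.

**Diversity partitioning.** A species' diet is split multiplicatively into
alpha (within individuals), beta = gamma/alpha, and gamma (species pool)
components at order *q*, and the Jaccard-type turnover
(1 − 1/β)/(1 − 1/N) ∈ [0, 1] measures how much of the species' diet exists
as between-individual variation.

**Spatial metrics.** From a habitat-suitability raster: potential range
size (cells strictly above the species' minimum-suitability floor) and
distribution homogeneity — the Hill evenness factor ¹D/⁰D of the normalised
cell-suitability distribution, 1 for a uniformly suitable range and → 0 as
suitability concentrates in a few cells.

**Association stage.** Species-level metrics are related by OLS linear
models; dRER, which carries one value per posterior tree draw, enters
random-intercept linear mixed models (REML) with Nakagawa marginal and
conditional R², the fixed-effect t referred to n_species − 2 df, and
draw-wise averaging of the two primer datasets.

**Synthetic data.** `nichebreadth.simulate` generates the whole study with
known ground truth — coalescent prey trees, branch-length-jittered posterior
draws, per-species prey pools with controllable evenness/regularity/
turnover, multinomial reads with depth variation, replicate dropout, blanks
and planted contaminants, and per-species rasters whose homogeneity can be
linearly coupled to the species' true dRER — so the full pipeline is
testable end to end without any external download.

## Worked example

```python
import nichebreadth as nb

cfg = nb.SimulationConfig(seed=1, n_species=5, n_individuals=6, n_otus=300,
                          pool_size=60, n_trees=5, depth_mean=10000,
                          coupling_slope=0.25)
asm = nb.simulate_assemblage(cfg)
records, results = nb.analyze_assemblage(asm)
for rec in records:
    print(rec.species, round(rec.dR, 1), round(rec.dRER, 2),
          round(rec.turnover, 3), round(rec.homogeneity, 3))
r = {c.contrast: c for c in results}["dRER_vs_homogeneity"]
print(f"dRER ~ homogeneity: t = {r.stat:.2f}, p = {r.p:.4f}, "
      f"R2m = {r.r2_marginal:.2f}, R2c = {r.r2_conditional:.2f}")
```

prints

```
SP1 36.0 1.67 0.064 0.303
SP2 57.0 3.64 0.146 0.925
SP3 58.5 1.83 0.201 0.281
SP4 60.0 3.43 0.456 0.843
SP5 59.0 2.48 0.377 0.529
dRER ~ homogeneity: t = 19.39, p = 0.0003, R2m = 0.98, R2c = 0.99
```

Each row is one simulated bat species: its detected prey richness (dR),
full dietary breadth (dRER, mean over 5 tree draws), prey turnover across
individuals, and raster homogeneity. The planted positive coupling between
dRER and homogeneity is recovered by the mixed model, while richness alone
would not show it — the dissociation the breadth decomposition is designed
to expose.

The same stages are available from the shell:

```bash
nichebreadth simulate --seed 3 --out sim/
nichebreadth qc --counts sim/counts_Zeale.tsv --meta sim/meta_Zeale.tsv --out qc/
nichebreadth diversity --profiles qc/profiles.tsv --trees sim/trees.nwk \
    --metrics dR,dRE,dRER --out breadth.tsv
nichebreadth partition --profiles qc/profiles.tsv --q 1 --out partition.tsv
nichebreadth spatial --raster sim/raster_SP1.asc --out spatial.tsv
```

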