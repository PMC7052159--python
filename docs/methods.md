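# Methods notes

This note records the models implemented by `nichebreadth`, the choices made
where common analysis conventions leave the design open, and what the
synthetic-data generator does and does not emulate.

## Metabarcoding QC

The sequence-reliability chain is applied in a fixed, logged order:

1. **Blank removal** (batch-scoped): an OTU detected with any reads in an
   *extraction* or *library* blank is zeroed in every non-blank sample of
   the same processing batch. PCR blanks are reported in the provenance log
   but do not drive removal. Blank columns are then dropped.
2. **Replicate concordance**: within each non-blank sample, an OTU is kept
   only if it has non-zero reads in at least `min_replicates` of the
   sample's PCR replicates (default 2 of 3). Blanks are exempt — their
   content is information for step 1, not diet.
3. **Replicate collapse**: surviving replicate counts are *summed*, not
   averaged, so the depth filter keeps integer read semantics.
4. **Depth filter**: samples with a collapsed total strictly below 5,000
   reads are removed.
5. **Relative-abundance filter**: per sample, OTUs strictly below 0.02% of
   the sample total are zeroed in a single pass; totals are not
   re-normalised between removals, so the filter is idempotent.

Boundary semantics are strict in both hard filters ("less than 5000",
"below 0.02%"): equality passes. The ordering of steps 1 and 2 is not
dictated by the rules themselves (they commute on most tables but not when
a blank OTU also fails concordance in a sample); blank removal first was
pinned so that the concordance rule never resurrects contaminant evidence.

Rarefaction curves use the exact hypergeometric expectation (computed in
log space) or optional resampling. The curvature index — area under the
curve divided by its enclosing rectangle — has no canonical published
formula; the AUC/rectangle form was chosen because it is dimensionless,
equals 1 for a saturated curve and 0.5 for a linear accumulation, and it is
used only for *reporting* under-sequenced samples (default flag threshold
0.9); the 5,000-read rule remains the only hard depth criterion.

Incidence-mode profiles are presence vectors normalised to sum to one, so
both modes produce valid probability inputs for every Hill computation.

## Hill numbers

Neutral Hill numbers use the defining power-sum formula with the q = 1
limit handled analytically (exp of Shannon entropy), never by numerical
approach to the limit. The phylogenetic Hill number follows the
mean-phylogenetic-diversity form: branch abundances are the summed
relative abundances of the leaves descending each branch, branch lengths
are normalised by the abundance-weighted mean depth T̄, making the result a
scale-free effective number of lineages. Trees are pruned to the profile
support before T̄ is computed — the quantity describes the consumed
assemblage, not the reference tree. The implementation does this without
mutating the tree: a single postorder pass keeps exactly the branches whose
descendant abundance is strictly between 0 and the total, which is the
branch set of the induced subtree rooted at the most recent common ancestor
of the support (degree-2 merges are immaterial because every term is linear
in branch length). A profile supported on a single OTU is one lineage by
definition. An independent naive oracle (explicit dendropy pruning plus
per-edge leaf enumeration) backs this equivalence in the test suite.

Species-level profiles are the equal-weight arithmetic mean of individual
relative-abundance vectors (renormalised), which removes sequencing-depth
bias between individuals; read-weighted pooling is available
(`pool="reads"`) for users who want depth-proportional pooling. dRER is
evaluated once per tree in the posterior set; the reported dispersion is
the sample standard deviation across draws divided by √N.

## Partitioning and turnover

Multiplicative partitioning uses equal subsystem weights w_j = 1/N
throughout; unequal weights are rejected at the interface rather than
silently reinterpreted. Alpha at q = 1 is exp of the mean Shannon entropy;
at q ≠ 1 the standard equal-weight Hill-alpha power sum. The turnover
measure is the Jaccard-type complement (1 − 1/β)/(1 − 1/N), which is 0 when
all individuals share one diet and 1 when their diets are disjoint — the
endpoint behaviour is enforced by test, which also distinguishes it from
the Sørensen-type variant ((β−1)/(N−1)). Partitioning defaults to q = 1 to
match the order used by dRE/dRER; q is exposed everywhere.

## Spatial metrics

The same minimum-suitability floor `s_min` gates both metrics, so the q = 0
entry of the spatial breadth profile coincides with the potential range
size. "Above" is strict. When no floor is supplied the smallest strictly
positive suitability in the raster is used — the per-species floor is study
configuration (e.g. a minimum-training-presence threshold) and should
normally be given explicitly. Cells are counted, not area-weighted; for
unprojected geographic rasters this ignores latitude-dependent cell area
and is flagged here deliberately. A raster whose qualifying cells are all
equal returns homogeneity exactly 1 (the defining limit is special-cased to
avoid returning 1 − ε from floating-point entropy).

Raster IO supports the ESRI ASCII grid (values round-trip bit-exactly; the
writer emits full-precision decimal representations) and single-band
float32 TIFF with NaN as nodata.

## Association stage

LMs are ordinary least squares with F, (1, n−2) df, R² and p. Metrics that
carry one value per posterior tree draw (dRER) enter a random-intercept
linear mixed model fitted by REML. Two design points deserve emphasis:

* **Orientation.** The draw-level metric must be the *response*: if the
  pseudoreplicated values were placed on the predictor side the response
  would be constant within species, and a zero slope plus free species
  intercepts would fit perfectly — the model is degenerate in that
  direction. With dRER draws as response and the species-level metric as
  fixed predictor, draw noise supplies the residual variance and the fit is
  well-posed. This also makes the conditional R² informative (< 1).
* **Inference.** The fixed-effect p-value is the Wald t referred to a t
  distribution with n_species − 2 degrees of freedom (the between-species
  information, one slot spent per fixed parameter). A likelihood-ratio test
  against the intercept-only model was rejected: with a species-level
  predictor the null model's within-species structure differs pathologically
  and the test is badly calibrated here, while the t-with-(n−2)-df
  convention reproduces the conventional small-sample behaviour of
  `lme4`-based pipelines.

R² follows the Nakagawa variance-decomposition convention:
R²m = Var_fixed/(Var_fixed + Var_random + Var_residual) and
R²c = (Var_fixed + Var_random)/(same). If the random-intercept variance
collapses to zero the fit falls back to OLS on the per-species draw means,
recorded in the result's `note`.

Primer averaging is arithmetic per metric and *draw-wise* for dRER (draw k
of one primer with draw k of the other), preserving the dispersion across
tree draws; species present in one primer dataset pass through flagged.
Recognised range size is an external input column (e.g. from published
cartography); no map processing is performed. The significance threshold is
0.05 and no multiple-testing correction is applied across the battery.

## Synthetic-data generator

The generator emulates the *structure* of a multi-species diet study: 7
predator species × 50 individuals × 3 PCR replicates × 2 primer sets by
default, a sparse OTU universe (2,000 by default), negative-binomial
per-replicate depths (mean 20,000, shape 5), per-replicate OTU dropout
(5%), processing batches with extraction/library/PCR blanks, planted
contaminant OTUs injected into blanks and their batch's samples, a small
fraction (2%) of samples forced below the depth filter, 50 posterior-like
trees obtained by lognormal branch-length jitter (sd 0.1) of a Kingman
coalescent prey tree, and per-species lognormal suitability rasters
(default 40 × 40 cells) with a range-occupancy fraction drawn from
(0.4, 0.95).

Dietary structure per species: a prey pool sampled from the tree with
clustering strength λ (leaf weights ∝ exp(−λ · distance to a focal leaf);
λ = 0 is uniform), a base profile ~ Dirichlet(α), and individual diets
formed by a shared-core/unique-owner split with turnover parameter τ (each
pool OTU is common to all individuals with probability 1 − τ, otherwise
owned by one individual), which makes τ = 0 give identical individuals and
τ = 1 disjoint diets exactly.

The spatial coupling is imposed on the raster *unevenness parameter*: the
target homogeneity of a species' raster is base + slope · z(true dRER) +
noise, and the lognormal sd is set to √(−2 ln h), using the large-raster
limit homogeneity → exp(−s²/2) for suitabilities ~ lognormal(0, s²).
Realised homogeneity therefore inherits sampling noise, as in an
observational design.

The default gradients place the dietary contrast on evenness (α from 0.15
to 2.0) and regularity (λ from 6 to 0) with prey-pool size constant, so
richness (dR) stays roughly flat across species while dRER varies — the
configuration in which a planted dRER–homogeneity coupling does not leak
into richness. The power analysis of the end-to-end dissociation uses a
sharper version of this condition (α fixed at 0.6, λ from 8 to 0).

**What the generator does not emulate:** sequence-level errors and chimeras
(QC input is already an OTU table), PCR amplification bias between taxa,
topological tree uncertainty (only branch lengths are jittered), spatial
autocorrelation within rasters, and any covariance between diet and space
other than the single planted coupling. Passing tests therefore demonstrate
correctness of the *computations* and recoverability of a planted signal
under multinomial sampling noise — not that real bat data satisfy the
model's assumptions.

## Problem sizes used by the tests

Unit tests run on small fixtures (≤ 150 OTUs, ≤ 6 individuals). The
end-to-end dissociation check runs 100 pipeline replicates at 50 species,
500 OTUs, 6 individuals/species, one primer, 5 tree draws and ~12k reads
per replicate; the mixed-model calibration check runs 200 fits at 100
species × 8 draws, with the ±2 SE band computed from the planted (known)
variance components. The richness-recovery check uses collapsed depths
near 50k reads with 10% dropout and active contamination. These sizes are
the package's own choices for a fast, deterministic suite; all stochastic
tests are seeded.

## Known limitations

* The LMM convention (REML, Wald t with n−2 df, Nakagawa R²) is one of
  several defensible small-sample conventions; estimates are cross-checked
  against `lme4` in the suite, p-value conventions differ across tools.
* Blank removal zeroes an OTU across the whole batch, which can discard
  genuine prey shared with a contaminated blank; this is the standard
  conservative rule, not an error model.
* Spatial metrics treat cells as exchangeable; no projection, area
  weighting, or adjacency is used.
* The incidence mode equalises detected OTUs within a sample, so
  sequencing-depth differences translate into richness differences only.
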