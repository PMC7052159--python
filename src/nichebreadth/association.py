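"""Linear-model and mixed-model associations between dietary and spatial metrics.

Species-level data with a single value per species are related by ordinary
least squares (LM).  Metrics carrying pseudoreplication across posterior tree
draws (dRER) enter a linear mixed model (LMM), fitted by REML, with the
draw-level dietary breadth as the pseudoreplicated response, the species-level
metric as fixed-effect predictor, and species as random intercept.  (The
reverse orientation — a response constant within species — is degenerate:
zero slope plus species intercepts fits it perfectly, so the draw-level
metric must sit on the response side.)
Mixed-model fit quality is summarised by Nakagawa-style variance-explained
ratios:

    r2_marginal    = Var_fixed / (Var_fixed + Var_random + Var_resid)
    r2_conditional = (Var_fixed + Var_random) / (same denominator)

p-values for the LMM fixed effect use the Wald t statistic referred to a t
distribution with n_species - 2 degrees of freedom — the between-species
information, one species slot spent on each of intercept and slope.  (A
likelihood-ratio test against the intercept-only model is ill-posed for this
design: the response is constant within species, so the null model's
residual variance collapses and its likelihood diverges.)  When the
random-intercept variance collapses to zero, the fit falls back to an LM on
species means, with a warning recorded on the result.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesRecord",
    "AssociationResult",
    "fit_lm",
    "fit_lmm",
    "average_primers",
    "run_contrast_battery",
]

SIGNIFICANCE_LEVEL = 0.05

# metrics a SpeciesRecord can carry; dRER is stored as all tree draws
_SCALAR_METRICS = (
    "dR",
    "dRE",
    "levins",
    "alpha",
    "turnover",
    "hunting_breadth",
    "habitat_breadth",
    "roosting_breadth",
    "potential_range_cells",
    "recognised_range_area",
    "homogeneity",
)


@dataclasses.dataclass
class SpeciesRecord:
    """Per-species metric bundle entering the association stage."""

    species: str
    dR: float | None = None
    dRE: float | None = None
    dRER_draws: np.ndarray | None = None
    levins: float | None = None
    alpha: float | None = None
    turnover: float | None = None
    hunting_breadth: float | None = None
    habitat_breadth: float | None = None
    roosting_breadth: float | None = None
    potential_range_cells: float | None = None
    recognised_range_area: float | None = None
    homogeneity: float | None = None
    primer: str | None = None
    single_primer: bool = False

    @property
    def dRER(self) -> float | None:
        if self.dRER_draws is None:
            return None
        return float(np.mean(self.dRER_draws))


@dataclasses.dataclass
class AssociationResult:
    """A fitted LM or LMM contrast."""

    contrast: str
    model: str  # "LM" or "LMM"
    response: str
    predictor: str
    estimate: float
    stat: float  # F for LM, t for LMM
    stat_name: str
    df: tuple
    p: float
    r2: float | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    n: int = 0
    note: str | None = None

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


def fit_lm(x, y, contrast: str = "", response: str = "y",
           predictor: str = "x") -> AssociationResult:
    """Ordinary least squares y ~ x on one value per species."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 species for an LM (got {n})")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationResult(
        contrast=contrast,
        model="LM",
        response=response,
        predictor=predictor,
        estimate=float(fit.params[1]),
        stat=float(fit.fvalue),
        stat_name="F",
        df=(1, n - 2),
        p=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        n=n,
    )


def _lmm_arrays(y_draws, x, species):
    y_draws = np.asarray(y_draws, dtype=float)
    x = np.asarray(x, dtype=float)
    if y_draws.ndim != 2:
        raise ValueError("y_draws must be (n_species, n_draws)")
    n_species, n_draws = y_draws.shape
    if x.size != n_species:
        raise ValueError("x must hold one value per species")
    if n_species < 3 or n_draws < 2:
        raise ValueError(
            f"LMM needs >=3 species and >=2 draws (got {n_species}, {n_draws})"
        )
    if species is None:
        species = [f"sp{i}" for i in range(n_species)]
    yy = y_draws.ravel()
    xx = np.repeat(x, n_draws)
    groups = np.repeat(np.asarray(species, dtype=object), n_draws)
    return yy, xx, groups, n_species


def fit_lmm(y_draws, x, species=None, contrast: str = "",
            response: str = "y", predictor: str = "x") -> AssociationResult:
    """Random-intercept LMM: draw-level response against species-level predictor.

    ``y_draws`` is an (n_species, n_draws) array of posterior-draw response
    values (the pseudoreplicated metric, e.g. dRER); ``x`` holds one
    predictor value per species, replicated across its draws.
    """
    yy, xx, groups, n_species = _lmm_arrays(y_draws, x, species)
    exog = sm.add_constant(xx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(yy, exog, groups=groups)
        fit = model.fit(reml=True)
        var_u = float(np.asarray(fit.cov_re)[0, 0])
        var_e = float(fit.scale)
        singular = not np.isfinite(var_u) or var_u <= 1e-10 * max(var_e, 1e-300)
        if singular:
            means = y_draws.mean(axis=1)
            res = fit_lm(np.asarray(x, dtype=float), means, contrast=contrast,
                         response=response, predictor=predictor)
            res.note = "singular random-intercept variance; fell back to LM"
            return res
        slope = float(fit.params[1])
        tval = float(fit.tvalues[1])
        var_f = float(np.var(slope * xx))
        denom = var_f + var_u + var_e
        # Wald t with between-species df; a full-vs-null LR test is ill-posed
        # here because the intercept-only model's residual variance collapses
        # when the response is constant within species
        p = float(2.0 * stats.t.sf(abs(tval), df=n_species - 2))
    return AssociationResult(
        contrast=contrast,
        model="LMM",
        response=response,
        predictor=predictor,
        estimate=slope,
        stat=tval,
        stat_name="t",
        df=(n_species - 2,),
        p=p,
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + var_u) / denom,
        n=n_species,
    )


def average_primers(records) -> SpeciesRecord:
    """Average one species' per-primer records into a single record.

    Scalar metrics are averaged arithmetically; dRER draws are averaged
    draw-wise (draw k of one primer with draw k of the other), preserving the
    dispersion across tree draws.  A species present in only one primer
    dataset passes through flagged.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to average")
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"records mix species: {sorted(species)}")
    if len(records) == 1:
        out = dataclasses.replace(records[0], primer=None, single_primer=True)
        return out
    merged = SpeciesRecord(species=records[0].species, primer=None)
    for metric in _SCALAR_METRICS:
        vals = [getattr(r, metric) for r in records]
        if all(v is not None for v in vals):
            setattr(merged, metric, float(np.mean(vals)))
    draws = [r.dRER_draws for r in records]
    if all(d is not None for d in draws):
        sizes = {len(d) for d in draws}
        if len(sizes) != 1:
            raise ValueError(f"mismatched dRER draw counts across primers: {sizes}")
        merged.dRER_draws = np.mean(np.vstack(draws), axis=0)
    return merged


# ---------------------------------------------------------------------------
# the standard contrast battery
# ---------------------------------------------------------------------------

# (contrast name, model, response metric, predictor metric); in LMM rows the
# response "dRER" is the full draw matrix, as an LM variable the draw mean
_CONTRASTS = [
    ("recognised_vs_potential_range", "LM", "recognised_range_area",
     "potential_range_cells"),
    ("homogeneity_vs_recognised_range", "LM", "homogeneity",
     "recognised_range_area"),
    ("dRER_vs_recognised_range", "LMM", "dRER", "recognised_range_area"),
    ("dR_vs_homogeneity", "LM", "dR", "homogeneity"),
    ("dRER_vs_homogeneity", "LMM", "dRER", "homogeneity"),
    ("alpha_vs_dRER", "LM", "alpha", "dRER"),
    ("turnover_vs_dRER", "LM", "turnover", "dRER"),
    ("turnover_vs_homogeneity", "LM", "turnover", "homogeneity"),
    ("hunting_vs_dRER", "LMM", "dRER", "hunting_breadth"),
    ("habitat_vs_dRER", "LMM", "dRER", "habitat_breadth"),
    ("roosting_vs_dRER", "LMM", "dRER", "roosting_breadth"),
    ("hunting_vs_recognised_range", "LM", "hunting_breadth",
     "recognised_range_area"),
    ("habitat_vs_recognised_range", "LM", "habitat_breadth",
     "recognised_range_area"),
    ("roosting_vs_recognised_range", "LM", "roosting_breadth",
     "recognised_range_area"),
    ("hunting_vs_homogeneity", "LM", "hunting_breadth", "homogeneity"),
    ("habitat_vs_homogeneity", "LM", "habitat_breadth", "homogeneity"),
    ("roosting_vs_homogeneity", "LM", "roosting_breadth", "homogeneity"),
]


def _metric_vector(records, metric):
    if metric == "dRER":
        vals = [r.dRER for r in records]
    else:
        vals = [getattr(r, metric) for r in records]
    if any(v is None for v in vals):
        return None
    return np.asarray(vals, dtype=float)


def run_contrast_battery(records) -> list[AssociationResult]:
    """Run the full association battery on a set of species records.

    Contrasts whose metrics are missing are skipped with a log entry; each
    returned result carries its model type, statistic, df, p and R² fields.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError(
            f"association battery needs at least 3 species (got {len(records)})"
        )
    species = [r.species for r in records]
    results = []
    for name, model, resp, pred in _CONTRASTS:
        x = _metric_vector(records, pred)
        if model == "LMM":
            draws = [r.dRER_draws for r in records]
            if x is None or any(d is None for d in draws):
                logger.info("contrast %s skipped: missing metric", name)
                continue
            res = fit_lmm(np.vstack(draws), x, species=species, contrast=name,
                          response=resp, predictor=pred)
        else:
            y = _metric_vector(records, resp)
            if x is None or y is None:
                logger.info("contrast %s skipped: missing metric", name)
                continue
            res = fit_lm(x, y, contrast=name, response=resp, predictor=pred)
        results.append(res)
    return results
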