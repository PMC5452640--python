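"""The six end-to-end genomic-prediction approaches and the predictive ability.

All approaches map a training set of plot data plus a coded marker matrix to
GEBVs for a validation set that shares no genotypes with the training set
(forward validation):

A1   year-wise adjusted means per disconnected year, genomic-prediction fit
     with fixed year effects and marker main effects only.
A1K  as A1 plus a block-diagonal marker-by-year term in the GP fit, so
     genotype-by-year signal is absorbed by kinship instead of leaking into
     the GEBVs; needs at least two training years.
A2   two-stage: one fit of all stage-one means with tester fixed, marker
     main effects, marker-by-year, and identity components for the other
     between-year effects.
A3   as A2 with one genotype-by-year variance per year (heterogeneous).
A4   three-stage: across-year adjusted genotype means with identity
     genotype-by-year, then an intercept-plus-markers GP fit.
A5   as A4 but the across-year means use marker kinship for genotype-by-year.

GEBVs always come from the marker main-effect block alone (``v = Z u_g``);
predicted genotype-by-year effects never enter a prediction for an unseen
year.  Predictive ability is the Pearson correlation between GEBVs and the
validation set's adjusted means, with a Fisher-z 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedmodel import ModelSpec, RandomTerm, reml_fit, gebv
from .stages import (
    stage1_all,
    yearwise_stage2_means,
    across_years_means_fixedG,
    across_years_means_kinshipGY,
    ACROSS_YEARS_IDENTITY_TERMS,
)

__all__ = [
    "PredictionResult",
    "approach_A1",
    "approach_A1K",
    "approach_A2",
    "approach_A3",
    "approach_A4",
    "approach_A5",
    "run_approach",
    "predictive_ability",
    "APPROACHES",
]


@dataclass
class PredictionResult:
    approach: str
    gebv: pd.Series
    rho_gp: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    n_pairs: int = 0
    fit_meta: dict = field(default_factory=dict)


def _check_forward(ts_plots: pd.DataFrame, vs_ids) -> None:
    overlap = set(ts_plots["genotype"].astype(str)) & set(map(str, vs_ids))
    if overlap:
        raise ValueError(
            f"forward-validation violation: VS genotypes present in TS: {sorted(overlap)[:10]}")


def _check_markers(Z: pd.DataFrame, ids) -> None:
    missing = sorted(set(map(str, ids)) - set(map(str, Z.index)))
    if missing:
        raise KeyError(f"genotypes without marker rows: {missing[:10]}")


def _meta(*fits):
    return {
        "variance_components": [f.variance_components for f in fits],
        "converged": all(f.converged for f in fits),
        "warnings": sum((f.warnings for f in fits), []),
    }


def _finish(name, fit, Z, vs_ids, vs_m2, extra_fits=()):
    v = gebv(fit, Z, pd.Index(vs_ids))
    res = PredictionResult(approach=name, gebv=v, fit_meta=_meta(fit, *extra_fits))
    if vs_m2 is not None:
        rho, ci, n = predictive_ability(v, vs_m2)
        res.rho_gp, res.ci95, res.n_pairs = rho, ci, n
    return res


def _yearwise_m2(ts_plots):
    m1 = stage1_all(ts_plots)
    out, fits = [], []
    for yr in sorted(m1["year"].unique()):
        m2y, fy = yearwise_stage2_means(m1, yr)
        out.append(m2y)
        fits.append(fy)
    return pd.concat(out, ignore_index=True), fits, m1


def approach_A1(ts_plots, Z, vs_ids, vs_m2=None) -> PredictionResult:
    """Year-wise means, then GP with fixed year effects and marker main effects."""
    _check_forward(ts_plots, vs_ids)
    _check_markers(Z, list(ts_plots["genotype"].unique()) + list(vs_ids))
    m2, fits, _ = _yearwise_m2(ts_plots)
    spec = ModelSpec(response="value", fixed=[("year",)],
                     random=[RandomTerm(structure="marker")],
                     weights="weight", markers=Z)
    fit = reml_fit(spec, m2)
    return _finish("A1", fit, Z, vs_ids, vs_m2, fits)


def approach_A1K(ts_plots, Z, vs_ids, vs_m2=None) -> PredictionResult:
    """A1 plus a marker-by-year kinship term; needs >= 2 disconnected training years."""
    _check_forward(ts_plots, vs_ids)
    _check_markers(Z, list(ts_plots["genotype"].unique()) + list(vs_ids))
    if ts_plots["year"].nunique() < 2:
        raise ValueError("A1K needs at least two training years: with a single year "
                         "a genotype-by-year effect over-parametrizes the model")
    m2, fits, _ = _yearwise_m2(ts_plots)
    spec = ModelSpec(response="value", fixed=[("year",)],
                     random=[RandomTerm(structure="marker"),
                             RandomTerm(structure="marker_by_year_hom")],
                     weights="weight", markers=Z)
    fit = reml_fit(spec, m2)
    return _finish("A1K", fit, Z, vs_ids, vs_m2, fits)


def _two_stage_fit(ts_plots, Z, het: bool):
    m1 = stage1_all(ts_plots)
    if m1["year"].nunique() < 2:
        raise ValueError("the across-years approaches need at least two training years")
    gy = RandomTerm(structure="marker_by_year_het" if het else "marker_by_year_hom")
    terms = [RandomTerm(structure="marker"), gy]
    terms += [RandomTerm(f) for f in ACROSS_YEARS_IDENTITY_TERMS
              if f != ("genotype", "year")]
    spec = ModelSpec(response="value", fixed=[("tester",)], random=terms,
                     weights="weight", markers=Z)
    return reml_fit(spec, m1)


def approach_A2(ts_plots, Z, vs_ids, vs_m2=None) -> PredictionResult:
    """Two-stage fit of all stage-one means; genotype-by-year via kinship."""
    _check_forward(ts_plots, vs_ids)
    _check_markers(Z, list(ts_plots["genotype"].unique()) + list(vs_ids))
    fit = _two_stage_fit(ts_plots, Z, het=False)
    return _finish("A2", fit, Z, vs_ids, vs_m2)


def approach_A3(ts_plots, Z, vs_ids, vs_m2=None) -> PredictionResult:
    """A2 with one genotype-by-year variance per year."""
    _check_forward(ts_plots, vs_ids)
    _check_markers(Z, list(ts_plots["genotype"].unique()) + list(vs_ids))
    fit = _two_stage_fit(ts_plots, Z, het=True)
    return _finish("A3", fit, Z, vs_ids, vs_m2)


def _gp_intercept_markers(m2, Z):
    spec = ModelSpec(response="value", fixed=[],
                     random=[RandomTerm(structure="marker")],
                     weights="weight", markers=Z)
    return reml_fit(spec, m2)


def approach_A4(ts_plots, Z, vs_ids, vs_m2=None) -> PredictionResult:
    """Three-stage without kinship for genotype-by-year: across-year means, then
    an intercept-plus-markers GP fit."""
    _check_forward(ts_plots, vs_ids)
    _check_markers(Z, list(ts_plots["genotype"].unique()) + list(vs_ids))
    m1 = stage1_all(ts_plots)
    if m1["year"].nunique() < 2:
        raise ValueError("the across-years approaches need at least two training years")
    m2, f2 = across_years_means_fixedG(m1)
    fit = _gp_intercept_markers(m2, Z)
    return _finish("A4", fit, Z, vs_ids, vs_m2, (f2,))


def approach_A5(ts_plots, Z, vs_ids, vs_m2=None) -> PredictionResult:
    """Three-stage with marker kinship on genotype-by-year in the second stage."""
    _check_forward(ts_plots, vs_ids)
    _check_markers(Z, list(ts_plots["genotype"].unique()) + list(vs_ids))
    m1 = stage1_all(ts_plots)
    if m1["year"].nunique() < 2:
        raise ValueError("the across-years approaches need at least two training years")
    m2, f2 = across_years_means_kinshipGY(m1, Z)
    fit = _gp_intercept_markers(m2, Z)
    return _finish("A5", fit, Z, vs_ids, vs_m2, (f2,))


APPROACHES = {
    "A1": approach_A1,
    "A1K": approach_A1K,
    "A2": approach_A2,
    "A3": approach_A3,
    "A4": approach_A4,
    "A5": approach_A5,
}


def run_approach(name, ts_plots, Z, vs_ids, vs_m2=None) -> PredictionResult:
    if name not in APPROACHES:
        raise KeyError(f"unknown approach {name!r}; choose from {sorted(APPROACHES)}")
    return APPROACHES[name](ts_plots, Z, vs_ids, vs_m2)


def predictive_ability(gebv_values: pd.Series, vs_m2) -> tuple:
    """Pearson correlation between GEBVs and validation-set adjusted means.

    ``vs_m2`` may be a GenotypeMeans frame (level-2 rows) or a Series indexed
    by genotype.  Returns ``(rho, (lo, hi), n)``; fewer than three matched
    pairs or a zero-variance vector yields NaN.
    """
    if isinstance(vs_m2, pd.DataFrame):
        vs = vs_m2[vs_m2["level"] == 2].set_index("genotype")["value"]
    else:
        vs = vs_m2
    gv = gebv_values.copy()
    gv.index = gv.index.map(str)
    vs = vs.copy()
    vs.index = vs.index.map(str)
    common = gv.index.intersection(vs.index)
    n = len(common)
    if n < 3:
        return np.nan, (np.nan, np.nan), n
    a, b = gv[common].to_numpy(), vs[common].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, (np.nan, np.nan), n
    rho = float(np.corrcoef(a, b)[0, 1])
    if n > 3 and abs(rho) < 1:
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    else:
        lo, hi = -1.0, 1.0
    return rho, (float(lo), float(hi)), n
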