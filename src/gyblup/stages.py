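"""Stage models: plot data -> adjusted genotype-by-tester means m1 -> genotype means m2.

Stage one fits each year-location combination separately: genotype-by-tester
cell means are fixed, the trial / replicate / incomplete-block hierarchy is
random, and the adjusted means leave with Smith weights (diagonal of the
inverse of their covariance).  Stage two combines the m1 rows either within
one year (year-wise), or across years with genotype fixed (with or without
the marker-kinship structure on the genotype-by-year term), always carrying
the stage-one weights as fixed residual weights.

The printed year-wise second-stage model carries no location main effect
(locations enter only through their interactions); the validation-set model
does include it.  Both are implemented exactly as printed, and
``include_L_main`` lets callers override the year-wise default.

Adjusted-means tables (``GenotypeMeans``) are plain DataFrames with columns
``level, genotype, tester, year, location, value, weight, provenance``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixedmodel import ModelSpec, RandomTerm, reml_fit, smith_weights

__all__ = [
    "stage1_means",
    "stage1_all",
    "yearwise_stage2_means",
    "across_years_means_fixedG",
    "across_years_means_kinshipGY",
    "vs_means",
]

MEANS_COLUMNS = ["level", "genotype", "tester", "year", "location",
                 "value", "weight", "provenance"]


def _means_frame(level, rows, provenance):
    df = pd.DataFrame(rows, columns=["genotype", "tester", "year", "location",
                                     "value", "weight"])
    df.insert(0, "level", level)
    df["provenance"] = provenance
    return df[MEANS_COLUMNS]


def stage1_means(plots: pd.DataFrame, year=None, location=None,
                 response: str = "yield") -> pd.DataFrame:
    """Adjusted genotype-by-tester means for one year-location combination.

    Fixed genotype-by-tester cells; random trial, replicate-within-trial and
    block-within-replicate.  Degenerate hierarchies (single trial, saturated
    designs) collapse gracefully.
    """
    df = plots
    if year is not None:
        df = df[df["year"] == year]
    if location is not None:
        df = df[df["location"] == location]
    if df.empty:
        raise ValueError(f"no plots for year={year!r}, location={location!r}")
    if df["year"].nunique() > 1 or df["location"].nunique() > 1:
        raise ValueError("stage1_means expects a single year-location combination")
    yr = df["year"].iloc[0]
    loc = df["location"].iloc[0]

    spec = ModelSpec(
        response=response,
        mean_term=("genotype", "tester"),
        fixed=[],
        random=[RandomTerm(("trial",)),
                RandomTerm(("trial", "replicate")),
                RandomTerm(("trial", "replicate", "block"))],
    )
    fit = reml_fit(spec, df)
    means = fit.adjusted_means()
    try:
        w = smith_weights(fit)
    except ValueError:
        # saturated stage: fall back to replicate counts
        counts = df.groupby(["genotype", "tester"]).size()
        w = pd.Series([counts.get(tuple(l.split("¦")), 1) for l in means.index],
                      index=means.index, dtype=float)
    rows = []
    for label, value in means.items():
        g, t = label.split("¦")
        rows.append((g, t, yr, loc, value, float(w[label])))
    return _means_frame(1, rows, "stage1")


def stage1_all(plots: pd.DataFrame, response: str = "yield") -> pd.DataFrame:
    """Stage-one driver: iterate all year-location combinations and stack the means."""
    out = []
    for (yr, loc), _ in plots.groupby(["year", "location"]):
        out.append(stage1_means(plots, yr, loc, response=response))
    return pd.concat(out, ignore_index=True)


def _fit_stage2(m1, random_terms, provenance, markers=None, year_key=None):
    spec = ModelSpec(
        response="value",
        mean_term=("genotype",),
        fixed=[("tester",)],
        random=random_terms,
        weights="weight",
        markers=markers,
    )
    fit = reml_fit(spec, m1)
    means = fit.adjusted_means()
    try:
        w = smith_weights(fit)
    except ValueError:
        w = pd.Series(1.0, index=means.index)
    rows = [(g, None, year_key, None, v, float(w[g])) for g, v in means.items()]
    return _means_frame(2, rows, provenance), fit


def yearwise_stage2_means(m1: pd.DataFrame, year=None, include_L_main: bool = False):
    """Per-year adjusted genotype means from m1 rows of a single year.

    Genotype and tester fixed; genotype-by-tester and the location
    interactions random; stage-one weights as residual weights.  The printed
    model omits a location main effect; ``include_L_main=True`` adds it.
    """
    df = m1[m1["level"] == 1]
    if year is not None:
        df = df[df["year"] == year]
    if df.empty:
        raise ValueError(f"no stage-1 means for year {year!r}")
    if df["year"].nunique() > 1:
        raise ValueError("yearwise_stage2_means expects a single year")
    yr = df["year"].iloc[0]
    terms = [RandomTerm(("genotype", "tester"))]
    if include_L_main:
        terms.append(RandomTerm(("location",)))
    terms += [RandomTerm(("location", "genotype")),
              RandomTerm(("location", "tester")),
              RandomTerm(("location", "genotype", "tester"))]
    means, fit = _fit_stage2(df, terms, "yearwise", year_key=yr)
    return means, fit


ACROSS_YEARS_IDENTITY_TERMS = [
    ("year",), ("location",), ("genotype", "year"), ("genotype", "location"),
    ("year", "location"), ("genotype", "year", "location"),
    ("genotype", "tester"), ("tester", "year"), ("tester", "location"),
    ("genotype", "tester", "year"), ("genotype", "tester", "location"),
    ("tester", "year", "location"), ("genotype", "tester", "year", "location"),
]


def across_years_means_fixedG(m1: pd.DataFrame):
    """Adjusted genotype means across years and locations, genotype fixed.

    All between-year effects random with identity structure, including
    genotype-by-year.  For disconnected years the genotype-by-year component
    is aliased with the fixed genotype means; the fit still succeeds and the
    component sits at zero with a warning.
    """
    df = m1[m1["level"] == 1]
    if df.empty:
        raise ValueError("no stage-1 means supplied")
    terms = [RandomTerm(f) for f in ACROSS_YEARS_IDENTITY_TERMS]
    return _fit_stage2(df, terms, "acrossyears-fixedG")


def across_years_means_kinshipGY(m1: pd.DataFrame, Z: pd.DataFrame):
    """As :func:`across_years_means_fixedG` with marker kinship on genotype-by-year.

    The genotype-by-year term carries the block-diagonal marker-by-year
    structure; every phenotyped genotype must have a marker row.
    """
    df = m1[m1["level"] == 1]
    if df.empty:
        raise ValueError("no stage-1 means supplied")
    missing = sorted(set(df["genotype"].astype(str)) - set(map(str, Z.index)))
    if missing:
        raise KeyError(f"genotypes without marker rows: {missing}")
    terms = [RandomTerm(f) for f in ACROSS_YEARS_IDENTITY_TERMS
             if f != ("genotype", "year")]
    terms.append(RandomTerm(structure="marker_by_year_hom"))
    return _fit_stage2(df, terms, "acrossyears-kinshipGY", markers=Z)


def _testers_locations_confounded(df: pd.DataFrame) -> bool:
    """Total tester-location confounding: no location carries more than one tester."""
    if df["location"].nunique() == 1:
        return True
    per_loc = df.groupby("location")["tester"].nunique()
    return bool((per_loc <= 1).all())


def vs_means(plots_vs: pd.DataFrame, confounded_tester_location: bool | None = None,
             response: str = "yield"):
    """Validation-set adjusted genotype means for one year of plot data.

    Uses the full location model unless testers and locations are totally
    confounded, in which case the location main effect and genotype-by-
    location are absorbed into the tester-by-location terms.  Auto-detection
    of total confounding overrides the flag.
    """
    if plots_vs["year"].nunique() != 1:
        raise ValueError("vs_means expects one validation year of plot data")
    yr = plots_vs["year"].iloc[0]
    m1 = stage1_all(plots_vs, response=response)
    detected = _testers_locations_confounded(m1)
    use_confounded = detected if confounded_tester_location is None else confounded_tester_location
    warn = None
    if detected and not use_confounded:
        warn = ("testers and locations are totally confounded; "
                "the reduced model overrides the flag")
        use_confounded = True
    if use_confounded:
        terms = [RandomTerm(("genotype", "tester")),
                 RandomTerm(("location", "tester")),
                 RandomTerm(("genotype", "tester", "location"))]
        prov = "vs-confounded"
    else:
        terms = [RandomTerm(("genotype", "tester")),
                 RandomTerm(("location",)),
                 RandomTerm(("location", "genotype")),
                 RandomTerm(("location", "tester")),
                 RandomTerm(("location", "genotype", "tester"))]
        prov = "vs"
    means, fit = _fit_stage2(m1, terms, prov, year_key=yr)
    if warn:
        fit.warnings.append(warn)
    return means, fit
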