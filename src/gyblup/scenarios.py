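"""Training/validation scenario construction and approach x scenario grids.

A scenario names the training-set composition as (stage, year) slices of the
plot table (a "control" scenario keeps only first-stage GCA1 slices, whose
years share no genotypes), the validation slice (one GCA1 year), an optional
relatedness filter on the validation genotypes (all / no parent in TS /
exactly one parent in TS), an optional top-yield fraction restricting the
training set to the best-performing genotypes, and a repeated-sampling rule
fixing the validation-set size across relatedness scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .approaches import run_approach
from .stages import across_years_means_fixedG, stage1_all, vs_means

__all__ = [
    "Scenario",
    "build_training_set",
    "relatedness_filter",
    "top_yield_filter",
    "sample_validation_draws",
    "run_grid",
]


@dataclass
class Scenario:
    name: str
    ts_composition: list  # [(stage, year), ...]
    vs_slice: tuple  # (stage, year)
    control: bool = False
    relatedness: str = "All"  # All | 0P | 1P
    top_fraction: float = 1.0
    vs_size: int | None = None
    iterations: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.relatedness not in ("All", "0P", "1P"):
            raise ValueError("relatedness must be All, 0P or 1P")
        ts_years = {y for _, y in self.ts_composition}
        if self.control and self.vs_slice[1] in ts_years:
            raise ValueError("control scenario: VS year must not appear in the TS")


def build_training_set(plots: pd.DataFrame, composition, control: bool = False):
    """Union of (stage, year) slices; control scenarios keep only GCA1 slices.

    Returns ``(subset, overlap)`` where ``overlap`` counts shared genotypes
    between every pair of years in the result.
    """
    parts = []
    for sl in composition:
        stage, year = sl[-2], sl[-1]  # accept (cycle, stage, year) too
        if control and stage != "GCA1":
            continue
        sub = plots[(plots["stage"] == stage) & (plots["year"] == year)]
        if sub.empty:
            raise ValueError(f"empty training-set slice: stage={stage}, year={year}")
        parts.append(sub)
    if not parts:
        raise ValueError("training-set composition selected no slices")
    ts = pd.concat(parts).drop_duplicates()
    by_year = ts.groupby("year")["genotype"].apply(set)
    years = list(by_year.index)
    overlap = {}
    for i, a in enumerate(years):
        for b in years[i + 1:]:
            overlap[(a, b)] = len(by_year[a] & by_year[b])
    return ts, overlap


def relatedness_filter(vs_ids, ts_ids, pedigree: pd.DataFrame, mode: str = "All"):
    """Restrict validation genotypes by parent count in the training set.

    ``0P``: neither parent in the TS genotype set; ``1P``: exactly one.
    Validation genotypes with unknown parents are excluded from 0P/1P with a
    warning list (second return value).
    """
    vs_ids = [str(g) for g in vs_ids]
    if mode == "All":
        return list(vs_ids), []
    ts_set = set(map(str, ts_ids))
    ped = pedigree.set_index(pedigree["genotype"].astype(str))
    unknown, keep = [], []
    for g in vs_ids:
        if g not in ped.index:
            unknown.append(g)
            continue
        p1, p2 = ped.loc[g, "parent1"], ped.loc[g, "parent2"]
        if p1 is None or p2 is None or (isinstance(p1, float) and math.isnan(p1)):
            unknown.append(g)
            continue
        n_in = int(str(p1) in ts_set) + int(str(p2) in ts_set)
        if (mode == "0P" and n_in == 0) or (mode == "1P" and n_in == 1):
            keep.append(g)
    return keep, unknown


def top_yield_filter(ts_plots: pd.DataFrame, fraction: float,
                     ranking_means: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Keep plots of the best-yielding ``ceil(fraction * n)`` genotypes.

    Ties at the cut are all retained.  ``ranking_means`` must cover every
    training-set genotype (Series indexed by genotype, or a GenotypeMeans
    frame).
    """
    if fraction <= 0:
        raise ValueError("fraction must be > 0")
    if fraction >= 1:
        return ts_plots
    if isinstance(ranking_means, pd.DataFrame):
        ranking_means = ranking_means.set_index("genotype")["value"]
    ranking_means = ranking_means.copy()
    ranking_means.index = ranking_means.index.map(str)
    genos = ts_plots["genotype"].astype(str).unique()
    missing = sorted(set(genos) - set(ranking_means.index))
    if missing:
        raise KeyError(f"ranking means missing for genotypes: {missing[:10]}")
    n_keep = math.ceil(fraction * len(genos))
    ranks = ranking_means[genos].sort_values(ascending=False)
    cut = ranks.iloc[n_keep - 1]
    keep = set(ranks[ranks >= cut].index)  # ties at the cut survive
    return ts_plots[ts_plots["genotype"].astype(str).isin(keep)]


def sample_validation_draws(vs_ids, size: int = 100, iterations: int = 10, seed: int = 0):
    """Simple random samples without replacement, fixing VS size across scenarios.

    If fewer ids than ``size`` are available every draw is the full set (the
    under-sized fallback)."""
    vs_ids = list(vs_ids)
    rng = np.random.default_rng(seed)
    if size >= len(vs_ids):
        return [list(vs_ids) for _ in range(iterations)]
    return [list(rng.choice(vs_ids, size=size, replace=False)) for _ in range(iterations)]


def _rank_means(ts_plots):
    m1 = stage1_all(ts_plots)
    if m1["year"].nunique() < 2:
        from .stages import yearwise_stage2_means
        m2, _ = yearwise_stage2_means(m1)
    else:
        m2, _ = across_years_means_fixedG(m1)
    return m2.set_index("genotype")["value"]


def run_grid(scenarios, approaches, plots, Z, pedigree) -> pd.DataFrame:
    """Evaluate each scenario x approach x draw; failures become NA rows.

    Returns the result table (one row per draw plus per-cell summary rows
    with the mean predictive ability and an across-draw 95% t-interval).
    """
    rows = []
    for sc in scenarios:
        try:
            ts, _ = build_training_set(plots, sc.ts_composition, sc.control)
            if sc.top_fraction < 1:
                ts = top_yield_filter(ts, sc.top_fraction, _rank_means(ts))
            vs_stage, vs_year = sc.vs_slice
            vsp = plots[(plots["stage"] == vs_stage) & (plots["year"] == vs_year)]
            if vsp.empty:
                raise ValueError(f"empty validation slice {sc.vs_slice}")
            vs_all = sorted(set(vsp["genotype"].astype(str)) -
                            set(ts["genotype"].astype(str)))
            vs_ids, _ = relatedness_filter(vs_all, ts["genotype"].unique(),
                                           pedigree, sc.relatedness)
            m2vs, _ = vs_means(vsp[vsp["genotype"].astype(str).isin(set(vs_ids))]
                               if sc.relatedness != "All" else vsp)
            draws = sample_validation_draws(
                vs_ids, sc.vs_size or len(vs_ids), sc.iterations, sc.seed)
        except Exception as exc:  # scenario-level failure: NA rows for all cells
            for ap in approaches:
                rows.append((sc.name, ap, "summary", np.nan, np.nan, np.nan, np.nan,
                             f"error: {exc}"))
            continue
        for ap in approaches:
            rhos = []
            for i, draw in enumerate(draws):
                try:
                    res = run_approach(ap, ts, Z, draw, m2vs)
                    rows.append((sc.name, ap, i, len(draw), res.rho_gp,
                                 res.ci95[0], res.ci95[1], "ok"))
                    rhos.append(res.rho_gp)
                except Exception as exc:
                    rows.append((sc.name, ap, i, len(draw), np.nan, np.nan, np.nan,
                                 f"error: {exc}"))
            vals = np.array([r for r in rhos if not np.isnan(r)])
            if vals.size:
                mean = vals.mean()
                if vals.size > 1 and vals.std(ddof=1) > 0:
                    hw = sps.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
                else:
                    hw = 0.0
                rows.append((sc.name, ap, "summary", np.nan, mean,
                             max(mean - hw, -1.0), min(mean + hw, 1.0), "ok"))
            else:
                rows.append((sc.name, ap, "summary", np.nan, np.nan, np.nan, np.nan,
                             "no successful draws"))
    return pd.DataFrame(rows, columns=["scenario", "approach", "draw", "n_vs",
                                       "rho_gp", "ci_low", "ci_high", "status"])
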