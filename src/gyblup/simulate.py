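"""Synthetic multi-cycle hybrid-breeding program generator.

Emulates the data structure the stage-wise analysis assumes: successive
selection cycles whose first-year (GCA1) trials are disconnected across
years, truncation selection advancing a fraction of candidates to GCA2 and
GCA3 in later years, testers shared within a cycle for GCA1/GCA2 and renewed
for GCA3 and for every new cycle, resolvable incomplete-block (alpha-design)
field layouts, and yields composed additively from genotype (marker-driven),
genotype-by-year (marker-driven, independent across years so the true
cross-year GY covariance is zero), location, tester and design effects plus
plot error.

The default variance components for G, GY, L, GL, YL and GYL (6.75, 0.58,
143.57, 1.11, 92.65, 3.83, all in (dt/ha)^2) are calibrated to magnitudes
estimated from commercial German hybrid rye yield trials; tester-related
variances have no comparable anchor and default to small fractions of the
genotypic variance.  The default program scale (three cycles of 300
genotypes, 500 markers) is deliberately reduced so a full program simulates
in seconds; a field-scale configuration is a matter of raising the counts.

No linkage map is modelled: offspring draw each marker independently from
one of the two parents.  The analysis models only consume marker
covariance, never recombination, so this loses nothing they can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProgramConfig",
    "DEFAULT_VARIANCES",
    "simulate_founders",
    "advance_cycle",
    "assign_field_design",
    "simulate_program",
    "simulate_crossed_trial",
]

STAGES = ("GCA1", "GCA2", "GCA3")

# G..GYL calibrated to the single-cycle German-program fit; tester terms unanchored
DEFAULT_VARIANCES = {
    "G": 6.75,
    "GY": 0.58,
    "L": 143.57,
    "GL": 1.11,
    "YL": 92.65,
    "GYL": 3.83,
    "T": 1.0,
    "GT": 0.5,
    "TY": 0.5,
    "TL": 0.5,
    "GTY": 0.5,
    "GTL": 0.5,
    "TYL": 0.5,
    "GTYL": 0.5,
    "trial": 1.0,
    "rep": 0.5,
    "block": 0.5,
    "plot_error": 12.0,
}


@dataclass
class ProgramConfig:
    n_cycles: int = 3
    genotypes_per_cycle: int = 300
    n_founders: int = 40
    markers: int = 500
    testers_per_stage: tuple = (1, 1, 2)
    locations_per_stage: tuple = (2, 3, 4)
    n_location_pool: int = 6
    advance_fractions: tuple = (0.10, 0.15)  # GCA1->GCA2, GCA2->GCA3 (product 1.5%)
    variance_components: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    replicates: int = 2
    blocks_per_replicate: int | None = None  # None: smallest count feasible for block_size
    block_size: tuple = (12, 16)
    founder_allele_freq: tuple = (0.2, 0.8)
    parent_recycle: float = 0.5  # prob. a parent is drawn from earlier-cycle lines
    first_year: int = 2009
    base_yield: float = 80.0
    program: str = "P1"
    gy_year_scale: dict = field(default_factory=dict)  # year -> multiplier on GY variance
    seed: int = 1

    def validate(self):
        if self.markers < 2:
            raise ValueError("need at least 2 markers")
        if not all(0 < f <= 1 for f in self.advance_fractions):
            raise ValueError("advance fractions must be in (0, 1]")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be non-negative")
        lo, hi = self.block_size
        if lo > hi or lo < 1:
            raise ValueError("invalid block size range")
        lo_f, hi_f = self.founder_allele_freq
        if not (0 < lo_f <= hi_f < 1):
            raise ValueError("founder allele frequency range must exclude fixation")
        return self


def simulate_founders(cfg: ProgramConfig, rng=None):
    """Fully inbred founder pool with per-marker allele frequencies from the configured range."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.founder_allele_freq
    freqs = rng.uniform(lo, hi, cfg.markers)
    calls = np.where(rng.random((cfg.n_founders, cfg.markers)) < freqs, 1, -1).astype(np.int8)
    ids = [f"F{i:03d}" for i in range(cfg.n_founders)]
    Z = pd.DataFrame(calls, index=ids, columns=[f"M{j:04d}" for j in range(cfg.markers)])
    ped = pd.DataFrame({"genotype": ids, "parent1": None, "parent2": None, "cycle": -1})
    return Z, ped


def advance_cycle(parent_Z: pd.DataFrame, parent_ids, n_offspring, cycle, rng, prefix="C"):
    """Inbred offspring: each marker drawn independently from parent1 or parent2 (no linkage)."""
    parent_ids = list(parent_ids)
    if len(parent_ids) < 2:
        raise ValueError("need at least two candidate parents")
    m = parent_Z.shape[1]
    ids, p1s, p2s = [], [], []
    calls = np.empty((n_offspring, m), dtype=np.int8)
    for i in range(n_offspring):
        p1, p2 = rng.choice(len(parent_ids), size=2, replace=False)
        a = parent_Z.loc[parent_ids[p1]].to_numpy()
        b = parent_Z.loc[parent_ids[p2]].to_numpy()
        pick = rng.random(m) < 0.5
        calls[i] = np.where(pick, a, b)
        ids.append(f"{prefix}{cycle}_{i:04d}")
        p1s.append(parent_ids[p1])
        p2s.append(parent_ids[p2])
    Z = pd.DataFrame(calls, index=ids, columns=parent_Z.columns)
    ped = pd.DataFrame({"genotype": ids, "parent1": p1s, "parent2": p2s, "cycle": cycle})
    return Z, ped


def assign_field_design(entries, cfg: ProgramConfig, rng) -> pd.DataFrame:
    """Resolvable alpha-type layout: every entry once per replicate, disjoint blocks per
    replicate, block sizes inside the configured range."""
    entries = list(entries)
    n = len(entries)
    lo, hi = cfg.block_size
    if cfg.blocks_per_replicate is not None:
        k = cfg.blocks_per_replicate
    else:
        k = max(1, -(-n // hi))  # ceil
    if not (k * lo <= n <= k * hi):
        if cfg.blocks_per_replicate is None and n < k * lo:
            pass  # small trials: blocks run under the configured minimum
        else:
            raise ValueError(
                f"design infeasible: {n} entries cannot fill {k} blocks of size {lo}..{hi}")
    rows = []
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    for rep in range(1, cfg.replicates + 1):
        order = rng.permutation(n)
        pos = 0
        for b, size in enumerate(sizes, start=1):
            for idx in order[pos:pos + size]:
                g, t = entries[idx]
                rows.append((g, t, rep, b))
            pos += size
    return pd.DataFrame(rows, columns=["genotype", "tester", "replicate", "block"])


class _EffectStore:
    """Lazily drawn iid effects keyed by factor-level tuples, one per variance component."""

    def __init__(self, variances, rng):
        self.var = variances
        self.rng = rng
        self.store = {name: {} for name in variances}
        self.scale = {}  # optional per-key variance multipliers

    def get(self, name, key, sd_scale=1.0):
        v = self.var.get(name, 0.0)
        if v <= 0:
            return 0.0
        d = self.store[name]
        if key not in d:
            d[key] = self.rng.normal(0.0, np.sqrt(v) * sd_scale)
        return d[key]


def simulate_program(cfg: ProgramConfig):
    """Full program: markers, pedigree, plot-level yields, and all true effects.

    Returns ``(plots, Z, pedigree, truth)`` where ``truth`` carries the true
    GEBV (``Z u_g``), the true marker effects ``u_g`` and per-year ``u_gy``,
    and the realized identity effects, for recovery testing.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vc = cfg.variance_components
    m = cfg.markers

    Zf, pedf = simulate_founders(cfg, rng)
    Z_all = [Zf]
    peds = [pedf]
    line_pool: list[str] = []  # earlier-cycle lines available as parents

    # marker-driven genetic main effects: var per genotype = m * var(u) = G
    u_g = rng.normal(0.0, np.sqrt(vc.get("G", 0.0) / m), m)
    u_gy: dict = {}

    effects = _EffectStore(
        {k: v for k, v in vc.items() if k not in ("G", "GY", "plot_error")}, rng)
    loc_pool = [f"L{i:02d}" for i in range(cfg.n_location_pool)]
    err_sd = np.sqrt(vc.get("plot_error", 0.0))

    plot_rows = []
    cycle_members: dict = {}

    def gy_effect(genotype_row, year):
        if vc.get("GY", 0.0) <= 0:
            return 0.0
        if year not in u_gy:
            scale = cfg.gy_year_scale.get(year, 1.0)
            u_gy[year] = rng.normal(0.0, np.sqrt(vc["GY"] * scale / m), m)
        return float(genotype_row @ u_gy[year])

    for c in range(1, cfg.n_cycles + 1):
        pool = list(Zf.index)
        recycled = list(line_pool)
        all_prev = pd.concat(Z_all)  # founders plus earlier-cycle lines as parents
        n_new = cfg.genotypes_per_cycle
        ids, p1s, p2s = [], [], []
        calls = np.empty((n_new, m), dtype=np.int8)
        for i in range(n_new):
            if recycled and rng.random() < cfg.parent_recycle:
                p1 = recycled[rng.integers(len(recycled))]
            else:
                p1 = pool[rng.integers(len(pool))]
            while True:
                if recycled and rng.random() < cfg.parent_recycle:
                    p2 = recycled[rng.integers(len(recycled))]
                else:
                    p2 = pool[rng.integers(len(pool))]
                if p2 != p1:
                    break
            a = all_prev.loc[p1].to_numpy()
            b = all_prev.loc[p2].to_numpy()
            pick = rng.random(m) < 0.5
            calls[i] = np.where(pick, a, b)
            gid = f"C{c}_{i:04d}"
            ids.append(gid)
            p1s.append(p1)
            p2s.append(p2)
        Zc = pd.DataFrame(calls, index=ids, columns=Zf.columns)
        Z_all.append(Zc)
        peds.append(pd.DataFrame(
            {"genotype": ids, "parent1": p1s, "parent2": p2s, "cycle": c}))
        line_pool.extend(ids)

        # testers: shared for GCA1/GCA2 within the cycle, new set at GCA3, new per cycle
        t12 = [f"T{c}_{j}" for j in range(max(cfg.testers_per_stage[0],
                                              cfg.testers_per_stage[1]))]
        t3 = [f"T{c}G3_{j}" for j in range(cfg.testers_per_stage[2])]
        stage_testers = (t12[: cfg.testers_per_stage[0]],
                         t12[: cfg.testers_per_stage[1]], t3)

        members = {0: list(ids)}
        genos_by_stage = {}
        for s, stage in enumerate(STAGES):
            year = cfg.first_year + (c - 1) + s
            cand = members[s]
            if not cand:
                break
            locs = list(rng.choice(loc_pool, size=min(cfg.locations_per_stage[s],
                                                      len(loc_pool)), replace=False))
            testers = stage_testers[s]
            stage_means: dict = {g: [] for g in cand}
            for loc in locs:
                entries = [(g, t) for g in cand for t in testers]
                layout = assign_field_design(entries, cfg, rng)
                trial = f"{year}_{stage}_{loc}_1"
                for g, t, rep, blk in layout.itertuples(index=False):
                    zr = Zc.loc[g].to_numpy(float)
                    yld = (
                        cfg.base_yield
                        + float(zr @ u_g)
                        + gy_effect(zr, year)
                        + effects.get("L", (loc,))
                        + effects.get("GL", (g, loc))
                        + effects.get("YL", (year, loc))
                        + effects.get("GYL", (g, year, loc))
                        + effects.get("T", (t,))
                        + effects.get("GT", (g, t))
                        + effects.get("TY", (t, year))
                        + effects.get("TL", (t, loc))
                        + effects.get("GTY", (g, t, year))
                        + effects.get("GTL", (g, t, loc))
                        + effects.get("TYL", (t, year, loc))
                        + effects.get("GTYL", (g, t, year, loc))
                        + effects.get("trial", (trial,))
                        + effects.get("rep", (trial, rep))
                        + effects.get("block", (trial, rep, blk))
                        + rng.normal(0.0, err_sd)
                    )
                    plot_rows.append((g, t, year, loc, trial, rep, blk, stage,
                                      cfg.program, yld))
                    stage_means[g].append(yld)
            genos_by_stage[stage] = list(cand)
            # truncation selection on simple testcross means
            if s < 2:
                frac = cfg.advance_fractions[s]
                n_keep = max(0, int(round(frac * len(cand))))
                ranked = sorted(cand, key=lambda g: -np.mean(stage_means[g]))
                members[s + 1] = ranked[:n_keep]
        cycle_members[c] = genos_by_stage

    plots = pd.DataFrame(plot_rows, columns=[
        "genotype", "tester", "year", "location", "trial", "replicate", "block",
        "stage", "program", "yield"])
    Z = pd.concat(Z_all)
    pedigree = pd.concat(peds, ignore_index=True)
    gebv_true = pd.Series(Z.to_numpy(float) @ u_g, index=Z.index, name="gebv_true")
    truth = {
        "u_g": pd.Series(u_g, index=Zf.columns),
        "u_gy": {y: pd.Series(v, index=Zf.columns) for y, v in u_gy.items()},
        "gebv": gebv_true,
        "effects": effects.store,
        "cycle_members": cycle_members,
    }
    return plots, Z, pedigree, truth


def simulate_crossed_trial(n_genotypes, n_years, n_locations, replicates,
                           variances=None, seed=0, base=80.0):
    """Fully crossed genotype x year x location trial with iid identity effects.

    A connected factorial companion to :func:`simulate_program`, used to
    validate variance-component recovery where G and GY are identifiable.
    Returns ``(plots, truth)`` with the realized component draws.
    """
    vc = dict(DEFAULT_VARIANCES) if variances is None else dict(variances)
    rng = np.random.default_rng(seed)
    genos = [f"G{i:03d}" for i in range(n_genotypes)]
    years = [2009 + i for i in range(n_years)]
    locs = [f"L{i:02d}" for i in range(n_locations)]

    def draw(n, name):
        v = vc.get(name, 0.0)
        return rng.normal(0, np.sqrt(v), n) if v > 0 else np.zeros(n)

    eff = {
        "G": dict(zip(genos, draw(len(genos), "G"))),
        "GY": {(g, y): e for (g, y), e in zip(
            [(g, y) for g in genos for y in years],
            draw(len(genos) * len(years), "GY"))},
        "L": dict(zip(locs, draw(len(locs), "L"))),
        "GL": {(g, l): e for (g, l), e in zip(
            [(g, l) for g in genos for l in locs],
            draw(len(genos) * len(locs), "GL"))},
        "YL": {(y, l): e for (y, l), e in zip(
            [(y, l) for y in years for l in locs],
            draw(len(years) * len(locs), "YL"))},
        "GYL": {(g, y, l): e for (g, y, l), e in zip(
            [(g, y, l) for g in genos for y in years for l in locs],
            draw(len(genos) * len(years) * len(locs), "GYL"))},
    }
    err_sd = np.sqrt(vc.get("plot_error", 0.0))
    rows = []
    for g in genos:
        for y in years:
            for l in locs:
                cell = (base + eff["G"][g] + eff["GY"][(g, y)] + eff["L"][l]
                        + eff["GL"][(g, l)] + eff["YL"][(y, l)] + eff["GYL"][(g, y, l)])
                for r in range(1, replicates + 1):
                    rows.append((g, "T1", y, l, f"{y}_{l}", r, 1, "GCA1", "P1",
                                 cell + rng.normal(0, err_sd)))
    plots = pd.DataFrame(rows, columns=[
        "genotype", "tester", "year", "location", "trial", "replicate", "block",
        "stage", "program", "yield"])
    return plots, eff
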