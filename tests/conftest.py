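import numpy as np
import pandas as pd
import pytest

from gyblup.simulate import DEFAULT_VARIANCES, ProgramConfig, simulate_program


@pytest.fixture(scope="session")
def small_program():
    """Three-cycle program at reduced scale, shared across read-only tests."""
    cfg = ProgramConfig(
        n_cycles=3, genotypes_per_cycle=40, markers=80, n_founders=20,
        locations_per_stage=(2, 2, 2), advance_fractions=(0.25, 0.2), seed=123,
    )
    plots, Z, ped, truth = simulate_program(cfg)
    return cfg, plots, Z, ped, truth


@pytest.fixture()
def toy_markers():
    rng = np.random.default_rng(42)
    ids = [f"G{i:02d}" for i in range(12)]
    Z = pd.DataFrame(
        rng.choice([-1, 1], size=(12, 30)),
        index=ids, columns=[f"M{j:02d}" for j in range(30)],
    )
    return Z


def balanced_plot_table(n_geno=20, testers=("T1", "T2"), locs=("L1", "L2"),
                        years=(2009, 2010), reps=1, seed=7, sd_error=2.0):
    """Balanced complete factorial plot table with additive effects."""
    rng = np.random.default_rng(seed)
    genos = [f"G{i:02d}" for i in range(n_geno)]
    ge = dict(zip(genos, rng.normal(0, 2.5, n_geno)))
    te = dict(zip(testers, rng.normal(0, 1, len(testers))))
    le = dict(zip(locs, rng.normal(0, 5, len(locs))))
    ye = dict(zip(years, rng.normal(0, 4, len(years))))
    gye = {(g, y): rng.normal(0, 1) for g in genos for y in years}
    gle = {(g, l): rng.normal(0, 1) for g in genos for l in locs}
    yle = {(y, l): rng.normal(0, 3) for y in years for l in locs}
    rows = []
    for g in genos:
        for t in testers:
            for y in years:
                for l in locs:
                    cell = (80 + ge[g] + te[t] + le[l] + ye[y]
                            + gye[(g, y)] + gle[(g, l)] + yle[(y, l)])
                    for r in range(1, reps + 1):
                        rows.append((g, t, y, l, f"{y}_{l}", r, 1, "GCA1", "P1",
                                     cell + rng.normal(0, sd_error)))
    return pd.DataFrame(rows, columns=[
        "genotype", "tester", "year", "location", "trial", "replicate", "block",
        "stage", "program", "yield"])


@pytest.fixture()
def balanced_plots():
    return balanced_plot_table()


@pytest.fixture(scope="session")
def control_ts_conditions():
    """Simulator settings for the disconnected control-TS dissection studies."""
    def make(seed, gy_variance):
        vc = dict(DEFAULT_VARIANCES)
        vc["GY"] = gy_variance
        return ProgramConfig(
            n_cycles=3, genotypes_per_cycle=100, markers=120, n_founders=20,
            locations_per_stage=(3, 3, 3), variance_components=vc,
            advance_fractions=(0.1, 0.15), seed=seed,
        )
    return make
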