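import numpy as np
import pandas as pd
import pytest

from gyblup.mixedmodel import (
    ModelSpec,
    RandomTerm,
    build_Zgy,
    gebv,
    parse_model_formula,
    reml_fit,
    smith_weights,
    solve_mme,
    term_name,
    vc_asymptotic_correlation,
)


def one_way(groups=10, reps=5, sd_g=2.0, sd_e=1.0, seed=1):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, sd_g, groups)
    rows = [(f"g{i:02d}", eff[i] + rng.normal(0, sd_e))
            for i in range(groups) for _ in range(reps)]
    return pd.DataFrame(rows, columns=["grp", "y"])


class TestRemlCore:
    def test_balanced_oneway_matches_anova_closed_form(self):
        df = one_way()
        fit = reml_fit(ModelSpec(response="y", random=[RandomTerm(("grp",))]), df)
        m = df.groupby("grp")["y"].mean()
        msb = 5 * m.var(ddof=1)
        msw = (df["y"] - df["grp"].map(m)).pow(2).sum() / (10 * 4)
        assert fit.variance_components["grp"] == pytest.approx((msb - msw) / 5, rel=1e-8)
        assert fit.variance_components["residual"] == pytest.approx(msw, rel=1e-8)
        assert fit.converged

    def test_null_component_lands_on_zero_boundary(self):
        hits = 0
        for s in range(60):
            df = one_way(groups=8, reps=4, sd_g=0.0, seed=s)
            fit = reml_fit(ModelSpec(response="y", random=[RandomTerm(("grp",))]), df)
            if fit.variance_components["grp"] == 0.0 and fit.boundary["grp"]:
                hits += 1
        # roughly half of null REML estimates land exactly on the zero
        # boundary; far fewer would indicate broken boundary handling
        assert hits >= 0.35 * 60

    def test_uniform_weight_rescaling_invariance(self):
        df = one_way().assign(w=1.0)
        spec = ModelSpec(response="y", random=[RandomTerm(("grp",))], weights="w")
        f1 = reml_fit(spec, df)
        f2 = reml_fit(spec, df.assign(w=2.0))
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)
        assert f2.variance_components["residual"] == pytest.approx(
            2 * f1.variance_components["residual"], rel=1e-6)

    def test_row_order_invariance(self):
        df = one_way(seed=3)
        spec = ModelSpec(response="y", random=[RandomTerm(("grp",))])
        f1 = reml_fit(spec, df)
        f2 = reml_fit(spec, df.sample(frac=1.0, random_state=0))
        assert f1.variance_components["grp"] == pytest.approx(
            f2.variance_components["grp"], abs=1e-10)
        assert np.allclose(np.sort(f1.beta), np.sort(f2.beta), atol=1e-10)

    def test_singular_fixed_part_drops_aliased_column(self):
        df = one_way(groups=4, reps=3)
        df["dup"] = df["grp"]  # identical factor twice in the fixed part
        spec = ModelSpec(response="y", mean_term=("grp",), fixed=[("dup",)], random=[])
        fit = reml_fit(spec, df)
        assert any("aliased fixed-effect" in w for w in fit.warnings)
        assert len(fit.adjusted_means()) == 4


class TestFormulaParser:
    def test_single_stage_trial_model_resolution(self):
        # the full factorial + nesting chain of the plot model resolves to
        # the 17 random terms of its expanded form
        fixed, random = parse_model_formula("T : G×Y×L + T·(G×Y×L) + (Y·L)/S/R/B")
        assert [term_name(t) for t in fixed] == ["T"]
        names = {term_name(t) for t in random}
        assert len(random) == 17
        assert {"G", "G·Y", "G·Y·L", "T·G·Y·L", "Y·L·S·R·B"} <= names

    def test_nesting_chain(self):
        _, random = parse_model_formula("G·T : S/R/B")
        assert [term_name(t) for t in random] == ["S", "S·R", "S·R·B"]

    def test_crossing_and_factorial(self):
        fixed, random = parse_model_formula("G + T : G·T + L·(G×T)")
        assert [term_name(t) for t in fixed] == ["G", "T"]
        assert [term_name(t) for t in random] == ["G·T", "L·G", "L·T", "L·G·T"]

    def test_duplicate_terms_collapse(self):
        _, random = parse_model_formula("G×Y + G·Y")
        assert len(random) == 3

    def test_malformed_formula_rejected(self):
        with pytest.raises(ValueError):
            parse_model_formula("G : T : L")
        with pytest.raises(ValueError):
            parse_model_formula("(G·T : S")


class TestBuildZgy:
    def test_single_year_equals_marker_matrix(self, toy_markers):
        mapping = {g: 2009 for g in toy_markers.index}
        Zgy = build_Zgy(toy_markers, mapping)
        got = Zgy.droplevel("year")
        assert np.allclose(got.loc[toy_markers.index].to_numpy(),
                           toy_markers.to_numpy())

    def test_cross_year_covariance_exactly_zero(self, toy_markers):
        ids = list(toy_markers.index)
        mapping = {g: (2009 if i < 6 else 2010) for i, g in enumerate(ids)}
        Zgy = build_Zgy(toy_markers, mapping)
        K = Zgy.to_numpy() @ Zgy.to_numpy().T
        years = Zgy.index.get_level_values("year")
        cross = K[np.ix_(years == 2009, years == 2010)]
        assert np.all(cross == 0.0)

    def test_matches_per_pair_same_year_dot_products(self):
        Z = pd.DataFrame([[1, -1], [1, 1], [-1, 1]], index=["a", "b", "c"],
                         columns=["m1", "m2"])
        mapping = {"a": 1, "b": 1, "c": 2}
        Zgy = build_Zgy(Z, mapping)
        K = Zgy.to_numpy() @ Zgy.to_numpy().T
        idx = {g: i for i, (y, g) in enumerate(Zgy.index)}
        for gi in "abc":
            for gj in "abc":
                expect = (float(Z.loc[gi] @ Z.loc[gj])
                          if mapping[gi] == mapping[gj] else 0.0)
                assert K[idx[gi], idx[gj]] == pytest.approx(expect)

    def test_unmapped_genotype_rejected(self, toy_markers):
        with pytest.raises(KeyError):
            build_Zgy(toy_markers, {"unknown": 2009})


class TestSolveMme:
    def make_marker_data(self, n=30, m=60, seed=7, sigma_u=0.3, sd_e=1.0):
        rng = np.random.default_rng(seed)
        Z = pd.DataFrame(rng.choice([-1, 1], size=(n, m)),
                         index=[f"G{i:02d}" for i in range(n)],
                         columns=[f"M{j}" for j in range(m)])
        u = rng.normal(0, sigma_u, m)
        y = Z.to_numpy(float) @ u + rng.normal(0, sd_e, n)
        return Z, pd.DataFrame({"genotype": Z.index, "y": y})

    def test_zero_marker_variance_gives_zero_gebv(self):
        Z, df = self.make_marker_data()
        spec = ModelSpec(response="y", random=[RandomTerm(structure="marker")], markers=Z)
        fit = solve_mme(spec, df, {"G(marker)": 0.0, "residual": 1.0})
        v = gebv(fit, Z, Z.index)
        assert np.allclose(v, 0.0)

    def test_no_random_terms_unit_weights_is_ols(self):
        df = one_way(groups=5, reps=4)
        spec = ModelSpec(response="y", mean_term=("grp",), random=[])
        fit = solve_mme(spec, df, {"residual": 1.0})
        ols = df.groupby("grp")["y"].mean()
        assert np.allclose(fit.adjusted_means()[ols.index], ols.to_numpy())

    def test_marker_and_kinship_parameterizations_agree(self):
        # RR-BLUP GEBV equals the GBLUP solution with K = Z Z^T
        Z, df = self.make_marker_data(n=8, m=20, seed=2)
        comps = {"G(marker)": 0.05, "residual": 0.8}
        spec = ModelSpec(response="y", random=[RandomTerm(structure="marker")], markers=Z)
        fit = solve_mme(spec, df, comps)
        v_rr = gebv(fit, Z, Z.index).to_numpy()
        K = Z.to_numpy(float) @ Z.to_numpy(float).T
        n = len(df)
        V = comps["G(marker)"] * K + comps["residual"] * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["y"].to_numpy())
        v_gb = comps["G(marker)"] * K @ Vi @ (df["y"].to_numpy() - (X @ b).ravel())
        assert np.abs(v_rr - v_gb).max() < 1e-8

    def test_gebv_available_for_unphenotyped_genotypes(self):
        Z, df = self.make_marker_data(n=20, m=30, seed=4)
        train = df.iloc[:15]
        spec = ModelSpec(response="y", random=[RandomTerm(structure="marker")], markers=Z)
        fit = solve_mme(spec, train, {"G(marker)": 0.05, "residual": 1.0})
        v = gebv(fit, Z, Z.index[15:])
        assert len(v) == 5 and np.isfinite(v).all()
        with pytest.raises(KeyError):
            gebv(fit, Z, ["missing_genotype"])


class TestAsymptoticCorrelation:
    def test_diagonal_is_one(self):
        df = one_way(seed=9)
        fit = reml_fit(ModelSpec(response="y", random=[RandomTerm(("grp",))]), df)
        corr = vc_asymptotic_correlation(fit)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_orthogonal_strata_nearly_uncorrelated(self):
        # two independent balanced strata -> their variance estimates are
        # close to orthogonal
        rng = np.random.default_rng(12)
        rows = []
        for a in range(12):
            for b in range(12):
                rows.append((f"a{a}", f"b{b}",
                             rng.normal(0, 2) if b == 0 else 0.0, 0.0))
        # independent crossed layout: y = row effect + column effect + error
        rows = []
        ae = rng.normal(0, 2, 12)
        be = rng.normal(0, 2, 12)
        for a in range(12):
            for b in range(12):
                rows.append((f"a{a}", f"b{b}", ae[a] + be[b] + rng.normal(0, 1)))
        df = pd.DataFrame(rows, columns=["fa", "fb", "y"])
        fit = reml_fit(ModelSpec(response="y",
                                 random=[RandomTerm(("fa",)), RandomTerm(("fb",))]), df)
        corr = vc_asymptotic_correlation(fit)
        assert abs(corr.loc["fa", "fb"]) < 0.15

    def test_disconnected_identity_g_gy_fully_confounded(self):
        # the ill-conditioning limit: disconnected years with identity G and
        # GY report asymptotic correlation -1
        rng = np.random.default_rng(5)
        rows = []
        for year in (2009, 2010):
            for g in range(10):
                gid = f"Y{year}_G{g}"
                ge, gye = rng.normal(0, 2), rng.normal(0, 1.5)
                for l in range(4):
                    rows.append((gid, year, f"L{l}", 80 + ge + gye + rng.normal(0, 1)))
        df = pd.DataFrame(rows, columns=["genotype", "year", "location", "y"])
        spec = ModelSpec(response="y", fixed=[("year",)],
                         random=[RandomTerm(("genotype",)),
                                 RandomTerm(("genotype", "year"))],
                         drop_duplicate_random=False)
        fit = reml_fit(spec, df)
        corr = vc_asymptotic_correlation(fit)
        assert corr.loc["G", "G·Y"] <= -0.99

    def test_zero_component_reported_na(self):
        df = one_way(groups=8, reps=4, sd_g=0.0, seed=17)
        fit = reml_fit(ModelSpec(response="y", random=[RandomTerm(("grp",))]), df)
        if fit.variance_components["grp"] == 0.0:
            corr = vc_asymptotic_correlation(fit)
            assert np.isnan(corr.loc["grp", "residual"])


class TestSmithWeights:
    def test_balanced_design_equal_weights(self):
        df = one_way(groups=6, reps=3)
        fit = reml_fit(ModelSpec(response="y", mean_term=("grp",), random=[]), df)
        w = smith_weights(fit)
        assert np.allclose(w, w.iloc[0])

    def test_more_plots_larger_weight(self):
        rng = np.random.default_rng(0)
        rows = ([("g1", rng.normal()) for _ in range(8)]
                + [("g2", rng.normal()) for _ in range(4)])
        df = pd.DataFrame(rows, columns=["grp", "y"])
        fit = reml_fit(ModelSpec(response="y", mean_term=("grp",), random=[]), df)
        w = smith_weights(fit)
        # iid errors: weight ratio equals the plot-count ratio
        assert w["g1"] / w["g2"] == pytest.approx(2.0, rel=1e-6)

    def test_diagonal_covariance_inverts_elementwise(self):
        df = one_way(groups=5, reps=2)
        fit = reml_fit(ModelSpec(response="y", mean_term=("grp",), random=[]), df)
        C = fit.beta_cov[np.ix_(fit.mean_idx, fit.mean_idx)]
        assert np.allclose(np.diag(C) * smith_weights(fit).to_numpy(), 1.0)


class TestMarkerByYearDissection:
    def test_joint_recovery_of_main_and_interaction_variance(self):
        # two years, genotypes replicated at the allele level only: the fit
        # still separates the marker main-effect variance from the
        # marker-by-year variance on average
        m, n = 60, 80
        sg, sgy, se = 6.75, 6.75, 2.0
        est = []
        for s in range(40):
            rng = np.random.default_rng(s)
            F = rng.choice([-1.0, 1.0], size=(15, m))
            def draw(nn):
                i1, i2 = rng.integers(15, size=nn), rng.integers(15, size=nn)
                pick = rng.random((nn, m)) < 0.5
                return np.where(pick, F[i1], F[i2])
            Z1, Z2 = draw(n), draw(n)
            ug = rng.normal(0, np.sqrt(sg / m), m)
            u1 = rng.normal(0, np.sqrt(sgy / m), m)
            u2 = rng.normal(0, np.sqrt(sgy / m), m)
            y = np.concatenate([
                Z1 @ ug + Z1 @ u1 + rng.normal(0, np.sqrt(se), n),
                Z2 @ ug + Z2 @ u2 + rng.normal(0, np.sqrt(se), n)])
            ids = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
            Z = pd.DataFrame(np.vstack([Z1, Z2]), index=ids)
            df = pd.DataFrame({"genotype": ids,
                               "year": [2009] * n + [2010] * n, "y": y})
            spec = ModelSpec(response="y", fixed=[("year",)],
                             random=[RandomTerm(structure="marker"),
                                     RandomTerm(structure="marker_by_year_hom")],
                             markers=Z)
            fit = reml_fit(spec, df)
            est.append([m * fit.variance_components["G(marker)"],
                        m * fit.variance_components["G·Y(marker)"]])
        est = np.array(est)
        for k, truth in enumerate([sg, sgy]):
            mean = est[:, k].mean()
            se_mc = est[:, k].std(ddof=1) / np.sqrt(len(est))
            assert (abs(mean - truth) / truth < 0.15) or (abs(mean - truth) < 3 * se_mc)
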