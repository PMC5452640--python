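"""REML estimation and BLUE/BLUP solution for the stage-wise trial models.

The engine fits Gaussian linear mixed models

    y = X beta + sum_k Z_k u_k + e,    u_k ~ N(0, sigma2_k I),
    e ~ N(0, sigma2_e diag(1/w))

where each random term contributes ``sigma2_k Z_k Z_k^T`` to the marginal
covariance.  Four covariance structures are supported for the random terms:

``identity``
    Z_k is the indicator matrix of a factor product; the classical variance
    component.
``marker``
    Z_k carries one row of the coded marker matrix per observation (ridge /
    RR-BLUP: ``var(Z u) = Z Z^T sigma2``, the marker-kinship term whose BLUPs
    are marker effects and whose linear combinations are GEBVs).
``marker_by_year_hom``
    block-diagonal marker-by-year design: each observation's marker row sits
    in the column block of its year, so the induced covariance is exactly
    zero between years -- any cross-year covariance must flow through the
    marker main-effect term.  One common variance for all years.
``marker_by_year_het``
    as above with one free variance per year.

Residual weights ``w`` are fixed known constants (Smith weights carried over
from the previous stage); a single residual scale multiplies them.

Estimation is average-information REML with EM fallback steps whenever the
AI update would leave the parameter space or decrease the restricted
likelihood, and projection of vanishing components onto the zero boundary
(boundary zeros are first-class results, flagged in the fit).  Dense linear
algebra throughout; the intended problem sizes (a few thousand mixed-model
equations at most) need no sparse machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "FitResult",
    "build_Zgy",
    "reml_fit",
    "solve_mme",
    "vc_asymptotic_correlation",
    "smith_weights",
    "term_name",
    "parse_model_formula",
]

FACTOR_ALIASES = {
    "genotype": "G",
    "tester": "T",
    "year": "Y",
    "location": "L",
    "trial": "S",
    "replicate": "R",
    "block": "B",
}


def term_name(factors) -> str:
    return "·".join(FACTOR_ALIASES.get(f, f) for f in factors)


def parse_model_formula(formula: str, alias: dict | None = None):
    """Parse the trial-model operator notation into factor-product terms.

    The colon separates fixed (first) from random effects; ``+`` joins
    terms; the dot ``·`` (or ``.``/``*``) crosses factors; ``×`` (or ``x``)
    builds the full factorial (A×B = A + B + A·B); ``/`` nests (A/B = A +
    A·B, chaining against the finest term so (Y·L)/S/R/B yields Y·L,
    Y·L·S, Y·L·S·R, Y·L·S·R·B).  Factor symbols map to data columns via
    ``alias`` (default: G, T, Y, L, S, R, B to the standard column names).

    Returns ``(fixed_terms, random_terms)`` as lists of column-name tuples,
    duplicates removed in first-appearance order.
    """
    if alias is None:
        alias = {v: k for k, v in FACTOR_ALIASES.items()}

    def tokenize(s):
        s = s.replace(" x ", " × ")  # ASCII factorial operator
        sym = {"·": "·", ".": "·", "*": "·", "×": "×",
               "/": "/", "+": "+", "(": "(", ")": ")"}
        out, i = [], 0
        while i < len(s):
            c = s[i]
            if c.isspace():
                i += 1
            elif c in sym:
                out.append(sym[c])
                i += 1
            else:
                j = i
                while j < len(s) and (s[j].isalnum() or s[j] == "_"):
                    j += 1
                if j == i:
                    raise ValueError(f"cannot parse formula near {s[i:]!r}")
                out.append(("name", s[i:j]))
                i = j
        return out

    def cross(A, B):
        return [ta + tb for ta in A for tb in B]

    def parse(tokens, pos):
        def atom(p):
            tok = tokens[p]
            if tok == "(":
                terms, p = expr(p + 1)
                if p >= len(tokens) or tokens[p] != ")":
                    raise ValueError("unbalanced parentheses in formula")
                return terms, p + 1
            if isinstance(tok, tuple) and tok[0] == "name":
                name = alias.get(tok[1], tok[1])
                return [(name,)], p + 1
            raise ValueError(f"unexpected token {tok!r}")

        def product(p):
            terms, p = atom(p)
            while p < len(tokens) and tokens[p] in ("·", "×", "/"):
                op = tokens[p]
                rhs, p = atom(p + 1)
                if op == "·":
                    terms = cross(terms, rhs)
                elif op == "×":
                    terms = terms + rhs + cross(terms, rhs)
                else:  # nesting against the finest term so far
                    finest = max(terms, key=len)
                    terms = terms + [finest + tb for tb in rhs]
            return terms, p

        def expr(p):
            terms, p = product(p)
            while p < len(tokens) and tokens[p] == "+":
                rhs, p = product(p + 1)
                terms = terms + rhs
            return terms, p

        return expr(pos)

    def dedupe(terms):
        seen, out = set(), []
        for t in terms:
            key = tuple(sorted(t))
            if key not in seen:
                seen.add(key)
                out.append(t)
        return out

    parts = formula.split(":")
    if len(parts) == 1:
        fixed_src, random_src = "", parts[0]
    elif len(parts) == 2:
        fixed_src, random_src = parts
    else:
        raise ValueError("at most one ':' (fixed : random) allowed")
    fixed = []
    if fixed_src.strip():
        toks = tokenize(fixed_src)
        fixed, end = parse(toks, 0)
        if end != len(toks):
            raise ValueError("trailing tokens in fixed part")
    random = []
    if random_src.strip():
        toks = tokenize(random_src)
        random, end = parse(toks, 0)
        if end != len(toks):
            raise ValueError("trailing tokens in random part")
    return dedupe(fixed), dedupe(random)


@dataclass(frozen=True)
class RandomTerm:
    """One random model term: a factor product plus a covariance-structure tag."""

    factors: tuple = ()
    structure: str = "identity"  # identity | marker | marker_by_year_hom | marker_by_year_het
    name: str = ""

    def label(self) -> str:
        if self.name:
            return self.name
        if self.structure == "marker":
            return "G(marker)"
        if self.structure.startswith("marker_by_year"):
            return "G·Y(marker)"
        return term_name(self.factors)


@dataclass
class ModelSpec:
    """Declarative description of one mixed-model fit.

    ``mean_term`` names the fixed factor product whose levels are cell-coded
    (no intercept) so its BLUEs are adjusted means; the remaining ``fixed``
    factors are deviation (sum-to-zero) coded.  With ``mean_term=None`` the
    fixed part is an intercept plus treatment-coded ``fixed`` factors.
    """

    response: str
    mean_term: tuple | None = None
    fixed: list = field(default_factory=list)  # list of factor-product tuples
    random: list = field(default_factory=list)  # list of RandomTerm
    weights: str | None = None
    markers: pd.DataFrame | None = None
    genotype_col: str = "genotype"
    year_col: str = "year"
    # identity random terms inducing the same covariance as an earlier one are
    # redundant reparameterizations; they are dropped unless a diagnostic fit
    # deliberately keeps them to expose the confounding in the information matrix
    drop_duplicate_random: bool = True


@dataclass
class FitResult:
    variance_components: dict
    boundary: dict
    beta: np.ndarray
    beta_labels: list
    beta_cov: np.ndarray
    mean_labels: list | None
    mean_idx: np.ndarray | None
    blups: dict
    marker_effects: pd.Series | None
    marker_by_year_effects: dict | None
    loglik: float
    info_matrix: np.ndarray
    param_names: list
    converged: bool
    n_iter: int
    warnings: list
    dropped_terms: dict
    random_term_labels: list
    n_obs: int

    def adjusted_means(self) -> pd.Series:
        if self.mean_labels is None:
            raise ValueError("fit has no mean (cell-coded) term")
        return pd.Series(self.beta[self.mean_idx], index=self.mean_labels, name="mean")

    def summary(self) -> str:
        lines = ["variance components:"]
        for k, v in self.variance_components.items():
            flag = " (boundary)" if self.boundary.get(k) else ""
            if isinstance(v, dict):
                for yr, vv in v.items():
                    lines.append(f"  {k}[{yr}]: {vv:.6g}{flag}")
            else:
                lines.append(f"  {k}: {v:.6g}{flag}")
        lines.append(f"REML loglik: {self.loglik:.6f}  (converged={self.converged}, "
                     f"iterations={self.n_iter})")
        for w in self.warnings:
            lines.append(f"note: {w}")
        return "\n".join(lines)

    def report(self) -> str:
        """Structured text report: components, asymptotic correlations, convergence."""
        parts = [self.summary()]
        try:
            corr = vc_asymptotic_correlation(self)
            parts.append("asymptotic correlations of variance estimates:")
            parts.append(corr.round(4).to_string())
        except Exception as exc:  # diagnostics must never mask the fit
            parts.append(f"asymptotic correlations unavailable: {exc}")
        return "\n".join(parts)


# ---------------------------------------------------------------------------
# design construction


def build_Zgy(Z: pd.DataFrame, year_of_genotype: dict) -> pd.DataFrame:
    """Block-diagonal marker-by-year matrix at the (year, genotype) level.

    Rows are sorted by (year, genotype); columns are markers x years.  The
    induced covariance ``Z_gy Z_gy^T`` is exactly zero between rows that
    belong to different years.
    """
    missing = [g for g in year_of_genotype if g not in Z.index]
    if missing:
        raise KeyError(f"genotypes without marker rows: {sorted(map(str, missing))}")
    items = sorted(year_of_genotype.items(), key=lambda kv: (str(kv[1]), str(kv[0])))
    years = sorted({str(y) for _, y in items})
    m = Z.shape[1]
    out = np.zeros((len(items), m * len(years)))
    index = []
    for i, (g, y) in enumerate(items):
        b = years.index(str(y))
        out[i, b * m:(b + 1) * m] = Z.loc[g].to_numpy(float)
        index.append((y, g))
    cols = [f"{y}:{mk}" for y in years for mk in Z.columns]
    return pd.DataFrame(out, index=pd.MultiIndex.from_tuples(index, names=["year", "genotype"]),
                        columns=cols)


def _partition_codes(data: pd.DataFrame, factors) -> np.ndarray:
    key = data[list(factors)].astype(str).agg("¦".join, axis=1)
    return pd.factorize(key, sort=True)


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(set(a.tolist())) == len(set(b.tolist()))


def _indicator(codes: np.ndarray, q: int) -> np.ndarray:
    Z = np.zeros((codes.size, q))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


class _Part:
    """One variance parameter: name, design Z (n x q), precomputed G = Z Z^T."""

    __slots__ = ("name", "Z", "G", "q", "kind", "meta")

    def __init__(self, name, Z, kind, meta=None):
        self.name = name
        self.Z = np.ascontiguousarray(Z, dtype=float)
        self.G = self.Z @ self.Z.T
        self.q = Z.shape[1]
        self.kind = kind
        self.meta = meta


def _marker_design(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    if spec.markers is None:
        raise ValueError("marker random term requires ModelSpec.markers")
    genos = data[spec.genotype_col].astype(str)
    missing = sorted(set(genos) - set(map(str, spec.markers.index)))
    if missing:
        raise KeyError(f"genotypes without marker rows: {missing}")
    Zm = spec.markers.copy()
    Zm.index = Zm.index.map(str)
    return Zm.loc[genos].to_numpy(float)


def _build_design(spec: ModelSpec, data: pd.DataFrame):
    data = data.reset_index(drop=True)
    y = data[spec.response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    n = len(y)
    if spec.weights is not None:
        w = data[spec.weights].to_numpy(float)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("residual weights must be strictly positive and finite")
    else:
        w = np.ones(n)

    warns: list[str] = []
    dropped: dict[str, str] = {}

    # ---- fixed part
    X_cols, X_labels = [], []
    mean_idx = None
    mean_labels = None
    fixed_partitions = []
    if spec.mean_term is not None:
        codes, levels = _partition_codes(data, spec.mean_term)
        q = len(levels)
        X_cols.append(_indicator(codes, q))
        mean_labels = list(levels)
        X_labels += [f"{term_name(spec.mean_term)}[{l}]" for l in levels]
        mean_idx = np.arange(q)
        fixed_partitions.append(codes)
    else:
        X_cols.append(np.ones((n, 1)))
        X_labels.append("(intercept)")
        fixed_partitions.append(np.zeros(n, dtype=int))

    for fac in spec.fixed:
        codes, levels = _partition_codes(data, fac)
        q = len(levels)
        if q < 2:
            warns.append(f"fixed term {term_name(fac)} has a single level and was dropped")
            dropped[term_name(fac)] = "single level"
            continue
        fixed_partitions.append(codes)
        if spec.mean_term is not None:
            # sum-to-zero coding: adjusted means refer to the average level
            C = np.zeros((n, q - 1))
            for j in range(q - 1):
                C[codes == j, j] = 1.0
            C[codes == q - 1, :] = -1.0
        else:
            C = _indicator(codes, q)[:, 1:]  # treatment coding, first level reference
        X_cols.append(C)
        X_labels += [f"{term_name(fac)}[{l}]" for l in levels[1:]]

    X = np.hstack(X_cols)

    # full-rank reduction: the mean-term cells (or the intercept) are protected;
    # remaining columns are kept only if they add rank (Gram-Schmidt screen), so
    # a tester column collinear with a set of cells is the one that gets dropped
    protected = len(mean_idx) if mean_idx is not None else 1
    basis, _ = np.linalg.qr(X[:, :protected])
    keep = list(range(protected))
    lost = []
    for j in range(protected, X.shape[1]):
        x = X[:, j]
        r = x - basis @ (basis.T @ x)
        r = r - basis @ (basis.T @ r)  # re-orthogonalize
        nr = np.linalg.norm(r)
        if nr > 1e-8 * max(1.0, np.linalg.norm(x)):
            basis = np.hstack([basis, (r / nr)[:, None]])
            keep.append(j)
        else:
            lost.append(X_labels[j])
    if lost:
        warns.append(f"aliased fixed-effect columns dropped: {lost}")
        X = X[:, keep]
        X_labels = [X_labels[j] for j in keep]

    # ---- random part
    parts: list[_Part] = []
    seen_partitions: list[tuple[str, np.ndarray]] = []
    for term in spec.random:
        lbl = term.label()
        if term.structure == "identity":
            codes, levels = _partition_codes(data, term.factors)
            q = len(levels)
            if q < 2:
                dropped[lbl] = "single level"
                warns.append(f"random term {lbl} has a single level and was dropped")
                continue
            if q == n:
                dropped[lbl] = "confounded with residual"
                warns.append(f"random term {lbl} has one level per observation "
                             "(confounded with the residual) and was dropped")
                continue
            aliased_fixed = next(
                (fp for fp in fixed_partitions if _same_partition(codes, fp)), None)
            if aliased_fixed is not None:
                dropped[lbl] = "aliased with fixed part"
                warns.append(f"random term {lbl} is aliased with a fixed term and was dropped; "
                             "its component is reported as 0")
                continue
            dup = next((nm for nm, sp in seen_partitions if _same_partition(codes, sp)), None)
            if dup is not None:
                if spec.drop_duplicate_random:
                    dropped[lbl] = f"confounded with {dup}"
                    warns.append(f"random term {lbl} induces the same covariance as {dup} "
                                 "and was dropped")
                    continue
                warns.append(f"random terms {lbl} and {dup} induce identical covariance "
                             "(confounded); both kept, estimates share a likelihood ridge")
            seen_partitions.append((lbl, codes))
            parts.append(_Part(lbl, _indicator(codes, q), "identity"))
        elif term.structure == "marker":
            parts.append(_Part(lbl, _marker_design(spec, data), "marker"))
        elif term.structure in ("marker_by_year_hom", "marker_by_year_het"):
            Zg = _marker_design(spec, data)
            years = pd.factorize(data[spec.year_col].astype(str), sort=True)
            ycodes, ylev = years
            if len(ylev) < 2:
                raise ValueError("marker-by-year term requires at least two years "
                                 "(a single year over-parametrizes the model)")
            if term.structure == "marker_by_year_hom":
                # one block-diagonal design; equivalent to sum of per-year pieces
                m = Zg.shape[1]
                Zgy = np.zeros((n, m * len(ylev)))
                for b in range(len(ylev)):
                    rows = ycodes == b
                    Zgy[rows, b * m:(b + 1) * m] = Zg[rows]
                parts.append(_Part(lbl, Zgy, "marker_by_year", meta={"years": list(ylev)}))
            else:
                for b, yl in enumerate(ylev):
                    Zr = np.zeros_like(Zg)
                    rows = ycodes == b
                    Zr[rows] = Zg[rows]
                    parts.append(_Part(f"{lbl}[{yl}]", Zr, "marker_by_year_het",
                                       meta={"year": yl, "group": lbl}))
        else:
            raise ValueError(f"unknown covariance structure {term.structure!r}")

    return data, y, X, X_labels, mean_idx, mean_labels, w, parts, warns, dropped


# ---------------------------------------------------------------------------
# REML core


def _vinv_quantities(theta, parts, D, X, y):
    n = len(y)
    V = theta[-1] * np.diag(D)
    for t, p in zip(theta[:-1], parts):
        if t > 0:
            V += t * p.G
    cF = cho_factor(V, lower=True, check_finite=False)
    dl = np.diag(cF[0])
    if (dl.max() / dl.min()) ** 2 > 1e8:
        # beyond this conditioning the restricted likelihood is numerical
        # noise; treat the state as infeasible so the optimizer backs off
        raise np.linalg.LinAlgError("ill-conditioned covariance matrix")
    logdetV = 2.0 * np.sum(np.log(np.diag(cF[0])))
    Vi = cho_solve(cF, np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sgn, logdetX = np.linalg.slogdet(XtViX)
    if sgn <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    C = np.linalg.inv(XtViX)
    P = Vi - ViX @ C @ ViX.T
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return V, Vi, C, P, Py, ll


def _scores_ai(theta, parts, D, P, Py):
    K = len(parts) + 1
    tr = np.empty(K)
    quad = np.empty(K)
    T = np.empty((len(Py), K))
    for k, p in enumerate(parts):
        tr[k] = float(np.sum(P * p.G))
        t = p.G @ Py
        T[:, k] = t
        quad[k] = float(Py @ t)
    tr[-1] = float(np.sum(np.diag(P) * D))
    T[:, -1] = D * Py
    quad[-1] = float(Py @ T[:, -1])
    score = 0.5 * (quad - tr)
    AI = 0.5 * (T.T @ P @ T)
    return score, AI, tr, quad


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    max_iter: int = 200,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
    start: dict | None = None,
    fixed_components: dict | None = None,
) -> FitResult:
    """Fit ``spec`` to ``data`` by AI-REML with EM fallback and boundary handling.

    ``fixed_components`` skips estimation and solves the mixed-model
    equations at the supplied variance components (used by :func:`solve_mme`).
    """
    (data, y, X, X_labels, mean_idx, mean_labels, w, parts,
     warns, dropped) = _build_design(spec, data)
    n, p = X.shape
    if n - p < 1 and fixed_components is None:
        return _saturated_fit(spec, data, y, X, X_labels, mean_idx, mean_labels,
                              parts, warns, dropped)
    D = 1.0 / w
    K = len(parts)
    names = [pt.name for pt in parts] + ["residual"]

    base = float(np.var(y)) if np.var(y) > 0 else 1.0
    theta = np.full(K + 1, base / (K + 1))
    # marker parts act through G with trace ~ n*m: start them on a comparable scale
    for k, pt in enumerate(parts):
        gbar = np.trace(pt.G) / n
        if gbar > 0:
            theta[k] = base / (K + 1) / gbar
    if start:
        for k, nm in enumerate(names):
            if nm in start:
                theta[k] = float(start[nm])

    if fixed_components is not None:
        for k, nm in enumerate(names):
            if nm not in fixed_components:
                raise KeyError(f"fixed_components missing {nm!r}")
            theta[k] = float(fixed_components[nm])
        theta[-1] = max(theta[-1], 1e-12 * base)
        V, Vi, C, P, Py, ll = _vinv_quantities(theta, parts, D, X, y)
        info = _expected_info(parts, D, P)
        return _pack(spec, data, theta, names, parts, X, X_labels, mean_idx, mean_labels,
                     C, Vi, Py, ll, info, True, 0, warns, dropped, n)

    floor = 1e-8 * base
    cap = 1e7 * base  # hard ceiling against degenerate (exact-fit) divergence
    at_bound = np.zeros(K + 1, dtype=bool)
    ll_prev = -np.inf
    converged = False
    it = 0
    V, Vi, C, P, Py, ll = _vinv_quantities(theta, parts, D, X, y)
    for it in range(1, max_iter + 1):
        score, AI, tr, quad = _scores_ai(theta, parts, D, P, Py)
        qs = np.array([pt.q for pt in parts] + [n], dtype=float)

        # release boundary components whose score turned positive
        release = at_bound & (score > 0)
        if release.any():
            theta[release] = floor * 10
            at_bound[release] = False

        free = ~at_bound
        em = theta + theta**2 * (quad - tr) / qs

        # growth restriction: no component may grow more than tenfold (plus a
        # base offset) in one update -- guards against wild AI/EM jumps when a
        # variance ratio is weakly identified or the fit is close to exact
        grow = 10.0 * theta + base

        if it <= 2:
            cand = np.where(free, np.minimum(np.maximum(em, 0.0), grow), 0.0)
            cand = np.minimum(cand, cap)
            cand[-1] = max(cand[-1], floor)
            try:
                Vq = _vinv_quantities(cand, parts, D, X, y)
            except np.linalg.LinAlgError:
                break  # cannot move without losing numerical footing
        else:
            idx = np.where(free)[0]
            Afree = AI[np.ix_(idx, idx)]
            try:
                delta = np.linalg.solve(Afree, score[idx])
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(Afree, score[idx], rcond=None)[0]
            step = 1.0
            cand = None
            Vq = None
            for _ in range(12):
                trial = theta.copy()
                trial[idx] = theta[idx] + step * delta
                if np.any(trial[idx] < 0):
                    neg = trial < 0
                    trial[neg] = np.where(free[:len(trial)][neg], 0.0, trial[neg])
                trial[~free] = 0.0
                trial = np.minimum(np.minimum(trial, grow), cap)
                trial[-1] = max(trial[-1], floor)
                try:
                    q = _vinv_quantities(trial, parts, D, X, y)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if q[5] >= ll - 1e-10 * (1 + abs(ll)):
                    cand, Vq = trial, q
                    break
                step *= 0.5
            if cand is None:
                cand = np.where(free, np.minimum(np.maximum(em, 0.0), grow), 0.0)
                cand = np.minimum(cand, cap)
                cand[-1] = max(cand[-1], floor)
                try:
                    Vq = _vinv_quantities(cand, parts, D, X, y)
                except np.linalg.LinAlgError:
                    break

        # boundary projection
        small = (cand < floor) & free
        small[-1] = False
        cand[small & (cand <= 0)] = 0.0
        at_bound = at_bound | (cand[:K + 1] == 0.0)
        at_bound[-1] = False

        dpar = np.max(np.abs(cand - theta) / (np.abs(theta) + base * 1e-3))
        theta = cand
        V, Vi, C, P, Py, ll_new = Vq
        if abs(ll_new - ll_prev) < tol_ll * (1 + abs(ll_new)) and dpar < tol_par:
            ll = ll_new
            converged = True
            break
        ll_prev = ll
        ll = ll_new

    if not converged:
        warns.append(f"REML did not converge in {max_iter} iterations")

    info = _expected_info(parts, D, P)
    return _pack(spec, data, theta, names, parts, X, X_labels, mean_idx, mean_labels,
                 C, Vi, Py, ll, info, converged, it, warns, dropped, n)


def _expected_info(parts, D, P):
    K = len(parts) + 1
    PG = [P @ p.G for p in parts] + [P * D[None, :]]
    info = np.empty((K, K))
    for a in range(K):
        for b in range(a, K):
            info[a, b] = info[b, a] = 0.5 * float(np.sum(PG[a] * PG[b].T))
    return info


def _pack(spec, data, theta, names, parts, X, X_labels, mean_idx, mean_labels,
          C, Vi, Py, ll, info, converged, it, warns, dropped, n):
    beta = C @ (X.T @ (Vi @ data[spec.response].to_numpy(float)))
    vc: dict = {}
    boundary: dict = {}
    het_groups: dict = {}
    blups: dict = {}
    marker_effects = None
    mby = None
    for k, pt in enumerate(parts):
        u = theta[k] * (pt.Z.T @ Py)
        if pt.kind == "marker":
            marker_effects = pd.Series(u, index=spec.markers.columns, name="u_g")
            vc[pt.name] = theta[k]
            boundary[pt.name] = theta[k] == 0.0
        elif pt.kind == "marker_by_year":
            m = spec.markers.shape[1]
            mby = {yr: pd.Series(u[b * m:(b + 1) * m], index=spec.markers.columns)
                   for b, yr in enumerate(pt.meta["years"])}
            vc[pt.name] = theta[k]
            boundary[pt.name] = theta[k] == 0.0
        elif pt.kind == "marker_by_year_het":
            grp = pt.meta["group"]
            het_groups.setdefault(grp, {})[pt.meta["year"]] = theta[k]
            if mby is None:
                mby = {}
            mby[pt.meta["year"]] = pd.Series(u, index=spec.markers.columns)
            boundary[f"{grp}[{pt.meta['year']}]"] = theta[k] == 0.0
        else:
            vc[pt.name] = theta[k]
            boundary[pt.name] = theta[k] == 0.0
        blups[pt.name] = u
    for grp, d in het_groups.items():
        vc[grp] = d
    for lbl, why in dropped.items():
        if "single level" not in why and lbl not in vc:
            vc[lbl] = 0.0
            boundary[lbl] = True
    vc["residual"] = theta[-1]
    boundary["residual"] = False
    return FitResult(
        variance_components=vc,
        boundary=boundary,
        beta=beta,
        beta_labels=X_labels,
        beta_cov=C,
        mean_labels=mean_labels,
        mean_idx=mean_idx,
        blups=blups,
        marker_effects=marker_effects,
        marker_by_year_effects=mby,
        loglik=ll,
        info_matrix=info,
        param_names=names,
        converged=converged,
        n_iter=it,
        warnings=warns,
        dropped_terms=dropped,
        random_term_labels=[pt.name for pt in parts],
        n_obs=n,
    )


def _saturated_fit(spec, data, y, X, X_labels, mean_idx, mean_labels, parts, warns, dropped):
    """Zero residual degrees of freedom: adjusted means are the (averaged) raw values."""
    warns = warns + ["saturated model (no residual degrees of freedom): "
                     "means equal raw values, weights equal replicate counts"]
    XtX = X.T @ X
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    counts = np.diag(XtX)
    C = np.diag(1.0 / np.maximum(counts, 1.0))
    vc = {pt.name: 0.0 for pt in parts}
    vc["residual"] = 0.0
    return FitResult(
        variance_components=vc,
        boundary={k: True for k in vc},
        beta=beta,
        beta_labels=X_labels,
        beta_cov=C,
        mean_labels=mean_labels,
        mean_idx=mean_idx,
        blups={},
        marker_effects=None,
        marker_by_year_effects=None,
        loglik=np.nan,
        info_matrix=np.zeros((len(parts) + 1, len(parts) + 1)),
        param_names=[pt.name for pt in parts] + ["residual"],
        converged=True,
        n_iter=0,
        warnings=warns,
        dropped_terms=dropped,
        random_term_labels=[pt.name for pt in parts],
        n_obs=len(y),
    )


def solve_mme(spec: ModelSpec, data: pd.DataFrame, variance_components: dict) -> FitResult:
    """Joint GLS/BLUP solution of the mixed-model equations at known components."""
    return reml_fit(spec, data, fixed_components=variance_components)


def gebv(fit: FitResult, Z: pd.DataFrame, ids) -> pd.Series:
    """GEBV ``v = Z u_g`` for any genotypes with marker rows (phenotyped or not)."""
    if fit.marker_effects is None:
        raise ValueError("fit has no marker main-effect term")
    ids = pd.Index(ids)
    missing = ids.difference(Z.index)
    if len(missing):
        raise KeyError(f"genotypes without marker rows: {sorted(map(str, missing))}")
    v = Z.loc[ids].to_numpy(float) @ fit.marker_effects.to_numpy()
    return pd.Series(v, index=ids, name="gebv")


def vc_asymptotic_correlation(fit: FitResult) -> pd.DataFrame:
    """Asymptotic correlation matrix of the variance-component estimates.

    Inverts the expected (average) information at convergence and scales to
    unit diagonal.  Parameters estimated as exactly zero are non-estimable
    and reported as NaN (mirroring the na entries of ill-conditioned fits).
    Exactly confounded pairs make the information singular; a vanishing
    ridge is added before inversion so those pairs report the limiting
    correlation -1.
    """
    I = np.asarray(fit.info_matrix, dtype=float)
    names = list(fit.param_names)
    k = I.shape[0]
    out = np.full((k, k), np.nan)
    zero = np.array([fit.boundary.get(nm, False) or
                     (np.isclose(_component_value(fit, nm), 0.0)) for nm in names])
    zero[-1] = fit.variance_components.get("residual", 1.0) == 0.0
    idx = np.where(~zero)[0]
    if idx.size:
        sub = I[np.ix_(idx, idx)]
        ridge = 0.0
        try:
            cond = np.linalg.cond(sub)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e10:
            ridge = 1e-12 * max(np.mean(np.diag(sub)), np.finfo(float).tiny)
        try:
            cov = np.linalg.inv(sub + ridge * np.eye(idx.size))
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(sub)
        d = np.sqrt(np.clip(np.diag(cov), np.finfo(float).tiny, None))
        corr = cov / np.outer(d, d)
        corr = np.clip(corr, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        out[np.ix_(idx, idx)] = corr
    return pd.DataFrame(out, index=names, columns=names)


def _component_value(fit: FitResult, name: str) -> float:
    if name in fit.variance_components:
        v = fit.variance_components[name]
        if isinstance(v, dict):
            return float(np.mean(list(v.values())))
        return float(v)
    # het components are stored as group[year]
    for grp, v in fit.variance_components.items():
        if isinstance(v, dict):
            for yr, vv in v.items():
                if name == f"{grp}[{yr}]":
                    return float(vv)
    return np.nan


def smith_weights(fit: FitResult) -> pd.Series:
    """Per-mean weights: diagonal of the inverse of the adjusted means' covariance.

    These are the diagonal elements carried to the next stage as the
    (inverse) residual variances of the adjusted means.
    """
    if fit.mean_labels is None or fit.mean_idx is None:
        raise ValueError("fit has no adjusted-mean term")
    Cm = fit.beta_cov[np.ix_(fit.mean_idx, fit.mean_idx)]
    if np.all(np.diag(Cm) == 0):  # saturated special case: weight = replicate count
        raise ValueError("degenerate zero covariance of means")
    try:
        Wi = np.linalg.inv(Cm)
    except np.linalg.LinAlgError:
        bad = [fit.mean_labels[i] for i in range(len(fit.mean_labels))]
        raise ValueError(f"singular covariance of adjusted means; aliased means among {bad}")
    w = np.diag(Wi).copy()
    if np.any(w <= 0):
        raise ValueError("non-positive Smith weights (covariance not positive definite)")
    return pd.Series(w, index=fit.mean_labels, name="weight")
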