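"""Statistical layer: mixed models, multiplicity control, PERMANOVA, Tukey HSD.

The study design is hierarchical — cafeterias nested within sites, six bags
per cafeteria — so all per-genus tests are linear mixed models with random
intercepts for site and for cafeteria-within-site (plus genus when pooling
across genera).  Models are fitted by REML with nonnegativity-constrained
variance components; fixed effects come from generalised least squares at
the REML estimates, and test degrees of freedom use the Satterthwaite
approximation from the observed REML information.

Community-level substrate effects are tested by PERMANOVA whose permutation
null shuffles group labels only *within* each cafeteria, respecting the
blocked design.  Per-genus p-values are Benjamini-Hochberg corrected, and
significant substrate models are followed up with Tukey HSD contrasts on
the studentized-range distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "hellinger",
    "LMMSpec",
    "LMMFit",
    "fit_lmm",
    "test_genus_intercepts",
    "bh_adjust",
    "PermanovaResult",
    "permanova_restricted",
    "bray_curtis",
    "tukey_hsd",
    "fig1_scatter",
]


def hellinger(row) -> np.ndarray:
    """Hellinger transformation: element-wise square root of relative
    abundances (values must lie in [0, 1])."""
    arr = np.asarray(row, dtype=float)
    if (arr < 0).any():
        raise ValueError("relative abundances must be nonnegative")
    if (arr > 1).any():
        raise ValueError("relative abundances must be <= 1")
    return np.sqrt(arr)


# ---------------------------------------------------------------------------
# REML linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class LMMSpec:
    """A mixed-model specification.

    ``fixed`` is the fixed-effect design matrix (first column the intercept);
    ``random`` maps factor names to per-observation level labels, each
    contributing one random-intercept variance component.  Nesting is
    expressed through the labels themselves (cafeteria ids are globally
    unique, so a plain "cafeteria" factor is cafeteria-within-site).
    """

    response: np.ndarray
    fixed: pd.DataFrame
    random: dict[str, np.ndarray]

    @classmethod
    def build(
        cls,
        response,
        factor=None,
        random: dict | None = None,
    ) -> "LMMSpec":
        """Intercept-only, or one categorical fixed factor (treatment coding,
        first level as reference)."""
        y = np.asarray(response, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response must be finite")
        X = pd.DataFrame({"(Intercept)": np.ones(len(y))})
        if factor is not None:
            labels = pd.Categorical(factor)
            dummies = pd.get_dummies(labels, drop_first=True, dtype=float)
            dummies.columns = [f"{c}" for c in dummies.columns]
            X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
        rnd = {k: np.asarray(v) for k, v in (random or {}).items()}
        for name, lab in rnd.items():
            if len(lab) != len(y):
                raise ValueError(f"random factor {name!r} length mismatch")
        return cls(response=y, fixed=X, random=rnd)


@dataclass
class LMMFit:
    """REML fit: estimates, variance components and test machinery."""

    spec: LMMSpec
    beta: np.ndarray
    cov_beta: np.ndarray
    vcomp: dict[str, float]  # includes "residual"
    reml_loglik: float
    converged: bool
    singular: bool
    factor_levels: list[str] = field(default_factory=list)
    _Z: list[np.ndarray] = field(default_factory=list, repr=False)
    _names: list[str] = field(default_factory=list, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)
    _theta_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def fixed_names(self) -> list[str]:
        return list(self.spec.fixed.columns)

    # -- Satterthwaite machinery ------------------------------------------
    def _cov_beta_at(self, theta: np.ndarray) -> np.ndarray:
        X = self.spec.fixed.to_numpy(dtype=float)
        V = _build_V(theta, self._Z, len(self.spec.response))
        Vi = np.linalg.inv(V)
        return np.linalg.inv(X.T @ Vi @ X)

    def contrast_variance_gradient(self, L: np.ndarray) -> np.ndarray:
        """d Var(L beta) / d theta by central differences."""
        theta = self._theta
        grad = np.zeros(len(theta))
        for i in range(len(theta)):
            h = max(1e-6, 1e-4 * abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] = max(0.0, tm[i] - h)
            step = tp[i] - tm[i]
            vp = float(L @ self._cov_beta_at(tp) @ L)
            vm = float(L @ self._cov_beta_at(tm) @ L)
            grad[i] = (vp - vm) / step
        return grad

    def satterthwaite_df(self, L: np.ndarray) -> float:
        """Denominator df for the single contrast L via Satterthwaite."""
        n, p = self.spec.fixed.shape
        resid_df = max(n - p, 1)
        if self._theta_cov is None:
            return float(resid_df)
        v = float(L @ self.cov_beta @ L)
        g = self.contrast_variance_gradient(L)
        denom = float(g @ self._theta_cov @ g)
        if denom <= 0 or not np.isfinite(denom):
            return float(resid_df)
        df = 2.0 * v**2 / denom
        return float(np.clip(df, 1.0, resid_df))

    def contrast_test(self, L) -> dict:
        """t-test of L'beta = 0 with Satterthwaite df."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.beta)
        se = float(np.sqrt(L @ self.cov_beta @ L))
        if se == 0.0:
            return {
                "estimate": est, "se": 0.0, "df": float("nan"),
                "t": float("nan"), "p": 1.0 if est == 0.0 else 0.0,
            }
        df = self.satterthwaite_df(L)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return {"estimate": est, "se": se, "df": df, "t": t, "p": float(p)}

    def intercept_test(self) -> dict:
        L = np.zeros(len(self.beta))
        L[0] = 1.0
        return self.contrast_test(L)

    def factor_ftest(self) -> dict:
        """F-test that all non-intercept fixed coefficients are zero.

        Multi-degree Satterthwaite: eigen-contrasts of the coefficient
        covariance each get a one-df Satterthwaite value; these are combined
        into a single denominator df.
        """
        p = len(self.beta)
        q = p - 1
        if q < 1:
            raise ValueError("no fixed factor in this model")
        Lmat = np.zeros((q, p))
        for i in range(q):
            Lmat[i, i + 1] = 1.0
        M = Lmat @ self.cov_beta @ Lmat.T
        est = Lmat @ self.beta
        F = float(est @ np.linalg.solve(M, est) / q)
        # eigen-contrasts
        w, U = np.linalg.eigh(M)
        nus = []
        for i in range(q):
            Li = U[:, i] @ Lmat
            nus.append(self.satterthwaite_df(Li))
        nus = [nu for nu in nus if nu > 2.0]
        if nus:
            E = sum(nu / (nu - 2.0) for nu in nus)
            ddf = 2.0 * E / (E - q) if E > q else float(len(self.spec.response) - p)
        else:
            ddf = float(max(len(self.spec.response) - p, 1))
        ddf = float(np.clip(ddf, 1.0, max(len(self.spec.response) - p, 1)))
        pval = float(stats.f.sf(F, q, ddf)) if np.isfinite(F) else float("nan")
        return {"F": F, "df_num": q, "df_den": ddf, "p": pval}


def _build_V(theta: np.ndarray, Z: list[np.ndarray], n: int) -> np.ndarray:
    V = theta[-1] * np.eye(n)
    for k, Zk in enumerate(Z):
        V += theta[k] * (Zk @ Zk.T)
    return V


def _neg2_reml(theta: np.ndarray, y: np.ndarray, X: np.ndarray, Z: list[np.ndarray]) -> float:
    n = len(y)
    V = _build_V(theta, Z, n)
    try:
        cf = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf))))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e10
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    return logdetV + logdetX + quad


def fit_lmm(spec: LMMSpec) -> LMMFit:
    """Fit a random-intercept mixed model by REML.

    Variance components are optimised under nonnegativity bounds from a
    deterministic start (half the response variance split across
    components); fixed effects are the GLS solution at the optimum.  A
    component estimated at (numerical) zero flags the fit as singular but is
    not an error.  Non-identifiable fixed designs raise.
    """
    y = spec.response
    X = spec.fixed.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed parameters than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is not identifiable")
    names = list(spec.random.keys())
    Z = []
    for name in names:
        labels = pd.Categorical(spec.random[name])
        Z.append(pd.get_dummies(labels, dtype=float).to_numpy())

    vy = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if vy == 0.0:
        # constant response: every component degenerate
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        vc = {name: 0.0 for name in names}
        vc["residual"] = 0.0
        return LMMFit(
            spec=spec, beta=beta, cov_beta=np.zeros((p, p)), vcomp=vc,
            reml_loglik=float("nan"), converged=True, singular=True,
            _Z=Z, _names=names, _theta=np.zeros(len(names) + 1), _theta_cov=None,
        )

    k = len(Z)
    start = np.full(k + 1, vy / (k + 1))
    bounds = [(0.0, 10.0 * vy)] * k + [(1e-10 * vy, 10.0 * vy)]
    res = optimize.minimize(
        _neg2_reml, start, args=(y, X, Z), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    theta = np.maximum(res.x, 0.0)
    tol = 1e-8 * vy
    singular = bool(np.any(theta[:k] <= tol)) if k else False

    V = _build_V(theta, Z, n)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (Vi_X.T @ y)

    # observed information for the free (non-boundary) components
    free = [i for i in range(k + 1) if theta[i] > tol]
    theta_cov = None
    if free:
        H = _numeric_hessian(
            lambda t: _neg2_reml(_expand(theta, free, t), y, X, Z),
            theta[free],
        )
        try:
            theta_cov_free = 2.0 * np.linalg.inv(H)
            theta_cov = np.zeros((k + 1, k + 1))
            for a, ia in enumerate(free):
                for b, ib in enumerate(free):
                    theta_cov[ia, ib] = theta_cov_free[a, b]
        except np.linalg.LinAlgError:
            theta_cov = None

    vc = {name: float(theta[i]) for i, name in enumerate(names)}
    vc["residual"] = float(theta[k])
    factor_levels = [c for c in spec.fixed.columns if c != "(Intercept)"]
    return LMMFit(
        spec=spec, beta=beta, cov_beta=cov_beta, vcomp=vc,
        reml_loglik=-0.5 * float(res.fun), converged=bool(res.success),
        singular=singular, factor_levels=factor_levels,
        _Z=Z, _names=names, _theta=theta, _theta_cov=theta_cov,
    )


def _expand(theta: np.ndarray, free: list[int], tfree: np.ndarray) -> np.ndarray:
    full = theta.copy()
    full[free] = np.maximum(tfree, 0.0)
    return full


def _numeric_hessian(f, x: np.ndarray) -> np.ndarray:
    m = len(x)
    H = np.zeros((m, m))
    h = np.maximum(1e-5, 1e-3 * np.abs(x))
    f0 = f(x)
    for i in range(m):
        for j in range(i, m):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# per-genus tests with BH correction
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(list(pvalues), dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_genus_intercepts(log_ratios: pd.DataFrame, min_records: int = 2) -> pd.DataFrame:
    """Per-genus intercept-only mixed models on the log ratios.

    For each (genus, ratio_type) with at least ``min_records`` cafeteria
    records, fits ``log_ratio ~ 1 + (1|site) + (1|cafeteria)`` and tests the
    intercept against zero; BH correction is applied across genera within
    each ratio_type family.  Returns one row per fitted model with columns
    genus, ratio_type, n_cafeterias, estimate, se, df, p, p_adj, singular.
    """
    rows = []
    for (rt, genus), grp in log_ratios.groupby(["ratio_type", "genus"], sort=True):
        if len(grp) < min_records:
            logger.info("genus %s (%s): only %d records; skipped", genus, rt, len(grp))
            continue
        spec = LMMSpec.build(
            grp["log_ratio"].to_numpy(),
            random={"site": grp["site"].to_numpy(), "cafeteria": grp["cafeteria"].to_numpy()},
        )
        fit = fit_lmm(spec)
        test = fit.intercept_test()
        rows.append(
            {
                "genus": genus,
                "ratio_type": rt,
                "n_cafeterias": int(grp["cafeteria"].nunique()),
                "estimate": test["estimate"],
                "se": test["se"],
                "df": test["df"],
                "p": test["p"],
                "singular": fit.singular,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["genus", "ratio_type", "n_cafeterias", "estimate", "se", "df", "p", "singular"],
    )
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out["p_adj"] = np.nan
    for rt, grp in out.groupby("ratio_type"):
        out.loc[grp.index, "p_adj"] = bh_adjust(grp["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# PERMANOVA with within-block permutations
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    blocks_used: int


def bray_curtis(data: np.ndarray) -> np.ndarray:
    """Bray-Curtis distance matrix between sample rows."""
    return squareform(pdist(np.asarray(data, dtype=float), metric="braycurtis"))


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_among, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total - ss_within, ss_within


def permanova_restricted(
    distance_matrix: np.ndarray,
    group_labels,
    blocks,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA whose permutations shuffle labels only within blocks.

    The pseudo-F is the classical among/within partition of squared
    dissimilarities; the null distribution permutes group labels
    independently and uniformly within each block (cafeteria), identity
    permutation allowed.  p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    D = np.asarray(distance_matrix, dtype=float)
    groups = np.asarray(group_labels)
    blocks = np.asarray(blocks)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be square symmetric with zero diagonal")
    if len(groups) != n or len(blocks) != n:
        raise ValueError("labels must match the distance matrix")
    uniq = np.unique(groups)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least two groups")
    block_idx = [np.flatnonzero(blocks == b) for b in np.unique(blocks)]
    multi = [idx for idx in block_idx if len(idx) > 1]
    for idx in block_idx:
        if len(idx) == 1:
            logger.info("block with single sample contributes no permutations")
    if not multi:
        raise ValueError("all blocks are singletons; no permutation is possible")

    d2 = D**2
    ss_a, ss_w = _permanova_ss(d2, groups)
    if ss_w <= 0:
        f_obs = np.inf
    else:
        f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))
    r2 = ss_a / (ss_a + ss_w) if (ss_a + ss_w) > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    perm = groups.copy()
    for _ in range(n_perm):
        for idx in multi:
            perm[idx] = groups[idx][rng.permutation(len(idx))]
        pa, pw = _permanova_ss(d2, perm)
        f_perm = np.inf if pw <= 0 else (pa / (a - 1)) / (pw / (n - a))
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(r2),
        p_value=float(p),
        n_permutations=n_perm,
        blocks_used=len(multi),
    )


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def tukey_hsd(fit: LMMFit) -> pd.DataFrame:
    """All-pairs Tukey HSD contrasts of a categorical fixed factor.

    Marginal means are intercept (reference level) and intercept + coefficient
    (other levels, treatment coding); each pairwise difference is tested on
    the studentized-range distribution with that contrast's Satterthwaite df.
    With two levels this reduces exactly to the unadjusted pairwise t-test.
    Returns columns level_a, level_b, estimate, se, df, p_adj.
    """
    k = len(fit.factor_levels) + 1
    if k < 2:
        raise ValueError("Tukey HSD needs a factor with at least 2 levels")
    p = len(fit.beta)
    # level i marginal-mean coefficient vector
    level_names = ["<reference>"] + list(fit.factor_levels)
    Ls = []
    for i in range(k):
        L = np.zeros(p)
        L[0] = 1.0
        if i > 0:
            L[i] = 1.0
        Ls.append(L)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        L = Ls[j] - Ls[i]
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ fit.cov_beta @ L))
        if se == 0.0:
            rows.append(
                {"level_a": level_names[i], "level_b": level_names[j],
                 "estimate": est, "se": 0.0, "df": float("nan"),
                 "p_adj": 1.0 if est == 0.0 else 0.0}
            )
            continue
        df = fit.satterthwaite_df(L)
        q = abs(est) / se * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, df))
        rows.append(
            {"level_a": level_names[i], "level_b": level_names[j],
             "estimate": est, "se": se, "df": df, "p_adj": min(p_adj, 1.0)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# figure
# ---------------------------------------------------------------------------

def fig1_scatter(
    intercepts: pd.DataFrame,
    abundances: pd.Series | None = None,
    path=None,
):
    """Scatter of per-genus bags-vs-roots (x) against soil-vs-sand (y)
    intercept estimates with SE error bars; point size scales with each
    genus's overall relative abundance.  Saves SVG/PNG when ``path`` given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide_est = intercepts.pivot(index="genus", columns="ratio_type", values="estimate")
    wide_se = intercepts.pivot(index="genus", columns="ratio_type", values="se")
    x = wide_est.get("bags_vs_roots")
    y = wide_est.get("soil_vs_sand")
    common = x.dropna().index.intersection(y.dropna().index)
    sizes = 60.0
    if abundances is not None:
        sizes = 600.0 * abundances.reindex(common).fillna(0.01).to_numpy()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(
        x[common], y[common],
        xerr=wide_se.loc[common, "bags_vs_roots"],
        yerr=wide_se.loc[common, "soil_vs_sand"],
        fmt="none", ecolor="0.6", zorder=1,
    )
    ax.scatter(x[common], y[common], s=sizes, zorder=2)
    for g in common:
        ax.annotate(g, (x[g], y[g]), fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.axhline(0.0, ls="--", c="0.4")
    ax.axvline(0.0, ls="--", c="0.4")
    ax.set_xlabel("log ratio: ingrowth bags vs roots")
    ax.set_ylabel("log ratio: soil bags vs sand bags")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
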