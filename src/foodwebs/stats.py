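"""Comparison layer: per-metric mixed models, Tukey letters, and PCA.

Each food-web metric is compared across web types (FS = foundation
species-dominated, BA = real bare, RR = random removal) with a linear
mixed model

    metric ~ web_type + (1 | ecosystem)

fitted by REML.  The web-type effect is tested with a one-way ANOVA
F-test whose denominator degrees of freedom use the Satterthwaite
approximation, and all-pairs Tukey comparisons (studentized-range
adjusted) are condensed into compact letter displays, letters ordered by
ascending group mean.

The model fit itself is delegated to :class:`statsmodels` ``MixedLM``;
the Satterthwaite machinery (closed-form REML likelihood for the
random-intercept model, its observed information over the two variance
components, and gradients of contrast variances) is implemented here
because statsmodels does not provide it.

The overall multivariate response is summarised by a principal component
analysis of the metric panel, on the covariance matrix by default so
that high-variance metrics (species number, links) dominate axis 1 as
they do in raw-scale food-web data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.decomposition import PCA

from .core import FoodWebError
from .metrics import METRIC_NAMES

__all__ = [
    "LmeResult",
    "PcaResult",
    "fit_metric_lme",
    "pca_metrics",
    "pc1_contrast",
    "simulate_metric_table",
    "lme_summary_table",
]

TYPE_ORDER = ("FS", "BA", "RR")


@dataclass
class LmeResult:
    """Mixed-model comparison of one metric across web types."""

    metric: str
    fstat: float
    df_num: float
    df_den: float
    pvalue: float
    group_means: dict[str, float]
    letters: dict[str, str]
    pairwise: pd.DataFrame  # columns: a, b, estimate, se, t, df, p_tukey
    log_transformed: bool = False
    fallback_ols: bool = False
    var_ecosystem: float = float("nan")
    var_residual: float = float("nan")


# ---------------------------------------------------------------------------
# closed-form REML for the random-intercept model


class _RandomInterceptREML:
    """REML likelihood and GLS quantities for y = X b + u[group] + e."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        codes, _ = pd.factorize(groups)
        self.n, self.p = self.X.shape
        self.idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
        self.ni = np.array([len(i) for i in self.idx])
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.Sx = np.stack([self.X[i].sum(axis=0) for i in self.idx])  # (g, p)
        self.Sy = np.array([self.y[i].sum() for i in self.idx])  # (g,)

    def _gls(self, sg2: float, se2: float):
        c = sg2 / (se2 + self.ni * sg2)  # (g,)
        XtWX = (self.XtX - (self.Sx.T * c) @ self.Sx) / se2
        XtWy = (self.Xty - self.Sx.T @ (c * self.Sy)) / se2
        ytWy = (self.yty - float(c @ self.Sy**2)) / se2
        beta = np.linalg.solve(XtWX, XtWy)
        return XtWX, XtWy, ytWy, beta

    def phi(self, sg2: float, se2: float) -> np.ndarray:
        XtWX, _, _, _ = self._gls(sg2, se2)
        return np.linalg.inv(XtWX)

    def beta(self, sg2: float, se2: float) -> np.ndarray:
        return self._gls(sg2, se2)[3]

    def loglik(self, sg2: float, se2: float) -> float:
        """REML log-likelihood up to an additive constant."""
        XtWX, XtWy, ytWy, beta = self._gls(sg2, se2)
        logdetV = float(
            np.sum((self.ni - 1) * np.log(se2) + np.log(se2 + self.ni * sg2))
        )
        _, logdetXtWX = np.linalg.slogdet(XtWX)
        rss = ytWy - float(beta @ XtWy)
        return -0.5 * (logdetV + logdetXtWX + rss)

    # -- Satterthwaite ---------------------------------------------------

    def theta_vcov(self, sg2: float, se2: float) -> np.ndarray:
        """Asymptotic covariance of (sg2, se2): inverse observed information
        of the REML likelihood, by central finite differences."""
        th = np.array([max(sg2, 0.0), se2], float)
        h = np.maximum(1e-7, 1e-4 * np.maximum(th, se2))
        # keep sg2 evaluations non-negative
        if th[0] - h[0] < 0:
            h[0] = max(th[0] / 2, 1e-10)
        H = np.empty((2, 2))
        f0 = self.loglik(*th)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                if i == j:
                    f1 = self.loglik(*np.maximum(th + ei, 1e-12))
                    f2 = self.loglik(*np.maximum(th - ei, 1e-12))
                    H[i, i] = (f1 - 2 * f0 + f2) / h[i] ** 2
                else:
                    fpp = self.loglik(*np.maximum(th + ei + ej, 1e-12))
                    fpm = self.loglik(*np.maximum(th + ei - ej, 1e-12))
                    fmp = self.loglik(*np.maximum(th - ei + ej, 1e-12))
                    fmm = self.loglik(*np.maximum(th - ei - ej, 1e-12))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        info = -H
        try:
            A = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(info)
        # guard against a non-PD observed information at the boundary
        if not np.all(np.isfinite(A)) or A[0, 0] < 0 or A[1, 1] < 0:
            A = np.linalg.pinv(np.abs(info) + 1e-12 * np.eye(2))
        return A

    def contrast_df(self, c: np.ndarray, sg2: float, se2: float,
                    A: np.ndarray) -> float:
        """Satterthwaite df for the single contrast c'beta:
        df = 2 f^2 / (grad f' A grad f) with f(theta) = c' Phi(theta) c."""
        th = np.array([max(sg2, 0.0), se2], float)
        h = np.maximum(1e-7, 1e-4 * np.maximum(th, se2))
        if th[0] - h[0] < 0:
            h[0] = max(th[0] / 2, 1e-10)

        def f(t):
            return float(c @ self.phi(max(t[0], 1e-12), max(t[1], 1e-12)) @ c)

        f0 = f(th)
        grad = np.array(
            [
                (f(th + np.eye(2)[i] * h[i]) - f(th - np.eye(2)[i] * h[i])) / (2 * h[i])
                for i in range(2)
            ]
        )
        denom = float(grad @ A @ grad)
        if denom <= 0:
            return float(self.n - self.p)
        return 2 * f0**2 / denom


# ---------------------------------------------------------------------------


def _letters(group_means: dict[str, float], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display: types share a letter iff they lie in a common
    maximal clique of the 'not significantly different' graph; letters are
    assigned to cliques in order of ascending mean."""
    g = nx.Graph()
    g.add_nodes_from(group_means)
    for pair in nonsig_pairs:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda cl: np.mean([group_means[m] for m in cl]))
    letters = {t: "" for t in group_means}
    for k, cl in enumerate(cliques):
        ch = chr(ord("a") + k)
        for m in cl:
            letters[m] += ch
    return {t: "".join(sorted(s)) for t, s in letters.items()}


def _design(table: pd.DataFrame, metric: str):
    types = [t for t in TYPE_ORDER if t in set(table["web_type"])]
    if len(types) < 2:
        raise FoodWebError("need >= 2 web types for a contrast")
    y = table[metric].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise FoodWebError(f"metric {metric!r} has missing values")
    X = np.ones((len(table), len(types)))
    for j, t in enumerate(types[1:], start=1):
        X[:, j] = (table["web_type"] == t).to_numpy(float)
    return y, X, types


def fit_metric_lme(
    table: pd.DataFrame,
    metric: str,
    log_transform: str = "auto",
    alpha: float = 0.05,
) -> LmeResult:
    """Mixed-model F-test (Satterthwaite df) plus Tukey letters for one metric.

    ``log_transform``: ``"auto"`` log-transforms the response when a
    Shapiro-Wilk test on the residuals rejects normality at alpha = 0.05
    and all values are positive; ``"on"``/``"off"`` force the choice.

    With a single ecosystem the random intercept is unidentifiable and
    the model falls back to a fixed-effects ANOVA (``fallback_ols``).
    """
    import statsmodels.api as sm
    from scipy.optimize import minimize

    y, X, types = _design(table, metric)
    groups = table["ecosystem"].to_numpy()
    n_eco = len(set(groups))

    def _fit(yv):
        """REML variance components: statsmodels fit on the standardized
        response, polished on the closed-form likelihood (the generic
        optimizer can stall at the sigma_g^2 = 0 boundary)."""
        if n_eco < 2:
            return None
        scale = yv.std() or 1.0
        ys = yv / scale
        starts = [(0.1, 1.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(ys, X, groups=groups).fit(
                    reml=True, method=["lbfgs", "powell"]
                )
                sg2, se2 = float(np.asarray(res.cov_re)[0, 0]), float(res.scale)
                if np.isfinite(sg2) and np.isfinite(se2) and se2 > 0:
                    starts.insert(0, (max(sg2, 1e-8), se2))
            except Exception:
                pass
        reml = _RandomInterceptREML(ys, X, groups)

        def objective(t):
            t = np.clip(t, -30.0, 30.0)
            try:
                val = -reml.loglik(np.exp(t[0]), np.exp(t[1]))
            except np.linalg.LinAlgError:
                return 1e12
            return val if np.isfinite(val) else 1e12

        best = None
        for s0 in starts:
            opt = minimize(
                objective, np.log(s0), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400},
            )
            if best is None or opt.fun < best.fun:
                best = opt
        sg2, se2 = np.exp(np.clip(best.x, -30.0, 30.0))
        if sg2 < 1e-8:
            sg2 = 0.0
        return float(sg2 * scale**2), float(se2 * scale**2)

    fit = _fit(y)
    logged = False
    if log_transform in ("auto", "on") and np.all(y > 0):
        if log_transform == "on":
            logged = True
        elif fit is not None:
            reml = _RandomInterceptREML(y, X, groups)
            resid = y - X @ reml.beta(max(fit[0], 1e-12), fit[1])
            if len(resid) >= 3 and st.shapiro(resid).pvalue < alpha:
                logged = True
        if logged:
            y = np.log(y)
            fit = _fit(y)

    if fit is None:
        # fixed-effects one-way ANOVA fallback
        return _ols_anova(table, metric, y, X, types, logged, alpha)

    sg2, se2 = fit
    reml = _RandomInterceptREML(y, X, groups)
    beta = reml.beta(max(sg2, 1e-12), se2)
    phi = reml.phi(max(sg2, 1e-12), se2)
    A = reml.theta_vcov(max(sg2, 1e-12), se2)

    q = len(types) - 1
    C = np.zeros((q, len(types)))
    for i in range(q):
        C[i, i + 1] = 1.0
    M = C @ phi @ C.T
    evals, evecs = np.linalg.eigh(M)
    # F as the mean of squared scaled eigen-contrast t statistics
    tsq = []
    dfs = []
    for lam, v in zip(evals, evecs.T):
        if lam <= 1e-14:
            continue
        c = v @ C
        tsq.append(float(c @ beta) ** 2 / lam)
        dfs.append(reml.contrast_df(c, sg2, se2, A))
    fstat = float(np.sum(tsq) / q)
    # pool the per-eigencontrast dfs (Satterthwaite combination)
    E = sum(d / (d - 2) for d in dfs if d > 2)
    df_den = 2 * E / (E - q) if E > q else float(reml.n - reml.p)
    pvalue = float(st.f.sf(fstat, q, df_den))

    means = {types[0]: beta[0]}
    for j, t in enumerate(types[1:], start=1):
        means[t] = beta[0] + beta[j]

    rows = []
    nonsig = set()
    k = len(types)
    for a, b in combinations(types, 2):
        c = np.zeros(len(types))
        if a != types[0]:
            c[types.index(a)] = 1.0
        if b != types[0]:
            c[types.index(b)] -= 1.0
        est = float(c @ beta)
        var = float(c @ phi @ c)
        df_c = reml.contrast_df(c, sg2, se2, A)
        tval = est / np.sqrt(var)
        p_tuk = float(st.studentized_range.sf(abs(tval) * np.sqrt(2), k, df_c))
        rows.append({"a": a, "b": b, "estimate": est, "se": np.sqrt(var),
                     "t": tval, "df": df_c, "p_tukey": p_tuk})
        if p_tuk >= alpha:
            nonsig.add(frozenset((a, b)))
    pairwise = pd.DataFrame(rows)

    return LmeResult(
        metric=metric,
        fstat=fstat,
        df_num=float(q),
        df_den=float(df_den),
        pvalue=pvalue,
        group_means=means,
        letters=_letters(means, nonsig),
        pairwise=pairwise,
        log_transformed=logged,
        fallback_ols=False,
        var_ecosystem=sg2,
        var_residual=se2,
    )


def _ols_anova(table, metric, y, X, types, logged, alpha) -> LmeResult:
    """Fixed-effects fallback when the random intercept is unidentifiable."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_den = n - p
    se2 = float(resid @ resid) / df_den
    phi = se2 * np.linalg.inv(X.T @ X)
    q = p - 1
    Cb = beta[1:]
    Cphi = phi[1:, 1:]
    fstat = float(Cb @ np.linalg.solve(Cphi, Cb)) / q
    pvalue = float(st.f.sf(fstat, q, df_den))
    means = {types[0]: beta[0]}
    for j, t in enumerate(types[1:], start=1):
        means[t] = beta[0] + beta[j]
    rows = []
    nonsig = set()
    for a, b in combinations(types, 2):
        c = np.zeros(p)
        if a != types[0]:
            c[types.index(a)] = 1.0
        if b != types[0]:
            c[types.index(b)] -= 1.0
        est = float(c @ beta)
        var = float(c @ phi @ c)
        tval = est / np.sqrt(var)
        p_tuk = float(st.studentized_range.sf(abs(tval) * np.sqrt(2), len(types), df_den))
        rows.append({"a": a, "b": b, "estimate": est, "se": np.sqrt(var),
                     "t": tval, "df": float(df_den), "p_tukey": p_tuk})
        if p_tuk >= alpha:
            nonsig.add(frozenset((a, b)))
    return LmeResult(
        metric=metric, fstat=fstat, df_num=float(q), df_den=float(df_den),
        pvalue=pvalue, group_means=means, letters=_letters(means, nonsig),
        pairwise=pd.DataFrame(rows), log_transformed=logged, fallback_ols=True,
        var_ecosystem=0.0, var_residual=se2,
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    total_variation: float
    variance_pct: np.ndarray  # per axis, sums to 100
    scores: pd.DataFrame  # rows aligned to the input table
    loadings: pd.DataFrame  # metrics x axes
    standardized: bool


def pca_metrics(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    standardize: bool = False,
) -> PcaResult:
    """PCA of the metric panel: webs as samples, metrics as variables.

    Covariance PCA by default (``standardize=False``); the total
    variation is then the trace of the metric covariance matrix.
    """
    metrics = metrics or [m for m in METRIC_NAMES if m in table.columns]
    if len(table) < 3:
        raise FoodWebError("PCA needs at least 3 webs")
    Z = table[metrics].to_numpy(float)
    if standardize:
        sd = Z.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [m for m, s in zip(metrics, sd) if s == 0]
            raise FoodWebError(f"constant metric columns under standardize: {const}")
        Z = (Z - Z.mean(axis=0)) / sd
    n_comp = min(len(table) - 1, len(metrics))
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z)
    cov = np.cov(Z, rowvar=False, ddof=1)
    total = float(np.trace(cov))
    axes = [f"PC{i + 1}" for i in range(n_comp)]
    return PcaResult(
        total_variation=total,
        variance_pct=pca.explained_variance_ / total * 100,
        scores=pd.DataFrame(scores, index=table.index, columns=axes),
        loadings=pd.DataFrame(pca.components_.T, index=metrics, columns=axes),
        standardized=standardize,
    )


def pc1_contrast(pca: PcaResult, table: pd.DataFrame, alpha: float = 0.05) -> LmeResult:
    """Mixed-model web-type contrast on the first principal component."""
    sub = table[["ecosystem", "web_type"]].copy()
    sub["pc1"] = pca.scores["PC1"].to_numpy()
    res = fit_metric_lme(sub, "pc1", log_transform="off", alpha=alpha)
    res.metric = "PC1"
    return res


# ---------------------------------------------------------------------------
# simulation + reporting helpers


def simulate_metric_table(
    n_ecosystems: int = 7,
    reps: int = 4,
    type_effects: dict[str, float] | None = None,
    ecosystem_sd: float = 1.0,
    residual_sd: float = 1.0,
    baseline: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a study table from the mixed-model generative process.

    Each ecosystem gets a Normal(0, ecosystem_sd) random intercept; each
    web of type t gets ``baseline + type_effects[t]`` plus residual
    noise.  Used for type-I-error and power calibration of the LME.
    """
    type_effects = type_effects or {t: 0.0 for t in TYPE_ORDER}
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_ecosystems):
        u = rng.normal(0, ecosystem_sd)
        for t, eff in type_effects.items():
            for r in range(reps):
                rows.append(
                    {
                        "ecosystem": f"eco{e}",
                        "web_type": t,
                        "replicate": f"r{r}",
                        "value": baseline + eff + u + rng.normal(0, residual_sd),
                    }
                )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "ns"


def lme_summary_table(table: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-metric summary: per-type mean +/- SE, F, significance, letters."""
    metrics = metrics or [m for m in METRIC_NAMES if m in table.columns]
    types = [t for t in TYPE_ORDER if t in set(table["web_type"])]
    rows = []
    for m in metrics:
        res = fit_metric_lme(table, m)
        row = {"metric": m}
        for t in types:
            vals = table.loc[table["web_type"] == t, m]
            row[f"{t}_mean"] = vals.mean()
            row[f"{t}_se"] = vals.std(ddof=1) / np.sqrt(len(vals))
        row.update(
            F=res.fstat, df_num=res.df_num, df_den=res.df_den, p=res.pvalue,
            signif=_stars(res.pvalue),
            letters=", ".join(res.letters[t] for t in types),
            log_transformed=res.log_transformed,
        )
        rows.append(row)
    return pd.DataFrame(rows)
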