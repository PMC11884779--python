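"""Linear mixed models of log substitution rate, and auxiliary tests.

The central model regresses the log substitution rate of an amino-acid pair
on its difference covariates (PC1 "charge", PC2 "size", minimum mutational
steps, pyrimidine-proportion difference, optionally GC difference and the
PC1:PC2 interaction), with random intercepts for amino-acid identity.
Because every amino acid appears in many pairs, the random effects are
*crossed*: in directed mode one intercept per donor identity and one per
acceptor identity (two variance components); in undirected mode the two pair
slots share a single per-amino-acid component.

Fitting is by REML (coefficient reporting) or ML (model comparison) through
``statsmodels`` MixedLM with variance components.  On top of that fit the
module computes Satterthwaite denominator degrees of freedom (gradient of
each coefficient's variance with respect to the variance components, paired
with the REML log-likelihood curvature) and Nakagawa–Schielzeth marginal and
conditional R².

Welch's heteroscedastic one-way ANOVA and Welch's t-test, used to compare
mutational covariates across step classes, are thin validated wrappers over
pingouin and scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .genetic_code import AA_ORDER

__all__ = [
    "ModelSpec",
    "LmmFit",
    "fit_lmm",
    "fit_by_steps",
    "compare_models",
    "marginal_r2",
    "welch_anova",
    "welch_t_test",
]

KNOWN_TERMS = ("PC1", "PC2", "min_steps", "pyr_diff", "gc_diff", "PC1:PC2")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed terms, random structure, scaling policy."""

    response: str = "log_rate"
    fixed: tuple[str, ...] = ("PC1", "PC2", "min_steps", "pyr_diff", "PC1:PC2")
    #: ("auto",) derives the crossed amino-acid intercepts from the pair
    #: columns (donor + acceptor when directed, one shared component when
    #: unordered); any other tuple names data columns used as iid
    #: random-intercept factors (e.g. mutational covariates as random terms).
    random: tuple[str, ...] = ("auto",)
    reml: bool = True
    zscore_response: bool = True
    zscore_predictors: bool = True
    satterthwaite: bool = True

    def __post_init__(self) -> None:
        if not self.random:
            raise ValueError("at least one random factor is required")
        for term in self.fixed:
            if ":" in term:
                a, b = term.split(":")
                if a not in self.fixed or b not in self.fixed:
                    raise ValueError(
                        f"interaction {term} requires both main effects in the spec"
                    )

    def without(self, *terms: str) -> "ModelSpec":
        return replace(self, fixed=tuple(t for t in self.fixed if t not in terms))

    def with_ml(self) -> "ModelSpec":
        return replace(self, reml=False)


@dataclass
class LmmFit:
    """Fitted mixed model: coefficient table, variances, fit statistics."""

    terms: list[str]
    beta: pd.Series
    se: pd.Series
    df: pd.Series
    t: pd.Series
    p: pd.Series
    var_u: dict[str, float]
    sigma2: float
    loglik: float
    aic: float
    n_params: int
    var_fixed: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    boundary: list[str]
    n: int
    reml: bool
    spec: ModelSpec
    scaling: dict = field(default_factory=dict)

    def summary_table(self, p_floor: float | None = None) -> pd.DataFrame:
        """Coefficient table (term, estimate, SE, df, t, p).

        ``p_floor`` truncates tiny p-values for display (e.g. 2e-16 prints
        as ``<2.0e-16``); estimates are never touched.
        """
        tab = pd.DataFrame(
            {
                "term": self.beta.index,
                "estimate": self.beta.values,
                "se": self.se.values,
                "df": self.df.values,
                "t": self.t.values,
                "p": self.p.values,
            }
        )
        if p_floor is not None:
            tab["p"] = [
                f"<{p_floor:.1e}" if p < p_floor else f"{p:.3g}" for p in tab["p"]
            ]
        return tab


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Build response, fixed design and per-slot random-factor columns."""
    y = data[spec.response].to_numpy(dtype=float)
    scaling: dict[str, tuple[float, float]] = {}
    if spec.zscore_response:
        mu, sd = y.mean(), y.std(ddof=1)
        if sd == 0:
            raise ValueError("response is constant; cannot z-score")
        y = (y - mu) / sd
        scaling[spec.response] = (mu, sd)

    mains: dict[str, np.ndarray] = {}
    for term in spec.fixed:
        if ":" in term:
            continue
        x = data[term].to_numpy(dtype=float)
        if spec.zscore_predictors:
            mu, sd = x.mean(), x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {term!r} is constant; cannot z-score")
            x = (x - mu) / sd
            scaling[term] = (mu, sd)
        mains[term] = x

    cols = {"Intercept": np.ones(len(y))}
    for term in spec.fixed:
        if ":" in term:
            a, b = term.split(":")
            cols[term] = mains[a] * mains[b]
        else:
            cols[term] = mains[term]
    X = pd.DataFrame(cols, index=data.index)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [c for c, d in zip(X.columns, np.abs(np.diag(r))) if d < 1e-10]
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")

    if spec.random == ("auto",):
        if "aa_from" in data.columns:
            slots = {"donor": data["aa_from"], "acceptor": data["aa_to"]}
            Zs = {
                name: pd.get_dummies(col).reindex(columns=list(AA_ORDER), fill_value=0)
                .to_numpy(dtype=float)
                for name, col in slots.items()
            }
        elif "aa1" in data.columns:
            z1 = pd.get_dummies(data["aa1"]).reindex(columns=list(AA_ORDER), fill_value=0)
            z2 = pd.get_dummies(data["aa2"]).reindex(columns=list(AA_ORDER), fill_value=0)
            Zs = {"aa": (z1 + z2).to_numpy(dtype=float)}
        else:
            raise ValueError("data must have aa_from/aa_to or aa1/aa2 columns")
    else:
        Zs = {
            name: pd.get_dummies(data[name].astype(str)).to_numpy(dtype=float)
            for name in spec.random
        }
    for name, Z in Zs.items():
        if (Z.sum(axis=0) > 0).sum() < 2:
            raise ValueError(f"random factor {name!r} has fewer than 2 levels")
    return y, X, Zs, scaling


def fit_lmm(data: pd.DataFrame, spec: ModelSpec | None = None) -> LmmFit:
    """Fit the Gaussian LMM with crossed amino-acid random intercepts.

    ``data`` is a pair feature table: one row per directed (``aa_from``,
    ``aa_to``) or unordered (``aa1``, ``aa2``) pair, with the response and
    all covariate columns named as in :data:`KNOWN_TERMS`.
    """
    spec = spec or ModelSpec()
    if not np.isfinite(data[spec.response].to_numpy(dtype=float)).all():
        raise ValueError("response contains non-finite values")
    y, X, Zs, scaling = _design(data, spec)
    n, p = X.shape

    frame = X.drop(columns=["Intercept"]).copy()
    frame["_y"] = y
    frame["_g"] = 1
    vc_formula = {}
    for name, Z in Zs.items():
        zcols = []
        for i in range(Z.shape[1]):
            cname = f"_{name}_{i}"
            frame[cname] = Z[:, i]
            zcols.append(cname)
        vc_formula[name] = "0 + " + " + ".join(zcols)
    fixed_rhs = " + ".join(f"Q('{c}')" for c in X.columns if c != "Intercept")
    formula = "_y ~ " + (fixed_rhs if fixed_rhs else "1")

    model = sm.MixedLM.from_formula(
        formula, groups="_g", vc_formula=vc_formula, data=frame
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # BFGS with a tight gradient tolerance resolves variance components
        # to near machine precision.  If it reports non-convergence (common
        # at a variance boundary) try the other optimizers, keep the best
        # likelihood, and validate that point with a direct local-optimality
        # probe rather than trusting optimizer flags — an optimizer can claim
        # success at a clearly worse point.
        candidates = []
        for method, kwargs in (
            ("bfgs", {"gtol": 1e-10}),
            ("cg", {}),
            ("powell", {}),
            (None, {}),
            ("lbfgs", {}),
        ):
            try:
                res = model.fit(reml=spec.reml, method=method, **kwargs)
            except Exception:
                continue
            if np.all(np.isfinite(np.asarray(res.params, dtype=float))):
                candidates.append(res)
            if candidates and candidates[-1].converged and method == "bfgs":
                break
    if not candidates:
        raise RuntimeError("mixed-model optimization failed for every optimizer")
    result = max(candidates, key=lambda r: r.llf)

    vc_names = list(model.exog_vc.names)
    vcomp = dict(zip(vc_names, np.asarray(result.vcomp, dtype=float)))
    sigma2 = float(result.scale)
    boundary = [k for k, v in vcomp.items() if v < 1e-6 * max(sigma2, 1.0)]

    theta_hat = np.array([vcomp[k] for k in vc_names] + [sigma2])
    Zarrs = [Zs[k] for k in vc_names]
    if not result.converged and not _is_local_optimum(
        y, X.to_numpy(), Zarrs, theta_hat, reml=spec.reml
    ):
        raise RuntimeError(
            "mixed-model optimizer did not converge and the returned point "
            f"is not a local optimum; final params: {result.params}"
        )

    beta = pd.Series(result.fe_params.to_numpy(), index=list(X.columns))

    # GLS covariance of beta at the estimated variance components; this is
    # the standard error convention of the mixed-model literature.
    se = pd.Series(
        np.sqrt(np.diag(_cov_beta(X.to_numpy(), Zarrs, theta_hat))),
        index=list(X.columns),
    )
    if spec.satterthwaite:
        dfs = _satterthwaite_dfs(y, X.to_numpy(), Zarrs, theta_hat, reml=spec.reml)
    else:
        dfs = np.full(p, float(n - p))
    dfs = np.clip(dfs, 1.0, float(n - p))
    df_ser = pd.Series(dfs, index=list(X.columns))
    tval = beta / se
    pval = pd.Series(
        2.0 * stats.t.sf(np.abs(tval.to_numpy()), df_ser.to_numpy()),
        index=list(X.columns),
    )

    n_params = p + len(vc_names) + 1
    loglik = float(result.llf)
    aic = -2.0 * loglik + 2.0 * n_params

    fitted_fixed = X.to_numpy() @ beta.to_numpy()
    var_fixed = float(np.var(fitted_fixed, ddof=1))
    # Undirected pairs carry two draws from the single shared component
    # (membership design has two unit loadings per row), so its variance
    # enters the decomposition twice; directed components are summed as-is.
    if vc_names == ["aa"]:
        var_random = 2.0 * vcomp["aa"]
    else:
        var_random = float(sum(vcomp.values()))
    total = var_fixed + var_random + sigma2
    r2m = var_fixed / total
    r2c = (var_fixed + var_random) / total

    return LmmFit(
        terms=list(spec.fixed),
        beta=beta,
        se=se,
        df=df_ser,
        t=tval,
        p=pval,
        var_u=vcomp,
        sigma2=sigma2,
        loglik=loglik,
        aic=aic,
        n_params=n_params,
        var_fixed=var_fixed,
        r2_marginal=r2m,
        r2_conditional=r2c,
        # either the optimizer reported success or the direct probe confirmed
        # a (possibly boundary) optimum — otherwise we raised above
        converged=True,
        boundary=boundary,
        n=n,
        reml=spec.reml,
        spec=spec,
        scaling=scaling,
    )


def _vmat(Zlist, theta, n):
    V = theta[-1] * np.eye(n)
    for v, Z in zip(theta[:-1], Zlist):
        V += v * (Z @ Z.T)
    return V


def _cov_beta(X, Zlist, theta):
    cf = cho_factor(_vmat(Zlist, theta, X.shape[0]))
    ViX = cho_solve(cf, X)
    return np.linalg.inv(X.T @ ViX)


def _profile_loglik(y, X, Zlist, theta, reml=True):
    """(RE)ML log-likelihood at given variance components, beta profiled out.

    Additive constants are omitted: only differences and curvature in theta
    are ever used.
    """
    cf = cho_factor(_vmat(Zlist, theta, X.shape[0]))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    r = y - X @ beta
    quad = float(r @ cho_solve(cf, r))
    ll = -0.5 * (logdet + quad)
    if reml:
        ll -= 0.5 * np.linalg.slogdet(XtViX)[1]
    return ll


def _is_local_optimum(y, X, Zlist, theta, reml=True, tol=1e-2):
    """Coordinate-wise probe that no feasible perturbation improves the fit."""
    try:
        ll0 = _profile_loglik(y, X, Zlist, theta, reml=reml)
    except np.linalg.LinAlgError:
        return False
    for m in range(len(theta)):
        for scale in (0.1, 0.01):
            step = scale * theta[m] + 1e-8
            for sign in (1.0, -1.0):
                th = theta.copy()
                th[m] += sign * step
                if th[m] < 0 or th[-1] <= 0:
                    continue
                try:
                    if _profile_loglik(y, X, Zlist, th, reml=reml) > ll0 + tol:
                        return False
                except np.linalg.LinAlgError:
                    continue
    return True


def _satterthwaite_dfs(y, X, Zlist, theta, reml=True):
    """Satterthwaite denominator df per fixed coefficient.

    df_j = 2 f_j^2 / (g_j' A g_j) with f_j = Var(beta_j | theta), g_j its
    gradient in the variance components theta = (v_1..v_K, sigma2), and A
    the asymptotic covariance of theta from the inverse negative Hessian of
    the (RE)ML log-likelihood.  Derivatives are central finite differences;
    the coefficient-variance gradient uses a relative 1e-6 step (absolute
    floor 1e-8 so zero-boundary components stay differentiable) and the
    log-likelihood Hessian a relative 1e-4 step, where the smaller step
    would be dominated by cancellation in second differences.
    """
    n, p = X.shape

    def cov_beta(th):
        return _cov_beta(X, Zlist, th)

    def loglik(th):
        return _profile_loglik(y, X, Zlist, th, reml=reml)

    k = len(theta)
    f0 = np.diag(cov_beta(theta))

    # gradient of each coefficient variance
    grad = np.zeros((p, k))
    for m in range(k):
        h = max(1e-8, 1e-6 * theta[m])
        tp, tm = theta.copy(), theta.copy()
        tp[m] += h
        tm[m] -= h
        grad[:, m] = (np.diag(cov_beta(tp)) - np.diag(cov_beta(tm))) / (2 * h)

    # Hessian of the log-likelihood
    steps = np.array([max(1e-5, 1e-4 * t) for t in theta])
    H = np.zeros((k, k))
    ll0 = loglik(theta)
    for m in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[m] += steps[m]
        tm[m] -= steps[m]
        H[m, m] = (loglik(tp) + loglik(tm) - 2 * ll0) / steps[m] ** 2
    for m in range(k):
        for l in range(m + 1, k):
            tpp, tmm, tpm, tmp = (theta.copy() for _ in range(4))
            tpp[[m, l]] += steps[[m, l]]
            tmm[[m, l]] -= steps[[m, l]]
            tpm[m] += steps[m]
            tpm[l] -= steps[l]
            tmp[m] -= steps[m]
            tmp[l] += steps[l]
            H[m, l] = H[l, m] = (
                loglik(tpp) + loglik(tmm) - loglik(tpm) - loglik(tmp)
            ) / (4 * steps[m] * steps[l])

    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(-H)
    dfs = np.empty(p)
    for j in range(p):
        denom = float(grad[j] @ A @ grad[j])
        dfs[j] = 2.0 * f0[j] ** 2 / denom if denom > 0 else float(n - p)
    return dfs


def fit_by_steps(
    data: pd.DataFrame, spec: ModelSpec, step_class: int
) -> LmmFit:
    """Fit the model on the subset of pairs separated by ``step_class`` mutations."""
    if "min_steps" in spec.fixed:
        raise ValueError("per-step fits require a spec without the min_steps term")
    subset = data[data["min_steps"] == step_class]
    if subset.empty:
        raise ValueError(f"no pairs with min_steps == {step_class}")
    fit = fit_lmm(subset.reset_index(drop=True), spec)
    if fit.boundary:
        warnings.warn(
            f"step-{step_class} subset (n={fit.n}): variance component(s) at "
            f"the zero boundary: {fit.boundary}",
            stacklevel=2,
        )
    return fit


def compare_models(full: LmmFit, reduced: LmmFit) -> dict:
    """Likelihood-ratio test of nested fixed-effect specifications (ML fits)."""
    if full.reml or reduced.reml:
        raise ValueError("model comparison requires ML fits (reml=False)")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced terms must be a subset)")
    if full.n != reduced.n:
        raise ValueError("models were fitted to different numbers of rows")
    df = len(full.terms) - len(reduced.terms)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {
        "chi2": chi2,
        "df": df,
        "p": p,
        "delta_aic": reduced.aic - full.aic,
    }


def marginal_r2(fit: LmmFit, conditional: bool = False) -> float:
    """Nakagawa–Schielzeth variance fraction explained by fixed effects.

    With ``conditional=True`` the random-intercept variance joins the
    numerator.
    """
    return fit.r2_conditional if conditional else fit.r2_marginal


def welch_anova(values, groups) -> dict:
    """Welch's heteroscedastic one-way ANOVA: {F, df1, df2, p}."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for g in labels:
        sub = values[groups == g]
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if np.var(sub, ddof=1) <= 0:
            raise ValueError(f"group {g!r} has zero variance")
    import pingouin as pg

    frame = pd.DataFrame({"value": values, "group": groups})
    res = pg.welch_anova(data=frame, dv="value", between="group").iloc[0]
    return {
        "F": float(res["F"]),
        "df1": float(res["ddof1"]),
        "df2": float(res["ddof2"]),
        "p": float(res["p_unc"]),
    }


def welch_t_test(x, y) -> dict:
    """Welch's unequal-variance two-sided t-test: {t, df, p}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}
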