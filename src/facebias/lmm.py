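"""Linear mixed models with Satterthwaite degrees of freedom.

All models in this package are random-intercept models, specified by a
list of grouping columns; when later factors nest inside the first
(e.g. subjects within social groups) the model is laid out with the
first factor as the outer grouping and the rest as variance
components, otherwise all factors are crossed variance components
within a single cluster. Estimation maximizes the exactly profiled
REML criterion (residual variance concentrated out; Woodbury identity
for the low-rank covariance) with a derivative-free search over the
one or two log variance ratios, from several starts: small,
boundary-prone variance components defeat generic gradient optimizers,
and the profiled search is both robust and fast at these problem
sizes. Components that land on the boundary are snapped to zero and
flagged as a singular fit — never silently dropped. Fits are
cross-checked against R's lme4/lmerTest in the test suite.

Denominator degrees of freedom for fixed-effect t-tests use the
Satterthwaite approximation: for a contrast ``l``, with
``f(theta) = l' (X' V(theta)^-1 X)^-1 l`` and ``A`` the asymptotic
covariance of the variance parameters (from the REML criterion's
finite-difference Hessian),

    df = 2 f(theta_hat)^2 / (g' A g),   g = grad f(theta_hat),

differentiating only over the variance parameters estimated away from
the boundary. With every component at zero this reduces to the
ordinary residual df, n - p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .exceptions import DegenerateInputError, SchemaError

__all__ = ["MixedModelResult", "fit_mixed_model"]

_ZERO_RATIO = 1e-8  # variance ratios below this snap to the boundary


@dataclass
class MixedModelResult:
    """A fitted linear mixed model.

    ``fixed_effects`` has one row per fixed-effect term with columns
    estimate, std_error, df, t_value, p_value (Satterthwaite df).
    ``random_variances`` maps each random-intercept factor to its
    estimated variance; ``singular`` flags a boundary fit.
    """

    fixed_effects: pd.DataFrame
    random_variances: dict
    residual_variance: float
    reml: bool
    converged: bool
    singular: bool
    n_obs: int
    metadata: dict = field(default_factory=dict)
    _beta: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _Z: list | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)
    _vc_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def term_names(self) -> list:
        return list(self.fixed_effects.index)

    def contrast(self, weights) -> dict:
        """Estimate, SE, Satterthwaite df, t and p for ``l' beta``."""
        l = np.asarray(weights, float)
        if l.shape != (self._X.shape[1],):
            raise ValueError(
                f"contrast length {l.shape} does not match {self._X.shape[1]} terms")
        est = float(l @ self._beta)
        if self._vc_cov is None:
            self._vc_cov = _vc_param_cov(self._theta, self._X, self._y, self._Z,
                                         self.reml)
        f0, df = _satterthwaite(l, self._theta, self._X, self._Z, self._vc_cov)
        se = float(np.sqrt(f0))
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return {"estimate": est, "std_error": se, "df": df, "t_value": t,
                "p_value": float(p)}

    def to_dict(self) -> dict:
        fe = self.fixed_effects.reset_index().rename(columns={"index": "term"})
        return {
            "fixed_effects": fe.to_dict(orient="records"),
            "random_variances": {k: float(v) for k, v in self.random_variances.items()},
            "residual_variance": float(self.residual_variance),
            "reml": self.reml,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": int(self.n_obs),
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# low-rank covariance algebra: V = sigma2 * W, W = I + sum_k lam_k Z_k Z_k'
# ---------------------------------------------------------------------------

def _one_hot(labels) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(labels))
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _w_factor(lam, Zs):
    """Woodbury factorization of W = I + sum lam_k Z_k Z_k'.

    Returns ``(fac, logdet_W)`` where ``fac`` applies W^-1 cheaply.
    """
    cols = [np.sqrt(lv) * Z for lv, Z in zip(lam, Zs) if lv > 0]
    if not cols:
        return None, 0.0
    Zt = np.hstack(cols)
    M = np.eye(Zt.shape[1]) + Zt.T @ Zt
    cf = cho_factor(M, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return (Zt, cf), logdet


def _w_solve(fac, B):
    if fac is None:
        return B
    Zt, cf = fac
    return B - Zt @ cho_solve(cf, Zt.T @ B)


def _profiled_crit(lam, X, y, Zs, reml=True):
    """REML/ML criterion with the residual variance profiled out.

    ``lam`` are variance ratios (component variance over residual
    variance). Returns (criterion, sigma2_hat) up to additive constants.
    """
    n, p = X.shape
    fac, logdetW = _w_factor(lam, Zs)
    WiX = _w_solve(fac, X)
    Wiy = _w_solve(fac, y)
    XtWiX = X.T @ WiX
    beta = np.linalg.solve(XtWiX, X.T @ Wiy)
    q = float(y @ Wiy - 2.0 * beta @ (X.T @ Wiy) + beta @ XtWiX @ beta)
    dof = (n - p) if reml else n
    s2 = max(q / dof, 1e-300)
    crit = logdetW + dof * np.log(s2)
    if reml:
        crit += float(np.linalg.slogdet(XtWiX)[1])
    return crit, s2


def _neg2_reml(theta, X, y, Zs, reml=True):
    """-2 log (restricted) likelihood at natural-scale variances, up to
    an additive constant."""
    n, p = X.shape
    s2 = theta[-1]
    lam = np.asarray(theta[:-1], float) / s2
    fac, logdetW = _w_factor(lam, Zs)
    WiX = _w_solve(fac, X)
    Wiy = _w_solve(fac, y)
    XtWiX = X.T @ WiX
    beta = np.linalg.solve(XtWiX, X.T @ Wiy)
    q = float(y @ Wiy - 2.0 * beta @ (X.T @ Wiy) + beta @ XtWiX @ beta)
    out = n * np.log(s2) + logdetW + q / s2
    if reml:
        out += float(np.linalg.slogdet(XtWiX)[1]) - p * np.log(s2)
    return out


def _gls(theta, X, y, Zs):
    """GLS fixed effects and their covariance at variance parameters theta."""
    s2 = theta[-1]
    lam = np.asarray(theta[:-1], float) / s2
    fac, _ = _w_factor(lam, Zs)
    WiX = _w_solve(fac, X)
    XtWiX = X.T @ WiX
    C = s2 * np.linalg.inv(XtWiX)
    beta = np.linalg.solve(XtWiX, WiX.T @ y)
    return beta, C


def _cov_beta(theta, X, Zs):
    s2 = theta[-1]
    lam = np.asarray(theta[:-1], float) / s2
    fac, _ = _w_factor(lam, Zs)
    return s2 * np.linalg.inv(X.T @ _w_solve(fac, X))


def _polish_reml(starts, X, y, Zs, reml=True):
    """Minimize the profiled criterion from the best of several starts
    (Nelder-Mead on log variance ratios); returns theta = (*variances,
    sigma2) with boundary ratios snapped to zero."""
    from scipy.optimize import minimize

    floor = 1e-10

    def crit_log(loglam):
        return _profiled_crit(np.exp(loglam), X, y, Zs, reml)[0]

    cands = sorted(
        (crit_log(np.log(np.maximum(np.asarray(s, float), floor))),
         np.log(np.maximum(np.asarray(s, float), floor)))
        for s in starts
    )
    best_val, best_lam = None, None
    for _, lam0 in cands[:2]:
        opt = minimize(crit_log, lam0, method="Nelder-Mead",
                       options=dict(xatol=1e-5, fatol=1e-8, maxiter=300))
        if best_val is None or opt.fun < best_val:
            best_val, best_lam = float(opt.fun), opt.x
    lam = np.exp(best_lam)
    lam[lam < _ZERO_RATIO] = 0.0
    val, s2 = _profiled_crit(lam, X, y, Zs, reml)
    if val > best_val + 1e-6:  # snapping must never cost criterion
        lam = np.exp(best_lam)
        _, s2 = _profiled_crit(lam, X, y, Zs, reml)
    return np.concatenate([lam * s2, [s2]])


# ---------------------------------------------------------------------------
# Satterthwaite df
# ---------------------------------------------------------------------------

def _fd_steps(theta, active, rel):
    scale = max(theta[-1], 1e-8)
    h = rel * np.maximum(np.abs(theta), 0.05 * scale)
    h[~active] = 0.0
    return h


def _active_mask(theta) -> np.ndarray:
    # components estimated at the boundary carry no local information
    active = np.asarray(theta, float) > 0
    active[-1] = True  # residual variance
    return active


def _vc_param_cov(theta, X, y, Zs, reml=True):
    """Asymptotic covariance of the active variance parameters: twice
    the pseudo-inverse of the criterion's finite-difference Hessian.

    Second differences need generous relative steps (1%) to beat
    cancellation in the O(n)-magnitude criterion.
    """
    active = _active_mask(theta)
    idx = np.flatnonzero(active)
    h = _fd_steps(theta, active, rel=1e-2)
    t0 = np.asarray(theta, float).copy()

    def crit(th):
        return _neg2_reml(th, X, y, Zs, reml)

    try:
        k = len(idx)
        H = np.zeros((k, k))
        for a in range(k):
            ea = np.zeros_like(t0)
            ea[idx[a]] = h[idx[a]]
            for b in range(a, k):
                eb = np.zeros_like(t0)
                eb[idx[b]] = h[idx[b]]
                H[a, b] = H[b, a] = (
                    crit(t0 + ea + eb) - crit(t0 + ea - eb)
                    - crit(t0 - ea + eb) + crit(t0 - ea - eb)
                ) / (4 * h[idx[a]] * h[idx[b]])
        A_small = 2.0 * np.linalg.pinv(H)
        A = np.zeros((len(t0), len(t0)))
        A[np.ix_(idx, idx)] = A_small
        return A
    except np.linalg.LinAlgError:
        return None


def _satterthwaite(l, theta, X, Zs, A):
    """Return (f(theta), df) for contrast l; falls back to the residual
    df when the variance information is degenerate or all components
    sit on the boundary."""
    n, p = X.shape
    fallback = max(n - p, 1)
    f0 = float(l @ _cov_beta(theta, X, Zs) @ l)
    if A is None:
        return f0, float(fallback)
    active = _active_mask(theta)
    if active.sum() == 1 and theta[:-1].sum() == 0.0:
        return f0, float(fallback)  # pure OLS
    h = _fd_steps(theta, active, rel=1e-3)
    t0 = np.asarray(theta, float).copy()

    def f(th):
        return float(l @ _cov_beta(th, X, Zs) @ l)

    try:
        g = np.zeros_like(t0)
        for i in np.flatnonzero(active):
            e = np.zeros_like(t0)
            e[i] = h[i]
            g[i] = (f(t0 + e) - f(t0 - e)) / (2 * h[i])
        denom = float(g @ A @ g)
        if not np.isfinite(denom) or denom <= 0:
            return f0, float(fallback)
        df = 2.0 * f0 * f0 / denom
        if not np.isfinite(df) or df <= 0:
            return f0, float(fallback)
        return f0, float(min(df, 1e7))
    except np.linalg.LinAlgError:
        return f0, float(fallback)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_mixed_model(
    data: pd.DataFrame,
    formula: str,
    random: "list[str] | tuple",
    reml: bool = True,
    variance_components: "dict | None" = None,
) -> MixedModelResult:
    """Fit a random-intercept linear mixed model with Satterthwaite df.

    Parameters
    ----------
    data : DataFrame with the response, fixed-effect and grouping columns.
    formula : patsy formula for the fixed effects, e.g. ``"bias_p ~ C(expression)"``.
    random : grouping columns receiving random intercepts, e.g.
        ``("group_id", "subject_id")``.
    reml : use REML (default) or ML estimation.
    variance_components : optionally fix each factor's variance (e.g. all
        zero); estimation is then plain GLS at those values with the
        residual variance estimated from the residuals, which reduces to
        OLS when all components are zero.
    """
    random = list(random)
    if not random:
        raise DegenerateInputError("at least one random-intercept factor is required")
    missing = [c for c in random if c not in data.columns]
    if missing:
        raise SchemaError(f"missing grouping column(s): {missing}")
    data = data.reset_index(drop=True)

    if variance_components is not None:
        return _fit_fixed_vc(data, formula, random, variance_components, reml)

    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    X = np.asarray(X_dm, float)
    y = np.asarray(y_dm, float).ravel()
    if len(y) <= X.shape[1] + 1:
        raise DegenerateInputError(
            f"too few observations ({len(y)}) for {X.shape[1]} fixed effects")
    Zs = [_one_hot(data[f]) for f in random]

    # spread of variance-ratio starts; the profiled search is cheap
    k = len(random)
    starts = [np.full(k, r) for r in (1e-3, 0.1, 1.0)]
    theta = _polish_reml(starts, X, y, Zs, reml)
    sigma2 = float(theta[-1])
    variances = {f: float(v) for f, v in zip(random, theta[:-1])}

    beta, _ = _gls(theta, X, y, Zs)
    term_names = list(X_dm.columns)
    singular = any(v == 0.0 for v in variances.values())

    result = MixedModelResult(
        fixed_effects=None,
        random_variances=variances,
        residual_variance=sigma2,
        reml=reml,
        converged=True,
        singular=singular,
        n_obs=len(y),
        metadata={"formula": formula, "random": random},
        _beta=beta, _X=X, _Z=Zs, _theta=theta, _y=y,
    )
    result.fixed_effects = _coef_table(result, term_names)
    return result


def _fit_fixed_vc(data, formula, random, variance_components, reml):
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    X = np.asarray(X_dm, float)
    y = np.asarray(y_dm, float).ravel()
    Zs = [_one_hot(data[f]) for f in random]
    vcs = np.array([float(variance_components.get(f, 0.0)) for f in random])
    if (vcs < 0).any():
        raise DegenerateInputError("variance components must be >= 0")
    n, p = X.shape
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    if vcs.sum() == 0.0:
        r = y - X @ beta_ols
        sigma2 = float(r @ r / (n - p if reml else n))
    else:
        # profile the residual variance given the fixed components
        from scipy.optimize import minimize_scalar

        def crit(log_s2):
            th = np.concatenate([vcs, [np.exp(log_s2)]])
            return _neg2_reml(th, X, y, Zs, reml)

        r = y - X @ beta_ols
        s2_0 = float(r @ r / max(n - p, 1))
        opt = minimize_scalar(crit, bracket=(np.log(s2_0) - 2, np.log(s2_0) + 2))
        sigma2 = float(np.exp(opt.x))
    theta = np.concatenate([vcs, [sigma2]])
    beta, _ = _gls(theta, X, y, Zs)

    result = MixedModelResult(
        fixed_effects=None,
        random_variances=dict(zip(random, vcs)),
        residual_variance=sigma2,
        reml=reml,
        converged=True,
        singular=bool((vcs == 0).any()),
        n_obs=n,
        metadata={"formula": formula, "random": random,
                  "variance_components_fixed": True},
        _beta=beta, _X=X, _Z=Zs, _theta=theta, _y=y,
        # no variance-parameter information when components are held
        # fixed: contrasts fall back to residual df (n - p)
        _vc_cov=np.zeros((len(random) + 1, len(random) + 1)),
    )
    result.fixed_effects = _coef_table(result, list(X_dm.columns))
    return result


def _coef_table(result: MixedModelResult, term_names) -> pd.DataFrame:
    p = result._X.shape[1]
    rows = []
    for j in range(p):
        l = np.zeros(p)
        l[j] = 1.0
        rows.append(result.contrast(l))
    tab = pd.DataFrame(rows, index=term_names)
    tab.index.name = "term"
    return tab[["estimate", "std_error", "df", "t_value", "p_value"]]
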