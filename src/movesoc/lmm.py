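"""Linear mixed models with crossed random intercepts and random slopes.

Small-n dense implementation: the marginal covariance V = sigma^2 (I + Z Psi Z')
is built explicitly and the profiled deviance (beta and sigma^2 concentrated
out) is minimised over the relative-Cholesky parameterisation of Psi, for
either maximum likelihood or REML.  Designed for the few-hundred-row datasets
this pipeline produces; validated against lme4 in the test suite.

Random structure is declared as a list of :class:`RandomTerm`; a term is a
grouping factor with an intercept and optionally a (by default correlated)
random slope on one model column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_SINGULAR_TOL = 1e-4


@dataclass(frozen=True)
class RandomTerm:
    """Random intercept for ``group``, plus an optional random slope."""

    group: str
    slope: str | None = None
    correlated: bool = True

    @property
    def n_params(self) -> int:
        if self.slope is None:
            return 1
        return 3 if self.correlated else 2


@dataclass
class LMMFit:
    """Fitted-model summary: coefficient table, variance parameters, fit stats."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    df_t: float
    sigma2: float
    theta: np.ndarray
    vc: dict
    loglik: float
    method: str
    n_obs: int
    n_fixed: int
    group_sizes: dict
    converged: bool
    singular: bool

    @property
    def n_params(self) -> int:
        """Fixed-effect parameter count (for LRT df bookkeeping)."""
        return self.n_fixed

    def coef_table(self) -> dict:
        return {
            name: {
                "estimate": float(b),
                "se": float(s),
                "t": float(t),
                "p": float(p),
            }
            for name, b, s, t, p in zip(
                self.names, self.beta, self.se, self.tvals, self.pvals
            )
        }


class _Structure:
    """Precomputed random-effect designs for one dataset."""

    def __init__(self, terms, groups, slopes, n):
        self.terms = terms
        self.Z = []           # per term: (indicator n x m, slope values or None)
        self.n = n
        for term in terms:
            codes, levels = groups[term.group]
            m = len(levels)
            ind = np.zeros((n, m))
            ind[np.arange(n), codes] = 1.0
            sl = slopes.get(term.slope) if term.slope is not None else None
            self.Z.append((ind, sl))

    def scaled_design(self, theta: np.ndarray) -> np.ndarray:
        """Columns W with V = I + W W' for the given relative-Cholesky theta."""
        cols = []
        k = 0
        for term, (ind, sl) in zip(self.terms, self.Z):
            if term.slope is None:
                cols.append(theta[k] * ind)
                k += 1
            else:
                zs = ind * sl[:, None]
                if term.correlated:
                    t0, t1, t2 = theta[k], theta[k + 1], theta[k + 2]
                    cols.append(t0 * ind + t1 * zs)
                    cols.append(t2 * zs)
                    k += 3
                else:
                    cols.append(theta[k] * ind)
                    cols.append(theta[k + 1] * zs)
                    k += 2
        return np.hstack(cols) if cols else np.empty((self.n, 0))


def _whitened_crossprods(theta, struct, X, y):
    """Woodbury-based quantities for V = I + W W' with W = scaled design.

    Returns (X'V^-1X, X'V^-1y, y'V^-1y, log|V|) at O(n q^2) for q random
    columns, avoiding the dense n x n factorisation.
    """
    from scipy.linalg import cho_factor, cho_solve

    W = struct.scaled_design(theta)
    q = W.shape[1]
    if q == 0:
        return X.T @ X, X.T @ y, float(y @ y), 0.0
    M = W.T @ W
    M[np.diag_indices_from(M)] += 1.0
    c, low = cho_factor(M, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    WtX = W.T @ X
    Wty = W.T @ y
    XtViX = X.T @ X - WtX.T @ cho_solve((c, low), WtX)
    XtViy = X.T @ y - WtX.T @ cho_solve((c, low), Wty)
    ytViy = float(y @ y - Wty @ cho_solve((c, low), Wty))
    return XtViX, XtViy, ytViy, logdet_v


def _profiled_neg2ll(theta, struct, X, y, reml):
    n, p = X.shape
    try:
        XtViX, XtViy, ytViy, logdet_v = _whitened_crossprods(theta, struct, X, y)
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return 1e10
    rss = float(ytViy - beta @ XtViy)
    if rss <= 0:
        return 1e10
    if reml:
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e10
        dof = n - p
        return (
            dof * math.log(2.0 * math.pi * rss / dof)
            + logdet_v
            + logdet_x
            + dof
        )
    return n * math.log(2.0 * math.pi * rss / n) + logdet_v + n


def _initial_thetas(terms):
    starts = []
    for scale in (1.0, 0.3, 2.5):
        th = []
        for term in terms:
            if term.slope is None:
                th.append(scale)
            elif term.correlated:
                th.extend([scale, 0.0, scale])
            else:
                th.extend([scale, scale])
        starts.append(np.array(th))
    return starts


def _bounds(terms):
    bounds = []
    for term in terms:
        if term.slope is None:
            bounds.append((0.0, None))
        elif term.correlated:
            bounds.extend([(0.0, None), (None, None), (0.0, None)])
        else:
            bounds.extend([(0.0, None), (0.0, None)])
    return bounds


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    data: "pd.DataFrame",
    random: list[RandomTerm],
    slope_columns: dict | None = None,
    method: str = "REML",
) -> LMMFit:
    """Fit a linear mixed model.

    ``data`` supplies the grouping factors named by ``random`` as columns;
    random-slope values are looked up in ``slope_columns`` (mapping column
    name -> array), falling back to the fixed-effects design column of the
    same name.  Never raises on a hard optimisation failure: the returned
    fit carries ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y have incompatible shapes")
    if n <= p:
        raise ValueError("more parameters than observations")
    reml = method.upper() == "REML"

    groups = {}
    group_sizes = {}
    for term in random:
        codes, levels = _factorize(data[term.group])
        groups[term.group] = (codes, levels)
        group_sizes[term.group] = len(levels)
    slopes = dict(slope_columns or {})
    for term in random:
        if term.slope is not None and term.slope not in slopes:
            try:
                slopes[term.slope] = X[:, names.index(term.slope)]
            except ValueError:
                raise KeyError(
                    f"random slope column {term.slope!r} not found"
                ) from None

    struct = _Structure(random, groups, slopes, n)

    if random:
        bounds = _bounds(random)
        best = None
        for theta0 in _initial_thetas(random):
            res = optimize.minimize(
                _profiled_neg2ll,
                theta0,
                args=(struct, X, y, reml),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun - 1e-8:
                best = res
            if best.success and best.fun < 1e9:
                break
        theta = best.x
        converged = bool(best.success) and best.fun < 1e9
        neg2ll = float(best.fun)
    else:       # fixed-effects-only: generalised least squares with V = I
        theta = np.empty(0)
        converged = True
        neg2ll = _profiled_neg2ll(theta, struct, X, y, reml)

    # final pass at the optimum for the coefficient table
    XtViX, XtViy, ytViy, _ = _whitened_crossprods(theta, struct, X, y)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = max(float(ytViy - beta @ XtViy), 0.0)
    sigma2 = rss / (n - p) if reml else rss / n
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    df_t = float(n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_t)
    loglik = -0.5 * neg2ll

    vc, singular = _variance_components(random, theta, sigma2)
    return LMMFit(
        names=list(names),
        beta=beta,
        se=se,
        tvals=tvals,
        pvals=pvals,
        df_t=df_t,
        sigma2=sigma2,
        theta=theta,
        vc=vc,
        loglik=loglik,
        method="REML" if reml else "ML",
        n_obs=n,
        n_fixed=p,
        group_sizes=group_sizes,
        converged=converged,
        singular=singular,
    )


def _factorize(col):
    import pandas as pd

    codes, levels = pd.factorize(col, sort=True)
    if (codes < 0).any():
        raise ValueError("missing values in grouping factor")
    return codes, levels


def _variance_components(terms, theta, sigma2):
    vc = {}
    singular = False
    k = 0
    for term in terms:
        if term.slope is None:
            sd = abs(theta[k]) * math.sqrt(max(sigma2, 0.0))
            vc[f"{term.group}"] = {"intercept_sd": sd}
            singular |= abs(theta[k]) < _SINGULAR_TOL
            k += 1
        else:
            if term.correlated:
                t0, t1, t2 = theta[k : k + 3]
                lam = np.array([[t0, 0.0], [t1, t2]])
                k += 3
            else:
                t0, t1 = theta[k : k + 2]
                lam = np.array([[t0, 0.0], [0.0, t1]])
                k += 2
            psi = lam @ lam.T * max(sigma2, 0.0)
            sd_i = math.sqrt(max(psi[0, 0], 0.0))
            sd_s = math.sqrt(max(psi[1, 1], 0.0))
            corr = psi[0, 1] / (sd_i * sd_s) if sd_i > 0 and sd_s > 0 else 0.0
            vc[f"{term.group}"] = {
                "intercept_sd": sd_i,
                f"slope_sd({term.slope})": sd_s,
                "corr": corr,
            }
            singular |= (
                abs(lam[0, 0]) < _SINGULAR_TOL
                or abs(lam[1, 1]) < _SINGULAR_TOL
                or abs(corr) > 0.999
            )
    return vc, singular


def lrt(full: LMMFit, null: LMMFit) -> tuple[int, float, float]:
    """Likelihood ratio test of nested ML fits: (df, chi2, p).

    Both fits must use maximum likelihood and share the random structure;
    the df is the fixed-effect parameter-count difference.
    """
    if full.method != "ML" or null.method != "ML":
        raise ValueError("LRT requires maximum-likelihood fits")
    if set(null.names) - set(full.names):
        raise ValueError("null model is not nested in the full model")
    df = full.n_fixed - null.n_fixed
    if df <= 0:
        raise ValueError("full model must add fixed-effect parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(chi2, df))
    return df, chi2, p
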