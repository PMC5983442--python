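"""Response-vs-N-addition curve fitting with AIC-based family selection.

Five model families describe how a response (yield, fixation or
mineralization rate) varies with the N addition level ``x``:

    linear        y = a + b*x
    log           y = a*log(x + 1) + c
    power         y = a*(x + 1)**b
    exponential   y = a*exp(b*(x + 1))
    quad_plateau  y = a + b*x + c*x**2 for x < x0, constant beyond,
                  with the join at the vertex x0 = -b/(2c), c < 0

The ``x + 1`` offsets keep the unfertilized (x = 0) treatment well-defined
in the log/power/exponential families. All families are fit by (weighted)
least squares; model quality is compared with the least-squares AIC

    AIC = n*ln(SSE/n) + 2*(k + 1)

(k parameters plus the error variance). A family counts as significant
when its effect parameter — the slope or shape coefficient that is zero
under no N response — differs from 0 by an asymptotic t-test at level
alpha, with standard errors from the Jacobian at the optimum. Selection
keeps significant fits only and returns the lowest AIC, with exact ties
broken by a fixed family order.

The quadratic-plateau family doubles as the agronomic-optimum estimator:
the join point is the minimum N rate achieving maximum yield. Following
the agronomic protocol, :func:`optimal_n` weights replicate observations
within each N level by the inverse of their rank (1, 1/2, 1/3, ...) of
distance from the level median, down-weighting outlying plots.

Usage follows the Model/Results convention: build a :class:`ResponseModel`
from arrays or a DataFrame, call :meth:`~ResponseModel.fit`, and read
estimates, standard errors and diagnostics off the returned
:class:`ResponseFit` (or print ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "FAMILY_ORDER",
    "DEFAULT_CANDIDATES",
    "ResponseData",
    "ResponseModel",
    "ResponseFit",
    "fit_family",
    "select_model",
    "optimal_n",
    "inverse_rank_weights",
]

#: Deterministic tie-break order for AIC ties.
FAMILY_ORDER = ("linear", "log", "power", "exponential", "quad_plateau")

#: Families screened by default when selecting a rate-response model.
#: The plateau family is reserved for yield/optimum estimation.
DEFAULT_CANDIDATES = ("linear", "log", "power", "exponential")

_EFFECT_PARAM = {
    "linear": "b",
    "log": "a",
    "power": "b",
    "exponential": "b",
    "quad_plateau": "b",
}

_N_PARAMS = {"linear": 2, "log": 2, "power": 2, "exponential": 2, "quad_plateau": 3}

_EXP_CLIP = 500.0  # exponent clip guarding overflow during multi-start search


@dataclass
class ResponseData:
    """Response observations vs N addition level.

    ``weights`` are relative least-squares weights (> 0); ``group`` is an
    optional site/period label carried through to outputs.
    """

    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if np.any(self.x < 0):
            raise ValueError("x (N addition) must be >= 0")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.x.shape:
                raise ValueError("weights must match x in shape")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        y: str,
        x: str = "treatment_kg_n",
        weights: str | None = None,
        group: str | None = None,
    ) -> "ResponseData":
        w = df[weights].to_numpy() if weights else None
        return cls(df[x].to_numpy(), df[y].to_numpy(), weights=w, group=group)


def _predict(family: str, params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if family == "linear":
        return params["a"] + params["b"] * x
    if family == "log":
        return params["a"] * np.log(x + 1.0) + params["c"]
    if family == "power":
        return params["a"] * np.power(x + 1.0, params["b"])
    if family == "exponential":
        return params["a"] * np.exp(np.clip(params["b"] * (x + 1.0), -_EXP_CLIP, _EXP_CLIP))
    if family == "quad_plateau":
        a, b, c = params["a"], params["b"], params["c"]
        if c == 0:
            return a + b * x
        x0 = -b / (2.0 * c)
        quad = a + b * x + c * x * x
        plateau = a - b * b / (4.0 * c)
        return np.where(x < x0, quad, plateau)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class ResponseFit:
    """Results of a single-family fit.

    Attributes
    ----------
    params, bse, tvalues, pvalues : dict
        Coefficient estimates, asymptotic SEs, t statistics and two-sided
        p-values (t distribution, ``n - k`` df).
    effect_param : str
        Name of the parameter tested for an N response.
    sse, aic : float
        Weighted error sum of squares and least-squares AIC.
    optimum_n : float or None
        Plateau join point, clamped to [0, max(x)] (plateau family only;
        0 when the fit falls back to linear).
    boundary : bool
        True when the unclamped join point lay outside the observed range.
    fallback_linear : bool
        Plateau curvature came out >= 0 and a linear fit was substituted.
    converged : bool
        False flags an optimization failure (never raised as an exception).
    """

    family: str
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    effect_param: str
    sse: float
    aic: float
    n: int
    k: int
    converged: bool = True
    optimum_n: float | None = None
    boundary: bool = False
    fallback_linear: bool = False
    group: str | None = None
    #: Extra-sum-of-squares F-test p-value of the whole model against the
    #: constant mean (plateau family only). The join-point profile makes the
    #: single-coefficient t-test anti-conservative near x0 = 0, so the
    #: no-effect decision for the agronomic optimum uses this instead.
    f_pvalue: float | None = None

    @property
    def effect_pvalue(self) -> float:
        return self.pvalues[self.effect_param]

    def significant(self, alpha: float = 0.05) -> bool:
        return self.converged and self.effect_pvalue < alpha

    def predict(self, x: np.ndarray) -> np.ndarray:
        fam = "linear" if self.fallback_linear else self.family
        return _predict(fam, self.params, x)

    def summary(self) -> str:
        lines = [
            f"Response fit: family={self.family}"
            + (f" (group={self.group})" if self.group else ""),
            f"n={self.n}  k={self.k}  SSE={self.sse:.6g}  AIC={self.aic:.3f}  "
            f"converged={self.converged}",
            f"{'param':>6} {'coef':>12} {'se':>12} {'t':>9} {'P>|t|':>9}",
        ]
        for name in self.params:
            lines.append(
                f"{name:>6} {self.params[name]:>12.5g} {self.bse[name]:>12.5g} "
                f"{self.tvalues[name]:>9.3g} {self.pvalues[name]:>9.3g}"
            )
        lines.append(f"effect parameter: {self.effect_param} "
                     f"(p={self.effect_pvalue:.3g})")
        if self.optimum_n is not None:
            tag = " [at range boundary]" if self.boundary else ""
            lines.append(f"optimum N: {self.optimum_n:.2f} kg N ha-1{tag}")
        if self.fallback_linear:
            lines.append("note: plateau curvature >= 0; linear fallback, optimum 0")
        return "\n".join(lines)


def _aic(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + 2.0 * (k + 1)


def _t_stats(
    params: dict[str, float], bse: dict[str, float], df: int
) -> tuple[dict[str, float], dict[str, float]]:
    tvals, pvals = {}, {}
    for name, value in params.items():
        se = bse[name]
        if se == 0.0 or not math.isfinite(se):
            t = math.inf if value != 0 else 0.0
        else:
            t = value / se
        tvals[name] = t
        if df <= 0:
            pvals[name] = math.nan
        else:
            pvals[name] = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return tvals, pvals


class ResponseModel:
    """A response-vs-N model of one family, ready to fit.

    Parameters
    ----------
    data : ResponseData
    family : str
        One of :data:`FAMILY_ORDER`.
    """

    def __init__(self, data: ResponseData, family: str = "linear") -> None:
        if family not in FAMILY_ORDER:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILY_ORDER}")
        k = _N_PARAMS[family]
        if len(data.x) < k + 2:
            raise ValueError(
                f"family {family!r} needs at least {k + 2} observations, got {len(data.x)}"
            )
        self.data = data
        self.family = family

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, y: str, x: str = "treatment_kg_n",
        family: str = "linear", weights: str | None = None, group: str | None = None,
    ) -> "ResponseModel":
        return cls(ResponseData.from_dataframe(df, y=y, x=x, weights=weights, group=group),
                   family=family)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> ResponseFit:
        x, y = self.data.x, self.data.y
        w = self.data.weights if self.data.weights is not None else np.ones_like(y)
        if self.family == "linear":
            return self._fit_wls(x, y, w, regressor=x, names=("a", "b"), order=("a", "b"))
        if self.family == "log":
            # y = a*log(x+1) + c: linear in (a, c)
            return self._fit_wls(
                x, y, w, regressor=np.log(x + 1.0), names=("c", "a"), order=("a", "c")
            )
        if self.family in ("power", "exponential"):
            return self._fit_nonlinear(x, y, w)
        return self._fit_plateau(x, y, w)

    def _finish(
        self,
        params: dict[str, float],
        bse: dict[str, float],
        sse: float,
        n: int,
        k: int,
        converged: bool = True,
        **extra,
    ) -> ResponseFit:
        tvals, pvals = _t_stats(params, bse, n - k)
        return ResponseFit(
            family=self.family,
            params=params,
            bse=bse,
            tvalues=tvals,
            pvalues=pvals,
            effect_param=_EFFECT_PARAM[self.family],
            sse=sse,
            aic=_aic(sse, n, k),
            n=n,
            k=k,
            converged=converged,
            group=self.data.group,
            **extra,
        )

    def _fit_wls(self, x, y, w, regressor, names, order) -> ResponseFit:
        """Closed-form weighted LS for families linear in their parameters.

        ``names`` maps (intercept, slope) of the design to parameter names;
        ``order`` fixes the reporting order.
        """
        X = sm.add_constant(regressor)
        res = sm.WLS(y, X, weights=w).fit()
        params = {names[0]: float(res.params[0]), names[1]: float(res.params[1])}
        bse = {names[0]: float(res.bse[0]), names[1]: float(res.bse[1])}
        resid = y - res.predict(X)
        sse = float(np.sum(w * resid**2))
        params = {k_: params[k_] for k_ in order}
        bse = {k_: bse[k_] for k_ in order}
        return self._finish(params, bse, sse, n=len(y), k=2)

    def _fit_nonlinear(self, x, y, w) -> ResponseFit:
        """Multi-start least squares for the power/exponential families.

        The shape parameter ``b`` is started on a fixed log-spaced grid of
        both signs (plus 0); the amplitude ``a`` is profiled in closed form
        at each start. The start grid is deterministic, so refitting the
        same data always returns the same solution.
        """
        sw = np.sqrt(w)
        u_of_b = (
            (lambda b: np.power(x + 1.0, b))
            if self.family == "power"
            else (lambda b: np.exp(np.clip(b * (x + 1.0), -_EXP_CLIP, _EXP_CLIP)))
        )

        def residuals(theta):
            a, b = theta
            return sw * (y - a * u_of_b(b))

        starts = []
        for b0 in (0.0, *(s * m for s in (1, -1) for m in (1e-3, 1e-2, 1e-1, 1.0))):
            u = u_of_b(b0)
            denom = float(np.sum(w * u * u))
            a0 = float(np.sum(w * u * y) / denom) if denom > 0 else 0.0
            starts.append((a0, b0))

        best = None
        with np.errstate(all="ignore"):  # extreme starts may overflow en route
            for theta0 in starts:
                try:
                    res = optimize.least_squares(
                        residuals, theta0, method="trf",
                        bounds=([-np.inf, -2.0], [np.inf, 2.0]), xtol=1e-12, ftol=1e-12,
                    )
                except Exception:
                    continue
                if not math.isfinite(res.cost):
                    continue
                if best is None or res.cost < best.cost:
                    best = res
        if best is None or not np.all(np.isfinite(best.x)):
            nanp = {"a": math.nan, "b": math.nan}
            return self._finish(nanp, dict(nanp), math.inf, n=len(y), k=2, converged=False)

        a_hat, b_hat = best.x
        sse = float(2.0 * best.cost)
        n, k = len(y), 2
        bse = _jacobian_bse(best.jac, sse, n, k)
        params = {"a": float(a_hat), "b": float(b_hat)}
        return self._finish(params, {"a": bse[0], "b": bse[1]}, sse, n=n, k=k)

    def _fit_plateau(self, x, y, w) -> ResponseFit:
        """Quadratic-plateau fit by profiling the join point.

        For a fixed join ``x0`` the curve is linear in (a, c) under the
        vertex constraint b = -2*c*x0, so the profile SSE(x0) is computed
        exactly on a deterministic grid over (0, 2*max(x)] and polished by
        bounded scalar minimization around the best grid point.
        """
        xmax = float(np.max(x))
        if xmax <= 0:
            raise ValueError("plateau fit needs at least one positive x")
        sw = np.sqrt(w)

        def profile(x0):
            z = np.where(x < x0, x * x - 2.0 * x0 * x, -x0 * x0)
            X = np.column_stack([np.ones_like(x), z])
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            resid = y - X @ beta
            return float(beta[0]), float(beta[1]), float(np.sum(w * resid**2))

        grid = np.linspace(xmax * 2.0 / 241.0, 2.0 * xmax, 241)
        sses = np.array([profile(g)[2] for g in grid])
        i = int(np.argmin(sses))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda g: profile(g)[2], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        x0_hat = float(res.x) if res.fun <= sses[i] else float(grid[i])
        a_hat, c_hat, sse = profile(x0_hat)

        if c_hat >= 0:
            # no concave response: fall back to a linear fit, optimum 0
            lin = ResponseModel(self.data, "linear").fit()
            return self._finish(
                dict(lin.params), dict(lin.bse), lin.sse, n=lin.n, k=2,
                optimum_n=0.0, fallback_linear=True,
            )

        b_hat = -2.0 * c_hat * x0_hat
        params = {"a": a_hat, "b": b_hat, "c": c_hat}
        n, k = len(y), 3
        jac = _numerical_jacobian(
            lambda th: sw * (y - _predict("quad_plateau", dict(zip("abc", th)), x)),
            np.array([a_hat, b_hat, c_hat]),
        )
        bse_arr = _jacobian_bse(jac, sse, n, k)
        bse = {"a": bse_arr[0], "b": bse_arr[1], "c": bse_arr[2]}
        boundary = not (0.0 <= x0_hat <= xmax)
        ybar = float(np.sum(w * y) / np.sum(w))
        sse0 = float(np.sum(w * (y - ybar) ** 2))
        if sse <= 0.0:
            f_p = 0.0
        elif n > k and sse0 > sse:
            fstat = ((sse0 - sse) / (k - 1)) / (sse / (n - k))
            f_p = float(stats.f.sf(fstat, k - 1, n - k))
        else:
            f_p = 1.0
        return self._finish(
            params, bse, sse, n=n, k=k,
            optimum_n=float(np.clip(x0_hat, 0.0, xmax)), boundary=boundary,
            f_pvalue=f_p,
        )


def _jacobian_bse(jac: np.ndarray, sse: float, n: int, k: int) -> np.ndarray:
    """Asymptotic SEs from the weighted-residual Jacobian at the optimum."""
    s2 = sse / (n - k) if n > k else math.nan
    jtj = jac.T @ jac
    try:
        cov = np.linalg.pinv(jtj) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(k, math.nan)


def _numerical_jacobian(fun, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    f0 = fun(theta)
    jac = np.empty((len(f0), len(theta)))
    for j in range(len(theta)):
        h = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        jac[:, j] = (fun(tp) - f0) / h
    return jac


# -- module-level operations ---------------------------------------------


def fit_family(data: ResponseData, family: str) -> ResponseFit:
    """Fit one family to the data (weighted least squares, multi-start)."""
    return ResponseModel(data, family).fit()


def select_model(
    data: ResponseData,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
) -> ResponseFit | None:
    """Significant fit with the lowest AIC, or None when nothing responds.

    Candidates whose effect parameter does not differ from 0 at level
    ``alpha`` are dropped; exact AIC ties (|dAIC| < 1e-9) break by the
    fixed order linear < log < power < exponential < quad_plateau.
    """
    if not candidates:
        raise ValueError("need at least one candidate family")
    fits = []
    for fam in candidates:
        try:
            fits.append(fit_family(data, fam))
        except ValueError:
            continue
    significant = [f for f in fits if f.significant(alpha) and not f.fallback_linear]
    if not significant:
        return None
    best = None
    for f in sorted(significant, key=lambda f: FAMILY_ORDER.index(f.family)):
        if best is None or f.aic < best.aic - 1e-9:
            best = f
    return best


def inverse_rank_weights(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Within-level inverse-rank weights for replicate observations.

    Replicates at each N level are ranked by distance from the level
    median (stable ties) and weighted 1, 1/2, 1/3, ..., so outlying plots
    count less in the plateau fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.empty_like(y)
    for level in np.unique(x):
        m = x == level
        dist = np.abs(y[m] - np.median(y[m]))
        rank = np.argsort(np.argsort(dist, kind="stable"), kind="stable")
        w[m] = 1.0 / (rank + 1.0)
    return w


def optimal_n(
    data: ResponseData,
    alpha: float = 0.05,
    weighting: str = "inverse_rank",
) -> ResponseFit:
    """Agronomic optimum N rate from a quadratic-plateau yield fit.

    ``weighting`` is 'inverse_rank' (default, replicate ranks within each
    level), 'uniform', or 'data' (use weights already on ``data``). The
    returned fit carries ``optimum_n``: the plateau join clamped to
    [0, max(x)], or 0 when the yield shows no significant N response (no
    concave curvature, or effect parameter not significant at ``alpha``).
    """
    if weighting == "inverse_rank":
        w = inverse_rank_weights(data.x, data.y)
    elif weighting == "uniform":
        w = np.ones_like(data.y)
    elif weighting == "data":
        w = data.weights if data.weights is not None else np.ones_like(data.y)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    weighted = ResponseData(data.x, data.y, weights=w, group=data.group)
    fit = ResponseModel(weighted, "quad_plateau").fit()
    no_effect = (
        fit.fallback_linear
        or (fit.f_pvalue is not None and fit.f_pvalue >= alpha)
        or (fit.f_pvalue is None and not fit.significant(alpha))
    )
    if no_effect:
        fit.optimum_n = 0.0
    return fit
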