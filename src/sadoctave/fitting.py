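"""Least-squares fitting of octave-scale SAD models and goodness-of-fit.

One model is fitted to one octave histogram by minimising the residual sum
of squares of ``S(R)`` over the observed octaves.  The constant GS model is
solved in closed form (its least-squares height is the mean count); all
other models go through :func:`scipy.optimize.least_squares` with analytic
bounds and a small deterministic multistart over the shape parameter, which
guards the heavy-tailed logCauchy objective against local minima.

Every fit is summarised by the adjusted coefficient of determination, a
chi-square goodness-of-fit test (with classical pooling of octaves whose
expected count is below a floor), and the residual-sum-of-squares forms of
AIC and BIC::

    AIC = n*ln(SS_res) + 2k - n*ln(n)
    BIC = n*ln(SS_res) + k*ln(n) - n*ln(n)

where ``n`` is the number of octaves entering the regression and ``k`` the
model's parameter count, so that AIC - BIC = k*(2 - ln n) identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .binning import OctaveHistogram
from .models import ModelSpec, evaluate_model, get_model

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_model",
    "adjusted_r_squared",
    "chi_square_gof",
    "information_criteria",
]

NEG_INF = float("-inf")


class InsufficientDataError(ValueError):
    """Fewer octaves than model parameters."""


@dataclass
class FitOptions:
    """Knobs of the fitting and testing procedure.

    ``df_convention`` selects the chi-square degrees of freedom,
    ``n - k`` (default) or ``n - k - 1``; ``chi2_floor`` is the minimum
    expected count per class before pooling (set to 0 to disable pooling);
    ``adjusted_r2`` switches between the adjusted and the plain coefficient
    of determination.
    """

    max_iterations: int = 2000
    tolerance: float = 1e-10
    alpha_level: float = 0.05
    r2_threshold: float = 0.50
    df_convention: str = "n-k"
    chi2_floor: float = 1.0
    adjusted_r2: bool = True
    alpha_starts: tuple[float, ...] = (0.3, 1.0, 3.0)
    lser_alpha_starts: tuple[float, ...] = (0.2, 0.5, 0.8)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        if self.df_convention not in ("n-k", "n-k-1"):
            raise ValueError("df_convention must be 'n-k' or 'n-k-1'")


@dataclass
class FitResult:
    """Parameter estimates and all goodness-of-fit statistics of one fit."""

    model: str
    theta: dict[str, float]
    ss_residual: float
    n: int
    k: int
    r_d2: float
    chi2: float
    df: int
    p_chi2: float  # NaN when df < 1
    aic: float
    bic: float
    s_star: float | None
    converged: bool
    fitted_values: np.ndarray = field(repr=False)
    octaves: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    constants: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "theta": {k: float(v) for k, v in self.theta.items()},
            "ss_residual": float(self.ss_residual),
            "n": self.n,
            "k": self.k,
            "r_d2": float(self.r_d2),
            "chi2": float(self.chi2),
            "df": self.df,
            "p_chi2": float(self.p_chi2),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "s_star": None if self.s_star is None else float(self.s_star),
            "converged": self.converged,
            "fitted_values": [float(v) for v in self.fitted_values],
            "octaves": [int(R) for R in self.octaves],
            "observed": [float(v) for v in self.observed],
        }
        if self.constants:
            d["constants"] = {k: float(v) for k, v in self.constants.items()}
        if self.message:
            d["message"] = self.message
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_row(self) -> dict:
        """Flat one-row record for CSV tables."""
        row = {"model": self.model}
        row.update({f"param_{k}": float(v) for k, v in self.theta.items()})
        row.update(
            n=self.n, k=self.k, ss_residual=float(self.ss_residual),
            r_d2=float(self.r_d2), chi2=float(self.chi2), df=self.df,
            p_chi2=float(self.p_chi2), aic=float(self.aic), bic=float(self.bic),
            s_star=None if self.s_star is None else float(self.s_star),
            converged=self.converged,
        )
        return row


def adjusted_r_squared(
    S_obs: Sequence[float], S_fit: Sequence[float], k: int, adjusted: bool = True
) -> float:
    """(Adjusted) coefficient of determination of a fitted octave curve.

    ``R_d^2 = 1 - [SS_res / (n - k)] / [SS_tot / (n - 1)]`` with ``SS_tot``
    about the mean of the observations.  May be negative for a model that
    does worse than the mean; the constant model with ``k = 1`` scores
    exactly zero.
    """
    S_obs = np.asarray(S_obs, dtype=float)
    S_fit = np.asarray(S_fit, dtype=float)
    n = S_obs.size
    if S_fit.size != n:
        raise ValueError("S_obs and S_fit must have equal length")
    if n <= k and adjusted:
        raise InsufficientDataError(f"adjusted R^2 undefined for n={n} <= k={k}")
    ss_res = float(np.sum((S_obs - S_fit) ** 2))
    ss_tot = float(np.sum((S_obs - S_obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observations have zero variance")
    if not adjusted:
        return 1.0 - ss_res / ss_tot
    return 1.0 - (ss_res / (n - k)) / (ss_tot / (n - 1))


def _pool_classes(
    S_obs: np.ndarray, S_fit: np.ndarray, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge classes with expected count below ``floor`` into their neighbor.

    Pooling proceeds from the outside in (classical low-expectation pooling
    for binned goodness-of-fit): while any pooled class stays below the
    floor and more than one class remains, the smallest-expectation class is
    merged with its inner neighbor (the adjacent class with the larger
    expectation).
    """
    obs = [float(v) for v in S_obs]
    fit = [float(v) for v in S_fit]
    while len(fit) > 1 and min(fit) < floor:
        i = int(np.argmin(fit))
        if i == 0:
            j = 1
        elif i == len(fit) - 1:
            j = i - 1
        else:
            j = i - 1 if fit[i - 1] >= fit[i + 1] else i + 1
        fv, ov = fit.pop(i), obs.pop(i)
        if j > i:
            j -= 1
        fit[j] += fv
        obs[j] += ov
    return np.asarray(obs), np.asarray(fit)


def chi_square_gof(
    S_obs: Sequence[float],
    S_fit: Sequence[float],
    k: int,
    floor: float = 1.0,
    df_convention: str = "n-k",
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of fitted to observed octave counts.

    Returns ``(chi2, df, P)`` with ``P`` the upper-tail probability; ``P``
    is NaN when the (pooled) class count leaves ``df < 1``.
    """
    S_obs = np.asarray(S_obs, dtype=float)
    S_fit = np.asarray(S_fit, dtype=float)
    if floor > 0:
        S_obs, S_fit = _pool_classes(S_obs, S_fit, floor)
    if np.any(S_fit <= 0):
        raise ValueError("chi-square test not applicable: non-positive expected counts")
    chi2 = float(np.sum((S_obs - S_fit) ** 2 / S_fit))
    df = S_obs.size - k - (1 if df_convention == "n-k-1" else 0)
    p = float(stats.chi2.sf(chi2, df)) if df >= 1 else float("nan")
    return chi2, int(df), p


def information_criteria(ss_residual: float, n: int, k: int) -> tuple[float, float]:
    """Residual-sum-of-squares AIC and BIC; lower is better.

    A perfect fit (``SS_res = 0``) is reported as ``-inf`` for both.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ss_residual < 0:
        raise ValueError("ss_residual must be non-negative")
    if ss_residual == 0.0:
        return NEG_INF, NEG_INF
    base = n * math.log(ss_residual) - n * math.log(n)
    return base + 2 * k, base + k * math.log(n)


def _starting_points(
    spec: ModelSpec, h: OctaveHistogram, opts: FitOptions
) -> list[np.ndarray]:
    Sm0 = float(h.counts.max())
    Rm0 = float(h.octaves[int(np.argmax(h.counts))])
    if spec.name == "bs":
        alpha0 = 1.0 / float(np.mean(np.exp2(h.octaves)))
        starts = [np.array([Sm0, alpha0])]
        starts += [np.array([Sm0, a]) for a in opts.alpha_starts]
        return starts
    if spec.name == "lser":
        return [np.array([Sm0, a]) for a in opts.lser_alpha_starts]
    if spec.name in ("ln", "lc", "ls"):
        return [np.array([Sm0, a, Rm0]) for a in opts.alpha_starts]
    return [np.array([Sm0])]  # on (gs is closed-form)


def _solver_bounds(
    spec: ModelSpec, h: OctaveHistogram
) -> tuple[np.ndarray, np.ndarray]:
    Sm_hi = 10.0 * float(h.counts.max())
    lo, hi = [1e-9], [Sm_hi]
    if spec.name in ("bs",):
        lo.append(1e-6), hi.append(np.inf)
    elif spec.name == "lser":
        lo.append(1e-6), hi.append(1.0 - 1e-9)
    elif spec.name in ("ln", "lc", "ls"):
        lo += [1e-6, float(h.octaves.min()) - 2.0]
        hi += [np.inf, float(h.octaves.max()) + 2.0]
    return np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)


def fit_model(
    spec: ModelSpec | str, h: OctaveHistogram, opts: FitOptions | None = None
) -> FitResult:
    """Fit one SAD model to an octave histogram by least squares.

    The best of all multistart solutions (by residual sum of squares) is
    kept; ``converged`` is False when no start converged, with statistics
    still reported at the best point found.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    opts = opts or FitOptions()
    R = h.octaves.astype(float)
    y = h.counts.astype(float)
    n = h.n
    if n < spec.k:
        raise InsufficientDataError(
            f"{spec.name}: {n} octaves cannot identify {spec.k} parameters"
        )
    if spec.name == "lser" and np.any(R < 0):
        raise ValueError("LSer is fit on octaves R >= 0 only")

    constants = (
        {"N_oct": h.N_oct, "R_max": float(h.R_max)} if spec.needs_data_constants else {}
    )

    if spec.name == "gs":
        theta_arr = np.array([float(y.mean())])
        converged, message = True, "closed form"
    else:
        def residuals(params: np.ndarray) -> np.ndarray:
            theta = dict(zip(spec.param_names, params))
            return evaluate_model(spec, theta, R, constants) - y

        lo, hi = _solver_bounds(spec, h)
        best: optimize.OptimizeResult | None = None
        for x0 in _starting_points(spec, h, opts):
            x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x0))
            try:
                sol = optimize.least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf",
                    ftol=opts.tolerance, xtol=opts.tolerance, gtol=opts.tolerance,
                    max_nfev=opts.max_iterations,
                )
            except Exception:  # a pathological start must not kill the fit
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(f"{spec.name}: all starting points failed")
        theta_arr = best.x
        converged, message = bool(best.success), str(best.message)

    theta = dict(zip(spec.param_names, map(float, theta_arr)))
    fitted = np.asarray(evaluate_model(spec, theta, R, constants), dtype=float)
    ss = float(np.sum((y - fitted) ** 2))
    r_d2 = adjusted_r_squared(y, fitted, spec.k, adjusted=opts.adjusted_r2)
    try:
        chi2, df, p = chi_square_gof(
            y, fitted, spec.k, floor=opts.chi2_floor, df_convention=opts.df_convention
        )
    except ValueError:
        chi2, df, p = float("nan"), 0, float("nan")
    aic, bic = information_criteria(ss, n, spec.k)
    s_star = None
    if spec.has_sstar:
        args = [theta[p_] for p_ in spec.param_names]
        s_star = float(spec.sstar(*args))
    return FitResult(
        model=spec.name, theta=theta, ss_residual=ss, n=n, k=spec.k, r_d2=r_d2,
        chi2=chi2, df=df, p_chi2=p, aic=aic, bic=bic, s_star=s_star,
        converged=converged, fitted_values=fitted, octaves=h.octaves.copy(),
        observed=y, constants=constants, message=message,
    )
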