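"""Weighted Langmuir isotherm fitting and the derived-quantity arithmetic.

The unfolded (or bound, or refolded) percentage from the histogram
subtraction is fitted against effector concentration with

    y(x) = alpha * x / (x + K_eq),

minimizing sum(((y_i - y(x_i)) / sigma_i)^2) over alpha in (0, 100] and
K_eq > 0 -- a weighted fit in which each point's uncertainty (standard
deviation over replicate datasets, or a binomial standard error for single
runs) is taken into account.  Parameter 1-sigma errors come from the
covariance at the optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lmfit import Model

from .exceptions import FitError, NoSignalError
from .states import IsothermParams, isotherm_eval

__all__ = [
    "TitrationSeries",
    "fit_langmuir",
    "relative_change",
    "fold_change",
    "write_fit_result",
    "format_report",
]


@dataclass
class TitrationSeries:
    """(concentration, response-percent, error) triples feeding the fit.

    ``mode`` is "unfolding" for the usual positive-lobe score and "folding"
    when the positive lobe tracks the *refolded* population (the relative
    folded population is plotted when a nucleotide suppresses unfolding, as
    in ADP titrations); the fit itself is identical, the label keeps reports
    honest.  The zero-concentration point is y = 0 by construction (it is
    the subtraction reference) and is excluded from the fit residuals unless
    ``include_zero`` is requested at fit time.
    """

    effector: str
    x: np.ndarray
    y: np.ndarray
    y_err: np.ndarray
    units: str = "nM"
    reference_description: str = ""
    mode: str = "unfolding"

    def __post_init__(self):
        order = np.argsort(np.asarray(self.x, dtype=float))
        self.x = np.asarray(self.x, dtype=float)[order]
        self.y = np.asarray(self.y, dtype=float)[order]
        self.y_err = np.asarray(self.y_err, dtype=float)[order]
        if not (self.x.size == self.y.size == self.y_err.size):
            raise ValueError("x, y and y_err must have equal length")
        if self.x.size >= 2 and np.any(np.diff(self.x) == 0):
            raise ValueError("duplicate concentrations in series; pool replicates first")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if self.mode not in ("unfolding", "folding"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _langmuir(x, alpha, k_eq):
    return alpha * x / (x + k_eq)


def fit_langmuir(
    series: TitrationSeries,
    init: IsothermParams | None = None,
    include_zero: bool = False,
    zero_sigma: float = 0.5,
) -> IsothermParams:
    """Weighted least-squares fit of the Langmuir isotherm to a titration.

    Initial guesses default to alpha0 = max(y) and K0 = x at the first point
    exceeding max(y)/2, which is robust for both saturating and
    non-saturating series.  Returns estimates with 1-sigma covariance errors;
    the chi-square and point count are attached to the result as ``chi2``
    and ``n_points`` attributes for reporting.
    """
    x, y, y_err = series.x, series.y, series.y_err
    if not include_zero:
        keep = x > 0
        x, y, y_err = x[keep], y[keep], y_err[keep]
    else:
        y_err = np.where(x == 0, zero_sigma, y_err)
    if x.size < 3:
        raise FitError(f"need at least 3 points to fit, got {x.size}")
    if np.any(y_err <= 0):
        raise FitError("all y_err must be positive for a weighted fit")
    if np.all(np.abs(y) < 1e-9):
        raise NoSignalError("no signal to fit: all responses are ~0")

    if init is None:
        alpha0 = float(np.clip(np.max(y), 1e-3, 100.0))
        above = np.nonzero(y > alpha0 / 2)[0]
        k0 = float(x[above[0]]) if above.size else float(np.median(x))
        k0 = max(k0, 1e-9)
    else:
        alpha0, k0 = init.alpha, init.k_eq

    model = Model(_langmuir)
    params = model.make_params(alpha=alpha0, k_eq=k0)
    params["alpha"].set(min=1e-9, max=100.0)
    params["k_eq"].set(min=1e-12)
    # y_err are absolute uncertainties (replicate SD or binomial SE), so the
    # covariance is not rescaled by the reduced chi-square
    result = model.fit(y, params, x=x, weights=1.0 / y_err, scale_covar=False)
    if not result.success:
        raise FitError(
            f"Langmuir fit did not converge: {result.message}",
            last_params={name: float(p.value) for name, p in result.params.items()},
            residual=float(np.sum(result.residual**2)),
        )
    alpha = float(result.params["alpha"].value)
    k_eq = float(result.params["k_eq"].value)
    alpha_err = float(result.params["alpha"].stderr or 0.0)
    k_eq_err = float(result.params["k_eq"].stderr or 0.0)
    fitted = IsothermParams(
        alpha=alpha, k_eq=k_eq, alpha_err=alpha_err, k_eq_err=k_eq_err, units=series.units
    )
    # Stash goodness-of-fit for reporting without widening the core type.
    object.__setattr__(fitted, "chi2", float(result.chisqr))
    object.__setattr__(fitted, "n_points", int(x.size))
    return fitted


def _round_half_away(value: float, decimals: int = 0) -> float:
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


def relative_change(a: float, b: float, rounded: bool = False) -> float:
    """Percent change of ``b`` relative to ``a``: 100*(b - a)/a.

    With ``rounded=True`` the result is rounded half-away-from-zero to the
    nearest integer percent (the convention used when such changes are
    quoted in prose, e.g. 40% -> 47% is an 18% increase).
    """
    if a <= 0:
        raise ValueError("baseline percentage must be positive")
    change = 100.0 * (b - a) / a
    return _round_half_away(change) if rounded else change


def fold_change(k_a: float, k_b: float, rounded: bool = False) -> float:
    """Ratio k_a / k_b; with ``rounded=True``, to one decimal place."""
    if k_b <= 0:
        raise ValueError("denominator must be positive")
    ratio = k_a / k_b
    return _round_half_away(ratio, decimals=1) if rounded else ratio


def write_fit_result(params: IsothermParams, series: TitrationSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "alpha": params.alpha,
        "alpha_err": params.alpha_err,
        "k_eq": params.k_eq,
        "k_eq_err": params.k_eq_err,
        "units": params.units,
        "chi2": getattr(params, "chi2", None),
        "n_points": getattr(params, "n_points", None),
        "effector": series.effector,
        "mode": series.mode,
        "reference_description": series.reference_description,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def format_report(params: IsothermParams, series: TitrationSeries) -> str:
    """One-page text report for a titration fit."""
    lines = [
        f"Langmuir isotherm fit: y = alpha*x/(x + K_eq)   [{series.mode}]",
        f"effector: {series.effector} ({series.units})",
        f"reference: {series.reference_description or '(zero-effector state)'}",
        "",
        f"alpha = {params.alpha:.1f} +/- {params.alpha_err:.1f} %",
        f"K_eq  = {params.k_eq:.3g} +/- {params.k_eq_err:.2g} {params.units}",
        f"chi2  = {getattr(params, 'chi2', float('nan')):.3g} "
        f"over {getattr(params, 'n_points', 0)} points",
        "",
        f"{'x (' + series.units + ')':>14} {'y (%)':>8} {'err':>6} {'fit':>8}",
    ]
    for xi, yi, ei in zip(series.x, series.y, series.y_err):
        fit = isotherm_eval(xi, params)
        lines.append(f"{xi:>14.4g} {yi:>8.2f} {ei:>6.2f} {fit:>8.2f}")
    if series.x.max() < 3 * params.k_eq:
        lines.append("")
        lines.append(
            "WARNING: saturation not reached (max x < 3*K_eq); alpha is extrapolated"
        )
    return "\n".join(lines)
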