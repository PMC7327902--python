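"""Binding isotherms, Hill-equation fitting, and group comparison.

A binding isotherm collects (free ligand concentration, response) points, where
the response is either a colocalization saturation fraction θ or a mean
zero-lag cross-correlation.  The Hill model

    θ([L]) = A · [L]^n_H / (K_d^n_H + [L]^n_H)

defines the apparent dissociation constant ``K_d`` (free-ligand concentration
at half-saturation) and the Hill coefficient ``n_H`` (cooperativity index).
A "literal" variant with an un-exponentiated ``K_d`` in the denominator,
θ = A·[L]^n_H/(K_d + [L]^n_H), is available behind a flag; it is dimensionally
inconsistent but occasionally encountered, so both are covered by tests.

Concentrations are in nM throughout unless noted otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "BindingIsotherm",
    "HillParameters",
    "TTestReport",
    "FitError",
    "hill_response",
    "compute_free_ligand",
    "fit_hill",
    "compare_groups",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is unidentifiable."""


@dataclass
class BindingIsotherm:
    """Titration points for one condition.

    Parameters
    ----------
    concentrations
        Free ligand concentrations (nM), strictly increasing, all positive.
    response
        Mean response at each concentration (saturation fraction or mean
        correlation).
    sd
        Standard deviation of the response at each concentration (optional;
        used as weights in fitting).
    n
        Replicate count per point (optional, informational).
    response_kind
        Either ``"saturation"`` or ``"correlation"``.
    group
        Free-form condition label (e.g. ``"pCa 9"``).
    """

    concentrations: np.ndarray
    response: np.ndarray
    sd: np.ndarray | None = None
    n: np.ndarray | None = None
    response_kind: Literal["saturation", "correlation"] = "saturation"
    group: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentrations.ndim != 1 or self.concentrations.shape != self.response.shape:
            raise ValueError("concentrations and response must be 1-D and equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.response.shape:
                raise ValueError("sd must match response shape")
            if np.any(self.sd < 0):
                raise ValueError("sd must be non-negative")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class HillParameters:
    """Hill fit result with asymptotic standard errors."""

    kd: float
    n_h: float
    kd_se: float
    n_h_se: float
    response_scale: float = 1.0
    response_scale_se: float = 0.0
    literal: bool = False
    n_points: int = 0
    rss: float = float("nan")
    covariance: np.ndarray | None = field(default=None, repr=False)

    def predict(self, concentrations: Sequence[float] | np.ndarray) -> np.ndarray:
        """Evaluate the fitted curve at the given free-ligand concentrations."""
        return hill_response(
            np.asarray(concentrations, dtype=float),
            self.kd,
            self.n_h,
            scale=self.response_scale,
            literal=self.literal,
        )


def hill_response(
    concentration: np.ndarray | float,
    kd: float,
    n_h: float,
    scale: float = 1.0,
    literal: bool = False,
) -> np.ndarray | float:
    """Hill isotherm response at free-ligand ``concentration``.

    The conventional form is ``scale·L^n_H/(K_d^n_H + L^n_H)``; with
    ``literal=True`` the denominator uses ``K_d`` un-exponentiated.
    """
    L = np.asarray(concentration, dtype=float)
    Ln = np.power(L, n_h)
    denom = (kd + Ln) if literal else (np.power(kd, n_h) + Ln)
    out = scale * Ln / denom
    return float(out) if np.isscalar(concentration) else out


def compute_free_ligand(
    total_ligand: float,
    theta: float,
    site_conc: float,
) -> float:
    """Free ligand concentration from mass conservation.

    ``free = total − θ·site_conc`` where ``site_conc`` is the concentration of
    lattice binding sites ([actin]/7 under the 1:1:7 Tn:Tpm:actin
    stoichiometry).  Clamped at zero with a warning if the bound amount
    nominally exceeds the total.
    """
    if total_ligand < 0 or site_conc < 0:
        raise ValueError("total_ligand and site_conc must be non-negative")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    free = total_ligand - theta * site_conc
    if free < 0:
        warnings.warn(
            f"bound ligand ({theta * site_conc:.4g}) exceeds total ({total_ligand:.4g}); "
            "free concentration clamped to 0",
            stacklevel=2,
        )
        free = 0.0
    return free


def _hill_model(fix_scale: float | None, literal: bool):
    if fix_scale is None:
        def model(L, kd, n_h, scale):
            return hill_response(L, kd, n_h, scale=scale, literal=literal)
    else:
        def model(L, kd, n_h):
            return hill_response(L, kd, n_h, scale=fix_scale, literal=literal)
    return model


def fit_hill(
    isotherm: BindingIsotherm,
    fix_scale: float | None = None,
    literal: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> HillParameters:
    """Weighted nonlinear least-squares fit of the Hill equation.

    Weights are ``1/sd²`` when per-point standard deviations are available and
    all positive; otherwise the fit is unweighted.  Initialization puts ``K_d``
    at the concentration nearest half-maximal response with ``n_H = 1``, plus
    ``n_starts − 1`` jittered restarts; the best (lowest residual sum of
    squares) converged solution is returned with asymptotic standard errors
    from the curvature at the optimum.

    Parameters
    ----------
    fix_scale
        Fix the plateau (e.g. ``1.0`` for saturation isotherms).  ``None``
        fits a free plateau, appropriate for correlation-based isotherms
        that saturate below 1.  Defaults per ``response_kind`` when ``None``
        and the isotherm is saturation-kind: the plateau is fixed at 1.
    literal
        Fit the printed, un-exponentiated-``K_d`` denominator instead of the
        conventional form.
    """
    if len(isotherm) < 4:
        raise FitError("need at least 4 titration points to fit the Hill equation")
    L = isotherm.concentrations
    y = isotherm.response
    if fix_scale is None and isotherm.response_kind == "saturation":
        fix_scale = 1.0
    yspan = float(np.ptp(y))
    if yspan < 1e-9:
        raise FitError("response is flat; Hill parameters unidentifiable")

    sigma = None
    if isotherm.sd is not None and np.all(isotherm.sd > 0):
        sigma = isotherm.sd

    scale_guess = fix_scale if fix_scale is not None else max(float(y.max()), 1e-6)
    half = 0.5 * scale_guess
    kd0 = float(L[np.argmin(np.abs(y - half))])
    rng = np.random.default_rng(seed)

    model = _hill_model(fix_scale, literal)
    n_free = 2 if fix_scale is not None else 3
    lower = [1e-12, 1e-3] + ([1e-12] if fix_scale is None else [])
    upper = [np.inf, 50.0] + ([np.inf] if fix_scale is None else [])

    best = None
    for i in range(n_starts):
        if i == 0:
            p0 = [kd0, 1.0]
        else:
            p0 = [kd0 * float(np.exp(rng.normal(0, 1.0))),
                  float(np.exp(rng.normal(0, 0.3)))]
        if fix_scale is None:
            p0 = p0 + [scale_guess * float(np.exp(rng.normal(0, 0.2))) if i else scale_guess]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, L, y, p0=p0, sigma=sigma,
                    bounds=(lower, upper), maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - model(L, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)

    if best is None:
        raise FitError(
            f"Hill fit failed to converge after {n_starts} starts "
            f"(n={len(L)}, response span={yspan:.3g})"
        )
    popt, pcov, rss = best
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return HillParameters(
        kd=float(popt[0]),
        n_h=float(popt[1]),
        kd_se=float(se[0]),
        n_h_se=float(se[1]),
        response_scale=float(popt[2]) if n_free == 3 else float(fix_scale),
        response_scale_se=float(se[2]) if n_free == 3 else 0.0,
        literal=literal,
        n_points=len(L),
        rss=rss,
        covariance=pcov,
    )


@dataclass
class TTestReport:
    """Two-tailed Student's t-test result."""

    t: float
    df: float
    p_value: float
    reject: bool
    alpha: float = 0.05


def compare_groups(
    sample_a: Sequence[float] | np.ndarray,
    sample_b: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> TTestReport:
    """Two-tailed t-test between replicate-level values of two conditions."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicate values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    p = float(res.pvalue)
    return TTestReport(t=float(res.statistic), df=float(df), p_value=p,
                       reject=bool(p < alpha), alpha=alpha)
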