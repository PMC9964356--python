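"""Regularization-parameter selection for zero-order Tikhonov ECGI.

Five classical data-driven selectors are provided, each choosing one
lambda per time instant from a predefined search interval:

``lcurve``
    Corner (maximum curvature) of the log-log plot of solution norm
    versus residual norm.
``gcv``
    Minimizer of the generalized cross-validation function
    ``G(lam) = ||(I - A(lam)) b||^2 / [Tr(I - A(lam)) / N_B]^2``
    with the trace expanded through the SVD.
``creso``
    Composite REsidual and Smoothing Operator: extrema of
    ``C = d/d(lam^2) [lam^2 eta^2 - rho^2]``; this implementation keeps
    the *last* (largest-lambda) local maximum, which avoids the
    under-regularized first maximum often seen on experimental data.
``zero_crossing``
    Smallest lambda at which the penalty contribution ``lam^2 eta^2``
    equals the squared residual norm ``rho^2``.
``ucurve``
    Minimizer of ``U(lam) = 1/rho^2 + 1/eta^2``.

The search interval defaults to ``[sigma_round(r/2), sigma_1]`` derived
from the singular spectrum, widened for GCV (lower bound 1e-30) and the
U-curve (upper bound 4.44).  A beat-level lambda is the median of the
per-instant selections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .tikhonov import BeatRecording, TransferModel, _curve_derivatives, _rho2_eta2

__all__ = [
    "METHODS", "SearchInterval", "SelectionResult",
    "predefined_interval", "lcurve_select", "gcv_select", "creso_select",
    "zero_crossing_select", "ucurve_select", "select_beat",
]

METHODS = ("lcurve", "gcv", "creso", "zero_crossing", "ucurve")

#: status flags attached to per-instant selections
OK = "converged"
FLAT = "flat_objective"
FALLBACK = "fallback"
NO_ROOT = "no_root"

GCV_LAM_MIN = 1e-30
UCURVE_LAM_MAX = 4.44
DEFAULT_N_GRID = 200


class DegenerateSpectrumError(ValueError):
    """Transfer matrix rank too low to define a search interval."""


@dataclass(frozen=True)
class SearchInterval:
    """Log-spaced lambda search interval."""

    lam_min: float
    lam_max: float
    n_grid: int = DEFAULT_N_GRID

    def __post_init__(self):
        if not (0 < self.lam_min < self.lam_max):
            raise ValueError("need 0 < lam_min < lam_max")
        if self.n_grid < 10:
            raise ValueError("n_grid must be >= 10")

    def grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.lam_min), np.log10(self.lam_max), self.n_grid
        )

    def clip(self, lam: float) -> float:
        return float(min(max(lam, self.lam_min), self.lam_max))


@dataclass(frozen=True)
class SelectionResult:
    """Per-instant lambdas for one beat plus their median."""

    method: str
    lam_per_instant: np.ndarray
    lam_beat: float
    interval: SearchInterval
    diagnostics: tuple[str, ...]
    instants: np.ndarray = field(default=None)

    @property
    def all_fallback(self) -> bool:
        return all(d != OK for d in self.diagnostics)


def _round_half_away(v: float) -> int:
    return int(np.floor(v + 0.5)) if v >= 0 else -int(np.floor(-v + 0.5))


def predefined_interval(
    tm: TransferModel, method: str, n_grid: int = DEFAULT_N_GRID
) -> SearchInterval:
    """Singular-value-derived search interval for a selector.

    Default is ``[sigma_round(r/2), sigma_1]`` with half-away-from-zero
    rounding of the 1-based index; GCV replaces the lower bound by
    1e-30, the U-curve replaces the upper bound by 4.44.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if tm.r < 2:
        raise DegenerateSpectrumError("rank < 2: no usable spectrum interval")
    idx = _round_half_away(tm.r / 2.0)          # 1-based index
    lam_min = float(tm.sigma[idx - 1])
    lam_max = float(tm.sigma[0])
    if method == "gcv":
        lam_min = GCV_LAM_MIN
    elif method == "ucurve":
        lam_max = UCURVE_LAM_MAX
    return SearchInterval(lam_min=lam_min, lam_max=lam_max, n_grid=n_grid)


# ---------------------------------------------------------------------------
# helpers

def _prep(tm: TransferModel, b: np.ndarray):
    b = np.asarray(b, dtype=float)
    if not np.any(b):
        raise ValueError("b must be nonzero")
    beta, b_perp2 = tm.projections(b)
    return tm.sigma[: tm.r], beta, float(b_perp2)


def _parabolic_refine(loglam: np.ndarray, y: np.ndarray, i: int,
                      mode: str) -> float:
    """Refine a grid extremum at index i by fitting a parabola in log-lambda.

    mode 'max' or 'min'.  Returns the refined log-lambda (falls back to
    the grid point for degenerate fits or edge indices).
    """
    if i == 0 or i == len(loglam) - 1:
        return float(loglam[i])
    x0, x1, x2 = loglam[i - 1], loglam[i], loglam[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    if (mode == "max" and denom >= 0) or (mode == "min" and denom <= 0):
        return float(x1)
    # equidistant-abscissa vertex formula
    h = 0.5 * (x2 - x0)
    shift = 0.5 * (y0 - y2) / denom * h
    if abs(shift) > h:
        return float(x1)
    return float(x1 + shift)


def _objective_refine(fun, loglam: np.ndarray, i: int) -> float:
    """Bounded scalar minimization of fun(lam) between grid neighbors."""
    lo = loglam[max(i - 1, 0)]
    hi = loglam[min(i + 1, len(loglam) - 1)]
    if hi <= lo:
        return float(np.exp(loglam[i]))
    res = minimize_scalar(
        lambda t: fun(np.exp(t)),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6 * max(1.0, abs(hi))},
    )
    return float(np.exp(res.x)) if res.success else float(np.exp(loglam[i]))


# ---------------------------------------------------------------------------
# objective curves (module-level so tests can probe them directly)

def lcurve_curvature(tm: TransferModel, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Analytic curvature of (log rho, log eta) parameterized by log lambda."""
    s, beta, b_perp2 = _prep(tm, b)
    return _curvature(s, beta, b_perp2, np.asarray(grid, dtype=float))


def _curvature(s, beta, b_perp2, lam):
    x = lam * lam
    rho2, eta2, drho2, deta2, d2rho2, d2eta2 = _curve_derivatives(
        s, beta, b_perp2, lam
    )
    # P = 0.5 log rho2, E = 0.5 log eta2, derivatives w.r.t. L = log lam
    # dP/dL = x rho2' / rho2 ;  d2P/dL2 = 2x [(rho2' + x rho2'')/rho2
    #                                          - x (rho2')^2 / rho2^2]
    with np.errstate(divide="ignore", invalid="ignore"):
        dP = x * drho2 / rho2
        dE = x * deta2 / eta2
        d2P = 2.0 * x * ((drho2 + x * d2rho2) / rho2 - x * (drho2 / rho2) ** 2)
        d2E = 2.0 * x * ((deta2 + x * d2eta2) / eta2 - x * (deta2 / eta2) ** 2)
        kappa = (dP * d2E - dE * d2P) / (dP * dP + dE * dE) ** 1.5
    return np.where(np.isfinite(kappa), kappa, -np.inf)


def gcv_objective(tm: TransferModel, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """G(lam) via the SVD expansion (valid for any grid of lambdas)."""
    s, beta, b_perp2 = _prep(tm, b)
    return _gcv(s, beta, b_perp2, tm.n_body, tm.r, np.asarray(grid, dtype=float))


def _gcv(s, beta, b_perp2, n_body, r, lam):
    x = lam * lam
    f = beta * beta
    F = 1.0 / (s[None, :] ** 2 + x[:, None])
    num = ((x[:, None] * F) ** 2) @ f + b_perp2
    trace = n_body - r + x * F.sum(axis=1)
    return num / (trace / n_body) ** 2


def gcv_trace(tm: TransferModel, lam: float) -> float:
    """Tr(I - A (A^T A + lam^2 I)^{-1} A^T) from the singular spectrum."""
    s = tm.sigma[: tm.r]
    x = lam * lam
    return float(tm.n_body - tm.r + np.sum(x / (s * s + x)))


def creso_objective(tm: TransferModel, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """C(lam) = d/d(lam^2) [lam^2 eta^2 - rho^2], closed form.

    Termwise: C(x) = sum_i sigma_i^2 beta_i^2 (sigma_i^2 - 3x) / (sigma_i^2 + x)^3.
    """
    s, beta, b_perp2 = _prep(tm, b)
    return _creso(s, beta, np.asarray(grid, dtype=float))


def _creso(s, beta, lam):
    x = lam * lam
    f = beta * beta
    s2 = s[None, :] ** 2
    F = 1.0 / (s2 + x[:, None])
    return (s2 * (s2 - 3.0 * x[:, None]) * F ** 3) @ f


def zc_objective(tm: TransferModel, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Zero-crossing function lam^2 eta^2 - rho^2."""
    s, beta, b_perp2 = _prep(tm, b)
    return _zc(s, beta, b_perp2, np.asarray(grid, dtype=float))


def _zc(s, beta, b_perp2, lam):
    rho2, eta2 = _rho2_eta2(s, beta, b_perp2, lam)
    return lam * lam * eta2 - rho2


def ucurve_objective(tm: TransferModel, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """U(lam) = 1/rho^2 + 1/eta^2 (inf where either norm vanishes)."""
    s, beta, b_perp2 = _prep(tm, b)
    rho2, eta2 = _rho2_eta2(s, beta, b_perp2, np.asarray(grid, dtype=float))
    with np.errstate(divide="ignore"):
        return np.where((rho2 > 0) & (eta2 > 0), 1.0 / rho2 + 1.0 / eta2, np.inf)


# ---------------------------------------------------------------------------
# selectors

def lcurve_select(
    tm: TransferModel, b: np.ndarray, interval: SearchInterval
) -> tuple[float, dict]:
    """L-corner: maximum curvature of the log-log L-curve.

    Returns ``(lam, diagnostics)`` where diagnostics carries the status
    flag and the curvature trace over the grid.
    """
    grid = interval.grid()
    s, beta, b_perp2 = _prep(tm, b)
    kappa = _curvature(s, beta, b_perp2, grid)
    diag = {"grid": grid, "curvature": kappa}
    if not np.any(kappa > 0):
        # no corner: fall back to the log-scale midpoint
        lam = float(np.sqrt(interval.lam_min * interval.lam_max))
        diag["status"] = FALLBACK
        return interval.clip(lam), diag
    i = int(np.argmax(kappa))
    loglam = np.log(grid)
    lam = float(np.exp(_parabolic_refine(loglam, kappa, i, "max")))
    diag["status"] = OK
    return interval.clip(lam), diag


def gcv_select(
    tm: TransferModel, b: np.ndarray, interval: SearchInterval
) -> tuple[float, dict]:
    """Minimize the GCV function G(lam) over the interval."""
    grid = interval.grid()
    s, beta, b_perp2 = _prep(tm, b)
    g = _gcv(s, beta, b_perp2, tm.n_body, tm.r, grid)
    diag = {"grid": grid, "objective": g}
    gmax = np.max(np.abs(g))
    if gmax == 0 or (np.max(g) - np.min(g)) <= 1e-12 * gmax:
        diag["status"] = FLAT
        return interval.lam_min, diag
    # G typically flattens into a plateau as lam -> 0; inside the plateau
    # the argmin location is floating-point noise, so take the smallest
    # lambda attaining the minimum to within 1e-12 relative.
    i = int(np.flatnonzero(g <= np.min(g) * (1.0 + 1e-12))[0])
    lam = _objective_refine(
        lambda l: float(_gcv(s, beta, b_perp2, tm.n_body, tm.r,
                             np.atleast_1d(l))[0]),
        np.log(grid), i,
    )
    diag["status"] = OK
    return interval.clip(lam), diag


def creso_select(
    tm: TransferModel, b: np.ndarray, interval: SearchInterval
) -> tuple[float, dict]:
    """Last (largest-lambda) strict local maximum of the CRESO curve."""
    grid = interval.grid()
    s, beta, b_perp2 = _prep(tm, b)
    c = _creso(s, beta, grid)
    diag = {"grid": grid, "objective": c}
    interior = np.flatnonzero(
        (c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])
    ) + 1
    if interior.size == 0:
        lam, zdiag = zero_crossing_select(tm, b, interval)
        diag["status"] = FALLBACK
        diag["fallback_to"] = "zero_crossing"
        return lam, diag
    i = int(interior[-1])
    lam = float(np.exp(_parabolic_refine(np.log(grid), c, i, "max")))
    diag["status"] = OK
    return interval.clip(lam), diag


def zero_crossing_select(
    tm: TransferModel, b: np.ndarray, interval: SearchInterval,
    rel_tol: float = 1e-6,
) -> tuple[float, dict]:
    """Smallest lambda with lam^2 eta^2 = rho^2 (positive -> non-positive).

    Scans the grid upward for the first sign change of the zero-crossing
    function and refines the root by bisection to ``rel_tol`` relative
    accuracy in lambda.
    """
    grid = interval.grid()
    s, beta, b_perp2 = _prep(tm, b)
    z = _zc(s, beta, b_perp2, grid)
    diag = {"grid": grid, "objective": z}
    idx = np.flatnonzero((z[:-1] > 0) & (z[1:] <= 0))
    if idx.size == 0:
        diag["status"] = NO_ROOT
        return interval.lam_max, diag
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    zfun = lambda l: float(_zc(s, beta, b_perp2, np.atleast_1d(l))[0])
    while (hi - lo) > rel_tol * hi:
        mid = np.sqrt(lo * hi)
        if zfun(mid) > 0:
            lo = mid
        else:
            hi = mid
    lam = float(np.sqrt(lo * hi))
    diag["status"] = OK
    return interval.clip(lam), diag


def ucurve_select(
    tm: TransferModel, b: np.ndarray, interval: SearchInterval
) -> tuple[float, dict]:
    """Minimize U(lam) = 1/rho^2 + 1/eta^2 over the interval."""
    grid = interval.grid()
    s, beta, b_perp2 = _prep(tm, b)
    rho2, eta2 = _rho2_eta2(s, beta, b_perp2, grid)
    valid = (rho2 > 0) & (eta2 > 0)
    if not np.any(valid):
        raise ValueError("U-curve undefined: rho or eta vanishes on the whole grid")
    u = np.where(valid, 1.0 / np.where(valid, rho2, 1.0)
                 + 1.0 / np.where(valid, eta2, 1.0), np.inf)
    diag = {"grid": grid, "objective": u}
    i = int(np.argmin(u))

    def ufun(l):
        r2, e2 = _rho2_eta2(s, beta, b_perp2, np.atleast_1d(l))
        if r2[0] <= 0 or e2[0] <= 0:
            return np.inf
        return float(1.0 / r2[0] + 1.0 / e2[0])

    lam = _objective_refine(ufun, np.log(grid), i)
    diag["status"] = OK
    return interval.clip(lam), diag


_SELECTORS = {
    "lcurve": lcurve_select,
    "gcv": gcv_select,
    "creso": creso_select,
    "zero_crossing": zero_crossing_select,
    "ucurve": ucurve_select,
}


def select_beat(
    tm: TransferModel,
    beat: BeatRecording,
    method: str,
    interval: SearchInterval | None = None,
    instants: np.ndarray | None = None,
    stride: int = 1,
) -> SelectionResult:
    """Run a per-instant selector over a beat and take the median lambda.

    Different time instants of one beat generally yield different
    lambdas; the beat-level value is their median (even count: mean of
    the two central order statistics), which preserves temporal
    coherence when the whole beat is reconstructed at a single lambda.

    Parameters
    ----------
    instants : optional index subset; default every sample (``stride``
        thins uniformly when > 1).
    """
    if method not in _SELECTORS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if interval is None:
        interval = predefined_interval(tm, method)
    if instants is None:
        # the annotated beat spans depolarization through repolarization;
        # trailing resting samples carry no beat information
        instants = np.arange(0, beat.t_window[1], stride)
    else:
        instants = np.asarray(instants, dtype=int)
        if instants.size == 0:
            raise ValueError("instants subset is empty")
    selector = _SELECTORS[method]
    lams = np.empty(instants.size)
    flags = []
    for k, t in enumerate(instants):
        b = beat.B[:, t]
        if not np.any(b):
            # silent instant: nothing to regularize
            lams[k] = interval.lam_min
            flags.append(FALLBACK)
            continue
        lam, diag = selector(tm, b, interval)
        lams[k] = lam
        flags.append(diag["status"])
    return SelectionResult(
        method=method,
        lam_per_instant=lams,
        lam_beat=float(np.median(lams)),
        interval=interval,
        diagnostics=tuple(flags),
        instants=instants,
    )
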