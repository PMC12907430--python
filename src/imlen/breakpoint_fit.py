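"""Continuous two-piece linear fit to the distance derivative.

The model is

    y(x) = a + b*x                  for x < k
    y(x) = a + b*k + c*(x - k)      for x >= k

with the transition point k (>= 0) reported as the intramural length.
For a fixed k the model is linear in (a, b, c) with basis
[1, min(x, k), max(x - k, 0)], so the fit is solved by profiling k:
an ordinary least-squares solve at each candidate k on a coarse grid,
followed by golden-section refinement around the coarse minimizer.
This search is deterministic and, because the 1-D profile is scanned
globally, does not depend on an initial guess. SSE ties are broken by
the smallest k (the shorter, more conservative intramural length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from imlen.distance_profile import DistanceProfile, build_profile
from imlen.errors import FitError, FitWindowWarning
from imlen.mesh_io import Centerline, EstimateResult, TriangleMesh

__all__ = [
    "PiecewiseModel",
    "FitSettings",
    "eval_model",
    "fit_piecewise",
    "fit_derivative",
    "estimate_im_length",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class PiecewiseModel:
    """Parameters of the continuous two-piece linear model.

    ``a`` is the intercept (derivative units), ``b`` and ``c`` the slopes
    of the two pieces (per mm), and ``k`` the transition arc length (mm).
    ``c`` is ``nan`` when the transition sits beyond all fitted data.
    """

    a: float
    b: float
    c: float
    k: float

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("transition point k must be >= 0")


def eval_model(model: PiecewiseModel, x):
    """Evaluate the two-piece model; continuous at ``x == k`` by construction."""
    x = np.asarray(x, dtype=np.float64)
    y = np.where(
        x < model.k,
        model.a + model.b * x,
        model.a + model.b * model.k + model.c * (x - model.k),
    )
    return y if y.ndim else float(y)


@dataclass(frozen=True)
class FitSettings:
    """Tunable parameters of the derivative fit.

    ``window_mm`` restricts the residuals to the first part of the
    profile (20 mm by default). ``k_max_mm`` bounds the transition
    search; ``None`` means the end of the available profile, which may
    exceed the window (the second slope is then unsupported by data and
    reported as undefined). ``coarse_step_mm`` and ``refine_tol_mm``
    control the deterministic profile search.
    """

    window_mm: float = 20.0
    spacing_mm: float = 0.001
    k_max_mm: float | None = None
    coarse_step_mm: float = 0.05
    refine_tol_mm: float = 1e-4

    def __post_init__(self):
        for name in ("window_mm", "spacing_mm", "coarse_step_mm", "refine_tol_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_max_mm is not None and self.k_max_mm < 0:
            raise ValueError("k_max_mm must be >= 0")


class _ProfileLS:
    """Least squares in (a, b, c) at any candidate k via prefix sums.

    For sorted x the normal-equation entries of the basis
    [1, min(x,k), max(x-k,0)] are combinations of prefix sums of
    1, x, x^2, y, x*y split at k, so each candidate costs O(1) after an
    O(n) precomputation.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]
        z = np.zeros(1)
        self.cx = np.concatenate([z, np.cumsum(self.x)])
        self.cxx = np.concatenate([z, np.cumsum(self.x * self.x)])
        self.cy = np.concatenate([z, np.cumsum(self.y)])
        self.cxy = np.concatenate([z, np.cumsum(self.x * self.y)])
        self.syy = float(np.sum(self.y * self.y))
        self.n = len(self.x)

    def solve(self, k: float) -> tuple[float, float, float, float, bool]:
        """Return (a, b, c, sse, c_defined) for the best model at this k."""
        i = int(np.searchsorted(self.x, k, side="left"))  # x[:i] < k
        n, n2 = self.n, self.n - i
        sx_lo, sxx_lo = self.cx[i], self.cxx[i]
        sy_lo, sxy_lo = self.cy[i], self.cxy[i]
        sx_hi = self.cx[n] - sx_lo
        sxx_hi = self.cxx[n] - sxx_lo
        sy_hi = self.cy[n] - sy_lo
        sxy_hi = self.cxy[n] - sxy_lo

        if n2 == 0:
            # transition beyond all data: plain line, c unsupported
            G = np.array([[n, sx_lo], [sx_lo, sxx_lo]])
            rhs = np.array([sy_lo, sxy_lo])
            coef, *_ = np.linalg.lstsq(G, rhs, rcond=None)
            a, b = float(coef[0]), float(coef[1])
            sse = self.syy - float(coef @ rhs)
            return a, b, float("nan"), max(sse, 0.0), False

        su = sx_lo + k * n2
        suu = sxx_lo + k * k * n2
        sv = sx_hi - k * n2
        svv = sxx_hi - 2.0 * k * sx_hi + k * k * n2
        suv = k * sv
        suy = sxy_lo + k * sy_hi
        svy = sxy_hi - k * sy_hi
        G = np.array([[n, su, sv], [su, suu, suv], [sv, suv, svv]])
        rhs = np.array([sy_lo + sy_hi, suy, svy])
        try:
            coef = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(G, rhs, rcond=None)
        sse = self.syy - float(coef @ rhs)
        return float(coef[0]), float(coef[1]), float(coef[2]), max(sse, 0.0), True

    def sse(self, k: float) -> float:
        return self.solve(k)[3]


def fit_derivative(
    x, y, settings: FitSettings | None = None, k_max_mm: float | None = None
) -> tuple[PiecewiseModel, float]:
    """Fit the two-piece model to explicit (x, y) samples.

    ``x`` must be non-negative arc lengths. The transition search runs
    over [0, k_max] on the coarse grid, then golden-section refinement
    around the coarse minimizer; the refined k is kept only when it
    strictly lowers the SSE, which preserves the smallest-k tie-break on
    flat SSE profiles.
    """
    settings = settings or FitSettings()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D arrays of equal length")
    if len(x) < 10:
        raise FitError(f"need >= 10 samples in the fit window, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise FitError("degenerate design: all arc-length values identical")

    ls = _ProfileLS(x, y)
    if k_max_mm is None:
        k_max_mm = settings.k_max_mm if settings.k_max_mm is not None else float(ls.x[-1])
    step = settings.coarse_step_mm
    candidates = np.arange(0.0, k_max_mm + 0.5 * step, step)
    if candidates.size == 0:
        candidates = np.array([0.0])
    sses = np.array([ls.sse(k) for k in candidates])
    best_sse = float(sses.min())
    tie_eps = 1e-9 * (1.0 + abs(best_sse))
    best_i = int(np.flatnonzero(sses <= best_sse + tie_eps)[0])  # smallest-k tie
    k_best = float(candidates[best_i])
    sse_best = float(sses[best_i])

    lo = candidates[best_i - 1] if best_i > 0 else 0.0
    hi = candidates[best_i + 1] if best_i + 1 < len(candidates) else k_max_mm
    k_ref, sse_ref = _golden_section(ls.sse, float(lo), float(hi), settings.refine_tol_mm)
    if sse_ref < sse_best - 1e-10 * (1.0 + sse_best):
        k_best, sse_best = k_ref, sse_ref

    a, b, c, sse, c_defined = ls.solve(k_best)
    if not c_defined:
        warnings.warn(
            f"transition k = {k_best:.3f} mm lies beyond the fitted data; "
            "the second slope is unsupported and reported as undefined",
            FitWindowWarning,
            stacklevel=2,
        )
    return PiecewiseModel(a=a, b=b, c=c, k=k_best), sse


def _golden_section(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Deterministic golden-section minimization of f on [lo, hi]."""
    if hi <= lo:
        return lo, f(lo)
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = f(x1), f(x2)
    while hi - lo > tol:
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _GOLDEN * (hi - lo)
            f1 = f(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _GOLDEN * (hi - lo)
            f2 = f(x2)
    return (x1, f1) if f1 <= f2 else (x2, f2)


def fit_piecewise(
    profile: DistanceProfile, settings: FitSettings | None = None
) -> tuple[PiecewiseModel, float]:
    """Fit the model to the derivative over the first ``window_mm`` of arc.

    The profile may be shorter than the window, in which case the fit is
    truncated with a warning rather than rejected. The transition search
    extends to the end of the available profile (not just the window)
    unless ``k_max_mm`` overrides it.
    """
    settings = settings or FitSettings()
    if profile.length_mm < settings.window_mm:
        warnings.warn(
            f"profile length {profile.length_mm:.2f} mm is shorter than the "
            f"{settings.window_mm:.2f} mm fit window; truncating the window",
            FitWindowWarning,
            stacklevel=2,
        )
    mask = profile.arc <= settings.window_mm + 1e-12
    k_max = settings.k_max_mm if settings.k_max_mm is not None else profile.length_mm
    return fit_derivative(
        profile.arc[mask], profile.deriv[mask], settings, k_max_mm=k_max
    )


def estimate_im_length(
    mesh: TriangleMesh,
    centerline: Centerline,
    settings: FitSettings | None = None,
    origin: str = "ostium",
) -> EstimateResult:
    """End-to-end pipeline: distance profile, derivative, two-piece fit.

    Deterministic for fixed inputs and settings; all stage warnings are
    accumulated into the result.
    """
    settings = settings or FitSettings()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        profile = build_profile(
            mesh, centerline, spacing_mm=settings.spacing_mm, origin=origin
        )
        model, sse = fit_piecewise(profile, settings)
    return EstimateResult(
        im_length_mm=model.k,
        a=model.a,
        b=model.b,
        c=model.c,
        k=model.k,
        window_mm=settings.window_mm,
        spacing_mm=settings.spacing_mm,
        sse=sse,
        ostium_offset_mm=profile.ostium_offset_mm,
        warnings=[str(w.message) for w in caught],
    )
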