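"""Inverse problem: mono/biexponential decomposition of PFG decay curves.

Two estimators in the scikit-learn idiom:

* :class:`MonoExponential` — log-domain line fit of a single-exponential
  decay, used for the water calibration standard.
* :class:`PeelOffBiexponential` — the "peel-off" (stripping) decomposition of
  a two-exponential decay: fit the slow phase on the large-b tail of
  ln A vs b, subtract it, fit the fast phase on the log-residuals, then
  optionally refine all three parameters by nonlinear least squares in the
  amplitude domain.  The initial-slope apparent diffusion coefficient

      ADC = -d ln A / db |_{b -> 0}

  is recorded alongside.

Both take ``X`` as a column of b-values (s/m^2) and ``y`` as normalized
amplitudes; thin wrappers :func:`fit_mono`, :func:`peel_off_fit` and
:func:`initial_slope_adc` operate directly on :class:`~tissuediff.signal.DecayCurve`.

Fitted diffusivities are *apparent* values at the acquisition's diffusion
time; they are reported as-is and never extrapolated to zero echo time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
    OrderViolationError,
    StrippingFailureError,
)
from .signal import DecayCurve

__all__ = [
    "ExponentialComponent",
    "BiexpFitResult",
    "MonoExponential",
    "PeelOffBiexponential",
    "fit_mono",
    "peel_off_fit",
    "initial_slope_adc",
]


@dataclass(frozen=True)
class ExponentialComponent:
    """One exponential term: diffusivity ``d`` (m^2/s) and its population."""

    d: float
    population: float


@dataclass(frozen=True)
class BiexpFitResult:
    """Fast/slow components, initial-slope ADC and fit diagnostics.

    Populations are renormalized to sum to exactly 1 (p1 + p2 = 1);
    ``population_sum_raw`` preserves the pre-normalization sum.
    ``method`` is one of ``peel_off``, ``peel_off_refined``, ``mono``.
    """

    fast: ExponentialComponent
    slow: ExponentialComponent
    adc_initial_slope: float
    method: str
    residual_rms: float
    n_points_used: int
    population_sum_raw: float = 1.0
    t_d: float | None = None

    @property
    def weighted_adc(self) -> float:
        """Population-weighted ADC of the fitted components, m^2/s."""
        return self.fast.population * self.fast.d + self.slow.population * self.slow.d


def _positive_points(b, a):
    b = np.asarray(b, dtype=float).reshape(-1)
    a = np.asarray(a, dtype=float).reshape(-1)
    keep = a > 0
    return b[keep], a[keep]


def _log_line(b, a):
    """Least-squares line through (b, ln a); returns (slope, intercept)."""
    slope, intercept = np.polyfit(b, np.log(a), 1)
    return slope, intercept


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise InvalidInputError("X must be a single column of b-values")
        X = X[:, 0]
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.shape != y.shape:
        raise InvalidInputError("X and y must have matching lengths")
    return X, y


class MonoExponential(RegressorMixin, BaseEstimator):
    """Single-exponential decay fit, A(b) = population * exp(-b * d).

    Ordinary least squares on ln A versus b; ``d_`` is minus the slope and
    ``population_`` the exponential of the intercept.  Requires at least
    three points with positive amplitude and a strictly positive fitted d.
    """

    def fit(self, X, y):
        b, a = _positive_points(*_as_xy(X, y))
        if b.size < 3:
            raise InsufficientDataError(
                f"mono-exponential fit needs >= 3 positive points, got {b.size}"
            )
        slope, intercept = _log_line(b, a)
        d = -slope
        if d <= 0:
            raise DegenerateFitError(f"fitted diffusivity must be > 0, got {d:.3e}")
        self.d_ = float(d)
        self.population_ = float(np.exp(intercept))
        self.n_points_used_ = int(b.size)
        resid = self.population_ * np.exp(-self.d_ * b) - a
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        return self

    def predict(self, X):
        b, _ = _as_xy(X, np.zeros(np.asarray(X).reshape(-1, 1).shape[0]))
        return self.population_ * np.exp(-self.d_ * b)

    @property
    def component_(self) -> ExponentialComponent:
        return ExponentialComponent(d=self.d_, population=self.population_)


def _initial_slope(b, a, n_initial):
    if n_initial < 2:
        raise InvalidInputError(f"n_initial must be >= 2, got {n_initial}")
    if n_initial > b.size:
        raise InvalidInputError(
            f"n_initial = {n_initial} exceeds the {b.size} usable points"
        )
    order = np.argsort(b)
    bs, as_ = b[order][:n_initial], a[order][:n_initial]
    slope, _ = _log_line(bs, as_)
    return -slope


def initial_slope_adc(curve: DecayCurve, n_initial: int = 3) -> float:
    """Initial-slope apparent diffusion coefficient, m^2/s.

    Minus the least-squares slope of ln A versus b over the ``n_initial``
    smallest-b points with positive amplitude.  For a mixture of exponentials
    this converges to the population-weighted ADC as the window shrinks
    toward b = 0, and can only decrease as the window widens (ln of a
    positive mixture of exponentials is convex in b).
    """
    b, a = _positive_points(curve.b_values, curve.amplitudes)
    return _initial_slope(b, a, n_initial)


class PeelOffBiexponential(RegressorMixin, BaseEstimator):
    """Peel-off (stripping) biexponential decay fit with optional refinement.

    Parameters
    ----------
    tail_fraction : float, default 0.4
        Fraction of the positive-amplitude points, taken from the largest-b
        end, used for the slow-phase line fit.  Must lie in (0, 0.8].
    refine : bool, default True
        Run amplitude-domain nonlinear least squares on the full two-term
        model, seeded by the stripped estimates.
    n_initial : int, default 3
        Points used for the initial-slope ADC.
    positivity_floor : float, default 1e-6
        Residuals below ``positivity_floor * max(A)`` are dropped before the
        fast-phase log fit, so noise-dominated differences never reach the
        log transform.
    fast_window_floor : float, default 0.05
        The fast-phase log fit only uses residuals above this fraction of
        the largest residual; beyond that point the residual is dominated
        by slow-phase subtraction error (or noise) rather than the fast
        exponential.

    Attributes
    ----------
    d_fast_, d_slow_ : float
        Apparent diffusivities, m^2/s, with ``d_fast_ > d_slow_``.
    p1_ : float
        Fast-phase population after renormalization (p1 + p2 = 1).
    adc_initial_slope_ : float
    method_ : str
    residual_rms_ : float
    result_ : BiexpFitResult
    """

    def __init__(
        self,
        tail_fraction: float = 0.4,
        refine: bool = True,
        n_initial: int = 3,
        positivity_floor: float = 1e-6,
        fast_window_floor: float = 0.05,
    ):
        self.tail_fraction = tail_fraction
        self.refine = refine
        self.n_initial = n_initial
        self.positivity_floor = positivity_floor
        self.fast_window_floor = fast_window_floor

    def _tail_mask(self, b, adc_rough):
        """Slow-phase window: the largest-b tail_fraction of points, further
        restricted to b where the fast phase has decayed to <= ~5%.

        The initial-slope ADC is a lower bound on the fast diffusivity, so
        b >= 3 / ADC_rough guarantees exp(-b d_fast) <= exp(-3).  If the
        restriction leaves < 3 points, fall back to the plain count-based
        tail.
        """
        n = b.size
        n_tail = max(int(np.ceil(self.tail_fraction * n)), 3)
        mask = np.zeros(n, dtype=bool)
        mask[-n_tail:] = True
        if adc_rough > 0:
            restricted = mask & (b >= 3.0 / adc_rough)
            if np.count_nonzero(restricted) >= 3:
                return restricted
        return mask

    def _strip(self, b, a, adc_rough):
        """Slow-then-fast stripping; returns (d_fast, d_slow, pop_fast, pop_slow)."""
        tail = self._tail_mask(b, adc_rough)
        slope, intercept = _log_line(b[tail], a[tail])
        d_slow = -slope
        pop_slow = float(np.exp(intercept))
        if d_slow <= 0:
            raise StrippingFailureError(
                f"tail fit gave non-positive slow diffusivity ({d_slow:.3e})"
            )
        resid = a - pop_slow * np.exp(-d_slow * b)
        floor = max(
            self.positivity_floor * float(np.max(a)),
            self.fast_window_floor * float(np.max(resid, initial=0.0)),
        )
        keep = resid > floor
        if np.count_nonzero(keep) < 3:
            raise StrippingFailureError(
                "fewer than 3 usable residual points after stripping the slow "
                "phase; the curve may be mono-exponential"
            )
        slope_f, intercept_f = _log_line(b[keep], resid[keep])
        d_fast = -slope_f
        pop_fast = float(np.exp(intercept_f))
        if d_fast <= 0:
            raise StrippingFailureError(
                f"residual fit gave non-positive fast diffusivity ({d_fast:.3e})"
            )
        return d_fast, d_slow, pop_fast, pop_slow

    def fit(self, X, y):
        if not 0 < self.tail_fraction <= 0.8:
            raise InvalidInputError(
                f"tail_fraction must lie in (0, 0.8], got {self.tail_fraction!r}"
            )
        b, a = _positive_points(*_as_xy(X, y))
        order = np.argsort(b)
        b, a = b[order], a[order]
        if b.size < 6:
            raise InsufficientDataError(
                f"peel-off fit needs >= 6 positive points, got {b.size}"
            )

        adc0 = _initial_slope(b, a, self.n_initial)
        # Windowing uses a separate rough decay-rate estimate taken where
        # the curve has attenuated to ~60%: the n_initial-point slope is an
        # unbiased ADC estimator but too noise-sensitive at very small b to
        # steer the tail selection.
        # A 20% attenuation is reached while the fast phase still dominates
        # for any appreciable fast fraction, so this crossing estimates the
        # early decay rate robustly even when the tiny-b window is noisy.
        adc_rough = adc0
        below = np.flatnonzero(a < 0.8 * a[0])
        if below.size and b[below[0]] > 0:
            adc_rough = float(-np.log(0.8) / b[below[0]])
        # Both rough rates bound the fast diffusivity from below; the decay
        # is sufficiently sampled if the larger of them carries max(b) past
        # ~3 decay constants of the fast phase.
        d_fast_bound = max(adc0, adc_rough)
        if d_fast_bound > 0 and b[-1] * d_fast_bound < 3.0:
            warnings.warn(
                "max(b) * ADC_rough < 3: the fast phase is not fully decayed "
                "in the tail window; slow-phase estimates may be biased",
                stacklevel=2,
            )

        d_fast, d_slow, pop_fast, pop_slow = self._strip(b, a, adc_rough)
        pop_sum = pop_fast + pop_slow
        p1 = pop_fast / pop_sum
        method = "peel_off"

        if self.refine:
            d_fast, d_slow, p1 = self._refine(b, a, d_fast, d_slow, p1)
            method = "peel_off_refined"
        # The two-term model is symmetric under swapping the components, so
        # a "swapped" solution is the same fit with exchanged labels:
        # canonicalize to d_fast > d_slow.  Only an exact tie is a genuine
        # order violation (the two phases are then unidentifiable).
        if d_fast < d_slow:
            d_fast, d_slow, p1 = d_slow, d_fast, 1.0 - p1
        if d_fast <= d_slow:
            raise OrderViolationError(
                f"{method} fit gave d_fast ({d_fast:.3e}) <= d_slow ({d_slow:.3e}): "
                "phases are unidentifiable"
            )

        model = p1 * np.exp(-d_fast * b) + (1 - p1) * np.exp(-d_slow * b)
        self.d_fast_ = float(d_fast)
        self.d_slow_ = float(d_slow)
        self.p1_ = float(p1)
        self.adc_initial_slope_ = float(adc0)
        self.method_ = method
        self.residual_rms_ = float(np.sqrt(np.mean((model - a) ** 2)))
        self.n_points_used_ = int(b.size)
        self.population_sum_raw_ = float(pop_sum)
        return self

    def _refine(self, b, a, d_fast0, d_slow0, p10):
        # Diffusivities are ~1e-9 to 1e-11, so the analytic Jacobian is
        # essential: finite-difference steps at these magnitudes underflow
        # into rounding noise.  x_scale evens out the ~1e2 parameter spread.
        def residuals(theta):
            df, ds, p1 = theta
            return p1 * np.exp(-df * b) + (1 - p1) * np.exp(-ds * b) - a

        def jacobian(theta):
            df, ds, p1 = theta
            ef, es = np.exp(-df * b), np.exp(-ds * b)
            return np.column_stack([-p1 * b * ef, -(1 - p1) * b * es, ef - es])

        x0 = np.array([d_fast0, max(d_slow0, 1e-16), np.clip(p10, 1e-6, 1 - 1e-6)])
        sol = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, 1.0]),
            x_scale=[max(d_fast0, 1e-12), max(d_slow0, 1e-14), 0.1],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])

    def predict(self, X):
        b, _ = _as_xy(X, np.zeros(np.asarray(X).reshape(-1, 1).shape[0]))
        return self.p1_ * np.exp(-self.d_fast_ * b) + (1 - self.p1_) * np.exp(
            -self.d_slow_ * b
        )

    def result(self, t_d: float | None = None) -> BiexpFitResult:
        return BiexpFitResult(
            fast=ExponentialComponent(d=self.d_fast_, population=self.p1_),
            slow=ExponentialComponent(d=self.d_slow_, population=1 - self.p1_),
            adc_initial_slope=self.adc_initial_slope_,
            method=self.method_,
            residual_rms=self.residual_rms_,
            n_points_used=self.n_points_used_,
            population_sum_raw=self.population_sum_raw_,
            t_d=t_d,
        )


def fit_mono(curve: DecayCurve) -> ExponentialComponent:
    """Fit a single-exponential decay to a curve; see :class:`MonoExponential`."""
    est = MonoExponential().fit(curve.b_values.reshape(-1, 1), curve.amplitudes)
    return est.component_


def peel_off_fit(
    curve: DecayCurve,
    tail_fraction: float = 0.4,
    refine: bool = True,
    n_initial: int = 3,
    t_d: float | None = None,
) -> BiexpFitResult:
    """Peel-off biexponential fit of a curve; see :class:`PeelOffBiexponential`.

    Raises
    ------
    StrippingFailureError
        When the slow-phase subtraction leaves < 3 usable points (callers may
        fall back to :func:`fit_mono`).
    OrderViolationError
        When the fitted fast diffusivity does not exceed the slow one.
    """
    est = PeelOffBiexponential(
        tail_fraction=tail_fraction, refine=refine, n_initial=n_initial
    ).fit(curve.b_values.reshape(-1, 1), curve.amplitudes)
    return est.result(t_d=t_d)
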