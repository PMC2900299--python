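"""Plate-reader growth-curve pipeline: logistic fitting, normalization,
smoothing, and derivative profiles.

Infection time courses from different knockout strains differ in their
background growth (rate and eventual plateau) as much as in their response
to phage.  To compare the infection response itself, each strain's curves
are non-dimensionalized by a logistic fit to that strain's *uninfected*
replicates: carrying capacity ``K`` becomes the characteristic population
and ``1/mu`` the characteristic time, so every uninfected curve maps onto
the same unit logistic.  Clustering then operates on the time derivative of
the smoothed, normalized curve — the feature that captures when and how
fast a culture grows, stalls, clears, and regrows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares
from statsmodels.nonparametric.smoothers_lowess import lowess

#: lowess window as a fraction of the number of points.
DEFAULT_WINDOW_FRAC = 0.1
#: robust reweighting passes for lowess.
LOWESS_ITERATIONS = 5
#: curves whose dynamic range is below this are treated as flat (no growth).
FLAT_THRESHOLD = 0.01
#: decline below a candidate peak needed to call clearance.
DEFAULT_CLEARANCE_DROP = 0.05
#: cells per ml of a 1.0 OD600 E. coli culture (standard conversion).
CELLS_PER_ML_PER_OD = 5e8


class FitError(RuntimeError):
    """Logistic fit failed or the curve carries no growth signal."""


class CurveError(ValueError):
    """Invalid curve input or mismatched curve metadata."""


@dataclass
class GrowthCurve:
    """One well's raw time course: absorbance at 600 nm vs time in hours."""

    strain_id: str
    condition: str  # "infected" or "uninfected"
    t: np.ndarray
    A: np.ndarray
    moi: float | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.condition not in ("infected", "uninfected"):
            raise CurveError(f"condition must be infected/uninfected, got {self.condition!r}")
        if len(self.t) != len(self.A):
            raise CurveError("t and A must have equal length")
        if len(self.t) < 10:
            raise CurveError("growth curve needs at least 10 time points")
        if np.any(np.diff(self.t) <= 0):
            raise CurveError("t must be strictly increasing")
        if np.any(self.A < 0):
            raise CurveError("absorbance must be >= 0")


@dataclass
class LogisticFit:
    """Least-squares logistic parameters of an uninfected background."""

    K: float
    mu: float
    E0: float
    rss: float
    strain_id: str | None = None


@dataclass
class NormalizedCurve:
    """Dimensionless curve: tau = mu t, y = (A - baseline)/K."""

    tau: np.ndarray
    y: np.ndarray
    strain_id: str = ""
    condition: str = "infected"
    moi: float | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.tau) != len(self.y):
            raise CurveError("tau and y must have equal length")
        if np.any(np.diff(self.tau) <= 0):
            raise CurveError("tau must be strictly increasing")


@dataclass
class DerivativeProfile:
    """dy/dtau of a smoothed normalized curve on a shared grid — the
    feature vector used for clustering."""

    tau_grid: np.ndarray
    dy: np.ndarray
    strain_id: str = ""

    def __post_init__(self) -> None:
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if len(self.tau_grid) != len(self.dy):
            raise CurveError("grid and derivative must have equal length")
        if not np.all(np.isfinite(self.dy)):
            raise CurveError("derivative profile contains non-finite values")


def default_baseline(curve: GrowthCurve) -> float:
    """Media blank estimate: minimum of the first three readings of the well.

    Removes the media offset without requiring a dedicated blank well.
    """
    return float(np.min(curve.A[:3]))


def logistic(t, K, mu, y0):
    """Dimensional logistic y(t) = K y0 / (y0 + (K - y0) exp(-mu t))."""
    t = np.asarray(t, dtype=float)
    return K * y0 / (y0 + (K - y0) * np.exp(-mu * t))


def fit_logistic(curves, baseline: float | None = None) -> LogisticFit:
    """Fit logistic growth (K, mu, E0) to uninfected curves by least squares.

    ``curves`` is one :class:`GrowthCurve` or a list of replicate curves
    fitted jointly (points pooled).  The baseline (media blank) is
    subtracted before fitting; by default it is estimated per curve from
    the first readings.  Raises :class:`FitError` for flat curves or
    non-convergence.
    """
    if isinstance(curves, GrowthCurve):
        curves = [curves]
    if not curves:
        raise CurveError("fit_logistic needs at least one curve")
    strain = curves[0].strain_id
    for c in curves:
        if c.condition != "uninfected":
            raise CurveError(
                f"logistic background fit expects uninfected curves ({strain})"
            )
        if c.strain_id != strain:
            raise CurveError("all curves in a joint fit must share a strain")

    t_all, y_all = [], []
    for c in curves:
        b = default_baseline(c) if baseline is None else baseline
        t_all.append(c.t)
        y_all.append(np.maximum(c.A - b, 0.0))
    t = np.concatenate(t_all)
    y = np.concatenate(y_all)

    if y.max() - y.min() < FLAT_THRESHOLD:
        raise FitError(f"flat curve for strain {strain!r}: no growth to fit")

    K0 = float(y.max())
    y0_guess = float(max(np.median(y[t <= t.min() + (t.max() - t.min()) * 0.05]),
                         1e-4 * K0))
    # crude rate guess from time to half capacity
    t_half = float(t[np.argmin(np.abs(y - K0 / 2))])
    mu0 = np.log(K0 / y0_guess) / max(t_half, 1e-6)
    mu0 = float(np.clip(mu0, 1e-3, 1e3))

    def resid(theta):
        K, mu, y0 = theta
        return logistic(t, K, mu, y0) - y

    res = least_squares(
        resid,
        x0=[K0, mu0, y0_guess],
        bounds=([1e-9, 1e-9, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    if not res.success:
        raise FitError(f"logistic fit did not converge for strain {strain!r}")
    K, mu, E0 = map(float, res.x)
    if not (0 < E0 < K):
        raise FitError(
            f"degenerate logistic fit for strain {strain!r}: E0={E0}, K={K}"
        )
    return LogisticFit(K=K, mu=mu, E0=E0, rss=float(np.sum(res.fun**2)),
                       strain_id=strain)


def normalize_curve(curve: GrowthCurve, fit: LogisticFit,
                    baseline: float | None = None) -> NormalizedCurve:
    """Non-dimensionalize a curve with its strain's background fit:
    tau = mu t, y = (A - baseline)/K floored at 0."""
    if fit.strain_id is not None and fit.strain_id != curve.strain_id:
        raise CurveError(
            f"fit is for strain {fit.strain_id!r}, curve is {curve.strain_id!r}"
        )
    b = default_baseline(curve) if baseline is None else baseline
    return NormalizedCurve(
        tau=fit.mu * curve.t,
        y=np.maximum((curve.A - b) / fit.K, 0.0),
        strain_id=curve.strain_id,
        condition=curve.condition,
        moi=curve.moi,
    )


def average_replicates(curves: list[NormalizedCurve],
                       n_grid: int | None = None) -> NormalizedCurve:
    """Pointwise mean of replicate curves, resampled by linear
    interpolation onto a shared tau grid (the intersection of ranges)."""
    if not curves:
        raise CurveError("average_replicates needs at least one curve")
    first = curves[0]
    for c in curves[1:]:
        if c.strain_id != first.strain_id or c.condition != first.condition:
            raise CurveError("replicates must share strain and condition")
    lo = max(c.tau[0] for c in curves)
    hi = min(c.tau[-1] for c in curves)
    if hi <= lo:
        raise CurveError("replicate tau ranges do not overlap")
    n = n_grid or max(len(c.tau) for c in curves)
    grid = np.linspace(lo, hi, n)
    ys = np.vstack([np.interp(grid, c.tau, c.y) for c in curves])
    return NormalizedCurve(
        tau=grid, y=ys.mean(axis=0),
        strain_id=first.strain_id, condition=first.condition, moi=first.moi,
    )


def smooth_curve(curve: NormalizedCurve,
                 window_frac: float = DEFAULT_WINDOW_FRAC) -> NormalizedCurve:
    """Robust locally-weighted regression (lowess) on the curve's own grid.

    ``window_frac`` is the smoothing span as a fraction of the number of
    points; robustness comes from iterative reweighting, which discounts
    outlier readings (bubbles, condensation) rather than averaging them in.
    """
    if not 0 < window_frac <= 1:
        raise CurveError(f"window_frac must be in (0, 1], got {window_frac}")
    if len(curve.tau) < 10:
        raise CurveError("smoothing needs at least 10 points")
    smoothed = lowess(
        curve.y, curve.tau, frac=window_frac, it=LOWESS_ITERATIONS,
        return_sorted=False,
    )
    return NormalizedCurve(
        tau=curve.tau, y=smoothed, strain_id=curve.strain_id,
        condition=curve.condition, moi=curve.moi,
    )


def derivative_profile(curve: NormalizedCurve,
                       grid: np.ndarray) -> DerivativeProfile:
    """Analytic first derivative of a cubic smoothing spline through the
    curve, evaluated on a common grid.

    The spline stiffness is set by the discrepancy criterion against the
    curve's own second-difference noise estimate, which avoids the noise
    amplification of finite differencing while keeping the derivative of
    sharp lysis transients stable across replicates.
    Raises :class:`CurveError` if the grid extends beyond the data.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < curve.tau[0] - 1e-12 or grid[-1] > curve.tau[-1] + 1e-12:
        raise CurveError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond curve range "
            f"[{curve.tau[0]}, {curve.tau[-1]}]"
        )
    spline = _discrepancy_spline(curve.tau, curve.y)
    dy = spline.derivative()(grid)
    return DerivativeProfile(tau_grid=grid, dy=dy, strain_id=curve.strain_id)


def _noise_variance(y: np.ndarray) -> float:
    """Third-difference noise estimate: smooth-trend contributions cancel
    to O(h^3) and the difference variance is 20 sigma^2 for white noise."""
    d3 = y[3:] - 3.0 * y[2:-1] + 3.0 * y[1:-2] - y[:-3]
    return float(np.mean(d3**2) / 20.0)


def _discrepancy_spline(x: np.ndarray, y: np.ndarray):
    """Cubic smoothing spline with stiffness set by the discrepancy
    criterion: the residual sum of squares is matched to the estimated
    noise level (n * sigma^2), the classic rule for smoothing with known
    noise.  Falls back to generalized cross-validation when the noise
    estimate is negligible (effectively noiseless input)."""
    n = len(y)
    target = n * _noise_variance(y)
    if target < 1e-14:
        return make_smoothing_spline(x, y)

    def rss(log_lam: float) -> float:
        spl = make_smoothing_spline(x, y, lam=10.0**log_lam)
        return float(np.sum((spl(x) - y) ** 2))

    lo, hi = -12.0, 4.0
    if rss(lo) >= target:
        best = lo
    elif rss(hi) <= target:
        best = hi
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if rss(mid) < target:
                lo = mid
            else:
                hi = mid
        best = 0.5 * (lo + hi)
    return make_smoothing_spline(x, y, lam=10.0**best)


def common_grid(curves: list[NormalizedCurve], n: int = 100) -> np.ndarray:
    """Uniform grid of n points on the intersection of the curves' tau
    ranges, shared by every derivative profile in a dataset."""
    if not curves:
        raise CurveError("common_grid needs at least one curve")
    lo = max(c.tau[0] for c in curves)
    hi = min(c.tau[-1] for c in curves)
    if hi <= lo:
        raise CurveError("curve tau ranges do not overlap")
    return np.linspace(lo, hi, n)


def clearance_onset(curve: NormalizedCurve,
                    drop: float = DEFAULT_CLEARANCE_DROP):
    """Locate the first peak after which the population visibly clears.

    Returns ``(peak_tau, peak_y)`` for the first local maximum followed by
    a decline of more than ``drop`` dimensionless population units, or
    ``None`` if the curve never declines that much (a valid outcome for
    uninfected or resistant strains).
    """
    y = curve.y
    n = len(y)
    for i in range(n - 1):
        is_peak = (i == 0 or y[i] >= y[i - 1]) and y[i] >= y[i + 1]
        if is_peak and np.min(y[i:]) < y[i] - drop:
            return float(curve.tau[i]), float(y[i])
    return None


def moi_difference(curve_high: NormalizedCurve, curve_low: NormalizedCurve,
                   tau_eval: float = 8.0, clamp: bool = False) -> float:
    """Population gap between low- and high-MOI infections at a fixed
    dimensionless time: y_low(tau_eval) - y_high(tau_eval).

    With ``clamp=True``, a tau_eval beyond either curve is replaced by the
    largest shared tau (for slow strains whose normalized course ends
    early); otherwise that situation raises :class:`CurveError`.
    """
    max_shared = min(curve_high.tau[-1], curve_low.tau[-1])
    if tau_eval > max_shared:
        if not clamp:
            raise CurveError(
                f"tau={tau_eval} beyond shared range (max {max_shared:.3g}); "
                "pass clamp=True to evaluate at the largest shared tau"
            )
        tau_eval = max_shared
    if tau_eval < max(curve_high.tau[0], curve_low.tau[0]):
        raise CurveError(f"tau={tau_eval} precedes both curves")
    y_h = float(np.interp(tau_eval, curve_high.tau, curve_high.y))
    y_l = float(np.interp(tau_eval, curve_low.tau, curve_low.y))
    return y_l - y_h


def compute_moi(cell_vol_ul: float, cell_od: float, phage_vol_ul: float,
                titer_pfu_per_ml: float,
                cells_per_ml_per_od: float = CELLS_PER_ML_PER_OD) -> float:
    """Multiplicity of infection (pfu per bacterium) at inoculation.

    pfu added = phage_vol * titer; cells added = cell_vol * OD * cells/ml/OD,
    with volumes in microliters and concentrations per milliliter.
    """
    for name, v in (("cell_vol_ul", cell_vol_ul), ("cell_od", cell_od),
                    ("phage_vol_ul", phage_vol_ul),
                    ("titer_pfu_per_ml", titer_pfu_per_ml),
                    ("cells_per_ml_per_od", cells_per_ml_per_od)):
        if v <= 0:
            raise CurveError(f"{name} must be > 0, got {v}")
    pfu = (phage_vol_ul / 1000.0) * titer_pfu_per_ml
    cells = (cell_vol_ul / 1000.0) * cell_od * cells_per_ml_per_od
    return pfu / cells
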