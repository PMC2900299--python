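"""Parameter-grid simulation study and identifiability analyses.

Sweeps the three key infection parameters — dimensionless infection rate
``k_i`` (the group k_i K / mu), lytic fraction ``f`` and burst size ``b`` —
over a fixed grid, classifies each simulated time course by how strongly it
deviates from the uninfected background, summarizes which parameters drive
which dynamical feature, and quantifies the central identifiability
problem: burst size and infection rate enter the observable bacterial
dynamics almost exclusively through their product ``b * k_i``, so time
courses alone cannot separate them — but the free-phage trajectory can.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    DEFAULT_E0,
    DEFAULT_MOI,
    DEFAULT_N_OUT,
    DEFAULT_TAU_END,
    IntegrationError,
    NondimParams,
    PopulationState,
    Trajectory,
    initial_state,
    simulate,
)
from .curves import DerivativeProfile, NormalizedCurve

#: the grid of the 125-simulation study.
DEFAULT_KI_VALUES = (0.0, 0.25, 0.75, 2.0, 5.0)
DEFAULT_F_VALUES = (0.0, 0.5, 0.75, 0.95, 1.0)
DEFAULT_B_VALUES = (0.0, 10.0, 20.0, 50.0, 100.0)

#: wild-type-like reference parameters (kappa, b, f).
WT_KAPPA, WT_B, WT_F = 1.0, 28.0, 0.75

#: sup-norm deviation from the uninfected curve below which a simulation is
#: called non-infective (a soft boundary, configurable everywhere it is used).
NO_EFFECT_THRESHOLD = 0.05
#: fraction of the peak below which the population must fall to call
#: high infectivity (clearance).
CLEARANCE_FRACTION = 0.5


class StudyError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterGrid:
    k_i_values: tuple = DEFAULT_KI_VALUES
    f_values: tuple = DEFAULT_F_VALUES
    b_values: tuple = DEFAULT_B_VALUES

    def combinations(self):
        """Cartesian product in deterministic lexicographic (k_i, f, b) order."""
        return itertools.product(self.k_i_values, self.f_values, self.b_values)

    def __len__(self) -> int:
        return len(self.k_i_values) * len(self.f_values) * len(self.b_values)


@dataclass
class InfectivityClass:
    label: str  # none / low / high
    deviation: float


def _default_init(E0: float, moi: float) -> PopulationState:
    return initial_state(E0=E0, moi=moi)


def run_grid(
    grid: ParameterGrid | None = None,
    mu_ratio: float = 0.7,
    K_ratio: float = 0.7,
    sigma: float = 0.0,
    E0: float = DEFAULT_E0,
    moi: float = DEFAULT_MOI,
    tau_end: float = DEFAULT_TAU_END,
    n_out: int = DEFAULT_N_OUT,
) -> tuple[list[Trajectory], list[tuple[NondimParams, str]]]:
    """Simulate every grid combination; returns (trajectories, failures).

    An integration failure on one combination is recorded and the sweep
    continues; failures is a list of (params, message).
    """
    grid = grid or ParameterGrid()
    trajs: list[Trajectory] = []
    failures: list[tuple[NondimParams, str]] = []
    for k_i, f, b in grid.combinations():
        p = NondimParams(kappa=k_i, b=b, f=f,
                         mu_ratio=mu_ratio, K_ratio=K_ratio, sigma=sigma)
        try:
            trajs.append(simulate(p, init=_default_init(E0, moi),
                                  tau_end=tau_end, n_out=n_out))
        except IntegrationError as exc:  # pragma: no cover - none on defaults
            failures.append((p, str(exc)))
    return trajs, failures


def uninfected_reference(
    mu_ratio: float = 0.7, K_ratio: float = 0.7,
    E0: float = DEFAULT_E0, tau_end: float = DEFAULT_TAU_END,
    n_out: int = DEFAULT_N_OUT,
) -> Trajectory:
    """The phage-free background simulation (lambda_0 = 0)."""
    p = NondimParams(kappa=0.0, b=0.0, f=0.0,
                     mu_ratio=mu_ratio, K_ratio=K_ratio)
    return simulate(p, init=PopulationState(E0, 0.0, 0.0),
                    tau_end=tau_end, n_out=n_out)


def _clears(total: np.ndarray, fraction: float, tol: float = 1e-9) -> bool:
    """True when, after growth first turns to decline, the population drops
    below ``fraction`` of its global maximum (lysogen regrowth may later
    exceed the pre-crash peak, so the drawdown is measured from the first
    decline onset, not from the global argmax)."""
    decl = np.flatnonzero(np.diff(total) < -tol)
    if len(decl) == 0:
        return False
    return bool(np.min(total[decl[0]:]) < fraction * np.max(total))


def classify_infectivity(
    traj: Trajectory, reference: Trajectory,
    none_threshold: float = NO_EFFECT_THRESHOLD,
    clearance_fraction: float = CLEARANCE_FRACTION,
) -> InfectivityClass:
    """Label a simulation none/low/high by its total-population deviation
    from the uninfected reference (sup-norm), calling "high" when the
    population visibly clears (drops below ``clearance_fraction`` of its
    maximum after growth turns to decline)."""
    if len(traj.tau) != len(reference.tau) or not np.allclose(
            traj.tau, reference.tau):
        raise StudyError("trajectory and reference must share one tau grid")
    total = traj.total
    deviation = float(np.max(np.abs(total - reference.total)))
    if deviation < none_threshold:
        return InfectivityClass("none", deviation)
    if _clears(total, clearance_fraction):
        return InfectivityClass("high", deviation)
    return InfectivityClass("low", deviation)


def overtake_time(traj: Trajectory, tol: float = 1e-5):
    """First dimensionless time at which lysis outpaces growth, i.e. the
    total population starts to decline; None if it never does.

    Per-step declines smaller than ``tol`` are ignored: the adaptive
    integrator leaves wiggles of a few 1e-6 near the logistic plateau.
    """
    total = traj.total
    decl = np.flatnonzero(np.diff(total) < -tol)
    if len(decl) == 0:
        return None
    return float(traj.tau[decl[0]])


def trajectory_profile(traj: Trajectory,
                       grid: np.ndarray | None = None) -> DerivativeProfile:
    """Derivative profile of a simulated total-population curve.

    Simulations are noiseless so no lowess pass is needed; the spline
    derivative is taken directly.
    """
    from .curves import derivative_profile

    nc = NormalizedCurve(tau=traj.tau, y=traj.total,
                         strain_id=_param_id(traj.params))
    if grid is None:
        grid = traj.tau
    return derivative_profile(nc, grid)


def _param_id(p: NondimParams) -> str:
    return f"ki={p.kappa:g}_f={p.f:g}_b={p.b:g}"


def parameter_effect_summary(trajs: list[Trajectory]) -> pd.DataFrame:
    """Per-trajectory summary table linking parameters to dynamical features.

    Columns: f, b, k_i, bk (= b * k_i), overtake_time (NaN if growth is
    never outpaced), lysogen_regrowth (E* at the horizon).
    """
    rows = []
    for traj in trajs:
        p = traj.params
        rows.append({
            "f": p.f, "b": p.b, "k_i": p.kappa, "bk": p.b * p.kappa,
            "overtake_time": overtake_time(traj),
            "lysogen_regrowth": float(traj.Estar[-1]),
        })
    df = pd.DataFrame(rows)
    df["overtake_time"] = df["overtake_time"].astype(float)
    return df


def bk_overtake_spearman(summary: pd.DataFrame) -> float:
    """Spearman correlation of b*k_i with overtake time among trajectories
    that are overtaken at all (negative: stronger infection, earlier lysis)."""
    sub = summary.dropna(subset=["overtake_time"])
    if len(sub) < 3:
        raise StudyError("too few overtaken trajectories for a correlation")
    rho, _ = stats.spearmanr(sub["bk"], sub["overtake_time"])
    return float(rho)


def cosine_similarity_curves(a: np.ndarray, b: np.ndarray) -> float:
    """cos(theta) between two time-course vectors on one grid."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise StudyError("cosine undefined for a zero curve")
    return float(np.dot(a, b) / (na * nb))


def deviation_scan(
    param: str,
    values,
    base: NondimParams | None = None,
    E0: float = DEFAULT_E0,
    moi: float = DEFAULT_MOI,
    tau_end: float = DEFAULT_TAU_END,
    n_out: int = DEFAULT_N_OUT,
) -> list[tuple[float, float]]:
    """How far the bacterial time course drifts as one parameter varies.

    For each value of ``param`` (one of k_i, b, f), returns (value,
    cos(theta)) between the varied and base total-population vectors, the
    base being the wild-type-like parameter point (k_i=1, b=28, f=0.75).
    A cosine of 1 means the curves are directionally identical.
    """
    if base is None:
        base = NondimParams(kappa=WT_KAPPA, b=WT_B, f=WT_F)
    field_map = {"k_i": "kappa", "b": "b", "f": "f"}
    if param not in field_map:
        raise StudyError(f"param must be one of {sorted(field_map)}, got {param!r}")
    init = _default_init(E0, moi)
    base_total = simulate(base, init=init, tau_end=tau_end, n_out=n_out).total
    out = []
    for v in values:
        p = base.replace(**{field_map[param]: float(v)})
        total = simulate(p, init=init, tau_end=tau_end, n_out=n_out).total
        out.append((float(v), cosine_similarity_curves(total, base_total)))
    return out


def phage_phase_classify(
    traj: Trajectory,
    constant_rtol: float = 1e-3,
    clearance_fraction: float = CLEARANCE_FRACTION,
) -> str:
    """Classify the free-phage trajectory into one of four regimes.

    Time courses that look identical in bacterial density separate cleanly
    in phage concentration:

    - ``no-adsorption``: lambda constant (phage cannot attach, k_i = 0);
    - ``no-production``: lambda monotonically declines (adsorbed but no
      viable progeny, b or f effectively 0);
    - ``low-production-accumulation``: lambda rises but the bacterial
      population never clears (weak productive infection);
    - ``productive-lysis``: lambda rises and the culture clears.
    """
    lam = traj.lam
    lam0 = lam[0]
    if lam0 == 0 and np.all(lam == 0):
        return "no-adsorption"
    scale = max(abs(lam0), np.max(np.abs(lam)))
    if scale == 0 or np.max(np.abs(lam - lam0)) <= constant_rtol * scale:
        return "no-adsorption"
    increases = np.max(lam) > lam0 * (1.0 + constant_rtol)
    if not increases:
        return "no-production"
    cleared = _clears(traj.total, clearance_fraction)
    return "productive-lysis" if cleared else "low-production-accumulation"


@dataclass
class ParameterFitResult:
    """Outcome of fitting (f, b*k_i) to an observed bacterial curve."""

    f_hat: float
    bk_hat: float
    loss: float
    converged: bool
    n_starts: int


def curve_loss(
    observed: NormalizedCurve,
    f: float,
    bk: float,
    b_ref: float = WT_B,
    mu_ratio: float = 0.7,
    K_ratio: float = 0.7,
    sigma: float = 0.0,
    moi: float = DEFAULT_MOI,
    E0: float = DEFAULT_E0,
) -> float:
    """RMS distance between an observed normalized curve and the simulated
    total population at (f, b*k_i).

    Because the bacterial dynamics depend on b and k_i almost only through
    their product, the simulation splits the product conventionally as
    b = b_ref, kappa = bk / b_ref.
    """
    kappa = bk / b_ref
    p = NondimParams(kappa=kappa, b=b_ref, f=f,
                     mu_ratio=mu_ratio, K_ratio=K_ratio, sigma=sigma)
    tau_end = float(observed.tau[-1])
    traj = simulate(p, init=_default_init(E0, moi),
                    tau_end=max(tau_end, 1e-3), n_out=max(len(observed.tau), 50))
    sim = np.interp(observed.tau, traj.tau, traj.total)
    return float(np.sqrt(np.mean((sim - observed.y) ** 2)))


def fit_parameters(
    observed: NormalizedCurve,
    b_ref: float = WT_B,
    mu_ratio: float = 0.7,
    K_ratio: float = 0.7,
    sigma: float = 0.0,
    moi: float = DEFAULT_MOI,
    E0: float = DEFAULT_E0,
    n_starts: int = 5,
) -> ParameterFitResult:
    """Least-squares fit of (f, b*k_i) to an observed bacterial time course.

    Only the product b*k_i is reported — b and k_i are not separately
    identifiable from bacterial dynamics (the loss surface has a flat
    ridge along constant product).  Search is bounded local optimization
    over f in [0, 1] and log10(b*k_i) in [-3, 3] from ``n_starts``
    deterministic multi-starts.
    """
    if len(observed.tau) < 10:
        raise StudyError("observed curve too short to fit")

    def loss_of(theta):
        f, log_bk = theta
        return curve_loss(observed, f=f, bk=10.0 ** log_bk, b_ref=b_ref,
                          mu_ratio=mu_ratio, K_ratio=K_ratio, sigma=sigma,
                          moi=moi, E0=E0)

    starts = [(0.75, np.log10(WT_B * WT_KAPPA)), (0.5, 0.0), (0.95, 2.0),
              (0.25, -1.5), (0.9, 1.0)][:n_starts]
    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            loss_of, x0=np.array(x0), method="Nelder-Mead",
            bounds=[(0.0, 1.0), (-3.0, 3.0)],
            options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 400},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    f_hat, log_bk = best.x
    return ParameterFitResult(
        f_hat=float(f_hat), bk_hat=float(10.0 ** log_bk),
        loss=float(best.fun), converged=any_success, n_starts=len(starts),
    )
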