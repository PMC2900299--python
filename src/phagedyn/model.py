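"""Three-population predator-prey model of temperate phage infection.

The model tracks three concentrations in a well-mixed batch culture:
uninfected bacteria ``E``, lysogens ``E*`` (cells carrying the phage genome
as a dormant prophage), and free infectious phage ``lambda``.  Uninfected
cells grow logistically with rate ``mu`` toward carrying capacity ``K``;
lysogens grow with their own, analogous parameters ``mu*`` and ``K*``.
Phage infect uninfected cells by mass action with rate constant ``k_i``.  A
fraction ``f`` of infections is lytic and releases a burst of ``b`` phage;
the remaining ``1 - f`` lysogenize.  Lysogens are immune to productive
superinfection but still adsorb phage, depleting the free pool.  Induction
of lysogens into lysis occurs at rate ``k_s`` (negligible under typical
conditions and zero by default).

For simulation the system is non-dimensionalized: time is rescaled by
``1/mu`` and every population by ``K``, so the uninfected growth rate and
capacity both become unity.  The infection rate collapses into the single
dimensionless group ``kappa = k_i * K / mu``; lysogen growth reduces to the
ratios ``mu*/mu`` and ``K*/K``; ``b`` and ``f`` are already dimensionless.

Scaled equations (tau = mu * t, populations in units of K):

    dE/dtau  = E (1 - E) - kappa E lam
    dE*/dtau = mu_ratio E* (1 - E*/K_ratio) + (1 - f) kappa E lam - sigma E*
    dlam/dtau = f b kappa E lam - kappa E lam - kappa E* lam + b sigma E*

where ``sigma = k_s / mu``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

# Adaptive-RK tolerances: conventional relative tolerance, with a tighter
# absolute floor so population undershoot during the lysis crash stays well
# inside 1e-6; negative transients are clipped only at reporting time.
RTOL = 1e-3
ATOL = 1e-8

#: Default initial uninfected population (units of K).
DEFAULT_E0 = 0.02
#: Default multiplicity of infection (pfu per bacterium) at inoculation.
DEFAULT_MOI = 2e-4
#: Default dimensionless simulation horizon and output resolution.
DEFAULT_TAU_END = 12.0
DEFAULT_N_OUT = 200


class ModelError(ValueError):
    """Invalid model parameters or state."""


class IntegrationError(RuntimeError):
    """The adaptive integrator failed (stiffness or blow-up)."""


@dataclass(frozen=True)
class ModelParams:
    """Dimensional rate constants and capacities of the infection model.

    Rates are per hour; ``K`` and ``K_star`` are in population units
    (OD-equivalent); ``k_i`` is per (population unit x hour); ``b`` is a
    dimensionless phage count per lysis and ``f`` a fraction in [0, 1].
    """

    mu: float
    K: float
    mu_star: float
    K_star: float
    k_i: float
    b: float
    f: float
    k_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu", "K", "mu_star", "K_star", "k_i", "b", "k_s"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.f <= 1.0:
            raise ModelError(f"lytic fraction f must lie in [0, 1], got {self.f}")


@dataclass(frozen=True)
class NondimParams:
    """Dimensionless parameter group of the scaled model.

    ``kappa = k_i K / mu`` is the only place the infection rate enters;
    ``mu_ratio = mu*/mu`` and ``K_ratio = K*/K`` describe lysogen growth
    relative to the uninfected background (0.7 by convention when not
    measured); ``sigma = k_s / mu`` is the scaled induction rate, zero by
    default.  ``shared_capacity`` switches the lysogen logistic term from
    self-limitation against ``K_ratio`` to limitation by the total
    bacterial population (a shared-resource variant).
    """

    kappa: float
    b: float
    f: float
    mu_ratio: float = 0.7
    K_ratio: float = 0.7
    sigma: float = 0.0
    shared_capacity: bool = False

    def __post_init__(self) -> None:
        for name in ("kappa", "b", "mu_ratio", "K_ratio", "sigma"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.f <= 1.0:
            raise ModelError(f"lytic fraction f must lie in [0, 1], got {self.f}")

    def replace(self, **kwargs) -> "NondimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous concentrations (E, E*, lambda) in units of K."""

    E: float
    Estar: float
    lam: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.Estar, self.lam], dtype=float)


def nondimensionalize(p: ModelParams) -> NondimParams:
    """Rescale dimensional parameters by the characteristic time 1/mu and
    population K."""
    if p.mu <= 0 or p.K <= 0:
        raise ModelError("nondimensionalization requires mu > 0 and K > 0")
    return NondimParams(
        kappa=p.k_i * p.K / p.mu,
        b=p.b,
        f=p.f,
        mu_ratio=p.mu_star / p.mu,
        K_ratio=p.K_star / p.K,
        sigma=p.k_s / p.mu,
    )


def ode_rhs(state, p: NondimParams) -> np.ndarray:
    """Right-hand side (dE/dtau, dE*/dtau, dlam/dtau) of the scaled model.

    ``state`` may be a :class:`PopulationState` or a length-3 array.
    Raises :class:`ModelError` on negative state components.
    """
    if isinstance(state, PopulationState):
        state = state.as_array()
    E, Estar, lam = float(state[0]), float(state[1]), float(state[2])
    if E < 0 or Estar < 0 or lam < 0:
        raise ModelError(f"negative state component in ({E}, {Estar}, {lam})")
    return _rhs(E, Estar, lam, p)


def _rhs(E: float, Estar: float, lam: float, p: NondimParams) -> np.ndarray:
    infect = p.kappa * E * lam
    if p.shared_capacity:
        lys_logistic = p.mu_ratio * Estar * (1.0 - (E + Estar) / p.K_ratio)
    else:
        lys_logistic = p.mu_ratio * Estar * (1.0 - Estar / p.K_ratio)
    dE = E * (1.0 - E) - infect
    dEstar = lys_logistic + (1.0 - p.f) * infect - p.sigma * Estar
    dlam = (
        p.f * p.b * infect
        - infect
        - p.kappa * Estar * lam
        + p.b * p.sigma * Estar
    )
    return np.array([dE, dEstar, dlam])


@dataclass
class Trajectory:
    """One simulation: a strictly increasing dimensionless time grid and the
    three population series, with the parameters that produced them."""

    tau: np.ndarray
    E: np.ndarray
    Estar: np.ndarray
    lam: np.ndarray
    params: NondimParams

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.Estar = np.asarray(self.Estar, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if not (len(self.tau) == len(self.E) == len(self.Estar) == len(self.lam)):
            raise ModelError("trajectory arrays must share one length")
        if np.any(np.diff(self.tau) <= 0):
            raise ModelError("tau must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        """E + E*: the bacterial population a plate reader actually sees."""
        return self.E + self.Estar

    def state_at(self, i: int) -> PopulationState:
        return PopulationState(self.E[i], self.Estar[i], self.lam[i])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tau": self.tau,
                "E": self.E,
                "Estar": self.Estar,
                "lambda": self.lam,
                "total": self.total,
            }
        )


def initial_state(E0: float = DEFAULT_E0, moi: float = DEFAULT_MOI,
                  Estar0: float = 0.0) -> PopulationState:
    """Standard inoculation: E0 uninfected cells, no lysogens, phage at
    ``moi * E0``."""
    return PopulationState(E0, Estar0, moi * E0)


def simulate(
    p: NondimParams,
    init: PopulationState | None = None,
    tau_end: float = DEFAULT_TAU_END,
    n_out: int = DEFAULT_N_OUT,
    clip: bool = True,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the scaled model with adaptive RK45 onto a uniform grid.

    Populations are clipped to zero for reporting when ``clip`` is true
    (transients down to about -atol are within integrator tolerance);
    pass ``clip=False`` to inspect the raw solver output.  Tighten
    ``rtol``/``atol`` when comparing against closed-form solutions.
    """
    if tau_end <= 0:
        raise ModelError(f"tau_end must be > 0, got {tau_end}")
    if n_out < 2:
        raise ModelError("n_out must be at least 2")
    if init is None:
        init = initial_state()
    y0 = init.as_array()
    if np.any(y0 < 0):
        raise ModelError("initial populations must be >= 0")
    tau = np.linspace(0.0, tau_end, n_out)
    sol = solve_ivp(
        lambda _t, y: _rhs(y[0], y[1], y[2], p),
        (0.0, tau_end),
        y0,
        method="RK45",
        t_eval=tau,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"RK45 failed for {p}: {sol.message}")
    y = sol.y
    if clip:
        y = np.maximum(y, 0.0)
    return Trajectory(tau=tau, E=y[0], Estar=y[1], lam=y[2], params=p)


def observed_total(traj: Trajectory) -> np.ndarray:
    """Experimentally observable bacterial series: E + E* per time point
    (the two populations are indistinguishable by absorbance)."""
    return traj.total


PARAM_KEYS = ("mu", "K", "mu_star", "K_star", "k_i", "b", "f", "k_s",
              "moi", "E0")


def params_to_dict(p: ModelParams, moi: float = DEFAULT_MOI,
                   E0: float | None = None) -> dict:
    """Flat key -> value serialization of a dimensional parameter set plus
    the inoculation settings (keys exactly: mu, K, mu_star, K_star, k_i,
    b, f, k_s, moi, E0)."""
    if E0 is None:
        E0 = DEFAULT_E0 * p.K
    return {"mu": p.mu, "K": p.K, "mu_star": p.mu_star, "K_star": p.K_star,
            "k_i": p.k_i, "b": p.b, "f": p.f, "k_s": p.k_s,
            "moi": moi, "E0": E0}


def params_from_dict(d: dict) -> tuple[ModelParams, float, float]:
    """Inverse of :func:`params_to_dict`: returns (params, moi, E0)."""
    unknown = set(d) - set(PARAM_KEYS)
    if unknown:
        raise ModelError(f"unknown parameter keys: {sorted(unknown)}")
    p = ModelParams(mu=float(d["mu"]), K=float(d["K"]),
                    mu_star=float(d["mu_star"]), K_star=float(d["K_star"]),
                    k_i=float(d["k_i"]), b=float(d["b"]), f=float(d["f"]),
                    k_s=float(d.get("k_s", 0.0)))
    return p, float(d.get("moi", DEFAULT_MOI)), \
        float(d.get("E0", DEFAULT_E0 * p.K))


def logistic_solution(tau, E0: float = DEFAULT_E0) -> np.ndarray:
    """Closed-form scaled logistic E(tau) = E0 / (E0 + (1 - E0) e^-tau),
    the exact uninfected solution (kappa = sigma = 0)."""
    tau = np.asarray(tau, dtype=float)
    return E0 / (E0 + (1.0 - E0) * np.exp(-tau))
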