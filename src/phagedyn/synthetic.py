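"""Synthetic plate-reader and plaque-count data generator.

Emulates the structure of an infection time-course experiment: for each
strain archetype, infected and uninfected wells (4 replicates each) are
"measured" over 38 reader cycles (~11 h) by simulating the infection model
in dimensional units, mapping population to OD600 (identity scale plus a
media baseline), and adding independent Gaussian read noise.  Plaque-count
series are Poisson samples around the model's free-phage trajectory at the
standard post-infection sampling times.  Everything is reproducible
bit-for-bit under a fixed seed.

Dimensional anchors (the model itself is simulated in scaled form): growth
rate 0.8/h and capacity 0.5 OD, so 38 cycles of 17 min span about 8.6
dimensionless time units — comparable to real nutrient-broth microplate
cultures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .curves import GrowthCurve
from .model import (
    DEFAULT_MOI,
    ModelParams,
    NondimParams,
    PopulationState,
    Trajectory,
    nondimensionalize,
    simulate,
)
from .titer import DEFAULT_SAMPLE_TIMES_MIN, PhageTimecourse

# dimensional anchors for emitted data
DEFAULT_MU = 0.8          # 1/h
DEFAULT_K = 0.5           # OD600 units
DEFAULT_E0_FRAC = 0.02    # of K
DEFAULT_BASELINE = 0.04   # OD600 media blank
DEFAULT_SIGMA_ADD = 0.005  # OD600 read noise SD
DEFAULT_N_CYCLES = 38
DEFAULT_CYCLE_MIN = 17.0
DEFAULT_N_REPLICATES = 4
#: initial dead time before the first measurement (minutes).
FIRST_READ_MIN = 10.0


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    sigma_add: float = DEFAULT_SIGMA_ADD
    baseline: float = DEFAULT_BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_add < 0:
            raise SyntheticError("sigma_add must be >= 0")


@dataclass(frozen=True)
class StrainArchetype:
    """A named parameter set emulating one class of knockout phenotype."""

    name: str
    params: ModelParams
    description: str = ""


def _dimensional(kappa: float, b: float, f: float,
                 mu: float = DEFAULT_MU, K: float = DEFAULT_K) -> ModelParams:
    # k_i chosen so the dimensionless group k_i K / mu equals kappa
    return ModelParams(mu=mu, K=K, mu_star=0.7 * mu, K_star=0.7 * K,
                       k_i=kappa * mu / K, b=b, f=f, k_s=0.0)


def builtin_archetypes() -> list[StrainArchetype]:
    """The standard panel of infection phenotypes.

    wild-type-like sits at the reference point (kappa=1, b=28, f=0.75);
    the others block or attenuate one step of the infection cycle.
    """
    return [
        StrainArchetype("wild-type-like", _dimensional(1.0, 28.0, 0.75),
                        "productive lysis, full clearance"),
        StrainArchetype("entry-blocked", _dimensional(0.0, 28.0, 0.75),
                        "phage cannot adsorb (receptor loss)"),
        StrainArchetype("replication-blocked", _dimensional(1.0, 0.0, 0.75),
                        "adsorbs but produces no viable progeny"),
        StrainArchetype("rate-reduced", _dimensional(0.05, 28.0, 0.75),
                        "strongly reduced infection rate"),
        StrainArchetype("lysogeny-biased", _dimensional(1.0, 28.0, 0.3),
                        "most infections lysogenize"),
        StrainArchetype("clearance-delayed", _dimensional(0.25, 28.0, 0.75),
                        "productive lysis overtaking growth late"),
    ]


#: archetype names whose bacterial dynamics are pairwise well separated —
#: the standard panel for planted-group recovery checks.
PLANTED_PANEL = ("wild-type-like", "clearance-delayed", "entry-blocked")


def planted_panel() -> list[StrainArchetype]:
    """Three archetypes with mutually distinct growth dynamics (early
    clearance, late clearance, no effect)."""
    by_name = {a.name: a for a in builtin_archetypes()}
    return [by_name[n] for n in PLANTED_PANEL]


SAMPLE_SEP = "~s"


def sample_panel(
    archetypes: list[StrainArchetype],
    n_samples: int = 3,
    **kwargs,
) -> list[GrowthCurve]:
    """Multiple independent culture samples per archetype, each with the
    full replicate structure.

    Mirrors a screen where the same strain is assayed on several plates:
    every sample is later averaged over its replicates and enters
    clustering as its own row.  Sample identity is encoded in the strain id
    as ``<name>~s<i>``; strip with :func:`sample_base`.
    """
    curves: list[GrowthCurve] = []
    for i in range(n_samples):
        named = [StrainArchetype(f"{a.name}{SAMPLE_SEP}{i}", a.params,
                                 a.description) for a in archetypes]
        curves.extend(generate_plate_curves(named, **kwargs))
    return curves


def sample_base(strain_id: str) -> str:
    """Archetype name behind a sample id (inverse of :func:`sample_panel`)."""
    return strain_id.split(SAMPLE_SEP)[0]


def _noise_rng(seed: int, name: str, condition: str, replicate: int,
               stream: int = 0) -> np.random.Generator:
    """Deterministic RNG keyed by (seed, strain, condition, replicate) so a
    replicate's noise stream is independent of which panel it appears in."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    cond = {"uninfected": 0, "infected": 1}[condition]
    return np.random.default_rng([seed, key, cond, replicate, stream])


def archetype_trajectory(
    archetype: StrainArchetype,
    infected: bool,
    moi: float = DEFAULT_MOI,
    t_max_h: float | None = None,
    n_out: int = 400,
) -> tuple[Trajectory, NondimParams, float, float]:
    """Simulate one archetype in scaled form; returns (trajectory,
    nondim params, mu, K) for mapping back to dimensional units."""
    p = nondimensionalize(archetype.params)
    mu, K = archetype.params.mu, archetype.params.K
    E0 = DEFAULT_E0_FRAC
    lam0 = moi * E0 if infected else 0.0
    if t_max_h is None:
        t_max_h = (FIRST_READ_MIN + DEFAULT_N_CYCLES * DEFAULT_CYCLE_MIN) / 60.0
    traj = simulate(p, init=PopulationState(E0, 0.0, lam0),
                    tau_end=mu * t_max_h, n_out=n_out)
    return traj, p, mu, K


def generate_plate_curves(
    archetypes: list[StrainArchetype] | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_cycles: int = DEFAULT_N_CYCLES,
    cycle_min: float = DEFAULT_CYCLE_MIN,
    noise: NoiseModel | None = None,
    moi: float = DEFAULT_MOI,
    conditions: tuple[str, ...] = ("uninfected", "infected"),
) -> list[GrowthCurve]:
    """Generate a full plate of growth curves: every archetype x condition
    x replicate, sampled at ``n_cycles`` reader cycles.

    At ``sigma_add = 0`` the curves equal the model solution (plus the
    baseline offset) exactly; noise draws are deterministic under the
    noise model's seed.
    """
    if n_replicates < 1 or n_cycles < 10:
        raise SyntheticError("need >= 1 replicate and >= 10 cycles")
    archetypes = archetypes if archetypes is not None else builtin_archetypes()
    noise = noise or NoiseModel()
    t_h = (FIRST_READ_MIN + cycle_min * np.arange(n_cycles)) / 60.0
    curves: list[GrowthCurve] = []
    for arch in archetypes:
        for condition in conditions:
            traj, _p, mu, K = archetype_trajectory(
                arch, infected=(condition == "infected"), moi=moi,
                t_max_h=float(t_h[-1]))
            total_od = np.interp(mu * t_h, traj.tau, traj.total) * K
            for rep in range(n_replicates):
                rng = _noise_rng(noise.seed, arch.name, condition, rep)
                eps = rng.normal(0.0, noise.sigma_add, size=n_cycles) \
                    if noise.sigma_add > 0 else np.zeros(n_cycles)
                A = np.maximum(total_od + noise.baseline + eps, 0.0)
                curves.append(GrowthCurve(
                    strain_id=arch.name, condition=condition, t=t_h.copy(),
                    A=A, moi=moi if condition == "infected" else None,
                    replicate=rep,
                ))
    return curves


def generate_titer_counts(
    traj: Trajectory,
    mu: float = DEFAULT_MU,
    times_min=DEFAULT_SAMPLE_TIMES_MIN,
    scale: float | None = None,
    dilutions=None,
    plated_vol_ml: float = 0.1,
    seed: int = 0,
    strain_id: str = "synthetic",
    target_initial_count: float = 500.0,
) -> PhageTimecourse:
    """Poisson-sampled plaque counts along a simulated phage trajectory.

    ``scale`` converts dimensionless lambda to pfu/ml; when omitted it is
    fixed by convention so the expected plate count at the first sampling
    time equals ``target_initial_count``.  Observed counts are Poisson
    draws around lambda(t) * scale * plated volume / dilution, and pfu/ml
    is back-computed from the counts as in a real assay.
    """
    times_min = np.asarray(times_min, dtype=float)
    tau_samples = mu * times_min / 60.0
    if tau_samples[-1] > traj.tau[-1] + 1e-9:
        raise SyntheticError(
            f"sampling time {times_min[-1]} min is beyond the trajectory"
        )
    lam = np.interp(tau_samples, traj.tau, traj.lam)
    dilutions = np.ones_like(lam) if dilutions is None \
        else np.asarray(dilutions, dtype=float)
    if scale is None:
        if lam[0] <= 0:
            raise SyntheticError("cannot auto-scale: lambda(t0) is zero")
        scale = target_initial_count * dilutions[0] / (lam[0] * plated_vol_ml)
    expected = lam * scale * plated_vol_ml / dilutions
    rng = np.random.default_rng([seed, zlib.crc32(strain_id.encode()) & 0x7FFFFFFF])
    counts = rng.poisson(expected).astype(float)
    pfu_ml = counts * dilutions / plated_vol_ml
    return PhageTimecourse(
        strain_id=strain_id, t_min=times_min, pfu_ml=pfu_ml,
        counts=counts, dilutions=dilutions, plated_vol_ml=plated_vol_ml,
    )


def moi_series_panel(
    archetype: StrainArchetype,
    moi_multipliers=(1.0, 10.0, 100.0),
    noise: NoiseModel | None = None,
    base_moi: float = DEFAULT_MOI,
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_cycles: int = DEFAULT_N_CYCLES,
    cycle_min: float = DEFAULT_CYCLE_MIN,
) -> list[GrowthCurve]:
    """Infected curves for one archetype at several MOI multipliers.

    Each replicate reuses one noise stream across multipliers (paired
    wells), so the multiplier-1 panel is identical to the corresponding
    ``generate_plate_curves`` infected output under the same seed.
    """
    noise = noise or NoiseModel()
    curves: list[GrowthCurve] = []
    for mult in moi_multipliers:
        moi = base_moi * float(mult)
        sub = generate_plate_curves(
            archetypes=[archetype], n_replicates=n_replicates,
            n_cycles=n_cycles, cycle_min=cycle_min, noise=noise, moi=moi,
            conditions=("infected",),
        )
        curves.extend(sub)
    return curves
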