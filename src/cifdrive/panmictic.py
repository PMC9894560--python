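"""Deterministic panmictic dynamics of the CifAB drive.

Continuous-generation ordinary differential equations, the
discrete-generation expectation map of the individual-based model,
two linked demes, a continuous drive influx, trajectory summary
metrics, and bisection searches for the introduction threshold.

Time is measured in generations; all abundances are relative to the
carrying capacity ``K = 1``.  Density dependence follows the logistic-like
birth/death pair ``b(N) = N*lam/((lam-1)*N + 1)`` and ``d(N) = N**2``,
which fixes ``b = d = 1`` at capacity and a per-capita growth rate of
``lam`` near zero density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .genetics import (
    Architecture,
    DriveParams,
    GenotypeState,
    GenotypeSystem,
    birth_weights,
    carrier_mask,
    fitness_vector,
    get_system,
    offspring_tensor,
    sterility_matrix,
    _allele_count_vector,
)

__all__ = [
    "EcologyParams",
    "ReleaseSpec",
    "Trajectory",
    "TrajectoryMetrics",
    "TwoDemeConfig",
    "InfluxConfig",
    "birth_rate",
    "death_rate",
    "ode_rhs",
    "integrate",
    "trajectory_metrics",
    "find_threshold",
    "discrete_step",
    "iterate_discrete",
    "find_discrete_threshold",
    "two_deme_integrate",
    "influx_integrate",
    "find_critical_influx",
    "reproduction_success",
]

#: solver tolerances; the threshold is reported to 0.001%, which needs a
#: tight integration of the near-threshold saddle dynamics
RTOL = 1e-9
ATOL = 1e-12


@dataclass(frozen=True)
class EcologyParams:
    """Population ecology: carrying capacity (fixed at 1) and low-density
    growth rate ``lam`` (per-capita growth rate as density -> 0)."""

    low_density_growth: float = 9.0
    capacity: float = 1.0

    def __post_init__(self) -> None:
        if self.low_density_growth <= 0:
            raise ValueError("low-density growth rate must be positive")
        if self.capacity != 1.0:
            raise ValueError("deterministic models use abundances relative to K; capacity is fixed at 1")


@dataclass(frozen=True)
class ReleaseSpec:
    """Initial condition of a panmictic run.

    By default drive homozygotes are introduced at frequency ``I`` into a
    population of total relative abundance 1 (``x = (I, 0, 1 - I)`` for
    CIFAB).  ``release_genotypes`` overrides this with explicit per-genotype
    fractions (remaining mass goes to the wild-type homozygote).
    """

    introduction_frequency: float = 0.0
    release_genotypes: dict[str, float] | None = None
    architecture: Architecture = Architecture.CIFAB

    def initial_state(self) -> GenotypeState:
        system = get_system(self.architecture)
        x = np.zeros(system.n)
        if self.release_genotypes is not None:
            for label, frac in self.release_genotypes.items():
                if frac < 0:
                    raise ValueError("released fractions must be nonnegative")
                x[system.index(label)] += frac
            if x.sum() > 1 + 1e-12:
                raise ValueError("released fractions must sum to <= 1")
            x[_wildtype_index(system)] += 1.0 - x.sum()
        else:
            I = self.introduction_frequency
            if not 0.0 <= I < 1.0:
                raise ValueError("introduction frequency must lie in [0, 1)")
            x[_drive_release_index(system)] = I
            x[_wildtype_index(system)] = 1.0 - I
        return GenotypeState(x, system)


def _wildtype_index(system: GenotypeSystem) -> int:
    return next(i for i, g in enumerate(system.genotypes) if g.n_cifA == 0 and g.n_cifB == 0 and g.n_cost == 0)


def _drive_release_index(system: GenotypeSystem) -> int:
    if system.architecture is Architecture.CIFAB:
        return system.index("dd")
    raise ValueError("default homozygote release is defined for CIFAB; use release_genotypes")


# ---------------------------------------------------------------------------
# birth / death and the ODE right-hand side
# ---------------------------------------------------------------------------

def birth_rate(N: float | np.ndarray, lam: float = 9.0):
    """Total birth rate ``N*lam/(N*(lam-1) + 1)``; equals 1 at capacity."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("population size must be nonnegative")
    return N * lam / (N * (lam - 1.0) + 1.0)


def death_rate(N: float | np.ndarray, lam: float = 9.0):
    """Density-dependent death rate ``N**2``."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("population size must be nonnegative")
    return N**2


class _OdeModel:
    """Precomputed arrays for one (params, system) pair; callable RHS."""

    def __init__(self, params: DriveParams, eco: EcologyParams, system: GenotypeSystem):
        self.system = system
        self.lam = eco.low_density_growth
        self.F = fitness_vector(params, system)
        self.fert = 1.0 - sterility_matrix(params, system).T  # [mother, father]
        self.O = offspring_tensor(system)
        # pair_tensor[i, j, k] = fert[i, j] * O[i, j, k]
        self.pair = self.fert[:, :, None] * self.O

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        x = np.maximum(x, 0.0)
        N = x.sum()
        bw = np.einsum("i,j,ijk->k", x, x, self.pair)
        return self.F * bw * self.lam / ((self.lam - 1.0) * N + 1.0) - x * N


def ode_rhs(
    state: GenotypeState | np.ndarray,
    params: DriveParams,
    eco: EcologyParams = EcologyParams(),
    system: GenotypeSystem | None = None,
) -> np.ndarray:
    """Per-genotype time derivatives of the 1-deme continuous model.

    ``dx_g/dt = F_g * birthweight_g * lam/((lam-1)N + 1) - x_g * N`` with
    birth weights taken directly as abundance products (the genotype-level
    generalization of ``b - d``).
    """
    if isinstance(state, GenotypeState):
        system = state.system
        x = state.x
    else:
        if system is None:
            raise TypeError("system required when state is a bare array")
        x = np.asarray(state, dtype=float)
    return _OdeModel(params, eco, system).rhs(0.0, x)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time series of genotype abundances with derived frequency series."""

    times: np.ndarray
    states: np.ndarray  # shape (T, n_genotypes)
    system: GenotypeSystem

    @property
    def N(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def allele_frequency(self, allele: str = "d") -> np.ndarray:
        counts = _allele_count_vector(self.system, allele)
        N = self.N
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (self.states @ counts) / (2.0 * N)
        return np.where(N > 0, f, 0.0)

    def carrier_frequency(self, gene: str = "cifA") -> np.ndarray:
        mask = carrier_mask(self.system, gene)
        N = self.N
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.states[:, mask].sum(axis=1) / N
        return np.where(N > 0, f, 0.0)

    def final_state(self) -> GenotypeState:
        return GenotypeState(self.states[-1], self.system)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.system.labels())
        df.insert(0, "time", self.times)
        df["N"] = self.N
        if self.system.architecture is Architecture.CIFAB:
            df["allele_frequency"] = self.allele_frequency("d")
            df["carrier_frequency"] = self.carrier_frequency("cifA")
        else:
            df["cifA_allele_frequency"] = self.allele_frequency("a")
            df["cifB_allele_frequency"] = self.allele_frequency("b")
            df["cifA_carrier_frequency"] = self.carrier_frequency("cifA")
            df["cifB_carrier_frequency"] = self.carrier_frequency("cifB")
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def integrate(
    release: ReleaseSpec | GenotypeState,
    params: DriveParams,
    eco: EcologyParams = EcologyParams(),
    t_end: float = 1000.0,
    samples_per_generation: int = 10,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the 1-deme continuous model over ``[0, t_end]``.

    Sampling defaults to 10 points per generation so that time-integral
    metrics converge under trapezoidal quadrature.
    """
    state = release.initial_state() if isinstance(release, ReleaseSpec) else release
    model = _OdeModel(params, eco, state.system)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, int(round(t_end * samples_per_generation)) + 1)
    sol = solve_ivp(
        model.rhs, (0.0, t_end), state.x, method="LSODA",
        t_eval=t_eval, rtol=RTOL, atol=ATOL,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE solver failed: {sol.message} (params={params})")
    return Trajectory(sol.t, np.maximum(sol.y.T, 0.0), state.system)


@dataclass
class TrajectoryMetrics:
    """Summary metrics of a panmictic trajectory (CIFAB conventions)."""

    average_allele_frequency: float
    average_carrier_frequency: float
    equilibrium_allele_frequency: float
    equilibrium_carrier_frequency: float
    first_generation_carrier_70: float | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def trajectory_metrics(traj: Trajectory, window: float = 100.0, allele: str = "d") -> TrajectoryMetrics:
    """Integral-average frequencies over the first ``window`` generations,
    end-of-run (equilibrium) frequencies, and the first generation at which
    carrier frequency reaches 70%.

    Averages divide the time integral of absolute drive-allele (or carrier)
    numbers by the time integral of population size.
    """
    if traj.times[-1] < window:
        raise ValueError(f"trajectory must span at least {window} generations")
    in_win = traj.times <= window
    t = traj.times[in_win]
    counts = _allele_count_vector(traj.system, allele) / 2.0
    alleles = traj.states[in_win] @ counts
    mask = carrier_mask(traj.system, "cifA")
    carriers = traj.states[in_win][:, mask].sum(axis=1)
    N = traj.N[in_win]
    int_N = np.trapezoid(N, t)
    avg_allele = float(np.trapezoid(alleles, t) / int_N)
    avg_carrier = float(np.trapezoid(carriers, t) / int_N)

    carrier = traj.carrier_frequency("cifA")
    crossing = np.nonzero(carrier >= 0.7)[0]
    first70 = float(traj.times[crossing[0]]) if crossing.size else None
    allele_f = traj.allele_frequency(allele)
    return TrajectoryMetrics(
        average_allele_frequency=avg_allele,
        average_carrier_frequency=avg_carrier,
        equilibrium_allele_frequency=float(allele_f[-1]),
        equilibrium_carrier_frequency=float(carrier[-1]),
        first_generation_carrier_70=first70,
    )


# ---------------------------------------------------------------------------
# threshold searches
# ---------------------------------------------------------------------------

def _establishes(I: float, params: DriveParams, eco: EcologyParams, t_end: float) -> bool:
    state = ReleaseSpec(I).initial_state()
    model = _OdeModel(params, eco, state.system)
    sol = solve_ivp(
        model.rhs, (0.0, t_end), state.x, method="LSODA",
        t_eval=[t_end], rtol=RTOL, atol=ATOL,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    x = np.maximum(sol.y[:, -1], 0.0)
    n = x.sum()
    return n > 0 and (x[0] + x[1]) / n > 0.7


def find_threshold(
    params: DriveParams,
    eco: EcologyParams = EcologyParams(),
    precision: float = 1e-5,
    t_end: float = 1000.0,
) -> float:
    """Introduction threshold of the continuous-generation model.

    Bisects the release frequency ``I`` on [0, 1]; success means drive
    carrier frequency above 70% at generation 1000 (by then the system has
    settled onto its equilibrium branch).  Returns 1.0 when no ``I < 1``
    establishes the drive.
    """
    hi = 1.0 - precision
    if not _establishes(hi, params, eco, t_end):
        return 1.0
    lo = 0.0
    hi_b = hi
    while hi_b - lo > precision:
        mid = 0.5 * (lo + hi_b)
        if _establishes(mid, params, eco, t_end):
            hi_b = mid
        else:
            lo = mid
    return 0.5 * (lo + hi_b)


# ---------------------------------------------------------------------------
# discrete-generation expectation map
# ---------------------------------------------------------------------------

class ExtinctionError(RuntimeError):
    """Raised when a discrete generation produces no offspring at all."""


def discrete_step(
    freq: np.ndarray,
    params: DriveParams,
    system: GenotypeSystem | None = None,
) -> np.ndarray:
    """One generation of the infinite-population limit of the IBM.

    Mothers contribute in proportion to their frequency times fitness
    (fecundity); fathers are sampled in proportion to frequency times
    fitness (mating success); a sterile pairing consumes the female's
    reproduction.  Density-dependent factors cancel in frequencies.
    """
    if system is None:
        system = get_system(Architecture.CIFAB)
    freq = np.asarray(freq, dtype=float)
    F = fitness_vector(params, system)
    fert = 1.0 - sterility_matrix(params, system).T  # [mother, father]
    O = offspring_tensor(system)
    wf = freq * F
    wm = freq * F
    tot_m = wm.sum()
    if tot_m <= 0:
        raise ExtinctionError("no reproducing males")
    wm = wm / tot_m
    mass = np.einsum("i,j,ij,ijk->k", wf, wm, fert, O)
    total = mass.sum()
    if total <= 0:
        raise ExtinctionError("all pairings sterile; population goes extinct")
    return mass / total


def iterate_discrete(
    freq0: np.ndarray,
    params: DriveParams,
    generations: int = 1000,
    system: GenotypeSystem | None = None,
) -> np.ndarray:
    """Iterate the discrete map; returns (generations+1, n) frequency array."""
    if system is None:
        system = get_system(Architecture.CIFAB)
    out = np.empty((generations + 1, system.n))
    out[0] = freq0
    f = np.asarray(freq0, dtype=float)
    for g in range(generations):
        try:
            f = discrete_step(f, params, system)
        except ExtinctionError:
            out[g + 1 :] = 0.0
            return out
        out[g + 1] = f
        # settle check: pure absorbing states stop changing
        if np.allclose(out[g], f, atol=1e-15):
            out[g + 1 :] = f
            break
    return out


def find_discrete_threshold(
    params: DriveParams | None = None,
    precision: float = 1e-5,
    generations: int = 1000,
) -> float:
    """Introduction threshold under the discrete-generation map (CIFAB)."""
    if params is None:
        params = DriveParams()
    system = get_system(Architecture.CIFAB)

    def success(I: float) -> bool:
        f = iterate_discrete(np.array([I, 0.0, 1.0 - I]), params, generations, system)[-1]
        return f[0] + f[1] > 0.7

    hi = 1.0 - precision
    if not success(hi):
        return 1.0
    lo = 0.0
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if success(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# two demes and continuous influx
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoDemeConfig:
    """Two panmictic demes coupled by reciprocal migration at rate ``m``.

    Following the model's formulation, migration exchanges per-genotype
    *growth rates*: ``dn1/dt = (1-m) g1 + m g2`` (``migrate_growth=True``).
    Standard density migration ``dn1/dt = g1 + m (n2 - n1)`` is available
    as the alternative.
    """

    migration_rate: float = 0.01
    release_deme1: ReleaseSpec = field(default_factory=lambda: ReleaseSpec(0.6))
    release_deme2: ReleaseSpec = field(default_factory=lambda: ReleaseSpec(0.0))
    migrate_growth: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.migration_rate <= 0.5:
            raise ValueError("migration rate must lie in [0, 0.5]")


def two_deme_integrate(
    cfg: TwoDemeConfig,
    params: DriveParams,
    eco: EcologyParams = EcologyParams(),
    t_end: float = 1000.0,
    samples_per_generation: int = 10,
) -> tuple[Trajectory, Trajectory]:
    s1 = cfg.release_deme1.initial_state()
    s2 = cfg.release_deme2.initial_state()
    system = s1.system
    model = _OdeModel(params, eco, system)
    n = system.n
    m = cfg.migration_rate

    if cfg.migrate_growth:
        def rhs(t, y):
            g1 = model.rhs(t, y[:n])
            g2 = model.rhs(t, y[n:])
            return np.concatenate([(1 - m) * g1 + m * g2, (1 - m) * g2 + m * g1])
    else:
        def rhs(t, y):
            x1, x2 = y[:n], y[n:]
            g1 = model.rhs(t, x1)
            g2 = model.rhs(t, x2)
            return np.concatenate([g1 + m * (x2 - x1), g2 + m * (x1 - x2)])

    t_eval = np.linspace(0.0, t_end, int(round(t_end * samples_per_generation)) + 1)
    sol = solve_ivp(rhs, (0.0, t_end), np.concatenate([s1.x, s2.x]),
                    method="LSODA", t_eval=t_eval, rtol=RTOL, atol=ATOL)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    y = np.maximum(sol.y.T, 0.0)
    return (Trajectory(sol.t, y[:, :n], system), Trajectory(sol.t, y[:, n:], system))


@dataclass(frozen=True)
class InfluxConfig:
    """Continuous influx of drive homozygotes into a single deme.

    ``phi`` is the per-generation influx expressed, by default, as a
    fraction of the *current* total population (source term ``phi * N`` on
    the drive-homozygote equation); set ``relative_to_capacity`` for a
    constant source ``phi * K``.
    """

    phi: float = 0.0
    relative_to_capacity: bool = False

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("influx must be nonnegative")


def influx_integrate(
    cfg: InfluxConfig,
    params: DriveParams,
    eco: EcologyParams = EcologyParams(),
    t_end: float = 1000.0,
    samples_per_generation: int = 10,
    release: ReleaseSpec | None = None,
) -> Trajectory:
    state = (release or ReleaseSpec(0.0)).initial_state()
    system = state.system
    model = _OdeModel(params, eco, system)
    i_dd = system.index("dd")

    def rhs(t, x):
        dx = model.rhs(t, x)
        src = cfg.phi if cfg.relative_to_capacity else cfg.phi * max(x.sum(), 0.0)
        dx[i_dd] += src
        return dx

    t_eval = np.linspace(0.0, t_end, int(round(t_end * samples_per_generation)) + 1)
    sol = solve_ivp(rhs, (0.0, t_end), state.x, method="LSODA",
                    t_eval=t_eval, rtol=RTOL, atol=ATOL)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return Trajectory(sol.t, np.maximum(sol.y.T, 0.0), system)


def find_critical_influx(
    params: DriveParams,
    eco: EcologyParams = EcologyParams(),
    precision: float = 1e-4,
    t_end: float = 1000.0,
    phi_max: float = 0.5,
) -> float:
    """Minimum continuous influx whose trajectory passes 70% carriers by
    generation 1000 (bisection on ``phi``)."""

    def success(phi: float) -> bool:
        traj = influx_integrate(InfluxConfig(phi), params, eco, t_end,
                                samples_per_generation=1)
        return bool(traj.carrier_frequency("cifA")[-1] > 0.7)

    lo, hi = 0.0, phi_max
    if not success(hi):
        raise RuntimeError(f"no influx below {phi_max} establishes the drive")
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if success(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def reproduction_success(x_wt: float, x_carrier: float) -> tuple[float, float]:
    """Reproduction success probabilities (wild-type, drive carriers).

    With a 1:1 sex ratio, a wild-type individual reproduces unless it is a
    female paired with a carrier male, and a carrier reproduces unless it
    is a male paired with a wild-type female; hence
    ``wt = (x_wt/(x_wt + x_c) + 1)/2`` and ``c = (x_c/(x_wt + x_c) + 1)/2``.
    """
    tot = x_wt + x_carrier
    if tot <= 0:
        raise ValueError("population must be nonempty")
    return (0.5 * (x_wt / tot + 1.0), 0.5 * (x_carrier / tot + 1.0))
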