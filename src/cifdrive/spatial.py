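"""Continuous-space deterministic model of the CifAB drive.

The 2D reaction-diffusion system on the unit arena is reduced to its two
symmetric forms: a 1D slab (for wave-of-advance measurements, initialized
with the left 30% of the arena as drive homozygotes) and a radially
symmetric form (for central circular releases, maximum radius 0.5).  The
reaction terms at every grid point are exactly the panmictic genotype
equations; diffusion uses ``D = v**2 / 2`` where ``v`` is the per-axis
standard deviation of parent-offspring displacement.

Boundaries are zero-flux (reflecting); the ``(1/r) du/dr`` polar term is
replaced by its symmetric limit ``d2u/dr2`` at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .genetics import Architecture, DriveParams, get_system
from .panmictic import EcologyParams, _OdeModel

__all__ = [
    "ReleaseMode",
    "ExpansionCriterion",
    "SlabRelease",
    "UniformCircle",
    "LinearRadial",
    "RingRelease",
    "SpaceTimeField",
    "NO_WAVE",
    "integrate_slab",
    "wave_speed",
    "wave_formation_boundary",
    "integrate_radial",
    "arena_carrier_frequency",
    "is_expanding",
    "CriticalReleaseResult",
    "critical_radius_uniform",
    "critical_size_linear",
    "critical_density_ring",
    "optimize_release",
    "integrate_cartesian_2d",
]

#: sentinel returned when no advancing wave forms within the horizon
NO_WAVE = float("nan")

PDE_RTOL = 1e-6
PDE_ATOL = 1e-9


class ReleaseMode(str, Enum):
    #: drive homozygotes added on top of wild-type at carrying density
    ADDITIVE = "additive"
    #: total density kept at carrying density inside the release area
    REPLACEMENT = "replacement"


class ExpansionCriterion(str, Enum):
    #: arena carrier frequency at generation 15 exceeds that at generation 10
    EXPANSION_10_15 = "expansion-10-15"
    #: arena carrier frequency exceeds 70% within 200 generations
    ESTABLISHMENT = "establishment"


@dataclass(frozen=True)
class SlabRelease:
    """Left ``fraction`` of the arena all drive homozygotes at carrying density."""

    fraction: float = 0.3


@dataclass(frozen=True)
class UniformCircle:
    """Central circular release at introduction frequency ``I``.

    In ADDITIVE mode the drive density inside the radius is ``I/(1-I)`` on
    top of wild-type at carrying density; in REPLACEMENT mode total density
    stays at carrying density (``dd = I``, ``ww = 1 - I``).
    """

    radius: float
    frequency: float = 0.8
    mode: ReleaseMode = ReleaseMode.ADDITIVE

    def profile(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        inside = r <= self.radius
        I = self.frequency
        if self.mode is ReleaseMode.ADDITIVE:
            dd = np.where(inside, I / (1.0 - I), 0.0)
            ww = np.ones_like(r)
        else:
            dd = np.where(inside, I, 0.0)
            ww = np.where(inside, 1.0 - I, 1.0)
        return dd, ww

    @property
    def release_size(self) -> float:
        """Released drive individuals relative to unit-area carrying capacity."""
        return float(np.pi * self.radius**2 * self.frequency / (1.0 - self.frequency))


@dataclass(frozen=True)
class LinearRadial:
    """Additive release with drive density ``k*r + b`` inside radius ``R``."""

    k: float
    b: float
    radius: float

    def profile(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dd = np.where(r <= self.radius, np.maximum(self.k * r + self.b, 0.0), 0.0)
        return dd, np.ones_like(r)

    @property
    def release_size(self) -> float:
        R = self.radius
        return float(2.0 / 3.0 * np.pi * self.k * R**3 + np.pi * self.b * R**2)


@dataclass(frozen=True)
class RingRelease:
    """Additive ring release: drive density ``h`` for ``r0 <= r <= r0 + d``."""

    r0: float
    width: float
    density: float

    def __post_init__(self) -> None:
        if self.density > 99.0:
            raise ValueError("ring release density is capped at h <= 99")
        if self.r0 + self.width > 0.5:
            raise ValueError("ring must fit inside the arena (max radius 0.5)")

    def profile(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        inside = (r >= self.r0) & (r <= self.r0 + self.width)
        return np.where(inside, self.density, 0.0), np.ones_like(r)

    @property
    def release_size(self) -> float:
        return float(self.density * np.pi * (2.0 * self.r0 * self.width + self.width**2))


@dataclass
class SpaceTimeField:
    """Method-of-lines solution: genotype densities over space and time."""

    times: np.ndarray
    positions: np.ndarray  # grid (x for slab, r for radial)
    fields: np.ndarray  # shape (T, n_genotypes, n_points)
    geometry: str  # "slab" or "radial"

    def N(self) -> np.ndarray:
        return self.fields.sum(axis=1)

    def carrier_frequency(self) -> np.ndarray:
        """Pointwise drive carrier frequency (x1 + x2) / N."""
        N = self.N()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (self.fields[:, 0] + self.fields[:, 1]) / N
        return np.where(N > 0, f, 0.0)

    def to_frame(self):
        import pandas as pd

        sys = get_system(Architecture.CIFAB)
        recs = []
        for it, t in enumerate(self.times):
            for ip, p in enumerate(self.positions):
                rec = {"time": t, "position": p}
                for ig, lab in enumerate(sys.labels()):
                    rec[lab] = self.fields[it, ig, ip]
                recs.append(rec)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def _slab_operator(nx: int, D: float) -> sparse.csr_matrix:
    dx = 1.0 / (nx - 1)
    main = np.full(nx, -2.0)
    off = np.ones(nx - 1)
    L = sparse.diags([off, main, off], [-1, 0, 1], format="lil")
    L[0, 1] = 2.0  # reflecting
    L[-1, -2] = 2.0
    return sparse.csr_matrix(L * (D / dx**2))


def _radial_operator(nr: int, D: float, r_max: float = 0.5) -> tuple[sparse.csr_matrix, np.ndarray]:
    r = np.linspace(0.0, r_max, nr)
    dr = r[1] - r[0]
    L = sparse.lil_matrix((nr, nr))
    for i in range(nr):
        if i == 0:
            # limit of u'' + u'/r at r=0 is 2 u''; symmetric ghost u[-1]=u[1]
            L[0, 0] = -4.0 / dr**2
            L[0, 1] = 4.0 / dr**2
        elif i == nr - 1:
            # reflecting outer boundary: u' = 0, so the u'/r term vanishes
            L[i, i] = -2.0 / dr**2
            L[i, i - 1] = 2.0 / dr**2
        else:
            L[i, i - 1] = 1.0 / dr**2 - 1.0 / (2 * dr * r[i])
            L[i, i] = -2.0 / dr**2
            L[i, i + 1] = 1.0 / dr**2 + 1.0 / (2 * dr * r[i])
    return sparse.csr_matrix(D * L), r


class _PdeModel:
    """Reaction-diffusion RHS over a 1D grid with 3 CIFAB genotypes."""

    def __init__(self, operator: sparse.csr_matrix, params: DriveParams, eco: EcologyParams):
        self.L = operator
        self.npts = operator.shape[0]
        system = get_system(Architecture.CIFAB)
        self.ode = _OdeModel(params, eco, system)
        self.ng = system.n

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        u = np.maximum(y.reshape(self.ng, self.npts), 0.0)
        N = u.sum(axis=0)
        lam = self.ode.lam
        dens = lam / ((lam - 1.0) * N + 1.0)
        # birth weights at every grid point: einsum over genotype pair tensor
        bw = np.einsum("ip,jp,ijk->kp", u, u, self.ode.pair)
        react = self.ode.F[:, None] * bw * dens[None, :] - u * N[None, :]
        diff = (self.L @ u.T).T
        return (react + diff).ravel()

    def jac_sparsity(self) -> sparse.csr_matrix:
        tri = sparse.csr_matrix((self.L != 0).astype(float) + sparse.eye(self.npts))
        return sparse.kron(sparse.eye(self.ng), tri) + sparse.kron(
            np.ones((self.ng, self.ng)), sparse.eye(self.npts)
        )


def _solve(model: _PdeModel, y0: np.ndarray, t_end: float, t_eval=None, events=None):
    sol = solve_ivp(
        model.rhs, (0.0, t_end), y0.ravel(), method="BDF",
        t_eval=t_eval, events=events,
        rtol=PDE_RTOL, atol=PDE_ATOL, jac_sparsity=model.jac_sparsity(),
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"PDE solver failed: {sol.message}")
    return sol


# ---------------------------------------------------------------------------
# slab model and wave speed
# ---------------------------------------------------------------------------

def integrate_slab(
    params: DriveParams,
    dispersion: float = 0.05,
    t_end: float = 100.0,
    nx: int = 512,
    release: SlabRelease = SlabRelease(),
    eco: EcologyParams = EcologyParams(),
    samples_per_generation: int = 2,
) -> SpaceTimeField:
    """Solve the 1D slab PDE: left fraction drive, remainder wild-type,
    all at carrying density."""
    D = dispersion**2 / 2.0
    model = _PdeModel(_slab_operator(nx, D), params, eco)
    x = np.linspace(0.0, 1.0, nx)
    u0 = np.zeros((3, nx))
    u0[0, x <= release.fraction] = 1.0
    u0[2, x > release.fraction] = 1.0
    t_eval = np.linspace(0.0, t_end, int(round(t_end * samples_per_generation)) + 1)
    sol = _solve(model, u0, t_end, t_eval=t_eval)
    fields = np.maximum(sol.y.T.reshape(-1, 3, nx), 0.0)
    return SpaceTimeField(sol.t, x, fields, "slab")


def wave_speed(
    params: DriveParams,
    dispersion: float = 0.05,
    t_end: float = 400.0,
    nx: int = 512,
    eco: EcologyParams = EcologyParams(),
    detection_points: tuple[float, float] = (0.5, 0.7),
    recession_point: float = 0.25,
) -> float:
    """Wave-of-advance speed from a left-30% slab release.

    The speed is ``(x2 - x1) / (t2 - t1)`` where ``t1``, ``t2`` are the
    first times pointwise carrier frequency reaches 50% at the two
    detection points.  Returns ``NO_WAVE`` (NaN) when the second crossing
    never occurs; a run is abandoned early when the front recedes behind
    ``recession_point`` (inside the initial drive slab), which implies the
    wave cannot advance.
    """
    D = dispersion**2 / 2.0
    model = _PdeModel(_slab_operator(nx, D), params, eco)
    x = np.linspace(0.0, 1.0, nx)
    u0 = np.zeros((3, nx))
    u0[0, x <= 0.3] = 1.0
    u0[2, x > 0.3] = 1.0
    i1 = int(np.argmin(np.abs(x - detection_points[0])))
    i2 = int(np.argmin(np.abs(x - detection_points[1])))
    ir = int(np.argmin(np.abs(x - recession_point)))
    nx_ = nx

    def carrier_at(idx, y):
        u = y.reshape(3, nx_)
        N = u[:, idx].sum()
        return (u[0, idx] + u[1, idx]) / N - 0.5 if N > 0 else -0.5

    def ev1(t, y):
        return carrier_at(i1, y)

    def ev2(t, y):
        return carrier_at(i2, y)

    def recede(t, y):
        return carrier_at(ir, y)

    ev1.direction = 1.0
    ev2.direction = 1.0
    ev2.terminal = True
    recede.direction = -1.0
    recede.terminal = True
    sol = _solve(model, u0, t_end, t_eval=[t_end], events=[ev1, ev2, recede])
    t1s, t2s = sol.t_events[0], sol.t_events[1]
    if len(t1s) == 0 or len(t2s) == 0:
        return NO_WAVE
    t1, t2 = t1s[0], t2s[0]
    if t2 <= t1:
        return NO_WAVE
    return float((detection_points[1] - detection_points[0]) / (t2 - t1))


def wave_formation_boundary(
    values: np.ndarray,
    vary: str = "fitness",
    dispersion: float = 0.05,
    nx: int = 512,
    t_end: float = 400.0,
) -> float:
    """Smallest parameter value on ``values`` at which a slab wave forms.

    ``vary='fitness'`` scans drive homozygote fitness (perfect efficiency);
    ``vary='efficiency'`` scans joint toxin=antidote efficiency at F=1.
    Returns NaN when none of the scanned values forms a wave.  The scan
    walks upward and stops at the first wave, relying on monotonicity of
    wave formation in both parameters.
    """
    for val in np.sort(np.asarray(values, dtype=float)):
        if vary == "fitness":
            p = DriveParams(fitness=val)
        elif vary == "efficiency":
            p = DriveParams(toxin_efficiency=val, antidote_efficiency=val)
        else:
            raise ValueError("vary must be 'fitness' or 'efficiency'")
        if np.isfinite(wave_speed(p, dispersion, t_end=t_end, nx=nx)):
            return float(val)
    return NO_WAVE


# ---------------------------------------------------------------------------
# radial model
# ---------------------------------------------------------------------------

def integrate_radial(
    release,
    params: DriveParams,
    dispersion: float = 0.03,
    t_end: float = 20.0,
    nr: int = 400,
    eco: EcologyParams = EcologyParams(),
    t_eval: np.ndarray | None = None,
    events=None,
):
    """Solve the radially symmetric PDE for a circular release.

    ``release`` is any shape with a ``profile(r) -> (dd, ww)`` method.
    Returns ``(SpaceTimeField, sol)`` where ``sol`` carries event times.
    """
    D = dispersion**2 / 2.0
    L, r = _radial_operator(nr, D)
    model = _PdeModel(L, params, eco)
    dd, ww = release.profile(r)
    u0 = np.zeros((3, nr))
    u0[0] = dd
    u0[2] = ww
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, int(round(t_end)) + 1)
    sol = _solve(model, u0, t_end, t_eval=t_eval, events=events)
    y = np.asarray(sol.y)
    if y.size == 0:  # terminal event fired before the first requested sample
        fields = np.empty((0, 3, nr))
    else:
        fields = np.maximum(y.T.reshape(-1, 3, nr), 0.0)
    return SpaceTimeField(np.asarray(sol.t), r, fields, "radial"), sol


def arena_carrier_frequency(r: np.ndarray, u: np.ndarray) -> float:
    """Whole-arena carrier frequency by annulus-weighted quadrature.

    ``u`` has shape (3, nr): genotype densities over the radial grid.
    """
    w = 2.0 * np.pi * r
    carrier = np.trapezoid(w * (u[0] + u[1]), r)
    total = np.trapezoid(w * u.sum(axis=0), r)
    return float(carrier / total) if total > 0 else 0.0


def is_expanding(field: SpaceTimeField, t_a: float = 10.0, t_b: float = 15.0) -> bool:
    """True iff the arena carrier frequency at ``t_b`` exceeds that at ``t_a``."""
    ia = int(np.argmin(np.abs(field.times - t_a)))
    ib = int(np.argmin(np.abs(field.times - t_b)))
    fa = arena_carrier_frequency(field.positions, field.fields[ia])
    fb = arena_carrier_frequency(field.positions, field.fields[ib])
    return fb > fa


@dataclass
class CriticalReleaseResult:
    """Outcome of a critical release-size search."""

    shape: object
    critical_parameter: float  # radius R or ring density h
    release_size: float  # Vc relative to unit-area carrying capacity
    applicable: bool = True


def _release_succeeds(
    release,
    params: DriveParams,
    dispersion: float,
    criterion: ExpansionCriterion,
    nr: int,
    establish_t_end: float = 200.0,
) -> bool:
    if criterion is ExpansionCriterion.EXPANSION_10_15:
        field, _ = integrate_radial(
            release, params, dispersion, t_end=15.0, nr=nr, t_eval=[0.0, 10.0, 15.0]
        )
        return is_expanding(field, 10.0, 15.0)

    # establishment: arena carrier frequency exceeds 70% within the horizon
    def established(t, y):
        u = np.maximum(y.reshape(3, nr), 0.0)
        r = np.linspace(0.0, 0.5, nr)
        return arena_carrier_frequency(r, u) - 0.7

    established.terminal = True
    established.direction = 1.0
    field, sol = integrate_radial(
        release, params, dispersion, t_end=establish_t_end, nr=nr,
        t_eval=[establish_t_end], events=[established],
    )
    if len(sol.t_events[0]) > 0:
        return True
    # releases large enough to start above 70% never cross upward; judge by
    # the end state instead
    if sol.t[-1] >= establish_t_end:
        r = np.linspace(0.0, 0.5, nr)
        return arena_carrier_frequency(r, field.fields[-1]) > 0.7
    return False


def critical_radius_uniform(
    params: DriveParams | None = None,
    frequency: float = 0.8,
    dispersion: float = 0.03,
    criterion: ExpansionCriterion = ExpansionCriterion.ESTABLISHMENT,
    mode: ReleaseMode = ReleaseMode.ADDITIVE,
    nr: int = 400,
    precision: float = 2e-4,
) -> CriticalReleaseResult:
    """Bisect the minimal radius of a uniform circular release.

    The reported ``release_size`` is ``Vc = pi R^2 I/(1-I)``.
    """
    params = params or DriveParams()

    def ok(R: float) -> bool:
        rel = UniformCircle(R, frequency, mode)
        return _release_succeeds(rel, params, dispersion, criterion, nr)

    lo, hi = 0.0, 0.5
    if not ok(hi):
        return CriticalReleaseResult(UniformCircle(hi, frequency, mode), hi,
                                     UniformCircle(hi, frequency, mode).release_size, False)
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    R = 0.5 * (lo + hi)
    shape = UniformCircle(R, frequency, mode)
    return CriticalReleaseResult(shape, R, shape.release_size)


def critical_size_linear(
    k: float,
    b: float,
    params: DriveParams | None = None,
    dispersion: float = 0.03,
    nr: int = 400,
    precision: float = 2e-4,
    criterion: ExpansionCriterion = ExpansionCriterion.EXPANSION_10_15,
) -> CriticalReleaseResult:
    """Critical radius (then ``Vc``) of a linear radial release ``kr + b``."""
    params = params or DriveParams()

    def ok(R: float) -> bool:
        return _release_succeeds(LinearRadial(k, b, R), params, dispersion, criterion, nr)

    lo, hi = 0.0, 0.5
    if not ok(hi):
        return CriticalReleaseResult(LinearRadial(k, b, hi), hi,
                                     LinearRadial(k, b, hi).release_size, False)
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    R = 0.5 * (lo + hi)
    shape = LinearRadial(k, b, R)
    return CriticalReleaseResult(shape, R, shape.release_size)


def critical_density_ring(
    r0: float,
    width: float,
    params: DriveParams | None = None,
    dispersion: float = 0.03,
    nr: int = 400,
    precision: float = 1e-3,
    criterion: ExpansionCriterion = ExpansionCriterion.EXPANSION_10_15,
    h_max: float = 99.0,
) -> CriticalReleaseResult:
    """Critical drive density ``h`` of a ring release; NOT_APPLICABLE
    (``applicable=False``) when no ``h <= 99`` lets the drive expand."""
    params = params or DriveParams()

    def ok(h: float) -> bool:
        return _release_succeeds(RingRelease(r0, width, h), params, dispersion, criterion, nr)

    lo, hi = 0.0, h_max
    if not ok(hi):
        return CriticalReleaseResult(RingRelease(r0, width, hi), hi,
                                     RingRelease(r0, width, hi).release_size, False)
    while hi - lo > precision * h_max:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    h = 0.5 * (lo + hi)
    shape = RingRelease(r0, width, h)
    return CriticalReleaseResult(shape, h, shape.release_size)


def optimize_release(
    family: str,
    grid: dict[str, np.ndarray],
    params: DriveParams | None = None,
    dispersion: float = 0.03,
    nr: int = 400,
) -> CriticalReleaseResult:
    """Scan a parameter grid of a release family for the minimal ``Vc``.

    ``family`` is 'linear' (grid keys 'k', 'b') or 'ring' (keys 'r0', 'd').
    """
    best: CriticalReleaseResult | None = None
    if family == "linear":
        for k in grid["k"]:
            for b in grid["b"]:
                res = critical_size_linear(float(k), float(b), params, dispersion, nr=nr)
                if res.applicable and (best is None or res.release_size < best.release_size):
                    best = res
    elif family == "ring":
        for r0 in grid["r0"]:
            for d in grid["d"]:
                if r0 + d > 0.5:
                    continue
                res = critical_density_ring(float(r0), float(d), params, dispersion, nr=nr)
                if res.applicable and (best is None or res.release_size < best.release_size):
                    best = res
    else:
        raise ValueError("family must be 'linear' or 'ring'")
    if best is None:
        raise RuntimeError("no release in the scanned grid lets the drive expand")
    return best


# ---------------------------------------------------------------------------
# 2D Cartesian reference solver (used as an independent check of the
# radial reduction on symmetric inputs)
# ---------------------------------------------------------------------------

def integrate_cartesian_2d(
    release,
    params: DriveParams,
    dispersion: float = 0.03,
    t_end: float = 10.0,
    n: int = 64,
    eco: EcologyParams = EcologyParams(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full 2D solve of the reaction-diffusion system on an n x n grid.

    Returns ``(x_grid, y_grid, field)`` with field shape (3, n, n) at
    ``t_end``.  The release profile is applied as a function of the
    distance to the arena center.
    """
    D = dispersion**2 / 2.0
    h = 1.0 / (n - 1)
    ax = np.linspace(0.0, 1.0, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(X - 0.5, Y - 0.5)
    dd, ww = release.profile(r.ravel())

    L1 = _slab_operator(n, 1.0) * h**2  # unscaled tridiagonal
    I = sparse.eye(n)
    Lap = (sparse.kron(L1, I) + sparse.kron(I, L1)) * (D / h**2)
    system = get_system(Architecture.CIFAB)
    ode = _OdeModel(params, eco, system)
    npts = n * n

    def rhs(t, y):
        u = np.maximum(y.reshape(3, npts), 0.0)
        N = u.sum(axis=0)
        dens = ode.lam / ((ode.lam - 1.0) * N + 1.0)
        bw = np.einsum("ip,jp,ijk->kp", u, u, ode.pair)
        react = ode.F[:, None] * bw * dens[None, :] - u * N[None, :]
        diff = (Lap @ u.T).T
        return (react + diff).ravel()

    tri = sparse.csr_matrix((Lap != 0).astype(float) + sparse.eye(npts))
    spar = sparse.kron(sparse.eye(3), tri) + sparse.kron(np.ones((3, 3)), sparse.eye(npts))
    u0 = np.zeros((3, npts))
    u0[0] = dd
    u0[2] = ww
    sol = solve_ivp(rhs, (0.0, t_end), u0.ravel(), method="BDF", t_eval=[t_end],
                    rtol=PDE_RTOL, atol=PDE_ATOL, jac_sparsity=spar)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"2D solver failed: {sol.message}")
    field = np.maximum(sol.y[:, -1].reshape(3, n, n), 0.0)
    return ax, ax, field
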