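"""Individual-based stochastic simulator with discrete, non-overlapping
generations — panmictic and 2D spatial.

Reproduction rules (both modes): each female samples candidate mates
(uniformly in the panmictic model, from within the mating radius in the
spatial model) and accepts each with probability equal to his relative
fitness, giving up after 10 rejections.  A sterile pairing (cytoplasmic
incompatibility) consumes her reproduction for the generation.  Offspring
counts are Binomial(M = 50, p = 2*F*sigma/M) with the mother's fitness F
and a density-dependent factor sigma; offspring genotypes draw one allele
per parent per locus; sexes are uniform.

Density dependence: panmictic ``sigma = (lam+1)/(lam*N/K + 1)`` so females
average 2 offspring at capacity and about ``2*(lam+1)`` near zero density.
The spatial model replaces ``N/K`` with a local competition ratio
``ca/ce`` where ``ca`` sums the triangular kernel ``i(r) = 1 - r/rc`` over
neighbours within the competition radius and ``ce = K * pi * rc**2 / 3``
is its expectation at uniform carrying density ``K`` (individuals per unit
area on the 1 x 1 arena).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .genetics import (
    Architecture,
    DriveParams,
    GenotypeSystem,
    carrier_mask,
    fitness_vector,
    get_system,
    offspring_tensor,
    sterility_matrix,
)

__all__ = [
    "IBMConfig",
    "SpatialIBMConfig",
    "Population",
    "SimOutcome",
    "panmictic_generation",
    "run_panmictic",
    "establishment_rate",
    "spatial_generation",
    "run_spatial_wave",
    "circle_release_establishment",
]


@dataclass(frozen=True)
class IBMConfig:
    """Panmictic simulator configuration."""

    capacity: int = 1000
    low_density_growth: float = 9.0
    max_offspring: int = 50
    max_generations: int = 300
    #: carrier frequency defining stochastic establishment
    establishment_frequency: float = 0.99

    def __post_init__(self) -> None:
        if self.capacity < 2:
            raise ValueError("carrying capacity must be at least 2")
        if self.max_offspring < 1:
            raise ValueError("max offspring must be at least 1")


@dataclass(frozen=True)
class SpatialIBMConfig:
    """Spatial additions: mating radius (defaults to the dispersion factor)
    and competition radius."""

    dispersion: float = 0.05
    mating_radius: float | None = None
    competition_radius: float = 0.01

    @property
    def rm(self) -> float:
        return self.dispersion if self.mating_radius is None else self.mating_radius


@dataclass
class Population:
    """Arrays of individuals: genotype index, sex, and (optionally) position."""

    genotype: np.ndarray  # int index into system.genotypes
    female: np.ndarray  # bool
    system: GenotypeSystem
    position: np.ndarray | None = None  # (n, 2) in [0,1]^2

    @property
    def size(self) -> int:
        return int(self.genotype.size)

    def carrier_frequency(self, gene: str = "cifA") -> float:
        if self.size == 0:
            return 0.0
        mask = carrier_mask(self.system, gene)
        return float(mask[self.genotype].mean())

    def allele_frequency(self, allele: str = "d") -> float:
        if self.size == 0:
            return 0.0
        from .genetics import _allele_count_vector

        counts = _allele_count_vector(self.system, allele)
        return float(counts[self.genotype].mean() / 2.0)

    def genotype_frequencies(self) -> np.ndarray:
        if self.size == 0:
            return np.zeros(self.system.n)
        return np.bincount(self.genotype, minlength=self.system.n) / self.size


def initial_population(
    I: float,
    cfg: IBMConfig,
    rng: np.random.Generator,
    system: GenotypeSystem | None = None,
    positions: bool = False,
) -> Population:
    """K individuals, a fraction ``I`` of them drive homozygotes, random sex."""
    system = system or get_system(Architecture.CIFAB)
    n = cfg.capacity
    n_drive = int(round(I * n))
    genotype = np.full(n, system.index("ww"), dtype=np.int64)
    genotype[:n_drive] = system.index("dd")
    female = rng.random(n) < 0.5
    pos = rng.random((n, 2)) if positions else None
    return Population(genotype, female, system, pos)


# ---------------------------------------------------------------------------
# shared reproduction machinery
# ---------------------------------------------------------------------------

class _GenotypeTables:
    """Per-(params, system) lookup tables used by the samplers."""

    def __init__(self, params: DriveParams, system: GenotypeSystem):
        self.system = system
        self.fitness = fitness_vector(params, system)
        self.rel_fitness = self.fitness / self.fitness.max()
        self.fertile = 1.0 - sterility_matrix(params, system)  # [male, female]
        O = offspring_tensor(system)  # [mother, father, child]
        self.offspring_cdf = np.cumsum(O, axis=2)


def _choose_mates(
    female_g: np.ndarray,
    male_g: np.ndarray,
    tables: _GenotypeTables,
    rng: np.random.Generator,
    max_attempts: int = 10,
) -> np.ndarray:
    """Uniform candidate draws with fitness-based acceptance; -1 = unmated."""
    n_f, n_m = female_g.size, male_g.size
    mate = np.full(n_f, -1, dtype=np.int64)
    if n_m == 0:
        return mate
    pending = np.arange(n_f)
    for _ in range(max_attempts):
        cand = rng.integers(0, n_m, size=pending.size)
        accept = rng.random(pending.size) < tables.rel_fitness[male_g[cand]]
        mate[pending[accept]] = cand[accept]
        pending = pending[~accept]
        if pending.size == 0:
            break
    return mate


def _offspring_genotypes(
    mother_g: np.ndarray,
    father_g: np.ndarray,
    tables: _GenotypeTables,
    rng: np.random.Generator,
) -> np.ndarray:
    u = rng.random(mother_g.size)
    cdf = tables.offspring_cdf[mother_g, father_g]  # (n, n_genotypes)
    return (u[:, None] > cdf).sum(axis=1).astype(np.int64)


def _brood(
    mothers: np.ndarray,
    sigma: np.ndarray,
    tables: _GenotypeTables,
    cfg: IBMConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring counts per mother: Binomial(M, 2*F*sigma/M), p clamped to 1."""
    M = cfg.max_offspring
    p = 2.0 * tables.fitness[mothers] * sigma / M
    p = np.minimum(p, 1.0)
    return rng.binomial(M, p)


# ---------------------------------------------------------------------------
# panmictic model
# ---------------------------------------------------------------------------

def panmictic_generation(
    pop: Population,
    params: DriveParams,
    cfg: IBMConfig,
    rng: np.random.Generator,
    tables: _GenotypeTables | None = None,
) -> Population:
    """One discrete generation of the panmictic individual-based model."""
    tables = tables or _GenotypeTables(params, pop.system)
    females = pop.genotype[pop.female]
    males = pop.genotype[~pop.female]
    if females.size == 0 or males.size == 0:
        return Population(np.empty(0, np.int64), np.empty(0, bool), pop.system)

    mate = _choose_mates(females, males, tables, rng)
    mated = mate >= 0
    mg = females[mated]
    fg = males[mate[mated]]
    fertile = rng.random(mg.size) < tables.fertile[fg, mg]
    mg, fg = mg[fertile], fg[fertile]

    lam = cfg.low_density_growth
    sigma = (lam + 1.0) / (lam * pop.size / cfg.capacity + 1.0)
    counts = _brood(mg, np.full(mg.size, sigma), tables, cfg, rng)

    mothers = np.repeat(mg, counts)
    fathers = np.repeat(fg, counts)
    child_g = _offspring_genotypes(mothers, fathers, tables, rng)
    child_f = rng.random(child_g.size) < 0.5
    return Population(child_g, child_f, pop.system)


@dataclass
class SimOutcome:
    """Result of one stochastic run."""

    established: bool
    generations: int
    final_size: int
    carrier_trace: np.ndarray = field(repr=False, default=None)


def run_panmictic(
    I: float,
    params: DriveParams,
    cfg: IBMConfig,
    rng: np.random.Generator,
) -> SimOutcome:
    """Run until establishment (carrier >= 99%), drive loss, or the
    300-generation cap."""
    system = get_system(Architecture.CIFAB)
    tables = _GenotypeTables(params, system)
    pop = initial_population(I, cfg, rng, system)
    trace = [pop.carrier_frequency()]
    for gen in range(1, cfg.max_generations + 1):
        pop = panmictic_generation(pop, params, cfg, rng, tables)
        c = pop.carrier_frequency()
        trace.append(c)
        if pop.size == 0 or c == 0.0:
            return SimOutcome(False, gen, pop.size, np.array(trace))
        if c >= cfg.establishment_frequency:
            return SimOutcome(True, gen, pop.size, np.array(trace))
    return SimOutcome(False, cfg.max_generations, pop.size, np.array(trace))


def establishment_rate(
    I: float,
    params: DriveParams,
    cfg: IBMConfig,
    replicates: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Fraction of replicates establishing, with its binomial standard error."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    ss = np.random.SeedSequence(seed)
    wins = 0
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        if run_panmictic(I, params, cfg, rng).established:
            wins += 1
    rate = wins / replicates
    se = float(np.sqrt(rate * (1.0 - rate) / replicates))
    return rate, se


# ---------------------------------------------------------------------------
# spatial model
# ---------------------------------------------------------------------------

def _competition_sigma(
    pos: np.ndarray,
    cfg: IBMConfig,
    sp: SpatialIBMConfig,
) -> np.ndarray:
    """Per-individual density factor from the local competition kernel."""
    rc = sp.competition_radius
    tree = cKDTree(pos)
    pairs = tree.query_pairs(rc, output_type="ndarray")
    ca = np.zeros(len(pos))
    if pairs.size:
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        w = 1.0 - d / rc
        np.add.at(ca, pairs[:, 0], w)
        np.add.at(ca, pairs[:, 1], w)
    ce = cfg.capacity * np.pi * rc**2 / 3.0
    lam = cfg.low_density_growth
    return (lam + 1.0) / (lam * ca / ce + 1.0)


def spatial_generation(
    pop: Population,
    params: DriveParams,
    cfg: IBMConfig,
    sp: SpatialIBMConfig,
    rng: np.random.Generator,
    tables: _GenotypeTables | None = None,
) -> Population:
    """One generation of the 2D spatial model.

    Mate choice is restricted to males within the mating radius; offspring
    are displaced from the mother by independent per-axis normal draws
    (s.d. = dispersion), redrawn until inside the arena.
    """
    tables = tables or _GenotypeTables(params, pop.system)
    fem = pop.female
    f_idx = np.nonzero(fem)[0]
    m_idx = np.nonzero(~fem)[0]
    if f_idx.size == 0 or m_idx.size == 0:
        return Population(np.empty(0, np.int64), np.empty(0, bool), pop.system,
                          np.empty((0, 2)))

    sigma = _competition_sigma(pop.position, cfg, sp)[f_idx]

    m_tree = cKDTree(pop.position[m_idx])
    neighbours = m_tree.query_ball_point(pop.position[f_idx], sp.rm)
    rel_fit = tables.rel_fitness
    mates = np.full(f_idx.size, -1, dtype=np.int64)
    for i, cand_local in enumerate(neighbours):
        if not cand_local:
            continue
        cands = rng.integers(0, len(cand_local), size=10)
        for c in cands:
            mi = m_idx[cand_local[c]]
            if rng.random() < rel_fit[pop.genotype[mi]]:
                mates[i] = mi
                break

    mated = mates >= 0
    mothers_i = f_idx[mated]
    fathers_i = mates[mated]
    mg = pop.genotype[mothers_i]
    fg = pop.genotype[fathers_i]
    fertile = rng.random(mg.size) < tables.fertile[fg, mg]
    mg, fg = mg[fertile], fg[fertile]
    mpos = pop.position[mothers_i][fertile]
    counts = _brood(mg, sigma[mated][fertile], tables, cfg, rng)

    mothers = np.repeat(mg, counts)
    fathers = np.repeat(fg, counts)
    origins = np.repeat(mpos, counts, axis=0)
    child_g = _offspring_genotypes(mothers, fathers, tables, rng)
    child_f = rng.random(child_g.size) < 0.5

    # dispersal: redraw displacements until the position is inside the arena
    child_pos = origins + rng.normal(0.0, sp.dispersion, size=origins.shape)
    bad = np.any((child_pos < 0.0) | (child_pos > 1.0), axis=1)
    while bad.any():
        child_pos[bad] = origins[bad] + rng.normal(
            0.0, sp.dispersion, size=(int(bad.sum()), 2)
        )
        bad = np.any((child_pos < 0.0) | (child_pos > 1.0), axis=1)
    return Population(child_g, child_f, pop.system, child_pos)


def run_spatial_wave(
    params: DriveParams,
    cfg: IBMConfig,
    sp: SpatialIBMConfig,
    rng: np.random.Generator,
    max_generations: int = 200,
    strips: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 0.55), (0.7, 0.75)),
) -> float:
    """Stochastic wave speed from a left-30% drive release.

    Carrier frequency is tracked per generation in two 0.05-wide strips;
    the speed is 0.2 / (t2 - t1) from the first generations each strip
    exceeds 50% carriers.  Returns NaN when the wave never arrives.
    """
    system = get_system(Architecture.CIFAB)
    tables = _GenotypeTables(params, system)
    pop = initial_population(0.0, cfg, rng, system, positions=True)
    pop.genotype[pop.position[:, 0] <= 0.3] = system.index("dd")
    mask_carr = carrier_mask(system, "cifA")
    t_cross = [None, None]
    for gen in range(1, max_generations + 1):
        pop = spatial_generation(pop, params, cfg, sp, rng, tables)
        if pop.size == 0:
            break
        x = pop.position[:, 0]
        carr = mask_carr[pop.genotype]
        for k, (lo, hi) in enumerate(strips):
            if t_cross[k] is None:
                sel = (x >= lo) & (x <= hi)
                if sel.any() and carr[sel].mean() > 0.5:
                    t_cross[k] = gen
        if t_cross[0] is not None and t_cross[1] is not None:
            ds = (strips[1][0] + strips[1][1]) / 2 - (strips[0][0] + strips[0][1]) / 2
            return float(ds / (t_cross[1] - t_cross[0]))
        # abandon once the drive is gone
        if not carr.any():
            break
    return float("nan")


def circle_release_establishment(
    radius: float,
    params: DriveParams,
    cfg: IBMConfig,
    sp: SpatialIBMConfig,
    replicates: int = 20,
    seed: int = 0,
    frequency: float = 0.8,
    max_generations: int = 300,
) -> tuple[float, float]:
    """Establishment rate of a central circular release (replacement mode:
    individuals inside the circle become drive homozygotes with
    probability ``frequency``)."""
    system = get_system(Architecture.CIFAB)
    tables = _GenotypeTables(params, system)
    mask_carr = carrier_mask(system, "cifA")
    ss = np.random.SeedSequence(seed)
    wins = 0
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        pop = initial_population(0.0, cfg, rng, system, positions=True)
        r = np.linalg.norm(pop.position - 0.5, axis=1)
        inside = (r <= radius) & (rng.random(pop.size) < frequency)
        pop.genotype[inside] = system.index("dd")
        for _ in range(max_generations):
            pop = spatial_generation(pop, params, cfg, sp, rng, tables)
            if pop.size == 0:
                break
            c = float(mask_carr[pop.genotype].mean())
            if c == 0.0:
                break
            if c >= cfg.establishment_frequency:
                wins += 1
                break
    rate = wins / replicates
    return rate, float(np.sqrt(rate * (1.0 - rate) / replicates))
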