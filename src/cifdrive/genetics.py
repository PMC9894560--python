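"""Genotype architectures and the cross engine for cifA/cifB toxin-antidote drives.

Cytoplasmic incompatibility (CI) is modeled as a paternal toxin with a
maternal antidote: a cross produces no viable offspring when the toxin
(carried by the father) takes effect and the antidote (maternal cifA
expression) does not.  Three drive architectures are supported:

* ``CIFAB`` -- cifA and cifB in one construct, a single biallelic locus
  with drive allele ``d`` and wild-type ``w``.  A ``d`` allele counts as
  both a cifA and a cifB copy.
* ``SL_ONE_LOCUS`` -- the self-limiting variant where cifA and cifB are
  separate alleles ``a`` and ``b`` sharing one locus with wild-type ``w``
  (6 unordered genotypes).
* ``SL_TWO_LOCUS`` -- cifA and cifB on two unlinked loci (alleles
  ``w1``/``a`` and ``w2``/``b``; 9 unordered genotypes).

Everything downstream (ODE, discrete map, PDE, individual-based model)
consumes the same small set of precomputed arrays: a fitness vector, a
cross-sterility matrix, and the Mendelian offspring tensor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np

__all__ = [
    "Architecture",
    "FitnessMode",
    "ToxinRule",
    "DriveParams",
    "Genotype",
    "GenotypeSystem",
    "GenotypeState",
    "genotype_fitness",
    "fitness_vector",
    "toxin_probability",
    "antidote_probability",
    "cross_sterility",
    "sterility_matrix",
    "mendelian_offspring",
    "offspring_tensor",
    "birth_weights",
]


class Architecture(str, Enum):
    CIFAB = "cifab"
    SL_ONE_LOCUS = "sl-one-locus"
    SL_TWO_LOCUS = "sl-two-locus"


class FitnessMode(str, Enum):
    MULTIPLICATIVE = "multiplicative"
    DOMINANCE = "dominance"


class ToxinRule(str, Enum):
    #: the male needs at least one cifA and one cifB copy for the toxin
    AB_REQUIRED = "ab-required"
    #: cifB alone suffices (as reported for Anopheles gambiae)
    B_SUFFICIENT = "b-sufficient"


@dataclass(frozen=True)
class DriveParams:
    """Drive-intrinsic parameters shared by every model.

    Parameters
    ----------
    fitness
        Relative fitness ``F`` of cost-bearing homozygotes (wild-type = 1).
        The cost attaches to the drive allele in CIFAB and to cifA in the
        self-limiting architectures.
    fitness_mode
        ``MULTIPLICATIVE``: heterozygote fitness ``sqrt(F)``.
        ``DOMINANCE``: heterozygote fitness ``1 - c*(1 - F)``.
    dominance
        Dominance coefficient ``c``; only used in ``DOMINANCE`` mode.
    toxin_efficiency, antidote_efficiency
        Per-allele probabilities ``Et`` and ``Ea`` that the toxin/antidote
        takes effect; efficiency reductions combine multiplicatively over
        allele copies.
    toxin_rule
        Which paternal genotypes produce the toxin in self-limiting
        architectures.  Irrelevant for CIFAB (``d`` carries both genes).
    """

    fitness: float = 1.0
    fitness_mode: FitnessMode = FitnessMode.MULTIPLICATIVE
    dominance: float = 0.5
    toxin_efficiency: float = 1.0
    antidote_efficiency: float = 1.0
    toxin_rule: ToxinRule = ToxinRule.AB_REQUIRED

    def __post_init__(self) -> None:
        for name in ("fitness", "dominance", "toxin_efficiency", "antidote_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class Genotype:
    """An unordered diploid genotype (parental origin is not tracked)."""

    label: str
    #: per-locus sorted allele pairs, e.g. (("d", "w"),) or (("a", "w1"), ("b", "b"))
    loci: tuple[tuple[str, str], ...]
    #: number of cifA-bearing allele copies (drive allele d counts)
    n_cifA: int
    #: number of cifB-bearing allele copies (drive allele d counts)
    n_cifB: int
    #: copies of the cost-bearing allele (d for CIFAB, a for self-limiting)
    n_cost: int

    def __str__(self) -> str:  # pragma: no cover
        return self.label


def _gametes(g: Genotype) -> list[tuple[tuple[str, ...], float]]:
    """Equiprobable gametes of ``g``: one allele per locus, independent loci."""
    per_locus = [tuple(set(pair)) for pair in g.loci]
    out: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*g.loci):
        out[combo] = out.get(combo, 0.0) + 1.0 / 2 ** len(g.loci)
    del per_locus
    return list(out.items())


class GenotypeSystem:
    """Enumeration of the diploid genotypes of one drive architecture.

    Provides index lookup by label and the precomputed Mendelian offspring
    tensor ``O[mother, father, child]``.
    """

    def __init__(self, architecture: Architecture):
        self.architecture = Architecture(architecture)
        self.genotypes: tuple[Genotype, ...] = _build_genotypes(self.architecture)
        self._index = {g.label: i for i, g in enumerate(self.genotypes)}
        self.n = len(self.genotypes)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.genotypes)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(
                f"unknown genotype {label!r} for architecture {self.architecture.value}"
            ) from None

    def genotype(self, label: str) -> Genotype:
        return self.genotypes[self.index(label)]

    def labels(self) -> list[str]:
        return [g.label for g in self.genotypes]

    def __contains__(self, g) -> bool:
        label = g.label if isinstance(g, Genotype) else g
        return label in self._index


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _build_genotypes(arch: Architecture) -> tuple[Genotype, ...]:
    if arch is Architecture.CIFAB:
        # ordered as x1 = dd, x2 = dw, x3 = ww
        defs = [("dd", ("d", "d")), ("dw", ("d", "w")), ("ww", ("w", "w"))]
        out = []
        for label, pair in defs:
            nd = pair.count("d")
            out.append(Genotype(label, (_canon_pair(*pair),), nd, nd, nd))
        return tuple(out)

    if arch is Architecture.SL_ONE_LOCUS:
        alleles = ("w", "a", "b")
        pairs = [
            _canon_pair(x, y)
            for x, y in itertools.combinations_with_replacement(alleles, 2)
        ]
        # conventional order: ww, wa, wb, aa, ab, bb
        order = ["ww", "aw", "bw", "aa", "ab", "bb"]
        labelled = {"".join(p): p for p in pairs}
        out = []
        for key in order:
            p = labelled[key]
            label = {"aw": "wa", "bw": "wb"}.get(key, key)
            out.append(
                Genotype(label, (p,), p.count("a"), p.count("b"), p.count("a"))
            )
        return tuple(out)

    if arch is Architecture.SL_TWO_LOCUS:
        locus1 = [("w1", "w1"), ("a", "w1"), ("a", "a")]
        locus2 = [("w2", "w2"), ("b", "w2"), ("b", "b")]
        out = []
        for p1 in locus1:
            for p2 in locus2:
                label = "".join(p1) + "/" + "".join(p2)
                out.append(
                    Genotype(
                        label,
                        (p1, p2),
                        p1.count("a"),
                        p2.count("b"),
                        p1.count("a"),
                    )
                )
        return tuple(out)

    raise ValueError(f"unknown architecture {arch!r}")


@lru_cache(maxsize=None)
def _system_cache(arch: Architecture) -> GenotypeSystem:
    return GenotypeSystem(arch)


def get_system(architecture: Architecture | str) -> GenotypeSystem:
    """Shared (cached) GenotypeSystem instance for an architecture."""
    return _system_cache(Architecture(architecture))


@dataclass
class GenotypeState:
    """Per-genotype abundances relative to carrying capacity."""

    x: np.ndarray
    system: GenotypeSystem

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (self.system.n,):
            raise ValueError(
                f"state length {self.x.shape} does not match the "
                f"{self.system.n} genotypes of {self.system.architecture.value}"
            )
        if np.any(self.x < 0):
            raise ValueError("genotype abundances must be nonnegative")

    @property
    def N(self) -> float:
        return float(self.x.sum())

    def allele_frequency(self, allele: str = "d") -> float:
        """Frequency of ``allele`` at its locus (0 when the population is empty)."""
        counts = _allele_count_vector(self.system, allele)
        n = self.N
        return float(self.x @ counts / (2 * n)) if n > 0 else 0.0

    def carrier_frequency(self, gene: str = "cifA") -> float:
        """Fraction of individuals carrying >= 1 copy of ``gene`` (cifA/cifB/drive)."""
        mask = carrier_mask(self.system, gene)
        n = self.N
        return float(self.x[mask].sum() / n) if n > 0 else 0.0


@lru_cache(maxsize=None)
def _allele_count_cache(arch: Architecture, allele: str) -> tuple[int, ...]:
    system = get_system(arch)
    return tuple(
        sum(pair.count(allele) for pair in g.loci) for g in system.genotypes
    )


def _allele_count_vector(system: GenotypeSystem, allele: str) -> np.ndarray:
    return np.array(_allele_count_cache(system.architecture, allele), dtype=float)


@lru_cache(maxsize=None)
def _carrier_mask_cache(arch: Architecture, gene: str) -> tuple[bool, ...]:
    system = get_system(arch)
    if gene in ("cifA", "drive", "d"):
        return tuple(g.n_cifA >= 1 for g in system.genotypes)
    if gene == "cifB":
        return tuple(g.n_cifB >= 1 for g in system.genotypes)
    raise ValueError(f"unknown gene {gene!r}; expected 'cifA', 'cifB' or 'drive'")


def carrier_mask(system: GenotypeSystem, gene: str = "cifA") -> np.ndarray:
    """Boolean mask over genotypes carrying >= 1 copy of the given gene."""
    return np.array(_carrier_mask_cache(system.architecture, gene))


# ---------------------------------------------------------------------------
# fitness, toxin, antidote
# ---------------------------------------------------------------------------

def genotype_fitness(g: Genotype | str, params: DriveParams, system: GenotypeSystem) -> float:
    """Viability/fecundity multiplier of a genotype (wild type = 1).

    The cost attaches to the drive allele (CIFAB) or to cifA copies only
    (self-limiting architectures); cifB carries no cost.
    """
    if isinstance(g, str):
        g = system.genotype(g)
    elif g.label not in system:
        raise KeyError(f"genotype {g.label!r} not in system")
    n = g.n_cost
    if n == 0:
        return 1.0
    if n == 2:
        return params.fitness
    if params.fitness_mode is FitnessMode.MULTIPLICATIVE:
        return float(np.sqrt(params.fitness))
    return 1.0 - params.dominance * (1.0 - params.fitness)


def toxin_probability(male_g: Genotype | str, params: DriveParams, system: GenotypeSystem) -> float:
    """Probability the paternal toxin takes effect in this male's offspring.

    Per-allele multiplicative efficiency: ``1 - (1 - Et)**n`` where ``n``
    counts the male's toxin-competent allele copies.  Under AB_REQUIRED a
    copy is toxin-competent only when matched by a cifA copy
    (``n = min(n_cifA, n_cifB)``); under B_SUFFICIENT ``n = n_cifB``.
    """
    if isinstance(male_g, str):
        male_g = system.genotype(male_g)
    et = params.toxin_efficiency
    if system.architecture is Architecture.CIFAB:
        n = male_g.n_cifB
    elif params.toxin_rule is ToxinRule.AB_REQUIRED:
        n = min(male_g.n_cifA, male_g.n_cifB)
    else:
        n = male_g.n_cifB
    return 1.0 - (1.0 - et) ** n if n else 0.0


def antidote_probability(female_g: Genotype | str, params: DriveParams, system: GenotypeSystem) -> float:
    """Probability the maternal antidote rescues: ``1 - (1 - Ea)**n_cifA``."""
    if isinstance(female_g, str):
        female_g = system.genotype(female_g)
    n = female_g.n_cifA
    return 1.0 - (1.0 - params.antidote_efficiency) ** n if n else 0.0


def cross_sterility(
    male_g: Genotype | str, female_g: Genotype | str, params: DriveParams, system: GenotypeSystem
) -> float:
    """Probability that a (male, female) pairing yields no viable offspring."""
    return toxin_probability(male_g, params, system) * (
        1.0 - antidote_probability(female_g, params, system)
    )


def fitness_vector(params: DriveParams, system: GenotypeSystem) -> np.ndarray:
    return np.array([genotype_fitness(g, params, system) for g in system.genotypes])


def sterility_matrix(params: DriveParams, system: GenotypeSystem) -> np.ndarray:
    """``S[male, female]`` = probability the cross produces no offspring."""
    tox = np.array([toxin_probability(g, params, system) for g in system.genotypes])
    anti = np.array([antidote_probability(g, params, system) for g in system.genotypes])
    return np.outer(tox, 1.0 - anti)


# ---------------------------------------------------------------------------
# Mendelian inheritance
# ---------------------------------------------------------------------------

def mendelian_offspring(
    male_g: Genotype | str, female_g: Genotype | str, system: GenotypeSystem
) -> dict[str, float]:
    """Offspring genotype distribution: one random allele per parent per locus."""
    if isinstance(male_g, str):
        male_g = system.genotype(male_g)
    if isinstance(female_g, str):
        female_g = system.genotype(female_g)
    out: dict[str, float] = {}
    for gam_m, p_m in _gametes(male_g):
        for gam_f, p_f in _gametes(female_g):
            loci = tuple(_canon_pair(a, b) for a, b in zip(gam_m, gam_f))
            label = _label_for(loci, system)
            out[label] = out.get(label, 0.0) + p_m * p_f
    return out


def _label_for(loci: tuple[tuple[str, str], ...], system: GenotypeSystem) -> str:
    for g in system.genotypes:
        if g.loci == loci:
            return g.label
    raise KeyError(f"no genotype with loci {loci}")


@lru_cache(maxsize=None)
def _offspring_tensor_cache(arch: Architecture) -> np.ndarray:
    system = get_system(arch)
    n = system.n
    O = np.zeros((n, n, n))
    for i, mother in enumerate(system.genotypes):
        for j, father in enumerate(system.genotypes):
            for label, p in mendelian_offspring(father, mother, system).items():
                O[i, j, system.index(label)] = p
    O.setflags(write=False)
    return O


def offspring_tensor(system: GenotypeSystem) -> np.ndarray:
    """``O[mother, father, child]`` = P(child genotype | parents)."""
    return _offspring_tensor_cache(system.architecture)


# ---------------------------------------------------------------------------
# birth weights (the "sum over combinations" of the dynamic models)
# ---------------------------------------------------------------------------

def birth_weights(
    x: np.ndarray | GenotypeState,
    params: DriveParams,
    system: GenotypeSystem | None = None,
) -> np.ndarray:
    """Per-offspring-genotype reproductive weight of a population state.

    For each offspring genotype ``k`` this sums, over ordered parental
    pairs (mother ``i``, father ``j``), the product of the parents'
    abundances, the pair fertility ``1 - cross_sterility``, and the
    Mendelian probability of producing ``k``.  Abundance products are used
    directly (no normalization); density dependence enters downstream.
    """
    if isinstance(x, GenotypeState):
        system = x.system
        x = x.x
    if system is None:
        raise TypeError("system required when x is a bare array")
    x = np.asarray(x, dtype=float)
    fert = 1.0 - sterility_matrix(params, system).T  # [mother, father]
    O = offspring_tensor(system)
    return np.einsum("i,j,ij,ijk->k", x, x, fert, O)


def cifab_polynomial_birth_weights(x: np.ndarray, params: DriveParams) -> np.ndarray:
    """CIFAB birth weights from the closed-form genotype polynomials.

    Kept as an independent regression check on the generic pair
    enumeration; not used by any model.
    """
    x1, x2, x3 = np.asarray(x, dtype=float)
    et, ea = params.toxin_efficiency, params.antidote_efficiency
    t2 = 1.0 - (1.0 - et) ** 2  # homozygote toxin probability
    dd = (
        x1**2 * (1 - t2 * (1 - ea) ** 2)
        + 0.25 * x2**2 * (1 - et * (1 - ea))
        + 0.5 * x1 * x2 * (2 - t2 * (1 - ea) - et * (1 - ea) ** 2)
    )
    wd = (
        0.5 * x2**2 * (1 - et * (1 - ea))
        + 0.5 * x2 * x3 * (2 - et)
        + x1 * x3 * (2 - t2)
        + 0.5 * x1 * x2 * (2 - et * (1 - ea) ** 2 - t2 * (1 - ea))
    )
    ww = x3**2 + 0.5 * x2 * x3 * (2 - et) + 0.25 * x2**2 * (1 - et * (1 - ea))
    return np.array([dd, wd, ww])
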