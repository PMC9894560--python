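"""Deterministic panmictic dynamics: birth/death rates, ODE behavior,
trajectory metrics, threshold searches, two demes, and influx."""

import numpy as np
import pytest

from cifdrive.genetics import DriveParams, GenotypeState, get_system
from cifdrive.panmictic import (
    EcologyParams,
    InfluxConfig,
    ReleaseSpec,
    TwoDemeConfig,
    birth_rate,
    death_rate,
    discrete_step,
    find_threshold,
    influx_integrate,
    integrate,
    iterate_discrete,
    ode_rhs,
    reproduction_success,
    trajectory_metrics,
    two_deme_integrate,
)

CIFAB = get_system("cifab")
IDEAL = DriveParams()  # F = 1, Et = Ea = 1


class TestBirthDeath:
    def test_equilibrium_at_capacity(self):
        assert birth_rate(1.0, 9.0) == pytest.approx(1.0)
        assert death_rate(1.0) == pytest.approx(1.0)

    def test_low_density_per_capita_growth_is_lambda(self):
        N = 1e-8
        assert birth_rate(N, 9.0) / N == pytest.approx(9.0, rel=1e-6)

    def test_half_capacity_values(self):
        assert birth_rate(0.5, 9.0) == pytest.approx(0.9)
        assert death_rate(0.5) == pytest.approx(0.25)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            birth_rate(-0.1)


class TestOdeRhs:
    def test_wildtype_equilibrium(self):
        state = GenotypeState(np.array([0.0, 0.0, 1.0]), CIFAB)
        assert ode_rhs(state, IDEAL) == pytest.approx([0.0, 0.0, 0.0], abs=1e-14)

    def test_neutral_drive_total_is_zero_at_capacity(self):
        p = DriveParams(toxin_efficiency=0.0)
        state = GenotypeState(np.array([0.3, 0.3, 0.4]), CIFAB)
        assert ode_rhs(state, p).sum() == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_derivative(self):
        # half drive homozygote, half wild-type, ideal drive: all mixed
        # pairings sterile, so d(ww)/dt = 0.25*lambda/lambda - 0.5 = -0.25
        state = GenotypeState(np.array([0.5, 0.0, 0.5]), CIFAB)
        dx = ode_rhs(state, IDEAL)
        assert dx[2] == pytest.approx(-0.25)
        assert dx[0] == pytest.approx(-0.25)
        # dd mothers x ww fathers are fertile (no paternal toxin) and
        # produce heterozygotes
        assert dx[1] == pytest.approx(0.25)


class TestIntegrate:
    def test_no_release_stays_wildtype(self):
        traj = integrate(ReleaseSpec(0.0), IDEAL, t_end=100, samples_per_generation=1)
        assert traj.carrier_frequency().max() == 0.0
        assert traj.N[-1] == pytest.approx(1.0, abs=1e-6)

    def test_population_recovers_to_capacity_without_drive(self):
        state = GenotypeState(np.array([0.0, 0.0, 0.05]), CIFAB)
        traj = integrate(state, IDEAL, t_end=50, samples_per_generation=2)
        assert traj.N[-1] == pytest.approx(1.0, abs=1e-6)

    def test_release_just_above_threshold_fixes(self):
        traj = integrate(ReleaseSpec(0.3606), IDEAL, samples_per_generation=1)
        assert traj.carrier_frequency()[-1] > 0.99

    def test_release_just_below_threshold_lost(self):
        traj = integrate(ReleaseSpec(0.3604), IDEAL, samples_per_generation=1)
        assert traj.carrier_frequency()[-1] < 0.01

    def test_near_threshold_trajectories_pass_near_half_carriers(self):
        """The unstable equilibrium sits at 50% carriers: both sides of
        the threshold approach it before departing."""
        lo = integrate(ReleaseSpec(0.3605), IDEAL, t_end=200, samples_per_generation=2)
        hi = integrate(ReleaseSpec(0.36051), IDEAL, t_end=200, samples_per_generation=2)
        assert np.abs(lo.carrier_frequency() - 0.5).min() < 0.01
        assert np.abs(hi.carrier_frequency() - 0.5).min() < 0.01

    def test_initial_allele_dip_after_homozygote_release(self):
        traj = integrate(ReleaseSpec(0.4), IDEAL, t_end=100, samples_per_generation=10)
        a = traj.allele_frequency("d")
        assert a[1 : 5 * 10].min() < a[0]


class TestMetrics:
    def test_full_release(self):
        traj = integrate(ReleaseSpec(release_genotypes={"dd": 1.0}), IDEAL,
                         t_end=1000, samples_per_generation=1)
        m = trajectory_metrics(traj)
        assert m.average_carrier_frequency == pytest.approx(1.0)
        assert m.first_generation_carrier_70 == 0.0

    def test_large_release_reaches_70_within_20_generations(self):
        traj = integrate(ReleaseSpec(0.8), IDEAL, t_end=1000, samples_per_generation=10)
        m = trajectory_metrics(traj)
        assert m.first_generation_carrier_70 is not None
        assert m.first_generation_carrier_70 <= 20.0

    def test_below_threshold_equilibrium_zero(self):
        traj = integrate(ReleaseSpec(0.3), IDEAL, t_end=1000, samples_per_generation=1)
        m = trajectory_metrics(traj)
        assert m.equilibrium_allele_frequency == pytest.approx(0.0, abs=1e-6)
        assert m.equilibrium_carrier_frequency == pytest.approx(0.0, abs=1e-6)


class TestThreshold:
    def test_ideal_drive_threshold(self):
        assert find_threshold(IDEAL) == pytest.approx(0.36051, abs=2e-5)

    def test_threshold_monotone_in_fitness(self):
        t95 = find_threshold(DriveParams(fitness=0.95))
        t90 = find_threshold(DriveParams(fitness=0.90))
        assert find_threshold(IDEAL) < t95 < t90

    def test_threshold_monotone_in_antidote_efficiency(self):
        t_lo = find_threshold(DriveParams(antidote_efficiency=0.8))
        t_hi = find_threshold(DriveParams(antidote_efficiency=1.0))
        assert t_hi < t_lo

    def test_low_fitness_never_establishes(self):
        assert find_threshold(DriveParams(fitness=0.70)) == 1.0

    def test_equilibrium_depends_on_fitness_not_release(self):
        """For 0.73 <= F <= 0.76 the nonzero equilibrium is set by fitness
        alone; the release size only selects loss vs establishment."""
        p = DriveParams(fitness=0.75)
        th = find_threshold(p)
        eq = []
        for I in (min(th + 0.05, 0.95), 0.95):
            traj = integrate(ReleaseSpec(I), p, samples_per_generation=1)
            eq.append(traj.carrier_frequency()[-1])
        assert eq[0] == pytest.approx(eq[1], abs=1e-4)
        assert eq[0] < 1.0


class TestDiscreteMap:
    def test_neutral_step_conserves_alleles_and_gives_hw(self):
        p = DriveParams(toxin_efficiency=0.0)
        f = np.array([0.3, 0.2, 0.5])
        nxt = discrete_step(f, p)
        q = f[0] + 0.5 * f[1]
        assert nxt == pytest.approx([q**2, 2 * q * (1 - q), (1 - q) ** 2])

    def test_drive_only_absorbing(self):
        nxt = discrete_step(np.array([1.0, 0.0, 0.0]), IDEAL)
        assert nxt == pytest.approx([1.0, 0.0, 0.0])

    def test_discrete_dip_deeper_than_continuous(self):
        """Both models dip in allele frequency after a homozygote release;
        the discrete-generation dip is deeper."""
        I = 0.4
        hist = iterate_discrete(np.array([I, 0.0, 1.0 - I]), IDEAL, generations=20)
        disc_allele = hist[:, 0] + 0.5 * hist[:, 1]
        traj = integrate(ReleaseSpec(I), IDEAL, t_end=20, samples_per_generation=10)
        cont_allele = traj.allele_frequency("d")
        assert disc_allele.min() < cont_allele.min() < I


class TestTwoDeme:
    def test_zero_migration_matches_single_deme(self):
        cfg = TwoDemeConfig(migration_rate=0.0, release_deme1=ReleaseSpec(0.6))
        tr1, tr2 = two_deme_integrate(cfg, IDEAL, t_end=100, samples_per_generation=1)
        single = integrate(ReleaseSpec(0.6), IDEAL, t_end=100, samples_per_generation=1)
        assert np.allclose(tr1.states, single.states, atol=1e-7)
        assert tr2.carrier_frequency().max() == 0.0

    def test_migration_redistributes_growth(self):
        """The sum of the two deme derivative vectors equals g1 + g2."""
        from cifdrive.panmictic import _OdeModel

        cfg = TwoDemeConfig(migration_rate=0.03, release_deme1=ReleaseSpec(0.5))
        model = _OdeModel(IDEAL, EcologyParams(), CIFAB)
        x1 = np.array([0.5, 0.0, 0.5])
        x2 = np.array([0.0, 0.0, 1.0])
        g1, g2 = model.rhs(0, x1), model.rhs(0, x2)
        m = cfg.migration_rate
        d1 = (1 - m) * g1 + m * g2
        d2 = (1 - m) * g2 + m * g1
        assert np.allclose(d1 + d2, g1 + g2)

    def test_low_migration_confines_drive(self):
        cfg = TwoDemeConfig(migration_rate=0.01, release_deme1=ReleaseSpec(0.7))
        tr1, tr2 = two_deme_integrate(cfg, DriveParams(fitness=0.95), t_end=300,
                                      samples_per_generation=1)
        assert tr1.carrier_frequency()[-1] > 0.7  # establishes at home
        assert tr2.carrier_frequency()[-1] < 0.3  # stays low next door


class TestInflux:
    def test_zero_influx_is_plain_model(self):
        traj = influx_integrate(InfluxConfig(0.0), IDEAL, t_end=50, samples_per_generation=1)
        assert traj.carrier_frequency().max() == 0.0

    def test_supercritical_influx_establishes(self):
        traj = influx_integrate(InfluxConfig(0.05), DriveParams(fitness=0.95),
                                t_end=1000, samples_per_generation=1)
        assert traj.carrier_frequency()[-1] > 0.7

    def test_subcritical_influx_low_equilibrium(self):
        traj = influx_integrate(InfluxConfig(0.03), DriveParams(fitness=0.95),
                                t_end=1000, samples_per_generation=1)
        assert traj.allele_frequency("d").max() < 0.15


class TestReproductionSuccess:
    def test_equal_frequencies_equal_success(self):
        wt, carrier = reproduction_success(0.5, 0.5)
        assert wt == carrier == pytest.approx(0.75)

    def test_extremes(self):
        assert reproduction_success(0.0, 1.0)[1] == pytest.approx(1.0)
        assert reproduction_success(1.0, 0.0)[0] == pytest.approx(1.0)

    def test_majority_advantage(self):
        wt, carrier = reproduction_success(0.3, 0.7)
        assert carrier > wt
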