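"""Cross-engine unit and property tests: fitness, toxin/antidote,
sterility, Mendelian inheritance, and birth weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cifdrive.genetics import (
    Architecture,
    DriveParams,
    FitnessMode,
    GenotypeState,
    ToxinRule,
    antidote_probability,
    birth_weights,
    cifab_polynomial_birth_weights,
    cross_sterility,
    fitness_vector,
    genotype_fitness,
    get_system,
    mendelian_offspring,
    offspring_tensor,
    sterility_matrix,
    toxin_probability,
)

CIFAB = get_system(Architecture.CIFAB)
SL1 = get_system(Architecture.SL_ONE_LOCUS)
SL2 = get_system(Architecture.SL_TWO_LOCUS)


class TestSystems:
    def test_genotype_counts(self):
        assert len(CIFAB) == 3
        assert len(SL1) == 6
        assert len(SL2) == 9

    def test_cifab_allele_counts_drive_counts_as_both_genes(self):
        dd = CIFAB.genotype("dd")
        assert (dd.n_cifA, dd.n_cifB) == (2, 2)
        dw = CIFAB.genotype("dw")
        assert (dw.n_cifA, dw.n_cifB) == (1, 1)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(KeyError):
            CIFAB.index("ab")

    def test_state_allele_frequencies_normalize(self):
        s = GenotypeState(np.array([0.2, 0.3, 0.5]), CIFAB)
        d = s.allele_frequency("d")
        w = s.allele_frequency("w")
        assert d + w == pytest.approx(1.0)
        assert d == pytest.approx((0.2 + 0.15) / 1.0)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            GenotypeState(np.array([-0.1, 0.5, 0.6]), CIFAB)


class TestFitness:
    @pytest.mark.parametrize(
        "g,params,expected",
        [
            ("dd", DriveParams(fitness=0.95), 0.95),
            ("dw", DriveParams(fitness=0.81), 0.9),
            ("dw", DriveParams(fitness=0.6, fitness_mode=FitnessMode.DOMINANCE, dominance=0.0), 1.0),
            ("dw", DriveParams(fitness=0.6, fitness_mode=FitnessMode.DOMINANCE, dominance=1.0), 0.6),
            ("ww", DriveParams(fitness=0.6), 1.0),
        ],
    )
    def test_cifab_fitness(self, g, params, expected):
        assert genotype_fitness(g, params, CIFAB) == pytest.approx(expected)

    def test_self_limiting_cost_on_cifA_only(self):
        p = DriveParams(fitness=0.81)
        assert genotype_fitness("bb", p, SL1) == 1.0
        assert genotype_fitness("ab", p, SL1) == pytest.approx(0.9)
        assert genotype_fitness("aa", p, SL1) == pytest.approx(0.81)
        assert genotype_fitness("w1w1/bb", p, SL2) == 1.0
        assert genotype_fitness("aa/bb", p, SL2) == pytest.approx(0.81)


class TestToxinAntidote:
    @pytest.mark.parametrize(
        "g,et,expected",
        [("dd", 0.5, 0.75), ("dw", 0.5, 0.5), ("ww", 0.9, 0.0)],
    )
    def test_cifab_toxin(self, g, et, expected):
        p = DriveParams(toxin_efficiency=et)
        assert toxin_probability(g, p, CIFAB) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "g,ea,expected",
        [("dd", 0.5, 0.75), ("dw", 1.0, 1.0), ("ww", 0.7, 0.0)],
    )
    def test_cifab_antidote(self, g, ea, expected):
        p = DriveParams(antidote_efficiency=ea)
        assert antidote_probability(g, p, CIFAB) == pytest.approx(expected)

    def test_toxin_rules_differ_only_for_split_constructs(self):
        # a male with cifB but no cifA is a toxin male only under B_SUFFICIENT
        ab_req = DriveParams(toxin_rule=ToxinRule.AB_REQUIRED)
        b_suf = DriveParams(toxin_rule=ToxinRule.B_SUFFICIENT)
        assert toxin_probability("wb", ab_req, SL1) == 0.0
        assert toxin_probability("wb", b_suf, SL1) == 1.0
        assert toxin_probability("ab", ab_req, SL1) == 1.0
        assert toxin_probability("w1w1/bb", ab_req, SL2) == 0.0
        assert toxin_probability("w1w1/bb", b_suf, SL2) == 1.0

    @pytest.mark.parametrize(
        "male,female,params,expected",
        [
            ("dd", "ww", DriveParams(toxin_efficiency=1.0), 1.0),
            ("dd", "dw", DriveParams(), 0.0),
            ("dd", "dw", DriveParams(toxin_efficiency=0.6, antidote_efficiency=0.3),
             (1 - 0.4**2) * 0.7),
        ],
    )
    def test_cross_sterility(self, male, female, params, expected):
        assert cross_sterility(male, female, params, CIFAB) == pytest.approx(expected)

    @given(et=st.floats(0, 1), ea=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_sterility_depends_only_on_toxin_and_cifA_counts(self, et, ea):
        """Heterozygote configuration is irrelevant: sterility factors
        through the male's toxin probability and the female's cifA count."""
        p = DriveParams(toxin_efficiency=et, antidote_efficiency=ea)
        # SL 1-locus: wa female has one cifA copy like the 2-locus aw1 female
        s1 = cross_sterility("ab", "wa", p, SL1)
        s2 = cross_sterility("aw1/bw2", "aw1/w2w2", p, SL2)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestMendelian:
    def test_het_cross(self):
        dist = mendelian_offspring("dw", "dw", CIFAB)
        assert dist == pytest.approx({"dd": 0.25, "dw": 0.5, "ww": 0.25})

    def test_one_locus_three_allele_cross(self):
        dist = mendelian_offspring("ab", "ww", SL1)
        assert dist == pytest.approx({"wa": 0.5, "wb": 0.5})

    def test_two_locus_fixed_gametes(self):
        dist = mendelian_offspring("aa/bb", "w1w1/w2w2", SL2)
        assert dist == pytest.approx({"aw1/bw2": 1.0})

    def test_two_locus_independent_assortment(self):
        dist = mendelian_offspring("aw1/bw2", "aw1/bw2", SL2)
        # per-locus 1/4 : 1/2 : 1/4, loci independent
        assert dist["aa/bb"] == pytest.approx(1 / 16)
        assert dist["aw1/bw2"] == pytest.approx(1 / 4)
        assert sum(dist.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("system", [CIFAB, SL1, SL2])
    def test_offspring_tensor_rows_normalize(self, system):
        O = offspring_tensor(system)
        assert np.allclose(O.sum(axis=2), 1.0)


def _brute_force_birth_weights(x, params, system):
    """Independent oracle: explicit double loop over ordered parent pairs."""
    out = np.zeros(system.n)
    for i, mother in enumerate(system.genotypes):
        for j, father in enumerate(system.genotypes):
            fert = 1.0 - cross_sterility(father, mother, params, system)
            for label, prob in mendelian_offspring(father, mother, system).items():
                out[system.index(label)] += x[i] * x[j] * fert * prob
    return out


class TestBirthWeights:
    def test_wildtype_only(self):
        w = birth_weights(np.array([0.0, 0.0, 1.0]), DriveParams(), CIFAB)
        assert w == pytest.approx([0.0, 0.0, 1.0])

    def test_heterozygotes_perfect_drive(self):
        w = birth_weights(np.array([0.0, 1.0, 0.0]), DriveParams(), CIFAB)
        assert w == pytest.approx([0.25, 0.5, 0.25])

    def test_heterozygotes_certain_toxin_no_antidote(self):
        """Every het x het pairing is sterile when the toxin always fires
        and the antidote never rescues."""
        p = DriveParams(toxin_efficiency=1.0, antidote_efficiency=0.0)
        w = birth_weights(np.array([0.0, 1.0, 0.0]), p, CIFAB)
        assert w == pytest.approx([0.0, 0.0, 0.0], abs=1e-15)

    @given(
        x=st.lists(st.floats(0, 2), min_size=3, max_size=3),
        et=st.floats(0, 1),
        ea=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_closed_form_polynomials(self, x, et, ea):
        x = np.array(x)
        p = DriveParams(toxin_efficiency=et, antidote_efficiency=ea)
        assert np.allclose(
            birth_weights(x, p, CIFAB),
            cifab_polynomial_birth_weights(x, p),
            atol=1e-12,
        )

    @pytest.mark.parametrize("system", [CIFAB, SL1, SL2])
    def test_matches_brute_force_enumeration(self, system):
        rng = np.random.default_rng(7)
        for _ in range(3):
            x = rng.random(system.n)
            p = DriveParams(
                toxin_efficiency=rng.random(),
                antidote_efficiency=rng.random(),
                toxin_rule=ToxinRule.B_SUFFICIENT if rng.random() < 0.5 else ToxinRule.AB_REQUIRED,
            )
            assert np.allclose(
                birth_weights(x, p, system),
                _brute_force_birth_weights(x, p, system),
                atol=1e-12,
            )

    @pytest.mark.parametrize("system", [CIFAB, SL2])
    def test_total_weight_conserves_fertility_mass(self, system):
        rng = np.random.default_rng(11)
        x = rng.random(system.n)
        p = DriveParams(toxin_efficiency=0.7, antidote_efficiency=0.4)
        fert = 1.0 - sterility_matrix(p, system).T
        expected = float(np.einsum("i,j,ij->", x, x, fert))
        assert birth_weights(x, p, system).sum() == pytest.approx(expected)

    def test_neutral_limit_hardy_weinberg(self):
        """Et = 0 and fitness 1: one normalized round of reproduction
        conserves allele frequency and yields Hardy-Weinberg proportions."""
        p = DriveParams(toxin_efficiency=0.0)
        x = np.array([0.35, 0.15, 0.5])
        w = birth_weights(x, p, CIFAB)
        w = w / w.sum()
        q = x[0] + 0.5 * x[1]  # drive allele frequency (N = 1)
        assert w[0] + 0.5 * w[1] == pytest.approx(q)
        assert w == pytest.approx([q**2, 2 * q * (1 - q), (1 - q) ** 2])
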