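"""Allelic (gamete-transmission) TRD model and the simplified screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epitrd.allelic import (
    ALLELIC_PARAM_NAMES,
    GAMETE_LABELS,
    PAIRWISE_NAMES,
    AllelicLikelihood,
    AllelicParams,
    Gamete,
    SimplifiedParams,
    gamete_probabilities,
    log_likelihood_allelic,
    offspring_probabilities_allelic,
    simplified_log_likelihood,
    simplified_transmission_counts,
    _gamete_weights,
)
from epitrd.trio_data import (
    GENOTYPE_LABELS,
    PairTrioData,
    TwoLocusGenotype,
    all_matings,
)

allelic_theta = st.tuples(
    st.floats(-0.5, 0.5, allow_nan=False),
    st.floats(-0.5, 0.5, allow_nan=False),
    *[st.floats(-1.0, 1.0, allow_nan=False) for _ in range(6)],
).map(np.array)


class TestCombinatorics:
    def test_six_pairwise_parameters_four_gametes(self):
        assert len(PAIRWISE_NAMES) == 6
        assert len(GAMETE_LABELS) == 4
        assert len(ALLELIC_PARAM_NAMES) == 8


class TestGameteProbabilities:
    def test_double_het_null_is_uniform(self):
        p = gamete_probabilities(TwoLocusGenotype.AaBb, AllelicParams())
        assert np.allclose(p, 0.25)

    def test_double_het_pairwise_boundary(self):
        p = gamete_probabilities(TwoLocusGenotype.AaBb, AllelicParams(beta_AB_ab=1.0))
        assert np.allclose(p, [0.5, 0.25, 0.25, 0.0])

    def test_single_het_direct_effect(self):
        p = gamete_probabilities(TwoLocusGenotype.AABb, AllelicParams(beta_B=0.25))
        assert np.allclose(p, [0.75, 0.25, 0.0, 0.0])

    def test_double_homozygote_single_gamete(self):
        p = gamete_probabilities(TwoLocusGenotype.AABB, AllelicParams())
        assert np.allclose(p, [1.0, 0.0, 0.0, 0.0])

    def test_single_het_pairwise_sign_convention(self):
        # the canonically earlier gamete of the pair gets (1 + beta)
        p = gamete_probabilities(TwoLocusGenotype.AABb, AllelicParams(beta_AB_Ab=0.5))
        assert np.allclose(p, [1.5 / 2.0, 0.5 / 2.0, 0.0, 0.0])

    @given(theta=allelic_theta)
    @settings(max_examples=30)
    def test_weights_nonnegative_all_parents(self, theta):
        for g in TwoLocusGenotype:
            w = _gamete_weights(g, theta)
            assert np.all(w >= 0)


class TestOffspringProbabilities:
    def test_null_is_mendelian_all_matings(self, matings):
        null = AllelicParams()
        for m in matings:
            p = offspring_probabilities_allelic(m, null)
            assert np.allclose(p, m.mendelian)

    def test_double_het_boundary_examples(self, hethet_mating):
        params = AllelicParams(beta_AB_ab=1.0)
        p = offspring_probabilities_allelic(hethet_mating, params)
        assert p[TwoLocusGenotype.aabb] == pytest.approx(0.0)
        assert p[TwoLocusGenotype.AaBb] == pytest.approx(0.125)

    @given(theta=allelic_theta)
    @settings(max_examples=30)
    def test_probability_vector_invariants(self, theta):
        params = AllelicParams.from_array(theta)
        for m in all_matings():
            p = offspring_probabilities_allelic(m, params)
            assert np.all(p >= -1e-15)
            assert p.sum() == pytest.approx(1.0)

    @given(theta=allelic_theta)
    @settings(max_examples=30)
    def test_joint_normalization_factorizes(self, theta):
        # the joint gamete-pair weight normalization equals the product
        # of the per-parent normalizations
        for m in all_matings():
            ws = _gamete_weights(m.sire_genotype, theta)
            wd = _gamete_weights(m.dam_genotype, theta)
            joint = np.outer(ws, wd).sum()
            assert joint == pytest.approx(ws.sum() * wd.sum(), rel=1e-12)

    def test_parental_origin_classes_sum_to_double_het(self, hethet_mating):
        params = AllelicParams(beta_A=0.2, beta_AB_ab=0.4, beta_Ab_aB=-0.3)
        ps = gamete_probabilities(hethet_mating.sire_genotype, params)
        pd_ = gamete_probabilities(hethet_mating.dam_genotype, params)
        # cis origin: AB + ab; trans origin: Ab + aB
        cis = ps[0] * pd_[3] + ps[3] * pd_[0]
        trans = ps[1] * pd_[2] + ps[2] * pd_[1]
        p = offspring_probabilities_allelic(hethet_mating, params)
        assert cis + trans == pytest.approx(p[TwoLocusGenotype.AaBb])

    @given(
        beta_a=st.floats(-0.4, 0.4, allow_nan=False),
        beta_b=st.floats(-0.4, 0.4, allow_nan=False),
    )
    @settings(max_examples=30)
    def test_direct_only_matches_two_independent_single_locus_models(
        self, beta_a, beta_b
    ):
        # oracle: two independent single-locus transmission models
        def single_locus(dosage, beta):
            if dosage == 2:
                return np.array([0.0, 1.0])
            if dosage == 0:
                return np.array([1.0, 0.0])
            return np.array([0.5 - beta, 0.5 + beta])

        params = AllelicParams(beta_A=beta_a, beta_B=beta_b)
        for m in all_matings():
            expected = np.zeros(9)
            sa = single_locus(m.sire_genotype.dosage_a, beta_a)
            da = single_locus(m.dam_genotype.dosage_a, beta_a)
            sb = single_locus(m.sire_genotype.dosage_b, beta_b)
            db = single_locus(m.dam_genotype.dosage_b, beta_b)
            for ca_s in (0, 1):
                for ca_d in (0, 1):
                    for cb_s in (0, 1):
                        for cb_d in (0, 1):
                            cls = TwoLocusGenotype.from_dosages(ca_s + ca_d, cb_s + cb_d)
                            expected[cls] += (
                                sa[ca_s] * da[ca_d] * sb[cb_s] * db[cb_d]
                            )
            p = offspring_probabilities_allelic(m, params)
            assert np.allclose(p, expected, atol=1e-12)


def _pair_counts(entries):
    counts = np.zeros((81, 9), dtype=np.int64)
    for (sire, dam, off), n in entries.items():
        m = 9 * int(TwoLocusGenotype[sire]) + int(TwoLocusGenotype[dam])
        counts[m, int(TwoLocusGenotype[off])] = n
    return PairTrioData("a", "b", counts)


class TestAllelicLikelihood:
    def test_single_offspring_null(self):
        d = _pair_counts({("AaBb", "AaBb", "AaBb"): 1})
        assert log_likelihood_allelic(d, AllelicParams()) == pytest.approx(
            np.log(4 / 16)
        )

    def test_zero_probability_class(self):
        d = _pair_counts({("AaBb", "AaBb", "aabb"): 1})
        assert log_likelihood_allelic(d, AllelicParams(beta_AB_ab=1.0)) == -np.inf

    def test_likelihood_factorizes_over_matings(self):
        d1 = _pair_counts({("AaBb", "AaBb", "AABB"): 3})
        d2 = _pair_counts({("AaBB", "AABb", "AaBb"): 2})
        both = _pair_counts(
            {("AaBb", "AaBb", "AABB"): 3, ("AaBB", "AABb", "AaBb"): 2}
        )
        params = AllelicParams(beta_A=0.1, beta_AB_ab=0.3)
        assert log_likelihood_allelic(both, params) == pytest.approx(
            log_likelihood_allelic(d1, params) + log_likelihood_allelic(d2, params)
        )


class TestSimplifiedScreen:
    def test_single_het_parent_transmission_scored(self):
        # sire AABb carries AB and Ab; dam aabb fixes its contribution;
        # offspring Aabb received b -> Ab transmitted, not AB
        d = _pair_counts({("AABb", "aabb", "Aabb"): 1})
        c = simplified_transmission_counts(d, "AB")
        assert (c.n_transmitted, c.n_alternative) == (0, 1)
        c = simplified_transmission_counts(d, "Ab")
        assert (c.n_transmitted, c.n_alternative) == (1, 0)

    def test_double_het_parent_not_informative(self):
        d = _pair_counts({("AaBb", "aabb", "AaBb"): 1})
        c = simplified_transmission_counts(d, "AB")
        # sire is double-het: excluded from the simplified screen; dam
        # does not carry AB
        assert c.n_informative_parents == 0

    def test_ambiguous_transmission_skipped(self):
        # both parents het at B with a heterozygous offspring at B
        d = _pair_counts({("AABb", "AABb", "AABb"): 1})
        c = simplified_transmission_counts(d, "AB")
        # both parents informative, both ambiguous
        assert c.n_informative_parents == 2
        assert c.n_ambiguous == 2
        assert c.n_transmitted + c.n_alternative == 0

    def test_unambiguous_homozygous_offspring(self):
        d = _pair_counts({("AABb", "AABb", "AABB"): 1})
        c = simplified_transmission_counts(d, "AB")
        assert (c.n_transmitted, c.n_alternative, c.n_ambiguous) == (2, 0, 0)

    def test_loglik_values(self):
        assert simplified_log_likelihood(1, 1, SimplifiedParams(0.0)) == pytest.approx(
            2 * np.log(0.5)
        )
        assert simplified_log_likelihood(3, 0, SimplifiedParams(0.5)) == pytest.approx(0.0)
        assert simplified_log_likelihood(3, 1, SimplifiedParams(0.5)) == -np.inf

    def test_screen_promotes_distorted_haplotype_only(self):
        from epitrd.allelic import simplified_screen
        from epitrd.inference import ChainConfig
        from epitrd.simulate import simulate_pair, SimConfig

        # plant preferential transmission of AB in single-heterozygous
        # parents (the carriers the screen scores)
        d = simulate_pair(
            SimConfig(
                n_dams=3_000, mechanism="allelic",
                mechanism_params=AllelicParams(beta_AB_Ab=0.8, beta_AB_aB=0.8),
                seed=21,
            )
        ).pair
        res = simplified_screen(
            d, single_snp_trd=0.0,
            chain_cfg=ChainConfig(n_iter=11_000, burn_in=1_000, seed=21),
        )
        by_gamete = {r.gamete: r for r in res}
        assert by_gamete["AB"].alpha_mean > 0.05
        assert by_gamete["AB"].promoted
        assert by_gamete["AB"].log10_bf > 2.0

    def test_screen_promotes_nothing_on_null_data(self):
        from epitrd.allelic import simplified_screen
        from epitrd.inference import ChainConfig
        from epitrd.simulate import simulate_pair, SimConfig

        d = simulate_pair(SimConfig(n_dams=3_000, seed=22)).pair
        res = simplified_screen(
            d, single_snp_trd=0.0,
            chain_cfg=ChainConfig(n_iter=11_000, burn_in=1_000, seed=22),
        )
        assert res and not any(r.promoted for r in res)

    def test_mle_at_zero_for_balanced_counts(self):
        # grid-search oracle: balanced counts maximize at alpha = 0
        grid = np.linspace(-0.49, 0.49, 981)
        lls = [simplified_log_likelihood(10, 10, SimplifiedParams(a)) for a in grid]
        assert abs(grid[int(np.argmax(lls))]) < 1e-9
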