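import itertools

import numpy as np
import pytest

from scstrmix.cell_sim import DropModel
from scstrmix.consensus import ConsensusProfile
from scstrmix.freq_panel import AlleleFrequencyTable, synthesize_frequency_table
from scstrmix.genotype_sim import GenotypeProfile, sample_genotype_fst
from scstrmix.inference import (
    RelationshipHypothesis,
    estimate_consensus_error_rates,
    genotype_probability,
    lr_related,
    lr_same_source,
    observation_distribution,
    observation_probability,
    prob_missing_contributor,
    profile_probability,
)


def consensus_from_genotype(genotype):
    return ConsensusProfile(
        calls={locus: genotype.pair(locus) for locus in genotype.loci},
        support={locus: (1, 1) for locus in genotype.loci},
        cluster_size=1,
    )


class TestProbMissingContributor:
    @pytest.mark.parametrize(
        "p, n, percent",
        [(0.01, 80, 44.75), (0.05, 80, 1.65), (0.05, 15, 46.33),
         (0.10, 10, 34.87), (0.50, 5, 3.13), (0.01, 500, 0.66)],
    )
    def test_printed_values(self, p, n, percent):
        # agree with the 2-decimal printed percentage to half a printed ulp
        assert abs(100 * prob_missing_contributor(p, n) - percent) <= 0.005 + 1e-12

    def test_boundaries(self):
        assert prob_missing_contributor(0.5, 1) == 0.5
        assert prob_missing_contributor(0.3, 0) == 1.0

    def test_out_of_range_rejected(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                prob_missing_contributor(p, 10)


class TestGenotypeProbability:
    def test_theta_zero_hardy_weinberg(self, one_locus_panel):
        p = 0.3
        assert genotype_probability((10.0, 10.0), "L1", one_locus_panel, 0.0) == \
            pytest.approx(p * p)
        q = 0.45
        assert genotype_probability((10.0, 11.0), "L1", one_locus_panel, 0.0) == \
            pytest.approx(2 * p * q)

    def test_balding_nichols_homozygote(self, one_locus_panel):
        assert genotype_probability((10.0, 10.0), "L1", one_locus_panel, 0.01) == \
            pytest.approx(0.3 * (0.01 + 0.99 * 0.3))  # 0.0921

    @pytest.mark.parametrize("fst", [0.0, 0.01, 0.05, 0.3])
    def test_distribution_sums_to_one(self, tiny_panel, fst):
        for locus in tiny_panel.loci:
            alleles = tiny_panel.alleles(locus)
            total = sum(
                genotype_probability((min(a, b), max(a, b)), locus, tiny_panel, fst)
                for a, b in itertools.combinations_with_replacement(alleles, 2)
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestObservationProbability:
    def test_noiseless_is_point_mass_on_truth(self, tiny_panel):
        model = DropModel(D=0.0, e=0.0)
        alleles = tiny_panel.alleles("LA")
        assert observation_probability((8.0, 9.0), (8.0, 9.0), model, alleles) == 1.0
        assert observation_probability((8.0, 8.0), (8.0, 9.0), model, alleles) == 0.0

    @pytest.mark.parametrize("d", [0.0, 0.05, 0.2, 1.0])
    @pytest.mark.parametrize("e", [0.0, 0.01, 0.3])
    @pytest.mark.parametrize("genotype", [(8.0, 8.0), (8.0, 10.0)])
    def test_distribution_sums_to_one(self, tiny_panel, d, e, genotype):
        model = DropModel(D=d, e=e)
        dist = observation_distribution(genotype, model, tiny_panel.alleles("LA"))
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_heterozygous_dropout_probability(self, tiny_panel):
        # losing exactly the smaller allele of a het with no miscall: D(1-D)(1-e)
        model = DropModel(D=0.2, e=0.01)
        prob = observation_probability((9.0,), (8.0, 9.0), model,
                                       tiny_panel.alleles("LA"))
        assert prob == pytest.approx(0.2 * 0.8 * 0.99 + 0.8 * 0.2 * 0.01 / 2)
        # second term: 8 survives but is miscalled into 9 (one of 2 others)


class TestLrSameSource:
    def test_reduces_to_inverse_rmp_without_noise(self, panel21):
        rng = np.random.default_rng(1)
        b = sample_genotype_fst(panel21, 0.01, rng)
        a = consensus_from_genotype(b)
        model = DropModel(D=0.0, e=0.0)
        lr = lr_same_source(a, b, model, panel21, fst=0.01)
        rmp = profile_probability(b, panel21, fst=0.01)
        assert lr == pytest.approx(1.0 / rmp, rel=1e-12)

    def test_mismatch_without_noise_gives_zero(self, tiny_panel):
        b = GenotypeProfile("B", {"LA": (8.0, 9.0), "LB": (9.0, 10.0)})
        a_geno = GenotypeProfile("A", {"LA": (8.0, 9.0), "LB": (8.0, 8.0)})
        a = consensus_from_genotype(a_geno)
        assert lr_same_source(a, b, DropModel(D=0.0, e=0.0), tiny_panel) == 0.0

    def test_single_locus_matches_hand_enumeration(self):
        # one 2-allele locus: every term of the LR written out longhand
        p, q = 0.7, 0.3
        panel = AlleleFrequencyTable(
            loci=("L",),
            alleles_by_locus={"L": (10.0, 11.0)},
            freqs_by_locus={"L": np.array([p, q])},
        )
        D, e = 0.2, 0.01
        model = DropModel(D=D, e=e)
        b = GenotypeProfile("B", {"L": (10.0, 11.0)})
        a = consensus_from_genotype(b)
        # observing (10, 11) from true het (10, 11): both survive and neither
        # miscalls, or both survive and both miscall (10->11, 11->10)
        num = (1 - D) ** 2 * ((1 - e) ** 2 + e * e)
        den = 2 * p * q
        assert lr_same_source(a, b, model, panel, fst=0.0) == \
            pytest.approx(num / den, rel=1e-12)

    def test_missing_locus_contributes_factor_one(self, tiny_panel):
        b = GenotypeProfile("B", {"LA": (8.0, 9.0), "LB": (9.0, 10.0)})
        a = ConsensusProfile(
            calls={"LA": (8.0, 9.0), "LB": (None, None)},
            support={"LA": (1, 1), "LB": (0, 0)},
            cluster_size=1,
        )
        lr, per_locus = lr_same_source(a, b, DropModel(D=0.0, e=0.0), tiny_panel,
                                       return_per_locus=True)
        assert per_locus["LB"] == 1.0

    def test_half_missing_locus_warns(self, tiny_panel):
        b = GenotypeProfile("B", {"LA": (8.0, 9.0), "LB": (9.0, 10.0)})
        a = ConsensusProfile(
            calls={"LA": (8.0, 9.0), "LB": (9.0, None)},
            support={"LA": (1, 1), "LB": (1, 0)},
            cluster_size=1,
        )
        with pytest.warns(UserWarning, match="half-missing"):
            lr_same_source(a, b, DropModel(D=0.1, e=0.0), tiny_panel)


def sibling_lr_oracle(obs, b_pair, p_by_allele, model, alleles):
    """Independent full-sibling single-locus LR: explicit IBD-state sums."""
    from scstrmix.inference import observation_probability as obs_prob

    def geno_prob_uncond():
        out = {}
        for a1, a2 in itertools.combinations_with_replacement(alleles, 2):
            pa, pb = p_by_allele[a1], p_by_allele[a2]
            out[(a1, a2)] = pa * pb if a1 == a2 else 2 * pa * pb
        return out

    uncond = geno_prob_uncond()

    def mixture(k0, k1, k2):
        total = 0.0
        # IBD2
        total += k2 * obs_prob(obs, b_pair, model, alleles)
        # IBD1: one allele copied from B, other a population draw
        for t in b_pair:
            for u in alleles:
                pair = (min(t, u), max(t, u))
                total += k1 * 0.5 * p_by_allele[u] * obs_prob(obs, pair, model, alleles)
        # IBD0
        for pair, pg in uncond.items():
            total += k0 * pg * obs_prob(obs, pair, model, alleles)
        return total

    return mixture(0.25, 0.5, 0.25) / mixture(1.0, 0.0, 0.0)


class TestLrRelated:
    def test_unrelated_hypothesis_is_identity(self, tiny_panel):
        rng = np.random.default_rng(2)
        b = sample_genotype_fst(tiny_panel, 0.01, rng)
        a_geno = sample_genotype_fst(tiny_panel, 0.01, rng, "A")
        a = consensus_from_genotype(a_geno)
        hyp = RelationshipHypothesis.from_kind("unrelated")
        lr = lr_related(a, b, hyp, DropModel(D=0.2, e=0.01), tiny_panel, fst=0.01)
        assert lr == pytest.approx(1.0, rel=1e-12)

    def test_parent_child_zero_sharing_impossible_without_noise(self, tiny_panel):
        b = GenotypeProfile("B", {"LA": (8.0, 8.0), "LB": (8.0, 9.0)})
        a_geno = GenotypeProfile("A", {"LA": (9.0, 10.0), "LB": (8.0, 9.0)})
        a = consensus_from_genotype(a_geno)
        hyp = RelationshipHypothesis.from_kind("parent-child")
        assert lr_related(a, b, hyp, DropModel(D=0.0, e=0.0), tiny_panel) == 0.0

    def test_full_sibling_single_locus_matches_oracle(self):
        p_by_allele = {10.0: 0.5, 11.0: 0.3, 12.0: 0.2}
        alleles = (10.0, 11.0, 12.0)
        panel = AlleleFrequencyTable(
            loci=("L",),
            alleles_by_locus={"L": alleles},
            freqs_by_locus={"L": np.array([0.5, 0.3, 0.2])},
        )
        model = DropModel(D=0.2, e=0.01)
        hyp = RelationshipHypothesis.from_kind("full-siblings")
        for b_pair in [(10.0, 10.0), (10.0, 11.0), (11.0, 12.0)]:
            for obs in [(10.0, 10.0), (10.0, 11.0), (12.0,), (11.0, 12.0)]:
                b = GenotypeProfile("B", {"L": b_pair})
                if len(obs) != 2:
                    continue
                a = ConsensusProfile(calls={"L": obs}, support={"L": (1, 1)},
                                     cluster_size=1)
                ours = lr_related(a, b, hyp, model, panel, fst=0.0)
                oracle = sibling_lr_oracle(obs, b_pair, p_by_allele, model, alleles)
                assert ours == pytest.approx(oracle, rel=1e-12)

    def test_same_source_dominates_kinship_for_identical_profiles(self, panel21):
        rng = np.random.default_rng(3)
        b = sample_genotype_fst(panel21, 0.0, rng)
        a = consensus_from_genotype(b)
        model = DropModel(D=0.0, e=0.0)
        lr_same = lr_same_source(a, b, model, panel21, fst=0.0)
        for kind in ("parent-child", "full-siblings"):
            hyp = RelationshipHypothesis.from_kind(kind)
            assert lr_same >= lr_related(a, b, hyp, model, panel21, fst=0.0)

    def test_invalid_ibd_rejected(self):
        with pytest.raises(ValueError):
            RelationshipHypothesis(kind="x", ibd_coefficients=(0.5, 0.2, 0.2))


class TestConsensusErrorRates:
    def test_rates_shrink_with_cluster_size(self, panel21):
        model = DropModel(D=0.2, e=0.01)
        rng = np.random.default_rng(4)
        single = estimate_consensus_error_rates(panel21, model, 1, n_sim=100, rng=rng)
        ten = estimate_consensus_error_rates(panel21, model, 10, n_sim=100, rng=rng)
        assert 0.0 <= ten.D < single.D
        assert ten.D2 < single.D2
        assert single.D == pytest.approx(0.2, abs=0.02)
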