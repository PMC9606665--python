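"""Pedigree, genomic and hybrid relationship matrices against hand and dense oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinvar import (
    GenotypeMatrix,
    Pedigree,
    PedigreeError,
    SingularMatrixError,
    blend_G_A,
    build_A,
    build_A_inverse,
    build_G_vanraden1,
    build_H_inverse,
    compute_inbreeding,
    invert_matrix,
    make_fixture,
)
from kinvar.relmat import AlignmentError

from conftest import random_pedigree


class TestInbreeding:
    def test_founders_are_not_inbred(self):
        ped = Pedigree.from_records([("1", 0, 0), ("2", 0, 0)])
        assert compute_inbreeding(ped).tolist() == [0.0, 0.0]

    def test_sire_daughter_mating(self):
        # 4 = (1, 3) where 3 = (1, 2): a(1,3) = 0.5 so F4 = 0.25
        ped = Pedigree.from_records(
            [("1", 0, 0), ("2", 0, 0), ("3", "1", "2"), ("4", "1", "3")]
        )
        assert compute_inbreeding(ped)[3] == pytest.approx(0.25)

    def test_fullsib_mating(self):
        # parents are full sibs: a(3,4) = 0.5 so F5 = 0.25
        F = compute_inbreeding(make_fixture("fullsib"))
        assert F[4] == pytest.approx(0.25)

    def test_diag_A_equals_one_plus_F(self):
        ped = random_pedigree(60, 10, np.random.default_rng(1))
        A = build_A(ped)
        assert np.allclose(np.diag(A.values), 1.0 + compute_inbreeding(ped))


class TestBuildA:
    def test_unrelated_founders_give_identity(self):
        ped = Pedigree.from_records([("1", 0, 0), ("2", 0, 0)])
        assert np.array_equal(build_A(ped).values, np.eye(2))

    def test_trio_tabular_values(self):
        A = build_A(make_fixture("trio"))
        expected = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
        assert np.allclose(A.values, expected)

    def test_fullsib_offspring_diagonal(self):
        A = build_A(make_fixture("fullsib"))
        assert A.values[4, 4] == pytest.approx(1.25)

    def test_parents_must_precede_offspring(self):
        with pytest.raises(PedigreeError):
            Pedigree.from_records([("3", "1", "2"), ("1", 0, 0), ("2", 0, 0)])


class TestBuildAInverse:
    def test_founders_only_identity(self):
        ped = Pedigree.from_records([(str(i), 0, 0) for i in range(1, 5)])
        assert np.array_equal(build_A_inverse(ped).values, np.eye(4))

    def test_trio_henderson_values(self):
        Ainv = build_A_inverse(make_fixture("trio"))
        expected = np.array([[1.5, 0.5, -1], [0.5, 1.5, -1], [-1, -1, 2]])
        assert np.allclose(Ainv.values, expected)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_henderson_rules_invert_tabular_A(self, seed):
        """Rule-based A-inverse times tabular A is the identity (oracle equivalence)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        ped = random_pedigree(n, max(2, n // 6), rng)
        A = build_A(ped)
        Ainv = build_A_inverse(ped)
        assert np.abs(Ainv.values @ A.values - np.eye(n)).max() < 1e-8

    def test_ignoring_inbreeding_breaks_exactness_on_inbred_pedigree(self):
        # individual 6 has an inbred parent (F5 = 0.25), so its
        # Mendelian-sampling variance depends on the inbreeding flag
        ped = Pedigree.from_records(
            [("1", 0, 0), ("2", 0, 0), ("3", "1", "2"), ("4", "1", "2"),
             ("5", "3", "4"), ("6", "5", "2")]
        )
        good = build_A_inverse(ped, use_inbreeding=True)
        biased = build_A_inverse(ped, use_inbreeding=False)
        A = build_A(ped).values
        assert np.abs(good.values @ A - np.eye(6)).max() < 1e-12
        assert np.abs(biased.values @ A - np.eye(6)).max() > 1e-3


class TestBuildG:
    def test_hand_example_two_individuals(self):
        # codings (1,-1) and (1,1) at p=0.5: denominator 2*(0.25+0.25)=1
        geno = GenotypeMatrix(
            ids=["a", "b"],
            markers=["m1", "m2"],
            dosages=np.array([[1, 0], [1, 1]]),
            coding="binary",
            allele_freqs=np.array([0.5, 0.5]),
        )
        G = build_G_vanraden1(geno).values
        assert G[0, 0] == pytest.approx(2.0)
        assert G[0, 1] == pytest.approx(0.0)
        assert G[1, 1] == pytest.approx(2.0)

    def test_fully_heterozygous_individual_has_zero_diagonal(self):
        # dosage 1 (coding 0) at every marker with p=0.5: each term (0-1+1)=0
        geno = GenotypeMatrix(
            ids=["het", "hom"],
            markers=[f"m{i}" for i in range(4)],
            dosages=np.array([[1, 1, 1, 1], [2, 2, 2, 2]]),
            allele_freqs=np.full(4, 0.5),
        )
        G = build_G_vanraden1(geno).values
        assert G[0, 0] == pytest.approx(0.0)

    def test_matches_elementwise_formula_on_toy_genotypes(self):
        """G equals the per-element sums of the centred-coding formula (oracle)."""
        geno = make_fixture("toy_geno")
        G = build_G_vanraden1(geno).values
        p = geno.allele_freqs
        M = geno.dosages - 1.0
        denom = 2.0 * np.sum(p * (1 - p))
        for i in range(len(geno.ids)):
            for j in range(i, len(geno.ids)):
                expected = np.sum((M[i] - 2 * p + 1) * (M[j] - 2 * p + 1)) / denom
                assert G[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permuting_individuals_permutes_G(self):
        geno = make_fixture("toy_geno")
        G = build_G_vanraden1(geno)
        perm = list(reversed(geno.ids))
        Gp = build_G_vanraden1(geno.subset(perm))
        assert np.allclose(Gp.values, G.submatrix(perm).values)

    def test_monomorphic_markers_raise(self):
        geno = GenotypeMatrix(
            ids=["a", "b"], markers=["m1"], dosages=np.array([[2], [2]])
        )
        with pytest.raises(ZeroDivisionError):
            build_G_vanraden1(geno)

    def test_maf_filter_drops_rare_markers(self):
        dosages = np.array([[0, 2, 1], [0, 2, 1], [0, 2, 0], [0, 1, 1]])
        geno = GenotypeMatrix(
            ids=list("abcd"), markers=["rare", "common1", "common2"], dosages=dosages
        )
        kept = geno.filter_maf(0.02)
        assert kept.markers == ["common1", "common2"]

    def test_G_approximates_A_on_gene_dropped_markers(self):
        """With thousands of unlinked markers, G estimates pedigree relationships."""
        from kinvar import SimulationConfig, simulate_population

        pop = simulate_population(
            SimulationConfig(
                n_founder_males=12,
                n_founder_females=12,
                n_generations=2,
                n_markers=2500,
                genotyped_generations=(0, 2),
                seed=9,
            )
        )
        geno = pop.genotypes
        # relationships in A are relative to the founders, so compare G on
        # the true base-population frequencies (the fixed-frequency override)
        based = GenotypeMatrix(
            ids=geno.ids,
            markers=geno.markers,
            dosages=geno.dosages,
            allele_freqs=pop.founder_allele_freqs,
        )
        G = build_G_vanraden1(based.filter_maf(0.02))
        A = build_A(pop.pedigree).submatrix(G.ids)
        assert np.mean(np.abs(G.values - A.values)) < 0.05


class TestBlend:
    def test_weight_limits(self):
        from kinvar import RelationshipMatrix

        geno = make_fixture("toy_geno")
        G = build_G_vanraden1(geno)
        A_sub = RelationshipMatrix(list(G.ids), np.eye(len(G)), kind="A")
        assert np.allclose(blend_G_A(G, A_sub, 1.0).values, G.values)
        assert np.allclose(blend_G_A(G, A_sub, 0.0).values, A_sub.values)

    def test_scalar_arithmetic(self):
        from kinvar import RelationshipMatrix

        G = RelationshipMatrix(["a", "b"], 2 * np.eye(2), kind="G")
        A = RelationshipMatrix(["a", "b"], np.eye(2), kind="A")
        assert np.allclose(blend_G_A(G, A, 0.95).values, 1.95 * np.eye(2))

    def test_id_mismatch_raises(self):
        from kinvar import RelationshipMatrix

        G = RelationshipMatrix(["a", "b"], np.eye(2), kind="G")
        A = RelationshipMatrix(["b", "a"], np.eye(2), kind="A")
        with pytest.raises(AlignmentError):
            blend_G_A(G, A)


class TestInvert:
    def test_identity_and_scaling(self):
        from kinvar import RelationshipMatrix

        K = RelationshipMatrix(["a", "b"], 2 * np.eye(2), kind="G")
        assert np.allclose(invert_matrix(K).values, 0.5 * np.eye(2))

    def test_near_singular_raises_with_eigenvalue(self):
        from kinvar import RelationshipMatrix

        K = RelationshipMatrix(
            ["a", "b", "c"], np.ones((3, 3)) + 1e-12 * np.eye(3), kind="custom"
        )
        with pytest.raises(SingularMatrixError) as err:
            invert_matrix(K)
        assert err.value.smallest_eigenvalue < 1e-6


class TestHInverse:
    def test_empty_genotyped_set_returns_A_inverse(self):
        ped = make_fixture("threegen")
        Ainv = build_A_inverse(ped)
        from kinvar import RelationshipMatrix

        empty = RelationshipMatrix([], np.zeros((0, 0)), kind="G")
        H = build_H_inverse(Ainv, empty, RelationshipMatrix([], np.zeros((0, 0)), kind="A"), [])
        assert np.array_equal(H.values, Ainv.values)

    def test_all_genotyped_collapses_to_G_inverse(self):
        ped = make_fixture("trio")
        A = build_A(ped)
        Ainv = build_A_inverse(ped)
        G = invert_matrix(invert_matrix(A))  # SPD proxy with A's ids
        from kinvar import RelationshipMatrix

        Gm = RelationshipMatrix(list(A.ids), G.values + 0.05 * np.eye(3), kind="G")
        H = build_H_inverse(Ainv, Gm, A.submatrix(A.ids, kind="A"), list(A.ids))
        assert np.allclose(H.values, invert_matrix(Gm).values, atol=1e-10)

    def test_equals_inverse_of_assembled_H(self):
        """H-inverse construction equals the dense inverse of the joint-distribution H."""
        from kinvar import SimulationConfig, simulate_population

        pop = simulate_population(
            SimulationConfig(
                n_founder_males=8,
                n_founder_females=8,
                n_generations=2,
                n_markers=300,
                genotyped_generations=(1, 2),
                seed=5,
            )
        )
        ped = pop.pedigree
        geno = pop.genotypes.filter_maf(0.02)
        genotyped = list(geno.ids[:8])
        A = build_A(ped)
        A22 = A.submatrix(genotyped, kind="A")
        G = blend_G_A(build_G_vanraden1(geno.subset(genotyped)), A22, 0.95)
        Hinv = build_H_inverse(build_A_inverse(ped), G, A22, genotyped)

        nong = [i for i in ped.ids if i not in set(genotyped)]
        order = nong + genotyped
        Ao = A.submatrix(order).values
        n1 = len(nong)
        A11, A12, A22v = Ao[:n1, :n1], Ao[:n1, n1:], Ao[n1:, n1:]
        A22i = np.linalg.inv(A22v)
        Gv = G.values
        H12 = A12 @ A22i @ Gv
        H = np.block(
            [
                [A11 + A12 @ A22i @ (Gv - A22v) @ A22i @ A12.T, H12],
                [H12.T, Gv],
            ]
        )
        idx = Hinv.index_of(order)
        assert np.abs(Hinv.values[np.ix_(idx, idx)] - np.linalg.inv(H)).max() < 1e-8
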