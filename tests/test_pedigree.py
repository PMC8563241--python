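"""Pedigree parsing, ordering and relationship-matrix construction."""

import io

import numpy as np
import pytest

from kradom.pedigree import (
    Pedigree,
    PedigreeError,
    PedigreeRecord,
    additive_relationship_matrix,
    dominance_relationship_matrix,
    gene_drop_relationships,
    read_pedigree,
    topological_order,
    write_pedigree,
)


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestReadPedigree:
    def test_minimal_valid_file(self):
        ped = read_pedigree(_csv("animal,sire,dam\ns,,\nd,0,0\no,s,d"))
        assert len(ped) == 3
        assert ped[0].sire is None and ped[1].dam is None
        assert (ped[2].sire, ped[2].dam) == ("s", "d")

    def test_self_ancestry_is_a_cycle_error(self):
        with pytest.raises(PedigreeError, match="cycle.*x"):
            read_pedigree(_csv("animal,sire,dam\nx,x,"))

    def test_two_animal_cycle_named(self):
        with pytest.raises(PedigreeError, match="cycle"):
            read_pedigree(_csv("animal,sire,dam\na,b,\nb,a,"))

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(_csv("animal,sire,dam\na,,\na,,"))

    def test_unlisted_parent_rejected_by_default(self):
        with pytest.raises(PedigreeError, match="ghost"):
            read_pedigree(_csv("animal,sire,dam\no,ghost,"))

    def test_add_missing_founders_creates_records(self):
        ped = read_pedigree(
            _csv("animal,sire,dam\no,ghost,"), add_missing_founders=True
        )
        assert len(ped) == 2
        assert ped[0].animal == "ghost" and ped[0].sire is None

    def test_dialect_column_mapping(self):
        ped = read_pedigree(
            _csv("ID,FATHER,MOTHER\no,,"),
            dialect={"animal": "ID", "sire": "FATHER", "dam": "MOTHER"},
        )
        assert ped[0].animal == "o"

    def test_roundtrip_through_csv(self, random_pedigree_factory):
        ped = random_pedigree_factory(np.random.default_rng(0))
        buf = io.StringIO()
        write_pedigree(ped, buf)
        again = read_pedigree(_csv(buf.getvalue()))
        assert again == ped


class TestTopologicalOrder:
    def test_offspring_before_parents_is_reordered(self):
        ped = read_pedigree(_csv("animal,sire,dam\no,s,d\ns,,\nd,,"))
        ordered = topological_order(ped)
        assert ordered.ids == ("s", "d", "o")
        assert ordered.is_ordered

    def test_idempotent_on_ordered_input(self, trio):
        assert topological_order(trio) == trio

    def test_stable_among_ties(self):
        ped = read_pedigree(_csv("animal,sire,dam\nb,,\na,,\nc,,"))
        assert topological_order(ped).ids == ("b", "a", "c")

    def test_five_generation_pedigree_exhaustive_scan(self):
        from kradom.simulate import SimulationConfig, simulate_pedigree

        cfg = SimulationConfig(n_lk_founders=6, n_sut_founders=6,
                               n_generations=5, n_offspring_per_mating=2, seed=0)
        ped = simulate_pedigree(cfg)
        rng = np.random.default_rng(1)
        shuffled = Pedigree([ped[i] for i in rng.permutation(len(ped))])
        ordered = topological_order(shuffled)
        for i, r in enumerate(ordered):
            for parent in (r.sire, r.dam):
                if parent is not None:
                    assert ordered.index(parent) < i


class TestAdditiveMatrix:
    def test_unrelated_founders_give_identity(self):
        ped = Pedigree([PedigreeRecord("a"), PedigreeRecord("b")])
        A = additive_relationship_matrix(ped)
        assert np.array_equal(A.values, np.eye(2))

    def test_parent_offspring_half_relationship(self, trio):
        A = additive_relationship_matrix(trio)
        assert A.loc("o", "s") == 0.5
        assert np.allclose(np.diag(A.values), 1.0)

    def test_full_sib_mating_inbred_diagonal(self, full_sib_mating):
        A = additive_relationship_matrix(full_sib_mating)
        assert A.loc("x", "x") == 1.25  # F = 0.25

    def test_requires_ordered_pedigree(self):
        ped = read_pedigree(_csv("animal,sire,dam\no,s,d\ns,,\nd,,"))
        with pytest.raises(PedigreeError, match="ordered"):
            additive_relationship_matrix(ped)


class TestDominanceMatrix:
    def test_full_sibs(self, full_sib_mating):
        D = dominance_relationship_matrix(full_sib_mating)
        assert D.loc("o1", "o2") == 0.25

    def test_paternal_half_sibs_zero(self):
        ped = Pedigree([
            PedigreeRecord("s"), PedigreeRecord("d1"), PedigreeRecord("d2"),
            PedigreeRecord("o1", "s", "d1"), PedigreeRecord("o2", "s", "d2"),
        ])
        D = dominance_relationship_matrix(ped)
        assert D.loc("o1", "o2") == 0.0

    def test_double_first_cousins(self):
        ped = Pedigree([
            PedigreeRecord(x) for x in "abcd"
        ] + [
            PedigreeRecord("s1", "a", "b"), PedigreeRecord("s2", "a", "b"),
            PedigreeRecord("m1", "c", "d"), PedigreeRecord("m2", "c", "d"),
            PedigreeRecord("i", "s1", "m1"), PedigreeRecord("j", "s2", "m2"),
        ])
        D = dominance_relationship_matrix(ped)
        assert D.loc("i", "j") == pytest.approx(0.0625)

    def test_unknown_parent_offdiagonal_zero_diag_one(self, trio):
        D = dominance_relationship_matrix(trio)
        assert np.allclose(np.diag(D.values), 1.0)
        assert D.loc("o", "s") == 0.0

    def test_mismatched_A_rejected(self, trio, full_sib_mating):
        A_other = additive_relationship_matrix(full_sib_mating)
        with pytest.raises(ValueError, match="ids"):
            dominance_relationship_matrix(trio, A_other)


class TestGeneDrop:
    def test_matches_closed_form_on_trio_and_sibs(self, full_sib_mating):
        gd = gene_drop_relationships(full_sib_mating, n_reps=100_000, seed=11)
        A = additive_relationship_matrix(full_sib_mating)
        # parent-offspring additive value is deterministic under gene drop
        assert gd.additive.loc("o1", "s") == 0.5
        i, j = 2, 3  # the full sibs
        se = gd.dominance_se[i, j]
        assert abs(gd.dominance.values[i, j] - 0.25) < 3 * se
        se_a = gd.additive_se[i, j]
        assert abs(gd.additive.values[i, j] - A.values[i, j]) < 3 * max(se_a, 1e-12)

    def test_deterministic_given_seed(self, trio):
        g1 = gene_drop_relationships(trio, n_reps=2000, seed=5)
        g2 = gene_drop_relationships(trio, n_reps=2000, seed=5)
        assert np.array_equal(g1.additive.values, g2.additive.values)
        assert np.array_equal(g1.dominance.values, g2.dominance.values)

    def test_rejects_bad_rep_count(self, trio):
        with pytest.raises(ValueError):
            gene_drop_relationships(trio, n_reps=0, seed=1)


class TestMatrixProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_psd_and_permutation_invariance(self, random_pedigree_factory, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree_factory(rng)
        A = additive_relationship_matrix(ped)
        D = dominance_relationship_matrix(ped, A)
        assert A.min_eigenvalue() >= -1e-8
        assert D.min_eigenvalue() >= -1e-8

        perm = rng.permutation(len(ped))
        shuffled = topological_order(Pedigree([ped[i] for i in perm]))
        A2 = additive_relationship_matrix(shuffled)
        D2 = dominance_relationship_matrix(shuffled, A2)
        for i in range(0, len(ped), 3):
            for j in range(0, len(ped), 3):
                a, b = ped.ids[i], ped.ids[j]
                assert A2.loc(a, b) == pytest.approx(A.loc(a, b), abs=1e-12)
                assert D2.loc(a, b) == pytest.approx(D.loc(a, b), abs=1e-12)

    def test_no_shared_ancestry_gives_identity(self):
        ped = Pedigree([PedigreeRecord(f"f{i}") for i in range(7)])
        assert np.array_equal(additive_relationship_matrix(ped).values, np.eye(7))
        assert np.array_equal(dominance_relationship_matrix(ped).values, np.eye(7))

    def test_triplet_export(self, full_sib_mating):
        A = additive_relationship_matrix(full_sib_mating)
        trip = A.to_triplets()
        n = len(full_sib_mating)
        assert len(trip) == n * (n + 1) // 2
        row = trip[(trip.row_id == "x") & (trip.col_id == "x")]
        assert row.value.iloc[0] == 1.25
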