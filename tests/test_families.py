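import numpy as np
import pytest

from bacsat import (
    FamilyConfig,
    TandemRepeat,
    assign_codes,
    best_cyclic_score,
    build_families,
    family_consensus,
    progressive_cluster,
    reverse_complement,
    score_matrix,
)
from bacsat.families import RepeatFamily, representative_unit

from conftest import mutate, random_dna
from oracles import best_cyclic_oracle

CFG = FamilyConfig()


def rotate(s, r):
    return s[r:] + s[:r]


def tr_from_unit(unit, start=1, copies=4):
    return TandemRepeat.from_units("g", start, tuple([unit] * copies))


class TestBestCyclicScore:
    def test_self_identity(self):
        u = random_dna(np.random.default_rng(0), 52)
        score, rot, strand = best_cyclic_score(u, u, CFG)
        assert (score, rot, strand) == (1.0, 0, "forward")

    def test_rotation_recovered(self):
        u = random_dna(np.random.default_rng(1), 52)
        score, rot, strand = best_cyclic_score(u, rotate(u, 7), CFG)
        assert score == 1.0
        assert strand == "forward"
        # rotating v by `rot` must reproduce u exactly
        assert rotate(rotate(u, 7), rot) == u

    def test_reverse_complement_strand(self):
        u = random_dna(np.random.default_rng(2), 52)
        score, rot, strand = best_cyclic_score(u, reverse_complement(u), CFG)
        assert score == 1.0
        assert strand == "reverse"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            best_cyclic_score("", "ACGT", CFG)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        u = random_dna(rng, int(rng.integers(20, 61)))
        v = random_dna(rng, int(rng.integers(20, 61)))
        score, _, _ = best_cyclic_score(u, v, CFG)
        assert score == pytest.approx(best_cyclic_oracle(u, v), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(200 + seed)
        u = random_dna(rng, int(rng.integers(20, 50)))
        v = random_dna(rng, int(rng.integers(20, 50)))
        assert best_cyclic_score(u, v, CFG)[0] == best_cyclic_score(v, u, CFG)[0]

    def test_invariant_under_rotation_and_rc(self):
        rng = np.random.default_rng(3)
        u, v = random_dna(rng, 40), random_dna(rng, 40)
        base = best_cyclic_score(u, v, CFG)[0]
        assert best_cyclic_score(rotate(u, 11), v, CFG)[0] == pytest.approx(base)
        assert best_cyclic_score(u, rotate(v, 23), CFG)[0] == pytest.approx(base)
        assert best_cyclic_score(u, reverse_complement(v), CFG)[0] == pytest.approx(base)


class TestScoreMatrix:
    def test_single_repeat(self):
        m = score_matrix([tr_from_unit(random_dna(np.random.default_rng(4), 52))], CFG)
        assert m.shape == (1, 1) and m[0, 0] == 1.0

    def test_identical_repeats(self):
        u = random_dna(np.random.default_rng(5), 52)
        m = score_matrix([tr_from_unit(u) for _ in range(3)], CFG)
        assert np.allclose(m, 1.0)

    def test_matches_oracle_elementwise(self):
        rng = np.random.default_rng(6)
        trs = [tr_from_unit(random_dna(rng, 30)) for _ in range(5)]
        m = score_matrix(trs, CFG)
        reps = [representative_unit(t) for t in trs]
        for i in range(5):
            for j in range(i + 1, 5):
                assert m[i, j] == pytest.approx(
                    best_cyclic_oracle(reps[i], reps[j]), abs=1e-12
                )
        assert np.allclose(m, m.T)


class TestProgressiveCluster:
    def test_all_identical_one_family(self):
        u = random_dna(np.random.default_rng(7), 52)
        trs = [tr_from_unit(u, start=1 + i * 1000) for i in range(5)]
        fams = build_families(trs, CFG)
        assert len(fams) == 1
        assert fams[0].member_count_c == 5

    def test_distinct_units_all_singletons(self):
        rng = np.random.default_rng(8)
        trs = [tr_from_unit(random_dna(rng, 52), start=1 + i * 1000) for i in range(6)]
        fams = build_families(trs, FamilyConfig(similarity_threshold=1.0))
        assert all(f.member_count_c == 1 for f in fams)
        assert len(fams) == 6

    def test_planted_two_families_recovered(self):
        rng = np.random.default_rng(9)
        anc1, anc2 = random_dna(rng, 52), random_dna(rng, 52)
        trs, labels = [], []
        for fam, anc in ((0, anc1), (1, anc2)):
            for i in range(5):
                unit = mutate(rng, anc, 0.08)
                trs.append(tr_from_unit(unit, start=1 + len(trs) * 1000))
                labels.append(fam)
        for j in range(2):
            trs.append(tr_from_unit(random_dna(rng, 52), start=1 + len(trs) * 1000))
            labels.append(2 + j)
        fams = build_families(trs, CFG)
        sizes = sorted(f.member_count_c for f in fams)
        assert sizes == [1, 1, 5, 5]
        # recovered partition equals the planted partition
        from sklearn.metrics import adjusted_rand_score

        id_of = {id(t): i for i, t in enumerate(trs)}
        pred = [0] * len(trs)
        for k, f in enumerate(fams):
            for m in f.members:
                pred[id_of[id(m)]] = k
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_partition_sums_to_input(self, small_planted):
        from bacsat import find_tandem_repeats

        genome, _ = small_planted
        trs = find_tandem_repeats(genome)
        fams = build_families(trs, CFG)
        assert sum(f.member_count_c for f in fams) == len(trs)

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        trs = [tr_from_unit(random_dna(rng, 40), start=1 + i * 500) for i in range(6)]
        a = build_families(trs, CFG)
        b = build_families(trs, CFG)
        assert [(f.code, f.consensus_unit) for f in a] == [
            (f.code, f.consensus_unit) for f in b
        ]


class TestFamilyConsensus:
    def test_identical_units_uppercase(self):
        assert family_consensus(["ACGTACGTAC"] * 4, CFG) == "ACGTACGTAC"

    def test_tied_column_is_n(self):
        members = ["AAAAAAAAAA", "AAAAAAAAAA", "AACAAAAAAA", "AACAAAAAAA"]
        cons = family_consensus(members, CFG)
        assert cons[2] == "n"
        assert cons[0] == "A"

    def test_partial_agreement_lowercase(self):
        # one column at 6/10 agreement -> lowercase
        members = ["AAGAAAAAAA"] * 6 + ["AATAAAAAAA"] * 4
        cons = family_consensus(members, CFG)
        assert cons[2] == "g"

    def test_requires_members(self):
        with pytest.raises(ValueError):
            family_consensus([], CFG)


class TestAssignCodes:
    def _fam(self, c, cons):
        return RepeatFamily(
            rank_a=0,
            consensus_length_b=len(cons),
            member_count_c=c,
            code="",
            members=[],
            consensus_unit=cons,
        )

    def test_rank_by_member_count(self):
        rng = np.random.default_rng(11)
        f = [
            self._fam(35, random_dna(rng, 52)),
            self._fam(139, random_dna(rng, 52)),
            self._fam(18, random_dna(rng, 52)),
        ]
        codes = [x.code for x in assign_codes(f)]
        assert codes == ["1_52_139", "2_52_35", "3_52_18"]

    def test_singleton_code(self):
        f = assign_codes([self._fam(1, "ACGTACGTACG")])
        assert f[0].code == "1_11_1"

    def test_equal_sizes_deterministic(self):
        a = self._fam(5, "AAAAACCCCCGG")
        b = self._fam(5, "AAAAACCCCCT")
        ranked = assign_codes([a, b])
        # longer consensus ranks first on ties
        assert ranked[0].consensus_unit == "AAAAACCCCCGG"
        assert [f.code for f in ranked] == ["1_12_5", "2_11_5"]
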