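import numpy as np
import pytest

from bacsat import (
    AlignConfig,
    Genome,
    MUM,
    PlantSpec,
    ceil_log4,
    cluster_mums,
    derive_strain,
    filter_anchors,
    find_mums,
    find_tandem_repeats,
    generate_genome,
    map_tr_conservation,
    recursive_refine,
    reverse_complement,
)

from conftest import mutate, random_dna
from oracles import find_mums_oracle

CFG = AlignConfig()


def as_tuples(mums):
    return sorted(
        (m.positions[0], m.positions[1], m.length_nt, m.strands[1]) for m in mums
    )


class TestFindMums:
    def test_identical_genomes_single_full_mum(self):
        s = random_dna(np.random.default_rng(0), 500)
        mums = find_mums([Genome("a", s), Genome("b", s)], min_len=20)
        assert len(mums) == 1
        m = mums[0]
        assert m.positions == (1, 1)
        assert m.length_nt == 500
        assert m.strands == ("+", "+")

    def test_reverse_complement_strand_flag(self):
        s = random_dna(np.random.default_rng(1), 500)
        mums = find_mums(
            [Genome("a", s), Genome("b", reverse_complement(s))], min_len=20
        )
        assert len(mums) == 1
        assert mums[0].length_nt == 500
        assert mums[0].strands == ("+", "-")

    def test_requires_two_genomes(self):
        with pytest.raises(ValueError):
            find_mums([Genome("a", "ACGT")], min_len=2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(300, 1200))
        a = random_dna(rng, n)
        if seed % 2:
            b = mutate(rng, a, 0.05)  # related pair: many MUMs
        else:
            b = random_dna(rng, n)  # unrelated pair: few or none
        got = as_tuples(find_mums([Genome("a", a), Genome("b", b)], min_len=8))
        assert got == find_mums_oracle(a, b, 8)

    def test_reported_mums_are_unique_and_maximal(self, small_planted):
        genome, truth = small_planted
        strain, _ = derive_strain(genome, truth, delete_fraction=0.3, seed=1)
        a, b = genome.sequence, strain.sequence
        for m in find_mums([genome, strain], min_len=20)[:5]:
            s = a[m.positions[0] - 1 : m.positions[0] - 1 + m.length_nt]
            for text in (a, b):
                occ = 0
                for hay in (text, reverse_complement(text)):
                    start = 0
                    while (i := hay.find(s, start)) >= 0:
                        occ += 1
                        start = i + 1
                assert occ == 1


class TestFilterAnchors:
    def test_log4_rule_exact_power(self):
        assert ceil_log4(4**11) == 11
        mums = [
            MUM(positions=(1, 1), length_nt=10, strands=("+", "+")),
            MUM(positions=(100, 100), length_nt=11, strands=("+", "+")),
        ]
        kept = filter_anchors(mums, 4**11, AlignConfig(min_anchor_nt=5))
        assert [m.length_nt for m in kept] == [11]

    def test_min_anchor_dominates(self):
        mums = [
            MUM(positions=(1, 1), length_nt=L, strands=("+", "+"))
            for L in (12, 19, 20, 33)
        ]
        kept = filter_anchors(mums, 1000, AlignConfig(min_anchor_nt=20))
        assert [m.length_nt for m in kept] == [20, 33]

    def test_empty(self):
        assert filter_anchors([], 10_000, CFG) == []


class TestRecursiveRefine:
    def test_no_large_gaps_unchanged(self):
        s = random_dna(np.random.default_rng(2), 400)
        genomes = [Genome("a", s), Genome("b", s)]
        anchors = find_mums(genomes, min_len=20)
        assert recursive_refine(genomes, anchors, CFG) == anchors

    def test_planted_block_recovered_in_gap(self):
        rng = np.random.default_rng(3)
        s1, s2 = random_dna(rng, 3000), random_dna(rng, 3000)
        block = random_dna(rng, 15)  # below the anchor threshold
        x = random_dna(rng, 500) + block + random_dna(rng, 500)
        y = random_dna(rng, 480) + block + random_dna(rng, 520)
        a, b = Genome("a", s1 + x + s2), Genome("b", s1 + y + s2)
        anchors = filter_anchors(
            find_mums([a, b], min_len=20), max(a.length_nt, b.length_nt), CFG
        )
        refined = recursive_refine([a, b], anchors, CFG)
        new = [m for m in refined if m not in anchors]
        assert any(
            m.length_nt >= 15
            and a.sequence[m.positions[0] - 1 : m.positions[0] - 1 + m.length_nt].find(
                block
            )
            >= 0
            for m in new
        )

    def test_multiple_planted_blocks(self):
        rng = np.random.default_rng(4)
        s = [random_dna(rng, 2500) for _ in range(6)]
        blocks = [random_dna(rng, 15) for _ in range(5)]
        xa, xb = "", ""
        for i, blk in enumerate(blocks):
            xa += s[i] + random_dna(rng, 300) + blk + random_dna(rng, 300)
            xb += s[i] + random_dna(rng, 310) + blk + random_dna(rng, 290)
        a, b = Genome("a", xa + s[5]), Genome("b", xb + s[5])
        anchors = filter_anchors(
            find_mums([a, b], min_len=20), max(a.length_nt, b.length_nt), CFG
        )
        refined = recursive_refine([a, b], anchors, CFG)
        found_blocks = 0
        for blk in blocks:
            if any(
                blk
                in a.sequence[m.positions[0] - 1 : m.positions[0] - 1 + m.length_nt]
                for m in refined
            ):
                found_blocks += 1
        assert found_blocks == 5


class TestClusterMums:
    def _mum(self, pa, pb, L=50):
        return MUM(positions=(pa, pb), length_nt=L, strands=("+", "+"))

    def test_close_mums_one_cluster(self):
        clusters = cluster_mums([self._mum(1, 1), self._mum(1551, 1551)], CFG)
        assert len(clusters) == 1

    def test_distant_mums_two_clusters(self):
        clusters = cluster_mums([self._mum(1, 1), self._mum(2551, 2551)], CFG)
        assert len(clusters) == 2

    def test_transitive_chaining(self):
        ms = [self._mum(1, 1), self._mum(1951, 1951), self._mum(3901, 3901)]
        clusters = cluster_mums(ms, CFG)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_partition(self):
        ms = [self._mum(1 + i * 1200, 1 + i * 1200) for i in range(5)]
        clusters = cluster_mums(ms, CFG)
        assert sum(len(c.members) for c in clusters) == 5


class TestConservation:
    def _pipeline(self, a, b, trs_a, trs_b):
        mums = find_mums([a, b], min_len=20)
        anchors = filter_anchors(mums, max(a.length_nt, b.length_nt), CFG)
        refined = recursive_refine([a, b], anchors, CFG)
        clusters = cluster_mums(refined, CFG)
        return map_tr_conservation([a, b], [trs_a, trs_b], clusters)

    def test_identical_strains_all_shared(self, small_planted):
        genome, _ = small_planted
        from dataclasses import replace

        clone = Genome("clone", genome.sequence)
        trs = find_tandem_repeats(genome)
        trs_b = [replace(tr, genome_id="clone") for tr in trs]
        df = self._pipeline(genome, clone, trs, trs_b)
        mine = df[df.genome_id == genome.id]
        assert (mine.status == "shared").all()
        assert (mine.length_ratio == 1.0).all()

    def test_deleted_arrays_become_strain_specific(self, small_planted):
        genome, truth = small_planted
        strain, truth_b = derive_strain(genome, truth, delete_fraction=0.3, seed=1)
        trs_a = find_tandem_repeats(genome)
        trs_b = find_tandem_repeats(strain)
        df = self._pipeline(genome, strain, trs_a, trs_b)
        mine = df[df.genome_id == genome.id]
        n_deleted = len(truth.arrays) - len(truth_b.arrays)
        assert (mine.status == "strain_specific").sum() == n_deleted
        assert (mine.status == "shared").sum() == len(truth.arrays) - n_deleted

    def test_truncated_array_length_ratio(self):
        # all arrays have 10 copies so a halved array is still detectable
        spec = PlantSpec(
            n_arrays=5, genome_length_nt=80_000, seed=21, copy_range=(10, 10)
        )
        genome, truth = generate_genome(spec)
        strain, truth_b = derive_strain(
            genome, truth, truncate_fraction=1.0 / len(truth.arrays), seed=5
        )
        trs_a = find_tandem_repeats(genome)
        trs_b = find_tandem_repeats(strain)
        df = self._pipeline(genome, strain, trs_a, trs_b)
        mine = df[df.genome_id == genome.id]
        assert (mine.status == "shared").all()
        ratios = sorted(mine.length_ratio)
        assert ratios[0] == pytest.approx(0.5, abs=0.15)
        assert all(r == pytest.approx(1.0) for r in ratios[1:])
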