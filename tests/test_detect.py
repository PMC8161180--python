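import numpy as np
import pytest

from bacsat import (
    DetectionConfig,
    Genome,
    PlantSpec,
    TandemRepeat,
    extend_tandem,
    filter_regularity,
    find_seed_clusters,
    find_tandem_repeats,
    generate_genome,
    similarity_score,
)
from bacsat.detect import is_micro_periodic

from conftest import embed_array, random_dna

CFG = DetectionConfig()


def _unique_background(rng, n):
    """Random DNA re-drawn until no 10-mer recurs (for small n)."""
    while True:
        s = random_dna(rng, n)
        kmers = [s[i : i + 10] for i in range(len(s) - 9)]
        if len(set(kmers)) == len(kmers):
            return s


def make_unit(rng, p):
    while True:
        u = random_dna(rng, p)
        kmers = [(u + u)[i : i + 10] for i in range(p)]
        if not is_micro_periodic(u) and len(set(kmers)) == len(kmers):
            return u


class TestSeedClusters:
    def test_planted_seed_cluster_found(self):
        rng = np.random.default_rng(0)
        seed = make_unit(rng, 10)
        bg = _unique_background(rng, 760)
        seq = bg[:100] + seed + bg[100:300] + seed + bg[300:400] + seed + bg[400:500] + seed + bg[500:]
        clusters = find_seed_clusters(seq, CFG)
        assert any(c.seed == seed for c in clusters)

    def test_all_unique_kmers_no_clusters(self):
        rng = np.random.default_rng(1)
        seq = _unique_background(rng, 800)
        assert find_seed_clusters(seq, CFG) == []

    def test_micro_periodic_seed_excluded(self):
        # "ATATATATAT" repeated 6x is a period-2 micro-repeat
        seq = "ATATATATAT" * 6 + random_dna(np.random.default_rng(2), 500)
        assert all(c.seed != "ATATATATAT" for c in find_seed_clusters(seq, CFG))

    def test_window_constraint(self):
        # 4 occurrences spread over >> 800 nt: no cluster at multiplicity 4
        rng = np.random.default_rng(3)
        seed = make_unit(rng, 10)
        parts = [random_dna(rng, 2000) for _ in range(5)]
        seq = parts[0]
        for p in parts[1:]:
            seq += seed + p
        cfg = DetectionConfig(seed_min_occurrences=4)
        assert all(c.seed != seed for c in find_seed_clusters(seq, cfg))


class TestExtendTandem:
    def _detect_single(self, seq):
        trs = find_tandem_repeats(Genome("g", seq), CFG)
        assert len(trs) == 1
        return trs[0]

    def test_exact_copies(self):
        rng = np.random.default_rng(4)
        u = make_unit(rng, 52)
        seq = embed_array(random_dna(rng, 900), [u] * 6, random_dna(rng, 900))
        tr = self._detect_single(seq)
        assert (tr.period_nt, tr.n_repeats, tr.homogeneity) == (52, 6, 1.0)

    def test_no_upper_copy_limit(self):
        rng = np.random.default_rng(5)
        u = make_unit(rng, 52)
        seq = embed_array(random_dna(rng, 900), [u] * 37, random_dna(rng, 900))
        tr = self._detect_single(seq)
        assert tr.n_repeats == 37
        assert tr.length_nt > 1900

    def test_one_copy_with_deletion(self):
        rng = np.random.default_rng(6)
        u = make_unit(rng, 52)
        u_del = u[:20] + u[21:]  # 1-nt deletion
        seq = embed_array(random_dna(rng, 900), [u, u, u_del, u], random_dna(rng, 900))
        tr = self._detect_single(seq)
        assert tr.n_repeats == 4
        assert tr.ni == 3
        assert tr.homogeneity == 1.0  # 51 nt is within +/-1 of the mode


class TestFilterRegularity:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([52] * 6, True),
            ([40] * 7 + [52] * 3, True),  # 7/10 = 0.7 >= 0.6
            ([52, 51, 40, 30, 20], False),  # modal +/-1 covers 2/5
        ],
    )
    def test_decisions(self, lengths, expected):
        rng = np.random.default_rng(7)
        units = tuple(random_dna(rng, L) for L in lengths)
        tr = TandemRepeat.from_units("g", 1, units)
        assert filter_regularity(tr, CFG) is expected


class TestSimilarityScore:
    def _tr(self, units):
        return TandemRepeat.from_units("g", 1, tuple(units))

    def test_identical_units(self):
        assert similarity_score(self._tr(["ACGTACGTGG"] * 5)) == 1.0

    def test_one_divergent_unit(self):
        u = "ACGTACGTGG"
        v = u[:3] + "A" + u[4:8] + "C" + u[9:]  # differs at 2 of 10 columns
        assert v != u and len(v) == 10
        score = similarity_score(self._tr([u, u, u, v]))
        assert score == pytest.approx((8 * 1.0 + 2 * 0.75) / 10)

    def test_even_split(self):
        score = similarity_score(self._tr(["AAAA", "AAAA", "TTTT", "TTTT"]))
        assert score == pytest.approx(0.5)

    def test_single_modal_unit_undefined(self):
        tr = self._tr(["ACGTACGTGG", "ACGTACGTG", "ACGTACGTACG"])
        assert similarity_score(tr) is None


class TestFindTandemRepeats:
    def test_random_genome_empty(self):
        rng = np.random.default_rng(8)
        g = Genome("r", random_dna(rng, 100_000))
        assert find_tandem_repeats(g, CFG) == []

    def test_planted_arrays_recovered_exactly(self, small_planted):
        genome, truth = small_planted
        trs = find_tandem_repeats(genome, CFG)
        got = [(t.start_nt, t.end_nt, t.period_nt, t.n_repeats) for t in trs]
        want = [(a.start_nt, a.end_nt, a.period_nt, a.copies) for a in truth.arrays]
        assert got == want

    def test_flank_shift_invariance(self):
        rng = np.random.default_rng(9)
        u = make_unit(rng, 52)
        core = embed_array(random_dna(rng, 900), [u] * 6, random_dna(rng, 900))
        base = find_tandem_repeats(Genome("g", core), CFG)
        shift = 1234
        padded = find_tandem_repeats(
            Genome("g", random_dna(rng, shift) + core + random_dna(rng, 800)), CFG
        )
        assert len(base) == len(padded) == 1
        assert padded[0].start_nt == base[0].start_nt + shift
        assert padded[0].units == base[0].units

    def test_monotonic_in_min_repeats(self, small_planted):
        genome, _ = small_planted
        counts = [
            len(find_tandem_repeats(genome, DetectionConfig(min_repeats=m)))
            for m in (4, 6, 8, 12)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_overlaps_and_sorted(self, small_planted):
        genome, _ = small_planted
        trs = find_tandem_repeats(genome, CFG)
        for a, b in zip(trs, trs[1:]):
            assert a.end_nt < b.start_nt

    def test_units_concatenate_to_substring(self, small_planted):
        genome, _ = small_planted
        for tr in find_tandem_repeats(genome, CFG):
            assert "".join(tr.units) == genome.sequence[tr.start_nt - 1 : tr.end_nt]
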