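"""Tandem-repeat detection.

The search works the way satellite finders built on exact seed words do:

1. every 10-mer (the minimum repeat length) of the genome is hashed and
   positions where the same word recurs at least ``min_repeats`` times
   within a sliding window of ``window_nt`` consecutive positions become
   candidate loci (:func:`find_seed_clusters`);
2. each candidate is extended outwards one unit at a time for as long as
   the next adjacent unit still aligns to the running consensus of the
   array (:func:`extend_tandem`), with no upper limit on the number of
   copies;
3. arrays whose unit lengths are too irregular are discarded: at least
   60% of the units must share the modal unit length to within +/-1 nt
   (:func:`filter_regularity`).

Seeds that are themselves perfect tandems of a 1-5 nt motif are eliminated
up front, so microsatellites never surface; a unit shorter than the 10-nt
seed instead appears at a multiple of its true period (a 7-nt unit is
reported with a 14-nt period).

Each accepted array carries two regularity statistics: ``homogeneity``
(fraction of units within +/-1 nt of the modal length; always >= 0.6 after
filtering) and ``ni``, the number of units with exactly the modal length.
The ``similarity_score`` is the mean column agreement over the positional
alignment of those ``ni`` equal-length units (1.0 means identical copies).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .io_formats import Genome

__all__ = [
    "DetectionConfig",
    "TandemRepeat",
    "SeedCluster",
    "find_seed_clusters",
    "extend_tandem",
    "filter_regularity",
    "similarity_score",
    "find_tandem_repeats",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Search parameters.

    Defaults target short tandem repeats with at least four copies inside
    an 800-nt region, unit length 10-270 nt, and the 60% / +/-1 nt length
    regularity filter.
    """

    min_unit_nt: int = 10
    max_unit_nt: int = 270
    min_repeats: int = 4
    window_nt: int = 800
    min_length_fraction: float = 0.6
    length_tolerance_nt: int = 1
    micro_period_max: int = 5
    #: minimum occurrences of a seed word within one window to open a
    #: candidate locus.  Defaults to ``min_repeats - 1`` (at least 2): an
    #: array at the minimum copy number stays seedable even when one copy
    #: has diverged past exact seed identity; the >= min_repeats
    #: constraint still applies to the extended array.
    seed_min_occurrences: Optional[int] = None
    #: minimum normalized alignment score (+1/-1/-2 scheme, divided by the
    #: unit length) for an adjacent unit to be absorbed during extension.
    extension_min_score: float = 0.5
    #: a unit scoring in [extension_weak_score, extension_min_score) is
    #: still absorbed when the unit beyond it scores strongly again —
    #: periodicity resuming marks a genuine but diverged internal copy.
    extension_weak_score: float = 0.0

    def __post_init__(self) -> None:
        if self.min_unit_nt < 2:
            raise ValueError("min_unit_nt must be >= 2")
        if self.max_unit_nt < self.min_unit_nt:
            raise ValueError("max_unit_nt must be >= min_unit_nt")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")

    @property
    def seed_occurrences(self) -> int:
        if self.seed_min_occurrences is not None:
            return self.seed_min_occurrences
        return max(2, self.min_repeats - 1)


def _modal_length(lengths: Sequence[int]) -> int:
    """Most common length; ties broken toward the smaller value."""
    counts = Counter(lengths)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


@dataclass(frozen=True)
class TandemRepeat:
    """A located array of consecutive repeat units.

    The concatenation of ``units`` equals the genome substring
    ``[start_nt, end_nt]`` (1-based, inclusive).  ``period_nt`` is the
    modal unit length; individual unit lengths may differ by indels.
    """

    genome_id: str
    start_nt: int
    period_nt: int
    units: Tuple[str, ...]
    ni: int
    homogeneity: float
    similarity_score: Optional[float]

    @property
    def n_repeats(self) -> int:
        return len(self.units)

    @property
    def end_nt(self) -> int:
        return self.start_nt + sum(len(u) for u in self.units) - 1

    @property
    def length_nt(self) -> int:
        return self.end_nt - self.start_nt + 1

    @staticmethod
    def from_units(
        genome_id: str,
        start_nt: int,
        units: Sequence[str],
        length_tolerance_nt: int = 1,
    ) -> "TandemRepeat":
        """Build a repeat from its units, deriving all statistics."""
        units = tuple(units)
        lengths = [len(u) for u in units]
        modal = _modal_length(lengths)
        ni = sum(1 for L in lengths if L == modal)
        homog = (
            sum(1 for L in lengths if abs(L - modal) <= length_tolerance_nt)
            / len(units)
        )
        modal_units = [u for u in units if len(u) == modal]
        sim = _column_agreement(modal_units) if ni >= 2 else None
        return TandemRepeat(
            genome_id=genome_id,
            start_nt=start_nt,
            period_nt=modal,
            units=units,
            ni=ni,
            homogeneity=homog,
            similarity_score=sim,
        )


@dataclass(frozen=True)
class SeedCluster:
    """A candidate locus: a seed word recurring within one window."""

    position: int  #: 0-based offset of the first seed occurrence in the run
    seed: str
    occurrences: Tuple[int, ...]  #: 0-based offsets of the clustered run


def is_micro_periodic(seq: str, micro_period_max: int = 5) -> bool:
    """True if ``seq`` repeats with period <= micro_period_max.

    Uses the stringological notion of a period (``seq[i] == seq[i - p]``
    for all ``i >= p``), so partial trailing copies count too.
    """
    n = len(seq)
    for p in range(1, min(micro_period_max, n - 1) + 1):
        if all(seq[i] == seq[i - p] for i in range(p, n)):
            return True
    return False


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def find_seed_clusters(sequence: str, config: DetectionConfig = DetectionConfig()) -> List[SeedCluster]:
    """Locate clusters of repeated seed words.

    A seed is the ``min_unit_nt``-mer starting at each position (skipping
    any containing ambiguity characters, and any that is a perfect tandem
    of a 1-5 nt motif).  A cluster is reported whenever
    ``config.seed_occurrences`` occurrences of the same seed fall within
    ``window_nt`` consecutive positions; sequences shorter than the window
    are treated as a single window.  One cluster is reported per
    qualifying run of occurrences.
    """
    k = config.min_unit_nt
    n = len(sequence)
    if n < k:
        return []
    codes = _encode(sequence)
    n_kmers = n - k + 1
    keys = np.zeros(n_kmers, dtype=np.uint64)
    valid = np.ones(n_kmers, dtype=bool)
    for j in range(k):
        col = codes[j : j + n_kmers]
        valid &= col < 4
        keys = keys * np.uint64(4) + col.astype(np.uint64)
    positions = np.nonzero(valid)[0]
    if positions.size == 0:
        return []
    keys = keys[valid]
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    pos_sorted = positions[order]
    # group boundaries of equal keys
    boundaries = np.nonzero(np.diff(keys_sorted))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [keys_sorted.size]))
    m = config.seed_occurrences
    span = config.window_nt - k  # max distance between first/last seed starts
    clusters: List[SeedCluster] = []
    for s, e in zip(starts, ends):
        if e - s < m:
            continue
        occ = np.sort(pos_sorted[s:e])
        within = occ[m - 1 :] - occ[: occ.size - m + 1] <= span
        if not within.any():
            continue
        seed = sequence[occ[0] : occ[0] + k]
        if is_micro_periodic(seed, config.micro_period_max):
            continue
        # one cluster per maximal run of window-compatible occurrences
        i = 0
        while i < within.size:
            if within[i]:
                j = i
                while j < within.size and within[j]:
                    j += 1
                # occurrences occ[i] .. occ[j-1+m-1] form one run
                run = occ[i : j + m - 1]
                clusters.append(
                    SeedCluster(
                        position=int(run[0]),
                        seed=seed,
                        occurrences=tuple(int(x) for x in run),
                    )
                )
                i = j
            else:
                i += 1
    clusters.sort(key=lambda c: (c.position, c.seed))
    return clusters


# ---------------------------------------------------------------------------
# Extension
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -2.0
    al.extend_gap_score = -2.0
    return al


_EXT_ALIGNER = _aligner()


def _norm_score(u: str, v: str) -> float:
    """Global alignment score normalized by the shorter length."""
    if not u or not v:
        return -1.0
    return _EXT_ALIGNER.score(u, v) / min(len(u), len(v))


def _majority_consensus(units: Sequence[str]) -> str:
    """Positional majority over equal-length strings (first-seen tie-break)."""
    if len(units) == 1:
        return units[0]
    out = []
    for col in zip(*units):
        counts = Counter(col)
        out.append(max(counts.items(), key=lambda kv: kv[1])[0])
    return "".join(out)


def _column_agreement(units: Sequence[str]) -> float:
    """Mean over columns of the frequency of the most common base."""
    n = len(units)
    cols = list(zip(*units))
    return sum(max(Counter(c).values()) / n for c in cols) / len(cols)


def _best_adjacent_unit(
    sequence: str,
    pos: int,
    ref: str,
    direction: int,
) -> Optional[Tuple[str, float]]:
    """Best-scoring unit adjacent to ``pos`` (direction +1 right, -1 left).

    Tries unit lengths within +/-2 nt of the reference length so copies
    carrying small indels keep the tiling in frame.  Returns the unit and
    its normalized score, or ``None`` at the sequence boundary.
    """
    p = len(ref)
    best: Optional[Tuple[float, int, str]] = None
    for L in range(max(1, p - 2), p + 3):
        if direction > 0:
            cand = sequence[pos : pos + L]
        else:
            cand = sequence[pos - L : pos]
        if len(cand) != L:
            continue
        score = _EXT_ALIGNER.score(ref, cand) / p
        # prefer the reference length on ties
        key = (score, -abs(L - p))
        if best is None or key > (best[0], -abs(best[1] - p)):
            best = (score, L, cand)
    if best is None:
        return None
    return best[2], best[0]


def _extend_at_period(
    sequence: str,
    anchor: int,
    period: int,
    config: DetectionConfig,
    cohort: Sequence[int] = (),
) -> Optional[Tuple[int, List[str]]]:
    """Tile units of ~``period`` nt outwards from ``anchor``.

    Returns the 0-based start and the unit list, or ``None`` when the
    first unit does not fit.  Growth continues while the adjacent unit
    aligns to the running modal-unit consensus at normalized score >=
    ``extension_min_score``.  ``cohort`` positions (the other seed
    occurrences, which share the anchor's phase) contribute slices to the
    reference consensus so that a single diverged anchor copy does not
    derail extension.
    """
    first = sequence[anchor : anchor + period]
    if len(first) < period:
        return None
    units: List[str] = [first]
    prior: List[str] = [
        sequence[o : o + period]
        for o in cohort
        if o != anchor and o + period <= len(sequence)
    ]

    def grow(pos: int, direction: int) -> Tuple[int, List[str]]:
        """Absorb units in one direction; weak units (score in the
        [weak, strong) band) are kept only when the unit beyond them
        scores strongly again."""
        grown: List[str] = []
        while 0 < pos < len(sequence):
            pool = units + grown + prior
            modal = _modal_length([len(x) for x in pool])
            ref = _majority_consensus([u for u in pool if len(u) == modal])
            res = _best_adjacent_unit(sequence, pos, ref, direction)
            if res is None:
                break
            cand, score = res
            if score >= config.extension_min_score:
                grown.append(cand)
                pos += direction * len(cand)
                continue
            if score >= config.extension_weak_score:
                ahead = pos + direction * len(cand)
                nxt = (
                    _best_adjacent_unit(sequence, ahead, ref, direction)
                    if 0 < ahead < len(sequence)
                    else None
                )
                if nxt is not None and nxt[1] >= config.extension_min_score:
                    grown.append(cand)
                    pos += direction * len(cand)
                    continue
            break
        return pos, grown

    _, right = grow(anchor + period, +1)
    units.extend(right)
    start, left = grow(anchor, -1)
    units[:0] = reversed(left)
    return start, units


def _mean_unit_score(units: Sequence[str]) -> float:
    """Mean normalized alignment score of the modal-length units against
    their own majority consensus.  Distinguishes a genuine finer period
    (units are mutually similar) from an artificial fold of unrelated
    sub-units."""
    modal = _modal_length([len(u) for u in units])
    modal_units = [u for u in units if len(u) == modal]
    cons = _majority_consensus(modal_units)
    return sum(_EXT_ALIGNER.score(cons, u) / modal for u in modal_units) / len(
        modal_units
    )


def _polish_boundaries(
    sequence: str, start0: int, units: List[str], config: DetectionConfig
) -> Tuple[int, List[str]]:
    """Snap array boundaries to the maximal periodic extent and re-tile.

    A seed can anchor the unit tiling out of phase with the true array
    boundary (e.g. when the same word also occurs by chance in the
    flanking background), leaving hybrid background/copy units at the
    ends.  The true boundary is recovered at base resolution: a position
    belongs to the array when it sits in a run of consecutive positions
    matching the sequence one period away.  Units are then re-tiled from
    the polished start (adaptive +/-2 nt lengths, so indel-carrying
    copies stay in frame).  Falls back to the input tiling when no
    periodic run is found.
    """
    p = _modal_length([len(u) for u in units])
    run = min(10, p)
    n = len(sequence)
    total = sum(len(u) for u in units)
    end_excl = start0 + total

    def periodic_fwd(x: int) -> bool:
        return x + p < n and sequence[x] == sequence[x + p]

    def periodic_back(x: int) -> bool:
        return x - p >= 0 and sequence[x] == sequence[x - p]

    # left boundary: first position opening a run of `run` periodic matches
    s = None
    for cand in range(start0, min(start0 + len(units[0]), end_excl - run) + 1):
        if all(periodic_fwd(x) for x in range(cand, cand + run)):
            s = cand
            break
    # right boundary: last position closing a periodic run
    t = None
    lo = max(end_excl - len(units[-1]), start0 + run)
    for cand in range(end_excl, lo - 1, -1):
        if all(periodic_back(x) for x in range(cand - run, cand)):
            t = cand
            break
    if s is None or t is None or t - s < 2 * p:
        return start0, units
    # single-base maximal extension (bounded by one period per side)
    grown = 0
    while s > 0 and grown < p and sequence[s - 1] == sequence[s - 1 + p]:
        s -= 1
        grown += 1
    grown = 0
    while t < n and grown < p and sequence[t] == sequence[t - p]:
        t += 1
        grown += 1

    # re-tile from the polished boundaries
    new_units: List[str] = []
    pos = s
    while pos < t:
        remaining = t - pos
        if remaining < p - 2 and new_units:
            new_units[-1] += sequence[pos:t]
            break
        if not new_units:
            L = min(p, remaining)
        else:
            modal = _modal_length([len(u) for u in new_units])
            ref = _majority_consensus(
                [u for u in new_units if len(u) == modal]
            )
            best_L, best_score = None, -np.inf
            for L_try in range(max(1, p - 2), p + 3):
                if L_try > remaining:
                    continue
                sc = _EXT_ALIGNER.score(ref, sequence[pos : pos + L_try]) / p
                if (sc, -abs(L_try - p)) > (
                    best_score,
                    -abs((best_L or p) - p),
                ):
                    best_L, best_score = L_try, sc
            L = best_L if best_L is not None else remaining
        new_units.append(sequence[pos : pos + L])
        pos += L
    if len(new_units) < config.min_repeats:
        return start0, units
    return s, new_units


def extend_tandem(
    sequence: str,
    locus: SeedCluster,
    config: DetectionConfig = DetectionConfig(),
) -> Optional[TandemRepeat]:
    """Extend a seed cluster into a full tandem array.

    The period is first estimated as the modal spacing between consecutive
    seed occurrences (ties toward the smaller spacing).  Because divergence
    can wipe the seed out of adjacent copies, the modal spacing may be a
    harmonic of the true period; after extension the array is therefore
    re-tiled at every integer sub-multiple of the period (smallest first)
    and the refold is kept when it reproduces the array at the finer
    period.  Returns ``None`` when the period falls outside the configured
    range, the final modal unit is micro-periodic, or fewer than
    ``min_repeats`` units are found.
    """
    occ = locus.occurrences
    if len(occ) < 2:
        return None
    gaps = [occ[i + 1] - occ[i] for i in range(len(occ) - 1)]
    gaps = [g for g in gaps if g >= 2]
    if not gaps:
        return None
    modal_gap = _modal_length(gaps)  # modal value, ties -> smaller
    # under divergence the seed drops out of some copies, so the modal
    # spacing may be a harmonic of the fundamental period; the smallest
    # observed spacing is a second candidate
    candidates = sorted(
        {
            p
            for p in (modal_gap, min(gaps))
            if config.min_unit_nt <= p <= config.max_unit_nt
        }
    )
    if not candidates:
        return None
    best_tr: Optional[TandemRepeat] = None
    for period in candidates:
        tr = _extend_tandem_at(sequence, occ, period, config)
        if tr is None:
            continue
        key = (filter_regularity(tr, config), tr.length_nt, tr.n_repeats)
        if best_tr is None or key > (
            filter_regularity(best_tr, config),
            best_tr.length_nt,
            best_tr.n_repeats,
        ):
            best_tr = tr
    return best_tr


def _extend_tandem_at(
    sequence: str,
    occ: Sequence[int],
    period: int,
    config: DetectionConfig,
) -> Optional[TandemRepeat]:
    """Extension + harmonic refold + boundary polish at one candidate
    period."""

    def in_phase(o: int, o2: int, q: int) -> bool:
        # |o - o2| within indel slack of a multiple of q
        d = abs(o - o2)
        k = round(d / q)
        return k > 0 and abs(d - k * q) <= 2 * max(1, k // 4) + 2

    # anchor at the occurrence with the most in-phase partners (central on
    # ties): the first occurrence can be a chance hit outside the array
    center = occ[len(occ) // 2]
    ranked = sorted(
        occ,
        key=lambda o: (
            -sum(in_phase(o, o2, period) for o2 in occ),
            abs(o - center),
        ),
    )
    for anchor in ranked[:3]:
        tr = _try_extend_anchor(sequence, occ, anchor, period, config, in_phase)
        if tr is not None:
            return tr
    return None


def _try_extend_anchor(
    sequence: str,
    occ: Sequence[int],
    anchor: int,
    period: int,
    config: DetectionConfig,
    in_phase,
) -> Optional[TandemRepeat]:

    def phase_cohort(q: int) -> List[int]:
        return [o for o in occ if in_phase(o, anchor, q)]

    res = _extend_at_period(sequence, anchor, period, config, phase_cohort(period))
    if res is None:
        return None
    start, units = res
    span = sum(len(u) for u in units)
    # refold at the fundamental period if the modal spacing was a harmonic
    if period >= 2 * config.min_unit_nt and len(units) >= 2:
        base_mean = _mean_unit_score(units)
        for k in range(period // config.min_unit_nt, 1, -1):
            q = round(period / k)
            if q < config.min_unit_nt or abs(q * k - period) > k:
                continue
            res_q = _extend_at_period(sequence, anchor, q, config, phase_cohort(q))
            if res_q is None:
                continue
            start_q, units_q = res_q
            span_q = sum(len(u) for u in units_q)
            fold = TandemRepeat.from_units(
                "", start_q + 1, units_q, config.length_tolerance_nt
            )
            # span guard against a collapsed fold; one coarse unit of
            # slack because the coarse tiling's boundary units can
            # overshoot into background
            if (
                len(units_q) >= config.min_repeats
                and span_q >= 0.8 * (span - period)
                and filter_regularity(fold, config)
                # a genuine finer period preserves the per-base unit
                # similarity; folding unrelated sub-units degrades it
                and _mean_unit_score(units_q)
                >= max(config.extension_min_score, base_mean - 0.1)
            ):
                start, units = start_q, units_q
                break

    if len(units) < config.min_repeats:
        return None
    start, units = _polish_boundaries(sequence, start, units, config)
    if len(units) < config.min_repeats:
        return None
    tr = TandemRepeat.from_units(
        genome_id="",
        start_nt=start + 1,
        units=units,
        length_tolerance_nt=config.length_tolerance_nt,
    )
    if tr.period_nt < config.min_unit_nt or tr.period_nt > config.max_unit_nt:
        return None
    modal_units = [u for u in tr.units if len(u) == tr.period_nt]
    if is_micro_periodic(_majority_consensus(modal_units), config.micro_period_max):
        return None
    return tr


def filter_regularity(tr: TandemRepeat, config: DetectionConfig = DetectionConfig()) -> bool:
    """Accept arrays whose homogeneity meets ``min_length_fraction``.

    Homogeneity counts units whose length is within
    ``length_tolerance_nt`` of the modal unit length.
    """
    lengths = [len(u) for u in tr.units]
    modal = _modal_length(lengths)
    homog = sum(
        1 for L in lengths if abs(L - modal) <= config.length_tolerance_nt
    ) / len(lengths)
    return homog >= config.min_length_fraction


def similarity_score(tr: TandemRepeat) -> Optional[float]:
    """Column-agreement score over the ``ni`` modal-length units.

    Equal-length units are stacked positionally (no gaps needed); the score
    is the mean over columns of the most common base's frequency.  ``None``
    when fewer than two modal-length units exist.
    """
    modal_units = [u for u in tr.units if len(u) == tr.period_nt]
    if len(modal_units) < 2:
        return None
    return _column_agreement(modal_units)


def _merge_overlaps(trs: List[TandemRepeat]) -> List[TandemRepeat]:
    """Keep one representative per set of overlapping detections.

    The representative is the detection with the most units (ties: smaller
    period, then leftmost start).
    """
    trs = sorted(trs, key=lambda t: (t.start_nt, t.end_nt))
    kept: List[TandemRepeat] = []
    for tr in trs:
        if kept and tr.start_nt <= kept[-1].end_nt:
            prev = kept[-1]
            better = (tr.n_repeats, -tr.period_nt, -tr.start_nt) > (
                prev.n_repeats,
                -prev.period_nt,
                -prev.start_nt,
            )
            if better:
                kept[-1] = tr
        else:
            kept.append(tr)
    return kept


def find_tandem_repeats(
    genome: Genome, config: DetectionConfig = DetectionConfig()
) -> List[TandemRepeat]:
    """Full detection pipeline on one genome.

    Seed clustering, extension, regularity filtering and overlap merging;
    output sorted by start coordinate.  Every emitted repeat satisfies all
    :class:`DetectionConfig` constraints.
    """
    clusters = find_seed_clusters(genome.sequence, config)
    found: List[TandemRepeat] = []
    covered: List[Tuple[int, int]] = []  # 0-based spans already explained
    for cl in clusters:
        if any(a <= cl.position < b for a, b in covered):
            continue
        tr = extend_tandem(genome.sequence, cl, config)
        if tr is None or not filter_regularity(tr, config):
            continue
        tr = TandemRepeat(
            genome_id=genome.id,
            start_nt=tr.start_nt,
            period_nt=tr.period_nt,
            units=tr.units,
            ni=tr.ni,
            homogeneity=tr.homogeneity,
            similarity_score=tr.similarity_score,
        )
        found.append(tr)
        covered.append((tr.start_nt - 1, tr.end_nt))
    merged = _merge_overlaps(found)
    merged.sort(key=lambda t: t.start_nt)
    return merged
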