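"""Synthetic genomes with planted tandem-repeat structure.

Every pipeline stage is exercised against genomes whose repeat content is
known exactly.  A genome is i.i.d. random background of configurable GC
content into which tandem arrays are planted: unit periods concentrate at
20-21 and 51-53 nt (the two constant-length classes observed in
*Bacillus*), with a minority class of multiple-of-three periods standing
in for coding repeats; copy numbers span 4-37 (most arrays short, a few
long); copies diverge from their family ancestor by per-base substitution
and optional +/-1 nt indels.  Arrays from the same family share one
ancestor unit, optionally carrying a short signal motif at a fixed unit
offset.  Arrays are separated by at least 1000 nt of background and never
overlap.

:func:`derive_strain` models strain turnover: a subset of arrays is
deleted or truncated to half its copies and new arrays are inserted,
while all non-repeat background is left untouched so MUM anchoring still
works between the strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .detect import is_micro_periodic
from .io_formats import Genome

__all__ = ["PlantSpec", "PlantedArray", "PlantedTruth", "generate_genome", "derive_strain"]

#: minimum background separation between planted arrays (nt)
MIN_GAP_NT = 1000

_PERIOD_CLASSES = (20, 21, 52, 0)  # 0 = "other" (drawn per-array)


@dataclass(frozen=True)
class PlantSpec:
    """Conditions for one synthetic genome."""

    n_arrays: int = 12
    #: weights over the period classes {20, 21, 52, other}
    period_weights: Tuple[float, float, float, float] = (0.15, 0.15, 0.55, 0.15)
    copy_range: Tuple[int, int] = (4, 37)
    divergence: float = 0.0  #: per-base substitution probability per copy
    indel_prob: float = 0.0  #: per-copy probability of a +/-1 nt length change
    n_families: int = 4
    signal_motif: Optional[str] = None
    signal_families: Tuple[int, ...] = (0,)
    background_gc: float = 0.40
    genome_length_nt: int = 1_000_000
    seed: int = 0


@dataclass(frozen=True)
class PlantedArray:
    start_nt: int  # 1-based, inclusive
    end_nt: int
    period_nt: int
    copies: int
    family: int
    ancestor: str


@dataclass(frozen=True)
class PlantedTruth:
    arrays: Tuple[PlantedArray, ...]
    signal_motif: Optional[str] = None


class CapacityError(ValueError):
    """Genome too short for the requested number of arrays."""


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _random_unit(rng: np.random.Generator, period: int, gc: float) -> str:
    """Ancestor unit screened against micro-periodicity and internal
    repeated 10-mers (so seed spacings reflect the true period)."""
    while True:
        unit = b"".join(_random_background(rng, period, gc)).decode()
        if is_micro_periodic(unit, 5):
            continue
        doubled = unit + unit  # internal repeats checked cyclically
        kmers = [doubled[i : i + 10] for i in range(period)]
        if len(set(kmers)) == len(kmers):
            return unit


def _mutate_copy(
    rng: np.random.Generator, unit: str, divergence: float, indel_prob: float
) -> str:
    bases = "ACGT"
    chars = list(unit)
    if divergence > 0:
        hits = np.nonzero(rng.random(len(chars)) < divergence)[0]
        for i in hits:
            alternatives = [b for b in bases if b != chars[i]]
            chars[i] = alternatives[rng.integers(3)]
    if indel_prob > 0 and rng.random() < indel_prob:
        if rng.random() < 0.5 and len(chars) > 2:
            del chars[rng.integers(len(chars))]
        else:
            chars.insert(int(rng.integers(len(chars) + 1)), bases[rng.integers(4)])
    return "".join(chars)


def _draw_period(rng: np.random.Generator, weights: Sequence[float]) -> int:
    w = np.asarray(weights, dtype=float)
    cls = int(rng.choice(4, p=w / w.sum()))
    if _PERIOD_CLASSES[cls] != 0:
        return _PERIOD_CLASSES[cls]
    # "other": a multiple-of-three period, the coding class
    return int(3 * rng.integers(4, 41))  # 12..120 nt


def generate_genome(spec: PlantSpec) -> Tuple[Genome, PlantedTruth]:
    """Emit a genome and the exact truth records describing it.

    Deterministic for a fixed seed.  Arrays are assigned round-robin to
    ``n_families`` families; each family has one ancestor unit (optionally
    carrying ``signal_motif`` at offset 3) and a fixed period.  Raises
    :class:`CapacityError` when the requested arrays plus minimum gaps do
    not fit in ``genome_length_nt``.
    """
    rng = np.random.default_rng(spec.seed)
    families: List[Tuple[int, str]] = []
    for f in range(spec.n_families):
        period = _draw_period(rng, spec.period_weights)
        unit = _random_unit(rng, period, spec.background_gc)
        if spec.signal_motif and f in spec.signal_families:
            if len(spec.signal_motif) + 3 > period:
                raise ValueError("signal_motif longer than the family unit")
            unit = (
                unit[:3]
                + spec.signal_motif.upper()
                + unit[3 + len(spec.signal_motif) :]
            )
            if is_micro_periodic(unit, 5):
                raise ValueError("signal_motif makes the unit micro-periodic")
        families.append((period, unit))

    arrays_seq: List[str] = []
    # period, copies, family, ancestor, first/last unit lengths
    arrays_meta: List[Tuple[int, int, int, str, int, int]] = []
    for a in range(spec.n_arrays):
        f = a % spec.n_families
        period, ancestor = families[f]
        copies = int(rng.integers(spec.copy_range[0], spec.copy_range[1] + 1))
        units = [
            _mutate_copy(rng, ancestor, spec.divergence, spec.indel_prob)
            for _ in range(copies)
        ]
        arrays_seq.append("".join(units))
        arrays_meta.append(
            (period, copies, f, ancestor, len(units[0]), len(units[-1]))
        )

    total_array = sum(len(s) for s in arrays_seq)
    min_needed = total_array + MIN_GAP_NT * (spec.n_arrays + 1)
    if min_needed > spec.genome_length_nt:
        raise CapacityError(
            f"genome_length_nt={spec.genome_length_nt} cannot hold "
            f"{spec.n_arrays} arrays ({min_needed} nt needed)"
        )
    # place arrays at random positions with >= MIN_GAP_NT background between
    slack = spec.genome_length_nt - min_needed
    cuts = np.sort(rng.integers(0, slack + 1, size=spec.n_arrays))
    gap_extra = np.diff(np.concatenate(([0], cuts)))
    parts: List[str] = []
    truth: List[PlantedArray] = []
    pos = 0  # 0-based length so far
    for i, (seq_arr, meta) in enumerate(zip(arrays_seq, arrays_meta)):
        gap = MIN_GAP_NT + int(gap_extra[i])
        parts.append(
            b"".join(_random_background(rng, gap, spec.background_gc)).decode()
        )
        pos += gap
        start = pos + 1
        parts.append(seq_arr)
        pos += len(seq_arr)
        period, copies, fam, ancestor, first_len, last_len = meta
        truth.append(
            PlantedArray(
                start_nt=start,
                end_nt=pos,
                period_nt=period,
                copies=copies,
                family=fam,
                ancestor=ancestor,
            )
        )
    tail = spec.genome_length_nt - pos
    parts.append(b"".join(_random_background(rng, tail, spec.background_gc)).decode())
    chars = list("".join(parts))
    # Crisp array boundaries: the background base immediately flanking an
    # array must not continue the array's periodicity, otherwise the
    # planted coordinates would not be the maximal periodic extent and
    # detection would legitimately report a shifted frame.
    for arr, meta in zip(truth, arrays_meta):
        first_len, last_len = meta[4], meta[5]
        a0, e0 = arr.start_nt - 1, arr.end_nt - 1
        if chars[a0 - 1] == chars[a0 - 1 + first_len]:
            chars[a0 - 1] = _different_base(chars[a0 - 1 + first_len], rng)
        if e0 + 1 < len(chars) and chars[e0 + 1] == chars[e0 + 1 - last_len]:
            chars[e0 + 1] = _different_base(chars[e0 + 1 - last_len], rng)
    genome = Genome(id=f"synth_seed{spec.seed}", sequence="".join(chars))
    assert genome.length_nt == spec.genome_length_nt
    return genome, PlantedTruth(arrays=tuple(truth), signal_motif=spec.signal_motif)


def _different_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def derive_strain(
    genome: Genome,
    truth: PlantedTruth,
    delete_fraction: float = 0.0,
    truncate_fraction: float = 0.0,
    insert_count: int = 0,
    seed: int = 0,
    spec: Optional[PlantSpec] = None,
) -> Tuple[Genome, PlantedTruth]:
    """Derive a strain by deleting, truncating, and inserting arrays.

    ``delete_fraction`` of the arrays (seeded choice) is removed entirely;
    ``truncate_fraction`` of the remaining arrays is cut to half its
    copies; ``insert_count`` new arrays (periods re-drawn from the
    original period mix) are inserted into background gaps.  Background
    outside the arrays is untouched.  Returns the new genome and its
    updated truth.
    """
    if not (0 <= delete_fraction <= 1 and 0 <= truncate_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spec = spec or PlantSpec()
    arrays = list(truth.arrays)
    n = len(arrays)
    n_del = int(round(delete_fraction * n))
    del_idx = set(rng.choice(n, size=n_del, replace=False).tolist()) if n_del else set()
    remaining = [i for i in range(n) if i not in del_idx]
    n_trunc = int(round(truncate_fraction * len(remaining)))
    trunc_idx = (
        set(rng.choice(remaining, size=n_trunc, replace=False).tolist())
        if n_trunc
        else set()
    )

    # rebuild the genome as alternating background / array segments
    segments: List[Tuple[str, Optional[PlantedArray]]] = []
    prev_end = 0  # 0-based exclusive
    for arr in arrays:
        segments.append((genome.sequence[prev_end : arr.start_nt - 1], None))
        segments.append((genome.sequence[arr.start_nt - 1 : arr.end_nt], arr))
        prev_end = arr.end_nt
    segments.append((genome.sequence[prev_end:], None))

    out_parts: List[str] = []
    new_truth: List[PlantedArray] = []
    pos = 0
    ai = 0
    for seg, arr in segments:
        if arr is None:
            out_parts.append(seg)
            pos += len(seg)
            continue
        idx = ai
        ai += 1
        if idx in del_idx:
            continue
        seq = seg
        copies = arr.copies
        if idx in trunc_idx:
            copies = max(1, arr.copies // 2)
            # keep the leading copies; unit boundaries are period-spaced
            # only approximately under indels, so cut proportionally
            keep = round(len(seg) * copies / arr.copies)
            seq = seg[:keep]
        out_parts.append(seq)
        new_truth.append(
            PlantedArray(
                start_nt=pos + 1,
                end_nt=pos + len(seq),
                period_nt=arr.period_nt,
                copies=copies,
                family=arr.family,
                ancestor=arr.ancestor,
            )
        )
        pos += len(seq)

    strain_genome = Genome(id=genome.id + "_strain", sequence="".join(out_parts))

    # insert new strain-specific arrays into sufficiently long background gaps
    for _ in range(insert_count):
        period = _draw_period(rng, spec.period_weights)
        unit = _random_unit(rng, period, spec.background_gc)
        copies = int(rng.integers(spec.copy_range[0], min(spec.copy_range[1], 10) + 1))
        insert_seq = "".join(
            _mutate_copy(rng, unit, spec.divergence, spec.indel_prob)
            for _ in range(copies)
        )
        taken = sorted((a.start_nt, a.end_nt) for a in new_truth)
        gaps = []
        prev = 0
        for s, e in taken:
            if s - 1 - prev >= 2 * MIN_GAP_NT + len(insert_seq):
                gaps.append((prev, s - 1))
            prev = e
        if len(strain_genome.sequence) - prev >= 2 * MIN_GAP_NT + len(insert_seq):
            gaps.append((prev, len(strain_genome.sequence)))
        if not gaps:
            break
        g_lo, g_hi = gaps[int(rng.integers(len(gaps)))]
        at = int(
            rng.integers(
                g_lo + MIN_GAP_NT, g_hi - MIN_GAP_NT - len(insert_seq) + 1
            )
        )
        seq = strain_genome.sequence
        strain_genome = Genome(
            id=strain_genome.id, sequence=seq[:at] + insert_seq + seq[at:]
        )
        shifted = []
        for a in new_truth:
            if a.start_nt > at:
                shifted.append(
                    replace(
                        a,
                        start_nt=a.start_nt + len(insert_seq),
                        end_nt=a.end_nt + len(insert_seq),
                    )
                )
            else:
                shifted.append(a)
        shifted.append(
            PlantedArray(
                start_nt=at + 1,
                end_nt=at + len(insert_seq),
                period_nt=period,
                copies=copies,
                family=-1,  # strain-specific, no ancestral family
                ancestor=unit,
            )
        )
        new_truth = sorted(shifted, key=lambda a: a.start_nt)

    new_truth.sort(key=lambda a: a.start_nt)
    return strain_genome, PlantedTruth(
        arrays=tuple(new_truth), signal_motif=truth.signal_motif
    )
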