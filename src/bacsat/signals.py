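"""Characteristic short signals shared across repeat units.

Species with abundant constant-length tandem repeats tend to carry a small
set of short sequences that recur in nearly every repeat unit of the
class, often together with their reverse complement inside the same unit.
This module discovers such signals by exhaustive k-mer enumeration
(longest k first) over the units and their reverse complements, followed
by a greedy degeneracy step that merges k-mers differing at up to two
positions collapsible to the IUPAC codes R (A/G), Y (C/T) or N whenever
the merge raises unit coverage.

Reported motifs are non-nested (no reported motif is an IUPAC-substring of
another) and must reach a minimum fraction of units carrying a match on
either strand (default 0.8).  Matching is IUPAC-aware; ambiguity
characters in the *units* never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .io_formats import reverse_complement

__all__ = [
    "SignalMotif",
    "iupac_match_at",
    "motif_occurs",
    "motif_coverage",
    "find_characteristic_signals",
]

#: IUPAC letter -> set of unambiguous bases it stands for.
IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class SignalMotif:
    """A (possibly degenerate) short signal with its coverage statistics."""

    consensus: str
    unit_coverage: float
    array_coverage: float
    strand_note: bool = False

    @property
    def length_k(self) -> int:
        return len(self.consensus)


def iupac_match_at(motif: str, unit: str, pos: int) -> bool:
    """Does ``motif`` match ``unit`` at offset ``pos`` (IUPAC semantics)?

    Ambiguous characters in the unit match nothing.
    """
    if pos < 0 or pos + len(motif) > len(unit):
        return False
    for m, b in zip(motif, unit[pos : pos + len(motif)]):
        if b not in "ACGT" or b not in IUPAC_SETS[m]:
            return False
    return True


def _match_positions(motif: str, unit: str) -> List[int]:
    return [
        i for i in range(len(unit) - len(motif) + 1) if iupac_match_at(motif, unit, i)
    ]


def motif_occurs(motif: str, unit: str) -> Tuple[bool, bool]:
    """(forward match present, reverse-complement match present)."""
    fwd = bool(_match_positions(motif, unit))
    rev = bool(_match_positions(reverse_complement(motif), unit))
    return fwd, rev


def motif_coverage(
    motif, units: Sequence[str], arrays: Optional[Sequence[Sequence[str]]] = None
) -> Tuple[float, float]:
    """Coverage of a motif over repeat units.

    ``unit_coverage`` is the fraction of units matched on either strand.
    ``array_coverage`` is the fraction of arrays in which at least half the
    units match; when ``arrays`` is not given each unit counts as its own
    single-unit array.
    """
    consensus = motif.consensus if isinstance(motif, SignalMotif) else str(motif)
    if not units:
        return 0.0, 0.0
    hits = [any(motif_occurs(consensus, u)) for u in units]
    unit_cov = sum(hits) / len(units)
    if arrays is None:
        arrays = [[u] for u in units]
    arr_hit = 0
    for arr in arrays:
        arr_hits = sum(1 for u in arr if any(motif_occurs(consensus, u)))
        if arr and arr_hits >= len(arr) / 2:
            arr_hit += 1
    return unit_cov, (arr_hit / len(arrays) if arrays else 0.0)


def _unit_kmer_sets(units: Sequence[str], k: int) -> List[Set[str]]:
    """Exact k-mer content of each unit, both strands, ambiguity skipped."""
    sets: List[Set[str]] = []
    for u in units:
        s: Set[str] = set()
        for seq in (u, reverse_complement(u)):
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if all(c in "ACGT" for c in kmer):
                    s.add(kmer)
        sets.append(s)
    return sets


def _merge_kmers(a: str, b: str) -> Optional[str]:
    """Collapse two equal-length k-mers into one degenerate pattern.

    Allowed only when they differ at <= 2 positions; a purine difference
    becomes R, a pyrimidine difference Y, anything else N.
    """
    diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if not diff or len(diff) > 2:
        return None
    out = list(a)
    for i in diff:
        pair = {a[i], b[i]}
        if pair <= set("AG"):
            out[i] = "R"
        elif pair <= set("CT"):
            out[i] = "Y"
        else:
            out[i] = "N"
    return "".join(out)


def _is_nested(candidate: str, reported: Sequence[str]) -> bool:
    """Is ``candidate`` an IUPAC-substring of any reported motif (either
    strand)?  Checked set-wise: candidate letter set a subset of the
    reported letter set at every offset position."""
    for rep in reported:
        for target in (rep, reverse_complement(rep)):
            if len(candidate) > len(target):
                continue
            for off in range(len(target) - len(candidate) + 1):
                if all(
                    IUPAC_SETS[c] <= IUPAC_SETS[t]
                    for c, t in zip(candidate, target[off : off + len(candidate)])
                ):
                    return True
    return False


def find_characteristic_signals(
    units: Sequence[str],
    k_min: int = 6,
    k_max: int = 30,
    min_unit_coverage: float = 0.8,
    arrays: Optional[Sequence[Sequence[str]]] = None,
) -> List[SignalMotif]:
    """Discover signals shared across the units of one genome/length class.

    For each k from ``k_max`` down to ``k_min``: exact k-mers reaching the
    coverage threshold are reported directly; pairs of k-mers at Hamming
    distance <= 2 whose merge (R/Y/N degeneracy) raises coverage to the
    threshold are reported as degenerate motifs.  Motifs nested inside an
    already-reported (longer) motif are suppressed.  Requires >= 4 units.
    """
    if len(units) < 4:
        raise ValueError("find_characteristic_signals requires >= 4 units")
    units = [u.upper() for u in units]
    n = len(units)
    reported: List[SignalMotif] = []
    reported_strs: List[str] = []
    for k in range(k_max, k_min - 1, -1):
        if k > max(len(u) for u in units):
            continue
        sets = _unit_kmer_sets(units, k)
        counts: Dict[str, int] = {}
        for s in sets:
            for kmer in s:
                counts[kmer] = counts.get(kmer, 0) + 1
        # deduplicate strand pairs: keep the lexicographically smaller of
        # (kmer, rc) as the representative
        candidates: List[Tuple[str, float]] = []
        seen: Set[str] = set()
        for kmer, c in counts.items():
            canon = min(kmer, reverse_complement(kmer))
            if canon in seen:
                continue
            seen.add(canon)
            cov = counts.get(canon, 0)
            rc = reverse_complement(canon)
            # unit-level coverage: units containing kmer on either strand
            cov_units = sum(1 for s in sets if canon in s or rc in s) / n
            candidates.append((canon, cov_units))
        hits: List[Tuple[str, float]] = [
            (kmer, cov) for kmer, cov in candidates if cov >= min_unit_coverage
        ]
        # degenerate merges among reasonably covered k-mers
        pool = [
            (kmer, cov)
            for kmer, cov in candidates
            if cov >= max(0.25, min_unit_coverage / 2)
        ]
        for (a, ca), (b, cb) in combinations(pool, 2):
            for bb in (b, reverse_complement(b)):
                merged = _merge_kmers(a, bb)
                if merged is None:
                    continue
                cov, _ = motif_coverage(merged, units)
                if cov >= min_unit_coverage and cov > max(ca, cb):
                    hits.append((merged, cov))
        # report non-nested, highest coverage first then lexicographic
        for kmer, cov in sorted(hits, key=lambda t: (-t[1], t[0])):
            if _is_nested(kmer, reported_strs):
                continue
            unit_cov, arr_cov = motif_coverage(kmer, units, arrays)
            both = any(all(motif_occurs(kmer, u)) for u in units)
            reported.append(
                SignalMotif(
                    consensus=kmer,
                    unit_coverage=unit_cov,
                    array_coverage=arr_cov,
                    strand_note=both,
                )
            )
            reported_strs.append(kmer)
    return reported
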