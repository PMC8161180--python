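"""Tandem-repeat families by cyclic-permutation similarity.

Units of a tandem array have no canonical start and no canonical strand,
so two arrays belong to the same family when some rotation of one unit,
on either strand, aligns well to the other.  The pairwise similarity is
the global alignment score (match +1, mismatch -1, gap -2), maximized
over all cyclic rotations of either argument and both orientations, and
normalized by the maximum attainable score (match_score times the shorter
length).  Negative normalized scores are clipped to 0.

Families are built by progressive agglomeration: the best-scoring pair of
clusters is merged, the merged cluster's degenerate consensus is
recomputed, scores to the remaining clusters are re-evaluated against
that consensus, and the process stops when the best available merge falls
below the similarity threshold (default 0.6).  Every input repeat ends up
in exactly one family.

Family codes follow the ``Fam_a_b_c`` convention: ``a`` ranks families by
descending member count, ``b`` is the consensus unit length, ``c`` the
member count.  Consensus letters are uppercase at column agreement >= 0.8,
lowercase at >= 0.5 and ``n`` below that (ties between bases give ``n``).
Because members may carry indels, ``b`` can differ slightly from the modal
unit length of the members.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .detect import TandemRepeat, _majority_consensus
from .io_formats import reverse_complement

__all__ = [
    "FamilyConfig",
    "RepeatFamily",
    "representative_unit",
    "best_cyclic_score",
    "score_matrix",
    "progressive_cluster",
    "family_consensus",
    "assign_codes",
    "build_families",
]


@dataclass(frozen=True)
class FamilyConfig:
    similarity_threshold: float = 0.6
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0
    consensus_upper_min: float = 0.8
    consensus_lower_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must be in (0, 1]")


@dataclass
class RepeatFamily:
    rank_a: int
    consensus_length_b: int
    member_count_c: int
    code: str
    members: List[TandemRepeat]
    consensus_unit: str


def _make_aligner(config: FamilyConfig) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    # Alphabet includes 'N' so degenerate consensus letters align neutrally.
    bases = "ACGTN"
    mat = np.full((5, 5), config.mismatch_score)
    for i in range(4):
        mat[i, i] = config.match_score
    mat[4, :] = 0.0
    mat[:, 4] = 0.0
    from Bio.Align import substitution_matrices

    al.substitution_matrix = substitution_matrices.Array(bases, dims=2, data=mat)
    al.open_gap_score = config.gap_score
    al.extend_gap_score = config.gap_score
    return al


def _sanitize(s: str) -> str:
    """Uppercase and collapse non-ACGT letters to N for alignment."""
    s = s.upper()
    return "".join(c if c in "ACGT" else "N" for c in s)


def representative_unit(tr: TandemRepeat) -> str:
    """One unit per tandem repeat: the positional majority consensus of its
    modal-length units."""
    modal = [u for u in tr.units if len(u) == tr.period_nt]
    return _majority_consensus(modal)


def best_cyclic_score(
    u: str,
    v: str,
    config: FamilyConfig = FamilyConfig(),
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Tuple[float, int, str]:
    """Best normalized global-alignment score over rotations and strands.

    Maximizes over all cyclic rotations of either argument and both
    orientations of ``v`` — a symmetric candidate set, so
    ``best_cyclic_score(u, v)[0] == best_cyclic_score(v, u)[0]`` exactly.
    Returns ``(score, rotation, strand)`` where ``rotation`` rotates ``v``
    (or its reverse complement for ``strand == "reverse"``) to the
    best-aligning phase; score is clipped to [0, 1].
    """
    if not u or not v:
        raise ValueError("best_cyclic_score requires nonempty sequences")
    al = aligner if aligner is not None else _make_aligner(config)
    u = _sanitize(u)
    v = _sanitize(v)
    denom = config.match_score * min(len(u), len(v))
    best = (-np.inf, 0, "forward")
    # rotations of v (both strands)
    for strand, w in (("forward", v), ("reverse", _sanitize(reverse_complement(v)))):
        ww = w + w
        for r in range(len(w)):
            s = al.score(u, ww[r : r + len(w)]) / denom
            if s > best[0]:
                best = (s, r, strand)
    # rotations of u (both strands of v fixed) — keeps the score symmetric
    uu = u + u
    for strand, w in (("forward", v), ("reverse", _sanitize(reverse_complement(v)))):
        for r in range(len(u)):
            s = al.score(uu[r : r + len(u)], w) / denom
            if s > best[0]:
                # for equal lengths a rotation of u by r pairs the same
                # phase as rotating v by len(v) - r
                rot = (len(v) - r) % len(v) if len(u) == len(v) else best[1]
                best = (s, rot, strand)
    score = min(1.0, max(0.0, best[0]))
    return score, best[1], best[2]


def score_matrix(
    trs: Sequence[TandemRepeat], config: FamilyConfig = FamilyConfig()
) -> np.ndarray:
    """Symmetric matrix of pairwise best cyclic scores of the repeats'
    representative units (diagonal 1)."""
    reps = [representative_unit(tr) for tr in trs]
    al = _make_aligner(config)
    n = len(reps)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s, _, _ = best_cyclic_score(reps[i], reps[j], config, aligner=al)
            mat[i, j] = mat[j, i] = s
    return mat


# ---------------------------------------------------------------------------
# Consensus via progressive profile alignment
# ---------------------------------------------------------------------------

def _align_to_profile(
    profile_cols: List[Counter],
    consensus: str,
    member: str,
    al: Align.PairwiseAligner,
    n_prev: int,
) -> Tuple[List[Counter], str]:
    """Merge ``member`` (already rotated/oriented) into the column profile.

    The member is globally aligned to the current plain-majority consensus
    string; alignment gaps in the consensus insert new columns (back-filled
    with gap counts for the previous members).
    """
    if not profile_cols:
        cols = [Counter({c: 1}) for c in member]
        return cols, member
    aln = al.align(_sanitize(consensus), _sanitize(member))[0]
    a, b = aln[0], aln[1]  # gapped strings
    new_cols: List[Counter] = []
    ci = 0  # index into existing profile columns
    mi = 0  # index into member
    for ca, cb in zip(a, b):
        if ca != "-" and cb != "-":
            col = profile_cols[ci]
            col[member[mi]] += 1
            new_cols.append(col)
            ci += 1
            mi += 1
        elif ca != "-":
            col = profile_cols[ci]
            col["-"] += 1
            new_cols.append(col)
            ci += 1
        else:
            col = Counter({"-": n_prev})
            col[member[mi]] += 1
            new_cols.append(col)
            mi += 1
    return new_cols, _profile_majority(new_cols)


def _profile_majority(cols: List[Counter]) -> str:
    """Working consensus: one character per profile column (kept in 1:1
    correspondence with the columns so later members can be mapped back)."""
    out = []
    for col in cols:
        bases = {b: c for b, c in col.items() if b in "ACGT"}
        out.append(max(bases.items(), key=lambda kv: kv[1])[0] if bases else "N")
    return "".join(out)


def family_consensus(
    members: Sequence[str], config: FamilyConfig = FamilyConfig()
) -> str:
    """Degenerate consensus of the members' units.

    Members are rotated/oriented by their best cyclic alignment to the
    growing profile and merged column-wise; columns where gaps dominate are
    dropped.  Letter case encodes column agreement (fraction of members,
    gaps included in the denominator): uppercase >= ``consensus_upper_min``,
    lowercase >= ``consensus_lower_min``, otherwise ``n``; a tie between two
    equally frequent bases gives ``n``.
    """
    if not members:
        raise ValueError("family_consensus requires >= 1 member")
    al = _make_aligner(config)
    first = members[0].upper()
    cols: List[Counter] = [Counter({c: 1}) for c in first]
    consensus = first
    for k, m in enumerate(members[1:], start=1):
        m = m.upper()
        _, rot, strand = best_cyclic_score(consensus, m, config, aligner=al)
        w = reverse_complement(m) if strand == "reverse" else m
        w = w[rot:] + w[:rot]
        cols, consensus = _align_to_profile(cols, consensus, w, al, n_prev=k)
    n = len(members)
    out = []
    for col in cols:
        bases = {b: c for b, c in col.items() if b in "ACGT"}
        total_gap = col.get("-", 0)
        if not bases or total_gap > n / 2:
            continue
        top = max(bases.values())
        winners = [b for b, c in bases.items() if c == top]
        freq = top / n
        if len(winners) > 1:
            out.append("n")
        elif freq >= config.consensus_upper_min:
            out.append(winners[0].upper())
        elif freq >= config.consensus_lower_min:
            out.append(winners[0].lower())
        else:
            out.append("n")
    return "".join(out)


# ---------------------------------------------------------------------------
# Progressive clustering
# ---------------------------------------------------------------------------

def progressive_cluster(
    matrix: np.ndarray,
    trs: Sequence[TandemRepeat],
    config: FamilyConfig = FamilyConfig(),
) -> List[RepeatFamily]:
    """Agglomerate repeats into families.

    Clusters are merged best-score-first (ties: smallest indices); after
    each merge the new cluster's consensus is recomputed and its scores to
    all remaining clusters re-evaluated consensus-vs-consensus.  Merging
    stops when the best available score drops below the threshold.
    """
    n = len(trs)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match number of repeats")
    al = _make_aligner(config)
    reps = [representative_unit(tr) for tr in trs]
    clusters: List[List[int]] = [[i] for i in range(n)]
    consensi: List[str] = list(reps)
    scores = matrix.astype(float).copy()
    np.fill_diagonal(scores, -np.inf)
    active = list(range(n))
    while len(active) > 1:
        best_pair = None
        best_s = -np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                s = scores[i, j]
                if s > best_s:
                    best_s = s
                    best_pair = (i, j)
        if best_pair is None or best_s < config.similarity_threshold:
            break
        i, j = best_pair
        clusters[i] = clusters[i] + clusters[j]
        active.remove(j)
        members = [reps[k] for k in clusters[i]]
        consensi[i] = family_consensus(members, config)
        for k in active:
            if k == i:
                continue
            s, _, _ = best_cyclic_score(consensi[i], consensi[k], config, aligner=al)
            scores[i, k] = scores[k, i] = s
    fams = []
    for i in active:
        members = [trs[k] for k in clusters[i]]
        cons = (
            consensi[i]
            if len(clusters[i]) > 1
            else family_consensus([reps[clusters[i][0]]], config)
        )
        fams.append(
            RepeatFamily(
                rank_a=0,
                consensus_length_b=len(cons),
                member_count_c=len(members),
                code="",
                members=members,
                consensus_unit=cons,
            )
        )
    return assign_codes(fams)


def assign_codes(families: List[RepeatFamily]) -> List[RepeatFamily]:
    """Fill ``rank_a`` and the ``a_b_c`` codes.

    Families are ranked by descending member count; ties go to the longer
    consensus, then lexicographically smaller consensus — a deterministic
    total order.
    """
    families = sorted(
        families,
        key=lambda f: (
            -f.member_count_c,
            -len(f.consensus_unit),
            f.consensus_unit,
        ),
    )
    for rank, fam in enumerate(families, start=1):
        fam.rank_a = rank
        fam.consensus_length_b = len(fam.consensus_unit)
        fam.code = f"{rank}_{fam.consensus_length_b}_{fam.member_count_c}"
    return families


def build_families(
    trs: Sequence[TandemRepeat], config: FamilyConfig = FamilyConfig()
) -> List[RepeatFamily]:
    """Score + cluster + code assignment in one call."""
    if not trs:
        return []
    mat = score_matrix(trs, config)
    return progressive_cluster(mat, trs, config)
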