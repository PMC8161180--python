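"""Multi-genome comparison through maximal unique matches (MUMs).

A MUM is a substring that occurs exactly once in every compared genome
(counting both strands) and cannot be extended in either direction without
breaking the match in at least one genome.  MUM anchoring is the classical
way to align closely related bacterial strains: long unique matches fix
the collinear backbone cheaply, and everything else is interpreted
relative to them.

The pipeline here mirrors the anchored-alignment recipe:

1. :func:`find_mums` enumerates all MUMs above a minimum length with a
   generalized suffix array over the forward and reverse-complement
   strands of every genome;
2. :func:`filter_anchors` keeps anchors no shorter than
   ``max(min_anchor_nt, ceil(log4(genome length)))`` — matches shorter
   than log4 of the genome length are expected by chance;
3. :func:`recursive_refine` re-runs the MUM search between adjacent
   anchors with a halving minimum length, stopping on regions shorter
   than ``recursion_stop_nt``;
4. :func:`cluster_mums` chains collinear consecutive MUMs separated by
   less than ``cluster_gap_nt`` in every genome;
5. :func:`map_tr_conservation` projects tandem-repeat coordinates through
   the flanking anchors of their cluster and labels each repeat shared,
   strain-specific or unanchored.

All coordinates are 1-based inclusive, in forward-strand orientation of
each genome; the first genome is always reported on its forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import TandemRepeat
from .io_formats import Genome

__all__ = [
    "AlignConfig",
    "MUM",
    "MUMCluster",
    "find_mums",
    "filter_anchors",
    "recursive_refine",
    "cluster_mums",
    "map_tr_conservation",
    "plot_alignment",
    "ceil_log4",
]


@dataclass(frozen=True)
class AlignConfig:
    min_anchor_nt: int = 20
    recursion_stop_nt: int = 100
    cluster_gap_nt: int = 2000

    def __post_init__(self) -> None:
        if min(self.min_anchor_nt, self.recursion_stop_nt, self.cluster_gap_nt) <= 0:
            raise ValueError("all AlignConfig parameters must be positive")


@dataclass(frozen=True)
class MUM:
    """A maximal unique match across all compared genomes.

    ``positions`` holds the 1-based forward-strand start in each genome;
    ``strands`` the orientation of the match in each genome relative to
    genome 1 (whose strand is always ``+``).
    """

    positions: Tuple[int, ...]
    length_nt: int
    strands: Tuple[str, ...]

    def start(self, g: int) -> int:
        return self.positions[g]

    def end(self, g: int) -> int:
        return self.positions[g] + self.length_nt - 1


@dataclass(frozen=True)
class MUMCluster:
    members: Tuple[MUM, ...]

    def span(self, g: int) -> Tuple[int, int]:
        return (
            min(m.start(g) for m in self.members),
            max(m.end(g) for m in self.members),
        )


def ceil_log4(n: int) -> int:
    """Smallest integer t with 4**t >= n (integer-exact)."""
    t, p = 0, 1
    while p < n:
        p *= 4
        t += 1
    return t


# ---------------------------------------------------------------------------
# Generalized suffix array machinery
# ---------------------------------------------------------------------------

_CODE = {b: i for i, b in enumerate("ACGT")}

_RC = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    # ambiguity characters are coded uniquely later, so a plain table is fine
    return seq.translate(_RC)[::-1]


def _suffix_array(arr: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n) via lexsort)."""
    n = arr.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    k = 1
    idx = np.arange(n)
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        pairs_r = rank[order]
        pairs_k = key2[order]
        new_rank = np.empty(n, dtype=np.int64)
        diff = np.empty(n, dtype=np.int64)
        diff[0] = 0
        if n > 1:
            diff[1:] = (pairs_r[1:] != pairs_r[:-1]) | (pairs_k[1:] != pairs_k[:-1])
        new_rank[order] = np.cumsum(diff)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _kasai_lcp(arr: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array: lcp[i] = lcp(suffix sa[i-1], suffix sa[i]); lcp[0] = 0."""
    n = arr.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    a = arr
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            maxh = n - max(i, j)
            while h < maxh and a[i + h] == a[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def _sliding_min(x: np.ndarray, w: int) -> np.ndarray:
    out = x[: x.size - w + 1].copy()
    for s in range(1, w):
        np.minimum(out, x[s : s + out.size], out=out)
    return out


def find_mums(
    genomes: Sequence[Genome], min_len: int = 20
) -> List[MUM]:
    """All MUMs of length >= ``min_len`` among the given genomes.

    The matched substring occurs exactly once in every genome (both
    strands counted) and is extendable in neither direction.  Sorted by
    position in the first genome.  Requires >= 2 genomes.
    """
    if len(genomes) < 2:
        raise ValueError("find_mums requires at least two genomes")
    k = len(genomes)
    # Build the concatenated coded text: forward and reverse complement of
    # every genome, each followed by a unique separator.  Ambiguity
    # characters get unique codes too, so they never participate in matches.
    chunks: List[np.ndarray] = []
    text_bounds: List[Tuple[int, int, int, int]] = []  # (start, end, genome, strand)
    unique_code = 4
    offset = 0
    for gi, g in enumerate(genomes):
        for strand, seq in ((0, g.sequence), (1, _rc(g.sequence))):
            codes = np.empty(len(seq) + 1, dtype=np.int64)
            for i, ch in enumerate(seq):
                c = _CODE.get(ch)
                if c is None:
                    c = unique_code
                    unique_code += 1
                codes[i] = c
            codes[-1] = unique_code  # separator
            unique_code += 1
            chunks.append(codes)
            text_bounds.append((offset, offset + len(seq), gi, strand))
            offset += len(codes)
    text = np.concatenate(chunks)
    n = text.size
    sa = _suffix_array(text)
    lcp = _kasai_lcp(text, sa)

    # map each text position to (genome, strand, local position, seq length)
    pos_genome = np.full(n, -1, dtype=np.int64)
    pos_strand = np.zeros(n, dtype=np.int64)
    pos_local = np.zeros(n, dtype=np.int64)
    pos_len = np.zeros(n, dtype=np.int64)
    for start, end, gi, strand in text_bounds:
        pos_genome[start:end] = gi
        pos_strand[start:end] = strand
        pos_local[start:end] = np.arange(end - start)
        pos_len[start:end] = end - start

    gid = pos_genome[sa]  # -1 for separator-start suffixes
    prev_char = np.where(sa > 0, text[np.maximum(sa - 1, 0)], -1)

    n_win = n - k + 1
    if n_win <= 0:
        return []
    # window internal minimum of lcp[i+1 .. i+k-1]
    inner = _sliding_min(lcp[1:], k - 1) if k > 1 else None
    L = inner[:n_win]
    left = lcp[:n_win]
    right = np.zeros(n_win, dtype=np.int64)
    right[: n - k] = lcp[k:]
    ok = (L >= min_len) & (left < L) & (right < L)
    # genome coverage: each genome exactly once in the window
    for g in range(k):
        cnt = np.zeros(n_win, dtype=np.int64)
        ind = (gid == g).astype(np.int64)
        for s in range(k):
            cnt += ind[s : s + n_win]
        ok &= cnt == 1
    # left-maximality: preceding characters not all equal
    pmin = prev_char[:n_win].copy()
    pmax = prev_char[:n_win].copy()
    for s in range(1, k):
        np.minimum(pmin, prev_char[s : s + n_win], out=pmin)
        np.maximum(pmax, prev_char[s : s + n_win], out=pmax)
    ok &= pmax != pmin

    mums: List[MUM] = []
    for i in np.nonzero(ok)[0]:
        length = int(L[i])
        window = sa[i : i + k]
        per_genome: Dict[int, Tuple[int, str]] = {}
        for p in window:
            g = int(pos_genome[p])
            local = int(pos_local[p])
            seqlen = int(pos_len[p])
            if pos_strand[p] == 0:
                start_fwd = local + 1
                strand = "+"
            else:
                start_fwd = seqlen - (local + length) + 1
                strand = "-"
            per_genome[g] = (start_fwd, strand)
        if per_genome[0][1] != "+":
            continue  # the mirror window reports this match
        mums.append(
            MUM(
                positions=tuple(per_genome[g][0] for g in range(k)),
                length_nt=length,
                strands=tuple(per_genome[g][1] for g in range(k)),
            )
        )
    mums.sort(key=lambda m: (m.positions[0], -m.length_nt))
    return mums


def filter_anchors(
    mums: Sequence[MUM], genome_len: int, config: AlignConfig = AlignConfig()
) -> List[MUM]:
    """Discard MUMs shorter than ``max(min_anchor_nt, ceil(log4(genome_len)))``."""
    threshold = max(config.min_anchor_nt, ceil_log4(genome_len))
    return [m for m in mums if m.length_nt >= threshold]


def _collinear_chain(mums: Sequence[MUM]) -> List[MUM]:
    """Heaviest strictly increasing (all genomes, all-forward) anchor chain.

    Weighted longest-increasing-subsequence on the anchors' positions;
    weight = MUM length.  Reverse-strand anchors are left out of the chain.
    """
    fw = [m for m in mums if all(s == "+" for s in m.strands)]
    fw.sort(key=lambda m: m.positions[0])
    n = len(fw)
    if n == 0:
        return []
    best = [0.0] * n
    prev = [-1] * n
    for i in range(n):
        best[i] = float(fw[i].length_nt)
        for j in range(i):
            # strictly increasing starts and ends in every genome; small
            # overlaps between adjacent matches are tolerated
            if all(
                fw[j].start(g) < fw[i].start(g) and fw[j].end(g) < fw[i].end(g)
                for g in range(len(fw[i].positions))
            ):
                cand = best[j] + fw[i].length_nt
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    i = int(np.argmax(best))
    chain: List[MUM] = []
    while i != -1:
        chain.append(fw[i])
        i = prev[i]
    chain.reverse()
    return chain


def recursive_refine(
    genomes: Sequence[Genome],
    anchors: Sequence[MUM],
    config: AlignConfig = AlignConfig(),
) -> List[MUM]:
    """Fill inter-anchor gaps with progressively shorter local MUMs.

    Between every pair of adjacent chained anchors (and the genome ends)
    the MUM search is repeated on the gap sub-regions with a minimum
    length that halves per recursion level (floor 8 nt); recursion stops
    on regions shorter than ``recursion_stop_nt``.  Returns the input
    anchors plus all newly found MUMs, sorted by genome-1 position.
    """
    k = len(genomes)
    found: List[MUM] = list(anchors)

    def refine(bounds: List[Tuple[int, int]], min_len: int) -> None:
        # bounds: per genome, 0-based half-open gap interval (clamped when
        # adjacent anchors overlap)
        bounds = [(a, max(a, b)) for a, b in bounds]
        lengths = [b - a for a, b in bounds]
        if min(lengths) < config.recursion_stop_nt:
            return
        subs = [
            Genome(id=g.id, sequence=g.sequence[a:b])
            for g, (a, b) in zip(genomes, bounds)
        ]
        local = find_mums(subs, min_len=min_len)
        if not local:
            return
        mapped = [
            MUM(
                positions=tuple(
                    p + bounds[g][0] for g, p in enumerate(m.positions)
                ),
                length_nt=m.length_nt,
                strands=m.strands,
            )
            for m in local
        ]
        found.extend(mapped)
        next_len = max(min_len // 2, 8)
        if next_len == min_len:
            return
        chain = _collinear_chain(mapped)
        for lo, hi in _gap_bounds(chain, bounds):
            refine([lo_hi for lo_hi in zip(lo, hi)], next_len)

    def _gap_bounds(chain, outer):
        # yield (per-genome gap starts, per-genome gap ends) between
        # consecutive chain anchors inside `outer`
        gaps = []
        prev_ends = [a for a, _ in outer]
        for m in chain:
            starts = [m.start(g) - 1 for g in range(k)]  # 0-based
            gaps.append((prev_ends, starts))
            prev_ends = [m.end(g) for g in range(k)]
        gaps.append((prev_ends, [b for _, b in outer]))
        return gaps

    chain = _collinear_chain(list(anchors))
    start_len = max(config.min_anchor_nt // 2, 8)
    outer = [(0, len(g.sequence)) for g in genomes]
    prev_ends = [0] * k
    segments: List[List[Tuple[int, int]]] = []
    for m in chain:
        segments.append(
            [(prev_ends[g], m.start(g) - 1) for g in range(k)]
        )
        prev_ends = [m.end(g) for g in range(k)]
    segments.append([(prev_ends[g], len(genomes[g].sequence)) for g in range(k)])
    for seg in segments:
        refine(seg, start_len)

    found.sort(key=lambda m: (m.positions[0], -m.length_nt))
    # de-duplicate (refinement can rediscover an anchor)
    seen = set()
    out = []
    for m in found:
        key = (m.positions, m.length_nt, m.strands)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def cluster_mums(
    mums: Sequence[MUM], config: AlignConfig = AlignConfig()
) -> List[MUMCluster]:
    """Chain collinear consecutive MUMs into gap-bounded clusters.

    Consecutive members must have strictly increasing starts, identical
    strand patterns, and inter-MUM gaps below ``cluster_gap_nt`` in every
    genome; chaining is transitive.  Every MUM lands in exactly one
    cluster.
    """
    ms = sorted(mums, key=lambda m: (m.positions[0], -m.length_nt))
    clusters: List[List[MUM]] = []
    for m in ms:
        if clusters:
            prev = clusters[-1][-1]
            k = len(m.positions)
            compatible = m.strands == prev.strands and all(
                prev.start(g) < m.start(g)
                and prev.end(g) < m.end(g)
                and m.start(g) - prev.end(g) < config.cluster_gap_nt
                for g in range(k)
            )
            if compatible:
                clusters[-1].append(m)
                continue
        clusters.append([m])
    return [MUMCluster(members=tuple(c)) for c in clusters]


# ---------------------------------------------------------------------------
# Tandem-repeat conservation across strains
# ---------------------------------------------------------------------------

def _project_coord(x: int, members: Sequence[MUM], g_from: int, g_to: int) -> int:
    """Project one coordinate through the nearest anchor at or left of it.

    Uses the offset of the member MUM with the largest start <= x (or the
    first member when x precedes them all) — a piecewise-constant shift
    map, which is all the approximate strain correspondence supports.
    """
    anchor = members[0]
    for m in members:
        if m.start(g_from) <= x:
            anchor = m
        else:
            break
    return x + (anchor.start(g_to) - anchor.start(g_from))


def _project(
    r_start: int,
    r_end: int,
    cluster: MUMCluster,
    g_from: int,
    g_to: int,
) -> Optional[Tuple[int, int]]:
    """Project an interval through a cluster's member MUMs."""
    members = sorted(cluster.members, key=lambda m: m.start(g_from))
    if not members:
        return None
    start = _project_coord(r_start, members, g_from, g_to)
    end = _project_coord(r_end, members, g_from, g_to)
    if end < start:
        start, end = end, start
    return start, end


def map_tr_conservation(
    genomes: Sequence[Genome],
    per_genome_repeats: Sequence[Sequence[TandemRepeat]],
    clusters: Sequence[MUMCluster],
) -> pd.DataFrame:
    """Label every tandem repeat shared / strain-specific / unanchored.

    Each repeat is projected through the member MUMs of the cluster that
    spans it — or, for repeats falling between clusters (e.g. inside a
    deletion longer than the cluster gap), through the pooled anchors of
    the flanking clusters — onto every other genome.  If the projected
    interval overlaps a repeat there the pair is ``shared`` (with
    ``length_ratio`` = shorter span / longer span), otherwise the repeat
    is ``strain_specific`` with respect to that genome.  Repeats are
    ``unanchored`` only when no cluster exists at all.  One row per
    (repeat, other genome).
    """
    k = len(genomes)
    pooled = MUMCluster(members=tuple(m for cl in clusters for m in cl.members))
    rows = []
    for gi in range(k):
        for tr in per_genome_repeats[gi]:
            # the cluster whose span in gi covers the repeat; repeats in
            # inter-cluster gaps fall back to the pooled anchor set
            home = None
            for cl in clusters:
                lo, hi = cl.span(gi)
                if lo <= tr.start_nt and tr.end_nt <= hi:
                    home = cl
                    break
            if home is None and pooled.members:
                home = pooled
            for gj in range(k):
                if gj == gi:
                    continue
                row = {
                    "genome_id": genomes[gi].id,
                    "start_nt": tr.start_nt,
                    "end_nt": tr.end_nt,
                    "period_nt": tr.period_nt,
                    "other_genome": genomes[gj].id,
                    "status": "unanchored",
                    "partner_start": pd.NA,
                    "length_ratio": pd.NA,
                }
                if home is not None:
                    proj = _project(tr.start_nt, tr.end_nt, home, gi, gj)
                    if proj is not None:
                        p_lo, p_hi = proj
                        partner = None
                        for other in per_genome_repeats[gj]:
                            if other.start_nt <= p_hi and other.end_nt >= p_lo:
                                partner = other
                                break
                        if partner is not None:
                            la = tr.length_nt
                            lb = partner.length_nt
                            row["status"] = "shared"
                            row["partner_start"] = partner.start_nt
                            row["length_ratio"] = min(la, lb) / max(la, lb)
                        else:
                            row["status"] = "strain_specific"
                rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "start_nt",
            "end_nt",
            "period_nt",
            "other_genome",
            "status",
            "partner_start",
            "length_ratio",
        ],
    )


def plot_alignment(
    genomes: Sequence[Genome],
    per_genome_repeats: Sequence[Sequence[TandemRepeat]],
    path,
) -> None:
    """Strain-comparison figure: one horizontal track per genome with
    vertical repeat marks whose thickness is proportional to repeat length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 1.2 * len(genomes) + 1))
    for i, (g, trs) in enumerate(zip(genomes, per_genome_repeats)):
        y = len(genomes) - i
        ax.hlines(y, 0, g.length_nt, color="0.7", lw=1)
        for tr in trs:
            ax.vlines(
                (tr.start_nt + tr.end_nt) / 2,
                y - 0.3,
                y + 0.3,
                color="black",
                lw=max(0.5, tr.length_nt / 200),
            )
        ax.text(0, y + 0.35, g.id, fontsize=8)
    ax.set_xlabel("genome position (nt)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
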