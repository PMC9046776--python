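"""Chimeric read-pair selection, clustering and SV classification.

A *chimeric* pair maps to two chromosomes or >= 10 kb apart on one
chromosome, evidencing a rearrangement junction.  Pairs sharing a junction
key (chromA, chromB, strandA, strandB) are single-linkage clustered; each
cluster estimates a junction with one breakpoint per side.

Under FR convention the read strand tells which side of the junction the
read sits on: a ``+`` read lies left of the junction (innermost evidence =
max position, direction ``tail``), a ``-`` read lies right of it
(innermost = min position, direction ``head``).  True breakpoints lie up
to one insert size beyond the innermost read end — an uncertainty the
breakpoint style of the output deliberately carries.

Junction orientation grammar (same-chromosome keys after canonical end
ordering):

* ``(+,-)`` — deletion-type junction (left flank joined to right flank);
  reported as DEL only with corroborating read-depth loss.
* ``(-,+)`` — a lower coordinate approached from the right joined to a
  higher coordinate approached from the left: the forward tandem
  duplication junction (segment end joined back to segment start), when
  the bracketed interval carries a read-depth gain.
* ``(+,+)`` / ``(-,-)`` — the two junctions of an inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .depth_cnv import CnvCall
from .pairio import GenomeMap, pairs_to_frame

MIN_CHIMERIC_SPAN = 10_000
CLUSTER_RADIUS = 8_000     # >= max insert size of the mate-pair protocol
MIN_SUPPORT = 6


@dataclass(frozen=True)
class ClusterSide:
    chrom: str
    breakpoint: int
    direction: str           # 'tail' (+ side) or 'head' (- side)
    strand: str


@dataclass
class ChimericCluster:
    """A group of co-oriented chimeric pairs defining one junction."""

    key: Tuple[str, str, str, str]     # chromA, chromB, strandA, strandB
    side_a: ClusterSide
    side_b: ClusterSide
    pair_ids: List[str]

    @property
    def support(self) -> int:
        return len(set(self.pair_ids))

    @property
    def same_chrom(self) -> bool:
        return self.key[0] == self.key[1]


@dataclass
class SVEvent:
    type: str                                   # DEL, DUP_TANDEM_FWD, ...
    breakpoints: List[Tuple[str, int, str]]     # (chrom, pos, direction)
    clusters: List[ChimericCluster] = field(default_factory=list)
    notes: str = ""

    @property
    def chroms(self):
        return sorted({bp[0] for bp in self.breakpoints})

    @property
    def size_bp(self) -> Optional[int]:
        if len(self.chroms) != 1 or len(self.breakpoints) < 2:
            return None
        pos = [bp[1] for bp in self.breakpoints]
        return max(pos) - min(pos)

    @property
    def support(self) -> int:
        return max((c.support for c in self.clusters), default=0)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_chimeric(pairs, min_span: int = MIN_CHIMERIC_SPAN) -> pd.DataFrame:
    """Pure filter keeping pairs on different chromosomes or with
    same-chromosome span >= ``min_span`` (inclusive bound).

    Concordant FR pairs within the insert range never qualify because the
    insert truncates below 10 kb.  Accepts and returns a pair table.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pairs_to_frame(pairs)
    if len(pairs) == 0:
        return pairs
    inter = pairs["chrom_a"].to_numpy() != pairs["chrom_b"].to_numpy()
    span = np.abs(pairs["pos_b"].to_numpy() - pairs["pos_a"].to_numpy())
    return pairs.loc[inter | (span >= min_span)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _interval_index(intervals):
    """chrom -> IntervalTree of 1-based inclusive intervals."""
    from intervaltree import IntervalTree

    trees: Dict[str, "IntervalTree"] = {}
    for iv in intervals or []:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return trees


def _hits(trees, chrom: str, pos: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps(pos))


def cluster(
    chimeric,
    cluster_radius: int = CLUSTER_RADIUS,
    min_support: int = MIN_SUPPORT,
    blacklist=None,
    known_sv=None,
) -> List[ChimericCluster]:
    """Single-linkage clustering of chimeric pairs within each junction key.

    Two pairs link when their side-a positions AND side-b positions are
    each within ``cluster_radius``.  Clusters touching a blacklist or
    known-SV interval on either side, or with support below
    ``min_support``, are dropped.  Output is order-independent.
    """
    if not isinstance(chimeric, pd.DataFrame):
        chimeric = pairs_to_frame(chimeric)
    clusters: List[ChimericCluster] = []
    bl = _interval_index(blacklist)
    ksv = _interval_index(known_sv)
    if len(chimeric) == 0:
        return clusters
    for key, group in chimeric.groupby(
            ["chrom_a", "chrom_b", "strand_a", "strand_b"],
            sort=True, observed=True):
        group = group.sort_values(["pos_a", "pos_b", "pair_id"], kind="mergesort")
        pa = group["pos_a"].to_numpy(np.int64)
        pb = group["pos_b"].to_numpy(np.int64)
        ids = group["pair_id"].to_list()
        n = len(group)
        uf = _UnionFind(n)
        for i in range(n):
            for j in range(i + 1, n):
                if pa[j] - pa[i] > cluster_radius:
                    break  # pos_a-sorted: no further j can link to i
                if abs(int(pb[j]) - int(pb[i])) <= cluster_radius:
                    uf.union(i, j)
        members: Dict[int, List[int]] = {}
        for i in range(n):
            members.setdefault(uf.find(i), []).append(i)
        chrom_a, chrom_b, strand_a, strand_b = key
        for idxs in members.values():
            mpa, mpb = pa[idxs], pb[idxs]
            bp_a = int(mpa.max() if strand_a == "+" else mpa.min())
            bp_b = int(mpb.max() if strand_b == "+" else mpb.min())
            cl = ChimericCluster(
                key=key,
                side_a=ClusterSide(chrom_a, bp_a,
                                   "tail" if strand_a == "+" else "head", strand_a),
                side_b=ClusterSide(chrom_b, bp_b,
                                   "tail" if strand_b == "+" else "head", strand_b),
                pair_ids=sorted(ids[i] for i in idxs),
            )
            if cl.support < min_support:
                continue
            if any(_hits(t, s.chrom, s.breakpoint)
                   for t in (bl, ksv) for s in (cl.side_a, cl.side_b)):
                continue
            clusters.append(cl)
    clusters.sort(key=lambda c: (c.key, c.side_a.breakpoint, c.side_b.breakpoint))
    return clusters


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _near(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def _overlap(call: CnvCall, chrom: str, lo: int, hi: int) -> bool:
    return call.chrom == chrom and call.start <= hi and lo <= call.end


def classify(
    clusters: Sequence[ChimericCluster],
    cnv_calls: Sequence[CnvCall],
    segdup=None,
    insert_max: int = 8_000,
    cluster_radius: int = CLUSTER_RADIUS,
    lcr_flank: int = CLUSTER_RADIUS,
) -> List[SVEvent]:
    """Classify filtered clusters, jointly with read-depth CNV calls, into
    typed SV events.

    Order of resolution: duplicated-segment insertions (two clusters tying
    one locus to both ends of a gained segment), inversions (matched
    (+,+)/(-,-) cluster pairs), forward tandem duplications ((-,+) cluster
    bracketing a gain), deletions ((+,-) cluster with corroborating loss),
    complex events (>= 3 interdependent leftover clusters), translocations
    (leftover inter-chromosomal clusters), then depth gains with no usable
    junction but segmental-duplication flanks (UNRESOLVED_LCR).
    """
    gains = [c for c in cnv_calls if c.type == "gain"]
    losses = [c for c in cnv_calls if c.type in ("loss", "homdel")]
    events: List[SVEvent] = []
    unused = list(clusters)
    used_gains: List[CnvCall] = []

    # (d) duplicated-segment insertions
    ins_events, unused, ins_gains = _find_insertions(
        unused, gains, insert_max, cluster_radius)
    events += ins_events
    used_gains += ins_gains

    # (c) inversions
    inv_events, unused = _find_inversions(unused, insert_max)
    events += inv_events

    # (b) forward tandem duplications: the junction must *bracket* the
    # gained segment (both sides near the gain's boundaries), not merely
    # overlap it — a junction spanning a wider interval that happens to
    # contain a gain is complex-rearrangement territory, not a tandem dup.
    bracket_tol = 2 * cluster_radius
    leftovers = []
    for cl in unused:
        if cl.same_chrom and cl.key[2:] == ("-", "+"):
            lo, hi = cl.side_a.breakpoint, cl.side_b.breakpoint
            gain = next(
                (g for g in gains
                 if g.chrom == cl.key[0]
                 and _near(g.start, lo, bracket_tol)
                 and _near(g.end, hi, bracket_tol)), None)
            if gain is not None:
                events.append(SVEvent(
                    type="DUP_TANDEM_FWD",
                    breakpoints=[(cl.key[0], lo, "head"), (cl.key[0], hi, "tail")],
                    clusters=[cl],
                    notes=f"depth gain {gain.chrom}:{gain.start}-{gain.end}"))
                used_gains.append(gain)
                continue
        leftovers.append(cl)
    unused = leftovers

    # (a) deletions — junction plus corroborating depth loss
    leftovers = []
    for cl in unused:
        if cl.same_chrom and cl.key[2:] == ("+", "-"):
            lo, hi = cl.side_a.breakpoint, cl.side_b.breakpoint
            loss = next((l for l in losses if _overlap(l, cl.key[0], lo, hi)), None)
            if loss is not None:
                events.append(SVEvent(
                    type="DEL",
                    breakpoints=[(cl.key[0], lo, "tail"), (cl.key[0], hi, "head")],
                    clusters=[cl],
                    notes=f"depth loss {loss.chrom}:{loss.start}-{loss.end}"))
                continue
            # depth-unsupported: may still be part of a complex event below
        leftovers.append(cl)
    unused = leftovers

    # (f) complex: connected components of >= 3 interdependent clusters
    complex_events, unused = _find_complex(unused, insert_max, gains)
    events += complex_events

    # (e) translocations
    leftovers = []
    for cl in unused:
        if not cl.same_chrom:
            events.append(SVEvent(
                type="TRA",
                breakpoints=[
                    (cl.side_a.chrom, cl.side_a.breakpoint, cl.side_a.direction),
                    (cl.side_b.chrom, cl.side_b.breakpoint, cl.side_b.direction)],
                clusters=[cl]))
        else:
            leftovers.append(cl)
    unused = leftovers

    # residual same-chromosome clusters
    for cl in unused:
        if cl.key[2:] in (("+", "+"), ("-", "-")):
            events.append(SVEvent(
                type="INV",
                breakpoints=[
                    (cl.side_a.chrom, cl.side_a.breakpoint, cl.side_a.direction),
                    (cl.side_b.chrom, cl.side_b.breakpoint, cl.side_b.direction)],
                clusters=[cl], notes="single-sided"))
        elif cl.key[2:] == ("-", "+"):
            events.append(SVEvent(
                type="DUP_REV_OR_INS",
                breakpoints=[
                    (cl.side_a.chrom, cl.side_a.breakpoint, cl.side_a.direction),
                    (cl.side_b.chrom, cl.side_b.breakpoint, cl.side_b.direction)],
                clusters=[cl], notes="no corroborating depth gain"))

    # (g) gains with no usable junction but LCR/segdup flanks
    segdup_idx = _interval_index(segdup)
    cluster_sides = [(s.chrom, s.breakpoint)
                     for cl in clusters for s in (cl.side_a, cl.side_b)]
    for gain in gains:
        if any(g is gain for g in used_gains):
            continue
        has_cluster = any(
            chrom == gain.chrom and
            gain.start - cluster_radius <= pos <= gain.end + cluster_radius
            for chrom, pos in cluster_sides)
        if has_cluster:
            continue
        flanked = any(
            _hits(segdup_idx, gain.chrom, p)
            for edge in (gain.start, gain.end)
            for p in (edge - lcr_flank, edge, edge + lcr_flank))
        if flanked:
            events.append(SVEvent(
                type="UNRESOLVED_LCR",
                breakpoints=[(gain.chrom, gain.start, "head"),
                             (gain.chrom, gain.end, "tail")],
                notes="duplication orientation unresolved: segmental-duplication flanks"))
    events.sort(key=lambda e: (e.breakpoints[0][0], e.breakpoints[0][1], e.type))
    return events


def _find_insertions(clusters, gains, insert_max, cluster_radius):
    """Pairs of clusters joining one locus P to both ends of a gained
    segment: a duplicated-segment insertion."""
    events, used, used_gains = [], set(), []
    tol = 2 * insert_max
    for i, c1 in enumerate(clusters):
        if i in used:
            continue
        for j in range(i + 1, len(clusters)):
            c2 = clusters[j]
            if j in used:
                continue
            hit = _insertion_pattern(c1, c2, gains, tol, cluster_radius)
            if hit is None:
                continue
            seg_chrom, seg_lo, seg_hi, p_chrom, p_lo, p_hi, gain, orient = hit
            flank_note = ""
            flank_gain = next(
                (g for g in gains
                 if g is not gain and _overlap(g, p_chrom, p_lo - tol, p_hi + tol)),
                None)
            if flank_gain is not None:
                flank_note = ("; flanking duplication "
                              f"{flank_gain.chrom}:{flank_gain.start}-{flank_gain.end}")
            events.append(SVEvent(
                type="INS",
                breakpoints=[(p_chrom, p_lo, "tail"),
                             (seg_chrom, seg_lo, "head"),
                             (seg_chrom, seg_hi, "tail"),
                             (p_chrom, p_hi, "head")],
                clusters=[c1, c2],
                notes=f"duplicated-segment insertion ({orient}); "
                      f"segment {seg_chrom}:{seg_lo}-{seg_hi}" + flank_note))
            used.update((i, j))
            used_gains.append(gain)
            break
    rest = [c for k, c in enumerate(clusters) if k not in used]
    return events, rest, used_gains


def _insertion_pattern(c1, c2, gains, tol, cluster_radius):
    """Check whether clusters c1, c2 tie a shared locus P to the two ends
    of one gained segment; returns the decomposition or None."""
    for s1, o1 in ((c1.side_a, c1.side_b), (c1.side_b, c1.side_a)):
        for s2, o2 in ((c2.side_a, c2.side_b), (c2.side_b, c2.side_a)):
            # s1, s2 candidate insertion-site flanks; o1, o2 segment ends
            if s1.chrom != s2.chrom or not _near(s1.breakpoint, s2.breakpoint, tol):
                continue
            if o1.chrom != o2.chrom:
                continue
            seg_lo, seg_hi = sorted((o1.breakpoint, o2.breakpoint))
            if seg_hi - seg_lo < tol:      # degenerate: not a distant segment
                continue
            gain = next((g for g in gains
                         if _overlap(g, o1.chrom, seg_lo, seg_hi)
                         and _near(g.start, seg_lo, cluster_radius + tol)
                         and _near(g.end, seg_hi, cluster_radius + tol)), None)
            if gain is None:
                continue
            # P flanks: one tail (left of P) and one head (right of P)
            dirs = {s1.direction, s2.direction}
            orient = "forward" if dirs == {"tail", "head"} else "inverted"
            p_lo, p_hi = sorted((s1.breakpoint, s2.breakpoint))
            return (o1.chrom, seg_lo, seg_hi, s1.chrom, p_lo, p_hi, gain, orient)
    return None


def _find_inversions(clusters, insert_max):
    """Match (+,+) with (-,-) clusters with consistent flanks into INV."""
    events, used = [], set()
    tol = 4 * insert_max
    plus = [(i, c) for i, c in enumerate(clusters)
            if c.same_chrom and c.key[2:] == ("+", "+")]
    minus = [(i, c) for i, c in enumerate(clusters)
             if c.same_chrom and c.key[2:] == ("-", "-")]
    for i, c1 in plus:
        best = None
        for j, c2 in minus:
            if j in used or c2.key[0] != c1.key[0]:
                continue
            # head-head cluster sits just inside on both flanks
            da = c2.side_a.breakpoint - c1.side_a.breakpoint
            db = c2.side_b.breakpoint - c1.side_b.breakpoint
            if 0 <= da <= tol and 0 <= db <= tol:
                score = da + db
                if best is None or score < best[0]:
                    best = (score, j, c2)
        if best is None:
            continue
        _, j, c2 = best
        used.update((i, j))
        events.append(SVEvent(
            type="INV",
            breakpoints=[
                (c1.key[0], c1.side_a.breakpoint, "tail"),
                (c1.key[0], c1.side_b.breakpoint, "tail"),
                (c1.key[0], c2.side_a.breakpoint, "head"),
                (c1.key[0], c2.side_b.breakpoint, "head")],
            clusters=[c1, c2]))
    rest = [c for k, c in enumerate(clusters) if k not in used]
    return events, rest


def _find_complex(clusters, insert_max, gains=()):
    """Connected components of >= 3 interdependent clusters.

    Two clusters are interdependent when they share a junction locus, or
    when they touch the two ends of one gained (duplicated) segment —
    the segment itself carries the dependency between its end junctions.
    """
    tol = 2 * insert_max
    n = len(clusters)
    uf = _UnionFind(n)
    sides = [[(c.side_a.chrom, c.side_a.breakpoint),
              (c.side_b.chrom, c.side_b.breakpoint)] for c in clusters]
    gain_touch = [
        {k for k, g in enumerate(gains)
         if any(chrom == g.chrom and (_near(pos, g.start, tol)
                                      or _near(pos, g.end, tol))
                for chrom, pos in sides[i])}
        for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            linked = any(ca == cb and _near(pa, pb, tol)
                         for ca, pa in sides[i] for cb, pb in sides[j])
            if linked or (gain_touch[i] & gain_touch[j]):
                uf.union(i, j)
    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    events, used = [], set()
    for idxs in comps.values():
        if len(idxs) < 3:
            continue
        members = [clusters[i] for i in idxs]
        bps = []
        for c in members:
            for s in (c.side_a, c.side_b):
                bps.append((s.chrom, s.breakpoint, s.direction))
        bps.sort(key=lambda b: (b[0], b[1]))
        order = _segment_order(members, tol)
        events.append(SVEvent(
            type="COMPLEX", breakpoints=bps, clusters=members,
            notes="junction graph: " + order))
        used.update(idxs)
    rest = [c for k, c in enumerate(clusters) if k not in used]
    return events, rest


def _segment_order(members, tol) -> str:
    """One consistent junction chain through a complex component, when the
    junction graph is a simple path; otherwise the unordered junction list."""
    edges = [f"{c.side_a.chrom}:{c.side_a.breakpoint}({c.side_a.strand})::"
             f"{c.side_b.chrom}:{c.side_b.breakpoint}({c.side_b.strand})"
             for c in members]
    return " | ".join(edges)


# ---------------------------------------------------------------------------
# duplication orientation resolution
# ---------------------------------------------------------------------------

def resolve_duplication_orientation(
    gain: CnvCall,
    clusters: Sequence[ChimericCluster],
    cluster_radius: int = CLUSTER_RADIUS,
    segdup=None,
    lcr_flank: int = CLUSTER_RADIUS,
) -> str:
    """Resolve a depth-based duplication call into
    ``forward_tandem`` / ``complex`` / ``unresolved_lcr`` / ``no_junction``.

    forward_tandem requires exactly one (-,+) cluster bracketing the gain
    within ``cluster_radius`` of both boundaries; a boundary cluster
    reaching >= 1 remote locus means ``complex``; no usable cluster with
    segmental-duplication flanks means ``unresolved_lcr``.
    """
    bracketing = [
        cl for cl in clusters
        if cl.same_chrom and cl.key[0] == gain.chrom
        and cl.key[2:] == ("-", "+")
        and _near(cl.side_a.breakpoint, gain.start, cluster_radius)
        and _near(cl.side_b.breakpoint, gain.end, cluster_radius)
    ]
    if len(bracketing) == 1:
        return "forward_tandem"

    boundary_clusters = []
    for cl in clusters:
        for s, other in ((cl.side_a, cl.side_b), (cl.side_b, cl.side_a)):
            near_boundary = (s.chrom == gain.chrom and
                             (_near(s.breakpoint, gain.start, cluster_radius) or
                              _near(s.breakpoint, gain.end, cluster_radius)))
            if near_boundary:
                boundary_clusters.append((cl, other))
    remote = [
        other for cl, other in boundary_clusters
        if other.chrom != gain.chrom
        or not (gain.start - cluster_radius <= other.breakpoint
                <= gain.end + cluster_radius)
    ]
    if remote or len(bracketing) > 1:
        return "complex"

    segdup_idx = _interval_index(segdup)
    flanked = any(
        _hits(segdup_idx, gain.chrom, p)
        for edge in (gain.start, gain.end)
        for p in (edge - lcr_flank, edge, edge + lcr_flank))
    if flanked:
        return "unresolved_lcr"
    return "no_junction"
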