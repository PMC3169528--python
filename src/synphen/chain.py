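"""Collinear anchor chaining and chain filtering.

A whole-genome synteny map is built from exact-match local alignments
(anchors) by chaining collinear hits, allowing a bounded stretch of
undetectable similarity between consecutive anchors (10 kb by default),
and then discarding chains that a larger chain overlaps by more than a
fraction (90% by default) of their span on either sequence.

Coordinates are 0-based half-open internally; text I/O is 1-based
inclusive (see :mod:`synphen.io`). Minus-strand anchors store query
coordinates on the forward strand with a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Anchor:
    """An exact-match local alignment between a reference and a query sequence."""

    ref_id: str
    qry_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"anchor strand must be '+' or '-', got {self.strand!r}")
        if self.ref_end <= self.ref_start:
            raise ValueError(f"anchor ref interval empty or inverted: {self}")
        if self.qry_end <= self.qry_start:
            raise ValueError(f"anchor qry interval empty or inverted: {self}")
        if self.ref_end - self.ref_start != self.qry_end - self.qry_start:
            raise ValueError(f"anchor is not an exact match (unequal lengths): {self}")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class Chain:
    """An ordered, collinear, gap-bounded run of anchors.

    Anchors share (ref_id, qry_id, strand); reference positions increase
    strictly along the chain, query positions increase (+) or decrease (-).
    ``score`` is the spanned reference length.
    """

    anchors: list[Anchor] = field(default_factory=list)

    @property
    def ref_id(self) -> str:
        return self.anchors[0].ref_id

    @property
    def qry_id(self) -> str:
        return self.anchors[0].qry_id

    @property
    def strand(self) -> str:
        return self.anchors[0].strand

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.anchors[0].ref_start, self.anchors[-1].ref_end)

    @property
    def qry_span(self) -> tuple[int, int]:
        starts = [a.qry_start for a in self.anchors]
        ends = [a.qry_end for a in self.anchors]
        return (min(starts), max(ends))

    @property
    def score(self) -> int:
        s, e = self.ref_span
        return e - s

    @property
    def aligned_length(self) -> int:
        """Sum of anchor lengths (alternative chain size measure)."""
        return sum(a.length for a in self.anchors)

    def __len__(self) -> int:
        return len(self.anchors)


def _compatible_gap(last: Anchor, nxt: Anchor, max_gap: int) -> tuple[int, int] | None:
    """Return (ref_gap, qry_gap) if ``nxt`` may follow ``last`` in a chain, else None.

    ``nxt`` must lie strictly after ``last`` on the reference and continue the
    query in the chain's direction; both inter-anchor gaps must be <= max_gap.
    Gaps may be negative (overlapping anchors).
    """
    if (last.ref_id, last.qry_id, last.strand) != (nxt.ref_id, nxt.qry_id, nxt.strand):
        return None
    if not (nxt.ref_start > last.ref_start and nxt.ref_end > last.ref_end):
        return None
    ref_gap = nxt.ref_start - last.ref_end
    if ref_gap > max_gap:
        return None
    if last.strand == "+":
        if not (nxt.qry_start > last.qry_start and nxt.qry_end > last.qry_end):
            return None
        qry_gap = nxt.qry_start - last.qry_end
    else:
        if not (nxt.qry_start < last.qry_start and nxt.qry_end < last.qry_end):
            return None
        qry_gap = last.qry_start - nxt.qry_end
    if qry_gap > max_gap:
        return None
    return ref_gap, qry_gap


def build_chains(anchors: list[Anchor], max_gap: int = 10_000) -> list[Chain]:
    """Partition anchors into collinear chains with bounded inter-anchor gaps.

    Anchors are processed in (ref_id, ref_start) order. Each anchor joins the
    open chain whose last anchor minimizes the reference gap among all
    compatible chains; ties break by smaller query gap, then by earlier chain
    creation; an anchor with no compatible chain opens a new one. Every input
    anchor belongs to exactly one output chain. Output is sorted by
    descending score, then (ref_id, ref_start).

    Parameters
    ----------
    anchors : validated exact-match anchors.
    max_gap : largest tolerated run of undetectable similarity, in bases, on
        either sequence between consecutive anchors (default 10,000).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    for i, a in enumerate(anchors):
        if not isinstance(a, Anchor):
            raise TypeError(f"record {i} is not an Anchor: {a!r}")
    ordered = sorted(
        anchors,
        key=lambda a: (a.ref_id, a.ref_start, a.ref_end, a.qry_id, a.qry_start, a.strand),
    )
    chains: list[Chain] = []
    for a in ordered:
        best: tuple[int, int, int] | None = None  # (ref_gap, qry_gap, chain_idx)
        for idx, ch in enumerate(chains):
            gaps = _compatible_gap(ch.anchors[-1], a, max_gap)
            if gaps is None:
                continue
            cand = (gaps[0], gaps[1], idx)
            if best is None or cand < best:
                best = cand
        if best is None:
            chains.append(Chain([a]))
        else:
            chains[best[2]].anchors.append(a)
    chains.sort(key=lambda c: (-c.score, c.ref_id, c.ref_span[0]))
    return chains


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _merged_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _footprint_overlap(span: tuple[int, int], footprint: list[tuple[int, int]]) -> int:
    return sum(_interval_overlap(span, iv) for iv in footprint)


def filter_chains(
    chains: list[Chain],
    overlap_frac: float = 0.9,
    length_mode: str = "span",
) -> list[Chain]:
    """Drop chains that a strictly larger chain overlaps by more than ``overlap_frac``.

    A chain is removed iff some chain of strictly greater score overlaps more
    than ``overlap_frac`` of its length on the reference OR on the query
    (same sequence required on the overlapping side). The overlap is measured
    against the larger chain's aligned footprint (its merged anchor
    intervals), not its raw span: a small chain sitting entirely inside a
    larger chain's inter-anchor gap conflicts with nothing and is kept. The
    comparison set is all strictly larger chains, retained or not, which
    makes the filter order-independent and idempotent. Kept chains retain
    their input order.

    ``length_mode`` selects the denominator of the overlap fraction:
    ``"span"`` (spanned length, default) or ``"aligned"`` (sum of anchor
    lengths).
    """
    if not (0.0 < overlap_frac <= 1.0):
        raise ValueError(f"overlap_frac must be in (0, 1], got {overlap_frac}")
    if length_mode not in ("span", "aligned"):
        raise ValueError(f"length_mode must be 'span' or 'aligned', got {length_mode!r}")

    def denom_ref(c: Chain) -> int:
        return c.score if length_mode == "span" else c.aligned_length

    def denom_qry(c: Chain) -> int:
        if length_mode == "span":
            s, e = c.qry_span
            return e - s
        return c.aligned_length

    ref_fp = {id(c): _merged_intervals([(a.ref_start, a.ref_end) for a in c.anchors])
              for c in chains}
    qry_fp = {id(c): _merged_intervals([(a.qry_start, a.qry_end) for a in c.anchors])
              for c in chains}
    kept = []
    for c in chains:
        removed = False
        for d in chains:
            if d is c or d.score <= c.score:
                continue
            if d.ref_id == c.ref_id:
                if _footprint_overlap(c.ref_span, ref_fp[id(d)]) > overlap_frac * denom_ref(c):
                    removed = True
                    break
            if d.qry_id == c.qry_id:
                if _footprint_overlap(c.qry_span, qry_fp[id(d)]) > overlap_frac * denom_qry(c):
                    removed = True
                    break
        if not removed:
            kept.append(c)
    return kept
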