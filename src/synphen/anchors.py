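"""Exact-match anchor finding between two genome sequence sets.

Anchors are maximal exact matches, on either strand, that are unique in
the reference — the same semantics as the maximal-unique-match seeds of
nucmer-style whole-genome aligners, which this module stands in for when
no external aligner output is available. Uniqueness is required on the
reference only; query-side repeats are allowed.

The search seeds on k-mers that occur exactly once in the reference and
extends each seed to its maximal exact match. A match containing a
reference-unique k-mer occurs at most once in the reference, so every
reported anchor is unique. A unique match every k-mer of which is
repeated elsewhere in the reference has no seed and is not reported;
outside of heavily repetitive sequence such matches do not arise.
"""

from __future__ import annotations

from Bio.Seq import reverse_complement

from .chain import Anchor

_VALID = set("ACGTN")


def _validate_seqs(seqs: dict[str, str], label: str) -> None:
    for name, s in seqs.items():
        bad = set(s) - _VALID
        if bad:
            raise ValueError(
                f"{label} sequence {name!r} contains non-ACGTN symbols: {sorted(bad)!r}"
            )


def _index_unique_kmers(ref: dict[str, str], k: int) -> dict[str, tuple[str, int]]:
    """Map each k-mer occurring exactly once in the reference to its position."""
    index: dict[str, tuple[str, int] | None] = {}
    for name, s in ref.items():
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            if kmer in index:
                index[kmer] = None  # repeated in reference
            else:
                index[kmer] = (name, i)
    return {kmer: pos for kmer, pos in index.items() if pos is not None}


def _extend(rseq: str, qseq: str, rp: int, qp: int, k: int) -> tuple[int, int, int]:
    """Extend an exact k-mer match maximally in both directions.

    Returns (ref_start, qry_start, length) in the orientation of ``qseq``.
    N never matches (including N vs N), so extensions stop at N.
    """
    i, j = rp, qp
    while i > 0 and j > 0 and rseq[i - 1] == qseq[j - 1] and rseq[i - 1] != "N":
        i -= 1
        j -= 1
    e_r, e_q = rp + k, qp + k
    n_r, n_q = len(rseq), len(qseq)
    while e_r < n_r and e_q < n_q and rseq[e_r] == qseq[e_q] and rseq[e_r] != "N":
        e_r += 1
        e_q += 1
    return i, j, e_r - i


def find_anchors(ref: dict[str, str], qry: dict[str, str], k: int = 20) -> list[Anchor]:
    """Find maximal exact matches of length >= k unique in the reference.

    Matches are reported on both query strands; minus-strand anchors carry
    forward-strand query coordinates with strand '-'. Output is sorted by
    (ref_id, ref_start). Empty inputs yield an empty list.
    """
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    _validate_seqs(ref, "reference")
    _validate_seqs(qry, "query")
    index = _index_unique_kmers(ref, k)
    seen: set[tuple] = set()
    anchors: list[Anchor] = []
    for qname, qfwd in qry.items():
        for strand, qseq in (("+", qfwd), ("-", reverse_complement(qfwd))):
            # per (ref_id, diagonal): rightmost query end already covered by a
            # reported match, to avoid re-extending seeds inside known matches
            diag_end: dict[tuple[str, int], int] = {}
            for qp in range(len(qseq) - k + 1):
                hit = index.get(qseq[qp : qp + k])
                if hit is None:
                    continue
                rname, rp = hit
                key = (rname, rp - qp)
                if diag_end.get(key, -1) >= qp + k:
                    continue
                rs, qs, length = _extend(ref[rname], qseq, rp, qp, k)
                diag_end[key] = qs + length
                if strand == "+":
                    q0, q1 = qs, qs + length
                else:
                    q0, q1 = len(qseq) - (qs + length), len(qseq) - qs
                rec = (rname, qname, rs, rs + length, q0, q1, strand)
                if rec not in seen:
                    seen.add(rec)
                    anchors.append(Anchor(*rec))
    anchors.sort(key=lambda a: (a.ref_id, a.ref_start, a.ref_end, a.qry_id, a.qry_start, a.strand))
    return anchors
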