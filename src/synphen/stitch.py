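"""Reference-guided scaffold ordering, orientation and stitching.

Draft scaffolds are ordered and oriented against one or more finished
reference genomes using the synteny chains they participate in (as
query), then concatenated into a stitched pseudo-genome with runs of
500 N between consecutive scaffolds. Scaffolds with no chain evidence
are appended after the placed ones, longest first.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import reverse_complement

from .chain import Chain


@dataclass
class ScaffoldPlacement:
    scaffold_id: str
    orientation: str  # '+' | '-'
    anchor_position: float  # median reference coordinate of the best chain
    reference_id: str | None
    placed: bool
    basis: str  # 'synteny' | 'unplaced'


def order_scaffolds(chains: list[Chain], scaffolds: dict[str, str]) -> list[ScaffoldPlacement]:
    """Order and orient scaffolds by their best synteny chains.

    Each scaffold's orientation is the strand of its highest-scoring chain
    and its anchor position the median reference coordinate of that chain's
    span. With several references, the reference carrying the greatest total
    chain score for a scaffold is used for that scaffold, and references are
    laid out in order of their genome-wide total chain score. Scaffolds with
    no chains are appended after placed ones, by descending length.
    """
    for ch in chains:
        if ch.qry_id not in scaffolds:
            raise KeyError(f"scaffold {ch.qry_id!r} named in chains but absent from FASTA")
    by_scaf: dict[str, list[Chain]] = {}
    ref_total: dict[str, int] = {}
    for ch in chains:
        by_scaf.setdefault(ch.qry_id, []).append(ch)
        ref_total[ch.ref_id] = ref_total.get(ch.ref_id, 0) + ch.score
    ref_rank = {r: i for i, r in enumerate(
        sorted(ref_total, key=lambda r: (-ref_total[r], r)))}

    placed: list[ScaffoldPlacement] = []
    unplaced: list[str] = []
    for name in scaffolds:
        chs = by_scaf.get(name)
        if not chs:
            unplaced.append(name)
            continue
        totals: dict[str, int] = {}
        for ch in chs:
            totals[ch.ref_id] = totals.get(ch.ref_id, 0) + ch.score
        ref = min(totals, key=lambda r: (-totals[r], r))
        best = min((c for c in chs if c.ref_id == ref),
                   key=lambda c: (-c.score, c.ref_span[0]))
        mid = (best.ref_span[0] + best.ref_span[1]) / 2.0
        placed.append(ScaffoldPlacement(name, best.strand, mid, ref, True, "synteny"))
    placed.sort(key=lambda p: (ref_rank[p.reference_id], p.anchor_position, p.scaffold_id))
    tail = sorted(unplaced, key=lambda n: (-len(scaffolds[n]), n))
    for name in tail:
        placed.append(ScaffoldPlacement(name, "+", float("nan"), None, False, "unplaced"))
    return placed


def stitch(
    placements: list[ScaffoldPlacement],
    scaffolds: dict[str, str],
    spacer: int = 500,
    terminal_spacer: bool = False,
) -> tuple[str, pd.DataFrame]:
    """Concatenate oriented scaffolds with N-run spacers.

    Returns the stitched sequence and a placement table with the 1-based
    inclusive interval of every scaffold in the stitched coordinate system.
    Spacers go between consecutive scaffolds only, unless ``terminal_spacer``
    also adds one at each outer end.
    """
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    if not placements:
        raise ValueError("nothing to stitch: empty placement list")
    parts: list[str] = []
    rows = []
    pos = 0
    if terminal_spacer:
        parts.append("N" * spacer)
        pos += spacer
    for i, p in enumerate(placements):
        if i > 0:
            parts.append("N" * spacer)
            pos += spacer
        seq = scaffolds[p.scaffold_id]
        if p.orientation == "-":
            seq = reverse_complement(seq)
        parts.append(seq)
        rows.append({
            "scaffold_id": p.scaffold_id,
            "start": pos + 1,
            "end": pos + len(seq),
            "orientation": p.orientation,
            "placed": p.placed,
            "basis": p.basis,
        })
        pos += len(seq)
    if terminal_spacer:
        parts.append("N" * spacer)
    return "".join(parts), pd.DataFrame(rows)


def write_agp(table: pd.DataFrame, object_name: str, path: str, spacer: int = 500) -> None:
    """Write an AGP v2.1 description of the stitched object.

    Components are the scaffolds at their stitched intervals; gaps are
    ``scaffold`` gaps with linkage ``yes`` and evidence ``align_genus``.
    """
    lines = ["##agp-version\t2.1"]
    part = 0
    prev_end = 0
    for _, row in table.iterrows():
        if row["start"] > prev_end + 1:
            part += 1
            lines.append("\t".join(map(str, [
                object_name, prev_end + 1, row["start"] - 1, part,
                "N", row["start"] - 1 - prev_end, "scaffold", "yes", "align_genus",
            ])))
        part += 1
        length = row["end"] - row["start"] + 1
        lines.append("\t".join(map(str, [
            object_name, row["start"], row["end"], part,
            "W", row["scaffold_id"], 1, length, row["orientation"],
        ])))
        prev_end = row["end"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
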