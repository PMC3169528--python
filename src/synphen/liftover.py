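"""Synteny-based gene liftover between bacterial genomes.

Gene models are transferred from an annotated reference genome to a
target genome by two routes and the better result is kept per gene:

1. *projection* — project the gene boundaries through the chain-derived
   coordinate map;
2. *realignment* — extract the projected region (plus padding) from the
   target and re-model the gene by aligning the reference CDS to it with
   free end gaps on the region side, then snapping to the nearest
   in-frame start/stop codons.

The winner is the candidate whose CDS scores higher in a global
alignment against the reference CDS. Bacterial genes are intronless, so
protein-spliced alignment is unnecessary: CDS-to-region glocal alignment
with start/stop adjustment preserves boundary-aware re-modeling without
an external gene-prediction dependency.

Scoring scheme (both for realignment and candidate selection): match +1,
mismatch -1, gap open -5, gap extend -1. Any fixed scheme satisfies a
"higher-scoring candidate wins" rule; this one is documented and
configurable. Ties go to projection (the cheaper method).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import reverse_complement

from .chain import Chain, _merged_intervals as _merge

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class GeneModel:
    """A coding gene on a genome; coordinates 0-based half-open, cds strand-corrected."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    cds: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MapHit:
    """Image of one reference position under the coordinate map."""

    qry_id: str
    pos: int
    strand: str
    approximate: bool
    chain_index: int


class CoordinateMap:
    """Piecewise monotone reference → target position map built from filtered chains.

    Positions inside anchors map exactly; positions in inter-anchor gaps map
    to the nearest anchor boundary plus an offset clamped into the target-side
    gap, flagged approximate; positions outside all chains are unmapped
    (``None``). Reference positions covered by several chains resolve to the
    highest-scoring one; a chain completely shadowed by larger chains is an
    error (the chain list was not filtered).
    """

    def __init__(self, chains: list[Chain]):
        # Chains may overlap on the reference: exact-match anchors extend a
        # base or two across rearrangement junctions, and a small chain may
        # live entirely inside a larger chain's inter-anchor gap. Reference
        # positions are claimed in two passes — anchor-covered (exact)
        # regions first, then gap (approximate) regions — by descending
        # chain score within each pass, so a chain's own anchors always beat
        # a bigger chain's gap. A chain whose anchors are entirely shadowed
        # means the input was not filtered.
        order = sorted(range(len(chains)),
                       key=lambda i: (-chains[i].score, chains[i].ref_span[0], i))
        claimed: dict[str, list[tuple[int, int, int]]] = {}

        def subtract(segments, rid):
            for cs, ce, _ in claimed.get(rid, []):
                segments = [
                    piece
                    for seg in segments
                    for piece in ((seg[0], min(seg[1], cs)), (max(seg[0], ce), seg[1]))
                    if piece[0] < piece[1]
                ]
            return segments

        for idx in order:
            ch = chains[idx]
            footprint = _merge([(a.ref_start, a.ref_end) for a in ch.anchors])
            free = subtract(footprint, ch.ref_id)
            if not free:
                s, e = ch.ref_span
                raise ValueError(
                    f"chain over reference {ch.ref_id!r} [{s},{e}) is entirely "
                    "shadowed by larger chains; run filter_chains first"
                )
            claimed.setdefault(ch.ref_id, []).extend((s, e, idx) for s, e in free)
        for idx in order:
            ch = chains[idx]
            span = [ch.ref_span]
            for s, e in subtract(span, ch.ref_id):
                claimed.setdefault(ch.ref_id, []).append((s, e, idx))
        self._chains = chains
        self._by_ref = {rid: sorted(segs) for rid, segs in claimed.items()}
        self._starts = {rid: [s for s, _, _ in segs]
                        for rid, segs in self._by_ref.items()}

    def map_position(self, ref_id: str, pos: int) -> MapHit | None:
        spans = self._by_ref.get(ref_id)
        if not spans:
            return None
        i = bisect.bisect_right(self._starts[ref_id], pos) - 1
        if i < 0:
            return None
        s, e, idx = spans[i]
        if not (s <= pos < e):
            return None
        return self._map_in_chain(self._chains[idx], idx, pos)

    @staticmethod
    def _map_in_chain(ch: Chain, idx: int, pos: int) -> MapHit:
        anchors = ch.anchors
        starts = [a.ref_start for a in anchors]
        j = bisect.bisect_right(starts, pos) - 1
        a = anchors[j]
        if pos < a.ref_end:  # inside anchor: exact
            if ch.strand == "+":
                q = a.qry_start + (pos - a.ref_start)
            else:
                q = a.qry_end - 1 - (pos - a.ref_start)
            return MapHit(ch.qry_id, q, ch.strand, approximate=False, chain_index=idx)
        # in the gap between anchors[j] and anchors[j+1]
        b = anchors[j + 1]
        off = pos - a.ref_end
        if ch.strand == "+":
            lo, hi = a.qry_end, max(a.qry_end, b.qry_start - 1)
            q = min(max(a.qry_end + off, lo), hi)
        else:
            lo, hi = min(b.qry_end, a.qry_start - 1), a.qry_start - 1
            q = min(max(a.qry_start - 1 - off, lo), hi)
        return MapHit(ch.qry_id, q, ch.strand, approximate=True, chain_index=idx)


def build_coordinate_map(chains: list[Chain]) -> CoordinateMap:
    """Build the reference → target coordinate map from filtered chains."""
    return CoordinateMap(chains)


@dataclass
class Candidate:
    """A candidate target-genome gene model produced by one liftover method."""

    method: str  # "projection" | "realignment"
    seq_id: str
    start: int
    end: int
    strand: str
    cds: str
    approximate: bool = False
    disrupted: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class LiftoverResult:
    """Outcome of transferring one gene to the target genome."""

    gene_id: str
    method: str | None
    seq_id: str | None
    start: int | None
    end: int | None
    strand: str | None
    alignment_score: float | None
    status: str  # mapped | approximate | disrupted | unmapped
    notes: str = ""


def _compose_strand(a: str, b: str) -> str:
    return "+" if a == b else "-"


def project_gene(gene: GeneModel, cmap: CoordinateMap) -> Candidate | None:
    """Project a gene's boundaries through the coordinate map.

    Returns ``None`` when both boundaries are unmapped. The candidate is
    flagged disrupted when the boundaries land on different chains or
    scaffolds (or only one boundary maps); approximate when either boundary
    fell in an inter-anchor gap. The CDS is filled in later from the target
    sequence by :func:`lift_gene`.
    """
    h1 = cmap.map_position(gene.seq_id, gene.start)
    h2 = cmap.map_position(gene.seq_id, gene.end - 1)
    if h1 is None and h2 is None:
        return None
    if h1 is None or h2 is None:
        h = h1 or h2
        return Candidate(
            "projection", h.qry_id, h.pos, h.pos + 1, _compose_strand(gene.strand, h.strand),
            cds="", approximate=True, disrupted=True, notes=["one boundary unmapped"],
        )
    if h1.qry_id != h2.qry_id or h1.chain_index != h2.chain_index:
        return Candidate(
            "projection", h1.qry_id, h1.pos, h1.pos + 1, _compose_strand(gene.strand, h1.strand),
            cds="", approximate=True, disrupted=True,
            notes=["boundaries on different chains/scaffolds"],
        )
    start, end = min(h1.pos, h2.pos), max(h1.pos, h2.pos) + 1
    return Candidate(
        "projection", h1.qry_id, start, end, _compose_strand(gene.strand, h1.strand),
        cds="", approximate=h1.approximate or h2.approximate,
    )


def make_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap_open: float = -5.0,
    gap_extend: float = -1.0, glocal: bool = False,
) -> Align.PairwiseAligner:
    """Aligner with the module's scoring scheme.

    ``glocal=True`` makes end gaps free on the *target* side only (global
    coverage of the query CDS, local placement in the region).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend  # first gap base costs open+extend
    aligner.extend_gap_score = gap_extend
    if glocal:
        # free end gaps for unaligned target (region) overhangs: deletions
        # relative to the query CDS at the alignment ends cost nothing
        try:
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_gap_score = 0.0
    return aligner


def global_score(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global alignment score of two sequences under the module's scheme."""
    if aligner is None:
        aligner = make_aligner()
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    return float(aligner.score(a, b))


def _snap_orf(region: str, fs: int, fe: int, window: int = 30) -> tuple[int, int, list[str]]:
    """Snap an aligned footprint [fs, fe) to in-frame start/stop codons.

    Searches for a start codon within ``window`` bases of fs (in the frame of
    fs) and the in-frame stop codon whose end is nearest fe (within
    window + 3). Returns (start, end, notes); end includes the stop codon.
    """
    notes: list[str] = []
    start = None
    for d in sorted(range(-window, window + 1, 3), key=lambda d: (abs(d), d)):
        s = fs + d
        if 0 <= s and s + 3 <= len(region) and region[s : s + 3] in START_CODONS:
            start = s
            break
    if start is None:
        start = max(0, fs)
        notes.append("no_start_codon")
    stop_ends = []
    p = start + 3
    limit = min(len(region), fe + window + 3)
    while p + 3 <= limit + 3 and p + 3 <= len(region):
        if region[p : p + 3] in STOP_CODONS:
            stop_ends.append(p + 3)
        p += 3
    end = None
    in_window = [e for e in stop_ends if abs(e - fe) <= window + 3]
    if in_window:
        end = min(in_window, key=lambda e: (abs(e - fe), e))
        if any(e < end for e in stop_ends):
            notes.append("internal_stop")
    elif stop_ends:
        end = stop_ends[0]
        notes.append("premature_stop" if end < fe - window else "no_stop_in_window")
    else:
        end = start + ((max(fe, start + 3) - start) // 3) * 3
        notes.append("no_stop_codon")
    return start, end, notes


def realign_gene(
    gene: GeneModel,
    target: dict[str, str],
    cmap: CoordinateMap,
    pad: int = 2000,
    aligner: Align.PairwiseAligner | None = None,
) -> Candidate | None:
    """Re-model a gene by aligning its CDS to the projected target region.

    The projected span (possibly approximate or single-boundary) is widened
    by ``pad`` bases on each side, oriented to the expected strand, and the
    reference CDS is aligned to it with free end gaps on the region side.
    The aligned footprint is snapped to the nearest in-frame start and stop
    codons (±30 bases); internal stops and alignment gaps are noted.
    Returns ``None`` when the gene projects nowhere at all.
    """
    proj = project_gene(gene, cmap)
    if proj is None:
        return None
    seq = target.get(proj.seq_id)
    if seq is None:
        raise KeyError(f"target scaffold {proj.seq_id!r} absent from sequence set")
    span = proj.end - proj.start
    extra = pad + (gene.length if span < gene.length // 2 else 0)
    rs = max(0, proj.start - extra)
    re_ = min(len(seq), proj.end + extra)
    region_fwd = seq[rs:re_]
    if not region_fwd:
        return None
    strand = proj.strand
    region = region_fwd if strand == "+" else reverse_complement(region_fwd)
    if aligner is None:
        aligner = make_aligner(glocal=True)
    # region is the aligner's target (free end gaps); the CDS is covered globally
    aln = aligner.align(region, gene.cds)[0]
    blocks = aln.aligned[0]  # aligned blocks on the region
    if len(blocks) == 0:
        return None
    fs, fe = int(blocks[0][0]), int(blocks[-1][1])
    notes: list[str] = []
    ngaps = len(aln.aligned[1]) - 1
    if ngaps > 0:
        notes.append(f"alignment_gaps={ngaps}")
    start, end, snap_notes = _snap_orf(region, fs, fe)
    notes.extend(snap_notes)
    cds = region[start:end]
    if len(cds) % 3 != 0:
        notes.append("frameshift")
    if strand == "+":
        gstart, gend = rs + start, rs + end
    else:
        gstart, gend = re_ - end, re_ - start
    return Candidate(
        "realignment", proj.seq_id, gstart, gend, strand, cds,
        approximate=proj.approximate, disrupted=False, notes=notes,
    )


def _extract_cds(target: dict[str, str], cand: Candidate) -> str:
    seq = target[cand.seq_id][cand.start : cand.end]
    return seq if cand.strand == "+" else reverse_complement(seq)


def select_mapping(
    proj: Candidate | None,
    realn: Candidate | None,
    ref_cds: str,
    aligner: Align.PairwiseAligner | None = None,
) -> LiftoverResult:
    """Pick the candidate whose CDS globally aligns best to the reference CDS.

    Ties and single-candidate cases favor projection. Both candidates absent
    yields status ``unmapped``. The winning candidate's status is ``mapped``
    for an exact-boundary projection or a clean realignment, ``approximate``
    when a boundary fell in an alignment gap, ``disrupted`` when the
    projection straddled chains or scaffolds.
    """
    gene_id = ""  # filled by lift_gene
    if aligner is None:
        aligner = make_aligner()
    scored: list[tuple[float, int, Candidate]] = []
    for rank, cand in ((0, proj), (1, realn)):
        if cand is None or not cand.cds:
            continue
        scored.append((global_score(cand.cds, ref_cds, aligner), rank, cand))
    if not scored:
        if proj is not None and proj.disrupted:
            return LiftoverResult(
                gene_id, "projection", proj.seq_id, proj.start, proj.end, proj.strand,
                None, "disrupted", ";".join(proj.notes),
            )
        return LiftoverResult(gene_id, None, None, None, None, None, None, "unmapped")
    score, _, best = max(scored, key=lambda t: (t[0], -t[1]))
    if best.disrupted:
        status = "disrupted"
    elif best.approximate and best.method == "projection":
        status = "approximate"
    elif "no_start_codon" in best.notes or "no_stop_codon" in best.notes or "frameshift" in best.notes:
        status = "approximate"
    else:
        status = "mapped"
    return LiftoverResult(
        gene_id, best.method, best.seq_id, best.start, best.end, best.strand,
        score, status, ";".join(best.notes),
    )


def lift_gene(
    gene: GeneModel,
    target: dict[str, str],
    cmap: CoordinateMap,
    pad: int = 2000,
) -> LiftoverResult:
    """Transfer one gene to the target genome by both methods and keep the best."""
    proj = project_gene(gene, cmap)
    if proj is not None and not proj.disrupted:
        proj.cds = _extract_cds(target, proj)
    realn = realign_gene(gene, target, cmap, pad=pad)
    res = select_mapping(proj, realn, gene.cds)
    res.gene_id = gene.gene_id
    return res


def lift_genes(
    genes: list[GeneModel],
    target: dict[str, str],
    cmap: CoordinateMap,
    pad: int = 2000,
) -> list[LiftoverResult]:
    return [lift_gene(g, target, cmap, pad=pad) for g in genes]


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def reconcile_orfs(
    mapped: list[LiftoverResult],
    abinitio: list[GeneModel],
    min_reciprocal_overlap: float = 0.5,
) -> list[GeneModel]:
    """Merge lifted genes with ab initio ORFs on the target genome.

    Same-strand, same-scaffold pairs whose reciprocal overlap meets the
    threshold merge into a single gene at the mapped coordinates, inheriting
    the reference gene id; pairs are assigned greedily by descending
    reciprocal overlap, each record used once. Unpaired entries pass through
    (ab initio ORFs as novel genes). Output sorted by (seq_id, start).
    """
    placed = [r for r in mapped if r.status in ("mapped", "approximate") and r.start is not None]
    pairs = []
    for i, r in enumerate(placed):
        for j, g in enumerate(abinitio):
            if r.seq_id != g.seq_id or r.strand != g.strand:
                continue
            ov = _reciprocal_overlap(r.start, r.end, g.start, g.end)
            if ov >= min_reciprocal_overlap:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_m: set[int] = set()
    used_a: set[int] = set()
    out: list[GeneModel] = []
    for ov, i, j in pairs:
        if i in used_m or j in used_a:
            continue
        used_m.add(i)
        used_a.add(j)
        r = placed[i]
        out.append(GeneModel(r.gene_id, r.seq_id, r.start, r.end, r.strand,
                             product="merged:mapped+ab_initio"))
    for i, r in enumerate(placed):
        if i not in used_m:
            out.append(GeneModel(r.gene_id, r.seq_id, r.start, r.end, r.strand,
                                 product="mapped_only"))
    for j, g in enumerate(abinitio):
        if j not in used_a:
            out.append(GeneModel(g.gene_id, g.seq_id, g.start, g.end, g.strand,
                                 cds=g.cds, product="ab_initio_only"))
    out.sort(key=lambda g: (g.seq_id, g.start, g.end, g.gene_id))
    return out


def find_orfs(seqs: dict[str, str], min_len: int = 90) -> list[GeneModel]:
    """Trivial six-frame longest-ORF finder (plumbing for reconciliation).

    Reports, per stop-to-stop segment in each frame and strand, the ORF from
    the first ATG to the closing stop codon, when at least ``min_len`` bases
    long (stop included).
    """
    out: list[GeneModel] = []
    n = 0
    for name, fwd in sorted(seqs.items()):
        for strand, seq in (("+", fwd), ("-", reverse_complement(fwd))):
            L = len(seq)
            for frame in range(3):
                first_atg = None
                for p in range(frame, L - 2, 3):
                    codon = seq[p : p + 3]
                    if first_atg is None and codon == "ATG":
                        first_atg = p
                    if codon in STOP_CODONS:
                        if first_atg is not None and (p + 3 - first_atg) >= min_len:
                            n += 1
                            s, e = first_atg, p + 3
                            if strand == "-":
                                s, e = L - e, L - s
                            out.append(GeneModel(f"orf_{n:05d}", name, s, e, strand))
                        seg_start = p + 3
                        first_atg = None
    out.sort(key=lambda g: (g.seq_id, g.start, g.end, g.strand))
    return out
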