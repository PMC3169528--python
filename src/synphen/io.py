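"""File I/O: FASTA, GFF3, anchor tables, chain tables, liftover tables.

All text formats use 1-based inclusive coordinates; the in-memory
convention is 0-based half-open. FASTA goes through Biopython; the
anchor dialect is tab-delimited
``ref_id qry_id ref_start ref_end qry_start qry_end strand length``
and the reader also accepts show-coords ``-T`` tabular output.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chain import Anchor, Chain
from .liftover import GeneModel, LiftoverResult

ANCHOR_COLUMNS = ["ref_id", "qry_id", "ref_start", "ref_end",
                  "qry_start", "qry_end", "strand", "length"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def write_anchors(anchors: list[Anchor], path) -> None:
    rows = [
        {
            "ref_id": a.ref_id, "qry_id": a.qry_id,
            "ref_start": a.ref_start + 1, "ref_end": a.ref_end,
            "qry_start": a.qry_start + 1, "qry_end": a.qry_end,
            "strand": a.strand, "length": a.length,
        }
        for a in anchors
    ]
    pd.DataFrame(rows, columns=ANCHOR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_anchors(path) -> list[Anchor]:
    """Read the native anchor dialect, or show-coords -T tabular output.

    show-coords -T lines have columns S1 E1 S2 E2 LEN1 LEN2 %IDY TAGS
    (reference then query tags); minus-strand hits carry E2 < S2.
    Only 100%-identity hits of equal length are accepted as anchors.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("ref_id"):
        df = pd.read_csv(path, sep="\t")
        out = []
        for row in df.itertuples(index=False):
            out.append(Anchor(row.ref_id, row.qry_id, row.ref_start - 1, row.ref_end,
                              row.qry_start - 1, row.qry_end, row.strand))
        return out
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or not parts[0].isdigit():
                continue  # headers of show-coords output
            s1, e1, s2, e2 = (int(parts[i]) for i in range(4))
            ref_id, qry_id = parts[-2], parts[-1]
            if s2 <= e2:
                strand, qs, qe = "+", s2, e2
            else:
                strand, qs, qe = "-", e2, s2
            out.append(Anchor(ref_id, qry_id, s1 - 1, e1, qs - 1, qe, strand))
    return out


def write_chains(chains: list[Chain], path) -> None:
    """Write chains as BED-like intervals plus a chain-membership column."""
    rows = []
    for ci, ch in enumerate(chains):
        for a in ch.anchors:
            rows.append({
                "ref_id": a.ref_id, "ref_start": a.ref_start + 1, "ref_end": a.ref_end,
                "qry_id": a.qry_id, "qry_start": a.qry_start + 1, "qry_end": a.qry_end,
                "strand": a.strand, "chain": ci, "chain_score": ch.score,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seq_id, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([
                g.seq_id, "synphen", "CDS", str(g.start + 1), str(g.end),
                ".", g.strand, "0", attrs,
            ]) + "\n")


def read_gff3(path, seqs: dict[str, str] | None = None) -> list[GeneModel]:
    """Read CDS features from a minimal GFF3; fill CDS strings when seqs given."""
    from Bio.Seq import reverse_complement

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            g = GeneModel(
                gene_id=attrs.get("ID", f"gene_{len(out) + 1}"),
                seq_id=parts[0], start=int(parts[3]) - 1, end=int(parts[4]),
                strand=parts[6], product=attrs.get("product", ""),
            )
            if seqs is not None and g.seq_id in seqs:
                sub = seqs[g.seq_id][g.start:g.end]
                g.cds = sub if g.strand == "+" else reverse_complement(sub)
            out.append(g)
    return out


def write_liftover_results(results: list[LiftoverResult], path) -> None:
    rows = []
    for r in results:
        rows.append({
            "gene_id": r.gene_id, "method": r.method, "seq_id": r.seq_id,
            "start": None if r.start is None else r.start + 1,
            "end": r.end, "strand": r.strand, "score": r.alignment_score,
            "status": r.status, "notes": r.notes,
        })
    pd.DataFrame(rows, columns=["gene_id", "method", "seq_id", "start", "end",
                                "strand", "score", "status", "notes"]).to_csv(
        path, index=False)
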