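#!/usr/bin/env python
"""Build the whole-genome synteny map: anchors -> chains -> filtered chains.

Finds maximal reference-unique exact matches between the reference and
the derived scaffolds, chains collinear anchors with the 10 kb gap
allowance, filters chains by the 90% overlap rule, and writes the anchor
and chain tables under results/synteny/.
"""

from pathlib import Path

import synphen as sp
from synphen import io

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "synteny"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = io.read_fasta(BASE / "data" / "reference.fasta")
    scaffolds = io.read_fasta(BASE / "data" / "derived_scaffolds.fasta")

    anchors = sp.find_anchors(ref, scaffolds, k=20)
    io.write_anchors(anchors, OUT / "anchors.tsv")
    chains = sp.build_chains(anchors, max_gap=10_000)
    filtered = sp.filter_chains(chains, overlap_frac=0.9)
    io.write_chains(filtered, OUT / "chains.tsv")

    print(f"{len(anchors)} anchors -> {len(chains)} chains -> "
          f"{len(filtered)} after the 90% overlap filter")
    for c in filtered:
        print(f"  {c.qry_id} {c.strand} ref {c.ref_span[0] + 1}-{c.ref_span[1]} "
              f"qry {c.qry_span[0] + 1}-{c.qry_span[1]} ({len(c)} anchors, "
              f"score {c.score})")


if __name__ == "__main__":
    main()
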