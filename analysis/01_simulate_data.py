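#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes a reference/derived genome pair (FASTA + GFF3 + truth tables), a
four-species 190-compound growth screen (long-format plate CSV), a
planted-partition protein-similarity edge list, and degradability
prediction tables for an "initial" and a "refined" model, all under
results/data/.
"""

import json
from pathlib import Path

import pandas as pd

import synphen as sp
from synphen import io

SEED = 20110901
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    pair = sp.simulate_genome_pair(
        ref_length=60_000, n_genes=12, sub_rate=0.01, indel_rate=0.0,
        n_inversions=1, n_translocations=1, n_scaffolds=4, seed=SEED,
        rearrangement_len=(11_000, 15_000),
    )
    io.write_fasta({"reference": pair.reference}, OUT / "reference.fasta")
    io.write_fasta(pair.derived_scaffolds, OUT / "derived_scaffolds.fasta")
    io.write_gff3(pair.genes, OUT / "reference_genes.gff3")
    truth_rows = []
    for g in pair.genes:
        im = pair.gene_images[g.gene_id]
        truth_rows.append({
            "gene_id": g.gene_id, "scaffold": im.scaffold,
            "start": None if im.start is None else im.start + 1, "end": im.end,
            "strand": im.strand, "disrupted": im.disrupted, "intact": im.intact,
        })
    pd.DataFrame(truth_rows).to_csv(OUT / "gene_image_truth.csv", index=False)
    print(f"genome pair: {len(pair.reference)} bp reference, "
          f"{len(pair.derived_scaffolds)} derived scaffolds, "
          f"{len(pair.event_log)} logged events, {len(pair.genes)} planted genes")

    truth = sp.default_plate_truth(noise_sd=0.02, seed=SEED)
    meas = sp.simulate_plate_screen(truth, growth_amplitude=0.6, seed=SEED + 1)
    meas.to_csv(OUT / "plate_measurements.csv", index=False)
    pd.DataFrame(
        [{"species": s, "compound": c, "grows": v}
         for (s, c), v in truth.growth_truth.items()]
    ).to_csv(OUT / "growth_truth.csv", index=False)
    print(f"plate screen: {len(truth.species)} species x {len(truth.compounds)} "
          f"compounds at {truth.timepoints} h, noise sd {truth.noise_sd}")

    blocks = [[f"fam{b}_g{i}" for i in range(6)] for b in range(5)]
    gt = sp.GraphTruth(blocks=blocks, p_within=0.9, p_between=0.0)
    edges = sp.simulate_similarity_graph(gt, seed=SEED + 2)
    edges.to_csv(OUT / "similarity_edges.tsv", sep="\t", index=False)
    json.dump(blocks, open(OUT / "planted_families.json", "w"), indent=1)
    print(f"similarity graph: {sum(map(len, blocks))} genes, {len(edges)} edges")

    growth_sp1 = pd.Series({c: truth.growth_truth[(truth.species[0], c)]
                            for c, _ in truth.compounds})
    for version, fp, fn in [("initial", 0.35, 0.30), ("refined", 0.20, 0.15)]:
        preds = sp.simulate_predictions(growth_sp1, fp, fn, seed=SEED + 3,
                                        model_version=version)
        preds.to_csv(OUT / f"predictions_{version}.csv", index=False)
    print(f"predictions: 2 model versions over {len(growth_sp1)} compounds")


if __name__ == "__main__":
    main()
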