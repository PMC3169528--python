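#!/usr/bin/env python
"""Normalize the growth screen, call substrates, cluster and summarize.

Applies the two-step background subtraction (uninoculated plate, then
no-carbon controls), calls growth substrates at A590 > 0.2 after 96 h,
clusters compounds by centered Pearson correlation with average linkage,
tallies substrates per chemical category, and checks the calls against
the planted truth. Writes results/plates/.
"""

from pathlib import Path

import pandas as pd

import synphen as sp
from synphen.plates import linkage_to_newick

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "plates"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meas = sp.load_plate_csv(BASE / "data" / "plate_measurements.csv")
    truth = pd.read_csv(BASE / "data" / "growth_truth.csv")

    matrix = sp.normalize_plates(meas)
    matrix.values.to_csv(OUT / "normalized_matrix.csv")
    calls = sp.call_growth(matrix, threshold=0.2, call_time=96.0)
    calls.calls.rename("growth").to_csv(OUT / "growth_calls.csv")

    truth_map = {(r.species, r.compound): r.grows for r in truth.itertuples(index=False)}
    n = len(calls.calls)
    correct = sum(bool(v) == truth_map[k] for k, v in calls.calls.items())
    print(f"growth calls: {int(calls.calls.sum())}/{n} positive; "
          f"accuracy vs planted truth {100.0 * correct / n:.1f}%")

    summary = sp.summarize_categories(calls)
    summary.to_csv(OUT / "category_summary.csv", index=False)
    for species, sub in summary.groupby("species"):
        counts = ", ".join(f"{r.category}: {r.n_growth}/{r.n_tested}"
                           for r in sub.itertuples(index=False))
        print(f"  {species}: {counts}")

    linkage, order = sp.cluster_compounds(matrix)
    (OUT / "compound_dendrogram.nwk").write_text(
        linkage_to_newick(linkage, sorted({c for _, c in calls.calls.index})) + "\n")
    ordered = matrix.values.unstack("species").loc[order]
    ordered.to_csv(OUT / "heatmap_matrix.tsv", sep="\t")
    print(f"clustered {len(order)} compounds ({linkage.shape[0]} merges); "
          f"leaf order written for heatmap rendering")


if __name__ == "__main__":
    main()
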