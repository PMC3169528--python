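# synphen

Comparative-genomics and phenotype-screen analysis pipeline for oleaginous
*Rhodococcus* — synteny mapping and annotation liftover between bacterial
genomes, reference-guided scaffold stitching, Biolog-style growth-screen
calling, Markov clustering of protein families for the triacylglycerol (TAGs)
cycle, and concordance between metabolic-model degradability predictions and
observed growth.

## The problem

*Rhodococcus opacus* PD630 converts a wide range of organic substrates into
triacylglycerols. Characterizing that capability from a draft genome requires
a chain of bespoke computations around standard tools:

* **Synteny map** — maximal reference-unique exact matches (anchors) between
  a finished relative's genome and the draft contigs are chained when
  collinear, allowing up to 10,000 bases of undetectable similarity between
  anchors, then chains that a larger chain overlaps by more than 90% of their
  length on either sequence are discarded.
* **Gene liftover** — each reference gene is transferred two ways: by
  projecting its boundaries through the synteny map, and by re-aligning its
  CDS to the projected target region (free end gaps on the region side,
  affine gaps, snap to in-frame start/stop codons); the candidate whose CDS
  scores higher in a global alignment against the reference CDS wins, and the
  result is reconciled with ab initio ORFs by reciprocal overlap.
* **Scaffold stitching** — draft scaffolds are ordered and oriented by their
  best synteny chains and concatenated with runs of 500 N into a
  pseudo-genome, described by an AGP v2.1 file.
* **Growth screen** — A590 plate readings at 44/72/96 h are normalized by
  subtracting the matching well of an uninoculated plate, averaging
  replicates, then subtracting the mean of the species' inoculated no-carbon
  control wells; a compound is a growth substrate when the normalized 96-h
  value exceeds 0.2. Compounds are clustered by centered Pearson correlation
  with average linkage and tallied per chemical category.
* **Gene families** — BLASTP-style similarity edges (e-value ≤ 1e-5, ≥ 10%
  aligned) weighted by −log10(e-value) are clustered with the Markov Cluster
  process at inflation 1.5 (the TribeMCL construction); families are
  cross-tabulated with per-gene species and EC assignments into the
  species × reaction count matrix behind TAGs-cycle heatmaps (display
  saturation at 15 genes; merged categories such as EC 6.2.1.1/2/3).
* **Concordance** — predicted-degradable vs observed-growth confusion counts
  give precision, recall, FPR, FNR, specificity and accuracy per model
  version, plus delta-by-refinement (refined − initial).

Every stage is driven by a synthetic-data generator with planted ground truth
(genome pairs with logged substitutions/indels/inversions/translocations and
scaffold fragmentation; plate time courses with plate offsets, compound
backgrounds and Gaussian noise; planted-partition similarity graphs;
prediction tables with planted error rates), so the whole pipeline is
testable without downloads.

## Worked example

```sh
python analysis/01_simulate_data.py
python analysis/02_synteny_map.py
python analysis/03_liftover_genes.py
```

which prints (fixed seed):

```
genome pair: 60000 bp reference, 4 derived scaffolds, 572 logged events, 12 planted genes
479 anchors -> 9 chains -> 9 after the 90% overlap filter
lifted 12 genes: statuses {'mapped': 11, 'approximate': 1}, methods {'projection': 10, 'realignment': 2}
exact-coordinate recovery on intact genes: 10/10 (100.0%)
```

The 60 kb reference carries 12 planted ORFs and the derived genome differs by
1% substitutions, one >10 kb inversion, one >10 kb translocation and
fragmentation into four scaffolds. Nine filtered chains tile the reference
(one per collinear block); the two genes cut by rearrangement breakpoints are
reported but excluded from the exact-recovery denominator; all ten intact
genes land at exactly their true coordinates. The remaining drivers
(`04`–`07`) stitch the scaffolds (61,500 bp = 60,000 scaffold bases + 3 × 500
N spacers), call the 190-compound screen at 100% accuracy against the planted
truth, recover all five planted gene families by MCL, and report concordance
metrics for an initial vs a refined simulated prediction set, e.g.

```
initial: TP=61 FP=33 TN=74 FN=22 precision=0.649 recall=0.735 accuracy=0.711
refined: TP=74 FP=25 TN=82 FN=9 precision=0.747 recall=0.892 accuracy=0.821
```

All outputs are written under `results/`.

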