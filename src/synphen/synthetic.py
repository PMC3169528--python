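"""Synthetic fixtures with known ground truth for every pipeline stage.

Four generators emulate the study's data with planted truth so that
chaining, liftover, stitching, growth calling, family clustering and
concordance can all be validated without external downloads:

* :func:`simulate_genome_pair` — a reference genome with planted ORFs
  and a derived genome related by substitutions, indels, inversions,
  translocations and scaffold fragmentation, with a per-position
  coordinate map and per-gene image truth (emulating a finished
  reference vs a draft relative's assembly);
* :func:`simulate_plate_screen` — plate absorbance time courses with
  per-plate offsets, per-compound chemical backgrounds, uninoculated
  plates, inoculated no-carbon control wells and truncated Gaussian
  noise around a known growth-truth table;
* :func:`simulate_similarity_graph` — a protein-similarity edge list
  with planted families (planted-partition random graph);
* :func:`simulate_predictions` — degradability predictions derived from
  a growth truth with planted false-positive/false-negative rates.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .liftover import GeneModel, STOP_CODONS

BASES = "ACGT"


# ---------------------------------------------------------------------------
# genome pair


@dataclass
class Event:
    """One mutational event; intervals are in the coordinate frame current
    at application time (events replay strictly in log order)."""

    kind: str  # substitution | insertion | deletion | inversion | translocation | fragmentation
    interval: tuple[int, int]
    params: dict = field(default_factory=dict)


@dataclass
class GeneImage:
    """Image of a reference gene on the derived genome."""

    scaffold: str | None
    start: int | None
    end: int | None
    strand: str | None
    disrupted: bool
    intact: bool  # contiguous, length-preserving image (substitutions only)


@dataclass
class GenomePairTruth:
    reference: str
    derived_scaffolds: dict[str, str]
    event_log: list[Event]
    coordinate_map: dict  # ref position -> (scaffold, pos, strand) or "deleted"
    genes: list[GeneModel]
    gene_images: dict[str, GeneImage]
    seed: int


# internal representation: derived genome as a list of mutable records
# [ref_pos (or -1 for inserted bases), strand (+1/-1), base, rearranged-flag]


def _items_from_reference(reference: str) -> list[list]:
    return [[i, 1, b, False] for i, b in enumerate(reference)]


def _apply_event(items: list[list], ev: Event, scaffold_cuts: list[int] | None = None):
    """Apply one event to the derived-genome item list, in place."""
    s, e = ev.interval
    if ev.kind == "substitution":
        items[s][2] = ev.params["to"]
    elif ev.kind == "deletion":
        del items[s:e]
    elif ev.kind == "insertion":
        ins = [[-1, 1, b, False] for b in ev.params["bases"]]
        items[s:s] = ins
    elif ev.kind == "inversion":
        seg = items[s:e]
        seg.reverse()
        for it in seg:
            it[1] = -it[1]
            it[2] = reverse_complement(it[2])
            it[3] = True
        items[s:e] = seg
    elif ev.kind == "translocation":
        dest = ev.params["dest"]
        seg = items[s:e]
        for it in seg:
            it[3] = True
        del items[s:e]
        if dest > s:
            dest -= e - s
        items[dest:dest] = seg
    elif ev.kind == "fragmentation":
        if scaffold_cuts is not None:
            scaffold_cuts.extend(ev.params["cuts"])
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")


def replay_events(reference: str, event_log: list[Event]) -> dict[str, str]:
    """Reconstruct the derived scaffolds by replaying the event log."""
    items = _items_from_reference(reference)
    cuts: list[int] = []
    for ev in event_log:
        _apply_event(items, ev, cuts)
    return _split_scaffolds(items, cuts)[0]


def _split_scaffolds(items: list[list], cuts: list[int]):
    bounds = [0] + sorted(cuts) + [len(items)]
    scaffolds: dict[str, str] = {}
    chunks: dict[str, list[list]] = {}
    for i, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
        name = f"scaffold_{i}"
        scaffolds[name] = "".join(it[2] for it in items[a:b])
        chunks[name] = items[a:b]
    return scaffolds, chunks


def _plant_genes(
    seq: list[str], n_genes: int, rng: np.random.Generator,
    min_len: int = 300, max_len: int = 900, margin: int = 100, spacing: int = 60,
) -> list[GeneModel]:
    L = len(seq)
    if n_genes * (min_len + spacing) + 2 * margin > L:
        raise ValueError(
            f"cannot place {n_genes} genes of >= {min_len} bp in a {L} bp reference"
        )
    sense_codons = [a + b + c for a in BASES for b in BASES for c in BASES
                    if a + b + c not in STOP_CODONS]
    placed: list[tuple[int, int]] = []
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        length = int(rng.integers(min_len // 3, max_len // 3 + 1)) * 3
        for _ in range(200):
            start = int(rng.integers(margin, L - margin - length))
            end = start + length
            if all(end + spacing <= s or start >= e + spacing for s, e in placed):
                break
        else:
            raise ValueError(
                f"could not place gene {gi + 1} of {n_genes} after 200 attempts; "
                "too many genes for this reference length"
            )
        placed.append((start, end))
        n_codons = length // 3 - 2
        body = "".join(rng.choice(sense_codons) for _ in range(n_codons))
        cds = "ATG" + body + str(rng.choice(STOP_CODONS))
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cds if strand == "+" else reverse_complement(cds)
        seq[start:end] = list(genomic)
        genes.append(GeneModel(f"gene_{gi + 1:04d}", "reference", start, end,
                               strand, cds=cds, product=f"planted ORF {gi + 1}"))
    genes.sort(key=lambda g: g.start)
    return genes


def _choose_interval(
    rng: np.random.Generator, items: list[list], min_len: int, max_len: int,
    attempts: int = 100,
) -> tuple[int, int]:
    """Pick an interval none of whose items was rearranged before."""
    n = len(items)
    hi = min(max_len, max(min_len, n // 3))
    for _ in range(attempts):
        length = int(rng.integers(min_len, hi + 1))
        if length >= n:
            continue
        s = int(rng.integers(0, n - length))
        if not any(items[i][3] for i in range(s, s + length)):
            return s, s + length
    raise ValueError(
        f"could not place a non-overlapping rearrangement interval in {attempts} attempts"
    )


def simulate_genome_pair(
    ref_length: int,
    n_genes: int,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    n_inversions: int = 0,
    n_translocations: int = 0,
    n_scaffolds: int = 1,
    seed: int = 0,
    max_indel_len: int = 10,
    rearrangement_len: tuple[int, int] = (500, 5000),
) -> GenomePairTruth:
    """Simulate a reference genome and a derived, rearranged draft relative.

    Planted genes are non-overlapping complete ORFs (ATG start, TAA/TAG/TGA
    stop, length a multiple of 3, both strands). Substitutions and indels
    are drawn per base; inversions and translocations act on mutually
    non-overlapping intervals (resampled up to 100 times, then an error);
    finally the derived sequence is fragmented into ``n_scaffolds`` pieces.
    The event log replays to the derived scaffolds exactly; the coordinate
    map gives every reference position's image (or "deleted"); per-gene
    images record disruption (split by a breakpoint) and intactness
    (contiguous, length-preserving image).
    """
    if ref_length < 1000:
        raise ValueError("ref_length must be >= 1000")
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    rng = np.random.default_rng(seed)

    seq = list(rng.choice(list(BASES), size=ref_length))
    genes = _plant_genes(seq, n_genes, rng)
    reference = "".join(seq)

    event_log: list[Event] = []
    items = _items_from_reference(reference)

    def log_and_apply(ev: Event):
        event_log.append(ev)
        _apply_event(items, ev, None)

    if sub_rate > 0:
        hits = np.flatnonzero(rng.random(ref_length) < sub_rate)
        for p in hits:
            old = reference[p]
            new = str(rng.choice([b for b in BASES if b != old]))
            log_and_apply(Event("substitution", (int(p), int(p) + 1),
                                {"from": old, "to": new}))
    if indel_rate > 0:
        n_ind = int(rng.binomial(ref_length, indel_rate))
        positions = sorted(rng.choice(ref_length, size=min(n_ind, ref_length),
                                      replace=False), reverse=True)
        for p in positions:
            length = int(rng.integers(1, max_indel_len + 1))
            if rng.random() < 0.5:
                end = min(int(p) + length, len(items))
                if end > int(p):
                    log_and_apply(Event("deletion", (int(p), end), {"length": end - int(p)}))
            else:
                bases = "".join(rng.choice(list(BASES), size=length))
                log_and_apply(Event("insertion", (int(p), int(p) + length),
                                    {"bases": bases}))

    lo, hi = rearrangement_len
    for _ in range(n_inversions):
        s, e = _choose_interval(rng, items, lo, hi)
        log_and_apply(Event("inversion", (s, e), {}))
    for _ in range(n_translocations):
        s, e = _choose_interval(rng, items, lo, hi)
        for _ in range(100):
            dest = int(rng.integers(0, len(items) - (e - s) + 1))
            if dest < s or dest >= e:
                probe = dest if dest < s else dest + (e - s)
                if probe >= len(items) or not items[min(probe, len(items) - 1)][3]:
                    break
        else:
            raise ValueError("could not place translocation destination in 100 attempts")
        log_and_apply(Event("translocation", (s, e), {"dest": dest}))

    cuts: list[int] = []
    if n_scaffolds > 1:
        if len(items) < n_scaffolds:
            raise ValueError("derived genome shorter than requested scaffold count")
        cuts = sorted(int(c) for c in rng.choice(
            np.arange(1, len(items)), size=n_scaffolds - 1, replace=False))
    event_log.append(Event("fragmentation", (0, len(items)), {"cuts": cuts}))

    scaffolds, chunks = _split_scaffolds(items, cuts)

    coordinate_map: dict = {p: "deleted" for p in range(ref_length)}
    for name, chunk in chunks.items():
        for pos, it in enumerate(chunk):
            if it[0] >= 0:
                coordinate_map[it[0]] = (name, pos, "+" if it[1] > 0 else "-")

    gene_images = {g.gene_id: _gene_image(g, coordinate_map) for g in genes}

    return GenomePairTruth(
        reference=reference, derived_scaffolds=scaffolds, event_log=event_log,
        coordinate_map=coordinate_map, genes=genes, gene_images=gene_images,
        seed=seed,
    )


def _gene_image(gene: GeneModel, cmap: dict) -> GeneImage:
    hits = [cmap[p] for p in range(gene.start, gene.end)]
    present = [h for h in hits if h != "deleted"]
    if not present:
        return GeneImage(None, None, None, None, disrupted=True, intact=False)
    scaffolds = {h[0] for h in present}
    strands = {h[2] for h in present}
    if len(scaffolds) > 1 or len(strands) > 1:
        return GeneImage(None, None, None, None, disrupted=True, intact=False)
    scaf = next(iter(scaffolds))
    block_strand = next(iter(strands))
    positions = [h[1] for h in present]
    start, end = min(positions), max(positions) + 1
    strand = gene.strand if block_strand == "+" else ("-" if gene.strand == "+" else "+")
    # a breakpoint through the gene scatters its image far beyond its length;
    # small internal indels merely stretch or shrink it
    disrupted = (end - start) > 2 * len(hits)
    contiguous = (
        not disrupted
        and len(present) == len(hits)
        and end - start == len(hits)
        and positions == (sorted(positions) if block_strand == "+"
                          else sorted(positions, reverse=True))
    )
    if disrupted:
        return GeneImage(scaf, start, end, strand, disrupted=True, intact=False)
    return GeneImage(scaf, start, end, strand,
                     disrupted=False, intact=contiguous)


# ---------------------------------------------------------------------------
# plate screen


@dataclass
class PlateTruth:
    """Ground truth and noise model for a simulated growth screen.

    ``growth_truth`` maps (species, compound) -> bool. ``baseline`` is the
    carbon-independent signal of inoculated wells (dye reduction by the
    inoculum itself); ``plate_offset_sd`` scatters a per-plate additive
    offset; ``compound_offset_sd`` scatters a per-compound chemical
    background applied identically to inoculated and uninoculated plates.
    """

    species: list[str]
    compounds: list[tuple[str, str]]  # (name, category)
    growth_truth: dict[tuple[str, str], bool]
    plate_offset: float = 0.1
    plate_offset_sd: float = 0.02
    compound_offset_sd: float = 0.05
    baseline: float = 0.1
    noise_sd: float = 0.0
    timepoints: tuple[float, ...] = (44.0, 72.0, 96.0)
    n_no_carbon: int = 6
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not self.species or not self.compounds:
            raise ValueError("species and compound lists must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_no_carbon < 1:
            raise ValueError("need at least one no-carbon control well")
        for sp in self.species:
            for name, _ in self.compounds:
                if (sp, name) not in self.growth_truth:
                    raise ValueError(f"growth_truth missing ({sp!r}, {name!r})")


# the screen's four chemical categories with the tested compound counts
# (64 carboxylic acids, 38 nitrogenous, 71 carbohydrates/alcohols, 17
# oligosaccharides: 190 compounds in total)
CATEGORY_COUNTS = {
    "carboxylic acids": 64,
    "nitrogen containing": 38,
    "carbohydrates and alcohols": 71,
    "oligosaccharides": 17,
}
CATEGORIES = tuple(CATEGORY_COUNTS)

DEFAULT_SPECIES = [
    "R. opacus PD630",
    "R. jostii RHA1",
    "C. glutamicum 13032",
    "R. eutropha H16",
]


def default_plate_truth(
    species: list[str] | None = None,
    n_compounds: int = 190,
    growth_fraction: float = 0.45,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> PlateTruth:
    """A default screen emulating the study conditions: four species and
    190 compounds split over the four chemical categories in the tested
    proportions (scaled when ``n_compounds`` differs), growth truth drawn
    independently per species at ``growth_fraction``."""
    rng = np.random.default_rng(seed)
    if species is None:
        species = list(DEFAULT_SPECIES)
    total = sum(CATEGORY_COUNTS.values())
    quota = {c: n_compounds * k / total for c, k in CATEGORY_COUNTS.items()}
    alloc = {c: int(q) for c, q in quota.items()}
    for c in sorted(quota, key=lambda c: quota[c] - alloc[c], reverse=True):
        if sum(alloc.values()) == n_compounds:
            break
        alloc[c] += 1
    compounds = []
    i = 0
    for c in CATEGORIES:
        for _ in range(alloc[c]):
            compounds.append((f"compound_{i + 1:03d}", c))
            i += 1
    truth = {(sp, name): bool(rng.random() < growth_fraction)
             for sp in species for name, _ in compounds}
    return PlateTruth(species=species, compounds=compounds, growth_truth=truth,
                      noise_sd=noise_sd, **kwargs)


def simulate_plate_screen(
    truth: PlateTruth, growth_amplitude: float = 0.6, seed: int = 0
) -> pd.DataFrame:
    """Emit raw plate readings (long format) for a planted growth truth.

    Each species gets one plate per replicate holding every compound plus
    ``n_no_carbon`` inoculated no-carbon wells; one uninoculated plate with
    the same layout is emitted. A growth well's expected 96-h reading is
    plate offset + compound background + baseline + ``growth_amplitude``
    (growth ramps linearly to its 96-h level); noise is Gaussian, truncated
    at zero absorbance.
    """
    if growth_amplitude < 0:
        raise ValueError("growth_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    comp_offset = {name: float(rng.normal(0.0, truth.compound_offset_sd))
                   for name, _ in truth.compounds}
    cat = dict(truth.compounds)
    layout: list[tuple[str, str, str]] = []  # (well, compound, category)
    wi = 0
    for name, c in truth.compounds:
        layout.append((f"W{wi + 1:03d}", name, c))
        wi += 1
    for k in range(truth.n_no_carbon):
        layout.append((f"W{wi + 1:03d}", NO_CARBON, "control"))
        wi += 1

    rows = []

    def emit(plate_id, species_label, growing: dict | None, offset: float):
        for well, compound, category in layout:
            for t in truth.timepoints:
                mu = offset + comp_offset.get(compound, 0.0)
                if species_label != "uninoculated":
                    mu += truth.baseline
                    if growing is not None and growing.get(compound, False):
                        mu += growth_amplitude * (t / max(truth.timepoints))
                a = mu + (rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0)
                rows.append({
                    "plate_id": plate_id, "well": well, "species": species_label,
                    "compound": compound, "category": category,
                    "time_h": t, "a590": max(a, 0.0),
                })

    uninoc_offset = truth.plate_offset + (
        float(rng.normal(0.0, truth.plate_offset_sd)) if truth.plate_offset_sd > 0 else 0.0)
    emit("uninoc_1", "uninoculated", None, uninoc_offset)
    for sp in truth.species:
        growing = {name: truth.growth_truth[(sp, name)] for name, _ in truth.compounds}
        for rep in range(truth.n_replicates):
            offset = truth.plate_offset + (
                float(rng.normal(0.0, truth.plate_offset_sd))
                if truth.plate_offset_sd > 0 else 0.0)
            emit(f"{sp}_p{rep + 1}", sp, growing, offset)
    return pd.DataFrame(rows)


NO_CARBON = "no_carbon"


# ---------------------------------------------------------------------------
# similarity graph


@dataclass
class GraphTruth:
    """Planted-partition truth for a protein-similarity graph."""

    blocks: list[list[str]]
    p_within: float = 0.9
    p_between: float = 0.0
    within_evalue: tuple[float, float] = (1e-50, 1e-10)
    between_evalue: tuple[float, float] = (1e-9, 1e-6)
    within_pct: tuple[float, float] = (40.0, 100.0)
    between_pct: tuple[float, float] = (15.0, 60.0)
    gene_species: dict[str, str] = field(default_factory=dict)
    gene_ec: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for blk in self.blocks:
            for g in blk:
                if g in seen:
                    raise ValueError(f"gene {g!r} appears in more than one block")
                seen.add(g)
        if not (0 <= self.p_between <= self.p_within <= 1):
            raise ValueError("need 0 <= p_between <= p_within <= 1")

    @property
    def genes(self) -> list[str]:
        return [g for blk in self.blocks for g in blk]


def simulate_similarity_graph(truth: GraphTruth, seed: int = 0) -> pd.DataFrame:
    """Emit a (gene_a, gene_b, e_value, pct_aligned) edge table, each
    unordered pair at most once, for a planted partition."""
    rng = np.random.default_rng(seed)
    block_of = {g: i for i, blk in enumerate(truth.blocks) for g in blk}
    genes = truth.genes

    def draw(rng, lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            same = block_of[a] == block_of[b]
            p = truth.p_within if same else truth.p_between
            if rng.random() >= p:
                continue
            if same:
                ev = draw(rng, *truth.within_evalue)
                pct = float(rng.uniform(*truth.within_pct))
            else:
                ev = draw(rng, *truth.between_evalue)
                pct = float(rng.uniform(*truth.between_pct))
            rows.append({"gene_a": a, "gene_b": b, "e_value": ev, "pct_aligned": pct})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "e_value", "pct_aligned"])


# ---------------------------------------------------------------------------
# degradability predictions


def simulate_predictions(
    growth_truth: pd.Series,
    fp_rate: float,
    fn_rate: float,
    seed: int = 0,
    model_version: str = "simulated",
) -> pd.DataFrame:
    """Derive a degradability prediction table from a growth truth.

    Each non-growth compound is predicted degradable with probability
    ``fp_rate``; each growth compound is predicted non-degradable with
    probability ``fn_rate``. Returns columns
    (compound, model_version, predicted_degradable).
    """
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for compound, grows in growth_truth.items():
        if bool(grows):
            pred = rng.random() >= fn_rate
        else:
            pred = rng.random() < fp_rate
        rows.append({"compound": compound, "model_version": model_version,
                     "predicted_degradable": bool(pred)})
    return pd.DataFrame(rows)
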