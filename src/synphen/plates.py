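"""Phenotype growth-screen normalization, growth calling and clustering.

Biolog-style plates read dye reduction as A590 over a time course
(44/72/96 h). Normalization has two subtraction steps: first the same
well on a paired uninoculated plate (removes plate/compound background),
then — after averaging replicate wells — the mean of the species'
inoculated no-carbon control wells (removes carbon-independent signal).
A compound is called a growth substrate when its normalized 96-h value
strictly exceeds 0.2 absorbance units. Compounds are clustered by
centered Pearson correlation of their growth profiles with average
linkage, and calls are summarized per chemical category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

REQUIRED_COLUMNS = ["plate_id", "well", "species", "compound", "category", "time_h", "a590"]
UNINOCULATED = "uninoculated"
NO_CARBON = "no_carbon"


@dataclass
class GrowthMatrix:
    """Normalized growth values, one row per (species, compound), one column per time."""

    values: pd.DataFrame  # MultiIndex (species, compound) x time_h
    replicates: pd.Series  # replicate wells averaged per (species, compound)
    categories: pd.Series  # compound -> category


@dataclass
class GrowthCallSet:
    calls: pd.Series  # MultiIndex (species, compound) -> bool
    threshold: float
    call_time: float
    categories: pd.Series


def load_plate_csv(path) -> pd.DataFrame:
    """Read the long-format plate CSV dialect (header required)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing required columns: {missing}")
    return df


def _pair_uninoculated(df: pd.DataFrame) -> dict[str, list[str]]:
    """Pair each inoculated plate with uninoculated plate(s) sharing its well layout."""
    layouts: dict[str, frozenset] = {}
    for pid, sub in df.groupby("plate_id"):
        layouts[pid] = frozenset(zip(sub["well"], sub["compound"]))
    uninoc = {pid for pid, sub in df.groupby("plate_id")
              if (sub["species"] == UNINOCULATED).all()}
    pairing: dict[str, list[str]] = {}
    for pid, layout in layouts.items():
        if pid in uninoc:
            continue
        partners = [u for u in sorted(uninoc) if layouts[u] == layout]
        if not partners:
            raise ValueError(
                f"no uninoculated plate matches the well layout of plate {pid!r}"
            )
        pairing[pid] = partners
    return pairing


def normalize_plates(measurements: pd.DataFrame) -> GrowthMatrix:
    """Two-step background subtraction of raw plate readings.

    Step 1: per well and time point, subtract the reading of the same well
    on the paired uninoculated plate. Step 2: average replicate wells per
    (species, compound, time). Step 3: subtract the mean of the species'
    no-carbon control wells (after step 1) at the same time point.
    Negative values are retained. Adding a constant to every reading of a
    plate and its uninoculated partner leaves the result unchanged.
    """
    df = measurements.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if (df["a590"] < 0).any():
        raise ValueError("raw A590 readings must be non-negative")
    pairing = _pair_uninoculated(df)
    uninoc_pids = {u for us in pairing.values() for u in us}
    background = (
        df[df["plate_id"].isin(uninoc_pids)]
        .groupby(["plate_id", "well", "time_h"])["a590"].mean()
    )

    inoc = df[~(df["species"] == UNINOCULATED)].copy()
    if inoc.empty:
        raise ValueError("no inoculated measurements in table")

    def well_background(row):
        vals = [background.get((u, row["well"], row["time_h"]), np.nan)
                for u in pairing[row["plate_id"]]]
        v = np.nanmean(vals)
        if np.isnan(v):
            raise ValueError(
                f"missing uninoculated counterpart for plate {row['plate_id']!r} "
                f"well {row['well']!r} at {row['time_h']} h"
            )
        return v

    inoc["step1"] = inoc["a590"] - inoc.apply(well_background, axis=1)

    nc = inoc[inoc["compound"] == NO_CARBON]
    if nc.empty:
        raise ValueError("no no-carbon control wells found")
    for sp in inoc["species"].unique():
        if nc[nc["species"] == sp].empty:
            raise ValueError(f"species {sp!r} has no no-carbon control wells")
    nc_mean = nc.groupby(["species", "time_h"])["step1"].mean()

    data = inoc[inoc["compound"] != NO_CARBON]
    grouped = data.groupby(["species", "compound", "time_h"])["step1"]
    averaged = grouped.mean()
    n_rep = grouped.size().groupby(["species", "compound"]).max()
    normalized = averaged - averaged.index.to_frame().apply(
        lambda r: nc_mean[(r["species"], r["time_h"])], axis=1
    )
    values = normalized.unstack("time_h")
    categories = (
        data.drop_duplicates("compound").set_index("compound")["category"].sort_index()
    )
    return GrowthMatrix(values=values, replicates=n_rep, categories=categories)


def call_growth(
    matrix: GrowthMatrix, threshold: float = 0.2, call_time: float = 96.0
) -> GrowthCallSet:
    """Call growth substrates: normalized A590 strictly above ``threshold`` at ``call_time``."""
    if call_time not in matrix.values.columns:
        raise ValueError(
            f"call time {call_time} h absent from matrix "
            f"(have {list(matrix.values.columns)})"
        )
    calls = matrix.values[call_time] > threshold
    return GrowthCallSet(calls=calls, threshold=threshold, call_time=call_time,
                         categories=matrix.categories)


def _profile_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - centered Pearson distance; zero-variance rows sit at distance 1."""
    n = profiles.shape[0]
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = norms > 0
    if ok.any():
        sub = centered[ok] / norms[ok, None]
        corr = np.clip(sub @ sub.T, -1.0, 1.0)
        dist[np.ix_(ok, ok)] = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_compounds(
    matrix: GrowthMatrix,
    species_subset: list[str] | None = None,
    time_subset: list[float] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Cluster compounds by their growth profiles across species and times.

    Distance is 1 - centered Pearson correlation between compound profile
    vectors (species x time, concatenated); agglomeration is average
    linkage. Compounds enter in sorted-name order, which fixes the leaf
    order deterministically. Returns (scipy linkage matrix, leaf order).
    """
    vals = matrix.values
    if species_subset is not None:
        vals = vals.loc[vals.index.get_level_values("species").isin(species_subset)]
    if time_subset is not None:
        vals = vals[time_subset]
    wide = vals.unstack("species")  # compound x (time, species)
    wide = wide.sort_index()
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 compounds to cluster")
    profiles = wide.to_numpy(dtype=float)
    profiles = np.nan_to_num(profiles, nan=0.0)
    condensed = _profile_distance(profiles)
    linkage = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(linkage)
    names = list(wide.index)
    return linkage, [names[i] for i in leaves]


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_dist):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_dist - node.dist:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{parent_dist - node.dist:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def summarize_categories(calls: GrowthCallSet,
                         categories: pd.Series | None = None) -> pd.DataFrame:
    """Count growth substrates per species and chemical category.

    Returns one row per (species, category) with the number of compounds
    tested, the number called growth substrates, and the percentage.
    """
    cats = calls.categories if categories is None else categories
    df = calls.calls.rename("growth").reset_index()
    unknown = set(df["compound"]) - set(cats.index)
    if unknown:
        raise ValueError(f"compounds without a category label: {sorted(unknown)}")
    df["category"] = df["compound"].map(cats)
    out = (
        df.groupby(["species", "category"])
        .agg(n_tested=("growth", "size"), n_growth=("growth", "sum"))
        .reset_index()
    )
    out["pct_growth"] = 100.0 * out["n_growth"] / out["n_tested"]
    return out
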