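"""Markov clustering of protein-similarity graphs and EC-indexed family counts.

An all-against-all protein similarity search (BLASTP-style edge lists)
is filtered at e-value <= 1e-5 and >= 10% alignment coverage, weighted
by -log10(e-value) (capped), and clustered with the Markov Cluster
process at inflation 1.5 — the TribeMCL construction. Families are then
cross-tabulated with per-gene species and EC assignments into the
species x reaction-category count matrix behind TAGs-cycle heatmaps,
where merged categories such as "6.2.1.1/2/3" alias several EC numbers
and heatmap export saturates at 15 genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

EDGE_COLUMNS = ["gene_a", "gene_b", "e_value", "pct_aligned"]


def build_graph(
    edges: pd.DataFrame,
    evalue_max: float = 1e-5,
    min_pct_aligned: float = 10.0,
    cap: float = 200.0,
) -> nx.Graph:
    """Build the weighted similarity graph from a BLASTP-style edge table.

    Edges failing either the e-value or the coverage filter are dropped;
    weight = min(-log10(e_value), cap), with e_value 0 mapped to the cap.
    Reciprocal duplicates merge by mean weight; self-edges are ignored
    (self-loops are added by :func:`mcl` itself).
    """
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    g = nx.Graph()
    for i, row in enumerate(edges.itertuples(index=False)):
        try:
            a, b = str(row.gene_a), str(row.gene_b)
            ev = float(row.e_value)
            pct = float(row.pct_aligned)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge row {i}: {exc}") from exc
        if ev < 0:
            raise ValueError(f"malformed edge row {i}: negative e-value {ev}")
        g.add_node(a)
        g.add_node(b)
        if a == b:
            continue
        if ev > evalue_max or pct < min_pct_aligned:
            continue
        w = cap if ev == 0 else min(-np.log10(ev), cap)
        if g.has_edge(a, b):
            prev = g[a][b]
            g[a][b]["weight"] = (prev["weight"] * prev["n"] + w) / (prev["n"] + 1)
            g[a][b]["n"] = prev["n"] + 1
        else:
            g.add_edge(a, b, weight=w, n=1)
    return g


@dataclass
class ClusterSet:
    """A partition of graph nodes into gene families."""

    families: list[list[str]]  # each sorted; list sorted by (-size, first member)
    inflation: float
    converged: bool
    n_iterations: int

    def membership(self) -> dict[str, int]:
        return {g: i for i, fam in enumerate(self.families) for g in fam}


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=0)
    s[s == 0] = 1.0
    return m / s


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    inspect=None,
) -> ClusterSet:
    """Markov clustering of a weighted undirected graph.

    Self-loops are added with weight max(max incident weight, 1); the
    adjacency matrix is column-normalized and then alternately expanded
    (matrix self-product) and inflated (elementwise power ``inflation``,
    renormalized) until the largest absolute column change drops below
    ``tol`` or ``max_iter`` is hit (the partition is still returned, with
    ``converged=False``). Families are the connected components of the
    limit matrix's attractor structure; singletons are allowed.

    ``inspect``, if given, is called with the stochastic matrix after every
    normalization (used to audit column stochasticity).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    for i in range(n):
        m[i, i] = max(m[i].max(), 1.0)
    m = _normalize_columns(m)
    if inspect is not None:
        inspect(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = _normalize_columns(np.power(expanded, inflation))
        if inspect is not None:
            inspect(inflated)
        delta = np.abs(inflated - m).max()
        m = inflated
        if delta < tol:
            converged = True
            break
    # attractor structure: nonzero entries of the limit matrix link each node
    # to its attractor(s); overlapping attractor systems merge via components
    eps = 10 * tol
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > eps)
    support.add_edges_from(zip(rows, cols))
    comps = [sorted(nodes[i] for i in c) for c in nx.connected_components(support)]
    comps.sort(key=lambda fam: (-len(fam), fam[0]))
    if not converged:
        import warnings

        warnings.warn(
            f"MCL did not converge in {max_iter} iterations (last delta above tol); "
            "returning the current partition",
            RuntimeWarning,
            stacklevel=2,
        )
    return ClusterSet(families=comps, inflation=inflation, converged=converged,
                      n_iterations=it)


@dataclass
class ECCountMatrix:
    """Gene counts per species and reaction category, with per-species totals."""

    counts: pd.DataFrame  # species x category, int
    species_totals: pd.Series  # distinct genes counted per species
    saturation: float = 15.0

    def display(self) -> pd.DataFrame:
        """Heatmap export: values clipped at the color-saturation threshold."""
        return self.counts.clip(upper=self.saturation)


def ec_count_matrix(
    clusters: ClusterSet,
    gene_species: dict[str, str],
    gene_ec: dict[str, set],
    category_map: dict[str, str],
    family_wide: bool = False,
) -> ECCountMatrix:
    """Cross-tabulate gene families with species and EC reaction categories.

    A family is *implicated* for a reaction category when at least one
    member carries an EC number in that category. By default (strict rule)
    count(species, category) is the number of that species' genes that
    belong to an implicated family AND themselves carry an EC in the
    category; with ``family_wide=True`` every member of an implicated
    family counts toward the category regardless of its own ECs. The
    per-species total counts distinct genes (a gene with several ECs
    counts once).
    """
    categories = sorted(set(category_map.values()))
    species = sorted(set(gene_species.values()))
    counts = pd.DataFrame(0, index=species, columns=categories, dtype=int)
    counted_genes: dict[str, set] = {sp: set() for sp in species}
    for fam in clusters.families:
        for g in fam:
            if g not in gene_species:
                raise KeyError(f"gene {g!r} has no species assignment")
        fam_cats = set()
        for g in fam:
            for ec in gene_ec.get(g, ()):
                cat = category_map.get(ec)
                if cat is not None:
                    fam_cats.add(cat)
        if not fam_cats:
            continue
        for g in fam:
            sp = gene_species[g]
            own_cats = {category_map[ec] for ec in gene_ec.get(g, ())
                        if ec in category_map}
            hit = fam_cats if family_wide else (own_cats & fam_cats)
            for cat in hit:
                counts.loc[sp, cat] += 1
            if hit:
                counted_genes[sp].add(g)
    totals = pd.Series({sp: len(gs) for sp, gs in counted_genes.items()}).sort_index()
    return ECCountMatrix(counts=counts, species_totals=totals)


def cluster_species(matrix: ECCountMatrix) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Cluster species by Pearson correlation of their reaction-count vectors.

    Distance is 1 - Pearson r, average linkage. Returns (linkage, leaf
    order, display matrix reordered by leaves and clipped at the
    saturation threshold; stored counts are untouched).
    """
    counts = matrix.counts
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 species to cluster")
    x = counts.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    n = x.shape[0]
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = norms > 0
    if ok.any():
        sub = centered[ok] / norms[ok, None]
        corr = np.clip(sub @ sub.T, -1.0, 1.0)
        dist[np.ix_(ok, ok)] = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = [counts.index[i] for i in hierarchy.leaves_list(linkage)]
    ordered = matrix.display().loc[leaves]
    return linkage, leaves, ordered
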