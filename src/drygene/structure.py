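"""Population differentiation and structure.

Covers the descriptive-structure layer of a candidate-gene panel:

* per-SNP pairwise Fst between taxa (Hudson's estimator),
* principal components of the genotype matrix,
* identity-by-state (IBS) kinship for mixed-model association,
* neighbor-joining dendrograms with column-bootstrap support,
* haplotype collapsing and Bandelt median-joining networks.

Neighbor joining is delegated to scikit-bio; the median-joining network
is implemented here (no installed package provides it): minimum-spanning
networks are iteratively augmented with quasi-median (Steiner) sequences
while doing so shortens the network, then unused inferred nodes are
pruned.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .variants import BASES, Alignment, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fst

def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson's per-SNP Fst estimate for two populations.

    Fst = 1 - Hw / Hb with Hw the mean within-population expected
    heterozygosity corrected for sample size (n/(n-1)) and
    Hb = p1(1-p2) + p2(1-p1).  The raw estimate can be slightly negative
    for identical sample frequencies; callers floor at 0 for reporting.
    Returns NaN when Hb = 0 (no between-population heterozygosity).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 haplotypes per population")
    hw = 0.5 * (
        n1 / (n1 - 1) * 2.0 * p1 * (1 - p1) + n2 / (n2 - 1) * 2.0 * p2 * (1 - p2)
    )
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb == 0:
        return float("nan")
    return 1.0 - hw / hb


def pairwise_fst(gm: GenotypeMatrix, pair: tuple[str, str]) -> pd.DataFrame:
    """Per-SNP Hudson Fst between two taxa.

    SNPs where either taxon has fewer than two non-missing haplotypes,
    or where the between heterozygosity is zero, are skipped.  Returns a
    frame with raw and floored (max(0, .)) values.
    """
    taxa = np.asarray(gm.taxa)
    rows = []
    for j, pos in enumerate(gm.positions):
        values = {}
        ok = True
        for label in pair:
            g = gm.data[taxa == label, j]
            g = g[~np.isnan(g)]
            if len(g) < 2:
                ok = False
                break
            values[label] = (float(np.mean(g)), len(g))
        if not ok:
            continue
        (p1, n1), (p2, n2) = values[pair[0]], values[pair[1]]
        fst = hudson_fst(p1, n1, p2, n2)
        if np.isnan(fst):
            continue
        rows.append({"position": pos, "fst_raw": fst, "fst": max(0.0, fst)})
    return pd.DataFrame(rows, columns=["position", "fst_raw", "fst"])


def fst_report(gm: GenotypeMatrix, pairs=None) -> pd.DataFrame:
    """Quartile summaries of per-SNP Fst for each taxon pair."""
    labels = sorted({t for t in gm.taxa if t})
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    rows = []
    for pair in pairs:
        per_snp = pairwise_fst(gm, pair)
        if per_snp.empty:
            continue
        q = np.percentile(per_snp["fst"], [0, 25, 50, 75, 100])
        rows.append(
            {
                "taxon1": pair[0],
                "taxon2": pair[1],
                "n_snps": len(per_snp),
                "min": q[0],
                "q25": q[1],
                "median": q[2],
                "q75": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA and kinship

def pca_genotypes(gm: GenotypeMatrix, n_components: int = 2):
    """Principal components of the mean-centered genotype matrix.

    Missing genotypes are imputed to the column mean (which becomes 0
    after centering).  Returns (scores DataFrame, explained-variance
    fractions), components ordered by decreasing variance.
    """
    if gm.n < 2 or gm.n_snps < 1:
        raise ValueError("PCA needs >= 2 individuals and >= 1 SNP")
    x = gm.data.copy()
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    x -= x.mean(axis=0)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(sv))
    var = sv**2
    total = var.sum()
    explained = var[:k] / total if total > 0 else np.zeros(k)
    scores = u[:, :k] * sv[:k]
    frame = pd.DataFrame(scores, index=gm.ids, columns=[f"PC{i+1}" for i in range(k)])
    frame.insert(0, "taxon", gm.taxa)
    return frame, explained


def ibs_kinship(gm: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state kinship: fraction of co-called SNPs with the
    same allele.  Diagonal is 1; a pair with zero co-observed SNPs is an
    error because downstream mixed models cannot use a missing entry."""
    if gm.n_snps < 1:
        raise ValueError("kinship needs >= 1 SNP")
    n = gm.n
    k = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(gm.data[i]) & ~np.isnan(gm.data[j])
            if not both.any():
                raise ValueError(
                    f"individuals {gm.ids[i]!r} and {gm.ids[j]!r} share no called SNPs"
                )
            k[i, j] = k[j, i] = np.mean(gm.data[i][both] == gm.data[j][both])
    return pd.DataFrame(k, index=gm.ids, columns=gm.ids)


# ---------------------------------------------------------------------------
# Distances and neighbor joining

def p_distance_matrix(aln: Alignment, jukes_cantor: bool = False) -> DistanceMatrix:
    """Pairwise p-distance (or Jukes-Cantor distance) with pairwise deletion."""
    chars = aln.char_matrix()
    valid = np.isin(chars, BASES)
    n = aln.n
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if not both.any():
                raise ValueError(f"{aln.ids[i]} and {aln.ids[j]} share no called sites")
            p = np.mean(chars[i][both] != chars[j][both])
            if jukes_cantor:
                if p >= 0.75:
                    raise ValueError("p-distance >= 0.75; Jukes-Cantor undefined")
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=aln.ids)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths floored at 0."""
    if len(distances.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 leaves")
    tree = nj(distances)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _bipartitions(tree: TreeNode, all_ids: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions, each encoded as the side not containing
    a fixed reference leaf (the alphabetically first id)."""
    ref = min(all_ids)
    parts = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_ids - side
        if 2 <= len(side) <= len(all_ids) - 2:
            parts.add(side)
    return parts


def bootstrap_nj(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    jukes_cantor: bool = False,
):
    """NJ tree plus column-bootstrap support.

    Resamples alignment columns with replacement, rebuilds the tree, and
    reports for each internal edge of the original tree the percentage
    of replicates containing the same bipartition.  Support values are
    written into the internal node names of the returned tree.
    """
    tree = nj_tree(p_distance_matrix(aln, jukes_cantor))
    all_ids = frozenset(aln.ids)
    original = _bipartitions(tree, all_ids)
    counts = {part: 0 for part in original}
    rng = np.random.default_rng(seed)
    chars = aln.char_matrix()
    for _ in range(replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        boot = Alignment(
            gene=aln.gene,
            ids=aln.ids,
            sequences=["".join(row) for row in chars[:, cols]],
            taxa=aln.taxa,
        )
        try:
            parts = _bipartitions(nj_tree(p_distance_matrix(boot, jukes_cantor)), all_ids)
        except ValueError:  # a replicate with no shared called sites
            continue
        for part in original:
            if part in parts:
                counts[part] += 1
    support = {part: 100.0 * c / replicates for part, c in counts.items()}
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        key = side if min(all_ids) not in side else all_ids - side
        if key in support:
            node.name = f"{support[key]:.0f}"
    return tree, support


# ---------------------------------------------------------------------------
# Haplotypes and median-joining networks

@dataclass
class HaplotypeSet:
    """Distinct haplotypes over the complete (no-missing) columns."""

    gene: str
    columns: list[int]  # 1-based alignment columns retained
    haplotypes: list[str]  # distinct strings over those columns
    freq: list[int]  # count per haplotype
    composition: list[dict]  # taxon -> count per haplotype
    assignments: dict = field(default_factory=dict)  # individual id -> haplotype index

    @property
    def diffs(self) -> np.ndarray:
        """Pairwise Hamming distances between haplotypes."""
        h = np.array([list(s) for s in self.haplotypes], dtype="U1")
        n = len(self.haplotypes)
        d = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = int(np.sum(h[i] != h[j]))
        return d


def collapse_haplotypes(aln: Alignment, variable_only: bool = False) -> HaplotypeSet:
    """Collapse sequences into distinct haplotypes.

    Columns with any missing call are dropped first (complete deletion);
    with ``variable_only`` the haplotype strings are further restricted
    to the columns still variable after deletion.
    """
    chars = aln.char_matrix()
    complete = np.isin(chars, BASES).all(axis=0)
    if not complete.any():
        raise ValueError(f"{aln.gene}: no complete columns for haplotyping")
    cols = np.nonzero(complete)[0]
    if variable_only:
        sub = chars[:, cols]
        var = np.array([len(set(sub[:, c])) > 1 for c in range(sub.shape[1])])
        cols = cols[var] if var.any() else cols[:1]
    strings = ["".join(chars[i, cols]) for i in range(aln.n)]
    haplotypes: list[str] = []
    freq: list[int] = []
    comp: list[dict] = []
    assignments: dict = {}
    for i, s in enumerate(strings):
        if s in haplotypes:
            h = haplotypes.index(s)
            freq[h] += 1
        else:
            haplotypes.append(s)
            freq.append(1)
            comp.append({})
            h = len(haplotypes) - 1
        taxon = aln.taxa[i]
        comp[h][taxon] = comp[h].get(taxon, 0) + 1
        assignments[aln.ids[i]] = h
    return HaplotypeSet(
        gene=aln.gene,
        columns=[int(c) + 1 for c in cols],
        haplotypes=haplotypes,
        freq=freq,
        composition=comp,
        assignments=assignments,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes: list[str], epsilon: int = 0) -> list[tuple[str, str, int]]:
    """Minimum-spanning-network edges (union of all MSTs within tolerance).

    Kruskal by increasing distance level: an edge at level d joins two
    nodes that were in different components before level d + epsilon was
    processed; components are merged only after a whole level.
    """
    dist = {}
    for a, b in itertools.combinations(nodes, 2):
        dist.setdefault(_hamming(a, b), []).append((a, b))
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    edges = []
    seen = set()
    merged_pairs = []
    levels = sorted(dist)
    for level in levels:
        # tolerance: also admit edges whose length exceeds the current
        # connecting level by at most epsilon
        admit = [e for l2 in levels if level <= l2 <= level + epsilon for e in dist[l2]]
        added_any = False
        for a, b in admit:
            if (a, b) not in seen and find(a) != find(b):
                w = _hamming(a, b)
                edges.append((a, b, w))
                seen.add((a, b))
                merged_pairs.append((a, b))
                added_any = True
        if added_any:
            for a, b in merged_pairs:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
            merged_pairs = []
        if len({find(v) for v in nodes}) == 1:
            break
    return edges


def _mst_weight(nodes: list[str]) -> int:
    """Total length of a minimum spanning tree over the node set."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        g.add_edge(a, b, weight=_hamming(a, b))
    return int(sum(d["weight"] for *_, d in nx.minimum_spanning_edges(g, data=True)))


def _quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Quasi-median sequences of three haplotypes.

    Per position: the majority state if one exists, otherwise each of
    the three states branches into its own candidate.
    """
    options = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append((a, b, c))
    return ["".join(combo) for combo in itertools.product(*options)]


def mj_network(hs: HaplotypeSet, epsilon: int = 0, max_rounds: int = 50) -> nx.Graph:
    """Bandelt median-joining network of a haplotype set.

    Starts from the minimum-spanning network of the observed haplotypes
    (tolerance ``epsilon``), then repeatedly adds the quasi-median of a
    connected triplet whenever doing so reduces the total spanning
    length, and finally prunes inferred (median) nodes that no longer
    shorten the network.  Node attributes: ``observed``, ``count``,
    ``taxa`` (taxon -> count); edge attribute ``weight`` is the number of
    substitutions.
    """
    observed = list(hs.haplotypes)
    nodes = list(observed)
    for _ in range(max_rounds):
        edges = _msn_edges(nodes, epsilon)
        adjacency = {v: set() for v in nodes}
        for a, b, _w in edges:
            adjacency[a].add(b)
            adjacency[b].add(a)
        base = _mst_weight(nodes)
        best = None
        candidates = set()
        for v in nodes:
            for a, b in itertools.combinations(sorted(adjacency[v]), 2):
                for m in _quasi_medians(a, v, b):
                    if m not in nodes:
                        candidates.add(m)
        for m in sorted(candidates):
            gain = base - _mst_weight(nodes + [m])
            if gain > 0 and (best is None or gain > best[0]):
                best = (gain, m)
        if best is None:
            break
        nodes.append(best[1])
    # prune inferred nodes whose removal does not lengthen the network
    changed = True
    while changed:
        changed = False
        for m in [v for v in nodes if v not in observed]:
            rest = [v for v in nodes if v != m]
            if _mst_weight(rest) <= _mst_weight(nodes):
                nodes = rest
                changed = True
    graph = nx.Graph(gene=hs.gene)
    for v in nodes:
        if v in observed:
            h = observed.index(v)
            graph.add_node(v, observed=True, count=hs.freq[h], taxa=dict(hs.composition[h]))
        else:
            graph.add_node(v, observed=False, count=0, taxa={})
    for a, b, w in _msn_edges(nodes, epsilon):
        graph.add_edge(a, b, weight=w)
    return graph


def network_tables(graph: nx.Graph):
    """Edge-list and node-attribute frames for CSV export."""
    edges = pd.DataFrame(
        [(a, b, d["weight"]) for a, b, d in graph.edges(data=True)],
        columns=["node1", "node2", "weight"],
    )
    nodes = pd.DataFrame(
        [
            {
                "haplotype": v,
                "observed": d["observed"],
                "count": d["count"],
                **{f"n_{t}": c for t, c in d["taxa"].items()},
            }
            for v, d in graph.nodes(data=True)
        ]
    )
    return edges, nodes
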