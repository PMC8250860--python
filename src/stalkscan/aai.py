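"""Average amino-acid identity (AAI), profile clustering, species groups.

AAI between two genomes is the mean percent identity over reciprocal
best-hit protein pairs passing identity and coverage cutoffs (defaults
30% / 70%). Genome relatedness is then summarized by Bray-Curtis
dissimilarity between AAI profile rows and average-linkage (UPGMA)
hierarchical clustering; connected components above a 95% AAI cutoff give
species-rank groups.

Conventions: coverage is the alignment span over the length of the
*shorter* sequence; best hits break ties by score then lexicographic gene
id; the standard deviation is the population sd (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ScoringScheme, align_pair, blosum62, kmer_set
from .genome_io import Genome


@dataclass(frozen=True)
class AAIResult:
    genome_a: str
    genome_b: str
    mean_pid: float   # nan when n_orthologs == 0
    sd_pid: float
    n_orthologs: int


def _best_hits(
    qgenes, tgenes, scheme: ScoringScheme, min_pid: float, min_cov: float,
    k: int = 4, min_shared: int = 1,
) -> dict[str, tuple[str, float, float, float]]:
    """query gene_id -> (target gene_id, pid, score, coverage_shorter).

    Candidate hits must clear both thresholds *before* best-hit selection
    (ranked by pid, ties by score then lexicographic id); otherwise tiny
    high-identity overlaps of unrelated genes would outrank true
    orthologs and break the reciprocity test.
    """
    index: dict[str, list[int]] = {}
    for ti, t in enumerate(tgenes):
        for km in kmer_set(t.protein_seq, k):
            index.setdefault(km, []).append(ti)
    hits: dict[str, tuple[str, float, float, float]] = {}
    for q in qgenes:
        counts: dict[int, int] = {}
        for km in kmer_set(q.protein_seq, k):
            for ti in index.get(km, ()):
                counts[ti] = counts.get(ti, 0) + 1
        best = None  # (pid, score, gene_id, coverage)
        for ti in sorted(counts):
            if counts[ti] < min_shared:
                continue
            t = tgenes[ti]
            st = align_pair(q.protein_seq, t.protein_seq, scheme)
            if st.pid < min_pid:
                continue
            # coverage relative to the shorter sequence
            if len(q.protein_seq) <= len(t.protein_seq):
                cov = st.query_cov
            else:
                cov = st.subject_cov
            if cov < min_cov:
                continue
            better = (
                best is None
                or (st.pid, st.score) > (best[0], best[1])
                or ((st.pid, st.score) == (best[0], best[1]) and t.gene_id < best[2])
            )
            if better:
                best = (st.pid, st.score, t.gene_id, cov)
        if best is not None:
            hits[q.gene_id] = (best[2], best[0], best[1], best[3])
    return hits


def compute_aai(
    a: Genome, b: Genome,
    min_pid: float = 30.0, min_cov: float = 70.0,
    scheme: ScoringScheme | None = None,
) -> AAIResult:
    """Two-way AAI over reciprocal best hits between two proteomes."""
    scheme = scheme or blosum62()
    fwd = _best_hits(a.genes, b.genes, scheme, min_pid, min_cov)
    rev = _best_hits(b.genes, a.genes, scheme, min_pid, min_cov)
    pids = []
    for qid, (tid, pid, _score, _cov) in sorted(fwd.items()):
        back = rev.get(tid)
        if back is None or back[0] != qid:
            continue
        pids.append(pid)
    if not pids:
        return AAIResult(a.genome_id, b.genome_id, float("nan"), float("nan"), 0)
    arr = np.asarray(pids)
    return AAIResult(a.genome_id, b.genome_id, float(arr.mean()),
                     float(arr.std()), len(arr))


@dataclass
class AAIMatrix:
    genomes: list[str]
    values: pd.DataFrame   # symmetric, diagonal 100
    sds: pd.DataFrame
    counts: pd.DataFrame


@dataclass
class DendroNode:
    """Binary merge-tree node; height is the cophenetic half-distance."""

    height: float
    name: str | None = None
    children: tuple = ()

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]


def bray_curtis_profile(values: pd.DataFrame, ga: str, gb: str) -> float:
    """Bray-Curtis between two AAI profile rows, excluding self/mutual entries."""
    others = [g for g in values.index if g not in (ga, gb)]
    if not others:
        return 0.0
    x = values.loc[ga, others].to_numpy(dtype=float)
    y = values.loc[gb, others].to_numpy(dtype=float)
    denom = float(np.sum(x + y))
    if denom == 0:
        return 0.0
    return float(np.sum(np.abs(x - y)) / denom)


def upgma(dist: pd.DataFrame) -> DendroNode:
    """Average-linkage agglomeration with pinned lexicographic tie-breaking.

    Cluster keys are their lexicographically smallest leaf; among
    minimum-distance pairs the smallest (key_i, key_j) pair merges first.
    Node heights are half the merge distance (ultrametric convention).
    """
    active: dict[str, DendroNode] = {
        g: DendroNode(height=0.0, name=g) for g in dist.index
    }
    sizes = {g: 1 for g in dist.index}
    d = {
        (min(a, b), max(a, b)): float(dist.loc[a, b])
        for a in dist.index for b in dist.index if a < b
    }
    while len(active) > 1:
        pair = min(d, key=lambda p: (d[p], p))
        a, b = pair
        h = d[pair] / 2.0
        node = DendroNode(height=h, children=(active[a], active[b]))
        na, nb = sizes[a], sizes[b]
        del active[a], active[b]
        for c in list(active):
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            dc = (na * d[key_a] + nb * d[key_b]) / (na + nb)
            del d[key_a], d[key_b]
            d[(min(a, c), max(a, c))] = dc  # temporarily keyed under a
        del d[pair]
        # re-key cluster under its smallest leaf (which is a, since a < b)
        active[a] = node
        sizes[a] = na + nb
    return next(iter(active.values()))


def aai_matrix_and_cluster(
    genomes: list[Genome],
    min_pid: float = 30.0, min_cov: float = 70.0,
    scheme: ScoringScheme | None = None,
    method: str = "braycurtis",
) -> tuple[AAIMatrix, DendroNode]:
    """All-pairs AAI plus average-linkage dendrogram of the profiles.

    ``method`` picks the dissimilarity: ``braycurtis`` (default) between
    AAI profile rows, or ``aai`` for 1 - AAI/100 directly.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    values = pd.DataFrame(100.0, index=ids, columns=ids)
    sds = pd.DataFrame(0.0, index=ids, columns=ids)
    counts = pd.DataFrame(0, index=ids, columns=ids)
    for g in genomes:
        counts.loc[g.genome_id, g.genome_id] = len(g.genes)
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            r = compute_aai(a, b, min_pid, min_cov, scheme)
            for x, y in ((a.genome_id, b.genome_id), (b.genome_id, a.genome_id)):
                values.loc[x, y] = r.mean_pid
                sds.loc[x, y] = r.sd_pid
                counts.loc[x, y] = r.n_orthologs
    mat = AAIMatrix(genomes=ids, values=values, sds=sds, counts=counts)

    if method == "braycurtis":
        dist = pd.DataFrame(0.0, index=ids, columns=ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                bc = bray_curtis_profile(values, a, b)
                dist.loc[a, b] = dist.loc[b, a] = bc
    elif method == "aai":
        dist = 1.0 - values / 100.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return mat, upgma(dist)


def species_groups(matrix: AAIMatrix, cutoff: float = 95.0) -> list[set[str]]:
    """Connected components of the strict AAI > cutoff graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(matrix.genomes)
    ids = matrix.genomes
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if float(matrix.values.loc[a, b]) > cutoff:
                g.add_edge(a, b)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda s: min(s))
    return comps
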