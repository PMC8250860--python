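"""Pan-genome construction by greedy pre-clustering plus Markov clustering.

The route mirrors the classic pan-genome recipe: drop partial sequences,
absorb near-identical redundancy with a greedy longest-first pre-cluster,
build an all-vs-all percent-identity graph over the representatives at the
chosen identity threshold, partition it with the Markov cluster algorithm
(inflation 1.5 by default), and re-expand pre-cluster members into the
final gene families. Downstream utilities partition the family table into
core / accessory / strain-specific sets, build gene accumulation curves
over random genome orderings, and fit a Heaps-law openness exponent.

Every numeric choice that the underlying method leaves open (pre-cluster
identity, MCL pruning, tie-breaking, self-loop weights) is pinned here so
runs are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .align import (
    ScoringScheme,
    align_pair,
    blosum62,
    shared_kmer_matrix,
)
from .genome_io import GeneRecord, Genome

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)


@dataclass(frozen=True)
class PanConfig:
    """Knobs of the pan-genome build, with pinned defaults."""

    min_len: int = 40               # partial-sequence filter (aa)
    pre_pid: float = 95.0           # greedy pre-cluster identity
    pre_cov: float = 90.0           # pre-cluster mutual coverage
    graph_min_cov: float = 25.0     # ortholog-graph mutual coverage floor
    inflation: float = 1.5
    mcl_tol: float = 1e-6
    mcl_prune: float = 1e-5
    mcl_max_iter: int = 100
    prescreen_k: int = 4


def filter_partial(
    genes: list[GeneRecord], min_len: int = 40
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split genes into (retained, rejected) by length and stop symbols."""
    retained, rejected = [], []
    for g in genes:
        if len(g.protein_seq) >= min_len and "*" not in g.protein_seq:
            retained.append(g)
        else:
            rejected.append(g)
    return retained, rejected


def _precluster_indexed(
    genes: list[GeneRecord],
    counts: np.ndarray,
    pre_pid: float,
    min_cov: float,
    scheme: ScoringScheme,
    k: int,
) -> dict[str, list[str]]:
    """Greedy pre-cluster pass over a precomputed shared-k-mer matrix."""
    lens = np.array([len(g.protein_seq) for g in genes], dtype=np.int32)
    order = sorted(range(len(genes)),
                   key=lambda i: (-lens[i], genes[i].gene_id))
    # near-identical pairs share the bulk of their k-mers (expected intact
    # fraction ~ pid**k for scattered substitutions), so the prescreen here
    # can demand far more than the ortholog-graph heuristic: 75% of the
    # expectation sits >3 sd below it for sequences >= 100 aa
    frac = 0.75 * (pre_pid / 100.0) ** k
    rep_idx: list[int] = []
    members: dict[str, list[str]] = {}
    for i in order:
        g = genes[i]
        assigned = False
        if rep_idx:
            arr = np.asarray(rep_idx)
            need = np.maximum(8, (frac * np.minimum(lens[i], lens[arr]))
                              .astype(np.int32))
            for ri in arr[counts[i, arr] >= need]:
                rep = genes[ri]
                st = align_pair(rep.protein_seq, g.protein_seq, scheme)
                if st.pid >= pre_pid and st.query_cov >= min_cov \
                        and st.subject_cov >= min_cov:
                    members[rep.gene_id].append(g.gene_id)
                    assigned = True
                    break
        if not assigned:
            rep_idx.append(i)
            members[g.gene_id] = []
    return members


def precluster(
    genes: list[GeneRecord],
    pre_pid: float = 95.0,
    min_cov: float = 90.0,
    scheme: ScoringScheme | None = None,
    k: int = 4,
) -> dict[str, list[str]]:
    """Greedy longest-first pre-clustering of near-identical sequences.

    Genes are visited longest first (ties by gene_id); each joins the
    earliest-created representative reaching ``pre_pid`` identity with
    mutual coverage ``min_cov``, otherwise it founds a new representative.
    Candidates come from a shared-k-mer prescreen. Returns representative
    gene_id -> absorbed member gene_ids (the representative itself is not
    listed).
    """
    if scheme is None:
        scheme = blosum62()
    counts = shared_kmer_matrix([g.protein_seq for g in genes], k)
    return _precluster_indexed(genes, counts, pre_pid, min_cov, scheme, k)


@dataclass
class SimilarityGraph:
    """Undirected pid-weighted graph over representative genes."""

    graph: nx.Graph
    threshold: float
    min_cov: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def _candidate_pairs(reps: list[GeneRecord], min_pid: float, k: int,
                     counts: np.ndarray | None = None) -> np.ndarray:
    """Index pairs (i < j) worth aligning, by shared-k-mer prescreen."""
    seqs = [g.protein_seq for g in reps]
    if counts is None:
        counts = shared_kmer_matrix(seqs, k)
    lens = np.array([len(s) for s in seqs], dtype=np.int32)
    lmin = np.minimum.outer(lens, lens)
    need = np.maximum(8, (0.3 * lmin * (min_pid / 100.0) ** k).astype(np.int32))
    ii, jj = np.nonzero(np.triu(counts >= need, k=1))
    return np.stack([ii, jj], axis=1)


def all_pairs_alignments(
    reps: list[GeneRecord],
    floor_pid: float,
    scheme: ScoringScheme | None = None,
    k: int = 4,
    counts: np.ndarray | None = None,
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """All-vs-all alignment of representatives above a prescreen floor.

    Returns (id_a, id_b) -> (pid, cov_a, cov_b) for pairs surviving the
    k-mer prescreen calibrated to ``floor_pid``; pairs below the prescreen
    are treated as unrelated. ``counts`` may carry a precomputed
    shared-k-mer matrix over ``reps``.
    """
    if scheme is None:
        scheme = blosum62()
    out: dict[tuple[str, str], tuple[float, float, float]] = {}
    for i, j in _candidate_pairs(reps, floor_pid, k, counts):
        a, b = reps[i], reps[j]
        st = align_pair(a.protein_seq, b.protein_seq, scheme)
        out[(a.gene_id, b.gene_id)] = (st.pid, st.query_cov, st.subject_cov)
    return out


def graph_from_alignments(
    reps: list[GeneRecord],
    pairs: dict[tuple[str, str], tuple[float, float, float]],
    min_pid: float,
    min_cov: float,
) -> SimilarityGraph:
    g = nx.Graph()
    g.add_nodes_from(r.gene_id for r in reps)
    for (u, v), (pid, ca, cb) in pairs.items():
        if pid >= min_pid and ca >= min_cov and cb >= min_cov:
            g.add_edge(u, v, pid=pid)
    return SimilarityGraph(graph=g, threshold=min_pid, min_cov=min_cov)


def build_similarity_graph(
    reps: list[GeneRecord],
    min_pid: float,
    min_cov: float = 25.0,
    scheme: ScoringScheme | None = None,
    k: int = 4,
) -> SimilarityGraph:
    """Edge (u, v) iff pid >= min_pid and both coverages >= min_cov."""
    pairs = all_pairs_alignments(reps, min_pid, scheme, k)
    return graph_from_alignments(reps, pairs, min_pid, min_cov)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _mcl_component(nodes: list[str], graph: nx.Graph, inflation: float,
                   tol: float, prune: float, max_iter: int) -> list[set[str]]:
    n = len(nodes)
    if n == 1:
        return [set(nodes)]
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, data in graph.subgraph(nodes).edges(data=True):
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = data["pid"]
    # self-loop = max incident edge weight
    for i in range(n):
        A[i, i] = A[i].max() if A[i].max() > 0 else 1.0
    M = A / A.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                       # expansion
        M = np.power(M, inflation)      # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge after %d iterations on a %d-node component; "
            "interpreting the current matrix", max_iter, n
        )

    attractors = [i for i in range(n) if M[i, i] > tol]
    if not attractors:
        # degenerate (e.g. oscillating) state: treat every node as its own
        attractors = list(range(n))

    # union attractors that carry flow to one another
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in attractors:
        for b in attractors:
            if a < b and (M[a, b] > 0 or M[b, a] > 0):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    clusters: dict[int, set[str]] = {}
    for a in attractors:
        clusters.setdefault(find(a), set()).add(nodes[a])
    for j in range(n):
        if j in parent:
            continue
        flows = M[attractors, j]
        best = flows.max()
        if best <= 0:
            clusters[len(nodes) + j] = {nodes[j]}  # unattracted singleton
            continue
        # largest flow wins; ties broken by lexicographic attractor node id
        cand = [attractors[i] for i in np.flatnonzero(flows == best)]
        a = min(cand, key=lambda x: nodes[x])
        clusters[find(a)].add(nodes[j])
    return list(clusters.values())


def mcl_cluster(
    sim: SimilarityGraph,
    inflation: float = 1.5,
    tol: float = 1e-6,
    prune: float = 1e-5,
    max_iter: int = 100,
) -> list[set[str]]:
    """Markov clustering of the similarity graph; returns a node partition.

    Runs independently on each connected component (components can never
    merge under expansion/inflation, so this is exact, not a heuristic).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    out: list[set[str]] = []
    for comp in nx.connected_components(sim.graph):
        out.extend(
            _mcl_component(sorted(comp), sim.graph, inflation, tol, prune, max_iter)
        )
    out.sort(key=lambda c: min(c))
    return out


# ---------------------------------------------------------------------------
# Families / pan-genome
# ---------------------------------------------------------------------------

@dataclass
class GeneFamily:
    """One ortholog cluster: genome -> member gene_ids (paralogs allowed)."""

    family_id: str
    members: dict[str, list[str]]
    representative: str

    def n_genomes(self) -> int:
        return len(self.members)

    def n_genes(self) -> int:
        return sum(len(v) for v in self.members.values())

    def all_gene_ids(self) -> list[str]:
        return [g for v in self.members.values() for g in v]

    def has_paralogs(self) -> bool:
        return any(len(v) > 1 for v in self.members.values())


@dataclass
class PanGenome:
    """Families plus the genome-by-family member-count matrix."""

    threshold: float
    families: list[GeneFamily]
    genomes: list[str]
    matrix: pd.DataFrame
    gene_records: dict[str, GeneRecord] = field(repr=False, default_factory=dict)

    def family_by_id(self, family_id: str) -> GeneFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def family_of_gene(self) -> dict[str, str]:
        out = {}
        for f in self.families:
            for g in f.all_gene_ids():
                out[g] = f.family_id
        return out


def _families_from_clusters(
    clusters: list[set[str]],
    pre_members: dict[str, list[str]],
    record_of: dict[str, GeneRecord],
    genomes: list[str],
    threshold: float,
) -> PanGenome:
    expanded: list[list[str]] = []
    for cl in clusters:
        genes: list[str] = []
        for rep in sorted(cl):
            genes.append(rep)
            genes.extend(pre_members[rep])
        expanded.append(genes)

    fams: list[GeneFamily] = []
    for genes in expanded:
        members: dict[str, list[str]] = {}
        for gid in sorted(genes):
            members.setdefault(record_of[gid].genome_id, []).append(gid)
        rep = max(genes, key=lambda g: (len(record_of[g].protein_seq), g))
        fams.append(GeneFamily(family_id="", members=members, representative=rep))
    fams.sort(key=lambda f: (-f.n_genomes(), -f.n_genes(), f.representative))
    width = max(5, len(str(len(fams))))
    for i, f in enumerate(fams):
        f.family_id = f"F{i + 1:0{width}d}"

    mat = pd.DataFrame(
        0, index=list(genomes), columns=[f.family_id for f in fams], dtype=int
    )
    for f in fams:
        for gid, genes in f.members.items():
            mat.loc[gid, f.family_id] = len(genes)
    return PanGenome(
        threshold=threshold, families=fams, genomes=list(genomes),
        matrix=mat, gene_records=record_of,
    )


def _prepare(genomes: list[Genome], config: PanConfig, scheme: ScoringScheme):
    """Shared front end: filter, pre-cluster, and one k-mer count matrix.

    The shared-k-mer matrix over all retained genes drives both the
    pre-cluster and the ortholog-graph prescreens, so it is computed once.
    """
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_ids in pan-genome input")
    all_genes = [gene for g in genomes for gene in g.genes]
    retained, _rejected = filter_partial(all_genes, config.min_len)
    record_of = {g.gene_id: g for g in retained}
    counts = shared_kmer_matrix([g.protein_seq for g in retained],
                                config.prescreen_k)
    pre = _precluster_indexed(retained, counts, config.pre_pid,
                              config.pre_cov, scheme, config.prescreen_k)
    reps = [record_of[r] for r in pre]
    pos_of = {g.gene_id: i for i, g in enumerate(retained)}
    rep_pos = np.array([pos_of[r.gene_id] for r in reps])
    rep_counts = counts[np.ix_(rep_pos, rep_pos)]
    return ids, record_of, pre, reps, rep_counts


def build_pangenome(
    genomes: list[Genome],
    min_pid: float,
    config: PanConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> PanGenome:
    """Full composition: filter -> precluster -> graph -> MCL -> families."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    config = config or PanConfig()
    scheme = scheme or blosum62()
    ids, record_of, pre, reps, rep_counts = _prepare(genomes, config, scheme)
    pairs = all_pairs_alignments(reps, min_pid, scheme, config.prescreen_k,
                                 rep_counts)
    sim = graph_from_alignments(reps, pairs, min_pid, config.graph_min_cov)
    clusters = mcl_cluster(sim, config.inflation, config.mcl_tol,
                           config.mcl_prune, config.mcl_max_iter)
    return _families_from_clusters(clusters, pre, record_of, ids, min_pid)


def build_pangenomes_sweep(
    genomes: list[Genome],
    thresholds: list[float],
    config: PanConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> dict[float, PanGenome]:
    """One pan-genome per threshold, sharing a single all-vs-all alignment.

    Alignments are computed once at the lowest threshold; per-threshold
    graphs are edge-filtered views, so the result is identical to calling
    :func:`build_pangenome` per threshold (modulo the prescreen, which is
    calibrated to the *lowest* threshold and therefore strictly more
    permissive for the higher ones).
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    config = config or PanConfig()
    scheme = scheme or blosum62()
    ids, record_of, pre, reps, rep_counts = _prepare(genomes, config, scheme)
    pairs = all_pairs_alignments(reps, min(thresholds), scheme,
                                 config.prescreen_k, rep_counts)
    out: dict[float, PanGenome] = {}
    for t in thresholds:
        sim = graph_from_alignments(reps, pairs, t, config.graph_min_cov)
        clusters = mcl_cluster(sim, config.inflation, config.mcl_tol,
                               config.mcl_prune, config.mcl_max_iter)
        out[t] = _families_from_clusters(clusters, pre, record_of, ids, t)
    return out


# ---------------------------------------------------------------------------
# Partition / accumulation / Heaps
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    core: list[str]
    accessory: list[str]
    unique: list[str]

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_accessory(self) -> int:
        return len(self.accessory)

    @property
    def n_unique(self) -> int:
        return len(self.unique)


def partition_pangenome(pan: PanGenome) -> Partition:
    """Split families into core (all genomes) / accessory (2..n-1) / unique (1)."""
    n = len(pan.genomes)
    core, accessory, unique = [], [], []
    for f in pan.families:
        k = f.n_genomes()
        if k == n:
            core.append(f.family_id)
        elif k == 1:
            unique.append(f.family_id)
        else:
            accessory.append(f.family_id)
    return Partition(core=core, accessory=accessory, unique=unique)


@dataclass
class AccumulationCurve:
    """Pan/core/new-gene trajectories over random genome orderings."""

    points: pd.DataFrame     # columns: N, mean/median/sd for pan, core, new
    seed: int
    n_perm: int


@dataclass
class HeapsFit:
    kappa: float
    gamma: float
    is_open: bool


OPENNESS_GAMMA = 0.01  # gamma above this counts as an open pan-genome


def fit_heaps(ns: np.ndarray, pan_sizes: np.ndarray) -> HeapsFit:
    """Least-squares fit of log(size) = log(kappa) + gamma * log(N)."""
    x = np.log(np.asarray(ns, dtype=float))
    y = np.log(np.asarray(pan_sizes, dtype=float))
    gamma, logk = np.polyfit(x, y, 1)
    return HeapsFit(kappa=float(np.exp(logk)), gamma=float(gamma),
                    is_open=bool(gamma > OPENNESS_GAMMA))


def accumulation_and_heaps(
    pan: PanGenome, n_perm: int = 100, seed: int = 42
) -> tuple[AccumulationCurve, HeapsFit]:
    """Gene accumulation curves over shuffled genome orders plus Heaps fit.

    Within every permutation the pan size is non-decreasing and the core
    size non-increasing in N; the Heaps exponent is fitted to the median
    pan size across permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    presence = pan.matrix.to_numpy() > 0  # genomes x families
    n = presence.shape[0]
    pan_sizes = np.zeros((n_perm, n), dtype=int)
    core_sizes = np.zeros((n_perm, n), dtype=int)
    new_genes = np.zeros((n_perm, n), dtype=int)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.zeros(presence.shape[1], dtype=bool)
        in_all = np.ones(presence.shape[1], dtype=bool)
        for step, gi in enumerate(order):
            row = presence[gi]
            new_genes[p, step] = int(np.count_nonzero(row & ~seen))
            seen |= row
            in_all &= row
            pan_sizes[p, step] = int(seen.sum())
            core_sizes[p, step] = int(in_all.sum())
    pts = pd.DataFrame({
        "N": np.arange(1, n + 1),
        "pan_mean": pan_sizes.mean(axis=0),
        "pan_median": np.median(pan_sizes, axis=0),
        "pan_sd": pan_sizes.std(axis=0),
        "core_mean": core_sizes.mean(axis=0),
        "core_median": np.median(core_sizes, axis=0),
        "core_sd": core_sizes.std(axis=0),
        "new_mean": new_genes.mean(axis=0),
        "new_median": np.median(new_genes, axis=0),
        "new_sd": new_genes.std(axis=0),
    })
    fit = fit_heaps(pts["N"].to_numpy(), pts["pan_median"].to_numpy())
    return AccumulationCurve(points=pts, seed=seed, n_perm=n_perm), fit
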