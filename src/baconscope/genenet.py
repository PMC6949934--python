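"""Gene-sharing classification of viral contigs.

Contigs are clustered by significantly shared homologous gene content:

1. all-vs-all local protein alignment scores, converted to bits with the
   Karlin–Altschul formula and thresholded (default > 50 bits);
2. Markov clustering (MCL, inflation 2) of the resulting homology graph
   into gene families;
3. an upper-tail hypergeometric p-value for the number of families shared
   by every contig pair;
4. Ward.D2 agglomerative clustering of the Euclidean distances between
   rows of the p-value matrix, with the cluster number chosen by mean
   silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

__all__ = [
    "ScoringScheme",
    "GeneFamilyGraph",
    "SharedContentMatrix",
    "ClusterAssignment",
    "filter_contigs",
    "pairwise_scores",
    "mcl",
    "shared_content",
    "ward_cluster",
]


@dataclass
class ScoringScheme:
    """Local-alignment scoring with Karlin–Altschul bit conversion.

    ``lambda_`` (nats per raw score unit) and ``K`` are the standard gapped
    BLOSUM62 constants, so the bit threshold lives on BLAST's scale:
    ``S_bits = (lambda * S_raw - ln K) / ln 2``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    K: float = 0.041
    bit_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def bits(self, raw: float) -> float:
        return (self.lambda_ * raw - np.log(self.K)) / np.log(2.0)


@dataclass
class GeneFamilyGraph:
    nodes: List[str]
    edges: Dict[Tuple[str, str], float]  # undirected; key sorted
    families: Dict[int, List[str]] = field(default_factory=dict)
    inflation: float = 2.0

    def family_of(self) -> Dict[str, int]:
        return {m: fid for fid, members in self.families.items() for m in members}


@dataclass
class SharedContentMatrix:
    contig_ids: List[str]
    n_families: np.ndarray  # families per contig (deduplicated)
    shared: np.ndarray  # pairwise shared family counts
    n_total: int
    p_values: np.ndarray  # upper-tail hypergeometric, 1 on the diagonal
    distances: np.ndarray  # Euclidean over p-value rows


@dataclass
class ClusterAssignment:
    labels: Dict[str, int]
    chosen_k: int
    silhouettes: Dict[str, float]
    linkage_matrix: np.ndarray
    mean_silhouette_by_k: Dict[int, float]
    degenerate: bool = False


def filter_contigs(orfs_by_contig: Dict[str, Sequence], min_orfs: int = 10) -> Dict[str, Sequence]:
    """Retain contigs with strictly more than ``min_orfs`` ORFs."""
    if min_orfs < 0:
        raise ValueError("min_orfs must be >= 0")
    return {cid: orfs for cid, orfs in orfs_by_contig.items() if len(orfs) > min_orfs}


_ALIGNER = None


def _aligner(scheme: ScoringScheme):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _kmer_sets(proteins: Dict[str, str], k: int) -> Dict[str, frozenset]:
    return {
        pid: frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))
        for pid, seq in proteins.items()
    }


def pairwise_scores(
    proteins: Dict[str, str],
    scheme: Optional[ScoringScheme] = None,
    prefilter: Optional[int] = 2,
    prefilter_k: int = 4,
) -> Dict[Tuple[str, str], float]:
    """All-vs-all local alignment scores above the bit threshold.

    Smith–Waterman with affine gaps (BLOSUM62 by default); the raw optimal
    score is converted to bits and the edge is kept when it is strictly
    above ``scheme.bit_threshold``. Self-edges are excluded.

    ``prefilter`` skips pairs sharing fewer than that many ``prefilter_k``-mers
    — a seeding heuristic in the spirit of word-based search tools that makes
    the quadratic step tractable; pass ``prefilter=None`` for the exact
    all-pairs computation.
    """
    scheme = scheme or ScoringScheme()
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    aligner = _aligner(scheme)
    ids = sorted(proteins)
    kmers = _kmer_sets(proteins, prefilter_k) if prefilter is not None else None
    edges: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        sa = proteins[a]
        if not sa:
            continue
        for b in ids[i + 1 :]:
            sb = proteins[b]
            if not sb:
                continue
            if kmers is not None and len(kmers[a] & kmers[b]) < prefilter:
                continue
            raw = aligner.score(sa, sb)
            bits = scheme.bits(raw)
            if bits > scheme.bit_threshold:
                edges[(a, b)] = bits
    return edges


def mcl(
    nodes: Iterable[str],
    edges: Dict[Tuple[str, str], float],
    inflation: float = 2.0,
    prune: float = 1e-6,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    self_loops: str = "max",
) -> GeneFamilyGraph:
    """Markov clustering of a weighted undirected graph into gene families.

    Iterates expansion (matrix squaring) and inflation (entrywise power
    ``inflation`` followed by column renormalisation), pruning entries below
    ``prune``, until the largest entry change is below ``tol``. Clusters are
    read from the attractor rows of the limit matrix; isolated nodes become
    singleton families. Self-loops are added with each node's maximum edge
    weight before normalisation (standard MCL regularisation).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(set(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in edges.items():
        if a == b:
            continue
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    if self_loops == "max":
        loop = M.max(axis=0)
        loop[loop == 0] = 1.0
        np.fill_diagonal(M, loop)
    else:
        np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        new = M @ M  # expansion
        np.power(new, inflation, out=new)  # inflation
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new
    else:
        raise RuntimeError(f"MCL did not converge in {max_iter} iterations")

    # attractors are nodes with mass on their own diagonal; each attractor row
    # lists its cluster members
    clusters: List[set] = []
    attractors = np.flatnonzero(np.diag(M) > 1e-8)
    for a in attractors:
        members = set(np.flatnonzero(M[a] > 1e-8)) | {a}
        for c in clusters:
            if c & members:
                c |= members
                break
        else:
            clusters.append(set(members))
    # merge overlapping clusters transitively
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    clusters.sort(key=lambda c: (-len(c), min(c)))
    families = {fid: sorted(nodes[i] for i in c) for fid, c in enumerate(clusters)}
    return GeneFamilyGraph(list(nodes), dict(edges), families, inflation)


def shared_content(contig_families: Dict[str, Iterable[int]]) -> SharedContentMatrix:
    """Hypergeometric significance of shared gene families per contig pair.

    With N total families in the dataset, contig i carrying ``n_i`` distinct
    families and the pair sharing ``k``, the p-value is
    ``P(X >= k)`` for ``X ~ Hypergeometric(N, n_i, n_j)``. Distances between
    contigs are Euclidean distances between rows of the p-value matrix.
    """
    ids = sorted(contig_families)
    fam_sets = {c: frozenset(contig_families[c]) for c in ids}
    all_fams = frozenset().union(*fam_sets.values()) if ids else frozenset()
    N = len(all_fams)
    if N == 0:
        raise ValueError("no gene families in dataset")
    n = len(ids)
    sizes = np.array([len(fam_sets[c]) for c in ids])
    shared = np.zeros((n, n), int)
    P = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            k = len(fam_sets[ids[i]] & fam_sets[ids[j]])
            shared[i, j] = shared[j, i] = k
            # upper tail P(X >= k)
            p = float(hypergeom.sf(k - 1, N, sizes[i], sizes[j]))
            P[i, j] = P[j, i] = min(p, 1.0)
    D = squareform(pdist(P, metric="euclidean"))
    return SharedContentMatrix(ids, sizes, shared, N, P, D)


def ward_cluster(
    matrix: SharedContentMatrix,
    k_range: Optional[Sequence[int]] = None,
) -> ClusterAssignment:
    """Ward.D2 hierarchical clustering with silhouette-selected k.

    scipy's ``linkage(..., method='ward')`` on a condensed Euclidean distance
    matrix applies the Ward.D2 Lance–Williams update. The cluster number is
    the value in ``k_range`` (default 2..min(15, n-1)) maximising the mean
    silhouette computed on the same distances.
    """
    from sklearn.metrics import silhouette_samples

    ids = matrix.contig_ids
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 contigs to cluster")
    D = matrix.distances
    if np.allclose(D, 0.0):
        labels = {c: 1 for c in ids}
        Z = linkage(squareform(D, checks=False), method="ward")
        return ClusterAssignment(labels, 1, {c: float("nan") for c in ids}, Z, {}, degenerate=True)
    if k_range is None:
        k_range = range(2, min(15, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range must contain values in [2, n-1]")
    Z = linkage(squareform(D, checks=False), method="ward")
    best_k, best_sil, best_labels, by_k = None, -np.inf, None, {}
    for k in k_range:
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(set(lab)) < 2:
            continue
        sil = silhouette_samples(D, lab, metric="precomputed")
        by_k[k] = float(sil.mean())
        if by_k[k] > best_sil:
            best_k, best_sil, best_labels, best_sil_vals = k, by_k[k], lab, sil
    if best_k is None:
        raise ValueError("no k in k_range produced more than one cluster")
    labels = {c: int(l) for c, l in zip(ids, best_labels)}
    sils = {c: float(s) for c, s in zip(ids, best_sil_vals)}
    return ClusterAssignment(labels, best_k, sils, Z, by_k)
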