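"""Domain and protein phylogenetics.

Alignment is progressive: a UPGMA guide tree over k-mer distances, then
profile–profile Needleman–Wunsch with BLOSUM62 and affine gaps. Gappy
columns can be trimmed at a minimum non-gap fraction (the ``gt`` convention:
retain a column iff its non-gap fraction is at least ``gt``). Trees are
neighbor-joining on Kimura-corrected protein distances with ordinary
(column-resampling) bootstrap support.

Two analyses specific to tandem domain arrays live here as well:
``position_clades`` asks whether domains occupying the same position in an
array form monophyletic clades (evolutionary stability of array order), and
``duplication_mode`` diagnoses whether an array grew by single-domain or
multi-domain block duplications from the offset structure of its all-vs-all
similarity matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genenet import ScoringScheme
from .phmm import AA_INDEX, AMINO_ACIDS, N_AA

__all__ = [
    "align",
    "trim",
    "concat",
    "distance_matrix",
    "nj_tree",
    "bootstrap",
    "position_clades",
    "duplication_mode",
    "DuplicationMatrix",
]


def _blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    S = np.zeros((N_AA, N_AA))
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            S[AA_INDEX[a], AA_INDEX[b]] = mat[a, b]
    return S


_S_CACHE: Optional[np.ndarray] = None


def _S() -> np.ndarray:
    global _S_CACHE
    if _S_CACHE is None:
        _S_CACHE = _blosum62()
    return _S_CACHE


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def _profile_counts(rows: List[str]) -> np.ndarray:
    """Per-column residue count matrix (ncol, 20); gaps contribute nothing."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, N_AA))
    for r in rows:
        for j, c in enumerate(r):
            if c != "-":
                counts[j, AA_INDEX[c]] += 1.0
    return counts


def _align_profiles(
    rows_a: List[str], rows_b: List[str], gap_open: float, gap_extend: float
) -> Tuple[List[str], List[str]]:
    """Affine-gap Needleman–Wunsch between two alignment profiles.

    Column score is the mean BLOSUM62 score over residue pairs, averaged over
    all row pairs (gapped rows contribute zero). Ties in the traceback prefer
    substitution, then a gap in the second profile, deterministically.
    """
    S = _S()
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    score = (ca @ S @ cb.T) / (na * nb)  # (la, lb)
    la, lb = score.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap columns inserted into B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap columns inserted into A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    PM = np.zeros((la + 1, lb + 1), np.int8)
    PX = np.zeros((la + 1, lb + 1), np.int8)
    PY = np.zeros((la + 1, lb + 1), np.int8)
    PX[2:, 0] = 1  # border gaps continue the same gap run
    PY[0, 2:] = 2
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, lb + 1):
            best = Mi1[j - 1]
            ptr = 0
            if Xi1[j - 1] > best:
                best, ptr = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, ptr = Yi1[j - 1], 2
            M[i, j] = best + score[i - 1, j - 1]
            PM[i, j] = ptr
            xo = Mi1[j] - gap_open
            xe = Xi1[j] - gap_extend
            X[i, j], PX[i, j] = (xo, 0) if xo >= xe else (xe, 1)
            yo = M[i, j - 1] - gap_open
            ye = Y[i, j - 1] - gap_extend
            Y[i, j], PY[i, j] = (yo, 0) if yo >= ye else (ye, 2)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: List[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("M")
            state = int(PM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("X")
            state = int(PX[i, j])
            i -= 1
        else:
            ops.append("Y")
            state = int(PY[i, j])
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for r, row in zip(rows_a, out_a):
                row.append(r[ia])
            for r, row in zip(rows_b, out_b):
                row.append(r[ib])
            ia += 1
            ib += 1
        elif op == "X":
            for r, row in zip(rows_a, out_a):
                row.append(r[ia])
            for row in out_b:
                row.append("-")
            ia += 1
        else:
            for row in out_a:
                row.append("-")
            for r, row in zip(rows_b, out_b):
                row.append(r[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align(
    seqs: Dict[str, str], gap_open: float = 11.0, gap_extend: float = 1.0, k: int = 3
) -> Dict[str, str]:
    """Progressive multiple alignment.

    Guide tree: UPGMA (average linkage) on pairwise k-mer distances over
    lexicographically sorted ids, which makes the result independent of the
    input dictionary order. A single sequence aligns trivially to itself.
    """
    ids = sorted(seqs)
    if len(ids) == 0:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}
    if len(ids) == 2:
        a, b = ids
        ra, rb = _align_profiles([seqs[a]], [seqs[b]], gap_open, gap_extend)
        return {a: ra[0], b: rb[0]}
    dvec = [
        _kmer_distance(seqs[a], seqs[b], k) for a, b in itertools.combinations(ids, 2)
    ]
    Z = linkage(np.array(dvec), method="average")
    clusters: Dict[int, Tuple[List[str], List[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(len(ids))
    }
    nxt = len(ids)
    for a_i, b_i, _, _ in Z:
        ids_a, rows_a = clusters.pop(int(a_i))
        ids_b, rows_b = clusters.pop(int(b_i))
        ra, rb = _align_profiles(rows_a, rows_b, gap_open, gap_extend)
        clusters[nxt] = (ids_a + ids_b, ra + rb)
        nxt += 1
    final_ids, final_rows = clusters.popitem()[1]
    return {i: r for i, r in sorted(zip(final_ids, final_rows))}


# ---------------------------------------------------------------------------
# Trimming and concatenation
# ---------------------------------------------------------------------------


def trim(msa: Dict[str, str], gt: float) -> Tuple[Dict[str, str], List[int]]:
    """Drop columns with non-gap fraction below ``gt``.

    Returns the trimmed alignment and the removed column indices. ``gt=0``
    is the identity; the operation is idempotent.
    """
    if not 0.0 <= gt <= 1.0:
        raise ValueError("gt must be in [0, 1]")
    rows = list(msa.values())
    ncol = len(rows[0])
    nongap = np.array([[c != "-" for c in r] for r in rows])
    frac = nongap.mean(axis=0)
    keep = frac >= gt
    if not keep.any():
        raise ValueError("trimming removed every column")
    removed = [int(i) for i in np.flatnonzero(~keep)]
    kept = np.flatnonzero(keep)
    return {k: "".join(v[i] for i in kept) for k, v in msa.items()}, removed


def concat(msas: Sequence[Dict[str, str]]) -> Tuple[Dict[str, str], List[Tuple[int, int]]]:
    """Concatenate alignments over the union of their ids.

    Ids missing from a block are padded with gaps there. Returns the
    concatenated alignment and per-source (start, end) column spans.
    """
    all_ids = sorted(set().union(*[set(m) for m in msas]))
    if not any(set(m) & set(n) for m, n in itertools.combinations(msas, 2)) and len(msas) > 1:
        raise ValueError("alignments share no ids; concatenation is meaningless")
    spans = []
    out = {i: [] for i in all_ids}
    pos = 0
    for m in msas:
        ncol = len(next(iter(m.values())))
        spans.append((pos, pos + ncol))
        pos += ncol
        for i in all_ids:
            out[i].append(m.get(i, "-" * ncol))
    return {i: "".join(parts) for i, parts in out.items()}, spans


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

SATURATION_CAP = 10.0


def kimura_distance(p: float) -> float:
    """Kimura's empirical correction for protein distance."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= np.exp(-SATURATION_CAP):
        return SATURATION_CAP
    return -np.log(arg)


def distance_matrix(
    msa: Dict[str, str], min_shared: int = 10
) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Kimura-corrected pairwise distances with pairwise gap deletion.

    p is the mismatch fraction over columns where both rows have residues;
    d = -ln(1 - p - 0.2 p^2), capped at 10 near saturation. Returns
    (ids, distances, low-coverage flags) where a flagged pair shared fewer
    than ``min_shared`` columns.
    """
    ids = sorted(msa)
    if len(ids) < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    arr = np.array([[c for c in msa[i]] for i in ids])
    nongap = arr != "-"
    n = len(ids)
    D = np.zeros((n, n))
    flags = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            shared = int(both.sum())
            if shared < min_shared:
                flags[i, j] = flags[j, i] = True
            if shared == 0:
                d = SATURATION_CAP
            else:
                p = float((arr[i, both] != arr[j, both]).mean())
                d = kimura_distance(p)
            D[i, j] = D[j, i] = d
    return ids, D, flags


def nj_tree(ids: Sequence[str], D: np.ndarray):
    """Neighbor-joining tree (skbio TreeNode), exact on additive matrices."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite values")
    if len(ids) == 3:
        # closed-form star: branch i = (d_ij + d_ik - d_jk) / 2
        from skbio import TreeNode

        a, b, c = ids
        la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2
        lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2
        lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2
        return TreeNode.read([f"({a}:{la:.10g},{b}:{lb:.10g},{c}:{lc:.10g});"])
    return nj(DistanceMatrix(D, list(ids)))


def _splits(tree, taxa: frozenset) -> set:
    """Non-trivial bipartitions of a tree, canonicalised by the side not
    containing the lexicographically smallest taxon."""
    ref = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def bootstrap(msa: Dict[str, str], B: int = 100, seed: int = 0, min_shared: int = 10):
    """NJ tree with column-resampling bootstrap support.

    Resamples alignment columns with replacement B times, rebuilds the NJ
    tree each time, and writes the percentage of replicates containing each
    internal split into the corresponding internal node name of the tree
    built from the original alignment.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ids, D, _ = distance_matrix(msa, min_shared=min_shared)
    tree = nj_tree(ids, D)
    taxa = frozenset(ids)
    rng = np.random.default_rng(seed)
    ncol = len(next(iter(msa.values())))
    counts: Dict[frozenset, int] = {}
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        rep = {k: "".join(v[c] for c in cols) for k, v in msa.items()}
        try:
            rids, rD, _ = distance_matrix(rep, min_shared=1)
            rtree = nj_tree(rids, rD)
        except ValueError:
            continue
        for s in _splits(rtree, taxa):
            counts[s] = counts.get(s, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if min(taxa) in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            node.name = f"{100.0 * counts.get(side, 0) / B:.0f}"
    return tree


# ---------------------------------------------------------------------------
# Position-in-array clades
# ---------------------------------------------------------------------------


def position_clades(tree, position_labels: Dict[str, int]) -> dict:
    """Monophyly of array-position classes on the unrooted tree.

    ``position_labels`` maps leaf name -> array position for tandem-array
    domains; leaves absent from the map (e.g. bacterial domains) are treated
    as neutral bystanders. A class is monophyletic when some edge of the
    (unrooted) tree separates exactly its members from every other labelled
    leaf — the rooted-tree artifact at the root is thereby avoided. For each
    class the report carries that verdict, the purity of its tightest
    containing clade (class members / labelled leaves on that side), and the
    number of unlabelled leaves on that side. The class whose clade contains
    the most unlabelled leaves is flagged as the candidate ancestral
    position.
    """
    tip_names = {t.name for t in tree.tips()}
    missing = [n for n in position_labels if n not in tip_names]
    if missing:
        raise ValueError(f"labelled leaves missing from tree: {missing[:3]}")
    labelled = set(position_labels)
    classes: Dict[int, List[str]] = {}
    for leaf, pos in position_labels.items():
        classes.setdefault(pos, []).append(leaf)
    # every bipartition side induced by an edge, as (side tip set)
    sides = []
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        sides.append(below)
        sides.append(frozenset(tip_names) - below)
    report = {}
    for pos, members in sorted(classes.items()):
        mset = set(members)
        if len(members) == 1:
            report[pos] = {
                "monophyletic": True,
                "purity": 1.0,
                "unlabelled_in_clade": 0,
                "class_size": 1,
            }
            continue
        mono = False
        tightest = None
        for side in sides:
            if not mset <= side:
                continue
            if labelled & side == mset:
                mono = True
            if tightest is None or len(side) < len(tightest):
                tightest = side
        lab_tight = labelled & tightest
        report[pos] = {
            "monophyletic": mono,
            "purity": len(mset) / len(lab_tight),
            "unlabelled_in_clade": len(tightest) - len(lab_tight),
            "class_size": len(members),
        }
    candidates = [p for p in report if report[p]["unlabelled_in_clade"] > 0]
    ancestral = (
        max(candidates, key=lambda p: report[p]["unlabelled_in_clade"]) if candidates else None
    )
    return {
        "classes": report,
        "n_monophyletic": sum(r["monophyletic"] for r in report.values()),
        "n_classes": len(report),
        "candidate_ancestral_position": ancestral,
    }


# ---------------------------------------------------------------------------
# Duplication mode
# ---------------------------------------------------------------------------


@dataclass
class DuplicationMatrix:
    """All-vs-all bit scores of one array's domains plus its offset profile."""

    bit_scores: np.ndarray  # (m, m), symmetric
    offset_profile: np.ndarray  # mean score at |i-j| = d, d = 1..m-1
    classification: str  # "single-domain" or "block:<b>"
    contrast: float  # s(1) - mean(s(d > 1)); nearest-neighbour excess


def duplication_mode(
    array_domains: Sequence[str],
    scheme: Optional[ScoringScheme] = None,
    mad_factor: float = 2.0,
) -> DuplicationMatrix:
    """Diagnose the growth mode of a tandem array from self-similarity.

    Computes the m x m local-alignment bit-score matrix of the domains in
    array order and its offset profile s(d), the mean score of pairs d apart.
    Block duplication of size b leaves a periodic signature: s(b) — and its
    harmonics s(2b), s(3b), ... — sit above the rest of the profile. A
    candidate b is accepted when s(b) exceeds the median of the
    *off-harmonic* offsets (d not a multiple of b) by more than
    ``mad_factor`` MADs of those offsets *and* exceeds s(1); harmonics are
    excluded from the background because they carry the same periodic
    signal and would otherwise mask it. Without such a signature the array
    is classified as grown by single-domain duplications.
    """
    scheme = scheme or ScoringScheme()
    m = len(array_domains)
    if m < 3:
        raise ValueError("need at least 3 domains to diagnose duplication mode")
    from .genenet import _aligner

    aligner = _aligner(scheme)
    B = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            raw = aligner.score(array_domains[i], array_domains[j])
            B[i, j] = B[j, i] = scheme.bits(raw)
    prof = np.array(
        [np.mean([B[i, i + d] for i in range(m - d)]) for d in range(1, m)]
    )
    classification = "single-domain"
    best_excess = 0.0
    for b in range(2, m):
        background = np.array([prof[d - 1] for d in range(1, m) if d % b != 0])
        if len(background) < 2:
            continue
        med = float(np.median(background))
        mad = float(np.median(np.abs(background - med)))
        excess = prof[b - 1] - (med + mad_factor * mad)
        if excess > 0 and prof[b - 1] > prof[0] and excess > best_excess:
            classification = f"block:{b}"
            best_excess = excess
    contrast = float(prof[0] - prof[1:].mean()) if m > 2 else 0.0
    return DuplicationMatrix(B, prof, classification, contrast)
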