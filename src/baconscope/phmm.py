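"""Profile hidden Markov models of protein domains.

A profile HMM is a positional probabilistic model of a domain family with
match, insert and delete states. This module builds profiles from multiple
alignments, scans proteins for local domain hits with a Plan7-style Viterbi
algorithm (log2-odds bit scores against a background model; uniform entry
over match states, free exit), and runs the iterative search-to-convergence
refinement in which the aligned hits of one round become the training
alignment of the next.

There is deliberately no forward/E-value stage: hits are thresholded on the
Viterbi bit score, which makes every reported hit exactly verifiable against
brute-force path enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

# transition bundle order, from match state k (0-based) to states at k+1
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

__all__ = [
    "ProfileHMM",
    "ProfileParams",
    "DomainHit",
    "ColumnStats",
    "build_profile",
    "search",
    "iterative_search",
    "column_stats",
    "read_hmmer3",
    "consensus",
]


@dataclass
class ProfileParams:
    """Tunable knobs for profile construction and search.

    match_column_threshold: columns whose non-gap fraction is at least this
        value become match states (unweighted rule).
    pseudocount_weight: Dirichlet weight alpha on the background when turning
        counts into emission probabilities.
    score_threshold_bits: minimum Viterbi bit score for a reported hit.
    """

    match_column_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    score_threshold_bits: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.match_column_threshold <= 1.0:
            raise ValueError("match_column_threshold must be in [0, 1]")
        if self.pseudocount_weight <= 0:
            raise ValueError("pseudocount_weight must be > 0")


@dataclass
class DomainHit:
    """A located domain occurrence on one protein.

    Envelope coordinates are 0-based half-open residue positions.
    ``array_position`` is filled in later by tandem-array detection
    (1-based, counted from the N-terminus).
    """

    orf_id: str
    env_start: int
    env_end: int
    bit_score: float
    iteration_found: int = 1
    array_position: Optional[int] = None
    aligned_row: Optional[str] = None  # residues over the profile's match columns

    def key(self) -> Tuple[str, int, int]:
        return (self.orf_id, self.env_start, self.env_end)


@dataclass
class ProfileHMM:
    """Positional emission/transition model with L match states."""

    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L, 20)
    transitions: np.ndarray  # (L, 7): MM MI MD IM II DM DD out of state k
    background: np.ndarray  # (20,)
    occupancy: np.ndarray  # (L,)
    L: int = field(init=False)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, float)
        self.insert_emissions = np.asarray(self.insert_emissions, float)
        self.transitions = np.asarray(self.transitions, float)
        self.background = np.asarray(self.background, float)
        self.occupancy = np.asarray(self.occupancy, float)
        self.L = self.match_emissions.shape[0]
        if self.L < 1:
            raise ValueError("profile must have at least one match state")
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        for name, rows in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
        ):
            if not np.allclose(rows.sum(axis=1), 1.0, atol=atol):
                raise ValueError(f"{name} rows must each sum to 1")
        t = self.transitions
        for name, cols in (("M", [T_MM, T_MI, T_MD]), ("I", [T_IM, T_II]), ("D", [T_DM, T_DD])):
            if not np.allclose(t[:, cols].sum(axis=1), 1.0, atol=atol):
                raise ValueError(f"{name}-state transition bundles must sum to 1")
        if abs(self.background.sum() - 1.0) > atol:
            raise ValueError("background must sum to 1")

    def to_json(self) -> dict:
        return {
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": self.transitions.tolist(),
            "background": self.background.tolist(),
            "occupancy": self.occupancy.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ProfileHMM":
        return cls(
            np.array(obj["match_emissions"]),
            np.array(obj["insert_emissions"]),
            np.array(obj["transitions"]),
            np.array(obj["background"]),
            np.array(obj["occupancy"]),
        )


@dataclass
class ColumnStats:
    """Per-match-column summaries of an alignment (logo-style statistics)."""

    occupancy: np.ndarray
    insert_probability: np.ndarray
    information_content: np.ndarray  # bits, in [0, log2 20]
    conservation: np.ndarray  # modal-residue frequency


UNIFORM_BG = np.full(N_AA, 1.0 / N_AA)


def _encode(protein: str) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[a] for a in protein), dtype=np.int64, count=len(protein))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in protein") from None


def _default_transitions(L: int) -> np.ndarray:
    t = np.zeros((L, 7))
    t[:, T_MM], t[:, T_MI], t[:, T_MD] = 0.9, 0.05, 0.05
    t[:, T_IM], t[:, T_II] = 0.8, 0.2
    t[:, T_DM], t[:, T_DD] = 0.8, 0.2
    return t


def build_profile(
    msa: Dict[str, str],
    params: Optional[ProfileParams] = None,
    background: Optional[np.ndarray] = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with non-gap fraction >= ``params.match_column_threshold`` become
    match states. Match emissions are Dirichlet-smoothed counts,
    ``(counts + alpha * background) / (n + alpha)``; occupancy of column k is
    the fraction of rows with a residue there. Transition probabilities are
    counted from the implied M/I/D state paths of the rows with the same
    pseudocount weight.
    """
    params = params or ProfileParams()
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    rows = list(msa.values())
    if len(rows) < 2:
        raise ValueError("alignment must have at least 2 rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows must have equal length")
    mat = np.array([[c for c in r.upper().replace(".", "-")] for r in rows])
    nongap = mat != "-"
    match_cols = np.flatnonzero(nongap.mean(axis=0) >= params.match_column_threshold)
    L = len(match_cols)
    if L == 0:
        raise ValueError("alignment has zero match columns at this threshold")

    alpha = params.pseudocount_weight
    emis = np.tile(alpha * bg, (L, 1))
    occ = np.zeros(L)
    for k, col in enumerate(match_cols):
        residues = mat[:, col][nongap[:, col]]
        occ[k] = len(residues) / len(rows)
        for a in residues:
            if a in AA_INDEX:
                emis[k, AA_INDEX[a]] += 1.0
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts from implied state paths
    is_match_col = np.zeros(ncol, bool)
    is_match_col[match_cols] = True
    col_to_state = -np.ones(ncol, int)
    col_to_state[match_cols] = np.arange(L)
    tc = np.full((L, 7), alpha / 7.0)
    for r in range(len(rows)):
        path = []  # (state_index, 'M'|'I'|'D')
        for col in range(ncol):
            if is_match_col[col]:
                path.append((col_to_state[col], "M" if nongap[r, col] else "D"))
            elif nongap[r, col]:
                # insert state attached to the preceding match state
                k = int(np.searchsorted(match_cols, col)) - 1
                if k >= 0:
                    path.append((k, "I"))
        for (k1, s1), (k2, s2) in zip(path, path[1:]):
            idx = {
                ("M", "M"): T_MM, ("M", "I"): T_MI, ("M", "D"): T_MD,
                ("I", "M"): T_IM, ("I", "I"): T_II,
                ("D", "M"): T_DM, ("D", "D"): T_DD,
            }.get((s1, s2))
            if idx is not None:
                tc[k1, idx] += 1.0
    t = np.zeros_like(tc)
    for cols in ([T_MM, T_MI, T_MD], [T_IM, T_II], [T_DM, T_DD]):
        t[:, cols] = tc[:, cols] / tc[:, cols].sum(axis=1, keepdims=True)

    return ProfileHMM(emis, np.tile(bg, (L, 1)), t, bg, occ)


def consensus(profile: ProfileHMM) -> str:
    """Most probable residue of every match state."""
    return "".join(AMINO_ACIDS[i] for i in profile.match_emissions.argmax(axis=1))


# ---------------------------------------------------------------------------
# Viterbi local search
# ---------------------------------------------------------------------------

_NEG = -1e30


def _viterbi_best(
    profile: ProfileHMM, xs: np.ndarray, masked: np.ndarray
) -> Tuple[float, Optional[dict]]:
    """Best local Viterbi alignment of one protein to the profile.

    Returns (bit_score, traceback-info). Local model: uniform entry into any
    match state (probability 1/L), free exit after any match state. Insert
    emissions score as background (zero odds). Masked residues are
    unalignable, so no path may claim or bridge them.
    """
    L = profile.L
    n = len(xs)
    with np.errstate(divide="ignore"):
        m_odds = np.log2(profile.match_emissions / profile.background)  # (L, 20)
        lt = np.log2(np.maximum(profile.transitions, 1e-300))
    entry = -np.log2(L)

    VM = np.full((n + 1, L), _NEG)
    VI = np.full((n + 1, L), _NEG)
    VD = np.full((n + 1, L), _NEG)
    # pointer codes: M from {0 entry, 1 M, 2 I, 3 D}; I from {1 M, 2 I}; D from {1 M, 3 D}
    PM = np.zeros((n + 1, L), np.int8)
    PI = np.zeros((n + 1, L), np.int8)
    PD = np.zeros((n + 1, L), np.int8)

    tMD = lt[:, T_MD]
    tDD = lt[:, T_DD]
    cumDD = np.concatenate([[0.0], np.cumsum(tDD[:-1])])  # path cost of D-chain up to state j

    best = (_NEG, -1, -1)
    for i in range(1, n + 1):
        xi = xs[i - 1]
        if masked[i - 1]:
            # residue unalignable: row stays -inf, breaking any path across it
            continue
        e = m_odds[:, xi]
        prevM = VM[i - 1]
        prevI = VI[i - 1]
        prevD = VD[i - 1]
        # match: entry vs diagonal moves from state j-1
        cand = np.full((4, L), _NEG)
        cand[0] = entry
        cand[1, 1:] = prevM[:-1] + lt[:-1, T_MM]
        cand[2, 1:] = prevI[:-1] + lt[:-1, T_IM]
        cand[3, 1:] = prevD[:-1] + lt[:-1, T_DM]
        src = cand.argmax(axis=0)
        VM[i] = e + cand[np.arange(4)[src], np.arange(L)]
        PM[i] = src
        # insert (emission odds 0 against background)
        up_m = prevM + lt[:, T_MI]
        up_i = prevI + lt[:, T_II]
        take_i = up_i > up_m
        VI[i] = np.where(take_i, up_i, up_m)
        PI[i] = np.where(take_i, 2, 1)
        # delete chain along j at fixed i: VD[j] = max(VM[j-1]+tMD, VD[j-1]+tDD)
        a = np.full(L, _NEG)
        a[1:] = VM[i][:-1] + tMD[:-1] - cumDD[1:]
        run = np.maximum.accumulate(a)
        VD[i] = run + cumDD
        PD[i] = np.where(np.isclose(VD[i], np.concatenate([[_NEG], VM[i][:-1] + tMD[:-1]]), atol=1e-12), 1, 3)
        jmax = int(VM[i].argmax())
        if VM[i, jmax] > best[0]:
            best = (VM[i, jmax], i, jmax)

    score, i, j = best
    if score <= _NEG / 2:
        return _NEG, None
    # traceback from the best match cell
    path: List[Tuple[int, int, str]] = []  # (protein pos i, state j, kind)
    state = "M"
    while True:
        path.append((i, j, state))
        if state == "M":
            p = PM[i, j]
            if p == 0:
                break
            i, j, state = i - 1, j - 1, {1: "M", 2: "I", 3: "D"}[int(p)]
        elif state == "I":
            i, state = i - 1, {1: "M", 2: "I"}[int(PI[i, j])]
        else:  # D
            j, state = j - 1, {1: "M", 3: "D"}[int(PD[i, j])]
    path.reverse()
    m_positions = [(pi, pj) for pi, pj, kind in path if kind == "M"]
    env_start = m_positions[0][0] - 1
    env_end = m_positions[-1][0]
    row = ["-"] * L
    for pi, pj, kind in path:
        if kind == "M":
            row[pj] = AMINO_ACIDS[xs[pi - 1]]
    return float(score), {
        "env_start": env_start,
        "env_end": env_end,
        "aligned_row": "".join(row),
    }


def search(
    profile: ProfileHMM,
    protein: str,
    params: Optional[ProfileParams] = None,
    orf_id: str = "query",
    iteration: int = 1,
) -> List[DomainHit]:
    """All non-overlapping local hits of ``profile`` on ``protein``.

    Iterated best-local-alignment: find the Viterbi-optimal hit, mask its
    envelope, rescan, until the best remaining score drops below
    ``params.score_threshold_bits``. Hits are returned sorted by envelope
    start and are guaranteed non-overlapping.
    """
    params = params or ProfileParams()
    if not protein:
        raise ValueError("protein must be non-empty")
    xs = _encode(protein)
    masked = np.zeros(len(xs), bool)
    hits: List[DomainHit] = []
    while True:
        score, info = _viterbi_best(profile, xs, masked)
        if info is None or score < params.score_threshold_bits:
            break
        hits.append(
            DomainHit(orf_id, info["env_start"], info["env_end"], score,
                      iteration_found=iteration, aligned_row=info["aligned_row"])
        )
        masked[info["env_start"]: info["env_end"]] = True
    hits.sort(key=lambda h: h.env_start)
    return hits


def search_all(
    profile: ProfileHMM,
    proteins: Dict[str, str],
    params: Optional[ProfileParams] = None,
    iteration: int = 1,
) -> List[DomainHit]:
    """Search every protein; concatenation of per-protein hit lists."""
    out: List[DomainHit] = []
    for oid, prot in proteins.items():
        if prot:
            out.extend(search(profile, prot, params, orf_id=oid, iteration=iteration))
    return out


def iterative_search(
    seed: ProfileHMM,
    proteins: Dict[str, str],
    params: Optional[ProfileParams] = None,
    max_iter: int = 10,
) -> Tuple[ProfileHMM, List[DomainHit], int, str]:
    """Iterative profile refinement until the hit set converges.

    Each round searches all proteins, realigns the hit envelopes on the
    profile's match columns (Viterbi-implied) and rebuilds the profile from
    that alignment. Stops when the (orf_id, envelope) set is identical
    between successive rounds, or after ``max_iter`` rounds.

    Returns ``(profile, hits, n_iterations, status)`` where status is
    "converged", "max_iter" or "no_hits".
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    params = params or ProfileParams()
    profile = seed
    prev_keys: Optional[set] = None
    hits: List[DomainHit] = []
    for it in range(1, max_iter + 1):
        hits = search_all(profile, proteins, params, iteration=it)
        keys = {h.key() for h in hits}
        if it == 1 and not keys:
            return seed, [], 1, "no_hits"
        if keys == prev_keys:
            return profile, hits, it, "converged"
        prev_keys = keys
        if len(keys) >= 2:
            msa = {f"{h.orf_id}/{h.env_start}-{h.env_end}": h.aligned_row for h in hits}
            profile = build_profile(msa, params, background=seed.background)
        # a single hit cannot rebuild a profile; keep searching with current one
    return profile, hits, max_iter, "max_iter"


# ---------------------------------------------------------------------------
# Column statistics (sequence-logo quantities)
# ---------------------------------------------------------------------------


def column_stats(msa: Dict[str, str], match_column_threshold: float = 0.5) -> ColumnStats:
    """Occupancy, insert probability, information content and conservation.

    Information content of a match column is ``log2(20) - H`` with ``H`` the
    Shannon entropy of its residue frequencies (gaps excluded; their effect
    appears in occupancy instead). Conservation is the modal-residue
    frequency. The insert probability of column k is the fraction of rows
    carrying at least one residue in the insert columns between match
    columns k and k+1. All-gap columns report occupancy 0 and IC 0.
    """
    rows = list(msa.values())
    if not rows:
        raise ValueError("alignment must be non-empty")
    mat = np.array([[c for c in r.upper().replace(".", "-")] for r in rows])
    nongap = mat != "-"
    frac = nongap.mean(axis=0)
    match_cols = np.flatnonzero(frac >= match_column_threshold)
    if len(match_cols) == 0:
        match_cols = np.arange(mat.shape[1])
    occ = frac[match_cols]
    ic = np.zeros(len(match_cols))
    cons = np.zeros(len(match_cols))
    for k, col in enumerate(match_cols):
        residues = mat[:, col][nongap[:, col]]
        if len(residues) == 0:
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        ic[k] = np.log2(N_AA) + np.sum(p * np.log2(p))
        cons[k] = p.max()
    ins = np.zeros(len(match_cols))
    for k in range(len(match_cols)):
        lo = match_cols[k] + 1
        hi = match_cols[k + 1] if k + 1 < len(match_cols) else mat.shape[1]
        if hi > lo:
            ins[k] = nongap[:, lo:hi].any(axis=1).mean()
    return ColumnStats(occ, ins, np.clip(ic, 0.0, None), cons)


# ---------------------------------------------------------------------------
# HMMER3 ASCII input (seed profiles such as Pfam PF13004)
# ---------------------------------------------------------------------------


def read_hmmer3(path) -> ProfileHMM:
    """Read a HMMER3 ASCII profile into a :class:`ProfileHMM` (read-only)."""
    from pyhmmer.plan7 import HMMFile

    with HMMFile(str(path)) as fh:
        hmm = fh.read()
    if hmm is None:
        raise ValueError(f"{path}: no HMM record found")
    me = np.asarray(hmm.match_emissions, float)[1:, :N_AA]  # row 0 = mute begin
    ie = np.asarray(hmm.insert_emissions, float)[1:, :N_AA]
    tp = np.asarray(hmm.transition_probabilities, float)[1:, :]
    occ = np.asarray(hmm.match_occupancy(), float)[1:]
    from pyhmmer.plan7 import Background

    bg = np.asarray(Background(hmm.alphabet).residue_frequencies, float)[:N_AA]
    me /= me.sum(axis=1, keepdims=True)
    ie /= ie.sum(axis=1, keepdims=True)
    bg /= bg.sum()
    # renormalise bundles defensively (ASCII rounding)
    t = tp.copy()
    for cols in ([T_MM, T_MI, T_MD], [T_IM, T_II], [T_DM, T_DD]):
        s = t[:, cols].sum(axis=1, keepdims=True)
        t[:, cols] = np.where(s > 0, t[:, cols] / s, 1.0 / len(cols))
    return ProfileHMM(me, ie, t, bg, np.clip(occ, 0.0, 1.0))
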