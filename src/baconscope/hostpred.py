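"""k-mer Markov phage–host prediction.

One fixed-order Markov model of nucleotide composition is trained per
candidate host genome (both strands, add-one smoothing); a phage contig is
scored against every model by its mean log-likelihood per base and hosts
are ranked by that score, the top-ranked genome being the predicted host.

Representative-genome selection per genus follows completeness C and
contamination M: argmax of C - 5*M, ties broken by the highest
coarse-consistency score, then lexicographic genome id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["GenomeRecord", "MarkovModel", "select_representatives", "train", "predict_host"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class GenomeRecord:
    genus: str
    genome_id: str
    completeness: float  # C, percent
    contamination: float  # M, percent
    coarse_consistency: float = 0.0
    path: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0.0:
            raise ValueError("contamination must be >= 0")

    @property
    def quality_score(self) -> float:
        return self.completeness - 5.0 * self.contamination


def select_representatives(records: Sequence[GenomeRecord]) -> Dict[str, GenomeRecord]:
    """Pick one genome per genus by C - 5*M, then coarse consistency, then id."""
    best: Dict[str, GenomeRecord] = {}
    for rec in records:
        cur = best.get(rec.genus)
        if cur is None:
            best[rec.genus] = rec
            continue
        key = (rec.quality_score, rec.coarse_consistency, [-ord(c) for c in rec.genome_id])
        cur_key = (cur.quality_score, cur.coarse_consistency, [-ord(c) for c in cur.genome_id])
        if key > cur_key:
            best[rec.genus] = rec
    return best


@dataclass
class MarkovModel:
    """Order-k nucleotide Markov chain with add-one smoothing."""

    k: int
    log_transitions: np.ndarray  # (4^k, 4) log P(next base | k-mer)
    genome_id: str = ""

    def __post_init__(self) -> None:
        probs = np.exp(self.log_transitions)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional distributions must sum to 1")


def _kmer_index(seq: str, start: int, k: int) -> Optional[int]:
    idx = 0
    for i in range(start, start + k):
        b = _BASE_INDEX.get(seq[i])
        if b is None:
            return None
        idx = (idx << 2) | b
    return idx


def train(genome: str, k: int = 3, genome_id: str = "") -> MarkovModel:
    """Train an order-k model on a genome sequence, counting both strands."""
    if k < 1:
        raise ValueError("k must be >= 1")
    genome = genome.upper()
    if len(genome) <= 4**k:
        raise ValueError(f"genome length {len(genome)} must exceed 4^k = {4**k}")
    counts = np.ones((4**k, 4))  # add-one smoothing
    for seq in (genome, genome.translate(_COMPLEMENT)[::-1]):
        # rolling k-mer index; restart after any non-ACGT base
        idx = 0
        valid = 0
        mask = 4**k - 1
        for ch in seq:
            b = _BASE_INDEX.get(ch)
            if b is None:
                valid = 0
                idx = 0
                continue
            if valid >= k:
                counts[idx & mask, b] += 1
            idx = ((idx << 2) | b) & mask
            valid += 1
    logp = np.log(counts / counts.sum(axis=1, keepdims=True))
    return MarkovModel(k, logp, genome_id)


def log_likelihood_per_base(model: MarkovModel, contig: str) -> float:
    """Mean log-likelihood per scored transition of ``contig`` under ``model``."""
    contig = contig.upper()
    k = model.k
    if len(contig) < k + 1:
        raise ValueError(f"contig shorter than k+1 = {k + 1}")
    total = 0.0
    n = 0
    idx = 0
    valid = 0
    mask = 4**k - 1
    for ch in contig:
        b = _BASE_INDEX.get(ch)
        if b is None:
            valid = 0
            idx = 0
            continue
        if valid >= k:
            total += model.log_transitions[idx & mask, b]
            n += 1
        idx = ((idx << 2) | b) & mask
        valid += 1
    if n == 0:
        raise ValueError("no scorable transitions in contig")
    return total / n


def predict_host(
    models: Dict[str, MarkovModel], contig: str
) -> Tuple[List[Tuple[str, float]], float]:
    """Rank hosts by mean log-likelihood per base; report the top-two margin."""
    scores = sorted(
        ((h, log_likelihood_per_base(m, contig)) for h, m in models.items()),
        key=lambda t: (-t[1], t[0]),
    )
    margin = scores[0][1] - scores[1][1] if len(scores) > 1 else float("inf")
    return scores, margin
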