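"""Domain architecture: tandem arrays, genomic neighbourhoods, tail association.

A tandem array is a run of two or more domain hits within one ORF whose
inter-envelope gaps never exceed a bound (default 30 residues, roughly two
thirds of one domain). Neighbourhoods collect the ORFs up to ``w`` positions
up- and downstream of a focal domain-bearing ORF on the same contig;
neighbourhoods whose labels are all "hypothetical protein" carry no
functional information and are excluded from association statistics.

Tail association is quantified as the difference between the fraction of
tandem-array ORFs and the fraction of single-domain ORFs that have at least
one tail-annotated neighbour, with a label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phmm import DomainHit

__all__ = [
    "TandemArray",
    "Neighbourhood",
    "TAIL_KEYWORDS",
    "detect_tandem",
    "architecture_summary",
    "neighbourhoods",
    "tail_association",
]

TAIL_KEYWORDS = ("tail", "tail fibre", "tail fiber", "tail spike", "baseplate")
HYPOTHETICAL = "hypothetical protein"


@dataclass
class TandemArray:
    orf_id: str
    hits: List[DomainHit]
    max_inter_domain_gap: int = 30
    is_tandem: bool = field(init=False)

    def __post_init__(self) -> None:
        hits = self.hits
        for a, b in zip(hits, hits[1:]):
            if b.env_start < a.env_end:
                raise ValueError(f"overlapping hits on {self.orf_id}")
        gaps = [b.env_start - a.env_end for a, b in zip(hits, hits[1:])]
        self.is_tandem = len(hits) >= 2 and all(g <= self.max_inter_domain_gap for g in gaps)
        for pos, h in enumerate(hits, start=1):
            h.array_position = pos

    @property
    def size(self) -> int:
        return len(self.hits)


@dataclass
class Neighbourhood:
    focal_orf_id: str
    window: int
    neighbours: List[Tuple[int, str, str]]  # (offset, orf_id, label), offset 0 = focal
    informative: bool = field(init=False)
    has_tail: bool = field(init=False)

    def __post_init__(self) -> None:
        labels = [lab for off, _, lab in self.neighbours if off != 0]
        self.informative = any(lab.lower() != HYPOTHETICAL for lab in labels)
        self.has_tail = any(
            any(kw in lab.lower() for kw in TAIL_KEYWORDS) for lab in labels
        )


def detect_tandem(orf_hits: Sequence[DomainHit], max_gap: int = 30) -> TandemArray:
    """Classify the hits of one ORF as a tandem array or not.

    Hits must be sorted and non-overlapping (the search contract); positions
    are assigned 1..m from the N-terminus regardless of the outcome.
    """
    hits = sorted(orf_hits, key=lambda h: h.env_start)
    if not hits:
        raise ValueError("detect_tandem requires at least one hit")
    return TandemArray(hits[0].orf_id, hits, max_inter_domain_gap=max_gap)


def architecture_summary(
    hits: Sequence[DomainHit],
    orf_to_contig: Dict[str, str],
    contig_cluster: Optional[Dict[str, int]] = None,
) -> Dict[str, pd.DataFrame]:
    """Histograms of domains-per-ORF and domain-ORFs-per-contig.

    Both tables carry a ``cluster`` column when cluster labels are supplied;
    unlabelled contigs get cluster -1.
    """
    per_orf: Dict[str, int] = {}
    for h in hits:
        per_orf[h.orf_id] = per_orf.get(h.orf_id, 0) + 1
    rows = []
    for oid, n in per_orf.items():
        contig = orf_to_contig[oid]
        cl = (contig_cluster or {}).get(contig, -1)
        rows.append({"orf_id": oid, "contig_id": contig, "n_domains": n, "cluster": cl})
    orf_df = pd.DataFrame(rows)
    if orf_df.empty:
        return {
            "domains_per_orf": pd.DataFrame(columns=["cluster", "n_domains", "n_orfs"]),
            "domain_orfs_per_contig": pd.DataFrame(columns=["cluster", "n_orfs", "n_contigs"]),
        }
    dpo = (
        orf_df.groupby(["cluster", "n_domains"]).size().rename("n_orfs").reset_index()
    )
    per_contig = orf_df.groupby(["cluster", "contig_id"]).size().rename("n_orfs").reset_index()
    opc = (
        per_contig.groupby(["cluster", "n_orfs"]).size().rename("n_contigs").reset_index()
    )
    return {"domains_per_orf": dpo, "domain_orfs_per_contig": opc}


def neighbourhoods(
    focal_orf_ids: Sequence[str],
    orf_order: Dict[str, List[str]],
    labels: Dict[str, str],
    w: int = 5,
) -> List[Neighbourhood]:
    """±w-ORF windows around each focal ORF, truncated at contig ends.

    ``orf_order`` maps contig id to its ORF ids sorted by coordinate;
    ``labels`` maps ORF id to a functional description ("hypothetical
    protein" allowed and treated as uninformative).
    """
    orf_to_contig = {oid: cid for cid, oids in orf_order.items() for oid in oids}
    out = []
    for focal in focal_orf_ids:
        if focal not in orf_to_contig:
            raise ValueError(f"focal ORF {focal!r} not present in ORF ordering")
        cid = orf_to_contig[focal]
        order = orf_order[cid]
        pos = order.index(focal)
        lo, hi = max(0, pos - w), min(len(order), pos + w + 1)
        neigh = [
            (i - pos, order[i], labels.get(order[i], HYPOTHETICAL)) for i in range(lo, hi)
        ]
        out.append(Neighbourhood(focal, w, neigh))
    return out


def tail_association(
    arrays: Sequence[TandemArray],
    neighbourhoods_by_orf: Dict[str, Neighbourhood],
    n_permutations: int = 999,
    seed: int = 0,
    return_null: bool = False,
):
    """Permutation test for tandem arrays sitting next to tail genes.

    Statistic: fraction of tandem-array ORFs with >= 1 tail-annotated
    neighbour minus the same fraction among single-domain ORFs, computed on
    informative neighbourhoods only. The p-value permutes the tandem/single
    labels across ORFs (one-sided, add-one corrected). With
    ``return_null=True`` the permuted statistics are returned as well, so
    calibration studies can apply randomized tie-breaking.
    """
    flags = []  # (is_tandem, has_tail)
    for arr in arrays:
        nb = neighbourhoods_by_orf.get(arr.orf_id)
        if nb is None or not nb.informative:
            continue
        flags.append((arr.is_tandem, nb.has_tail))
    if not flags:
        raise ValueError("no informative neighbourhoods available")
    is_tandem = np.array([f[0] for f in flags])
    has_tail = np.array([f[1] for f in flags], float)
    if is_tandem.all() or not is_tandem.any():
        raise ValueError("need both tandem and single-domain ORFs for the contrast")

    def stat(mask: np.ndarray) -> float:
        return float(has_tail[mask].mean() - has_tail[~mask].mean())

    observed = stat(is_tandem)
    rng = np.random.default_rng(seed)
    n_tandem = int(is_tandem.sum())
    null_stats = np.empty(n_permutations)
    for r in range(n_permutations):
        perm = np.zeros(len(flags), bool)
        perm[rng.choice(len(flags), size=n_tandem, replace=False)] = True
        null_stats[r] = stat(perm)
    p = (int((null_stats >= observed - 1e-12).sum()) + 1) / (n_permutations + 1)
    if return_null:
        return observed, p, null_stats
    return observed, p
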