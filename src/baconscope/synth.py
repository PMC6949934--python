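"""Synthetic phage-genome generator with known ground truth.

Emulates the data structures the pipeline is built to analyse: viral
contigs carrying 10–200 genes with lineage-structured shared gene-family
content; designated ORFs carrying arrays of a ~45-residue domain with four
strongly conserved residues; tandem arrays grown by replaying an explicit
duplication-event history (single-domain or multi-domain block copies) with
controlled divergence; horizontal transfer of domain-bearing ORFs between
otherwise dissimilar lineages; tail/non-tail functional labels placed
around domain ORFs by a configurable policy; and compositionally distinct
bacterial host genomes from which phage contigs can be sampled.

Every draw flows from one integer seed, so a configuration reproduces its
dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .phmm import AA_INDEX, AMINO_ACIDS, N_AA
from .seqio import Contig

__all__ = [
    "SynthConfig",
    "SimulatedTruth",
    "simulate_dataset",
    "replay_history",
    "sample_history",
    "make_seed_alignment",
    "simulate_host_genomes",
    "mutate_protein",
    "shuffled_negative",
]

DOMAIN_LENGTH = 45
CONSERVED_POSITIONS = (10, 26, 32, 44)
CONSERVED_RESIDUES = ("W", "N", "R", "Q")

_INFORMATIVE_LABELS = (
    "portal protein",
    "terminase large subunit",
    "major capsid protein",
    "DNA polymerase",
    "primase",
    "ssb protein",
)
_TAIL_LABELS = ("tail fibre protein", "tail spike protein", "baseplate protein", "tail protein")

_CODONS = {  # one codon per amino acid keeps reverse translation simple
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass
class SynthConfig:
    """Study conditions for one simulated dataset."""

    seed: int = 0
    n_lineages: int = 7
    contigs_per_lineage: int = 8
    genes_per_contig: Tuple[int, int] = (15, 30)
    n_shared_families: int = 30
    families_per_lineage: int = 25
    p_within: float = 0.9  # a gene draws from the lineage pool at this rate
    family_mutation_rate: float = 0.05
    domain_length: int = DOMAIN_LENGTH
    conserved_positions: Tuple[int, ...] = CONSERVED_POSITIONS
    conserved_residues: Tuple[str, ...] = CONSERVED_RESIDUES
    array_sizes: Dict[int, float] = field(default_factory=lambda: {1: 0.5, 8: 0.5})
    duplication_mode: str = "single"  # or "block:<b>"
    divergence: float = 0.05  # substitutions per site per duplication event
    lineage_domain_divergence: float = 0.10
    hgt_rate: float = 0.1
    tail_label_policy: str = "tandem_only"  # or "uniform", "none"
    informative_label_rate: float = 0.3
    linker_range: Tuple[int, int] = (3, 10)
    family_length_range: Tuple[int, int] = (60, 120)

    def __post_init__(self) -> None:
        for p in (self.p_within, self.hgt_rate, self.divergence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates and probabilities must be in [0, 1]")
        if len(self.conserved_positions) != len(self.conserved_residues):
            raise ValueError("conserved positions and residues must pair up")
        if any(p >= self.domain_length for p in self.conserved_positions):
            raise ValueError("conserved positions must fall inside the domain")
        if min(self.array_sizes) < 1:
            raise ValueError("array sizes must be >= 1")
        if max(self.array_sizes) + 2 > self.genes_per_contig[0]:
            raise ValueError("contigs have too few genes to host the largest array")


@dataclass
class OrfTruth:
    orf_id: str
    contig_id: str
    gene_index: int
    start: int
    end: int
    protein: str
    family_id: int
    label: str
    domains: List[Tuple[int, int, int]] = field(default_factory=list)
    # (env_start, env_end, array_position)


@dataclass
class SimulatedTruth:
    lineage_of: Dict[str, int]
    orfs: List[OrfTruth]
    events: Dict[str, List[Tuple[int, int]]]  # orf_id -> duplication history
    transfers: List[Tuple[str, str, str]]  # (donor contig, recipient contig, orf_id)
    ancestral_domain: str
    lineage_domains: Dict[int, str]

    def orfs_by_contig(self) -> Dict[str, List[OrfTruth]]:
        out: Dict[str, List[OrfTruth]] = {}
        for o in self.orfs:
            out.setdefault(o.contig_id, []).append(o)
        for v in out.values():
            v.sort(key=lambda o: o.gene_index)
        return out

    def proteins(self) -> Dict[str, str]:
        return {o.orf_id: o.protein for o in self.orfs}

    def to_json(self) -> dict:
        return {
            "lineage_of": self.lineage_of,
            "orfs": [
                {
                    "orf_id": o.orf_id, "contig_id": o.contig_id,
                    "gene_index": o.gene_index, "start": o.start, "end": o.end,
                    "protein": o.protein, "family_id": o.family_id,
                    "label": o.label, "domains": o.domains,
                }
                for o in self.orfs
            ],
            "events": self.events,
            "transfers": self.transfers,
            "ancestral_domain": self.ancestral_domain,
            "lineage_domains": self.lineage_domains,
        }


# ---------------------------------------------------------------------------
# Residue-level machinery
# ---------------------------------------------------------------------------

_EXCHANGE: Optional[np.ndarray] = None


def _exchange_matrix() -> np.ndarray:
    """BLOSUM62-conditional exchange probabilities P(b | a), b != a.

    Proportional to 2^(S/2) off the diagonal, so substitutions favour
    biochemically similar residues and diverged copies stay alignable.
    """
    global _EXCHANGE
    if _EXCHANGE is None:
        from Bio.Align import substitution_matrices

        S = substitution_matrices.load("BLOSUM62")
        E = np.zeros((N_AA, N_AA))
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                if a != b:
                    E[AA_INDEX[a], AA_INDEX[b]] = 2.0 ** (S[a, b] / 2.0)
        E /= E.sum(axis=1, keepdims=True)
        _EXCHANGE = E
    return _EXCHANGE


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, size=length))


def mutate_protein(
    protein: str,
    rate: float,
    rng: np.random.Generator,
    frozen: Sequence[int] = (),
) -> str:
    """Substitute residues at ``rate`` per site, never touching ``frozen``."""
    E = _exchange_matrix()
    frozen_set = set(frozen)
    out = list(protein)
    for i, a in enumerate(out):
        if i in frozen_set:
            continue
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.choice(N_AA, p=E[AA_INDEX[a]])]
    return "".join(out)


def shuffled_negative(protein: str, rng: np.random.Generator) -> str:
    """Length- and composition-matched negative control."""
    chars = list(protein)
    rng.shuffle(chars)
    return "".join(chars)


def _ancestral_domain(cfg: SynthConfig, rng: np.random.Generator) -> str:
    dom = list(random_protein(rng, cfg.domain_length))
    for pos, res in zip(cfg.conserved_positions, cfg.conserved_residues):
        dom[pos] = res
    return "".join(dom)


def make_seed_alignment(
    cfg: SynthConfig, rng: np.random.Generator, n_rows: int = 20, divergence: float = 0.1
) -> Tuple[str, Dict[str, str]]:
    """An ancestral domain plus a gap-free alignment of diverged copies.

    Stands in for a curated seed alignment of the domain family (used to
    build the seed profile that starts the iterative search).
    """
    ancestor = _ancestral_domain(cfg, rng)
    rows = {
        f"seed{i:03d}": mutate_protein(ancestor, divergence, rng, cfg.conserved_positions)
        for i in range(n_rows)
    }
    return ancestor, rows


# ---------------------------------------------------------------------------
# Duplication histories
# ---------------------------------------------------------------------------


def sample_history(
    target_size: int, mode: str, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Draw a duplication-event list growing an array from 1 to target_size.

    ``mode`` is "single" (every event copies one domain at a random internal
    position) or "block:<b>" (grow to b by single copies, then copy aligned
    b-sized blocks). Events are (position, size) with position the 0-based
    start of the copied block in the current array.
    """
    events: List[Tuple[int, int]] = []
    size = 1
    if mode == "single":
        while size < target_size:
            events.append((int(rng.integers(0, size)), 1))
            size += 1
        return events
    if mode.startswith("block:"):
        b = int(mode.split(":", 1)[1])
        if b < 2:
            raise ValueError("block size must be >= 2")
        while size < min(b, target_size):
            events.append((int(rng.integers(0, size)), 1))
            size += 1
        while size + b <= target_size:
            n_blocks = size // b
            events.append((int(rng.integers(0, max(n_blocks, 1))) * b, b))
            size += b
        while size < target_size:
            events.append((int(rng.integers(0, size)), 1))
            size += 1
        return events
    raise ValueError(f"unknown duplication mode {mode!r}")


def replay_history(
    ancestor_domain: str,
    events: Sequence[Tuple[int, int]],
    divergence: float,
    seed: int,
    conserved_positions: Sequence[int] = CONSERVED_POSITIONS,
) -> Tuple[List[str], List[int]]:
    """Replay a duplication history from a single ancestral domain.

    Each event copies the contiguous block ``array[pos:pos+size]`` and
    inserts the copy immediately after it; every domain then accumulates
    substitutions at ``divergence`` per site (conserved positions frozen).
    Returns the final ordered array and a per-domain trace of the ancestor
    index each copy descends from.
    """
    rng = np.random.default_rng(seed)
    array = [ancestor_domain]
    trace = [0]
    for pos, size in events:
        if pos < 0 or size < 1 or pos + size > len(array):
            raise ValueError(f"event ({pos}, {size}) out of bounds for array of {len(array)}")
        block = array[pos : pos + size]
        block_trace = trace[pos : pos + size]
        array[pos + size : pos + size] = list(block)
        trace[pos + size : pos + size] = list(block_trace)
        array = [
            mutate_protein(d, divergence, rng, conserved_positions) for d in array
        ]
    return array, trace


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------


def _reverse_translate(protein: str) -> str:
    # proteins start with M by construction, so codon 0 is the ATG start
    return "".join(_CODONS[a] for a in protein) + "TAA"


def _spacer(rng: np.random.Generator, lo: int = 10, hi: int = 50) -> str:
    """Intergenic spacer that insulates ORF calls.

    The C/T body contains no start or stop codons; the trailing TAA cassette
    puts a stop in all three forward frames, so an upstream reading frame can
    never run through the spacer and pre-empt the next gene's start codon.
    """
    n = int(rng.integers(lo, hi + 1))
    body = "".join("CT"[i] for i in rng.integers(0, 2, size=n))
    return body + "TAATTAATTAA"


def simulate_dataset(cfg: SynthConfig) -> Tuple[List[Contig], SimulatedTruth]:
    """Generate contigs plus complete ground truth. Deterministic in cfg.seed.

    Each lineage draws gene families from a private pool plus a pool shared
    across lineages; one ORF per contig carries a domain array built by
    replaying a sampled duplication history from the lineage's ancestral
    domain; tail / informative / hypothetical labels are assigned per the
    tail-label policy; domain-bearing ORFs hop between lineages at the
    horizontal-transfer rate.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = _ancestral_domain(cfg, rng)
    lineage_domains = {
        li: mutate_protein(ancestor, cfg.lineage_domain_divergence, rng, cfg.conserved_positions)
        for li in range(cfg.n_lineages)
    }

    # gene-family ancestors: shared pool + per-lineage private pools
    n_fams = cfg.n_shared_families + cfg.n_lineages * cfg.families_per_lineage
    fam_ancestors = [
        random_protein(rng, int(rng.integers(*cfg.family_length_range)))
        for _ in range(n_fams)
    ]
    shared_pool = list(range(cfg.n_shared_families))
    lineage_pool = {
        li: list(
            range(
                cfg.n_shared_families + li * cfg.families_per_lineage,
                cfg.n_shared_families + (li + 1) * cfg.families_per_lineage,
            )
        )
        for li in range(cfg.n_lineages)
    }

    sizes = sorted(cfg.array_sizes)
    size_p = np.array([cfg.array_sizes[s] for s in sizes], float)
    size_p /= size_p.sum()

    contigs: List[Contig] = []
    lineage_of: Dict[str, int] = {}
    orfs: List[OrfTruth] = []
    events: Dict[str, List[Tuple[int, int]]] = {}
    domain_orfs_by_lineage: Dict[int, List[OrfTruth]] = {li: [] for li in range(cfg.n_lineages)}

    for li in range(cfg.n_lineages):
        for ci in range(cfg.contigs_per_lineage):
            cid = f"L{li}C{ci}"
            lineage_of[cid] = li
            n_genes = int(rng.integers(cfg.genes_per_contig[0], cfg.genes_per_contig[1] + 1))
            # pick families
            fams = []
            for _ in range(n_genes):
                pool = lineage_pool[li] if rng.random() < cfg.p_within else shared_pool
                fams.append(int(rng.choice(pool)))
            # one domain-carrying ORF per contig, away from contig edges
            domain_gene = int(rng.integers(1, n_genes - 1))
            array_size = int(rng.choice(sizes, p=size_p))
            contig_orfs: List[OrfTruth] = []
            for gi in range(n_genes):
                oid = f"{cid}|g{gi}"
                protein = mutate_protein(
                    fam_ancestors[fams[gi]], cfg.family_mutation_rate, rng
                )
                rec = OrfTruth(
                    oid, cid, gi, -1, -1, "M" + protein[1:], fams[gi], "hypothetical protein"
                )
                if gi == domain_gene:
                    hist = sample_history(array_size, cfg.duplication_mode, rng) if array_size > 1 else []
                    array, _ = replay_history(
                        lineage_domains[li], hist, cfg.divergence,
                        int(rng.integers(0, 2**31 - 1)), cfg.conserved_positions,
                    )
                    events[oid] = hist
                    lo, hi = cfg.linker_range
                    parts = [random_protein(rng, int(rng.integers(5, 15)))]
                    doms = []
                    for pos, dom in enumerate(array, start=1):
                        start = sum(len(p) for p in parts)
                        parts.append(dom)
                        doms.append((start, start + len(dom), pos))
                        if pos < len(array):
                            parts.append(random_protein(rng, int(rng.integers(lo, hi + 1))))
                    parts.append(random_protein(rng, int(rng.integers(5, 15))))
                    rec.protein = "M" + "".join(parts)[1:]
                    rec.domains = doms
                    rec.family_id = -1  # domain ORFs are their own family
                contig_orfs.append(rec)
            domain_orfs_by_lineage[li].append(contig_orfs[domain_gene])
            orfs.extend(contig_orfs)

    # horizontal transfer of domain-bearing ORFs between lineages
    transfers: List[Tuple[str, str, str]] = []
    all_contig_ids = sorted(lineage_of)
    for cid in all_contig_ids:
        if rng.random() >= cfg.hgt_rate:
            continue
        li = lineage_of[cid]
        donors = [o for lj, lst in domain_orfs_by_lineage.items() if lj != li for o in lst]
        if not donors:
            continue
        donor = donors[int(rng.integers(0, len(donors)))]
        recip_orfs = [o for o in orfs if o.contig_id == cid]
        new_gi = max(o.gene_index for o in recip_orfs) + 1
        oid = f"{cid}|g{new_gi}"
        copy = OrfTruth(
            oid, cid, new_gi, -1, -1, donor.protein, -1, "hypothetical protein",
            domains=list(donor.domains),
        )
        if donor.orf_id in events:
            events[oid] = list(events[donor.orf_id])
        orfs.append(copy)
        transfers.append((donor.contig_id, cid, oid))

    truth = SimulatedTruth(lineage_of, orfs, events, transfers, ancestor, lineage_domains)
    _assign_labels(cfg, rng, truth)
    contigs = _emit_contigs(rng, truth)
    return contigs, truth


def _assign_labels(cfg: SynthConfig, rng: np.random.Generator, truth: SimulatedTruth) -> None:
    by_contig = truth.orfs_by_contig()
    for cid, lst in by_contig.items():
        # background informative labels keep neighbourhoods informative
        for o in lst:
            if not o.domains and rng.random() < cfg.informative_label_rate:
                o.label = _INFORMATIVE_LABELS[int(rng.integers(0, len(_INFORMATIVE_LABELS)))]
        if cfg.tail_label_policy == "none":
            continue
        for idx, o in enumerate(lst):
            if not o.domains:
                continue
            is_tandem = len(o.domains) >= 2
            if cfg.tail_label_policy == "tandem_only":
                place_tail = is_tandem
            elif cfg.tail_label_policy == "uniform":
                place_tail = rng.random() < 0.5
            else:
                raise ValueError(f"unknown tail_label_policy {cfg.tail_label_policy!r}")
            neigh = [j for j in (idx - 1, idx + 1) if 0 <= j < len(lst)]
            for j in neigh:
                if place_tail:
                    lst[j].label = _TAIL_LABELS[int(rng.integers(0, len(_TAIL_LABELS)))]
                elif lst[j].label == "hypothetical protein":
                    lst[j].label = _INFORMATIVE_LABELS[int(rng.integers(0, len(_INFORMATIVE_LABELS)))]


def _emit_contigs(rng: np.random.Generator, truth: SimulatedTruth) -> List[Contig]:
    contigs = []
    for cid, lst in sorted(truth.orfs_by_contig().items()):
        parts = [_spacer(rng)]
        pos = len(parts[0])
        for o in lst:
            dna = _reverse_translate(o.protein)
            o.start, o.end = pos, pos + len(dna)
            parts.append(dna)
            pos += len(dna)
            sp = _spacer(rng)
            parts.append(sp)
            pos += len(sp)
        contigs.append(Contig(cid, "".join(parts), {"lineage": str(truth.lineage_of[cid])}))
    return contigs


# ---------------------------------------------------------------------------
# Host genomes
# ---------------------------------------------------------------------------


def simulate_host_genomes(
    n_genera: int, length: int, seed: int
) -> Dict[str, str]:
    """Compositionally distinct bacterial genomes, one per genus.

    Each genus gets its own dinucleotide transition bias (a Dirichlet draw
    per preceding base), giving k-mer signatures a Markov scorer can tell
    apart. Genomes are labelled genus0..genusN-1.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for g in range(n_genera):
        trans = rng.dirichlet(np.full(4, 0.6), size=4)  # P(next | prev), spiky
        bases = np.empty(length, np.int64)
        bases[0] = rng.integers(0, 4)
        for i in range(1, length):
            bases[i] = rng.choice(4, p=trans[bases[i - 1]])
        out[f"genus{g}"] = "".join("ACGT"[b] for b in bases)
    return out


def sample_phage_from_host(host_genome: str, length: int, seed: int) -> str:
    """A phage-like contig sharing its host's composition: a random slice
    with light point mutation."""
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(host_genome) - length))
    seq = list(host_genome[start : start + length])
    for i in range(len(seq)):
        if rng.random() < 0.05:
            seq[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(seq)
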