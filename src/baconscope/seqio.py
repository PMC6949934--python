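"""Sequence and annotation I/O plus ORF prediction.

Everything downstream of this module works on proteins; this module turns
viral contigs (DNA FASTA) into :class:`Orf` records under the bacterial/
archaeal genetic code (translation table 11), and reads/writes the standard
text formats the pipeline touches: FASTA, Stockholm, GFF3, Newick,
HMMER3-ASCII (read-only) and TSV.

Coordinates are 0-based half-open internally; GFF3 export converts to
1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "Orf",
    "ParseError",
    "translate",
    "predict_orfs",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "write_stockholm",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "write_newick",
    "read_tsv",
    "write_tsv",
    "read_write_formats",
]

# Translation table 11 (bacterial/archaeal). Starts: ATG/GTG/TTG.
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_T11 = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_bases):
    for _j, _b2 in enumerate(_bases):
        for _k, _b3 in enumerate(_bases):
            _T11[_b1 + _b2 + _b3] = _aas[16 * _i + 4 * _j + _k]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; message names the line."""


@dataclass
class Contig:
    """A viral contig: DNA over {A,C,G,T,N} with free-form metadata."""

    id: str
    seq: str
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Orf:
    """A predicted open reading frame on a contig.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand regardless of ``strand``; ``protein`` excludes the stop.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    index_on_contig: int = -1

    @property
    def id(self) -> str:
        return f"{self.contig_id}|orf{self.index_on_contig}"


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate DNA under table 11; terminal stop dropped.

    Codons containing ``N`` are skipped (no ``X`` emitted) so proteins stay
    ambiguity-free for profile scoring. An internal stop raises ``ValueError``
    naming the offending codon position.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    n_codons = len(dna) // 3
    out: List[str] = []
    for i in range(n_codons):
        codon = dna[3 * i : 3 * i + 3]
        if "N" in codon:
            continue  # unresolvable codon: skip, do not emit X
        aa = _T11[codon]
        if aa == "*":
            if i == n_codons - 1:
                break  # terminal stop consumed
            raise ValueError(f"internal stop codon {codon} at codon position {i}")
        out.append(aa)
    return "".join(out)


def _orfs_in_frame(seq: str, frame: int, min_aa_length: int) -> List[tuple]:
    """Maximal ORFs in one forward frame of ``seq``.

    An ORF runs from the first start codon after the preceding stop through
    the next in-frame stop codon (inclusive). Returns (start, end) 0-based
    half-open nucleotide intervals on ``seq``.
    """
    found = []
    pending_start: Optional[int] = None
    i = frame
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if "N" not in codon and _T11[codon] == "*":
            if pending_start is not None:
                n_aa = (i - pending_start) // 3
                if n_aa >= min_aa_length:
                    found.append((pending_start, i + 3))
            pending_start = None
        elif pending_start is None and codon in START_CODONS:
            pending_start = i
        i += 3
    return found


def predict_orfs(contig: Contig, min_aa_length: int = 30) -> List[Orf]:
    """Call maximal ORFs on both strands under translation table 11.

    A simple maximal-ORF caller: start codons ATG/GTG/TTG, stops TAA/TAG/TGA,
    first start after the previous stop, ORFs must end in a stop codon. No
    coding statistics (GC frame bias, RBS) are used. Results are sorted by
    forward-strand start coordinate and ranked into ``index_on_contig``.
    """
    if min_aa_length < 1:
        raise ValueError("min_aa_length must be >= 1")
    seq = contig.seq
    n = len(seq)
    orfs: List[Orf] = []
    for frame in range(3):
        for s, e in _orfs_in_frame(seq, frame, min_aa_length):
            orfs.append(Orf(contig.id, s, e, "+", translate(seq[s:e])))
    rc = reverse_complement(seq)
    for frame in range(3):
        for s, e in _orfs_in_frame(rc, frame, min_aa_length):
            # map back to forward-strand coordinates
            orfs.append(Orf(contig.id, n - e, n - s, "-", translate(rc[s:e])))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    for idx, orf in enumerate(orfs):
        orf.index_on_contig = idx
    return orfs


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_fasta(path) -> List[Contig]:
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: expected FASTA header '>' first")
                break
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(Contig(rec.id, str(rec.seq)))
    return records


def write_fasta(records, path) -> None:
    seqs = [SeqRecord(Seq(r.seq if isinstance(r, Contig) else r[1]),
                      id=r.id if isinstance(r, Contig) else r[0],
                      description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_stockholm(path) -> Dict[str, str]:
    """Read a Stockholm alignment; '.' and '-' gaps both normalised to '-'."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# STOCKHOLM"):
            raise ParseError(f"{path}:1: not a Stockholm file (missing '# STOCKHOLM' header)")
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return {rec.id: str(rec.seq).upper().replace(".", "-") for rec in aln}


def write_stockholm(rows: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(k) for k in rows) + 2
        for name, seq in rows.items():
            fh.write(f"{name:<{width}}{seq}\n")
        fh.write("//\n")


def write_gff3(orfs: List[Orf], contigs: List[Contig], path, hits=None) -> None:
    """Write ORFs as CDS features; optional domain hits as child features.

    ``hits`` maps orf id -> list of (env_start, env_end, bit_score) residue
    intervals; they are projected onto nucleotide coordinates.
    """
    lengths = {c.id: len(c) for c in contigs}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, ln in lengths.items():
            fh.write(f"##sequence-region {cid} 1 {ln}\n")
        for orf in orfs:
            oid = orf.id
            fh.write(
                f"{orf.contig_id}\tbaconscope\tCDS\t{orf.start + 1}\t{orf.end}\t.\t"
                f"{orf.strand}\t0\tID={oid}\n"
            )
            for h in (hits or {}).get(oid, []):
                env_start, env_end, score = h[:3]
                if orf.strand == "+":
                    ns, ne = orf.start + 3 * env_start, orf.start + 3 * env_end
                else:
                    ns, ne = orf.end - 3 * env_end, orf.end - 3 * env_start
                fh.write(
                    f"{orf.contig_id}\tbaconscope\tprotein_domain\t{ns + 1}\t{ne}\t"
                    f"{score:.1f}\t{orf.strand}\t.\tParent={oid}\n"
                )


def read_gff3(path) -> List[dict]:
    """Read a GFF3 file into feature dicts with 0-based half-open coords."""
    path = Path(path)
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, source, ftype, start, end, score, strand, phase, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            feats.append(
                {
                    "seqid": seqid,
                    "type": ftype,
                    "start": start_i - 1,
                    "end": end_i,
                    "score": None if score == "." else float(score),
                    "strand": strand,
                    "attributes": attr_map,
                }
            )
    return feats


def read_newick(path):
    """Read a Newick tree as an skbio TreeNode."""
    from skbio import TreeNode

    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ParseError(f"{path}: {exc}") from exc


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")


def read_tsv(path, **kwargs):
    import pandas as pd

    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


_READERS = {
    "FASTA": read_fasta,
    "Stockholm": read_stockholm,
    "GFF3": read_gff3,
    "Newick": read_newick,
    "TSV": read_tsv,
}


def read_write_formats(path, format: str):
    """Dispatch reading of any supported format by name.

    ``HMMER3-ASCII`` is read-only and returns a :class:`~baconscope.phmm.ProfileHMM`.
    """
    if format == "HMMER3-ASCII":
        from .phmm import read_hmmer3

        return read_hmmer3(path)
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; expected one of "
            f"{sorted(_READERS) + ['HMMER3-ASCII']}"
        ) from None
    return reader(path)
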