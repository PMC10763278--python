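"""Six-frame translation of genome contigs and protein↔genome coordinate maps.

A fragmented, unannotated assembly offers no gene models, so every contig is
translated conceptually in all six reading frames — three offsets on each
strand — with stop codons retained as ``*``.  Motif searches then operate on
these protein strings, and any protein-level span can be mapped back to exact
forward-strand genomic coordinates.

Coordinates are 0-based half-open on the forward genome strand throughout;
strand is carried separately.  Writers that emit GFF3 convert to 1-based
inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Contig",
    "FrameTranslation",
    "InvalidSequenceError",
    "translate_six_frames",
    "map_protein_span",
    "extract_peptide",
    "read_genome_fasta",
    "write_frames_fasta",
]

_VALID_LETTERS = frozenset("ACGTN")


class InvalidSequenceError(ValueError):
    """Raised for empty sequences, non-IUPAC letters or duplicate contig ids."""


@dataclass(frozen=True)
class Contig:
    """A nucleotide sequence record over {A, C, G, T, N} (uppercase)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise InvalidSequenceError(f"contig {self.id!r}: empty sequence")
        bad = set(seq) - _VALID_LETTERS
        if bad:
            raise InvalidSequenceError(
                f"contig {self.id!r}: non-IUPAC letters {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual protein strings of a contig.

    ``offset`` counts the bases skipped at the 5' end of the reading strand
    (the forward strand for ``+`` frames, the reverse complement for ``-``
    frames).  ``residues`` uses the 20 amino-acid letters plus ``*`` for stop
    codons and ``X`` for codons whose N-containing ambiguity does not resolve
    to a single amino acid.  Translation is never split into ORFs.
    """

    contig_id: str
    strand: str  # '+' or '-'
    offset: int  # 0, 1 or 2
    residues: str
    contig_length: int

    @property
    def name(self) -> str:
        return f"{self.contig_id}|{self.strand}{self.offset}"


def _translate(seq: str, offset: int) -> str:
    usable = (len(seq) - offset) // 3
    if usable <= 0:
        return ""
    return str(Seq(seq[offset : offset + 3 * usable]).translate())


def translate_six_frames(contig: Contig) -> list[FrameTranslation]:
    """Translate a contig in all six reading frames.

    Returns the frames in the fixed order (+,0), (+,1), (+,2), (-,0), (-,1),
    (-,2).  Frame ``(-,k)`` reads the reverse complement with ``k`` bases
    skipped at its 5' end, i.e. at the 3' end of the forward strand.
    """
    fwd = contig.sequence
    rev = str(Seq(fwd).reverse_complement())
    frames = []
    for strand, seq in (("+", fwd), ("-", rev)):
        for offset in range(3):
            frames.append(
                FrameTranslation(
                    contig_id=contig.id,
                    strand=strand,
                    offset=offset,
                    residues=_translate(seq, offset),
                    contig_length=contig.length,
                )
            )
    return frames


def map_protein_span(
    frame: FrameTranslation, start: int, end: int
) -> tuple[str, int, int, str]:
    """Map a residue span ``[start, end)`` to forward-strand genomic coordinates.

    Returns ``(contig_id, begin, end, strand)`` with 0-based half-open
    coordinates.  For ``-`` frames the interval is mirrored from the contig's
    3' end.  Extracting the interval, orienting by strand and translating
    reproduces the residue span exactly.
    """
    n = len(frame.residues)
    if not (0 <= start < end <= n):
        raise IndexError(
            f"residue span [{start}, {end}) out of range for frame of {n} residues"
        )
    if frame.strand == "+":
        begin = frame.offset + 3 * start
        stop = frame.offset + 3 * end
    else:
        stop = frame.contig_length - frame.offset - 3 * start
        begin = frame.contig_length - frame.offset - 3 * end
    return frame.contig_id, begin, stop, frame.strand


def extract_peptide(contig: Contig, begin: int, end: int, strand: str) -> str:
    """Translate the genomic interval ``[begin, end)`` oriented by strand."""
    chunk = contig.sequence[begin:end]
    if strand == "-":
        chunk = str(Seq(chunk).reverse_complement())
    return str(Seq(chunk).translate()) if chunk else ""


def read_genome_fasta(path) -> list[Contig]:
    """Read a (possibly multi-record, wrapped) nucleotide FASTA file."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InvalidSequenceError(f"duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, sequence=str(rec.seq)))
    if not contigs:
        raise InvalidSequenceError(f"no FASTA records found in {path}")
    return contigs


def write_frames_fasta(frames: list[FrameTranslation], path) -> None:
    """Write frame translations as FASTA with ``<contig>|<strand><offset>`` headers."""
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f">{frame.name}\n")
            res = frame.residues
            for i in range(0, len(res), 60):
                fh.write(res[i : i + 60] + "\n")
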