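"""Seeded synthetic plant genomes with implanted family genes and decoys.

The simulator emulates the gene architectures that determine detectability:
coding sequences with canonical GT..AG introns, genes on both strands, the
two-motif bait span falling in one, two or three exons, pseudogenes with a
premature stop between the motifs, single-motif and wrong-orientation decoys,
and contig fragmentation.  Every implanted element is recorded in a ground
truth manifest together with its expected detectability per method:

* one-exon baits — found by both the exact two-motif scan and the expanded
  consensus search;
* two-exon baits (intron between the motifs) — found only by the expanded
  search, as a pair of hits;
* three-exon baits — found by neither: the introns are placed inside the
  anchor motifs, so no exon carries an intact anchor;
* pseudogenes — expanded search only (the scan suppresses spans with an
  internal stop by default); the resulting locus is flagged;
* decoys — found by neither method.

Background sequence is i.i.d. nucleotide noise at a configurable GC fraction
(default 0.44, typical of plant genomes); no repeat structure or assembly-gap
N runs are modelled.  Identical spec + seed reproduces the genome and
manifest byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .adjudicate import DEFAULT_MAX_GAP
from .consensus import ConsensusQuery
from .families import get_family
from .frames import Contig
from .motifs import AA20, MotifSpec

__all__ = [
    "SyntheticSpec",
    "TruthRecord",
    "TruthManifest",
    "SpecError",
    "build_gene_model",
    "simulate_genome",
    "write_genome_fasta",
    "write_manifest",
    "read_manifest",
]

CLS_ONE_EXON = "one_exon"
CLS_TWO_EXON = "two_exon"
CLS_THREE_EXON = "three_exon"
CLS_PSEUDOGENE = "pseudogene"
CLS_SINGLE_MOTIF = "single_motif_decoy"
CLS_WRONG_ORDER = "wrong_order_decoy"

# (expected_detect_two_motif, expected_detect_expanded) per element class
_EXPECTATIONS = {
    CLS_ONE_EXON: (True, True),
    CLS_TWO_EXON: (False, True),
    CLS_THREE_EXON: (False, False),
    CLS_PSEUDOGENE: (False, True),
    CLS_SINGLE_MOTIF: (False, False),
    CLS_WRONG_ORDER: (False, False),
}


class SpecError(ValueError):
    """Raised for invalid simulation specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic genome.

    Element counts follow the exon-distribution bookkeeping of the reference
    inventories (baits present in one, two or three exons) plus the decoy
    classes; defaults mirror the best-characterised reference family row
    (11 family genes: 8 one-exon + 3 two-exon baits) with one single-motif
    and one wrong-orientation decoy per strand-policy draw.
    """

    family: str = "P3A"
    n_one_exon: int = 8
    n_two_exon: int = 3
    n_three_exon: int = 0
    n_pseudogene: int = 0
    n_single_motif: int = 2
    n_wrong_order: int = 2
    strand_policy: str = "both"  # both | plus | minus
    intron_length: tuple[int, int] = (300, 2000)
    background_length: int = 5_000_000
    gc: float = 0.44
    target_contig_size: int | None = 200_000
    breakpoints: tuple[int, ...] | None = None  # explicit cuts; may cut genes
    pad_residues: int = 40
    min_spacer: int = 2 * DEFAULT_MAX_GAP + 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_one_exon, self.n_two_exon, self.n_three_exon,
            self.n_pseudogene, self.n_single_motif, self.n_wrong_order,
        )
        if any(n < 0 for n in counts):
            raise SpecError("element counts must be >= 0")
        lo, hi = self.intron_length
        if lo < 20 or hi < lo:
            raise SpecError("intron length range must be >= 20 bp and ordered")
        if not 0 < self.gc < 1:
            raise SpecError("gc must be in (0, 1)")
        if self.strand_policy not in ("both", "plus", "minus"):
            raise SpecError(f"unknown strand policy {self.strand_policy!r}")

    @property
    def n_elements(self) -> int:
        return (
            self.n_one_exon + self.n_two_exon + self.n_three_exon
            + self.n_pseudogene + self.n_single_motif + self.n_wrong_order
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted element (contig-local coordinates)."""

    element_id: str
    cls: str
    contig: str
    start: int
    end: int
    strand: str
    bait_exons: tuple[tuple[int, int], ...]  # bait-span pieces, forward coords
    expected_detect_two_motif: bool
    expected_detect_expanded: bool
    contig_edge: bool = False

    @property
    def n_bait_exons(self) -> int:
        return len(self.bait_exons)


@dataclass(frozen=True)
class TruthManifest:
    records: tuple[TruthRecord, ...]

    def by_class(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.cls] = counts.get(rec.cls, 0) + 1
        return counts

    def expected_counts(self) -> tuple[int, int]:
        """(two_motif, expanded) expected locus counts over intact elements."""
        two = sum(
            1 for r in self.records
            if r.expected_detect_two_motif and not r.contig_edge
        )
        exp = sum(
            1 for r in self.records
            if r.expected_detect_expanded and not r.contig_edge
        )
        return two, exp


# --- codon machinery -------------------------------------------------------

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    if set(_codon) <= set("ACGT"):
        _CODONS_FOR.setdefault(_aa, []).append(_codon)
_CODONS_FOR["*"] = sorted(standard_dna_table.stop_codons)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _random_peptide(
    rng: np.random.Generator, n: int, forbidden: list[MotifSpec]
) -> str:
    """Random residues containing no occurrence of any forbidden motif."""
    letters = list(AA20)
    for _ in range(100):
        pep = "".join(rng.choice(letters, size=n)) if n else ""
        if all(not m.find_all(pep) for m in forbidden):
            return pep
    raise SpecError("could not draw a motif-free random peptide")


def build_gene_model(
    protein_template: str,
    intron_insertions: list[tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]]]:
    """Reverse-translate a protein template into a gene with introns.

    Codons are drawn uniformly among synonymous choices; ``*`` in the
    template becomes a stop codon.  Each intron — given as ``(codon_index,
    length)`` with the index strictly inside the coding sequence — is
    inserted at that codon boundary and begins ``GT`` / ends ``AG``.
    Returns the gene string and the exon map (gene-local intervals);
    concatenating the exons and translating reproduces the template.
    """
    n = len(protein_template)
    cds = "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein_template)
    introns = sorted(intron_insertions)
    for idx, length in introns:
        if not 0 < idx < n:
            raise SpecError(f"intron codon index {idx} not inside the CDS")
        if length < 4:
            raise SpecError(f"intron of {length} bp cannot hold GT..AG")
    parts: list[str] = []
    exon_map: list[tuple[int, int]] = []
    pos = 0  # gene coordinate
    prev = 0  # codon index
    for idx, length in introns:
        exon = cds[3 * prev : 3 * idx]
        parts.append(exon)
        exon_map.append((pos, pos + len(exon)))
        pos += len(exon)
        interior = _random_dna(rng, length - 4, 0.4)
        parts.append("GT" + interior + "AG")
        pos += length
        prev = idx
    exon = cds[3 * prev :]
    parts.append(exon)
    exon_map.append((pos, pos + len(exon)))
    return "".join(parts), exon_map


def _codon_to_gene(introns: list[tuple[int, int]], codon_idx: int) -> int:
    """Gene coordinate of the start of a codon, accounting for introns."""
    return 3 * codon_idx + sum(L for idx, L in introns if idx <= codon_idx)


@dataclass
class _Element:
    cls: str
    gene: str
    strand: str
    bait_codon_range: tuple[int, int]
    introns: list[tuple[int, int]]

    def bait_pieces(self) -> list[tuple[int, int]]:
        """Gene-local nt intervals of the bait span, one per bait exon."""
        b0, b1 = self.bait_codon_range
        cuts = [b0] + [i for i, _ in sorted(self.introns) if b0 < i < b1] + [b1]
        pieces = []
        for lo, hi in zip(cuts, cuts[1:]):
            start = _codon_to_gene(self.introns, lo)
            end = 3 * hi + sum(L for i, L in self.introns if i < hi)
            pieces.append((start, end))
        return pieces


def _make_elements(
    spec: SyntheticSpec, bait: ConsensusQuery, rng: np.random.Generator
) -> list[_Element]:
    us, ue = bait.upstream_anchor
    ds, de = bait.downstream_anchor
    blen = len(bait.residues)
    pad = spec.pad_residues
    fams = [get_family(spec.family).upstream, get_family(spec.family).downstream]

    def strand() -> str:
        if spec.strand_policy == "plus":
            return "+"
        if spec.strand_policy == "minus":
            return "-"
        return "+" if rng.integers(2) == 0 else "-"

    def intron_len() -> int:
        lo, hi = spec.intron_length
        return int(rng.integers(lo, hi + 1))

    def gene_element(cls: str) -> _Element:
        template = (
            _random_peptide(rng, pad, fams)
            + bait.residues
            + _random_peptide(rng, pad, fams)
        )
        b0, b1 = pad, pad + blen
        introns: list[tuple[int, int]] = []
        if cls == CLS_ONE_EXON or cls == CLS_PSEUDOGENE:
            # an intron in the 5' pad: the gene is spliced, the bait is not
            introns = [(pad // 2, intron_len())]
        elif cls == CLS_TWO_EXON:
            margin = 6
            lo = max(b0 + ue + margin, b0 + 25)
            hi = min(b0 + ds - margin, b1 - 25)
            split = int(rng.integers(lo, hi + 1)) if hi >= lo else b0 + (ue + ds) // 2
            introns = [(split, intron_len())]
        elif cls == CLS_THREE_EXON:
            # split both anchor motifs across exon junctions: no exon keeps
            # an intact anchor, which is what defeats both search modes
            introns = [(b0 + us + 1, intron_len()), (b0 + ds + 2, intron_len())]
        if cls == CLS_PSEUDOGENE:
            stop_at = b0 + (ue + ds) // 2
            template = template[:stop_at] + "*" + template[stop_at + 1 :]
        gene, _ = build_gene_model(template, introns, rng)
        return _Element(cls, gene, strand(), (b0, b1), introns)

    def decoy_element(cls: str) -> _Element:
        ctx = 12
        if cls == CLS_SINGLE_MOTIF:
            core = bait.residues[: ue + 10]
        else:  # wrong order: DKTGT segment first, family-motif segment after
            down_seg = bait.residues[max(0, ds - ctx) : min(blen, de + ctx)]
            up_seg = bait.residues[max(0, us - ctx) : min(blen, ue + ctx)]
            spacer = _random_peptide(rng, ds - ue, fams)
            core = down_seg + spacer + up_seg
        template = (
            _random_peptide(rng, pad, fams) + core + _random_peptide(rng, pad, fams)
        )
        gene, _ = build_gene_model(template, [], rng)
        return _Element(cls, gene, strand(), (pad, pad + len(core)), [])

    elements: list[_Element] = []
    for cls, count in (
        (CLS_ONE_EXON, spec.n_one_exon),
        (CLS_TWO_EXON, spec.n_two_exon),
        (CLS_THREE_EXON, spec.n_three_exon),
        (CLS_PSEUDOGENE, spec.n_pseudogene),
    ):
        elements.extend(gene_element(cls) for _ in range(count))
    for cls, count in (
        (CLS_SINGLE_MOTIF, spec.n_single_motif),
        (CLS_WRONG_ORDER, spec.n_wrong_order),
    ):
        elements.extend(decoy_element(cls) for _ in range(count))
    order = rng.permutation(len(elements))
    return [elements[i] for i in order]


def simulate_genome(spec: SyntheticSpec) -> tuple[list[Contig], TruthManifest]:
    """Generate a fragmented synthetic genome plus its ground-truth manifest.

    Elements are placed non-overlapping, separated by random intergenic
    spacers totalling ``spec.background_length``; fragmentation happens after
    placement.  With ``target_contig_size`` set, cuts fall at intergenic
    spacer midpoints, so no element is broken; explicit ``breakpoints`` may
    cut elements, which are then marked ``contig_edge`` in the manifest.
    """
    rng = np.random.default_rng(spec.seed)
    bait = get_family(spec.family).consensus_query()
    elements = _make_elements(spec, bait, rng)
    n = len(elements)

    extra = spec.background_length - (n + 1) * spec.min_spacer if n else 0
    if n and extra < 0:
        raise SpecError(
            f"background of {spec.background_length} bp too short for {n} "
            f"elements at min spacer {spec.min_spacer} bp"
        )
    if n:
        shares = rng.multinomial(extra, [1.0 / (n + 1)] * (n + 1))
        spacers = [spec.min_spacer + int(s) for s in shares]
    else:
        spacers = [spec.background_length]

    parts: list[str] = []
    pos = 0
    spans: list[tuple[int, int]] = []  # global element spans
    midpoints: list[int] = []  # candidate intergenic cut points
    for i, elem in enumerate(elements + [None]):
        spacer = _random_dna(rng, spacers[i], spec.gc)
        midpoints.append(pos + spacers[i] // 2)
        parts.append(spacer)
        pos += spacers[i]
        if elem is None:
            break
        seq = elem.gene if elem.strand == "+" else _reverse_complement(elem.gene)
        spans.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    genome = "".join(parts)

    if spec.breakpoints is not None:
        cuts = sorted(b for b in spec.breakpoints if 0 < b < len(genome))
    elif spec.target_contig_size:
        cuts = []
        last = 0
        for m in midpoints:
            if m - last >= spec.target_contig_size:
                cuts.append(m)
                last = m
    else:
        cuts = []
    bounds = [0] + cuts + [len(genome)]
    contigs = [
        Contig(id=f"contig_{i + 1:04d}", sequence=genome[lo:hi])
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
        if hi > lo
    ]

    def locate(gpos: int) -> tuple[int, int]:
        """(contig index, local coordinate) of a global position."""
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            if lo <= gpos < hi:
                return i, gpos - lo
        return len(bounds) - 2, gpos - bounds[-2]

    records = []
    for i, (elem, (g0, g1)) in enumerate(zip(elements, spans)):
        ci0, local0 = locate(g0)
        ci1, _ = locate(g1 - 1)
        cut = ci0 != ci1
        glen = len(elem.gene)
        pieces = []
        for p0, p1 in elem.bait_pieces():
            if elem.strand == "+":
                a, b = g0 + p0, g0 + p1
            else:
                a, b = g0 + glen - p1, g0 + glen - p0
            pieces.append((a - bounds[ci0], b - bounds[ci0]))
        pieces.sort()
        expect_two, expect_exp = _EXPECTATIONS[elem.cls]
        records.append(
            TruthRecord(
                element_id=f"elem_{i + 1:03d}",
                cls=elem.cls,
                contig=contigs[ci0].id if contigs else "",
                start=local0,
                end=local0 + glen,
                strand=elem.strand,
                bait_exons=tuple(pieces),
                expected_detect_two_motif=expect_two and not cut,
                expected_detect_expanded=expect_exp and not cut,
                contig_edge=cut,
            )
        )
    return contigs, TruthManifest(tuple(records))


def write_genome_fasta(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, contig.length, 70):
                fh.write(contig.sequence[i : i + 70] + "\n")


_MANIFEST_COLS = [
    "element_id", "class", "contig", "start", "end", "strand", "bait_exons",
    "expect_two_motif", "expect_expanded", "contig_edge",
]


def write_manifest(manifest: TruthManifest, path) -> None:
    """Tab-separated ground truth, one record per element."""
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for r in manifest.records:
            exons = ";".join(f"{a}-{b}" for a, b in r.bait_exons)
            fh.write(
                "\t".join(
                    [
                        r.element_id, r.cls, r.contig, str(r.start), str(r.end),
                        r.strand, exons,
                        str(int(r.expected_detect_two_motif)),
                        str(int(r.expected_detect_expanded)),
                        str(int(r.contig_edge)),
                    ]
                )
                + "\n"
            )


def read_manifest(path) -> TruthManifest:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == _MANIFEST_COLS, f"unexpected manifest header {header}"
        for line in fh:
            (eid, cls, contig, start, end, strand, exons, two, exp, edge
             ) = line.rstrip("\n").split("\t")
            pieces = tuple(
                tuple(int(x) for x in piece.split("-"))
                for piece in exons.split(";")
                if piece
            )
            records.append(
                TruthRecord(
                    element_id=eid, cls=cls, contig=contig, start=int(start),
                    end=int(end), strand=strand, bait_exons=pieces,
                    expected_detect_two_motif=bool(int(two)),
                    expected_detect_expanded=bool(int(exp)),
                    contig_edge=bool(int(edge)),
                )
            )
    return TruthManifest(tuple(records))
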