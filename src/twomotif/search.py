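"""Searching six-frame translations with two-motif or consensus-bait queries.

Two search modes are provided:

* :func:`scan_two_motif` — an exact scan for the family motif followed by the
  DKTGT anchor at a fixed residue spacing (± tolerance).  Fast and specific,
  but blind to occurrences where an intron falls between the motifs.
* :func:`local_align_search` — Smith–Waterman local alignment of a consensus
  bait (BLOSUM62, affine gaps, BLAST-style E-value reporting).  When the bait
  span is interrupted by an intron, the two exon pieces surface as separate
  hits — usually in different reading frames of the same strand — each
  covering one anchor; the adjudicator pairs them back into one locus.

Both report :class:`Hit` records carrying exact forward-strand genomic
coordinates obtained through :func:`twomotif.frames.map_protein_span`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from skbio.alignment import pair_align
from skbio.sequence import Protein

from .consensus import ConsensusQuery
from .frames import FrameTranslation, map_protein_span
from .motifs import TwoMotifQuery

__all__ = [
    "Hit",
    "ScoringParams",
    "ConfigError",
    "scan_two_motif",
    "local_align_search",
    "score_threshold",
    "write_hits_tsv",
]

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"


class ConfigError(ValueError):
    """Raised for degenerate scoring parameters."""


@dataclass(frozen=True)
class ScoringParams:
    """Scoring for the consensus-bait local alignment search.

    Defaults are BLASTP-style: BLOSUM62 with affine gap penalties (open 11,
    extend 1) and an E-value reporting threshold of 1e-3, suited to ~60-mer
    baits.  ``karlin_lambda``/``karlin_k`` are the standard gapped BLOSUM62
    (11,1) Karlin–Altschul parameters used to convert raw scores into
    E-values against the whole translated genome.  A hit is reportable only
    if it covers at least one anchor motif with at most
    ``anchor_max_mismatch`` mismatches inside the anchor.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    e_threshold: float = 1e-3
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    anchor_max_mismatch: int = 1
    chunk_size: int = 50_000
    max_hits_per_chunk: int = 50

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ConfigError("gap penalties must be positive")
        if self.e_threshold <= 0:
            raise ConfigError("E-value threshold must be positive")


@dataclass(frozen=True)
class Hit:
    """One match of a query against one reading frame.

    ``score`` is the alignment score for consensus hits and the number of
    matched residues for exact scan hits; ``evalue`` is None for scan hits.
    ``anchors_covered`` names the anchor motifs lying inside the aligned
    region; scan hits always cover both.
    """

    contig_id: str
    strand: str
    offset: int
    prot_start: int
    prot_end: int
    g_start: int
    g_end: int
    peptide: str
    score: float
    evalue: float | None = None
    anchors_covered: frozenset = field(default_factory=frozenset)
    query_span: tuple[int, int] | None = None

    @property
    def span_bp(self) -> int:
        return self.g_end - self.g_start


def _sort_key(hit: Hit):
    return (hit.contig_id, hit.g_start, hit.g_end, hit.strand, hit.offset)


def scan_two_motif(
    frames: list[FrameTranslation],
    query: TwoMotifQuery,
    allow_internal_stop: bool = False,
) -> list[Hit]:
    """Exact scan for upstream motif + spacing ± tolerance + downstream motif.

    By default a candidate whose inter-motif span contains a stop codon is
    suppressed; pass ``allow_internal_stop=True`` to keep such spans (e.g.
    for pseudogene discovery).
    """
    hits: list[Hit] = []
    for frame in frames:
        residues = frame.residues
        if not residues:
            continue
        ups = query.upstream.find_all(residues)
        downs = query.downstream.find_all(residues)
        down_ends: dict[int, list[int]] = {}
        for d_start, d_end in downs:
            down_ends.setdefault(d_start, []).append(d_end)
        for u_start, u_end in ups:
            for gap in range(
                query.spacing - query.tolerance, query.spacing + query.tolerance + 1
            ):
                if gap < 0:
                    continue
                d_start = u_end + gap
                for d_end in down_ends.get(d_start, ()):
                    between = residues[u_end:d_start]
                    if "*" in between and not allow_internal_stop:
                        continue
                    contig_id, g_start, g_end, strand = map_protein_span(
                        frame, u_start, d_end
                    )
                    hits.append(
                        Hit(
                            contig_id=contig_id,
                            strand=strand,
                            offset=frame.offset,
                            prot_start=u_start,
                            prot_end=d_end,
                            g_start=g_start,
                            g_end=g_end,
                            peptide=residues[u_start:d_end],
                            score=float(d_end - u_start),
                            evalue=None,
                            anchors_covered=frozenset({UPSTREAM, DOWNSTREAM}),
                            query_span=None,
                        )
                    )
    return sorted(hits, key=_sort_key)


def score_threshold(params: ScoringParams, query_len: int, db_residues: int) -> float:
    """Smallest raw score whose E-value is at or below the reporting threshold.

    Inverts E = K·m·n·exp(−λ·S).
    """
    if query_len <= 0 or db_residues <= 0:
        raise ConfigError("query and database must be non-empty")
    return (
        math.log(params.karlin_k * query_len * db_residues)
        - math.log(params.e_threshold)
    ) / params.karlin_lambda


def _evalue(params: ScoringParams, score: float, query_len: int, db_n: int) -> float:
    return params.karlin_k * query_len * db_n * math.exp(-params.karlin_lambda * score)


def _anchor_mismatches(
    qa: str, ta: str, q_start: int, anchor: tuple[int, int]
) -> int | None:
    """Mismatches (incl. gaps) within an anchor interval of an aligned pair.

    ``qa``/``ta`` are the aligned query/target strings, ``q_start`` the query
    index of the first aligned column.  Returns None when the alignment does
    not fully cover the anchor.
    """
    a_start, a_end = anchor
    q_idx = q_start
    mismatches = 0
    covered = 0
    for qc, tc in zip(qa, ta):
        if qc != "-" and a_start <= q_idx < a_end:
            covered += 1
            if tc == "-" or qc.upper() != tc.upper():
                mismatches += 1
        if qc != "-":
            q_idx += 1
    if covered < a_end - a_start:
        return None
    return mismatches


def _chunk_hits(
    frame: FrameTranslation,
    chunk_start: int,
    chunk: str,
    q_prot: Protein,
    query: ConsensusQuery,
    params: ScoringParams,
    threshold: float,
    db_n: int,
) -> list[Hit]:
    """Iteratively align the bait against one chunk, masking each reported
    alignment, until the best remaining score falls below threshold."""
    out: list[Hit] = []
    work = list(chunk)
    m = len(query.residues)
    for _ in range(params.max_hits_per_chunk):
        t_prot = Protein("".join(work))
        res = pair_align(
            q_prot,
            t_prot,
            mode="local",
            sub_score=params.matrix,
            gap_cost=(params.gap_open, params.gap_extend),
        )
        if not res.paths or res.score < threshold:
            break
        (q0, q1), (t0, t1) = (tuple(r) for r in res.paths[0].ranges)
        qa, ta = res.paths[0].to_aligned((q_prot, t_prot))
        anchors = set()
        for name, interval in (
            (UPSTREAM, query.upstream_anchor),
            (DOWNSTREAM, query.downstream_anchor),
        ):
            mism = _anchor_mismatches(qa, ta, q0, interval)
            if mism is not None and mism <= params.anchor_max_mismatch:
                anchors.add(name)
        abs_t0, abs_t1 = chunk_start + t0, chunk_start + t1
        if anchors and t1 > t0:
            contig_id, g_start, g_end, strand = map_protein_span(
                frame, abs_t0, abs_t1
            )
            out.append(
                Hit(
                    contig_id=contig_id,
                    strand=strand,
                    offset=frame.offset,
                    prot_start=abs_t0,
                    prot_end=abs_t1,
                    g_start=g_start,
                    g_end=g_end,
                    peptide=frame.residues[abs_t0:abs_t1],
                    score=float(res.score),
                    evalue=_evalue(params, res.score, m, db_n),
                    anchors_covered=frozenset(anchors),
                    query_span=(q0, q1),
                )
            )
        # mask the aligned region so further occurrences can surface
        for i in range(t0, max(t1, t0 + 1)):
            work[i] = "*"
    return out


def local_align_search(
    frames: list[FrameTranslation],
    query: ConsensusQuery,
    params: ScoringParams | None = None,
) -> list[Hit]:
    """Local-alignment search of a consensus bait across all frames.

    Frames are processed in overlapping chunks; within each chunk, optimal
    local alignments are reported and masked iteratively, so several
    occurrences (or the two exon pieces of an intron-split occurrence) all
    surface.  Hits are deduplicated across chunk overlaps and sorted by
    contig then genomic start.
    """
    params = params or ScoringParams()
    if not query.residues:
        raise ConfigError("empty consensus query")
    m = len(query.residues)
    db_n = sum(len(f.residues) for f in frames)
    if db_n == 0:
        return []
    threshold = score_threshold(params, m, db_n)
    q_prot = Protein(query.residues)
    overlap = 2 * m
    step = max(params.chunk_size - overlap, overlap)

    best: dict[tuple, Hit] = {}
    for frame in frames:
        residues = frame.residues
        if not residues:
            continue
        start = 0
        while True:
            chunk = residues[start : start + params.chunk_size]
            for hit in _chunk_hits(
                frame, start, chunk, q_prot, query, params, threshold, db_n
            ):
                key = (hit.contig_id, hit.strand, hit.offset, hit.prot_start, hit.prot_end)
                if key not in best or hit.score > best[key].score:
                    best[key] = hit
            if start + params.chunk_size >= len(residues):
                break
            start += step

    # a hit truncated at a chunk boundary reappears complete in the next,
    # overlapping chunk; keep only the best-scoring of overlapping hits
    # within each frame
    by_frame: dict[tuple, list[Hit]] = {}
    for hit in best.values():
        by_frame.setdefault((hit.contig_id, hit.strand, hit.offset), []).append(hit)
    kept: list[Hit] = []
    for group in by_frame.values():
        group.sort(key=lambda h: -h.score)
        chosen: list[Hit] = []
        for hit in group:
            if all(
                hit.prot_end <= other.prot_start or hit.prot_start >= other.prot_end
                for other in chosen
            ):
                chosen.append(hit)
        kept.extend(chosen)
    return sorted(kept, key=_sort_key)


def write_hits_tsv(hits: list[Hit], path) -> None:
    """Write hits as TSV (genomic span shown 1-based inclusive)."""
    cols = [
        "contig",
        "strand",
        "frame_offset",
        "prot_start",
        "prot_end",
        "g_start_1based",
        "g_end",
        "score",
        "evalue",
        "anchors",
        "peptide",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.contig_id,
                        h.strand,
                        str(h.offset),
                        str(h.prot_start),
                        str(h.prot_end),
                        str(h.g_start + 1),
                        str(h.g_end),
                        f"{h.score:g}",
                        "NA" if h.evalue is None else f"{h.evalue:.3g}",
                        ",".join(sorted(h.anchors_covered)),
                        h.peptide,
                    ]
                )
                + "\n"
            )
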