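"""Adjudication of raw hits into candidate family-member loci.

A reported hit only becomes a family member after inspection of orientation
and distance: a single hit covering both anchor motifs is a locus outright; a
pair of same-contig, same-strand hits, each covering a different anchor, in
correct protein orientation along the genome and within a distance cap, is an
intron-split locus; anything else — wrong orientation, excessive distance,
unpaired single-anchor hits away from contig edges — is rejected with an
explicit reason so the manual-inspection step stays auditable.

Near-identical loci (possible collapsed repeats or tandem duplicates) are
flagged rather than merged: automatic collapsing would hide true tandem
duplicates, while flags leave the judgment call to the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from .frames import Contig
from .search import DOWNSTREAM, UPSTREAM, Hit

__all__ = [
    "LocusCall",
    "Rejection",
    "InventoryReport",
    "SINGLE_SPAN",
    "INTRON_SPLIT_PAIR",
    "PARTIAL",
    "pair_and_classify",
    "flag_near_duplicates",
    "count_inventory",
    "write_gff3",
    "write_summary_tsv",
]

SINGLE_SPAN = "single_span"
INTRON_SPLIT_PAIR = "intron_split_pair"
PARTIAL = "partial"  # one anchor found, partner likely beyond the contig edge

FLAG_STOP = "contains_stop"
FLAG_DUP = "near_identical_duplicate"
FLAG_EDGE = "contig_edge"

DEFAULT_MAX_GAP = 15_000  # bp; plant introns are rarely longer


@dataclass(frozen=True)
class LocusCall:
    """An adjudicated candidate family-member locus."""

    contig_id: str
    strand: str
    g_start: int
    g_end: int
    family: str
    support: str  # SINGLE_SPAN, INTRON_SPLIT_PAIR or PARTIAL
    hits: tuple[Hit, ...]
    flags: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class Rejection:
    """A hit group that failed adjudication, with the reason."""

    hits: tuple[Hit, ...]
    reason: str


@dataclass(frozen=True)
class InventoryReport:
    """Per-family and per-support-class locus counts with full provenance.

    As the P2A and P2B family motifs coincide, any families whose names start
    with ``P2`` are additionally reported merged under the key ``P2``.
    Partial (contig-edge) calls are tallied separately and never contribute
    to family counts.
    """

    family_counts: dict[str, int]
    support_counts: dict[str, int]
    calls: tuple[LocusCall, ...]
    rejections: tuple[Rejection, ...]


@dataclass
class _Unit:
    """Overlap-merged hits from one strand of one contig."""

    g_start: int
    g_end: int
    hits: list[Hit]

    @property
    def anchors(self) -> frozenset:
        out: set = set()
        for h in self.hits:
            out |= h.anchors_covered
        return frozenset(out)


def _merge_units(hits: list[Hit]) -> list[_Unit]:
    """Merge hits overlapping by >= 1 bp on the same strand into units."""
    units: list[_Unit] = []
    for hit in sorted(hits, key=lambda h: (h.g_start, h.g_end)):
        if units and hit.g_start < units[-1].g_end:
            units[-1].g_end = max(units[-1].g_end, hit.g_end)
            units[-1].hits.append(hit)
        else:
            units.append(_Unit(hit.g_start, hit.g_end, [hit]))
    return units


def _unit_flags(unit: _Unit) -> set:
    return {FLAG_STOP} if any("*" in h.peptide for h in unit.hits) else set()


def _call(units: list[_Unit], contig: str, strand: str, family: str, support: str,
          extra_flags: set = frozenset()) -> LocusCall:
    hits = tuple(h for u in units for h in u.hits)
    flags: set = set(extra_flags)
    for u in units:
        flags |= _unit_flags(u)
    return LocusCall(
        contig_id=contig,
        strand=strand,
        g_start=min(u.g_start for u in units),
        g_end=max(u.g_end for u in units),
        family=family,
        support=support,
        hits=hits,
        flags=frozenset(flags),
    )


def _pair_group(
    units: list[_Unit],
    contig: str,
    strand: str,
    family: str,
    max_gap: int,
    contig_length: int | None,
    calls: list[LocusCall],
    rejections: list[Rejection],
) -> None:
    """Adjudicate the units of one (contig, strand) group."""
    singles: list[_Unit] = []
    for unit in units:
        anchors = unit.anchors
        if UPSTREAM in anchors and DOWNSTREAM in anchors:
            calls.append(_call([unit], contig, strand, family, SINGLE_SPAN))
        else:
            singles.append(unit)

    # walk in protein orientation: 5'→3' of the coding strand
    ordered = sorted(singles, key=lambda u: u.g_start, reverse=(strand == "-"))

    def genomic_gap(first: _Unit, second: _Unit) -> int:
        if strand == "+":
            return second.g_start - first.g_end
        return first.g_start - second.g_end

    pending: list[_Unit] = []  # upstream-anchor units awaiting a partner
    leftovers: list[tuple[str, _Unit]] = []
    for unit in ordered:
        if unit.anchors == frozenset({UPSTREAM}):
            pending.append(unit)
        elif unit.anchors == frozenset({DOWNSTREAM}):
            mate = None
            for cand in reversed(pending):  # nearest preceding upstream unit
                if 0 <= genomic_gap(cand, unit) <= max_gap:
                    mate = cand
                    break
            if mate is not None:
                pending.remove(mate)
                calls.append(
                    _call([mate, unit], contig, strand, family, INTRON_SPLIT_PAIR)
                )
            else:
                leftovers.append((DOWNSTREAM, unit))
        else:  # no anchors recorded; cannot adjudicate
            rejections.append(
                Rejection(tuple(unit.hits), "hit covers no anchor motif")
            )
    leftovers.extend((UPSTREAM, u) for u in pending)

    # wrong-orientation pairs (downstream anchor 5' of upstream anchor) and
    # correct-orientation pairs that exceed the distance cap
    leftovers.sort(key=lambda kv: kv[1].g_start, reverse=(strand == "-"))
    used = [False] * len(leftovers)
    for i, (kind_i, u_i) in enumerate(leftovers):
        if used[i] or kind_i != DOWNSTREAM:
            continue
        for j, (kind_j, u_j) in enumerate(leftovers):
            if used[j] or kind_j != UPSTREAM or j == i:
                continue
            gap_wrong = genomic_gap(u_i, u_j)  # downstream before upstream
            gap_far = genomic_gap(u_j, u_i)
            if 0 <= gap_wrong <= max_gap:
                rejections.append(
                    Rejection(
                        tuple(u_i.hits + u_j.hits),
                        "wrong orientation: downstream anchor precedes upstream "
                        "anchor in protein order",
                    )
                )
                used[i] = used[j] = True
                break
            if gap_far > max_gap:
                rejections.append(
                    Rejection(
                        tuple(u_j.hits + u_i.hits),
                        f"motif pair {gap_far} bp apart exceeds max_gap={max_gap}",
                    )
                )
                used[i] = used[j] = True
                break

    for flag, (kind, unit) in zip(used, leftovers):
        if flag:
            continue
        # distance from the unit to the contig edge on the side where the
        # missing anchor would lie (downstream anchor is 3'-ward in protein
        # orientation, upstream anchor 5'-ward)
        if contig_length is not None:
            if (kind == UPSTREAM) == (strand == "+"):
                edge = contig_length - unit.g_end
            else:
                edge = unit.g_start
            if edge <= max_gap:
                calls.append(
                    _call([unit], contig, strand, family, PARTIAL, {FLAG_EDGE})
                )
                continue
        rejections.append(
            Rejection(
                tuple(unit.hits),
                f"unpaired hit covering only the {kind} anchor",
            )
        )


def pair_and_classify(
    hits: list[Hit],
    max_gap: int = DEFAULT_MAX_GAP,
    family: str = "",
    contig_lengths: dict[str, int] | None = None,
) -> tuple[list[LocusCall], list[Rejection]]:
    """Apply orientation, proximity and intron-split pairing to raw hits.

    Every input hit ends up in exactly one :class:`LocusCall` or one
    :class:`Rejection`.  When ``contig_lengths`` is given, single-anchor hits
    whose missing partner would fall within ``max_gap`` of the contig edge
    become ``partial`` calls flagged ``contig_edge`` (the fragmented-assembly
    case) instead of rejections.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    calls: list[LocusCall] = []
    rejections: list[Rejection] = []
    groups: dict[tuple[str, str], list[Hit]] = {}
    for hit in hits:
        groups.setdefault((hit.contig_id, hit.strand), []).append(hit)
    for (contig, strand) in sorted(groups):
        units = _merge_units(groups[(contig, strand)])
        length = contig_lengths.get(contig) if contig_lengths else None
        _pair_group(
            units, contig, strand, family, max_gap, length, calls, rejections
        )
    calls.sort(key=lambda c: (c.contig_id, c.g_start, c.strand))
    return calls, rejections


def flag_near_duplicates(
    calls: list[LocusCall],
    contigs: dict[str, Contig],
    max_gap: int = DEFAULT_MAX_GAP,
    min_identity: float = 0.99,
) -> list[LocusCall]:
    """Flag pairs of nearby loci whose spans are near-identical copies.

    Both loci of a same-contig pair within ``max_gap`` of each other whose
    nucleotide identity is at least ``min_identity`` receive the
    ``near_identical_duplicate`` flag; none is removed.
    """
    flagged = set()
    for i, a in enumerate(calls):
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if a.contig_id != b.contig_id:
                continue
            gap = max(b.g_start - a.g_end, a.g_start - b.g_end, 0)
            if gap > max_gap:
                continue
            seq_a = contigs[a.contig_id].sequence[a.g_start : a.g_end]
            seq_b = contigs[b.contig_id].sequence[b.g_start : b.g_end]
            if not seq_a or not seq_b:
                continue
            dist = edlib.align(seq_a, seq_b, task="distance")["editDistance"]
            if 1 - dist / max(len(seq_a), len(seq_b)) >= min_identity:
                flagged.update({i, j})
    return [
        replace(c, flags=c.flags | {FLAG_DUP}) if i in flagged else c
        for i, c in enumerate(calls)
    ]


def count_inventory(
    calls: list[LocusCall], rejections: list[Rejection] = ()
) -> InventoryReport:
    """Tally adjudicated loci per family and per support class.

    Loci flagged ``contains_stop`` are counted like any other — the approach
    cannot distinguish true genes from pseudogenes, so they stay in the count
    but keep their flag.  Partial (contig-edge) calls are never counted as
    family members.
    """
    family_counts: dict[str, int] = {}
    support_counts = {SINGLE_SPAN: 0, INTRON_SPLIT_PAIR: 0, PARTIAL: 0}
    for call in calls:
        support_counts[call.support] += 1
        if call.support == PARTIAL:
            continue
        family_counts[call.family] = family_counts.get(call.family, 0) + 1
    p2 = sum(n for fam, n in family_counts.items() if fam.startswith("P2"))
    if p2:
        family_counts["P2"] = p2
    return InventoryReport(
        family_counts=family_counts,
        support_counts=support_counts,
        calls=tuple(calls),
        rejections=tuple(rejections),
    )


def _gff3_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(calls: list[LocusCall], path) -> None:
    """Write locus calls as GFF3 ``protein_match`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, call in enumerate(calls, start=1):
            attrs = (
                f"ID=locus{i:04d};family={_gff3_escape(call.family or 'NA')};"
                f"support={call.support};flags={','.join(sorted(call.flags)) or 'none'};"
                f"n_hits={len(call.hits)}"
            )
            score = max((h.score for h in call.hits), default=0.0)
            fh.write(
                "\t".join(
                    [
                        call.contig_id,
                        "twomotif",
                        "protein_match",
                        str(call.g_start + 1),
                        str(call.g_end),
                        f"{score:g}",
                        call.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_summary_tsv(report: InventoryReport, path) -> None:
    """Per-family summary: n_loci, n_single_span, n_split, n_partial, n_flagged."""
    rows: dict[str, dict[str, int]] = {}
    for call in report.calls:
        row = rows.setdefault(
            call.family or "NA",
            {"n_loci": 0, "n_single_span": 0, "n_split": 0, "n_partial": 0,
             "n_flagged": 0},
        )
        if call.support == SINGLE_SPAN:
            row["n_loci"] += 1
            row["n_single_span"] += 1
        elif call.support == INTRON_SPLIT_PAIR:
            row["n_loci"] += 1
            row["n_split"] += 1
        else:
            row["n_partial"] += 1
        if call.flags:
            row["n_flagged"] += 1
    with open(path, "w") as fh:
        fh.write("family\tn_loci\tn_single_span\tn_split\tn_partial\tn_flagged\n")
        for fam in sorted(rows):
            r = rows[fam]
            fh.write(
                f"{fam}\t{r['n_loci']}\t{r['n_single_span']}\t{r['n_split']}\t"
                f"{r['n_partial']}\t{r['n_flagged']}\n"
            )
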