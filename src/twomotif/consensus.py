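"""Consensus-bait construction from a family protein alignment.

The expanded search replaces the bare motif pair with a short consensus
window: the majority-rule consensus of an aligned family protein set, taken
from just before the family motif to just after DKTGT plus a configurable
flank on each outer side.  For the P-type ATPase families these windows come
out at roughly 55-70 residues.  To score a genome without training on it, the
organism under test can be rotated out of the alignment before the consensus
is formed.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass

from Bio import SeqIO

from .motifs import MotifSpec, _ordered_occurrence

__all__ = [
    "AlignedRecord",
    "ProteinAlignment",
    "ConsensusQuery",
    "AnchorError",
    "InsufficientDataError",
    "DEFAULT_FLANK",
    "locate_anchor_columns",
    "build_consensus_query",
    "read_alignment_fasta",
    "write_query_fasta",
]

DEFAULT_FLANK = 8  # residues kept outside each anchor; gives 55-70-mer baits


class AnchorError(ValueError):
    """Raised when no anchor placement is supported by a majority of rows."""


class InsufficientDataError(ValueError):
    """Raised when fewer than two rows remain after organism exclusion."""


@dataclass(frozen=True)
class AlignedRecord:
    seq_id: str
    organism: str
    aligned: str  # residues plus '-' gaps


@dataclass(frozen=True)
class ProteinAlignment:
    """An aligned family protein set; all rows equal length, >= 2 rows."""

    records: tuple[AlignedRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise InsufficientDataError("alignment needs at least 2 rows")
        lengths = {len(r.aligned) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")

    @property
    def columns(self) -> int:
        return len(self.records[0].aligned)

    def without_organism(self, organism: str) -> "ProteinAlignment":
        kept = tuple(r for r in self.records if r.organism != organism)
        if len(kept) < 2:
            raise InsufficientDataError(
                f"excluding {organism!r} leaves {len(kept)} row(s)"
            )
        return ProteinAlignment(kept)


@dataclass(frozen=True)
class ConsensusQuery:
    """An ungapped consensus bait with the anchor motif positions recorded."""

    family: str
    residues: str
    upstream_anchor: tuple[int, int]  # residue interval within `residues`
    downstream_anchor: tuple[int, int]
    flank: int
    excluded_organism: str | None = None

    def __post_init__(self) -> None:
        us, ue = self.upstream_anchor
        ds, de = self.downstream_anchor
        if not (0 <= us < ue <= ds < de <= len(self.residues)):
            raise ValueError("anchors must be present, ordered and in range")

    def __len__(self) -> int:
        return len(self.residues)


def _row_anchor_columns(
    record: AlignedRecord, upstream: MotifSpec, downstream: MotifSpec
) -> tuple[tuple[int, ...], tuple[int, ...]] | None:
    """Alignment columns holding each anchor residue in one row, or None."""
    cols = [i for i, c in enumerate(record.aligned) if c != "-"]
    ungapped = record.aligned.replace("-", "").upper()
    occ = _ordered_occurrence(ungapped, upstream, downstream)
    if occ is None:
        return None
    (us, ue), (ds, de) = occ
    return tuple(cols[us:ue]), tuple(cols[ds:de])


def locate_anchor_columns(
    alignment: ProteinAlignment, upstream: MotifSpec, downstream: MotifSpec
) -> tuple[tuple[int, ...], tuple[int, ...], list[str]]:
    """Anchor columns supported by most rows, plus the non-conforming rows.

    Returns ``(upstream_columns, downstream_columns, outlier_seq_ids)``.
    Raises :class:`AnchorError` unless one placement is supported by more than
    half of the rows.
    """
    votes: Counter = Counter()
    placements: dict[str, tuple | None] = {}
    for rec in alignment.records:
        placement = _row_anchor_columns(rec, upstream, downstream)
        placements[rec.seq_id] = placement
        if placement is not None:
            votes[placement] += 1
    if not votes:
        raise AnchorError("no row contains both motifs in order")
    placement, support = votes.most_common(1)[0]
    if support * 2 <= len(alignment.records):
        raise AnchorError(
            f"best anchor placement supported by only {support} of "
            f"{len(alignment.records)} rows"
        )
    outliers = [sid for sid, p in placements.items() if p != placement]
    return placement[0], placement[1], outliers


def build_consensus_query(
    alignment: ProteinAlignment,
    upstream: MotifSpec,
    downstream: MotifSpec,
    flank: int = DEFAULT_FLANK,
    exclude_organism: str | None = None,
    family: str = "",
) -> ConsensusQuery:
    """Majority-rule consensus over the window spanning both anchors.

    Per column within ``[upstream start - flank, downstream end + flank]`` the
    consensus residue is the most frequent non-gap residue (ties broken
    alphabetically); columns that are gap in more than half of the rows are
    dropped.  Anchor intervals are recomputed on the ungapped consensus.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if exclude_organism is not None:
        alignment = alignment.without_organism(exclude_organism)
    up_cols, down_cols, _ = locate_anchor_columns(alignment, upstream, downstream)
    lo = max(0, up_cols[0] - flank)
    hi = min(alignment.columns, down_cols[-1] + 1 + flank)

    n_rows = len(alignment.records)
    residues: list[str] = []
    col_of_residue: list[int] = []
    for col in range(lo, hi):
        column = [r.aligned[col].upper() for r in alignment.records]
        counts = Counter(c for c in column if c != "-")
        n_gaps = n_rows - sum(counts.values())
        if n_gaps * 2 > n_rows:
            continue
        best = max(counts.values())
        residues.append(min(c for c, n in counts.items() if n == best))
        col_of_residue.append(col)

    pos = {col: i for i, col in enumerate(col_of_residue)}
    try:
        up_anchor = (pos[up_cols[0]], pos[up_cols[-1]] + 1)
        down_anchor = (pos[down_cols[0]], pos[down_cols[-1]] + 1)
    except KeyError as exc:  # pragma: no cover - excluded by majority support
        raise AnchorError(f"anchor column {exc} dropped as gap-majority") from exc
    return ConsensusQuery(
        family=family,
        residues="".join(residues),
        upstream_anchor=up_anchor,
        downstream_anchor=down_anchor,
        flank=flank,
        excluded_organism=exclude_organism,
    )


_ORGANISM_RE = re.compile(r"organism=(\S+)")


def read_alignment_fasta(path) -> ProteinAlignment:
    """Read an aligned FASTA; organism tags from an ``organism=...`` header field.

    Records lacking the tag fall back to their sequence id as organism.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _ORGANISM_RE.search(rec.description)
        organism = m.group(1) if m else rec.id
        records.append(
            AlignedRecord(seq_id=rec.id, organism=organism, aligned=str(rec.seq))
        )
    return ProteinAlignment(tuple(records))


def write_query_fasta(query: ConsensusQuery, path, sidecar: bool = True) -> None:
    """Write the bait as single-record FASTA plus a JSON metadata sidecar."""
    name = query.family or "consensus"
    with open(path, "w") as fh:
        fh.write(f">{name}_bait\n{query.residues}\n")
    if sidecar:
        meta = {
            "family": query.family,
            "length": len(query.residues),
            "upstream_anchor": list(query.upstream_anchor),
            "downstream_anchor": list(query.downstream_anchor),
            "flank": query.flank,
            "excluded_organism": query.excluded_organism,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)
            fh.write("\n")
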