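"""Family motif patterns and fixed-spacing two-motif queries.

Every P-type ATPase carries the invariant DKTGT phosphorylation-site motif;
each family additionally has a short diagnostic motif upstream of it (P1B:
CPC/SPC, P2A/B: PEXL, P3A: PIA, P4: PIS, P5: PPXXP).  A two-motif query is
the pair of motifs plus the number of residues strictly between them; hits
require both motifs in order at that spacing (± a small tolerance).

Pattern syntax: the 20 amino-acid letters, ``X`` as a single-residue wildcard
and ``/`` separating alternatives.  A wildcard matches any residue (including
``X`` in the target) but never a stop; a literal letter matches only itself,
so an ``X`` produced by an ambiguous codon never satisfies a literal.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "AA20",
    "MotifSpec",
    "TwoMotifQuery",
    "SpacingResult",
    "MotifParseError",
    "ReferenceSpacingError",
    "parse_motif_spec",
    "derive_spacing",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_WILDCARD_CLASS = "[" + AA20 + "X]"


class MotifParseError(ValueError):
    """Raised for motif patterns with characters outside the amino-acid alphabet."""


class ReferenceSpacingError(ValueError):
    """Raised when a reference protein lacks an ordered occurrence of both motifs."""


@dataclass(frozen=True)
class MotifSpec:
    """A short degenerate amino-acid pattern, possibly with alternatives."""

    alternatives: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise MotifParseError("motif has no alternatives")
        for alt in self.alternatives:
            if not alt:
                raise MotifParseError("empty motif alternative")
            bad = set(alt) - set(AA20 + "X")
            if bad:
                raise MotifParseError(
                    f"illegal characters {sorted(bad)!r} in motif {alt!r}"
                )

    def render(self) -> str:
        return "/".join(self.alternatives)

    def _regex(self) -> re.Pattern:
        parts = []
        for alt in self.alternatives:
            parts.append("".join(_WILDCARD_CLASS if c == "X" else c for c in alt))
        # lookahead so overlapping occurrences are all reported
        return re.compile("(?=(" + "|".join(parts) + "))")

    def find_all(self, residues: str) -> list[tuple[int, int]]:
        """All (start, end) occurrences in a residue string, in order."""
        hits = []
        for m in self._regex().finditer(residues):
            hits.append((m.start(), m.start() + len(m.group(1))))
        return hits


def parse_motif_spec(text: str) -> MotifSpec:
    """Parse a pattern like ``"CPC/SPC"`` or ``"PPXXP"`` (case-insensitive)."""
    if not text:
        raise MotifParseError("empty motif pattern")
    return MotifSpec(tuple(part.upper() for part in text.split("/")))


@dataclass(frozen=True)
class TwoMotifQuery:
    """Family motif + DKTGT motif + fixed spacing (residues strictly between).

    ``tolerance`` is the allowed deviation of the spacing; the flexible-search
    variant used to catch every P4 member corresponds to ``tolerance=1``.
    """

    family: str
    upstream: MotifSpec
    downstream: MotifSpec
    spacing: int
    tolerance: int = 0

    def __post_init__(self) -> None:
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class SpacingResult:
    """Modal motif spacing plus the full distribution over references."""

    spacing: int
    distribution: dict[int, int] = field(hash=False)


def _ordered_occurrence(
    residues: str, upstream: MotifSpec, downstream: MotifSpec
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """The adjudicated (upstream, downstream) occurrence pair, or None.

    Of the downstream occurrences preceded by at least one upstream
    occurrence, the first is used; of the candidate upstream occurrences, the
    one closest upstream of it is used (the family motif sits in transmembrane
    helix four, immediately preceding the P domain).
    """
    ups = upstream.find_all(residues)
    downs = downstream.find_all(residues)
    for d_start, d_end in downs:
        before = [(s, e) for s, e in ups if e <= d_start]
        if before:
            up = max(before, key=lambda se: se[1])
            return up, (d_start, d_end)
    return None


def derive_spacing(
    reference_proteins,
    upstream: MotifSpec,
    downstream: MotifSpec,
) -> SpacingResult:
    """Modal residue count strictly between the two motifs over references.

    ``reference_proteins`` is a sequence of amino-acid strings or of
    ``(id, string)`` pairs.  Ties in the mode are broken toward the smaller
    spacing.  A reference lacking an ordered occurrence of both motifs raises
    :class:`ReferenceSpacingError` naming the sequence.
    """
    spacings: Counter[int] = Counter()
    for i, ref in enumerate(reference_proteins):
        if isinstance(ref, tuple):
            name, seq = ref
        else:
            name, seq = f"reference[{i}]", ref
        occ = _ordered_occurrence(seq.upper(), upstream, downstream)
        if occ is None:
            raise ReferenceSpacingError(
                f"{name}: no in-order occurrence of {upstream.render()} "
                f"before {downstream.render()}"
            )
        (u_start, u_end), (d_start, d_end) = occ
        spacings[d_start - u_end] += 1
    if not spacings:
        raise ReferenceSpacingError("no reference proteins given")
    best = max(spacings.values())
    mode = min(s for s, c in spacings.items() if c == best)
    return SpacingResult(spacing=mode, distribution=dict(sorted(spacings.items())))
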