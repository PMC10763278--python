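"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from twomotif.frames import Contig, FrameTranslation
from twomotif.motifs import MotifSpec, TwoMotifQuery

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# --- independent genetic-code oracle ---------------------------------------
# Standard code spelled out by TCAG-order index, independently of Biopython.
_BASES = "TCAG"
_AA_BY_INDEX = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_ORACLE = {
    a + b + c: _AA_BY_INDEX[16 * _BASES.index(a) + 4 * _BASES.index(b) + _BASES.index(c)]
    for a in _BASES
    for b in _BASES
    for c in _BASES
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def oracle_translate_codon(codon: str) -> str:
    """Translate one codon; N resolved only if all substitutions agree."""
    if "N" not in codon:
        return CODON_ORACLE[codon]
    options = {""}
    for base in codon:
        repl = "ACGT" if base == "N" else base
        options = {prefix + b for prefix in options for b in repl}
    aas = {CODON_ORACLE[c] for c in options}
    return aas.pop() if len(aas) == 1 else "X"


def oracle_translate(seq: str, offset: int) -> str:
    usable = (len(seq) - offset) // 3
    return "".join(
        oracle_translate_codon(seq[offset + 3 * i : offset + 3 * i + 3])
        for i in range(max(usable, 0))
    )


def oracle_six_frames(seq: str) -> dict[tuple[str, int], str]:
    rc = revcomp(seq)
    return {
        (strand, offset): oracle_translate(s, offset)
        for strand, s in (("+", seq), ("-", rc))
        for offset in range(3)
    }


# --- naive two-motif enumeration oracle ------------------------------------

def _matches_at(residues: str, pattern: str, pos: int) -> bool:
    if pos + len(pattern) > len(residues):
        return False
    for pat, res in zip(pattern, residues[pos : pos + len(pattern)]):
        if pat == "X":
            if res == "*":
                return False
        elif res != pat:
            return False
    return True


def oracle_scan(
    residues: str, query: TwoMotifQuery, allow_internal_stop: bool = False
) -> list[tuple[int, int]]:
    """Try every start position; return (start, end) residue spans of hits."""
    spans = []
    for i in range(len(residues)):
        for up in query.upstream.alternatives:
            if not _matches_at(residues, up, i):
                continue
            u_end = i + len(up)
            for gap in range(
                query.spacing - query.tolerance, query.spacing + query.tolerance + 1
            ):
                if gap < 0:
                    continue
                for down in query.downstream.alternatives:
                    if not _matches_at(residues, down, u_end + gap):
                        continue
                    if "*" in residues[u_end : u_end + gap] and not allow_internal_stop:
                        continue
                    spans.append((i, u_end + gap + len(down)))
    return sorted(set(spans))


# --- misc helpers ----------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, with_n: bool = False) -> str:
    letters = list("ACGTN") if with_n else list("ACGT")
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(letters, size=n, p=probs))


def make_frame(residues: str, strand: str = "+", offset: int = 0) -> FrameTranslation:
    """A standalone frame whose coordinates are self-consistent."""
    return FrameTranslation(
        contig_id="synthetic",
        strand=strand,
        offset=offset,
        residues=residues,
        contig_length=offset + 3 * len(residues),
    )


@pytest.fixture(scope="session")
def p3a():
    from twomotif.families import get_family

    return get_family("P3A")


@pytest.fixture(scope="session")
def p3a_bait(p3a):
    return p3a.consensus_query()


def simple_motif(text: str) -> MotifSpec:
    from twomotif.motifs import parse_motif_spec

    return parse_motif_spec(text)
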