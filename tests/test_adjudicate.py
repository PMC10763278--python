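"""Hit adjudication: orientation, pairing, deduplication and counting."""

import numpy as np
import pytest

from twomotif.adjudicate import (
    FLAG_DUP,
    FLAG_EDGE,
    FLAG_STOP,
    INTRON_SPLIT_PAIR,
    PARTIAL,
    SINGLE_SPAN,
    count_inventory,
    flag_near_duplicates,
    pair_and_classify,
    write_gff3,
)
from twomotif.frames import Contig
from twomotif.search import DOWNSTREAM, UPSTREAM, Hit

BOTH = frozenset({UPSTREAM, DOWNSTREAM})
UP = frozenset({UPSTREAM})
DOWN = frozenset({DOWNSTREAM})


def mk_hit(contig="c1", strand="+", g_start=1000, g_end=1200, anchors=BOTH,
           peptide="PIAMMDKTGT", offset=0, score=100.0):
    return Hit(
        contig_id=contig, strand=strand, offset=offset,
        prot_start=g_start // 3, prot_end=g_end // 3,
        g_start=g_start, g_end=g_end, peptide=peptide,
        score=score, evalue=1e-10, anchors_covered=anchors,
    )


class TestPairing:
    def test_single_hit_both_anchors(self):
        calls, rejections = pair_and_classify([mk_hit()])
        assert len(calls) == 1 and not rejections
        assert calls[0].support == SINGLE_SPAN
        assert calls[0].flags == frozenset()

    def test_intron_split_pair_plus_strand(self):
        up = mk_hit(g_start=1000, g_end=1100, anchors=UP)
        down = mk_hit(g_start=1900, g_end=2000, anchors=DOWN)
        calls, rejections = pair_and_classify([up, down])
        assert [c.support for c in calls] == [INTRON_SPLIT_PAIR]
        assert (calls[0].g_start, calls[0].g_end) == (1000, 2000)
        assert not rejections

    def test_intron_split_pair_minus_strand(self):
        # on the minus strand the upstream anchor lies 3'-ward in fwd coords
        up = mk_hit(strand="-", g_start=1900, g_end=2000, anchors=UP)
        down = mk_hit(strand="-", g_start=1000, g_end=1100, anchors=DOWN)
        calls, rejections = pair_and_classify([up, down])
        assert [c.support for c in calls] == [INTRON_SPLIT_PAIR]
        assert not rejections

    def test_wrong_orientation_rejected(self):
        down = mk_hit(g_start=1000, g_end=1100, anchors=DOWN)
        up = mk_hit(g_start=1900, g_end=2000, anchors=UP)
        calls, rejections = pair_and_classify([down, up])
        assert calls == []
        assert len(rejections) == 1
        assert "wrong orientation" in rejections[0].reason
        assert len(rejections[0].hits) == 2

    def test_distant_pair_rejected(self):
        up = mk_hit(g_start=1000, g_end=1100, anchors=UP)
        down = mk_hit(g_start=40_000, g_end=40_100, anchors=DOWN)
        calls, rejections = pair_and_classify([up, down], max_gap=15_000)
        assert calls == []
        assert len(rejections) == 1
        assert "exceeds max_gap" in rejections[0].reason

    def test_two_adjacent_genes_paired_in_order(self):
        hits = [
            mk_hit(g_start=1000, g_end=1100, anchors=UP),
            mk_hit(g_start=2000, g_end=2100, anchors=DOWN),
            mk_hit(g_start=6000, g_end=6100, anchors=UP),
            mk_hit(g_start=7000, g_end=7100, anchors=DOWN),
        ]
        calls, rejections = pair_and_classify(hits, max_gap=15_000)
        spans = sorted((c.g_start, c.g_end) for c in calls)
        assert spans == [(1000, 2100), (6000, 7100)]
        assert not rejections

    def test_overlapping_frames_merged_into_one_locus(self):
        a = mk_hit(g_start=1000, g_end=1200, anchors=UP, offset=0)
        b = mk_hit(g_start=1150, g_end=1350, anchors=DOWN, offset=2)
        calls, rejections = pair_and_classify([a, b])
        assert len(calls) == 1 and not rejections
        assert calls[0].support == SINGLE_SPAN  # merged unit has both anchors
        assert len(calls[0].hits) == 2

    def test_unpaired_hit_near_contig_edge_is_partial(self):
        # upstream-anchor hit on + strand: partner expected 3'-ward,
        # but the contig ends 2 kb later
        hit = mk_hit(g_start=1000, g_end=1100, anchors=UP)
        calls, rejections = pair_and_classify(
            [hit], contig_lengths={"c1": 3000}
        )
        assert [c.support for c in calls] == [PARTIAL]
        assert FLAG_EDGE in calls[0].flags
        assert not rejections

    def test_unpaired_hit_far_from_edge_rejected(self):
        hit = mk_hit(g_start=50_000, g_end=50_100, anchors=UP)
        calls, rejections = pair_and_classify(
            [hit], contig_lengths={"c1": 200_000}
        )
        assert calls == []
        assert "unpaired" in rejections[0].reason

    def test_stop_in_peptide_flags_locus(self):
        calls, _ = pair_and_classify([mk_hit(peptide="PIAM*MDKTGT")])
        assert FLAG_STOP in calls[0].flags

    def test_every_hit_lands_exactly_once(self):
        rng = np.random.default_rng(0)
        hits = []
        for i in range(40):
            start = int(rng.integers(0, 500_000))
            anchors = (BOTH, UP, DOWN)[int(rng.integers(3))]
            hits.append(
                mk_hit(
                    contig=f"c{int(rng.integers(3))}",
                    strand="+-"[int(rng.integers(2))],
                    g_start=start,
                    g_end=start + int(rng.integers(50, 400)),
                    anchors=anchors,
                )
            )
        calls, rejections = pair_and_classify(hits, contig_lengths=None)
        placed = [h for c in calls for h in c.hits] + [
            h for r in rejections for h in r.hits
        ]
        assert len(placed) == len(hits)
        assert {id(h) for h in placed} == {id(h) for h in hits}

    def test_counts_invariant_under_hit_order(self):
        hits = [
            mk_hit(g_start=1000, g_end=1100, anchors=UP),
            mk_hit(g_start=2000, g_end=2100, anchors=DOWN),
            mk_hit(g_start=9000, g_end=9300, anchors=BOTH),
        ]
        rng = np.random.default_rng(1)
        baseline = None
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            calls, _ = pair_and_classify(perm, family="P3A")
            counts = count_inventory(calls).family_counts
            baseline = baseline or counts
            assert counts == baseline
        assert baseline == {"P3A": 2}

    def test_invalid_max_gap(self):
        with pytest.raises(ValueError):
            pair_and_classify([], max_gap=0)


class TestCounting:
    def test_empty_calls_all_zero(self):
        report = count_inventory([])
        assert report.family_counts == {}
        assert all(v == 0 for v in report.support_counts.values())

    def test_p2_families_merged(self):
        hits = [
            mk_hit(g_start=1000 + 5000 * i, g_end=1200 + 5000 * i)
            for i in range(11)
        ]
        calls = []
        for i, hit in enumerate(hits):
            family = "P2A" if i < 10 else "P2B"
            got, _ = pair_and_classify([hit], family=family)
            calls.extend(got)
        counts = count_inventory(calls).family_counts
        assert counts["P2A"] == 10 and counts["P2B"] == 1
        assert counts["P2"] == 11

    def test_partials_not_counted_as_members(self):
        up = mk_hit(g_start=1000, g_end=1100, anchors=UP)
        calls, _ = pair_and_classify(
            [up], family="P3A", contig_lengths={"c1": 2000}
        )
        report = count_inventory(calls)
        assert report.family_counts == {}
        assert report.support_counts[PARTIAL] == 1

    def test_stop_flagged_loci_still_counted(self):
        calls, _ = pair_and_classify(
            [mk_hit(peptide="PIA*DKTGT")], family="P3A"
        )
        report = count_inventory(calls)
        assert report.family_counts == {"P3A": 1}


class TestDuplicates:
    def test_near_identical_copies_both_flagged(self):
        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(list("ACGT"), size=600))
        contig = Contig("c1", unit + "TTTTAAAACCCC" + unit + "G" * 400)
        calls = []
        for start in (0, 612):
            got, _ = pair_and_classify(
                [mk_hit(g_start=start, g_end=start + 600)], family="P3A"
            )
            calls.extend(got)
        flagged = flag_near_duplicates(calls, {"c1": contig})
        assert all(FLAG_DUP in c.flags for c in flagged)
        report = count_inventory(flagged)
        assert report.family_counts == {"P3A": 2}  # flagged, never collapsed

    def test_dissimilar_neighbours_not_flagged(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        contig = Contig("c1", seq)
        calls = []
        for start in (0, 1000):
            got, _ = pair_and_classify(
                [mk_hit(g_start=start, g_end=start + 600)], family="P3A"
            )
            calls.extend(got)
        flagged = flag_near_duplicates(calls, {"c1": contig})
        assert all(FLAG_DUP not in c.flags for c in flagged)


def test_gff3_output_format(tmp_path):
    calls, _ = pair_and_classify([mk_hit()], family="P3A")
    path = tmp_path / "loci.gff3"
    write_gff3(calls, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    fields = lines[1].split("\t")
    assert fields[2] == "protein_match"
    assert int(fields[3]) == 1001  # 1-based inclusive start
    assert int(fields[4]) == 1200
    assert "family=P3A" in fields[8]
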