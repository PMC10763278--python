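"""Two-motif scanning and consensus-bait local alignment."""

import numpy as np
import pytest
from skbio.alignment import pair_align
from skbio.sequence import Protein

from twomotif.frames import Contig, translate_six_frames
from twomotif.motifs import TwoMotifQuery, parse_motif_spec
from twomotif.search import (
    DOWNSTREAM,
    UPSTREAM,
    ConfigError,
    ScoringParams,
    local_align_search,
    scan_two_motif,
    score_threshold,
)

from conftest import make_frame, oracle_scan, random_dna

PIA = parse_motif_spec("PIA")
DKTGT = parse_motif_spec("DKTGT")
AA_POOL = list("ACDEFGHIKLMNQRSTVWY")  # no P, avoids accidental motifs


def query(spacing=40, tolerance=0):
    return TwoMotifQuery(
        family="P3A", upstream=PIA, downstream=DKTGT,
        spacing=spacing, tolerance=tolerance,
    )


def residue_noise(rng, n):
    return "".join(rng.choice(AA_POOL, size=n))


class TestScanTwoMotif:
    def test_constructed_match_found_once(self):
        rng = np.random.default_rng(1)
        frame = make_frame(
            residue_noise(rng, 20) + "PIA" + residue_noise(rng, 40) + "DKTGT"
            + residue_noise(rng, 20)
        )
        hits = scan_two_motif([frame], query())
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.prot_start, hit.prot_end) == (20, 68)
        assert (hit.g_start, hit.g_end) == (60, 204)
        assert hit.anchors_covered == {UPSTREAM, DOWNSTREAM}

    def test_spacing_tolerance(self):
        rng = np.random.default_rng(2)
        frame = make_frame(
            residue_noise(rng, 10) + "PIA" + residue_noise(rng, 40) + "DKTGT"
        )
        assert scan_two_motif([frame], query(spacing=41)) == []
        assert len(scan_two_motif([frame], query(spacing=41, tolerance=1))) == 1

    def test_wrong_order_not_matched(self):
        rng = np.random.default_rng(3)
        frame = make_frame(
            residue_noise(rng, 10) + "DKTGT" + residue_noise(rng, 40) + "PIA"
        )
        assert scan_two_motif([frame], query()) == []

    def test_internal_stop_suppressed_by_default(self):
        rng = np.random.default_rng(4)
        between = residue_noise(rng, 18) + "*" + residue_noise(rng, 21)
        frame = make_frame("PIA" + between + "DKTGT")
        assert scan_two_motif([frame], query()) == []
        kept = scan_two_motif([frame], query(), allow_internal_stop=True)
        assert len(kept) == 1
        assert "*" in kept[0].peptide

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_enumeration_oracle(self, seed):
        """Exact agreement with brute-force enumeration on small genomes."""
        rng = np.random.default_rng(seed)
        q = query(spacing=15, tolerance=1)
        # DNA background salted with in-frame implants so hits exist
        implant = "CCAATTGCT" + random_dna(rng, 45) + "GATAAAACTGGTACT"
        pieces = [random_dna(rng, 600), implant, random_dna(rng, 500),
                  implant, random_dna(rng, 400)]
        contig = Contig("c", "".join(pieces))
        frames = translate_six_frames(contig)
        hits = scan_two_motif(frames, q, allow_internal_stop=True)
        got = {
            (h.strand, h.offset, h.prot_start, h.prot_end) for h in hits
        }
        expected = set()
        for frame in frames:
            for start, end in oracle_scan(frame.residues, q, True):
                expected.add((frame.strand, frame.offset, start, end))
        assert got == expected

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(7)
        implant = "CCAATTGCT" + random_dna(rng, 120) + "GATAAAACTGGTACT"
        seq = random_dna(rng, 300) + implant + random_dna(rng, 300)
        rc = str(
            seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        )
        q = query(spacing=40)
        fwd = scan_two_motif(translate_six_frames(Contig("c", seq)), q, True)
        rev = scan_two_motif(translate_six_frames(Contig("c", rc)), q, True)
        assert len(fwd) == len(rev) == 1
        L = len(seq)
        assert {(L - h.g_end, L - h.g_start) for h in rev} == {
            (h.g_start, h.g_end) for h in fwd
        }
        assert {h.strand for h in fwd} != {h.strand for h in rev}


class TestLocalAlignSearch:
    def test_verbatim_bait_scores_self_alignment(self, p3a_bait):
        rng = np.random.default_rng(11)
        frame = make_frame(
            residue_noise(rng, 100) + p3a_bait.residues + residue_noise(rng, 100)
        )
        hits = local_align_search([frame], p3a_bait)
        assert len(hits) == 1
        hit = hits[0]
        self_score = pair_align(
            Protein(p3a_bait.residues), Protein(p3a_bait.residues),
            mode="local", sub_score="BLOSUM62", gap_cost=(11, 1),
        ).score
        assert hit.score == self_score
        assert hit.anchors_covered == {UPSTREAM, DOWNSTREAM}
        assert (hit.prot_start, hit.prot_end) == (100, 100 + len(p3a_bait))
        assert hit.evalue < 1e-20

    def test_interrupted_bait_yields_one_hit_per_half(self, p3a_bait):
        rng = np.random.default_rng(12)
        split = 32
        frame = make_frame(
            residue_noise(rng, 60) + p3a_bait.residues[:split]
            + residue_noise(rng, 170) + p3a_bait.residues[split:]
            + residue_noise(rng, 60)
        )
        hits = local_align_search([frame], p3a_bait)
        assert len(hits) == 2
        anchors = sorted(tuple(sorted(h.anchors_covered)) for h in hits)
        assert anchors == [(DOWNSTREAM,), (UPSTREAM,)]

    def test_anchorless_similarity_not_reported(self, p3a_bait):
        """A strong alignment that covers no intact anchor is filtered."""
        rng = np.random.default_rng(13)
        a0, a1 = p3a_bait.upstream_anchor[0], p3a_bait.downstream_anchor[1]
        middle = p3a_bait.residues[p3a_bait.upstream_anchor[1] + 2 :
                                   p3a_bait.downstream_anchor[0] - 2]
        frame = make_frame(
            residue_noise(rng, 50) + middle + residue_noise(rng, 50)
        )
        assert a1 - a0 > len(middle)  # sanity: middle excludes both anchors
        assert local_align_search([frame], p3a_bait) == []

    def test_empirical_null_on_random_background(self, p3a_bait):
        """Random 50 kb genomes essentially never produce a reportable hit."""
        clean = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            contig = Contig("null", random_dna(rng, 50_000))
            hits = local_align_search(translate_six_frames(contig), p3a_bait)
            clean += not hits
        assert clean >= 0.95 * n_seeds

    def test_degenerate_scoring_rejected(self):
        with pytest.raises(ConfigError):
            ScoringParams(gap_open=0)
        with pytest.raises(ConfigError):
            ScoringParams(gap_extend=-1)
        with pytest.raises(ConfigError):
            ScoringParams(e_threshold=0)

    def test_threshold_monotone_in_database_size(self):
        params = ScoringParams()
        assert score_threshold(params, 60, 10_000_000) > score_threshold(
            params, 60, 100_000
        )

    def test_hits_sorted_by_contig_then_start(self, p3a_bait):
        rng = np.random.default_rng(14)
        bait = p3a_bait.residues
        frames = []
        for cid in ("b", "a"):
            res = (residue_noise(rng, 30) + bait + residue_noise(rng, 200)
                   + bait + residue_noise(rng, 30))
            frame = make_frame(res)
            frames.append(
                type(frame)(
                    contig_id=cid, strand="+", offset=0,
                    residues=res, contig_length=3 * len(res),
                )
            )
        hits = local_align_search(frames, p3a_bait)
        keys = [(h.contig_id, h.g_start) for h in hits]
        assert keys == sorted(keys)
        assert len(hits) == 4
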