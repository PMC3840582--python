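"""Genome mapping vs brute force, folding, hairpin excision/evaluation
and the dominance curation step."""

import numpy as np
import pytest

from bolmir.core import PipelineConfig, revcomp, rna
from bolmir.novel import (
    GenomicHit,
    HairpinCandidate,
    dominance_filter,
    evaluate_hairpin,
    excise_candidates,
    fold,
    map_tags,
)


def brute_force_hits(tag, references, max_mismatch):
    """Independent oracle: scan every offset on both strands."""
    out = set()
    tag = rna(tag)
    for rid, ref in references.items():
        ref = rna(ref)
        for strand in "+-":
            q = tag if strand == "+" else revcomp(tag)
            for s in range(len(ref) - len(tag) + 1):
                mism = sum(1 for a, b in zip(q, ref[s : s + len(tag)]) if a != b)
                if mism <= max_mismatch:
                    out.add((rid, s, s + len(tag), strand, mism))
    return out


class TestMapTags:
    def test_exact_hit_coordinates(self):
        ref = "G" * 100 + "UGAAGCUGCCAGCAUGAUCUA" + "C" * 100
        hits = map_tags(["UGAAGCUGCCAGCAUGAUCUA"], {"c1": ref}, max_mismatch=0)
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd[0].start == 100 and fwd[0].end == 121 and fwd[0].edits == 0

    def test_one_mismatch_only_in_genome_mode(self):
        ref = "G" * 50 + "UGAAGCUGCCAGCAUGAUCUA" + "C" * 50
        tag = "UGAAGCUGCCAGCAUGAACUA"  # one substitution
        assert not map_tags([tag], {"c": ref}, max_mismatch=0)
        hits = map_tags([tag], {"c": ref}, max_mismatch=1)
        assert any(h.edits == 1 for h in hits)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        alpha = np.array(list("ACGU"))
        for _ in range(100):
            ref = "".join(alpha[rng.integers(0, 4, 120)])
            # half the cases: plant the tag with 0-1 errors
            if rng.random() < 0.5:
                s = int(rng.integers(0, 99))
                tag = list(ref[s : s + 21])
                if rng.random() < 0.5:
                    tag[int(rng.integers(0, 21))] = str(rng.choice(list("ACGU")))
                tag = "".join(tag)
            else:
                tag = "".join(alpha[rng.integers(0, 4, 21)])
            for m in (0, 1):
                got = {
                    (h.ref_id, h.start, h.end, h.strand, h.edits)
                    for h in map_tags([tag], {"r": ref}, max_mismatch=m)
                }
                assert got == brute_force_hits(tag, {"r": ref}, m)


class TestFold:
    def test_polya_has_no_structure(self):
        structure, mfe = fold("A" * 60)
        assert structure == "." * 60 and mfe == 0.0

    def test_gc_stem_below_threshold(self):
        stem = "GC" * 15
        seq = stem + "AAAA" + revcomp(stem)
        _, mfe = fold(seq)
        assert mfe < -18.0

    def test_deterministic(self):
        seq = "GGGGCCCCAAAAGGGGCCCCAAAAGGGGCCCCAAAAGGGG"
        assert fold(seq) == fold(seq)

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            fold("ACGX" * 15)


class TestExciseEvaluate:
    def _hairpin_contig(self, rng_seed=11):
        rng = np.random.default_rng(rng_seed)
        alpha = np.array(list("ACGU"))
        mature = "".join(alpha[rng.integers(0, 4, 21)])
        loop = "".join(alpha[rng.integers(0, 4, 12)])
        precursor = mature + loop + revcomp(mature)
        flank5 = "".join(alpha[rng.integers(0, 4, 300)])
        flank3 = "".join(alpha[rng.integers(0, 4, 300)])
        contig = flank5 + precursor + flank3
        return mature, contig, len(flank5)

    def test_planted_precursor_recovered_on_its_arm(self):
        mature, contig, start = self._hairpin_contig()
        hit = GenomicHit("c", start, start + 21, "+", 0, mature)
        cands = excise_candidates(hit, contig)
        accepted = [c for c in cands if evaluate_hairpin(c)[0]]
        assert accepted
        assert accepted[0].arm == "5p"
        assert accepted[0].duplex_pairs >= 16

    def test_loop_spanning_mature_rejected(self):
        mature, contig, start = self._hairpin_contig()
        # a "mature" centered on the loop pairs with itself or not at all
        loop_hit = GenomicHit("c", start + 21, start + 21 + 21, "+", 0, "")
        cands = excise_candidates(loop_hit, contig)
        assert all(c.arm in ("5p", "3p") for c in cands)  # loop candidates were dropped

    def test_window_clipped_at_origin(self):
        mature, contig, start = self._hairpin_contig()
        hit = GenomicHit("c", 10, 31, "+", 0, contig[10:31])
        cands = excise_candidates(hit, contig)  # start-250 < 0 must not raise
        assert isinstance(cands, list)

    def test_minus_strand_candidate(self):
        mature, contig, start = self._hairpin_contig()
        # the star arm maps on the minus strand as revcomp(mature)
        star_start = start + 21 + 12
        hit = GenomicHit("c", star_start, star_start + 21, "-", 0, mature)
        cands = excise_candidates(hit, contig)
        assert any(evaluate_hairpin(c)[0] for c in cands)


class TestEvaluateRules:
    def _cand(self, **kw):
        base = dict(
            precursor_seq="A" * 54, structure="." * 54, mfe=-30.0,
            mature_span=(0, 21), star_span=(33, 54), duplex_pairs=18,
            max_bulge=2, asymmetry=1, arm="5p",
        )
        base.update(kw)
        return HairpinCandidate(**base)

    def test_all_criteria_pass(self):
        ok, reasons = evaluate_hairpin(self._cand())
        assert ok and not reasons

    def test_fifteen_pairs_rejected(self):
        ok, reasons = evaluate_hairpin(self._cand(duplex_pairs=15))
        assert not ok and reasons == ["duplex_pairs"]

    def test_mfe_above_threshold_rejected(self):
        ok, reasons = evaluate_hairpin(self._cand(mfe=-17.5))
        assert not ok and reasons == ["mfe"]

    def test_bulge_and_asymmetry(self):
        assert evaluate_hairpin(self._cand(max_bulge=5))[1] == ["max_bulge"]
        assert evaluate_hairpin(self._cand(asymmetry=5))[1] == ["asymmetry"]

    def test_boundary_values_accepted(self):
        ok, _ = evaluate_hairpin(self._cand(mfe=-18.0, duplex_pairs=16, max_bulge=4, asymmetry=4))
        assert ok


class TestDominance:
    def _setup(self, mature_count, other_count):
        c = HairpinCandidate(
            precursor_seq="A" * 100, structure="." * 100, mfe=-30.0,
            mature_span=(10, 31), star_span=(60, 81), duplex_pairs=18,
            max_bulge=1, asymmetry=0, arm="5p", ref_id="c", precursor_start=200,
            strand="+", mature_seq="M" ,
        )
        hits = [GenomicHit("c", 210, 231, "+", 0, "M"), GenomicHit("c", 250, 271, "+", 0, "X")]
        counts = {"M": mature_count, "X": other_count}
        return c, hits, counts

    def test_dominant_mature_kept(self):
        c, hits, counts = self._setup(80, 20)
        out = dominance_filter([c], hits, counts)
        assert out and out[0].dominance == pytest.approx(0.8)

    def test_minority_mature_dropped(self):
        c, hits, counts = self._setup(30, 70)
        assert not dominance_filter([c], hits, counts)

    def test_overlapping_candidates_collapse(self):
        c1, hits, counts = self._setup(80, 20)
        c2, _, _ = self._setup(80, 20)
        c2.precursor_start = 230  # overlaps c1's window
        c2.mature_span = (20, 41)
        out = dominance_filter([c1, c2], hits + [GenomicHit("c", 250, 271, "+", 0, "M")], counts)
        assert len(out) == 1


def test_planted_hairpins_all_pass_self_oracle(small_sim):
    """Every planted precursor, excised at its planted locus and folded,
    satisfies the structural acceptance rules (generator self-oracle)."""
    _, genome, _, truth, _ = small_sim
    n_pass = 0
    planted = [(f, m, s, l) for f, m, s, l in truth.planted_mirnas if l]
    for fam, mature, star, locus in planted:
        contig, span = locus.split(":")
        seq = rna(genome[contig])
        i = seq.find(mature)
        assert i >= 0
        hit = GenomicHit(contig, i, i + len(mature), "+", 0, mature)
        if any(evaluate_hairpin(c)[0] for c in excise_candidates(hit, seq)):
            n_pass += 1
    assert n_pass == len(planted)
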