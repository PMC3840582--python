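"""Edit-bounded matcher vs a full dynamic-programming oracle, cascade order,
conserved classification and the family abundance filter."""

import numpy as np
import pytest

from bolmir.core import PipelineConfig, collapse_tags, normalize_counts
from bolmir.homology import (
    MatureRef,
    RefSet,
    align_tag,
    annotate_cascade,
    classify_conserved,
    filter_families,
    parse_mature_header,
)


def edit_distance_infix(tag: str, ref: str) -> int:
    """Independent oracle: minimum edit distance of tag against any
    location in ref (tag fully consumed), by full DP over all end points."""
    n, m = len(tag), len(ref)
    prev = [0] * (m + 1)  # free start anywhere in ref
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (tag[i - 1] != ref[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)


class TestAlignTag:
    def test_identity_substring(self):
        ref = "G" * 30 + "UGAAGCUGCCAGCAUGAUCUA" + "C" * 30
        aln = align_tag("UGAAGCUGCCAGCAUGAUCUA", ref, max_edits=2)
        assert aln is not None
        assert aln.mismatches == 0 and aln.gaps == 0

    def test_seed_edit_disqualifies(self):
        ref = "UGAAGCUGCCAGCAUGAUCUA"
        tag = ref[:4] + ("A" if ref[4] != "A" else "C") + ref[5:]  # edit at pos 5
        assert align_tag(tag, ref, max_edits=1, protect_seed=True) is None
        # without protection the same tag matches
        assert align_tag(tag, ref, max_edits=1, protect_seed=False) is not None

    def test_two_nonseed_mismatches_allowed(self):
        ref = "UGAAGCUGCCAGCAUGAUCUA"
        tag = list(ref)
        for pos in (9, 14):  # 1-based 10 and 15, outside the seed
            tag[pos] = "A" if ref[pos] != "A" else "C"
        aln = align_tag("".join(tag), ref, max_edits=3, protect_seed=True)
        assert aln is not None
        assert aln.mismatches == 2 and aln.seed_violations == 0

    def test_length_difference_over_two_rejected(self):
        ref = "UGAAGCUGCCAGCAUGAUCUAGCA"  # 24 nt
        tag = ref[:21]  # 21 nt, 0 edits
        assert align_tag(tag, ref, max_edits=1, protect_seed=True) is None
        assert align_tag(tag, ref, max_edits=1, protect_seed=False) is not None

    def test_empty_tag_errors(self):
        with pytest.raises(ValueError):
            align_tag("", "ACGU", 1)

    def test_min_edit_distance_matches_full_dp_oracle(self):
        rng = np.random.default_rng(42)
        alpha = np.array(list("ACGU"))
        for _ in range(200):
            tag = "".join(alpha[rng.integers(0, 4, rng.integers(18, 26))])
            ref = "".join(alpha[rng.integers(0, 4, rng.integers(18, 31))])
            expected = edit_distance_infix(tag, ref)
            aln = align_tag(tag, ref, max_edits=30)
            assert aln is not None
            assert aln.mismatches + aln.gaps == expected

    def test_no_match_beyond_budget(self):
        rng = np.random.default_rng(1)
        alpha = np.array(list("ACGU"))
        checked = 0
        for _ in range(100):
            tag = "".join(alpha[rng.integers(0, 4, 21)])
            ref = "".join(alpha[rng.integers(0, 4, 25)])
            d = edit_distance_infix(tag, ref)
            if d > 3:
                assert align_tag(tag, ref, max_edits=3) is None
                checked += 1
        assert checked > 50


class TestCascade:
    @pytest.fixture()
    def refsets(self):
        return [
            RefSet(category="tRNA", sequences={"trna1": "ACGUACGUACGUACGUACGUACG"}),
            RefSet(category="repeat", sequences={"rep1": "ACGUACGUACGUACGUACGUACG"}),
        ]

    def test_first_refset_wins(self, refsets):
        table = normalize_counts(collapse_tags({"L1": ["ACGUACGUACGUACGUACGUA"]}))
        records, _ = annotate_cascade(table, refsets)
        assert records["ACGUACGUACGUACGUACGUA"].category == "tRNA"

    def test_no_match_is_unannotated(self, refsets):
        table = normalize_counts(collapse_tags({"L1": ["GGGGGGCCCCCCGGGGGGCCC"]}))
        records, _ = annotate_cascade(table, refsets)
        rec = records["GGGGGGCCCCCCGGGGGGCCC"]
        assert rec.category == "unannotated" and rec.reference_id == ""

    def test_categories_partition_tags(self, small_sim):
        scfg, _, bundle, _, libs = small_sim
        from bolmir.qc import qc_filter

        clean = {lib: qc_filter(reads, scfg.adapter3, scfg.adapter5)[0] for lib, reads in libs.items()}
        table = normalize_counts(collapse_tags(clean))
        records, ledger = annotate_cascade(table, bundle.refsets)
        assert set(records) == {t.seq for t in table.tags}
        # ledger unique counts per library (unannotated row included)
        # partition the clean unique tags
        for lib in table.library_ids:
            clean_row = ledger[ledger.category == "clean_reads"].iloc[0]
            cat_sum = ledger[ledger.category != "clean_reads"][f"unique_{lib}"].sum()
            assert cat_sum == clean_row[f"unique_{lib}"]

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            RefSet(category="mystery", sequences={})


class TestClassifyConserved:
    NATIVE = [MatureRef("bol-mirA", "UGAAGCUGCCAGCAUGAUCUA", "MIR167", False, True)]
    OTHER = [MatureRef("ath-mirA", "UGAAGCUGCCAGCAUGAUCUA", "MIR167", False, False)]
    STAR = [MatureRef("bol-mirA*", "UAGAUCAUGCUGGCAGCUUCA", "MIR167", True, True)]

    def test_exact_native_match(self):
        out = classify_conserved(["UGAAGCUGCCAGCAUGAUCUA"], self.NATIVE, self.OTHER)
        assert len(out) == 1
        a = out[0]
        assert a.family == "MIR167" and a.source_mirna == "bol-mirA"
        assert a.evidence.edits == 0 and not a.is_star

    def test_three_nonseed_edits_only_matches_other_plant_pass(self):
        tag = list(self.NATIVE[0].seq)
        for pos in (9, 13, 17):
            tag[pos] = "A" if tag[pos] != "A" else "C"
        out = classify_conserved(["".join(tag)], self.NATIVE, self.OTHER)
        assert len(out) == 1
        assert out[0].source_mirna == "ath-mirA"

    def test_star_reference_flags_star(self):
        out = classify_conserved([self.STAR[0].seq], self.STAR, [])
        assert out[0].is_star

    def test_seed_protection_absolute(self, small_sim):
        _, _, bundle, _, _ = small_sim
        tags = [r.seq for r in bundle.mirna_native[:10]]
        out = classify_conserved(tags, bundle.mirna_native, bundle.mirna_other)
        assert all(a.evidence.seed_violations == 0 for a in out)


class TestFilterFamilies:
    def _table(self, norm_per_lib):
        table = collapse_tags({"L1": ["ACGUACGUACGUACGUACGUA"]})
        table.library_totals = {"L1": 1_000_000}
        normalize_counts(table)
        table.tags[0].norm = {"L1": norm_per_lib}
        table.tags[0].mean_norm = norm_per_lib
        return table

    def _assign(self, family):
        aln = align_tag("ACGUACGUACGUACGUACGUA", "ACGUACGUACGUACGUACGUA", 1, ref_id="m1")
        from bolmir.homology import FamilyAssignment

        return [FamilyAssignment("ACGUACGUACGUACGUACGUA", family, "m1", False, aln)]

    def test_low_abundance_non_brassicaceae_dropped(self):
        kept, dropped = filter_families(self._assign("MIRX"), self._table(12.0), set())
        assert not kept and dropped[0].family == "MIRX"

    def test_abundant_non_brassicaceae_kept(self):
        kept, dropped = filter_families(self._assign("MIRX"), self._table(20.0), set())
        assert kept and not dropped

    def test_brassicaceae_family_exempt(self):
        kept, dropped = filter_families(self._assign("MIRX"), self._table(3.0), {"MIRX"})
        assert kept and not dropped


def test_parse_mature_header():
    ref = parse_mature_header("bol-mir169a|family=MIR169|star=0|native=1", "ACGT")
    assert ref.family == "MIR169" and not ref.star and ref.native
    assert ref.seq == "ACGU"
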