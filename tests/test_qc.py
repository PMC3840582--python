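"""Read-cleaning rules: per-rule rejection, ordering, idempotence."""

import pytest

from bolmir.core import PipelineConfig, SmallRNARead
from bolmir.qc import find_adapter3, qc_filter

ADAPTER3 = "UGGAAUUCUCGGGUGCCAAGG"
ADAPTER5 = "GUUCAGAGUUCUACAGUCCGACGAUC"


def _read(seq, qual=None, rid="r"):
    qual = tuple(qual) if qual is not None else tuple([40] * len(seq))
    return SmallRNARead(rid, seq, qual)


def _with_adapter(insert, read_len=36):
    return (insert + ADAPTER3)[:read_len]


class TestRules:
    def test_clean_read_survives_and_is_trimmed(self):
        insert = "ACGUACGUACGUACGUACGUA"  # 21 nt
        clean, rep = qc_filter([_read(_with_adapter(insert))], ADAPTER3, ADAPTER5)
        assert clean == [insert]
        assert rep.clean_reads == 1

    def test_n_base_removed(self):
        seq = _with_adapter("ACGUACGUACGUACGUACGUA")
        seq = "N" + seq[1:]
        _, rep = qc_filter([_read(seq)], ADAPTER3, ADAPTER5)
        assert rep.removed_n == 1 and rep.clean_reads == 0

    def test_five_bases_below_q10_removed(self):
        seq = _with_adapter("ACGUACGUACGUACGUACGUA")
        qual = [40] * len(seq)
        for i in range(5):
            qual[i] = 9
        _, rep = qc_filter([_read(seq, qual)], ADAPTER3, ADAPTER5)
        assert rep.removed_q10 == 1

    def test_four_bases_below_q10_kept(self):
        seq = _with_adapter("ACGUACGUACGUACGUACGUA")
        qual = [40] * len(seq)
        for i in range(4):
            qual[i] = 9
        _, rep = qc_filter([_read(seq, qual)], ADAPTER3, ADAPTER5)
        assert rep.clean_reads == 1

    def test_seven_bases_below_q13_removed(self):
        seq = _with_adapter("ACGUACGUACGUACGUACGUA")
        qual = [40] * len(seq)
        for i in range(7):
            qual[i] = 11  # below 13 but not below 10
        _, rep = qc_filter([_read(seq, qual)], ADAPTER3, ADAPTER5)
        assert rep.removed_q13 == 1

    def test_short_insert_removed(self):
        _, rep = qc_filter([_read(_with_adapter("ACGUACGUACGUACGUA"))], ADAPTER3, ADAPTER5)  # 17 nt
        assert rep.removed_short == 1

    def test_adapter_dimer_counts_as_short(self):
        _, rep = qc_filter([_read(ADAPTER3 + ADAPTER3[:10])], ADAPTER3, ADAPTER5)
        assert rep.removed_short == 1

    def test_missing_adapter_removed(self):
        _, rep = qc_filter([_read("ACGU" * 9)], ADAPTER3, ADAPTER5)
        assert rep.removed_no_3prime_adapter == 1

    def test_polya_removed(self):
        _, rep = qc_filter([_read(_with_adapter("A" * 22))], ADAPTER3, ADAPTER5)
        assert rep.removed_polyA == 1

    def test_5prime_contaminant_removed(self):
        insert = ADAPTER5[:8] + "CGCGCGCGCGCGU"
        _, rep = qc_filter([_read(_with_adapter(insert))], ADAPTER3, ADAPTER5)
        assert rep.removed_5prime_adapter == 1


class TestAccountingAndProperties:
    def test_partition_accounting(self, small_sim):
        _, _, _, _, libs = small_sim
        scfg = small_sim[0]
        _, rep = qc_filter(libs["lib1"], scfg.adapter3, scfg.adapter5)
        removed = sum(v for k, v in rep.to_dict().items() if k.startswith("removed_"))
        assert rep.clean_reads + removed == rep.input_reads == scfg.reads_per_library

    def test_idempotent_on_clean_output(self, small_sim):
        scfg, _, _, _, libs = small_sim
        clean, _ = qc_filter(libs["lib1"], scfg.adapter3, scfg.adapter5)
        again, rep2 = qc_filter(
            [SmallRNARead(f"c{i}", s, tuple([40] * len(s))) for i, s in enumerate(clean)],
            scfg.adapter3,
            scfg.adapter5,
            require_adapter3=False,
        )
        assert again == clean
        assert rep2.clean_reads == rep2.input_reads

    def test_monotone_in_min_read_len(self, small_sim):
        scfg, _, _, _, libs = small_sim
        n_prev = None
        for mrl in (18, 20, 22, 24):
            _, rep = qc_filter(
                libs["lib1"], scfg.adapter3, scfg.adapter5, PipelineConfig(min_read_len=mrl)
            )
            if n_prev is not None:
                assert rep.clean_reads <= n_prev
            n_prev = rep.clean_reads

    def test_labeled_negatives_all_removed_no_planted_lost(self):
        """With error_rate=0 every labeled QC-negative read is removed and
        every planted read survives."""
        from bolmir.simulate import SimConfig, simulate_libraries, simulate_references

        scfg = SimConfig(rng_seed=3, reads_per_library=2000, n_libraries=1, error_rate=0.0)
        _, _, truth = simulate_references(scfg)
        libs = simulate_libraries(scfg, truth)
        reads = libs["lib1"]
        survivors_ids = set()
        kept = []
        for r in reads:
            clean, rep = qc_filter([r], scfg.adapter3, scfg.adapter5)
            if rep.clean_reads:
                survivors_ids.add(r.read_id)
                kept.append((r.read_id, clean[0]))
        neg = [r.read_id for r in reads if "_neg:" in r.read_id]
        ok = [r.read_id for r in reads if "_ok:" in r.read_id]
        assert not (set(neg) & survivors_ids), "a labeled negative survived"
        assert set(ok) <= survivors_ids, "a clean planted read was removed"
        # surviving inserts equal planted sequences exactly
        planted = set(truth.expected_category)
        assert all(s in planted for _, s in kept)


def test_find_adapter3_prefix_with_one_mismatch():
    insert = "ACGUACGUACGUACGUACGUA"
    read = insert + "UGGAAUACUCGG"  # adapter prefix with one mismatch
    assert find_adapter3(read, ADAPTER3) == len(insert)
    assert find_adapter3("ACGU" * 9, ADAPTER3) == -1
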