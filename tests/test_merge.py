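"""The Phase-2 merge engine: ordering, strategies, induction, counters."""

import itertools

import numpy as np
import pytest

from gesa import (
    Collection,
    CollectionStore,
    GenSpec,
    MergeConfig,
    SENTINEL,
    count_inducible,
    generate,
    lemma1_decide,
    merge,
    toy_collection,
)
from gesa.collection_io import FormatError
from gesa.merge import StringBuffer, StringBufferOverflow
from gesa.pipeline import build_collection_esas, build_gesa

from conftest import (
    ALL_FLAG_COMBOS,
    TOY_LCPS,
    TOY_ORDER,
    merge_records,
    naive_gesa,
)


class TestLemma1Decide:
    def test_worked_triple(self):
        # reference AGA$; A = AGAGA$ (lcp 3), B = ATAGA$ (lcp 1)
        assert lemma1_decide(3, 1) == (-1, 1)
        assert lemma1_decide(1, 3) == (1, 1)

    def test_tie_defers_to_characters(self):
        assert lemma1_decide(0, 0) == (0, 0)
        assert lemma1_decide(5, 5) == (0, 5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lemma1_decide(-1, 0)

    def test_agrees_with_direct_comparison(self):
        rng = np.random.default_rng(11)
        from conftest import direct_lcp, random_text

        for _ in range(300):
            base = random_text(rng, int(rng.integers(1, 30)), 2) + b"\x00"
            sufs = sorted(
                {base[int(rng.integers(0, len(base))):] for _ in range(3)}
            )
            if len(sufs) < 3:
                continue
            ref, a, b = sufs[0], *sorted(sufs[1:], key=lambda s: s)
            sign, val = lemma1_decide(direct_lcp(ref, a), direct_lcp(ref, b))
            if sign != 0:
                assert sign == (-1 if a < b else 1)
                assert val == direct_lcp(a, b)
            else:
                assert val <= direct_lcp(a, b)


class TestStringBuffer:
    def test_walkthrough_assembly(self):
        # ESA_1 of GATAGA$, p = 3: rank 5 fills GA$, rank 6 splices TAG at
        # offset h = min(2, 0+3) = 2, giving GATAG(#)
        buf = StringBuffer(8)
        h = buf.assemble(b"GA\x00", 0, 0, 3)
        assert (h, bytes(buf.buf[: buf.valid_len])) == (0, b"GA\x00")
        h = buf.assemble(b"TAG", 2, h, 3)
        assert h == 2
        assert bytes(buf.buf[: buf.valid_len]) == b"GATAG"

    def test_first_rank_starts_at_zero(self):
        buf = StringBuffer(8)
        assert buf.assemble(b"XYZ", 0, 0, 3) == 0
        assert bytes(buf.buf[:3]) == b"XYZ"

    def test_overflow_raises(self):
        buf = StringBuffer(4)
        buf.assemble(b"ABC", 0, 0, 3)
        with pytest.raises(StringBufferOverflow):
            buf.assemble(b"DEF", 3, 0, 3)  # h=3, needs 3+3+1 > 4 slots

    def test_clip_keeps_only_valid_prefix(self):
        buf = StringBuffer(4)
        buf.assemble(b"ABC", 0, 0, 3)
        h = buf.clip(b"DEF", 3, 0, 3)
        assert h == 3
        assert bytes(buf.buf[: buf.valid_len]) == b"ABC"  # partial but true


class TestToyMerge:
    def test_matches_frozen_ground_truth(self, toy):
        res, recs = merge_records(toy, p=3, s=8)
        assert [(r.str, r.suf) for r in recs] == TOY_ORDER
        assert [r.lcp for r in recs] == TOY_LCPS
        texts = {r.id: r.text for r in toy.strings}
        for rec in recs:
            want = texts[rec.str][rec.suf - 2] if rec.suf > 1 else SENTINEL
            assert rec.bwt == want

    def test_all_strategy_combos_bit_identical(self, toy, tmp_path):
        baseline = None
        for pa, lc, ind in ALL_FLAG_COMBOS:
            res, recs = merge_records(toy, pa=pa, lc=lc, ind=ind, p=3, s=8)
            if baseline is None:
                baseline = recs
            assert recs == baseline

    def test_bucket_traces_match_walkthrough(self, toy):
        res, _ = merge_records(toy, p=3, s=8)
        log = res.bucket_log
        assert log[ord("G")] == [(1, 0), (2, 2), (2, 2), (1, 2)]
        assert log[ord("T")] == [(1, 0), (2, 4)]
        assert log[ord("A")] == [(1, 0), (2, 1)]
        assert res.stats.induced_count == 8  # 8 of the 14 suffixes

    def test_induced_records_occupy_bucket_head(self, toy):
        """Within each first-symbol group of the output, drained (induced)
        records precede heap-emitted ones; for the toy the G-group is
        GA$ GA$ GAGA$ GATAGA$, all four induced, at positions 9-12."""
        res, recs = merge_records(toy, p=3, s=8)
        g = [(r.str, r.suf) for r in recs[8:12]]
        assert g == [(1, 5), (2, 5), (2, 3), (1, 1)]
        assert [r.lcp for r in recs[8:12]] == [0, 2, 2, 2]


class TestMergeProperties:
    def test_single_source_is_its_own_esa(self):
        coll = Collection.from_texts([b"BANANA"])
        truth = naive_gesa(coll)
        for ind in (True, False):
            _, recs = merge_records(coll, ind=ind, p=2, s=8)
            assert recs == truth
            assert all(r.str == 1 for r in recs)

    def test_duplicate_strings_tie_by_rank(self):
        coll = Collection.from_texts([b"AB", b"AB"])
        _, recs = merge_records(coll, p=2, s=8)
        assert [(r.str, r.suf) for r in recs] == [
            (1, 3), (2, 3), (1, 1), (2, 1), (1, 2), (2, 2)
        ]
        assert [r.lcp for r in recs] == [0, 0, 0, 2, 0, 1]

    def test_random_collections_all_flag_subsets(self):
        """Merge output is bit-identical to the brute-force ground truth for
        every strategy subset, across varied random collections."""
        rng = np.random.default_rng(5150)
        for trial in range(40):
            spec = GenSpec(
                m=int(rng.integers(1, 7)),
                length=(1, int(rng.choice([10, 40, 90]))),
                sigma=int(rng.choice([2, 4, 20])),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            coll = generate(spec)
            truth = naive_gesa(coll)
            for pa, lc, ind in ALL_FLAG_COMBOS:
                _, recs = merge_records(
                    coll, pa=pa, lc=lc, ind=ind, p=3, s=10, e=4, o=5, c=2
                )
                assert recs == truth, (spec, pa, lc, ind)

    def test_induced_count_equals_descents(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            coll = generate(GenSpec(
                m=int(rng.integers(1, 6)), length=(1, 60),
                sigma=int(rng.choice([2, 4])),
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
            res, _ = merge_records(coll)
            assert res.stats.induced_count == count_inducible(coll)

    def test_char_comparisons_not_increased_by_lcp_shortcut(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            coll = generate(GenSpec(
                m=int(rng.integers(2, 7)), length=(1, 60),
                sigma=int(rng.choice([2, 4])),
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
            for pa, ind in itertools.product([True, False], repeat=2):
                r_on, recs_on = merge_records(coll, pa=pa, lc=True, ind=ind)
                r_off, recs_off = merge_records(coll, pa=pa, lc=False, ind=ind)
                assert recs_on == recs_off
                assert (
                    r_on.stats.char_comparisons <= r_off.stats.char_comparisons
                )

    def test_prefix_assembly_never_adds_window_reads(self):
        rng = np.random.default_rng(13)
        for _ in range(8):
            coll = generate(GenSpec(
                m=int(rng.integers(2, 6)), length=(1, 50),
                sigma=2, seed=int(rng.integers(0, 2**31 - 1)),
            ))
            for lc, ind in itertools.product([True, False], repeat=2):
                r_on, _ = merge_records(coll, pa=True, lc=lc, ind=ind, p=4)
                r_off, _ = merge_records(coll, pa=False, lc=lc, ind=ind, p=0)
                assert (
                    r_on.stats.string_window_reads
                    <= r_off.stats.string_window_reads
                )

    def test_long_shared_prefixes_force_window_fallback(self):
        """When maxlcp exceeds the string buffer the engine degrades to
        repeated windowed reads but stays correct (the stated worst case)."""
        coll = generate(GenSpec(
            m=4, length=(1, 8), sigma=4, mode="adversarial_lcp",
            target_lcp=200, seed=21,
        ))
        res, recs = merge_records(coll, p=4, s=24)
        assert recs == naive_gesa(coll)
        assert res.stats.string_window_reads > 0

    def test_deterministic_outputs(self, toy, tmp_path):
        stats_a = None
        paths = []
        for tag in ("a", "b"):
            wd = tmp_path / tag
            res, _ = build_gesa(toy, MergeConfig(p=3, s=8), workdir=wd)
            paths.append(res.path)
            if stats_a is None:
                stats_a = res.stats.as_dict()
            else:
                assert res.stats.as_dict() == stats_a
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestMergeErrors:
    def test_mismatched_p_rejected(self, toy, tmp_path):
        paths = build_collection_esas(toy, 3, tmp_path, induction_aware=True)
        store = CollectionStore(toy)
        with pytest.raises(FormatError, match="p="):
            merge(paths, store, MergeConfig(p=5, s=8), tmp_path / "out.gesa")

    def test_wrong_file_count_rejected(self, toy, tmp_path):
        paths = build_collection_esas(toy, 3, tmp_path)
        store = CollectionStore(toy)
        with pytest.raises(FormatError, match="2 strings"):
            merge(paths[:1], store, MergeConfig(p=3, s=8), tmp_path / "o.gesa")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MergeConfig(p=5, s=3)  # buffer cannot hold entry + marker
        with pytest.raises(ValueError):
            MergeConfig(e=0)
        with pytest.raises(ValueError):
            MergeConfig(p=-1)
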