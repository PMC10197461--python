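"""Index construction: concat, SA/BWT, run-length encoding, thresholds,
sampled document array, serialization."""

import numpy as np
import pytest

from conftest import lcp_of, naive_bwt_rotation_sort, naive_suffix_array
from minidx.index import (
    CompressedIndex,
    IndexFormatError,
    build_concat,
    build_index,
    build_sampled_doc_array,
    build_thresholds,
    bwt_from_sa,
    deserialize,
    lcp_from_sa,
    run_length_encode,
    serialize,
    suffix_array,
)
from minidx.query import lf_map
from minidx.simulate import random_sequence


def _random_text(rng, max_len=200, sigma=4):
    return rng.integers(0, sigma, size=int(rng.integers(2, max_len))).tolist()


class TestBuildConcat:
    def test_single_document(self):
        ct = build_concat([np.array([0, 1])], [0], sigma=4)
        # sentinel code 0, data offset by n_docs=1
        assert ct.symbols.tolist() == [1, 2, 0]
        assert ct.n == 3

    def test_two_documents_boundaries(self):
        ct = build_concat([np.array([0]), np.array([1, 2])], [0, 1], sigma=4)
        assert ct.doc_boundaries.tolist() == [0, 2]
        assert ct.n_docs == 2
        # two sentinels, ranked by document order
        assert ct.symbols.tolist() == [2, 0, 3, 4, 1]

    def test_roundtrip_split_at_sentinels(self):
        docs = [np.array([3, 1, 2]), np.array([0, 0]), np.array([2])]
        ct = build_concat(docs, [0, 0, 1], sigma=4)
        rec, cur = [], []
        for s in ct.symbols.tolist():
            if s < ct.n_docs:
                rec.append(cur)
                cur = []
            else:
                cur.append(s - ct.n_docs)
        assert rec == [d.tolist() for d in docs]

    def test_empty_document_rejected(self):
        with pytest.raises(ValueError):
            build_concat([np.array([], dtype=int)], [0], sigma=4)


class TestSuffixArrayBwt:
    def test_aaa_sentinel(self):
        ct = build_concat([np.array([0, 0, 0])], [0], sigma=4)
        sa = suffix_array(ct.symbols)
        assert sa.tolist() == [3, 2, 1, 0]

    def test_matches_naive_sort(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            ct = build_concat(
                [np.asarray(_random_text(rng, 250))], [0], sigma=4
            )
            sa = suffix_array(ct.symbols)
            assert sa.tolist() == naive_suffix_array(ct.symbols.tolist())

    def test_suffixes_strictly_increasing(self):
        rng = np.random.default_rng(7)
        ct = build_concat([np.asarray(_random_text(rng, 100))], [0], sigma=4)
        sa = suffix_array(ct.symbols)
        syms = ct.symbols.tolist()
        for a, b in zip(sa, sa[1:]):
            assert syms[a:] < syms[b:]

    def test_bwt_matches_rotation_sort(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            ct = build_concat(
                [np.asarray(_random_text(rng, 120))], [0], sigma=4
            )
            sa = suffix_array(ct.symbols)
            bwt = bwt_from_sa(ct.symbols, sa)
            assert bwt.tolist() == naive_bwt_rotation_sort(ct.symbols.tolist())

    def test_multi_document_sa_matches_naive(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            docs = [
                np.asarray(_random_text(rng, 60))
                for _ in range(int(rng.integers(2, 5)))
            ]
            ct = build_concat(docs, list(range(len(docs))), sigma=4)
            sa = suffix_array(ct.symbols)
            assert sa.tolist() == naive_suffix_array(ct.symbols.tolist())


class TestRunLengthEncode:
    def test_small_cases(self):
        rl = run_length_encode(np.array([1, 1, 1, 2]))
        assert rl.run_chars.tolist() == [1, 2]
        assert rl.run_lengths.tolist() == [3, 1]
        assert rl.r == 2

    def test_all_distinct(self):
        rl = run_length_encode(np.arange(5))
        assert rl.r == 5

    def test_decode_and_invariants(self):
        rng = np.random.default_rng(3)
        bwt = rng.integers(0, 3, size=500)
        rl = run_length_encode(bwt)
        assert rl.decode().tolist() == bwt.tolist()
        assert int(rl.run_lengths.sum()) == bwt.size
        assert (rl.run_chars[1:] != rl.run_chars[:-1]).all()

    def test_repetitive_collection_compresses_better_than_random(self):
        rng = np.random.default_rng(99)
        base = random_sequence(5000, rng)

        def mutate(seq):
            chars = list(seq)
            for pos in rng.integers(0, len(chars), size=25):  # 0.5% divergence
                chars[pos] = "ACGT"[int(rng.integers(0, 4))]
            return "".join(chars)

        strains = [mutate(base) for _ in range(10)]
        randoms = [random_sequence(5000, rng) for _ in range(10)]

        def n_over_r(docs):
            idx = build_index(
                docs, [0] * len(docs), digest=False, alphabet_mode="dna",
                add_revcomp=False,
            )
            return idx.n / idx.r

        assert n_over_r(strains) > 5 * n_over_r(randoms)


class TestThresholds:
    def test_two_run_text_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(21)
        found = 0
        while found < 5:
            ct = build_concat(
                [np.asarray(_random_text(rng, 20, sigma=3))], [0], sigma=3
            )
            sa = suffix_array(ct.symbols)
            bwt = bwt_from_sa(ct.symbols, sa)
            rl = run_length_encode(bwt)
            lcp = lcp_from_sa(ct.symbols, sa)
            table = build_thresholds(rl, lcp)
            run_ends = rl.run_starts + rl.run_lengths - 1
            for c, thr in table.by_char.items():
                runs = [j for j in range(rl.r) if rl.run_chars[j] == c]
                for i, t in enumerate(thr.tolist()):
                    e = int(run_ends[runs[i]])
                    s = int(rl.run_starts[runs[i + 1]])
                    seg = lcp[e + 1 : s + 1].tolist()
                    assert t == e + 1 + seg.index(min(seg))
                    assert e < t <= s
                    found += 1

    def test_single_run_character_has_no_threshold(self):
        ct = build_concat([np.asarray([0, 1, 1, 1])], [0], sigma=4)
        sa = suffix_array(ct.symbols)
        rl = run_length_encode(bwt_from_sa(ct.symbols, sa))
        lcp = lcp_from_sa(ct.symbols, sa)
        table = build_thresholds(rl, lcp)
        for c, thr in table.by_char.items():
            runs = sum(1 for ch in rl.run_chars.tolist() if ch == c)
            assert len(thr) == runs - 1


class TestSampledDocArray:
    def test_single_document_all_labels_equal(self):
        rng = np.random.default_rng(31)
        ct = build_concat([np.asarray(_random_text(rng, 100))], [3], sigma=4)
        sa = suffix_array(ct.symbols)
        rl = run_length_encode(bwt_from_sa(ct.symbols, sa))
        sda = build_sampled_doc_array(sa, rl, ct)
        assert (sda.first_labels == 3).all()
        assert (sda.last_labels == 3).all()
        assert sda.first_labels.size == rl.r

    def test_disjoint_alphabet_documents(self):
        # doc0 over {0,1}, doc1 over {2,3}: every non-sentinel boundary must
        # label the document owning the symbol at that suffix
        rng = np.random.default_rng(33)
        d0 = rng.integers(0, 2, size=40)
        d1 = rng.integers(2, 4, size=40)
        ct = build_concat([d0, d1], [0, 1], sigma=4)
        sa = suffix_array(ct.symbols)
        rl = run_length_encode(bwt_from_sa(ct.symbols, sa))
        sda = build_sampled_doc_array(sa, rl, ct)
        run_ends = rl.run_starts + rl.run_lengths - 1
        for j in range(rl.r):
            for row, lab in ((rl.run_starts[j], sda.first_labels[j]),
                             (run_ends[j], sda.last_labels[j])):
                pos = int(sa[row])
                expected = ct.doc_labels[ct.doc_of(pos)]
                assert lab == expected

    def test_direct_sa_lookup_consistency(self):
        rng = np.random.default_rng(35)
        docs = [np.asarray(_random_text(rng, 80)) for _ in range(4)]
        ct = build_concat(docs, [0, 1, 1, 2], sigma=4)
        sa = suffix_array(ct.symbols)
        rl = run_length_encode(bwt_from_sa(ct.symbols, sa))
        sda = build_sampled_doc_array(sa, rl, ct)
        run_ends = rl.run_starts + rl.run_lengths - 1
        expect_first = [
            int(ct.doc_labels[ct.doc_of(int(sa[r]))]) for r in rl.run_starts
        ]
        expect_last = [
            int(ct.doc_labels[ct.doc_of(int(sa[r]))]) for r in run_ends
        ]
        assert sda.first_labels.tolist() == expect_first
        assert sda.last_labels.tolist() == expect_last

    def test_label_width_bound(self):
        sda = build_sampled_doc_array(
            *_tiny_index_parts(n_docs=8)
        )
        assert sda.bits_per_entry == 3  # ceil(log2 8)


def _tiny_index_parts(n_docs=8):
    rng = np.random.default_rng(41)
    docs = [rng.integers(0, 4, size=20) for _ in range(n_docs)]
    ct = build_concat(docs, list(range(n_docs)), sigma=4)
    sa = suffix_array(ct.symbols)
    rl = run_length_encode(bwt_from_sa(ct.symbols, sa))
    return sa, rl, ct


class TestLfConsistency:
    def test_lf_visits_all_rows_once_and_inverts(self):
        rng = np.random.default_rng(51)
        for _ in range(10):
            docs = [np.asarray(_random_text(rng, 80)) for _ in range(2)]
            idx = _index_from_docs(docs)
            n = idx.n
            seen = set()
            row = 0
            for _ in range(n):
                assert row not in seen
                seen.add(row)
                row = lf_map(idx, row)
            assert row == 0 and len(seen) == n


def _index_from_docs(docs):
    from minidx.digest import decode_dna

    seqs = [decode_dna(d) for d in docs]
    return build_index(
        seqs, [0] * len(seqs), digest=False, alphabet_mode="dna",
        add_revcomp=False,
    )


class TestSerialization:
    def _build(self, tmp_path, **kw):
        rng = np.random.default_rng(61)
        docs = [random_sequence(300, rng) for _ in range(3)]
        idx = build_index(
            docs, [0, 1, 2], alphabet_mode="minimizer", doc_array=True,
            ms_support=kw.get("ms_support", False),
            null_params={"n_reads": 10, "read_len": 100, "seed": 1,
                         "min_count": 5},
        )
        return idx, docs

    def test_roundtrip_structural_equality(self, tmp_path):
        idx, _ = self._build(tmp_path, ms_support=True)
        serialize(idx, tmp_path / "idx")
        loaded = deserialize(tmp_path / "idx")
        assert loaded.n == idx.n and loaded.r == idx.r
        assert loaded.rlbwt.run_chars.tolist() == idx.rlbwt.run_chars.tolist()
        assert loaded.rlbwt.run_lengths.tolist() == idx.rlbwt.run_lengths.tolist()
        for c in idx.thresholds.by_char:
            assert (
                loaded.thresholds.by_char[c].tolist()
                == idx.thresholds.by_char[c].tolist()
            )
        assert loaded.doc_array.first_labels.tolist() == idx.doc_array.first_labels.tolist()
        assert loaded.doc_array.last_labels.tolist() == idx.doc_array.last_labels.tolist()
        assert loaded.text.tolist() == idx.text.tolist()
        assert loaded.null_threshold == idx.null_threshold
        assert loaded.scheme == idx.scheme

    def test_rebuild_is_byte_identical(self, tmp_path):
        idx1, docs = self._build(tmp_path)
        idx2, _ = self._build(tmp_path)
        p1 = serialize(idx1, tmp_path / "a")
        p2 = serialize(idx2, tmp_path / "b")
        for f1 in sorted(p1.iterdir()):
            f2 = p2 / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_truncated_component_errors(self, tmp_path):
        idx, _ = self._build(tmp_path)
        p = serialize(idx, tmp_path / "idx")
        data = (p / "run_chars.npy").read_bytes()
        (p / "run_chars.npy").write_bytes(data[: len(data) // 2])
        with pytest.raises(IndexFormatError):
            deserialize(p)

    def test_bad_magic_named_in_error(self, tmp_path):
        idx, _ = self._build(tmp_path)
        p = serialize(idx, tmp_path / "idx")
        hdr = (p / "header.txt").read_text().replace("MINIDX", "BOGUS!")
        (p / "header.txt").write_text(hdr)
        with pytest.raises(IndexFormatError, match="MINIDX"):
            deserialize(p)
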