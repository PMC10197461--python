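"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from minidx import build_index
from minidx.simulate import random_sequence


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; never reuse index code paths)


def naive_ms(text: str, pattern: str) -> list[int]:
    """Matching statistics by binary search over ``str.find`` occurrence."""
    out = []
    for i in range(len(pattern)):
        lo, hi = 0, len(pattern) - i
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if text.find(pattern[i : i + mid]) >= 0:
                lo = mid
            else:
                hi = mid - 1
        out.append(lo)
    return out


def naive_suffix_array(symbols) -> list[int]:
    syms = list(symbols)
    return sorted(range(len(syms)), key=lambda i: syms[i:])


def naive_bwt_rotation_sort(symbols) -> list[int]:
    """BWT as the last column of the sorted rotation matrix."""
    syms = list(symbols)
    n = len(syms)
    rotations = sorted(range(n), key=lambda i: syms[i:] + syms[:i])
    return [syms[(i - 1) % n] for i in rotations]


def lcp_of(a: list[int], b: list[int]) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


# ---------------------------------------------------------------------------
# shared heavy fixtures


@pytest.fixture(scope="session")
def ms_oracle_run():
    """1000 random (reference, read) pairs: exact MS vs the naive oracle.

    Shared by the MS-equivalence and PML-bound checks so the pairs are
    computed once.
    """
    from minidx.query import compute_ms, compute_pmls

    rng = np.random.default_rng(20260926)
    mismatch_pairs = 0
    pml_violations = 0
    n_pairs = 1000
    suffix_property_violations = 0
    for _ in range(n_pairs):
        ref = random_sequence(int(rng.integers(20, 2001)), rng)
        if rng.random() < 0.5:
            ln = int(rng.integers(1, 101))
            start = int(rng.integers(0, max(1, len(ref) - ln)))
            pat = ref[start : start + ln]
        else:
            pat = random_sequence(int(rng.integers(1, 101)), rng)
        idx = build_index(
            [ref], [0], digest=False, alphabet_mode="dna",
            add_revcomp=False, ms_support=True,
        )
        enc = idx.encode_read(pat)
        ms = compute_ms(enc, idx)
        if ms.tolist() != naive_ms(ref, pat):
            mismatch_pairs += 1
        pml, _, _ = compute_pmls(enc, idx)
        pml_violations += int((pml > ms).sum())
        suffix_property_violations += int((ms[1:] < ms[:-1] - 1).sum())
    return {
        "n_pairs": n_pairs,
        "ms_mismatch_pairs": mismatch_pairs,
        "pml_violations": pml_violations,
        "suffix_property_violations": suffix_property_violations,
    }


@pytest.fixture(scope="session")
def five_strain_index():
    """Index of 5 strains (5 kb, 1% divergence, both strands, k=4, w=11)
    with a stored null-PML threshold — the binary-classification setting."""
    from minidx import MinimizerScheme
    from minidx.simulate import PangenomeSpec, simulate_pangenome

    docs, labels, _ = simulate_pangenome(
        PangenomeSpec(
            n_classes=1, strains_per_class=5, genome_length=5000,
            intra_class_divergence=0.01, seed=101,
        )
    )
    idx = build_index(
        docs, labels, scheme=MinimizerScheme(k=4, w=11),
        alphabet_mode="minimizer", doc_array=True,
        null_params={"n_reads": 500, "read_len": 2000, "seed": 101,
                     "min_count": 5},
    )
    return idx, docs, labels
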