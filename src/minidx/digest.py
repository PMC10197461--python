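"""Minimizer digestion of DNA sequences.

A minimizer scheme is parameterised by a small window size ``k`` and a large
window size ``w`` (``w > k``).  Sliding a length-``w`` window over a sequence,
the constituent k-mer with the minimal hash value is selected as the window's
minimizer; ties go to the leftmost k-mer.  The *digest* of a sequence is the
concatenation of the selected minimizers with runs of equal minimizers
collapsed to a single occurrence.  The digest may be expressed over the plain
DNA alphabet (each minimizer contributes its ``k`` bases) or over the
*minimizer alphabet*, where each of the :math:`4^k` possible k-mers is a
single symbol (256 symbols for ``k = 4``).

Digesting both the reference collection and the reads with the same scheme
shrinks the text handed to the compressed index while preserving long exact
matches, which is what the downstream matching-statistics machinery needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MinimizerScheme",
    "AlphabetSpec",
    "DigestSequence",
    "DNA_BASES",
    "DEFAULT_K",
    "DEFAULT_W",
    "DEFAULT_HASH_SEED",
    "kmer_hash",
    "window_minimizer",
    "digest_sequence",
    "encode_minimizer",
    "decode_minimizer",
    "encode_dna",
    "decode_dna",
    "reverse_complement",
]

DNA_BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ACGT_SEGMENT = re.compile(r"[ACGT]+")

DEFAULT_K = 4
DEFAULT_W = 11
# Fixed default seed so that digests (and therefore indexes) are reproducible
# across machines and runs.
DEFAULT_HASH_SEED = 0x5BD1E995

_U64 = np.uint64
_MASK64 = _U64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class MinimizerScheme:
    """Digestion parameters: k-mer size, window size, and hash seed."""

    k: int = DEFAULT_K
    w: int = DEFAULT_W
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.w <= self.k:
            raise ValueError(f"w must exceed k, got w={self.w}, k={self.k}")


@dataclass(frozen=True)
class AlphabetSpec:
    """Symbol space of a (possibly digested) text.

    ``mode`` is ``"dna"`` (4 nucleotide symbols) or ``"minimizer"`` (one
    symbol per possible k-mer, i.e. ``4**k`` symbols).
    """

    mode: str
    symbol_count: int

    @classmethod
    def dna(cls) -> "AlphabetSpec":
        return cls("dna", 4)

    @classmethod
    def minimizer(cls, k: int) -> "AlphabetSpec":
        return cls("minimizer", 4**k)

    def __post_init__(self) -> None:
        if self.mode not in ("dna", "minimizer"):
            raise ValueError(f"unknown alphabet mode {self.mode!r}")


@dataclass
class DigestSequence:
    """A digested (or plain-encoded) sequence of integer symbol codes."""

    symbols: np.ndarray
    source_length: int
    alphabet: AlphabetSpec
    scheme: Optional[MinimizerScheme] = field(default=None)

    def __len__(self) -> int:
        return int(self.symbols.size)


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer: a well-mixed bijection on 64-bit integers."""
    with np.errstate(over="ignore"):
        x = (x + _U64(0x9E3779B97F4A7C15)) & _MASK64
        x = x ^ (x >> _U64(30))
        x = (x * _U64(0xBF58476D1CE4E5B9)) & _MASK64
        x = x ^ (x >> _U64(27))
        x = (x * _U64(0x94D049BB133111EB)) & _MASK64
        x = x ^ (x >> _U64(31))
    return x


def _hash_codes(codes: np.ndarray, seed: int) -> np.ndarray:
    """Hash packed k-mer codes (vectorised)."""
    seeded = _mix64(np.asarray(_U64(seed & 0xFFFFFFFFFFFFFFFF)))
    return _mix64(codes.astype(_U64) ^ seeded)


def encode_dna(seq: str) -> np.ndarray:
    """Encode an ACGT string as base codes 0..3 (A=0, C=1, G=2, T=3).

    Raises ``ValueError`` on any other character.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    if (codes < 0).any():
        bad = chr(int(arr[codes < 0][0]))
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode_dna(codes: np.ndarray) -> str:
    return "".join(DNA_BASES[int(c)] for c in codes)


def encode_minimizer(kmer: str) -> int:
    """Pack a k-mer into its 2-bit code (bijective over the 4^k k-mers)."""
    code = 0
    for ch in kmer.upper():
        try:
            code = (code << 2) | _BASE_CODE[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer") from None
    return code


def decode_minimizer(code: int, k: int) -> str:
    out = []
    for shift in range((k - 1) * 2, -2, -2):
        out.append(DNA_BASES[(code >> shift) & 3])
    return "".join(out)


def kmer_hash(kmer: str, seed: int = DEFAULT_HASH_SEED) -> int:
    """Deterministic 64-bit hash of a k-mer; pure in (kmer, seed)."""
    code = encode_minimizer(kmer)
    return int(_hash_codes(np.asarray([code], dtype=_U64), seed)[0])


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit codes of every k-mer of a base-code array."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=_U64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(_U64)
    return (win.astype(_U64) * weights).sum(axis=1)


def window_minimizer(window: str, scheme: MinimizerScheme) -> tuple[str, int]:
    """Minimizer of a single length-``w`` window.

    Returns the k-mer with the minimal hash among the ``w - k + 1``
    constituent k-mers and its offset in the window; ties break to the
    leftmost offset.
    """
    if len(window) != scheme.w:
        raise ValueError(
            f"window length {len(window)} != scheme w {scheme.w}"
        )
    codes = encode_dna(window)
    hashes = _hash_codes(_kmer_codes(codes, scheme.k), scheme.hash_seed)
    off = int(np.argmin(hashes))  # argmin returns the leftmost minimum
    return window[off : off + scheme.k], off


def _digest_segment(codes: np.ndarray, scheme: MinimizerScheme) -> np.ndarray:
    """Minimizer codes (run-collapsed) of one ACGT-only segment."""
    k, w = scheme.k, scheme.w
    if codes.size < w:
        return np.empty(0, dtype=np.int64)
    kcodes = _kmer_codes(codes, k)
    hashes = _hash_codes(kcodes, scheme.hash_seed)
    # one minimizer per length-w window == per (w-k+1)-window of k-mer hashes
    hwin = np.lib.stride_tricks.sliding_window_view(hashes, w - k + 1)
    offs = np.argmin(hwin, axis=1)  # leftmost tie-break
    sel = kcodes[np.arange(offs.size) + offs].astype(np.int64)
    # collapse equal-minimizer runs (consecutive equal values → one symbol;
    # this also collapses repeated selections of the same occurrence)
    keep = np.empty(sel.size, dtype=bool)
    keep[0] = True
    keep[1:] = sel[1:] != sel[:-1]
    return sel[keep]


def digest_sequence(
    seq: str,
    scheme: MinimizerScheme,
    alphabet: AlphabetSpec,
) -> DigestSequence:
    """Digest a DNA sequence into minimizer symbols.

    The length-``w`` window slides one base at a time; each window's
    minimizer is appended only when it differs from the previously appended
    one.  Non-ACGT characters split the sequence into segments that are
    digested independently and concatenated.  Sequences shorter than ``w``
    yield an empty digest.

    Under the minimizer alphabet each selected k-mer becomes one symbol;
    under the DNA alphabet each contributes its ``k`` base codes.
    """
    pieces = [
        _digest_segment(encode_dna(m.group(0)), scheme)
        for m in _ACGT_SEGMENT.finditer(seq.upper())
    ]
    if pieces:
        mins = np.concatenate(pieces)
    else:
        mins = np.empty(0, dtype=np.int64)
    if alphabet.mode == "minimizer":
        symbols = mins
    else:
        # spell each minimizer back out as k DNA base codes
        if mins.size:
            shifts = np.arange(scheme.k - 1, -1, -1) * 2
            symbols = ((mins[:, None] >> shifts[None, :]) & 3).reshape(-1)
        else:
            symbols = np.empty(0, dtype=np.int64)
    return DigestSequence(
        symbols=symbols.astype(np.int64),
        source_length=len(seq),
        alphabet=alphabet,
        scheme=scheme,
    )


def encode_sequence(
    seq: str,
    scheme: Optional[MinimizerScheme],
    alphabet: AlphabetSpec,
    digest: bool = True,
) -> DigestSequence:
    """Encode a sequence the way an index expects: digested or plain DNA.

    With ``digest=False`` the sequence passes through as base codes
    (non-ACGT characters are dropped); otherwise it is minimizer-digested.
    """
    if digest:
        if scheme is None:
            raise ValueError("digestion requested but no scheme given")
        return digest_sequence(seq, scheme, alphabet)
    pieces = [
        encode_dna(m.group(0)) for m in _ACGT_SEGMENT.finditer(seq.upper())
    ]
    symbols = (
        np.concatenate(pieces) if pieces else np.empty(0, dtype=np.int64)
    )
    return DigestSequence(
        symbols=symbols, source_length=len(seq), alphabet=alphabet, scheme=None
    )
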