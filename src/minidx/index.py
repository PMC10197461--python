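"""Construction of the compressed index.

The index core is the run-length encoded Burrows–Wheeler transform (BWT) of
the concatenated document collection.  For a text ``T[0..n-1]``, ``BWT[i]``
is the character preceding the i-th lexicographically smallest suffix of
``T``; ``r`` denotes the number of maximal equal-character runs in the BWT
and governs index size (repetitive collections have ``n/r >> 1``).

On top of the run-length BWT the index carries:

* a *thresholds* table — for every gap between consecutive BWT runs of the
  same character, the row at which the preferred jump direction (up to the
  earlier run's last row vs. down to the later run's first row) flips.  The
  threshold sits at the leftmost minimum of the LCP array inside the gap, so
  a threshold-directed jump always lands on the boundary suffix sharing the
  longer prefix with the current match;
* an optional *sampled document array* — 2r class labels, recording the
  class of the suffix at the first and last row of every run, enough to
  emit a class label whenever a query jumps to a run boundary;
* optional suffix-array samples at run boundaries plus the text itself,
  needed only for exact matching statistics (second-pass length
  resolution).

Each document is terminated by its own sentinel; sentinels rank below every
data symbol and among themselves by document order, which makes the suffix
order (and hence the serialized index) fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .digest import (
    AlphabetSpec,
    DigestSequence,
    MinimizerScheme,
    encode_sequence,
    reverse_complement,
)

__all__ = [
    "ConcatenatedText",
    "RunLengthBWT",
    "ThresholdsTable",
    "SampledDocArray",
    "CompressedIndex",
    "IndexFormatError",
    "build_concat",
    "suffix_array",
    "bwt_from_sa",
    "lcp_from_sa",
    "run_length_encode",
    "build_thresholds",
    "build_sampled_doc_array",
    "build_index",
    "serialize",
    "deserialize",
]

FORMAT_MAGIC = "MINIDX"
FORMAT_VERSION = 1


class IndexFormatError(RuntimeError):
    """Raised when an on-disk index is missing, truncated, or mismatched."""


# ---------------------------------------------------------------------------
# concatenated text


@dataclass
class ConcatenatedText:
    """Documents concatenated with one sentinel each.

    Internal symbol codes: sentinel of document ``d`` is code ``d``
    (0 <= d < n_docs); data symbol ``s`` of the external alphabet becomes
    ``s + n_docs``.  Sentinels therefore rank below all data symbols and
    among themselves by document order.
    """

    symbols: np.ndarray
    doc_boundaries: np.ndarray  # start offset of each document
    doc_labels: np.ndarray  # class id per document
    n_docs: int
    sigma: int  # external (non-sentinel) alphabet size

    @property
    def n(self) -> int:
        return int(self.symbols.size)

    def doc_of(self, pos: int) -> int:
        """Document index containing text offset ``pos``."""
        return int(np.searchsorted(self.doc_boundaries, pos, side="right")) - 1


def build_concat(
    documents: Sequence[np.ndarray | DigestSequence],
    labels: Sequence[int],
    sigma: int,
) -> ConcatenatedText:
    """Concatenate documents, appending one sentinel per document."""
    if len(documents) != len(labels):
        raise ValueError("documents and labels differ in length")
    if not documents:
        raise ValueError("need at least one document")
    d = len(documents)
    parts = []
    boundaries = []
    offset = 0
    for i, doc in enumerate(documents):
        syms = doc.symbols if isinstance(doc, DigestSequence) else np.asarray(doc)
        syms = syms.astype(np.int64)
        if syms.size == 0:
            raise ValueError(f"document {i} is empty")
        if syms.min() < 0 or syms.max() >= sigma:
            raise ValueError(f"document {i} has symbols outside alphabet 0..{sigma-1}")
        boundaries.append(offset)
        parts.append(syms + d)
        parts.append(np.asarray([i], dtype=np.int64))
        offset += syms.size + 1
    return ConcatenatedText(
        symbols=np.concatenate(parts),
        doc_boundaries=np.asarray(boundaries, dtype=np.int64),
        doc_labels=np.asarray(labels, dtype=np.int64),
        n_docs=d,
        sigma=sigma,
    )


# ---------------------------------------------------------------------------
# suffix array / BWT / LCP


def suffix_array(symbols: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers) with numpy sorts.

    O(n log n) sorts of O(n log n) total work; exact lexicographic order
    over arbitrary integer alphabets.  Positions past the end compare
    smaller than any symbol, which is the standard convention and is
    unambiguous here because every document ends in a unique sentinel.
    """
    t = np.asarray(symbols, dtype=np.int64)
    n = t.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    _, rank = np.unique(t, return_inverse=True)
    rank = rank.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while rank[sa[-1]] != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        if k < n:
            second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        r0, r1 = rank[sa], second[sa]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r0[1:] != r0[:-1]) | (r1[1:] != r1[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed)
        rank = new_rank
        k *= 2
    return sa.astype(np.int64)


def bwt_from_sa(symbols: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """``BWT[i] = T[sa[i] - 1]``, wrapping to the final symbol at sa[i]=0."""
    t = np.asarray(symbols, dtype=np.int64)
    return t[(np.asarray(sa) - 1) % t.size]


def lcp_from_sa(symbols: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array by Kasai's algorithm; ``lcp[i] = lcp(T[sa[i-1]..], T[sa[i]..])``."""
    t = np.asarray(symbols, dtype=np.int64).tolist()
    n = len(t)
    sa_l = np.asarray(sa).tolist()
    rank = [0] * n
    for i, s in enumerate(sa_l):
        rank[s] = i
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return np.asarray(lcp, dtype=np.int64)


# ---------------------------------------------------------------------------
# run-length BWT


@dataclass
class RunLengthBWT:
    """Run-length encoded BWT with the bookkeeping needed for LF steps."""

    run_chars: np.ndarray  # internal symbol code per run
    run_lengths: np.ndarray
    run_starts: np.ndarray  # BWT offset of each run start
    char_counts: np.ndarray  # C array: #symbols with code < c (len = codes+1)
    occ_before: np.ndarray  # per run: #occurrences of its char in earlier runs

    @property
    def r(self) -> int:
        return int(self.run_chars.size)

    @property
    def n(self) -> int:
        return int(self.run_lengths.sum())

    def decode(self) -> np.ndarray:
        return np.repeat(self.run_chars, self.run_lengths)


def run_length_encode(bwt: np.ndarray) -> RunLengthBWT:
    """Maximal equal-character runs of the BWT plus rank scaffolding."""
    bwt = np.asarray(bwt, dtype=np.int64)
    n = bwt.size
    if n == 0:
        raise ValueError("empty BWT")
    edge = np.empty(n, dtype=bool)
    edge[0] = True
    edge[1:] = bwt[1:] != bwt[:-1]
    run_starts = np.flatnonzero(edge).astype(np.int64)
    run_chars = bwt[run_starts]
    run_lengths = np.diff(np.append(run_starts, n)).astype(np.int64)

    n_codes = int(bwt.max()) + 1
    totals = np.bincount(bwt, minlength=n_codes).astype(np.int64)
    char_counts = np.zeros(n_codes + 1, dtype=np.int64)
    char_counts[1:] = np.cumsum(totals)

    occ_before = np.zeros(run_chars.size, dtype=np.int64)
    seen: dict[int, int] = {}
    rc = run_chars.tolist()
    rl = run_lengths.tolist()
    for j, (c, ln) in enumerate(zip(rc, rl)):
        occ_before[j] = seen.get(c, 0)
        seen[c] = seen.get(c, 0) + ln
    return RunLengthBWT(run_chars, run_lengths, run_starts, char_counts, occ_before)


# ---------------------------------------------------------------------------
# thresholds


@dataclass
class ThresholdsTable:
    """Per-character jump thresholds between consecutive same-character runs.

    For character ``c`` with runs at (BWT-row) boundaries
    ``(s_0, e_0), (s_1, e_1), ...``, ``thresholds[c][i]`` is the row of the
    leftmost minimum of the LCP array in ``(e_i, s_{i+1}]``.  A query at row
    ``q`` strictly above the threshold jumps up to ``e_i``; at or below it
    jumps down to ``s_{i+1}``.
    """

    by_char: dict[int, np.ndarray] = field(default_factory=dict)

    def flatten(self, run_chars: np.ndarray) -> np.ndarray:
        """Thresholds in canonical order (chars ascending) for serialization."""
        chunks = [
            self.by_char[c]
            for c in sorted(set(run_chars.tolist()))
            if c in self.by_char
        ]
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(chunks).astype(np.int64)

    @classmethod
    def unflatten(cls, flat: np.ndarray, run_chars: np.ndarray) -> "ThresholdsTable":
        counts: dict[int, int] = {}
        for c in run_chars.tolist():
            counts[c] = counts.get(c, 0) + 1
        table = cls()
        pos = 0
        for c in sorted(counts):
            m = counts[c]
            if m >= 2:
                table.by_char[c] = np.asarray(flat[pos : pos + m - 1], dtype=np.int64)
                pos += m - 1
        if pos != len(flat):
            raise IndexFormatError("thresholds array length inconsistent with runs")
        return table


def build_thresholds(rlbwt: RunLengthBWT, lcp: np.ndarray) -> ThresholdsTable:
    """Thresholds from the LCP array.

    A character appearing in a single run needs no threshold (the jump
    direction is forced).
    """
    lcp = np.asarray(lcp, dtype=np.int64)
    run_ends = rlbwt.run_starts + rlbwt.run_lengths - 1
    by_run: dict[int, list[int]] = {}
    for j, c in enumerate(rlbwt.run_chars.tolist()):
        by_run.setdefault(c, []).append(j)
    table = ThresholdsTable()
    for c, runs in by_run.items():
        if len(runs) < 2:
            continue
        thr = np.empty(len(runs) - 1, dtype=np.int64)
        for i in range(len(runs) - 1):
            e = int(run_ends[runs[i]])
            s = int(rlbwt.run_starts[runs[i + 1]])
            seg = lcp[e + 1 : s + 1]
            thr[i] = e + 1 + int(np.argmin(seg))  # leftmost minimum
        table.by_char[c] = thr
    return table


# ---------------------------------------------------------------------------
# sampled document array


@dataclass
class SampledDocArray:
    """Class labels of the suffixes at the first and last row of every run.

    2r entries total; each entry is a class id in ``0..n_classes-1`` and
    information-theoretically needs only ``ceil(log2 c)`` bits.
    """

    first_labels: np.ndarray
    last_labels: np.ndarray
    n_classes: int

    @property
    def bits_per_entry(self) -> int:
        return max(1, int(np.ceil(np.log2(max(self.n_classes, 2)))))


def build_sampled_doc_array(
    sa: np.ndarray, rlbwt: RunLengthBWT, text: ConcatenatedText
) -> SampledDocArray:
    """Labels at run boundaries, looked up through the suffix array."""
    sa = np.asarray(sa)
    starts = rlbwt.run_starts
    ends = starts + rlbwt.run_lengths - 1
    docs_first = np.searchsorted(text.doc_boundaries, sa[starts], side="right") - 1
    docs_last = np.searchsorted(text.doc_boundaries, sa[ends], side="right") - 1
    n_classes = int(text.doc_labels.max()) + 1 if text.doc_labels.size else 1
    return SampledDocArray(
        first_labels=text.doc_labels[docs_first].astype(np.int64),
        last_labels=text.doc_labels[docs_last].astype(np.int64),
        n_classes=n_classes,
    )


# ---------------------------------------------------------------------------
# the bundled index


@dataclass
class CompressedIndex:
    """Everything needed to stream pseudomatching lengths against the text."""

    scheme: Optional[MinimizerScheme]
    alphabet: AlphabetSpec
    digest_enabled: bool
    n_docs: int
    sigma: int
    rlbwt: RunLengthBWT
    thresholds: ThresholdsTable
    doc_array: Optional[SampledDocArray] = None
    sa_run_starts: Optional[np.ndarray] = None  # SA samples (MS mode only)
    sa_run_ends: Optional[np.ndarray] = None
    text: Optional[np.ndarray] = None  # internal codes (MS mode only)
    null_threshold: Optional[int] = None
    null_counts: Optional[dict[int, int]] = None
    null_params: Optional[dict] = None
    class_names: Optional[list[str]] = None

    # query-time scaffolding, built lazily (see query module)
    _qcache: Optional[dict] = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.rlbwt.n

    @property
    def r(self) -> int:
        return self.rlbwt.r

    @property
    def ms_support(self) -> bool:
        return self.text is not None and self.sa_run_starts is not None

    def encode_read(self, seq: str) -> DigestSequence:
        """Encode a read exactly the way the indexed documents were."""
        return encode_sequence(
            seq, self.scheme, self.alphabet, digest=self.digest_enabled
        )

    def component_sizes(self) -> dict[str, int]:
        """Serialized byte count per component (in-memory nbytes)."""
        sizes = {
            "run_chars": self.rlbwt.run_chars.astype(np.uint32).nbytes,
            "run_lengths": self.rlbwt.run_lengths.nbytes,
            "thresholds": self.thresholds.flatten(self.rlbwt.run_chars).nbytes,
        }
        if self.doc_array is not None:
            labels = np.concatenate(
                [self.doc_array.first_labels, self.doc_array.last_labels]
            )
            sizes["doc_array"] = labels.astype(_label_dtype(self.doc_array.n_classes)).nbytes
        if self.ms_support:
            sizes["sa_samples"] = self.sa_run_starts.nbytes + self.sa_run_ends.nbytes
            sizes["text"] = self.text.nbytes
        return sizes


def _label_dtype(n_classes: int):
    if n_classes <= 256:
        return np.uint8
    if n_classes <= 65536:
        return np.uint16
    return np.uint32


def build_index(
    documents: Sequence[str],
    labels: Sequence[int],
    scheme: Optional[MinimizerScheme] = None,
    alphabet_mode: str = "minimizer",
    digest: bool = True,
    add_revcomp: bool = True,
    doc_array: bool = False,
    ms_support: bool = False,
    null_params: Optional[dict] = None,
    class_names: Optional[list[str]] = None,
) -> CompressedIndex:
    """Build the full index from raw DNA documents.

    ``documents`` are DNA strings with class ids ``labels`` (one per
    document).  With ``add_revcomp`` (the default) the reverse complement of
    every document is added as a document of the same class before
    digestion, so reads can be queried in their given orientation.

    ``null_params`` — dict with keys ``n_reads``, ``read_len``, ``seed``,
    ``min_count`` — triggers computation of the null-PML classification
    threshold at build time (stored in the bundle).
    """
    if digest and scheme is None:
        scheme = MinimizerScheme()
    if alphabet_mode == "minimizer":
        if not digest:
            raise ValueError("minimizer alphabet requires digestion")
        alphabet = AlphabetSpec.minimizer(scheme.k)
    else:
        alphabet = AlphabetSpec.dna()

    seqs = list(documents)
    labs = list(labels)
    if add_revcomp:
        seqs = seqs + [reverse_complement(s) for s in documents]
        labs = labs + list(labels)

    encoded = [
        encode_sequence(s, scheme, alphabet, digest=digest) for s in seqs
    ]
    text = build_concat(encoded, labs, sigma=alphabet.symbol_count)
    sa = suffix_array(text.symbols)
    bwt = bwt_from_sa(text.symbols, sa)
    rlbwt = run_length_encode(bwt)
    lcp = lcp_from_sa(text.symbols, sa)
    thresholds = build_thresholds(rlbwt, lcp)
    sda = build_sampled_doc_array(sa, rlbwt, text) if doc_array else None

    idx = CompressedIndex(
        scheme=scheme if digest else None,
        alphabet=alphabet,
        digest_enabled=digest,
        n_docs=text.n_docs,
        sigma=alphabet.symbol_count,
        rlbwt=rlbwt,
        thresholds=thresholds,
        doc_array=sda,
        class_names=class_names,
    )
    if ms_support:
        ends = rlbwt.run_starts + rlbwt.run_lengths - 1
        idx.sa_run_starts = sa[rlbwt.run_starts].astype(np.int64)
        idx.sa_run_ends = sa[ends].astype(np.int64)
        idx.text = text.symbols.astype(np.int64)

    if null_params is not None:
        from .classify import compute_threshold, sample_null_pmls

        null = sample_null_pmls(
            idx,
            documents,
            n_reads=null_params.get("n_reads", 500),
            read_len=null_params.get("read_len", 2000),
            seed=null_params.get("seed", 1),
        )
        thr = compute_threshold(null, min_count=null_params.get("min_count", 5))
        idx.null_threshold = thr.value
        idx.null_counts = dict(null.counts)
        idx.null_params = {
            "n_reads": null.n_reads,
            "read_len": null.read_len,
            "seed": null.seed,
            "min_count": thr.min_count,
        }
    return idx


# ---------------------------------------------------------------------------
# serialization


_ARRAYS = {
    "run_chars.npy": ("rlbwt", "run_chars", np.int64),
    "run_lengths.npy": ("rlbwt", "run_lengths", np.int64),
}


def serialize(index: CompressedIndex, path: str | Path) -> Path:
    """Write the index as a directory: text header + little-endian arrays.

    Rebuilding from the same inputs and seed produces byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    hdr = {
        "magic": FORMAT_MAGIC,
        "version": FORMAT_VERSION,
        "alphabet": index.alphabet.mode,
        "sigma": index.sigma,
        "digest": int(index.digest_enabled),
        "k": index.scheme.k if index.scheme else "",
        "w": index.scheme.w if index.scheme else "",
        "hash_seed": index.scheme.hash_seed if index.scheme else "",
        "n_docs": index.n_docs,
        "n": index.n,
        "r": index.r,
        "doc_array": int(index.doc_array is not None),
        "n_classes": index.doc_array.n_classes if index.doc_array else "",
        "ms_support": int(index.ms_support),
        "null_threshold": (
            index.null_threshold if index.null_threshold is not None else ""
        ),
    }
    with open(path / "header.txt", "w") as fh:
        for key, val in hdr.items():
            fh.write(f"{key}={val}\n")
    np.save(path / "run_chars.npy", index.rlbwt.run_chars.astype("<i8"))
    np.save(path / "run_lengths.npy", index.rlbwt.run_lengths.astype("<i8"))
    np.save(
        path / "thresholds.npy",
        index.thresholds.flatten(index.rlbwt.run_chars).astype("<i8"),
    )
    if index.doc_array is not None:
        dt = _label_dtype(index.doc_array.n_classes)
        np.save(path / "doc_first.npy", index.doc_array.first_labels.astype(dt))
        np.save(path / "doc_last.npy", index.doc_array.last_labels.astype(dt))
    if index.ms_support:
        np.save(path / "sa_run_starts.npy", index.sa_run_starts.astype("<i8"))
        np.save(path / "sa_run_ends.npy", index.sa_run_ends.astype("<i8"))
        np.save(path / "text.npy", index.text.astype("<i8"))
    meta = {}
    if index.null_counts is not None:
        meta["null_counts"] = {str(k): v for k, v in sorted(index.null_counts.items())}
    if index.null_params is not None:
        meta["null_params"] = index.null_params
    if index.class_names is not None:
        meta["class_names"] = index.class_names
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=0)
    return path


def _load_array(path: Path, name: str) -> np.ndarray:
    fp = path / name
    if not fp.exists():
        raise IndexFormatError(f"missing index component {name} in {path}")
    try:
        return np.load(fp)
    except Exception as exc:  # truncated / corrupt file
        raise IndexFormatError(f"corrupt index component {name}: {exc}") from exc


def deserialize(path: str | Path) -> CompressedIndex:
    """Load an index directory written by :func:`serialize`."""
    path = Path(path)
    hdr_path = path / "header.txt"
    if not hdr_path.exists():
        raise IndexFormatError(f"no index header at {hdr_path}")
    hdr: dict[str, str] = {}
    for line in hdr_path.read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            hdr[key] = val
    if hdr.get("magic") != FORMAT_MAGIC:
        raise IndexFormatError(
            f"bad magic: expected {FORMAT_MAGIC!r}, found {hdr.get('magic')!r}"
        )
    if int(hdr.get("version", -1)) != FORMAT_VERSION:
        raise IndexFormatError(
            f"unsupported version: expected {FORMAT_VERSION}, "
            f"found {hdr.get('version')!r}"
        )
    digest = bool(int(hdr["digest"]))
    scheme = (
        MinimizerScheme(int(hdr["k"]), int(hdr["w"]), int(hdr["hash_seed"]))
        if digest
        else None
    )
    alphabet = (
        AlphabetSpec.minimizer(scheme.k)
        if hdr["alphabet"] == "minimizer"
        else AlphabetSpec.dna()
    )
    run_chars = _load_array(path, "run_chars.npy").astype(np.int64)
    run_lengths = _load_array(path, "run_lengths.npy").astype(np.int64)
    bwt = np.repeat(run_chars, run_lengths)
    rlbwt = run_length_encode(bwt)
    thresholds = ThresholdsTable.unflatten(
        _load_array(path, "thresholds.npy").astype(np.int64), run_chars
    )
    idx = CompressedIndex(
        scheme=scheme,
        alphabet=alphabet,
        digest_enabled=digest,
        n_docs=int(hdr["n_docs"]),
        sigma=int(hdr["sigma"]),
        rlbwt=rlbwt,
        thresholds=thresholds,
    )
    if int(hdr.get("doc_array", 0)):
        idx.doc_array = SampledDocArray(
            first_labels=_load_array(path, "doc_first.npy").astype(np.int64),
            last_labels=_load_array(path, "doc_last.npy").astype(np.int64),
            n_classes=int(hdr["n_classes"]),
        )
    if int(hdr.get("ms_support", 0)):
        idx.sa_run_starts = _load_array(path, "sa_run_starts.npy").astype(np.int64)
        idx.sa_run_ends = _load_array(path, "sa_run_ends.npy").astype(np.int64)
        idx.text = _load_array(path, "text.npy").astype(np.int64)
    if hdr.get("null_threshold", "") != "":
        idx.null_threshold = int(hdr["null_threshold"])
    meta_path = path / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if "null_counts" in meta:
            idx.null_counts = {int(k): v for k, v in meta["null_counts"].items()}
        if "null_params" in meta:
            idx.null_params = meta["null_params"]
        if "class_names" in meta:
            idx.class_names = meta["class_names"]
    if int(hdr["n"]) != idx.n or int(hdr["r"]) != idx.r:
        raise IndexFormatError(
            f"header n/r ({hdr['n']}/{hdr['r']}) disagree with arrays "
            f"({idx.n}/{idx.r})"
        )
    return idx
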