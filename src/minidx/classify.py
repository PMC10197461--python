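"""Read classification on top of pseudomatching lengths.

The binary decision rule works as follows.  At build time, "null" reads —
substrings of the reference, *character-reversed* (not reverse
complemented), so they keep the base composition but share no real
homology — are pushed through the same digestion and PML machinery as real
reads.  The classification threshold is the largest null PML occurring at
least ``min_count`` (default 5) times.  At query time a read's PML vector
is cut into non-overlapping windows of 150 symbols (a trailing short
window merges into the previous one); a window is "above" when its maximum
PML strictly exceeds the threshold, and the read is called *present* when
strictly more than half of its windows are above.

Multi-class calls aggregate the class labels the sampled document array
emits along the read and take the plurality class.  The contamination scan
flags assembly contigs whose 25th-percentile PML against a contaminant
index is 2 or greater.  The adaptive-sampling driver replays the binary
rule on growing read prefixes delivered in 180 bp batches (up to 4),
ejecting at the first *present* verdict.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .index import CompressedIndex
from .query import NO_LABEL, compute_pmls

__all__ = [
    "NullDistribution",
    "ClassificationThreshold",
    "ReadCall",
    "MultiClassCall",
    "ContigReport",
    "AdaptiveTrace",
    "sample_null_pmls",
    "compute_threshold",
    "classify_read",
    "classify_multiclass",
    "contamination_scan",
    "adaptive_batches",
]

DEFAULT_WINDOW = 150
DEFAULT_MIN_COUNT = 5
DEFAULT_NULL_READS = 500
DEFAULT_NULL_READ_LEN = 2000
DEFAULT_BATCH_BASES = 180
DEFAULT_MAX_BATCHES = 4


@dataclass
class NullDistribution:
    """Pooled frequencies of null (reversed-substring) PML values."""

    counts: dict[int, int]
    n_reads: int
    read_len: int
    seed: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ClassificationThreshold:
    """Largest null PML occurring at least ``min_count`` times (0 if none)."""

    value: int
    min_count: int = DEFAULT_MIN_COUNT


@dataclass
class ReadCall:
    read_id: str
    present: bool
    windows_total: int
    windows_above: int
    window_max_pmls: list[int] = field(default_factory=list)

    @property
    def max_pml(self) -> int:
        return max(self.window_max_pmls) if self.window_max_pmls else 0


@dataclass
class MultiClassCall:
    read_id: str
    called_class: Optional[int]  # None when no label was ever emitted
    fractions: dict[int, float]
    tie: bool = False

    @property
    def called_fraction(self) -> float:
        if self.called_class is None:
            return 0.0
        return self.fractions.get(self.called_class, 0.0)


@dataclass
class ContigReport:
    contig_id: str
    p25_pml: Optional[float]  # None when the contig digests to nothing
    suspicious: bool
    n_symbols: int = 0


@dataclass
class AdaptiveTrace:
    read_id: str
    verdicts: list[bool]
    decision: str  # "eject" | "retain"
    decision_batch: Optional[int]  # 1-based batch of ejection, None if retained


def sample_null_pmls(
    index: CompressedIndex,
    documents: Sequence[str],
    n_reads: int = DEFAULT_NULL_READS,
    read_len: int = DEFAULT_NULL_READ_LEN,
    seed: int = 1,
) -> NullDistribution:
    """Null PML distribution from reversed reference substrings.

    Substring start positions are drawn uniformly over the pooled bases of
    the original (pre-digest) documents; each substring is character-
    reversed and then digested and queried exactly like a real read.
    Documents shorter than ``read_len`` contribute correspondingly shorter
    substrings (with a warning).
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.asarray([len(d) for d in documents], dtype=np.float64)
    probs = lengths / lengths.sum()
    counts: Counter[int] = Counter()
    warned = False
    for _ in range(n_reads):
        di = int(rng.choice(len(documents), p=probs))
        doc = documents[di]
        ln = read_len
        if len(doc) < read_len:
            if not warned:
                warnings.warn(
                    f"reference document shorter than null read length "
                    f"{read_len}; using whole document"
                )
                warned = True
            ln = len(doc)
        start = int(rng.integers(0, len(doc) - ln + 1))
        null_read = doc[start : start + ln][::-1]  # reverse, not revcomp
        enc = index.encode_read(null_read)
        pmls, _, _ = compute_pmls(enc, index)
        counts.update(int(v) for v in pmls)
    return NullDistribution(
        counts=dict(counts), n_reads=n_reads, read_len=read_len, seed=seed
    )


def compute_threshold(
    null: NullDistribution, min_count: int = DEFAULT_MIN_COUNT
) -> ClassificationThreshold:
    """max{v : counts[v] >= min_count}, or 0 when no value qualifies."""
    if not null.counts:
        raise ValueError("empty null distribution")
    qualifying = [v for v, c in null.counts.items() if c >= min_count]
    return ClassificationThreshold(
        value=max(qualifying) if qualifying else 0, min_count=min_count
    )


def _windows(m: int, window: int) -> list[tuple[int, int]]:
    """Window boundaries: full windows from the left, trailing short window
    merged into the previous one; a read shorter than one window is a
    single window."""
    n_win = max(1, m // window)
    spans = []
    for i in range(n_win):
        lo = i * window
        hi = (i + 1) * window if i < n_win - 1 else m
        spans.append((lo, hi))
    return spans


def classify_read(
    pmls: np.ndarray | Sequence[int],
    threshold: ClassificationThreshold | int,
    window: int = DEFAULT_WINDOW,
    read_id: str = "",
) -> ReadCall:
    """Windowed majority rule over PML maxima.

    A window is above iff its maximum PML strictly exceeds the threshold;
    the read is *present* iff strictly more than half the windows are
    above.
    """
    thr = threshold.value if isinstance(threshold, ClassificationThreshold) else int(threshold)
    vals = np.asarray(pmls, dtype=np.int64)
    if vals.size == 0:
        return ReadCall(read_id, False, 0, 0, [])
    spans = _windows(int(vals.size), window)
    maxima = [int(vals[lo:hi].max()) for lo, hi in spans]
    above = sum(1 for mx in maxima if mx > thr)
    present = above > len(spans) / 2
    return ReadCall(read_id, present, len(spans), above, maxima)


def classify_multiclass(
    ca: np.ndarray | Sequence[int],
    read_id: str = "",
) -> MultiClassCall:
    """Plurality vote over the emitted class labels.

    Labels equal to ``NO_LABEL`` (positions before the first case-2 event)
    are excluded; ties break to the smallest class id and are flagged.
    """
    labels = [int(v) for v in ca if int(v) != NO_LABEL]
    if not labels:
        return MultiClassCall(read_id, None, {}, tie=False)
    counts = Counter(labels)
    total = len(labels)
    fractions = {c: k / total for c, k in sorted(counts.items())}
    best = max(counts.values())
    winners = sorted(c for c, k in counts.items() if k == best)
    return MultiClassCall(
        read_id, winners[0], fractions, tie=len(winners) > 1
    )


def contamination_scan(
    contigs: Sequence[tuple[str, str]],
    index: CompressedIndex,
    percentile: float = 25.0,
    cutoff: float = 2.0,
) -> list[ContigReport]:
    """Flag contigs whose PML distribution is shifted high.

    Each contig is digested and queried as one long read; the contig is
    *suspicious* iff the ``percentile``-th percentile of its PMLs is at
    least ``cutoff`` (inclusive).  Contigs shorter than the digestion
    window yield a no-data report.
    """
    reports = []
    for cid, seq in contigs:
        enc = index.encode_read(seq)
        if len(enc) == 0:
            reports.append(ContigReport(cid, None, False, 0))
            continue
        pmls, _, _ = compute_pmls(enc, index)
        p = float(np.percentile(pmls, percentile))
        reports.append(ContigReport(cid, p, p >= cutoff, int(pmls.size)))
    return reports


def adaptive_batches(
    read_seq: str,
    index: CompressedIndex,
    threshold: ClassificationThreshold | int,
    batch_bases: int = DEFAULT_BATCH_BASES,
    max_batches: int = DEFAULT_MAX_BATCHES,
    window: int = DEFAULT_WINDOW,
    read_id: str = "",
) -> AdaptiveTrace:
    """Simulated adaptive-sampling decision over successive read prefixes.

    After each accumulated prefix of ``b * batch_bases`` bases
    (b = 1..max_batches) the binary rule runs on the prefix's PMLs; the
    first *present* verdict ejects the read at that batch, otherwise the
    read is retained.  PMLs are recomputed on the accumulated prefix at
    each batch: batches arrive at the left-to-right front of the read while
    the matcher consumes symbols right-to-left, so exact splicing is not
    available in this direction (the pause/resume API covers callers that
    extend leftwards).
    """
    verdicts: list[bool] = []
    for b in range(1, max_batches + 1):
        prefix = read_seq[: b * batch_bases]
        enc = index.encode_read(prefix)
        pmls, _, _ = compute_pmls(enc, index)
        call = classify_read(pmls, threshold, window=window, read_id=read_id)
        verdicts.append(call.present)
        if call.present:
            return AdaptiveTrace(read_id, verdicts, "eject", b)
        if len(prefix) >= len(read_seq):
            break  # whole read examined
    return AdaptiveTrace(read_id, verdicts, "retain", None)
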