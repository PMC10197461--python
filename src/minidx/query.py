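"""Streaming matching against the compressed index.

The engine walks a read right-to-left through the run-length BWT using the
LF mapping.  At each step with next read character ``c`` and current row
``q`` one of two things happens:

* **case 1** — ``BWT[q] == c``: the match extends; the length counter goes
  up by one and the walk takes one LF step;
* **case 2** — ``BWT[q] != c``: the walk jumps, guided by the thresholds
  table, to the nearer boundary (last row of the previous ``c``-run or
  first row of the next ``c``-run) that preserves the longer match; the
  length counter resets to 0 and — when a sampled document array is
  present — the class label stored at that boundary is recorded.

The per-position values of the length counter are the *pseudomatching
lengths* (PMLs); they are upper-bounded by the exact matching statistics
(MS), which a second pass can recover exactly when the index keeps
suffix-array samples at run boundaries plus the text (``ms_support``).

State is a tiny serializable tuple, so matching can pause after a batch of
symbols and resume when the next batch arrives.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .digest import DigestSequence
from .index import CompressedIndex

__all__ = ["MatchState", "lf_map", "compute_pmls", "compute_ms", "resume"]

NO_LABEL = -1  # class label sentinel: no case-2 event observed yet


@dataclass
class MatchState:
    """Pause/resume state of the right-to-left PML walk."""

    row: int = 0
    length: int = 0
    last_label: int = NO_LABEL
    consumed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "row": self.row,
                "length": self.length,
                "last_label": self.last_label,
                "consumed": self.consumed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MatchState":
        return cls(**json.loads(text))


def _query_tables(index: CompressedIndex) -> dict:
    """Python-native lookup tables for the hot query loop (cached)."""
    if index._qcache is not None:
        return index._qcache
    rl = index.rlbwt
    run_starts = rl.run_starts.tolist()
    run_chars = rl.run_chars.tolist()
    run_lengths = rl.run_lengths.tolist()
    occ_before = rl.occ_before.tolist()
    cc = rl.char_counts.tolist()
    n_codes = len(cc) - 1
    run_ends = [s + l - 1 for s, l in zip(run_starts, run_lengths)]

    by_char: dict[int, dict] = {}
    for j, c in enumerate(run_chars):
        entry = by_char.setdefault(
            c, {"runs": [], "starts": [], "ends": []}
        )
        entry["runs"].append(j)
        entry["starts"].append(run_starts[j])
        entry["ends"].append(run_ends[j])
    for c, entry in by_char.items():
        thr = index.thresholds.by_char.get(c)
        entry["thr"] = thr.tolist() if thr is not None else []

    if index.doc_array is not None:
        first_labels = index.doc_array.first_labels.tolist()
        last_labels = index.doc_array.last_labels.tolist()
    else:
        first_labels = last_labels = None

    index._qcache = {
        "run_starts": run_starts,
        "run_chars": run_chars,
        "run_ends": run_ends,
        "occ_before": occ_before,
        "C": cc,
        "n_codes": n_codes,
        "by_char": by_char,
        "first_labels": first_labels,
        "last_labels": last_labels,
        "n": rl.n,
        "offset": index.n_docs,  # internal code = external symbol + n_docs
    }
    return index._qcache


def _run_of(tables: dict, row: int) -> int:
    return bisect_right(tables["run_starts"], row) - 1


def _lf(tables: dict, row: int, run: int) -> int:
    c = tables["run_chars"][run]
    return (
        tables["C"][c]
        + tables["occ_before"][run]
        + (row - tables["run_starts"][run])
    )


def lf_map(index: CompressedIndex, row: int) -> int:
    """The LF mapping: row of the suffix one character longer."""
    tables = _query_tables(index)
    if not (0 <= row < tables["n"]):
        raise ValueError(f"row {row} outside 0..{tables['n'] - 1}")
    return _lf(tables, row, _run_of(tables, row))


def _jump(tables: dict, row: int, c: int):
    """Threshold-directed jump to the nearest preferred ``c``-run boundary.

    Returns ``(boundary_row, run_index, is_run_start)``; the caller is at a
    row whose BWT character differs from ``c``.
    """
    entry = tables["by_char"][c]
    starts = entry["starts"]
    idx = bisect_left(starts, row)  # runs[:idx] lie above (smaller rows)
    if idx == 0:
        j = entry["runs"][0]
        return starts[0], j, True  # jump down to the first c-run
    if idx == len(starts):
        j = entry["runs"][-1]
        return entry["ends"][-1], j, False  # jump up to the last c-run
    if row < entry["thr"][idx - 1]:
        j = entry["runs"][idx - 1]
        return entry["ends"][idx - 1], j, False  # up
    j = entry["runs"][idx]
    return starts[idx], j, True  # down


def _symbols_of(read) -> list[int]:
    if isinstance(read, DigestSequence):
        return read.symbols.tolist()
    return list(int(s) for s in read)


def compute_pmls(
    read: DigestSequence | Sequence[int],
    index: CompressedIndex,
    state: Optional[MatchState] = None,
) -> tuple[np.ndarray, np.ndarray, MatchState]:
    """Pseudomatching lengths (and class labels) of a read.

    ``read`` holds external symbol codes in left-to-right order; processing
    runs right-to-left and the returned vectors are re-reported
    left-to-right.  A case-2 jump emits PML 0 at the jump position; the
    matched character at the jumped-to boundary contributes to the next
    (leftward) position's increment.  Symbols absent from the index
    entirely emit PML 0 and leave the row unchanged.

    When the index carries a sampled document array, the class vector holds
    the boundary label recorded at the most recent case-2 event
    (``NO_LABEL`` before the first one); otherwise it is all ``NO_LABEL``.

    Passing the returned state back in with an earlier (left-adjacent)
    chunk of the same read continues the walk exactly where it stopped.
    """
    tables = _query_tables(index)
    offset = tables["offset"]
    by_char = tables["by_char"]
    run_chars = tables["run_chars"]
    first_labels = tables["first_labels"]
    last_labels = tables["last_labels"]
    has_labels = first_labels is not None

    if state is None:
        state = MatchState()
    row = state.row
    length = state.length
    last_label = state.last_label

    symbols = _symbols_of(read)
    pmls: list[int] = []
    labels: list[int] = []
    for sym in reversed(symbols):
        c = sym + offset
        entry = by_char.get(c)
        if entry is None:
            # symbol never occurs in the index: universal mismatch
            length = 0
            pmls.append(0)
            labels.append(last_label)
            continue
        run = _run_of(tables, row)
        if run_chars[run] == c:
            length += 1
            pmls.append(length)
            labels.append(last_label)
            row = _lf(tables, row, run)
        else:
            brow, brun, is_start = _jump(tables, row, c)
            length = 0
            pmls.append(0)
            if has_labels:
                last_label = (
                    first_labels[brun] if is_start else last_labels[brun]
                )
            labels.append(last_label)
            row = _lf(tables, brow, brun)

    new_state = MatchState(
        row=row,
        length=length,
        last_label=last_label,
        consumed=state.consumed + len(symbols),
    )
    return (
        np.asarray(pmls[::-1], dtype=np.int64),
        np.asarray(labels[::-1], dtype=np.int64),
        new_state,
    )


def resume(
    state: MatchState,
    additional: DigestSequence | Sequence[int],
    index: CompressedIndex,
) -> tuple[np.ndarray, np.ndarray, MatchState]:
    """Continue a paused walk with the chunk immediately to the left.

    Output over the concatenation of chunks (later chunks first) is
    identical to a single :func:`compute_pmls` call on the whole read.
    """
    return compute_pmls(additional, index, state=state)


def compute_ms(
    read: DigestSequence | Sequence[int],
    index: CompressedIndex,
) -> np.ndarray:
    """Exact matching statistics via the two-pass algorithm.

    ``MS[i]`` is the length of the longest prefix of the read's i-th suffix
    occurring anywhere in the indexed text.  The first pass mirrors the PML
    walk but tracks, through suffix-array samples at run boundaries, a text
    offset where a longest-match candidate begins; the second pass resolves
    each length by direct character comparison against the text.  Requires
    an index built with MS support.
    """
    if not index.ms_support:
        raise ValueError(
            "index lacks MS support; rebuild with ms_support=True "
            "(SA samples and text are needed for the second pass)"
        )
    tables = _query_tables(index)
    offset = tables["offset"]
    by_char = tables["by_char"]
    run_chars = tables["run_chars"]
    n = tables["n"]
    sa_starts = index.sa_run_starts.tolist()
    sa_ends = index.sa_run_ends.tolist()
    text = index.text.tolist()

    symbols = _symbols_of(read)
    m = len(symbols)
    row = 0
    cur_sa = sa_starts[0]  # SA[0]: row 0 starts run 0
    offsets = [0] * m
    for i in range(m - 1, -1, -1):
        c = symbols[i] + offset
        entry = by_char.get(c)
        if entry is None:
            offsets[i] = cur_sa
            continue
        run = _run_of(tables, row)
        if run_chars[run] == c:
            row = _lf(tables, row, run)
            cur_sa = cur_sa - 1 if cur_sa > 0 else n - 1
        else:
            brow, brun, is_start = _jump(tables, row, c)
            cur_sa = sa_starts[brun] if is_start else sa_ends[brun]
            row = _lf(tables, brow, brun)
            cur_sa -= 1  # boundary row's BWT char is c, so its SA entry > 0
        offsets[i] = cur_sa

    int_read = [s + offset for s in symbols]
    ms = np.zeros(m, dtype=np.int64)
    for i in range(m):
        p = offsets[i]
        ln = 0
        while i + ln < m and p + ln < n and int_read[i + ln] == text[p + ln]:
            ln += 1
        ms[i] = ln
    return ms
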