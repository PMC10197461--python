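"""Seeded synthetic pangenomes and reads.

Every experiment in the test suite runs against data from this module: a
pangenome of classes (each class a base genome mutated from a common
ancestor at the inter-class rate) with strains per class (mutated from the
class base at the intra-class rate), and reads drawn as substrings of the
strains — either strand — with substitution errors.  All generation is
deterministic under the given seed.

The generator emulates the repetitive structure that makes run-length BWT
indexes small (near-identical strains) and the error structure that breaks
exact matches (uniform substitutions); it does not emulate indels, ONT
homopolymer artifacts, or realistic read-length distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .digest import DNA_BASES, reverse_complement

__all__ = [
    "PangenomeSpec",
    "ReadSimSpec",
    "SimRead",
    "simulate_pangenome",
    "simulate_reads",
    "random_sequence",
]


@dataclass(frozen=True)
class PangenomeSpec:
    n_classes: int = 1
    strains_per_class: int = 5
    genome_length: int = 5000
    intra_class_divergence: float = 0.01
    inter_class_divergence: float = 0.10
    seed: int = 1

    def __post_init__(self) -> None:
        for rate in (self.intra_class_divergence, self.inter_class_divergence):
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"divergence {rate} outside [0, 1)")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")


@dataclass(frozen=True)
class ReadSimSpec:
    read_length: int = 1000
    error_rate: float = 0.05  # substitution rate (ONT-like 95% identity)
    n_reads: int = 200
    origin: str = "indexed"  # "indexed" | "random"
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError(f"error_rate {self.error_rate} outside [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class SimRead:
    read_id: str
    seq: str
    true_class: Optional[int]  # None for random reads
    doc_index: Optional[int]
    position: Optional[int]
    strand: str  # "+", "-", or "." for random reads
    n_errors: int = 0


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.asarray(list(DNA_BASES))[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each base independently at ``rate`` with a different base."""
    if rate <= 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.zeros(arr.size, dtype=np.int64)
    for i, b in enumerate(DNA_BASES):
        codes[arr == ord(b)] = i
    hits = rng.random(arr.size) < rate
    n = int(hits.sum())
    if n:
        # shift by 1..3 mod 4 guarantees a different base
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=n)) % 4
    bases = np.frombuffer(DNA_BASES.encode("ascii"), dtype=np.uint8)
    return bases[codes].tobytes().decode("ascii"), n


def simulate_pangenome(
    spec: PangenomeSpec,
) -> tuple[list[str], list[int], list[str]]:
    """Generate strain genomes: (documents, class labels, document names)."""
    rng = np.random.default_rng(spec.seed)
    ancestor = random_sequence(spec.genome_length, rng)
    documents: list[str] = []
    labels: list[int] = []
    names: list[str] = []
    for cls in range(spec.n_classes):
        base, _ = _mutate(ancestor, spec.inter_class_divergence, rng)
        for s in range(spec.strains_per_class):
            strain, _ = _mutate(base, spec.intra_class_divergence, rng)
            documents.append(strain)
            labels.append(cls)
            names.append(f"class{cls}_strain{s}")
    return documents, labels, names


def simulate_reads(
    documents: Sequence[str],
    labels: Sequence[int],
    spec: ReadSimSpec,
) -> list[SimRead]:
    """Draw reads from the documents (or i.i.d. random reads).

    Indexed reads come from a uniformly chosen document at a uniform
    position, from either strand with probability 1/2, with substitution
    errors at ``error_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[SimRead] = []
    if spec.origin == "random":
        for i in range(spec.n_reads):
            reads.append(
                SimRead(
                    read_id=f"random_{i}",
                    seq=random_sequence(spec.read_length, rng),
                    true_class=None,
                    doc_index=None,
                    position=None,
                    strand=".",
                )
            )
        return reads
    for di, doc in enumerate(documents):
        if len(doc) < spec.read_length:
            raise ValueError(
                f"read_length {spec.read_length} exceeds document {di} "
                f"length {len(doc)}"
            )
    for i in range(spec.n_reads):
        di = int(rng.integers(0, len(documents)))
        doc = documents[di]
        pos = int(rng.integers(0, len(doc) - spec.read_length + 1))
        frag = doc[pos : pos + spec.read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        seq, n_err = _mutate(frag, spec.error_rate, rng)
        reads.append(
            SimRead(
                read_id=f"read_{i}",
                seq=seq,
                true_class=int(labels[di]),
                doc_index=di,
                position=pos,
                strand=strand,
                n_errors=n_err,
            )
        )
    return reads
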