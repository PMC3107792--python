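"""Hexamer-priming bias correction.

Random-hexamer priming over/under-represents certain starting hexamers.
Each read gets a weight b(h) = (average frequency of its starting hexamer h
in the middle of reads) / (frequency of h at read start); read-class
multiplicities then sum these weights instead of counting reads. Hexamer
frequencies in the middle of reads are assumed unaffected by priming bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

MIN_READ_LEN = 12
_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _hexamer_index(seq: str) -> int | None:
    idx = 0
    for ch in seq:
        b = _BASE.get(ch)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


@dataclass
class HexamerProfile:
    """Observed hexamer distributions o_hat[i, h] per start position i
    (0-based; position i spans read bases i..i+5) and derived weights b."""

    read_len: int
    o_hat: np.ndarray  # (read_len - 5, 4096), rows sum to 1
    b: np.ndarray | None = None  # (4096,)

    def weight(self, hexamer: str) -> float:
        if self.b is None:
            raise ValueError("weights not computed; call hexamer_weight_table")
        idx = _hexamer_index(hexamer.upper()) if len(hexamer) == 6 else None
        if idx is None:
            return 1.0
        return float(self.b[idx])


def iter_fastq_sequences(path: str) -> Iterator[str]:
    """Sequences from an uncompressed FASTQ file."""
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip()


def hexamer_distributions(reads: Iterable[str], read_len: int) -> HexamerProfile:
    """Tabulate o_hat[i, h], the proportion of reads with hexamer h starting
    at position i, for every i in 0..read_len-6. Reads containing N within
    the window are excluded from that position's counts."""
    if read_len < MIN_READ_LEN:
        raise ValueError(
            f"reads of length {read_len} are too short for hexamer correction"
        )
    n_pos = read_len - 5
    counts = np.zeros((n_pos, 4096), dtype=np.int64)
    n_reads = 0
    for seq in reads:
        seq = seq.upper()
        n_reads += 1
        for i in range(min(n_pos, max(0, len(seq) - 5))):
            idx = _hexamer_index(seq[i : i + 6])
            if idx is not None:
                counts[i, idx] += 1
    if n_reads == 0:
        raise ValueError("no reads for hexamer profiling")
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return HexamerProfile(read_len=read_len, o_hat=counts / totals)


def hexamer_weight_table(
    profile: HexamerProfile, mid_start: int | None = None
) -> HexamerProfile:
    """Fill in b(h) = mean_{i in [mid_start, read_len-6]} o_hat[i, h] /
    o_hat[0, h], with b(h) = 1 where h never starts a read. ``mid_start``
    defaults to the middle of the read."""
    l = profile.read_len
    if mid_start is None:
        mid_start = (l + 1) // 2
    if not (1 <= mid_start <= l - 6):
        raise ValueError("mid_start outside valid range")
    mid = profile.o_hat[mid_start:].mean(axis=0)
    first = profile.o_hat[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(first > 0, mid / first, 1.0)
    profile.b = b
    return profile


def read_bias_weights(
    profile: HexamerProfile, sequences: Iterable[str]
) -> Iterator[float]:
    """b(h(r)) for each read sequence, 1.0 for unresolvable hexamers."""
    for seq in sequences:
        yield profile.weight(seq[:6])
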