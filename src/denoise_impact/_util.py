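"""Small shared sequence/array helpers (private)."""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def bytes_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def max_run_length(seq: str) -> int:
    """Length of the longest homopolymer run."""
    if not seq:
        return 0
    a = seq_to_bytes(seq)
    if a.size == 1:
        return 1
    breaks = np.flatnonzero(a[1:] != a[:-1])
    edges = np.concatenate(([-1], breaks, [a.size - 1]))
    return int(np.diff(edges).max())


def run_mask(arr: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs of >= min_run."""
    n = arr.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    breaks = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [n]))
    mask = np.zeros(n, dtype=bool)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()
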