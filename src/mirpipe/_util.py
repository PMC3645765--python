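"""Shared low-level sequence helpers: encoding, reverse complement, ungapped matching.

All coordinates are 0-based half-open. Sequences are uppercase DNA strings over
{A,C,G,T,N}; RNA input (U) is accepted where noted and normalised to DNA.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTUNacgtun", b"TGCAANtgcaan")

#: byte value of the ambiguous base; a tag 'N' mismatches every reference base
N_BYTE = ord("N")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (output is DNA)."""
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


def as_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorised comparison."""
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def find_matches(query: str, reference: str, max_mismatches: int = 0) -> list[tuple[int, int]]:
    """All ungapped full-length placements of ``query`` inside ``reference``.

    Returns ``(start, n_mismatches)`` pairs sorted by start. An 'N' in the
    query counts as a mismatch at every position; an 'N' in the reference
    mismatches everything as well.
    """
    lq, lr = len(query), len(reference)
    if lq == 0 or lq > lr:
        return []
    if max_mismatches == 0:
        out = []
        pos = reference.find(query)
        while pos != -1:
            out.append((pos, 0))
            pos = reference.find(query, pos + 1)
        if "N" in query:
            return []  # N never matches anything, so exact hits are impossible
        return out
    q = encode(query)
    r = encode(reference)
    windows = np.lib.stride_tricks.sliding_window_view(r, lq)
    bad = (windows != q) | (q == N_BYTE) | (windows == N_BYTE)
    mm = bad.sum(axis=1)
    starts = np.nonzero(mm <= max_mismatches)[0]
    return [(int(s), int(mm[s])) for s in starts]


def scan_tags(
    tags: Iterable[str],
    reference: str,
    max_mismatches: int,
    chunk: int = 128,
) -> dict[str, list[tuple[int, int]]]:
    """Batch version of :func:`find_matches` for many tags against one reference.

    Tags are grouped by length so each group shares one sliding-window view of
    the reference. Returns only tags with at least one hit.
    """
    tags = list(dict.fromkeys(tags))
    hits: dict[str, list[tuple[int, int]]] = {}
    if not reference:
        return hits
    r = encode(reference)
    by_len: dict[int, list[str]] = {}
    for t in tags:
        if 0 < len(t) <= len(reference):
            by_len.setdefault(len(t), []).append(t)
    ref_has_n = N_BYTE in r
    for lq, group in by_len.items():
        windows = np.lib.stride_tricks.sliding_window_view(r, lq)
        if ref_has_n:
            win_n = windows == N_BYTE
        arr = np.vstack([encode(t) for t in group])
        for lo in range(0, len(group), chunk):
            block = arr[lo : lo + chunk]
            bad = (windows[None, :, :] != block[:, None, :]) | (block[:, None, :] == N_BYTE)
            if ref_has_n:
                bad |= win_n[None, :, :]
            mm = bad.sum(axis=2, dtype=np.int32)
            rows, starts = np.nonzero(mm <= max_mismatches)
            for row, start in zip(rows.tolist(), starts.tolist()):
                hits.setdefault(group[lo + row], []).append((start, int(mm[row, start])))
    for v in hits.values():
        v.sort()
    return hits


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_dna_array(rng: np.random.Generator, length: int) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=length)]
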