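"""Low-level k-mer machinery: 2-bit encoding, canonical hashing, winnowing.

Sequences are handled as uint8 code arrays (A=0, C=1, G=2, T=3, anything
else 4).  A k-mer is packed into a uint64 (2 bits per base, k <= 31), the
canonical form is the smaller of the forward and reverse-complement
packings, and the packed value is scrambled with a splitmix64 finalizer
seeded with a fixed 64-bit seed so results are reproducible across
platforms.  K-mers overlapping a non-ACGT base hash to a sentinel and are
never sampled.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

#: sentinel hash for k-mers containing an ambiguous base; real hashes are
#: masked to 63 bits so they can never collide with it.
SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)
_MASK63 = np.uint64(0x7FFFFFFFFFFFFFFF)

DEFAULT_HASH_SEED = 42

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Encode an (uppercase) DNA string to uint8 codes."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 decodes to ``N``."""
    return _DECODE[codes].tobytes().decode("ascii")


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (wrapping uint64 arithmetic)."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def canonical_hashes(
    codes: np.ndarray, k: int, seed: int = DEFAULT_HASH_SEED
) -> np.ndarray:
    """Hash every k-mer start position of ``codes``.

    Returns a uint64 array of length ``len(codes) - k + 1`` (empty if the
    sequence is shorter than k).  Position ``i`` holds the seeded
    splitmix64 hash of the canonical (strand-independent) k-mer starting
    at ``i``, or :data:`SENTINEL` if that k-mer overlaps a non-ACGT base.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64)
    win = sliding_window_view(codes.astype(np.uint64), k)
    pw_fwd = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    fwd = win @ pw_fwd
    # reverse complement packs complemented bases with reversed weights
    rev = (np.uint64(3) - win) @ pw_fwd[::-1]
    h = splitmix64(np.minimum(fwd, rev) ^ np.uint64(seed)) & _MASK63
    # windows overlapping an ambiguous base -> sentinel
    bad = np.cumsum(codes > 3)
    nbad = bad[k - 1 :].copy()
    nbad[1:] -= bad[:-k]
    h[nbad > 0] = SENTINEL
    return h


@njit(cache=True)
def _winnow_kernel(hashes, w):  # pragma: no cover - numba
    n = hashes.shape[0]
    if n < w:
        return np.empty(0, np.int64)
    out = np.empty(n, np.int64)
    dq = np.empty(n, np.int64)  # monotonic deque of candidate indices
    m = 0
    head = 0
    tail = 0
    last = -1
    for i in range(n):
        # keep deque hashes non-decreasing; ties resolve to the leftmost
        while tail > head and hashes[dq[tail - 1]] > hashes[i]:
            tail -= 1
        dq[tail] = i
        tail += 1
        if dq[head] <= i - w:
            head += 1
        if i >= w - 1:
            p = dq[head]
            if p != last and hashes[p] != 0xFFFFFFFFFFFFFFFF:
                out[m] = p
                m += 1
                last = p
    return out[:m]


def winnow(hashes: np.ndarray, w: int) -> np.ndarray:
    """Positions of window minima over windows of ``w`` consecutive k-mers.

    Standard winnowing: for each window the leftmost minimum-hash k-mer is
    selected; selections repeated across overlapping windows are emitted
    once.  Sentinel (ambiguous) k-mers are never selected.  Expected
    density on random sequence is 2/(w+1).
    """
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")
    return _winnow_kernel(np.ascontiguousarray(hashes), w)


def minimizer_arrays(
    codes: np.ndarray, k: int, w: int, seed: int = DEFAULT_HASH_SEED
) -> tuple[np.ndarray, np.ndarray]:
    """Winnowed minimizers of a code array: ``(hashes, positions)``."""
    h = canonical_hashes(codes, k, seed)
    pos = winnow(h, w)
    return h[pos], pos


def valid_hash_set(codes: np.ndarray, k: int, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Sorted unique canonical k-mer hashes, ambiguous k-mers excluded."""
    h = canonical_hashes(codes, k, seed)
    return np.unique(h[h != SENTINEL])
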