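"""Hamming distances on aligned DNA with the shared gap/N exclusion rule.

Every stage that compares sequences (artifact filtering, networks, AMOVA)
counts differences only at columns where *both* sequences carry an unambiguous
base (A, C, G or T).  Gaps and Ns are alignment bookkeeping, not substitutions,
so they never contribute mutational steps.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

# A, C, G, T -> 0..3; everything else (gap, N, ambiguity codes) -> 255.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i

VALID_CODE_MAX = 3


def encode(seqs: Iterable[str]) -> np.ndarray:
    """Encode equal-length DNA strings as a (n, L) uint8 matrix (ACGT -> 0..3, other -> 255)."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    raw = np.frombuffer("".join(seqs).upper().encode("ascii"), dtype=np.uint8)
    return _LUT[raw.reshape(len(seqs), -1)]


def hamming(a: str | np.ndarray, b: str | np.ndarray) -> int:
    """Substitution distance between two aligned sequences, ignoring gap/N columns."""
    if isinstance(a, str):
        a = encode([a])[0]
    if isinstance(b, str):
        b = encode([b])[0]
    ok = (a <= VALID_CODE_MAX) & (b <= VALID_CODE_MAX)
    return int(np.count_nonzero((a != b) & ok))


def pairwise_matrix(encoded: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise substitution distances for a (n, L) encoded alignment."""
    n = encoded.shape[0]
    valid = encoded <= VALID_CODE_MAX
    dist = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        ok = valid[i] & valid
        diff = (encoded[i] != encoded) & ok
        dist[i] = diff.sum(axis=1)
    return dist


def distances_to_pool(query: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Distances from one encoded sequence to each row of an encoded pool."""
    ok = (query <= VALID_CODE_MAX) & (pool <= VALID_CODE_MAX)
    return ((query != pool) & ok).sum(axis=1)
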