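"""Weighted base-pair maximization for RNA secondary structure.

A Nussinov-style dynamic program over non-crossing structures with a
minimum hairpin loop of 3 unpaired nucleotides.  Pairs are weighted
GC=3, AU=2, GU=1; the optimal total weight, negated, serves as a
pseudo-free-energy (<= 0, more negative = more stable).  Unlike a
thermodynamic nearest-neighbour model this DP is exactly checkable
against brute-force enumeration, which the test suite does.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import RibostatError

#: minimum number of unpaired nucleotides enclosed by any base pair
MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# pair weights indexed by (code_i, code_j); N (code 4) never pairs
_W = np.zeros((5, 5), dtype=np.int32)
_W[2, 1] = _W[1, 2] = 3  # G-C
_W[0, 3] = _W[3, 0] = 2  # A-U
_W[2, 3] = _W[3, 2] = 1  # G-U


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes; rejects invalid characters."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise RibostatError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _nussinov(enc, weights, min_loop):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            w = weights[enc[i], enc[j]]
            if w > 0 and M[i + 1, j - 1] + w > best:
                best = M[i + 1, j - 1] + w
            for k in range(i + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return M[0, n - 1] if n else 0


def max_pair_weight(seq: str) -> int:
    """Maximum total pair weight over all non-crossing structures."""
    if len(seq) <= MIN_LOOP + 1:
        return 0
    return int(_nussinov(encode(seq), _W, MIN_LOOP))


def tiled_pair_weight(seq: str, window: int) -> int:
    """Sum of optimal pair weights over consecutive tiles of <= window nt.

    Equals :func:`max_pair_weight` whenever ``len(seq) <= window``; for longer
    sequences it is a lower bound that scales linearly with length, which is
    what the length-normalized structure features need.
    """
    if window < MIN_LOOP + 2:
        raise RibostatError(f"window must be >= {MIN_LOOP + 2}")
    return sum(
        max_pair_weight(seq[i : i + window]) for i in range(0, len(seq), window)
    )


def enumerate_structures(seq: str):
    """Yield every non-crossing structure (as a tuple of pair index tuples).

    Brute-force oracle used by tests; exponential, keep sequences short.
    """
    enc = encode(seq)
    n = len(enc)

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield ()
            return
        i = positions[0]
        rest = positions[1:]
        # i unpaired
        for s in rec(rest):
            yield s
        # i paired with some j
        for jx, j in enumerate(rest):
            if j - i <= MIN_LOOP:
                continue
            if _W[enc[i], enc[j]] == 0:
                continue
            inner = tuple(p for p in rest[:jx] if i < p < j)
            outer = tuple(p for p in rest[jx + 1 :] if p > j)
            for si in rec(inner):
                for so in rec(outer):
                    yield ((i, j),) + si + so

    yield from rec(tuple(range(n)))


def brute_force_pair_weight(seq: str) -> int:
    """Exhaustive-enumeration optimum; oracle for the DP."""
    enc = encode(seq)
    best = 0
    for struct in enumerate_structures(seq):
        w = sum(int(_W[enc[i], enc[j]]) for i, j in struct)
        if w > best:
            best = w
    return best
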