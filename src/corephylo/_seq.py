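"""Low-level nucleotide encoding and suffix-array utilities.

Sequences are held as ``numpy.uint8`` arrays with the fixed code
``A=0, C=1, G=2, T=3``; ``N`` and every other IUPAC ambiguity code map to
``N_CODE`` (4).  Downstream call tracks extend this alphabet with
``GAP_CODE`` (5) and ``AMBIG_CODE`` (6).
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3
N_CODE = 4
GAP_CODE = 5
AMBIG_CODE = 6

BASES = "ACGT"

IUPAC = set("ACGTRYSWKMBDHVN")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
for _b in "RYSWKMBDHVN":
    _ENCODE[ord(_b)] = N_CODE
    _ENCODE[ord(_b.lower())] = N_CODE

_DECODE = np.frombuffer(b"ACGTN-?", dtype=np.uint8)

# complement for codes 0..4 (N -> N); 5/6 map to themselves
_COMPLEMENT = np.array([3, 2, 1, 0, 4, 5, 6], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; raises on non-IUPAC chars."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"non-IUPAC character {seq[pos]!r} at offset {pos}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes (including GAP/AMBIG) back to a string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def suffix_array(s: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling (O(n log^2 n)).

    Accepts any integer dtype; values need not be small.  Returns the
    permutation ``sa`` with ``s[sa[0]:] < s[sa[1]:] < ...`` where comparison
    treats running off the end as smaller than any symbol.
    """
    s = np.asarray(s, dtype=np.int64)
    n = len(s)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # initial ranks from single symbols
    order = np.argsort(s, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.concatenate(([0], np.cumsum(s[order][1:] != s[order][:-1])))
    k = 1
    tmp = np.empty(n, dtype=np.int64)
    while True:
        if rank[order[-1]] == n - 1:
            break
        # secondary key: rank of suffix i+k (or -1 past the end)
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        r_o = rank[order]
        s_o = second[order]
        changed = np.empty(n, dtype=bool)
        changed[0] = False
        changed[1:] = (r_o[1:] != r_o[:-1]) | (s_o[1:] != s_o[:-1])
        tmp[order] = np.cumsum(changed)
        rank, tmp = tmp.copy(), rank
        k *= 2
    return order


def lcp_array(s: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP array: ``lcp[i] = LCP(s[sa[i-1]:], s[sa[i]:])``, lcp[0]=0."""
    n = len(s)
    lcp = np.zeros(n, dtype=np.int64)
    if n == 0:
        return lcp
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    h = 0
    sl = s  # local alias
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and sl[i + h] == sl[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp
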