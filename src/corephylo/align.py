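"""Banded global alignment with affine gap costs (Gotoh's algorithm).

Edit scripts are lists of ``(op, length)`` pairs:

* ``"M"`` - exact match run (consumes both sequences),
* ``"X"`` - substitution run (consumes both),
* ``"D"`` - gap in the query (consumes reference only),
* ``"I"`` - gap in the reference (consumes query only).

A gap of length g costs ``gap_open + g * gap_extend``.  The band is placed
around the main diagonal, widened by the length difference of the two
sequences plus ``band_pad``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = np.int32(-(10**9) // 2)

EditScript = list[tuple[str, int]]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


def merge_ops(ops: EditScript) -> EditScript:
    out: EditScript = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def ops_lengths(ops: EditScript) -> tuple[int, int]:
    """(reference bases consumed, query bases consumed)."""
    ref = sum(n for op, n in ops if op in "MXD")
    qry = sum(n for op, n in ops if op in "MXI")
    return ref, qry


def score_ops(ops: EditScript, scoring: Scoring = DEFAULT_SCORING) -> int:
    total = 0
    for op, n in ops:
        if op == "M":
            total += scoring.match * n
        elif op == "X":
            total += scoring.mismatch * n
        else:
            total += scoring.gap_open + scoring.gap_extend * n
    return total


def banded_global_align(
    a: np.ndarray,
    b: np.ndarray,
    scoring: Scoring = DEFAULT_SCORING,
    band_pad: int = 50,
) -> tuple[int, EditScript]:
    """Globally align code arrays ``a`` (reference) and ``b`` (query).

    Returns ``(score, edit_script)``.  Codes >= 4 (N/ambiguous) never match.
    """
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0, []
    if n == 0:
        return scoring.gap_open + scoring.gap_extend * m, [("I", m)]
    if m == 0:
        return scoring.gap_open + scoring.gap_extend * n, [("D", n)]

    lo = min(0, m - n) - band_pad
    hi = max(0, m - n) + band_pad
    width = hi - lo + 1

    # band storage: column c of row i holds cell (i, j) with j = i + lo + c
    M = np.full((n + 1, width), NEG_INF, dtype=np.int32)
    X = np.full((n + 1, width), NEG_INF, dtype=np.int32)  # gap in query (op D)
    Y = np.full((n + 1, width), NEG_INF, dtype=np.int32)  # gap in reference (op I)

    go, ge = scoring.gap_open, scoring.gap_extend

    def cols(i: int) -> tuple[int, int]:
        j_lo = max(0, i + lo)
        j_hi = min(m, i + hi)
        return j_lo, j_hi

    # row 0
    j0_lo, j0_hi = cols(0)
    c0 = np.arange(j0_lo, j0_hi + 1) - lo
    M[0, -lo] = 0
    js = np.arange(j0_lo, j0_hi + 1)
    pos = js > 0
    Y[0, c0[pos]] = go + ge * js[pos]

    a64 = a.astype(np.int16)
    b64 = b.astype(np.int16)

    for i in range(1, n + 1):
        j_lo, j_hi = cols(i)
        if j_lo > j_hi:
            continue
        c = np.arange(j_lo, j_hi + 1) - (i + lo)

        # vertical: from row i-1, same j -> band column c+1
        cp = c + 1
        valid_v = cp < width
        Xi = np.full(len(c), NEG_INF, dtype=np.int32)
        prev_best_v = np.maximum(M[i - 1], Y[i - 1])
        Xi[valid_v] = ge + np.maximum(
            X[i - 1, cp[valid_v]], go + prev_best_v[cp[valid_v]]
        )
        np.clip(Xi, NEG_INF, None, out=Xi)
        X[i, c] = Xi

        # diagonal: from row i-1, j-1 -> same band column c
        js = np.arange(j_lo, j_hi + 1)
        diag_prev = np.maximum(np.maximum(M[i - 1, c], X[i - 1, c]), Y[i - 1, c])
        Mi = np.full(len(c), NEG_INF, dtype=np.int32)
        has_diag = js > 0
        if has_diag.any():
            aj = a64[i - 1]
            sub = np.where(
                (b64[js[has_diag] - 1] == aj) & (aj < 4),
                scoring.match,
                scoring.mismatch,
            ).astype(np.int32)
            Mi[has_diag] = diag_prev[has_diag] + sub
        Mi[diag_prev <= NEG_INF // 2] = NEG_INF
        if j_lo == 0 and i > 0:
            Mi[js == 0] = NEG_INF
        M[i, c] = Mi

        # horizontal scan: Y[i][j] = ge + max(Y[i][j-1], go + max(M,X)[i][j-1])
        row_best = np.maximum(M[i, c], X[i, c])
        Yi = np.full(len(c), NEG_INF, dtype=np.int32)
        prev_y = np.int64(NEG_INF)
        prev_b = np.int64(NEG_INF)
        first_j = js[0]
        if first_j > 0 and c[0] - 1 >= 0:
            prev_y = int(Y[i, c[0] - 1])
            prev_b = int(max(M[i, c[0] - 1], X[i, c[0] - 1]))
        for idx in range(len(c)):
            if js[idx] > 0:
                cand = max(prev_y, go + prev_b)
                if cand > NEG_INF // 2:
                    Yi[idx] = ge + cand
            prev_y = int(Yi[idx])
            prev_b = int(row_best[idx])
        Y[i, c] = Yi

    # traceback
    c_end = m - (n + lo)
    scores = (int(M[n, c_end]), int(X[n, c_end]), int(Y[n, c_end]))
    state = int(np.argmax(scores))
    score = scores[state]
    if score <= NEG_INF // 2:
        raise ValueError("band too narrow for these sequences")

    ops_rev: EditScript = []
    i, j = n, m
    names = "MXY"
    while i > 0 or j > 0:
        st = names[state]
        c = j - (i + lo)
        if st == "M":
            op = "M" if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else "X"
            ops_rev.append((op, 1))
            prev = (
                int(M[i - 1, c]) if 0 <= c < width else NEG_INF,
                int(X[i - 1, c]) if 0 <= c < width else NEG_INF,
                int(Y[i - 1, c]) if 0 <= c < width else NEG_INF,
            )
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax(prev))
        elif st == "X":  # gap in query, consumed a[i-1]
            ops_rev.append(("D", 1))
            cur = int(X[i, c])
            cp = c + 1
            from_x = int(X[i - 1, cp]) if 0 <= cp < width else NEG_INF
            i = i - 1
            if cur == ge + from_x:
                state = 1
            else:
                c2 = j - (i + lo)
                prev = (
                    int(M[i, c2]) if 0 <= c2 < width else NEG_INF,
                    NEG_INF,
                    int(Y[i, c2]) if 0 <= c2 < width else NEG_INF,
                )
                state = int(np.argmax(prev))
        else:  # Y: gap in reference, consumed b[j-1]
            ops_rev.append(("I", 1))
            cur = int(Y[i, c])
            cm = c - 1
            from_y = int(Y[i, cm]) if 0 <= cm < width else NEG_INF
            j = j - 1
            if cur == ge + from_y:
                state = 2
            else:
                c2 = j - (i + lo)
                prev = (
                    int(M[i, c2]) if 0 <= c2 < width else NEG_INF,
                    int(X[i, c2]) if 0 <= c2 < width else NEG_INF,
                    NEG_INF,
                )
                state = int(np.argmax(prev))
    ops_rev.reverse()
    return score, merge_ops(ops_rev)
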