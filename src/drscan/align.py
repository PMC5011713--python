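"""Global pairwise alignment used for the "similar ratio" statistic.

Scoring is match +1, mismatch -1, linear gap -2.  Among all score-optimal
global alignments the one with the most identical aligned pairs is taken,
so the reported identity count is well defined even when several
alignments tie on score.  N is treated as matching nothing.

The inner DP is JIT-compiled with numba when available; a pure-Python
fallback keeps the package importable without it.
"""

from __future__ import annotations

import numpy as np

from ._seq import N_CODE, encode

MATCH = 1
MISMATCH = -1
GAP = -2

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _nw_dual(a: np.ndarray, b: np.ndarray) -> int:  # pragma: no cover - numba
    m, n = len(a), len(b)
    S = np.empty((m + 1, n + 1), dtype=np.int32)
    I = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        S[0, j] = GAP * j
        I[0, j] = 0
    for i in range(1, m + 1):
        S[i, 0] = GAP * i
        I[i, 0] = 0
        ai = a[i - 1]
        for j in range(1, n + 1):
            eq = 1 if (ai == b[j - 1] and ai != N_CODE) else 0
            sub = MATCH if eq == 1 else MISMATCH
            sd = S[i - 1, j - 1] + sub
            idd = I[i - 1, j - 1] + eq
            su = S[i - 1, j] + GAP
            iu = I[i - 1, j]
            sl = S[i, j - 1] + GAP
            il = I[i, j - 1]
            bs = sd
            bi = idd
            if su > bs or (su == bs and iu > bi):
                bs, bi = su, iu
            if sl > bs or (sl == bs and il > bi):
                bs, bi = sl, il
            S[i, j] = bs
            I[i, j] = bi
    return I[m, n]


def _nw_dual_py(a: np.ndarray, b: np.ndarray) -> int:
    m, n = len(a), len(b)
    S = [[GAP * j for j in range(n + 1)]]
    I = [[0] * (n + 1)]
    for i in range(1, m + 1):
        Sp, Ip = S[-1], I[-1]
        Sr = [GAP * i] + [0] * n
        Ir = [0] * (n + 1)
        ai = a[i - 1]
        for j in range(1, n + 1):
            eq = 1 if (ai == b[j - 1] and ai != N_CODE) else 0
            cands = (
                (Sp[j - 1] + (MATCH if eq else MISMATCH), Ip[j - 1] + eq),
                (Sp[j] + GAP, Ip[j]),
                (Sr[j - 1] + GAP, Ir[j - 1]),
            )
            Sr[j], Ir[j] = max(cands)
        S.append(Sr)
        I.append(Ir)
    return I[m][n]


def global_identity_count(a: str, b: str) -> int:
    """Number of identical aligned base pairs in the optimal global alignment.

    Among co-optimal alignments the maximal identity count is returned.
    """
    ca, cb = encode(a), encode(b)
    if _HAVE_NUMBA:
        return int(_nw_dual(ca, cb))
    return int(_nw_dual_py(ca, cb))
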