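"""Hot path for the exhaustive subset search: PLS1 cross-validated PRESS.

A single NIPALS pass yields nested predictions for every component count,
so one fit per fold prices all candidate component numbers at once. The
kernel is JIT-compiled with numba when available; a pure-numpy twin with
identical semantics serves as fallback and as an in-suite cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def _cv_press_impl(Xtr, ntr, Xte, nte, ytr, yte, cols, kmax):
    """PRESS per component count (1..kmax) summed over folds.

    Xtr/Xte are fold-padded (F, max_n, C) arrays already standardized per
    training fold; ytr/yte are centered on the training-fold mean. ``cols``
    selects the feature subset.
    """
    F = Xtr.shape[0]
    s = cols.shape[0]
    press = np.zeros(kmax)
    for f in range(F):
        n1 = ntr[f]
        n2 = nte[f]
        X = np.empty((n1, s))
        Xt = np.empty((n2, s))
        for a in range(s):
            c = cols[a]
            for i in range(n1):
                X[i, a] = Xtr[f, i, c]
            for i in range(n2):
                Xt[i, a] = Xte[f, i, c]
        y = ytr[f, :n1].copy()
        res = yte[f, :n2].copy()
        w = np.empty(s)
        p = np.empty(s)
        t = np.empty(n1)
        tt = np.empty(n2)
        for k in range(kmax):
            norm = 0.0
            for a in range(s):
                acc = 0.0
                for i in range(n1):
                    acc += X[i, a] * y[i]
                w[a] = acc
                norm += acc * acc
            norm = math.sqrt(norm)
            if norm < 1e-12:
                val = 0.0
                for i in range(n2):
                    val += res[i] * res[i]
                for kk in range(k, kmax):
                    press[kk] += val
                break
            for a in range(s):
                w[a] /= norm
            tsq = 0.0
            for i in range(n1):
                acc = 0.0
                for a in range(s):
                    acc += X[i, a] * w[a]
                t[i] = acc
                tsq += acc * acc
            if tsq < 1e-30:
                val = 0.0
                for i in range(n2):
                    val += res[i] * res[i]
                for kk in range(k, kmax):
                    press[kk] += val
                break
            qk = 0.0
            for i in range(n1):
                qk += y[i] * t[i]
            qk /= tsq
            for a in range(s):
                acc = 0.0
                for i in range(n1):
                    acc += X[i, a] * t[i]
                p[a] = acc / tsq
            for i in range(n1):
                for a in range(s):
                    X[i, a] -= t[i] * p[a]
                y[i] -= qk * t[i]
            val = 0.0
            for i in range(n2):
                acc = 0.0
                for a in range(s):
                    acc += Xt[i, a] * w[a]
                tt[i] = acc
            for i in range(n2):
                res[i] -= qk * tt[i]
                for a in range(s):
                    Xt[i, a] -= tt[i] * p[a]
                val += res[i] * res[i]
            press[k] += val
    return press


cv_press_numpy = _cv_press_impl

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    cv_press = njit(cache=False)(_cv_press_impl)
except ImportError:  # pragma: no cover
    cv_press = _cv_press_impl
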