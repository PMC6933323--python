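"""Independent reference implementations used only to check the package.

Each oracle deliberately takes the most direct route available — textbook
formulas, exhaustive enumeration, generic numerical minimization, pair
counting — and shares no code with the implementation under test.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize


def pearson_direct(x, y) -> float:
    """Textbook Pearson correlation: centered cross-product over the product
    of root sums of squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def nw_affine_enumerate(a: str, b: str, match: float, mismatch: float,
                        gap_open: float, gap_extend: float) -> float:
    """Best global-alignment score by enumerating all alignments recursively.

    State: position in each sequence plus which sequence (if any) the previous
    column gapped, so gap opening vs extension is charged correctly.  A gap of
    length L costs gap_open + (L-1)*gap_extend.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1, "m"))
        if i < len(a):  # a[i] against a gap in b
            g = gap_extend if prev == "b" else gap_open
            options.append(g + best(i + 1, j, "b"))
        if j < len(b):  # b[j] against a gap in a
            g = gap_extend if prev == "a" else gap_open
            options.append(g + best(i, j + 1, "a"))
        return max(options)

    return best(0, 0, "m")


def ridge_column_minimizer(M: np.ndarray, alpha: float) -> np.ndarray:
    """Minimize alpha*||m_j - M c||^2 + ||c||^2 column by column with a
    generic second-order numerical optimizer."""
    n = M.shape[1]
    C = np.empty((n, n))
    H = 2 * alpha * (M.T @ M) + 2 * np.eye(n)
    for j in range(n):
        m_j = M[:, j]

        def q(c):
            r = m_j - M @ c
            return alpha * (r @ r) + c @ c

        def grad(c):
            return 2 * alpha * (M.T @ (M @ c - m_j)) + 2 * c

        res = minimize(q, np.zeros(n), jac=grad, hess=lambda c: H,
                       method="trust-exact", options={"gtol": 1e-12})
        C[:, j] = res.x
    return C


def auc_pair_counting(scores, labels) -> float:
    """Concordant-pair AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = len(pos) * len(neg)
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(conc / total)
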