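"""Independent oracles used to validate the implementation.

These deliberately avoid the code paths they check: the NNLS oracle solves
the nonnegative least-squares problem by exhaustive enumeration of active
sets (unconstrained least squares on every column subset, keeping feasible
candidates), and the quantile oracle implements the linear-interpolation
definition directly.
"""

from itertools import combinations

import numpy as np


def nnls_exhaustive(design: np.ndarray, y: np.ndarray, tol: float = 1e-9):
    """Global NNLS optimum by enumerating all column subsets.

    The optimum of min ||Ax - y|| s.t. x >= 0 is attained on some support
    set where the unconstrained LS solution is nonnegative; enumerating
    all supports and keeping the feasible candidate with the smallest
    residual therefore finds it. Exponential in columns — tiny instances
    only.
    """
    n = design.shape[1]
    best_res = float(np.linalg.norm(y))  # empty support
    best_x = np.zeros(n)
    for k in range(1, n + 1):
        for support in combinations(range(n), k):
            sub = design[:, support]
            xs, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if (xs >= -tol).all():
                x = np.zeros(n)
                x[list(support)] = np.clip(xs, 0.0, None)
                res = float(np.linalg.norm(design @ x - y))
                if res < best_res:
                    best_res, best_x = res, x
    return best_x, best_res


def quantile_linear(values, q: float) -> float:
    """Linear-interpolation sample quantile, written from the definition."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def morans_i_direct(values, w: np.ndarray) -> float:
    """Moran's I from the definition, dense double loop."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return (n / w.sum()) * num / (z @ z)
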