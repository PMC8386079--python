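"""Independent oracle for small non-negative least-squares problems.

Solves min ||A x - b||^2 s.t. x >= 0 exactly by enumerating all 2^K
candidate supports: for each subset of columns the unconstrained
least-squares solution is computed, kept if it is non-negative, and the
feasible candidate with the smallest objective wins. The optimal active
set's support appears among the candidates, so the minimum over feasible
candidates is the global optimum. Exponential in K — intended for K <= 10
cross-checks only, and entirely independent of scipy's Lawson–Hanson
implementation.
"""

from itertools import combinations

import numpy as np


def nnls_bruteforce(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (x, objective) for min ||Ax - b||², x >= 0."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    G, K = A.shape
    best_x = np.zeros(K)
    best_obj = float(b @ b)
    for size in range(1, K + 1):
        for support in combinations(range(K), size):
            sub = A[:, support]
            coef, *_ = np.linalg.lstsq(sub, b, rcond=None)
            if (coef < -1e-12).any():
                continue
            x = np.zeros(K)
            x[list(support)] = np.clip(coef, 0.0, None)
            obj = float(np.sum((A @ x - b) ** 2))
            if obj < best_obj:
                best_obj, best_x = obj, x
    return best_x, best_obj
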