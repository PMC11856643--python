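"""Elementary symmetric functions of item easiness parameters.

The conditional likelihood of the Rasch model factors through the elementary
symmetric polynomials gamma_r(eps) of the item easiness values
``eps_j = exp(-sigma_j)``: given a raw score r, the person parameter drops out
and the probability of a response pattern x with score r is
``prod_j eps_j^{x_j} / gamma_r``.  The summation algorithm below is the
standard numerically stable way to evaluate gamma and the single-item
deletions needed for its derivatives.
"""

from __future__ import annotations

import numpy as np

__all__ = ["esf", "esf_deleted", "conditional_item_probs"]


def esf(eps: np.ndarray) -> np.ndarray:
    """All elementary symmetric polynomials ``gamma_0 .. gamma_n`` of ``eps``.

    Summation algorithm: sequentially multiply out ``prod_j (1 + eps_j t)``.
    """
    eps = np.asarray(eps, dtype=float)
    n = eps.size
    g = np.zeros(n + 1)
    g[0] = 1.0
    for e in eps:
        g[1:] = g[1:] + e * g[:-1]
    return g


def esf_deleted(eps: np.ndarray) -> np.ndarray:
    """Matrix ``G[j, r] = gamma_r(eps with item j removed)``, shape (n, n).

    Needed for the conditional-likelihood gradient and for exact conditional
    item probabilities.  Recomputed per item (O(n^3) total), which is robust
    against the cancellation that plagues the polynomial-division shortcut.
    """
    eps = np.asarray(eps, dtype=float)
    n = eps.size
    out = np.empty((n, n))
    for j in range(n):
        out[j] = esf(np.delete(eps, j))
    return out


def conditional_item_probs(eps: np.ndarray) -> np.ndarray:
    """Exact ``P(X_j = 1 | raw score r)`` under the Rasch model.

    Returns a matrix of shape (n_items, n_items + 1) indexed by raw score
    ``r = 0 .. n``; columns 0 and n are the degenerate all-wrong / all-right
    cases (0 and 1 respectively).
    """
    eps = np.asarray(eps, dtype=float)
    n = eps.size
    g = esf(eps)
    g_del = esf_deleted(eps)
    probs = np.zeros((n, n + 1))
    for r in range(1, n):
        probs[:, r] = eps * g_del[:, r - 1] / g[r]
    probs[:, n] = 1.0
    return probs
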