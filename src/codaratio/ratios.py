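"""Exact and relaxed log-ratio transforms.

Two families of scale-invariant CoDa features are supported:

* **balances** -- log-ratios of geometric means of two disjoint feature sets,

  .. math:: B(x; J^+, J^-) = \\frac{1}{p^+}\\sum_{j \\in J^+} \\log x_j
            - \\frac{1}{p^-}\\sum_{j \\in J^-} \\log x_j

* **amalgamations** -- log-ratios of sums,

  .. math:: A(x; J^+, J^-) = \\log \\frac{\\sum_{j \\in J^+} x_j}{\\sum_{j \\in J^-} x_j}

Searching over subset pairs is combinatorial, so both are given a
differentiable *relaxation*: an unconstrained weight vector w is squashed to
soft assignments w-tilde in (-1, 1), whose positive part weights the
numerator and negative part the denominator.  In the saturated limit
(|w| large) the relaxed forms coincide with the exact ones, which is what
lets gradient descent stand in for subset search.

Natural logarithms are used throughout; any other base would simply be
absorbed by the downstream regression slope.
"""

from __future__ import annotations

import numpy as np

from .data import BalancePartition, CompositionMatrix

#: floor for the L1 norms of the soft-assignment halves; keeps the relaxed
#: balance defined (and its gradient finite) at the all-zero configuration.
DEFAULT_EPS = 1e-8


def _values(x) -> np.ndarray:
    if isinstance(x, CompositionMatrix):
        return x.values
    v = np.asarray(x, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    return v


def soft_assign(w) -> np.ndarray:
    """Map unconstrained assignment weights to soft assignments in (-1, 1).

    w_tilde = 2*sigmoid(w) - 1 = tanh(w/2), componentwise.  Large positive
    weights softly assign a feature to the numerator, large negative ones to
    the denominator, and weights near zero exclude it.
    """
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("assignment weights must be finite")
    return np.tanh(w / 2.0)


def weights_from_soft(w_tilde) -> np.ndarray:
    """Inverse of :func:`soft_assign`: w = 2*atanh(w_tilde)."""
    w_tilde = np.asarray(w_tilde, dtype=float)
    if np.any(np.abs(w_tilde) >= 1):
        raise ValueError("soft assignments must lie strictly inside (-1, 1)")
    return 2.0 * np.arctanh(w_tilde)


def soft_parts(w_tilde) -> tuple[np.ndarray, np.ndarray]:
    """Rectified positive and negative parts of a soft assignment."""
    w_tilde = np.asarray(w_tilde, dtype=float)
    return np.maximum(w_tilde, 0.0), np.maximum(-w_tilde, 0.0)


def hard_weights(part: BalancePartition, p: int, magnitude: float = 50.0) -> np.ndarray:
    """Assignment weights that saturate the soft assignment onto a partition."""
    part.require_within(p)
    w = np.zeros(p)
    w[list(part.j_plus)] = magnitude
    w[list(part.j_minus)] = -magnitude
    return w


def exact_balance(x, part: BalancePartition) -> np.ndarray:
    """Per-sample balance: log-ratio of geometric means over (J+, J-)."""
    part.require_valid()
    v = _values(x)
    part.require_within(v.shape[1])
    logv = np.log(v)
    return logv[:, list(part.j_plus)].mean(axis=1) - logv[:, list(part.j_minus)].mean(axis=1)


def exact_amalgamation(x, part: BalancePartition) -> np.ndarray:
    """Per-sample amalgamation: log-ratio of sums over (J+, J-)."""
    part.require_valid()
    v = _values(x)
    part.require_within(v.shape[1])
    num = v[:, list(part.j_plus)].sum(axis=1)
    den = v[:, list(part.j_minus)].sum(axis=1)
    return np.log(num) - np.log(den)


def exact_ratio(x, part: BalancePartition, ratio_type: str) -> np.ndarray:
    """Dispatch to :func:`exact_balance` or :func:`exact_amalgamation`."""
    if ratio_type == "balance":
        return exact_balance(x, part)
    if ratio_type == "amalgamation":
        return exact_amalgamation(x, part)
    raise ValueError(f"unknown ratio_type {ratio_type!r}")


def relaxed_balance(x, w, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Differentiable balance surrogate: weighted geometric means over all parts.

    B_i = (w+ . log x_i)/||w+||_1 - (w- . log x_i)/||w-||_1, where w+/w- are
    the rectified parts of soft_assign(w) and each L1 norm is floored at
    ``eps`` to keep the expression defined near the all-zero assignment.
    """
    u, v = soft_parts(soft_assign(w))
    logx = np.log(_values(x))
    su = max(u.sum(), eps)
    sv = max(v.sum(), eps)
    return logx @ u / su - logx @ v / sv


def relaxed_amalgamation(x, w, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Differentiable amalgamation surrogate: weighted sums over all parts.

    A_i = log((w+ . x_i + eps) / (w- . x_i + eps)); the additive eps guards
    the case of an all-zero side.
    """
    u, v = soft_parts(soft_assign(w))
    vals = _values(x)
    return np.log(vals @ u + eps) - np.log(vals @ v + eps)


def relaxed_ratio(x, w, ratio_type: str, eps: float = DEFAULT_EPS) -> np.ndarray:
    if ratio_type == "balance":
        return relaxed_balance(x, w, eps)
    if ratio_type == "amalgamation":
        return relaxed_amalgamation(x, w, eps)
    raise ValueError(f"unknown ratio_type {ratio_type!r}")
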