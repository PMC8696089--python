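"""Exhaustive brute-force solver of the combinatorial log-ratio problem.

For small p, every ordered pair of disjoint nonempty index subsets
(3^p - 2^(p+1) + 1 of them) is evaluated by a univariate logistic refit on
its exact ratio, and the training cross-entropy minimizer is returned.  This
is the ground truth against which the continuous relaxation is validated.
The module is deliberately dumb: no pruning, no heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

import numpy as np

from .data import BalancePartition, CompositionMatrix, validate_outcome
from .discretize import refit_linear
from .optim import cross_entropy_loss
from .ratios import exact_ratio

MAX_P = 12


def partition_count(p: int) -> int:
    """Number of ordered pairs of disjoint nonempty subsets of p items."""
    return 3**p - 2 ** (p + 1) + 1


def enumerate_partitions(p: int) -> Iterator[BalancePartition]:
    """Yield every valid ordered partition exactly once (deterministic order).

    Each feature is assigned to numerator (+), denominator (-) or neither;
    assignments with an empty side are skipped.  Refuses p > 12 to guard
    against exponential blowup.
    """
    if p < 2:
        raise ValueError("need p >= 2")
    if p > MAX_P:
        raise ValueError(f"refusing exhaustive enumeration for p={p} > {MAX_P}")
    for assignment in product((0, 1, -1), repeat=p):
        j_plus = tuple(j for j, a in enumerate(assignment) if a == 1)
        j_minus = tuple(j for j, a in enumerate(assignment) if a == -1)
        if j_plus and j_minus:
            yield BalancePartition(j_plus, j_minus)


@dataclass
class OracleResult:
    best_partition: BalancePartition
    best_loss: float
    n_partitions_evaluated: int
    per_partition_losses: list[tuple[BalancePartition, float]] | None = None


def oracle_best_ratio(x: CompositionMatrix, y, ratio_type: str = "balance",
                      keep_table: bool = False) -> OracleResult:
    """Globally optimal single ratio by exhaustive search.

    Ties in training cross-entropy break toward the lexicographically
    smallest (j_plus, j_minus) pair.
    """
    y = validate_outcome(y, x.n, require_both_classes=True)
    offset = np.zeros(x.n)
    best_key = None
    best_part = None
    best_loss = np.inf
    table = [] if keep_table else None
    count = 0
    for part in enumerate_partitions(x.p):
        count += 1
        alpha, beta = refit_linear(x, y, offset, part, ratio_type)
        loss = cross_entropy_loss(alpha + beta * exact_ratio(x, part, ratio_type), y)
        if table is not None:
            table.append((part, loss))
        key = (loss, part.j_plus, part.j_minus)
        if best_key is None or key < best_key:
            best_key = key
            best_part = part
            best_loss = loss
    return OracleResult(best_part, float(best_loss), count, table)
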