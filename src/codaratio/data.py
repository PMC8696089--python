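"""Core containers: positive abundance matrices and log-ratio partitions.

Compositional data (CoDa) are non-negative vectors whose totals are
uninformative -- only relative part sizes carry meaning.  All downstream
log-ratio machinery requires strictly positive entries, so zero counts must
be handled (e.g. by a pseudocount, see :func:`codaratio.simulate.apply_pseudocount`)
before a :class:`CompositionMatrix` can be built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DegeneratePartitionError(ValueError):
    """Raised when a log-ratio is requested for a partition with an empty side."""


def _as_name_list(names: Sequence[str] | None, k: int, prefix: str) -> list[str]:
    if names is None:
        width = max(3, len(str(k)))
        return [f"{prefix}{i+1:0{width}d}" for i in range(k)]
    return [str(v) for v in names]


@dataclass
class CompositionMatrix:
    """An n x p table of strictly positive abundances, samples in rows.

    Parameters
    ----------
    values
        Array of shape (n_samples, n_features) with every entry > 0.
    feature_names
        p unique identifiers (taxa, genes, metabolites ...).
    sample_ids
        n unique sample identifiers.
    """

    values: np.ndarray
    feature_names: list[str] = None
    sample_ids: list[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (samples x features)")
        n, p = self.values.shape
        if n < 1:
            raise ValueError("need at least one sample")
        if p < 2:
            raise ValueError("need at least two features to form a log-ratio")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundances must be finite")
        if np.any(self.values <= 0):
            raise ValueError(
                "abundances must be strictly positive; apply a pseudocount to "
                "zero counts first"
            )
        self.feature_names = _as_name_list(self.feature_names, p, "f")
        self.sample_ids = _as_name_list(self.sample_ids, n, "s")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match column count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx) -> "CompositionMatrix":
        idx = np.asarray(idx)
        return CompositionMatrix(
            self.values[idx],
            list(self.feature_names),
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CompositionMatrix":
        return cls(df.to_numpy(dtype=float), list(map(str, df.columns)), list(map(str, df.index)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


@dataclass(frozen=True)
class BalancePartition:
    """A pair of disjoint feature-index subsets (J+, J-) defining one log-ratio.

    Indices are 0-based and stored sorted.  A partition is *valid* when both
    sides are nonempty; degenerate partitions may exist transiently during
    threshold sweeps but cannot be evaluated as a ratio.
    """

    j_plus: tuple[int, ...]
    j_minus: tuple[int, ...]

    def __post_init__(self) -> None:
        jp = tuple(sorted(int(j) for j in self.j_plus))
        jm = tuple(sorted(int(j) for j in self.j_minus))
        if any(j < 0 for j in jp + jm):
            raise ValueError("feature indices must be non-negative")
        if set(jp) & set(jm):
            raise ValueError("numerator and denominator sets must be disjoint")
        if len(set(jp)) != len(jp) or len(set(jm)) != len(jm):
            raise ValueError("repeated index within a side")
        object.__setattr__(self, "j_plus", jp)
        object.__setattr__(self, "j_minus", jm)

    @property
    def p_plus(self) -> int:
        return len(self.j_plus)

    @property
    def p_minus(self) -> int:
        return len(self.j_minus)

    @property
    def n_active(self) -> int:
        return self.p_plus + self.p_minus

    @property
    def is_valid(self) -> bool:
        return self.p_plus >= 1 and self.p_minus >= 1

    def require_valid(self) -> None:
        if not self.is_valid:
            raise DegeneratePartitionError(
                "log-ratio needs at least one feature on each side "
                f"(got {self.p_plus}+ / {self.p_minus}-)"
            )

    def require_within(self, p: int) -> None:
        if self.j_plus and self.j_plus[-1] >= p:
            raise ValueError(f"numerator index {self.j_plus[-1]} out of range for p={p}")
        if self.j_minus and self.j_minus[-1] >= p:
            raise ValueError(f"denominator index {self.j_minus[-1]} out of range for p={p}")

    def swapped(self) -> "BalancePartition":
        return BalancePartition(self.j_minus, self.j_plus)


def validate_outcome(y, n: int | None = None, require_both_classes: bool = False) -> np.ndarray:
    """Validate a binary outcome vector and return it as an int array."""
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("outcome must be a 1-D vector")
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("outcome labels must be binary in {0, 1}")
    y = y.astype(int)
    if n is not None and y.size != n:
        raise ValueError(f"outcome length {y.size} does not match sample count {n}")
    if require_both_classes and np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    return y
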