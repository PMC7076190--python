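"""Gu-Xu identifiability checks for a DINA Q-matrix.

The DINA model parameters are identifiable iff (after row permutation) the
Q-matrix contains the K x K identity as a submatrix (completeness), every
attribute is required by at least three items, and the columns of the
remaining (J-K) x K submatrix Q* are pairwise distinct.  These conditions are
jointly sufficient and necessary, so the report's ``identifiable`` flag is a
definitive verdict for the DINA model; estimation with a deficient Q-matrix
is still permitted (with a warning) since real assessments are routinely
analyzed regardless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import QMatrix

__all__ = [
    "IdentifiabilityReport",
    "check_completeness",
    "check_attribute_counts",
    "check_distinct_columns",
    "check_identifiability",
]


@dataclass(frozen=True)
class IdentifiabilityReport:
    complete: bool
    attribute_counts: np.ndarray
    min_count_ok: bool
    distinct_columns_ok: bool
    identifiable: bool
    identity_row_indices: tuple[int, ...] | None

    def to_dict(self) -> dict:
        return {
            "complete": self.complete,
            "attribute_counts": [int(c) for c in self.attribute_counts],
            "min_count_ok": self.min_count_ok,
            "distinct_columns_ok": self.distinct_columns_ok,
            "identifiable": self.identifiable,
            "identity_row_indices": (
                None
                if self.identity_row_indices is None
                else [int(i) for i in self.identity_row_indices]
            ),
        }

    def __str__(self) -> str:
        lines = [
            f"complete (contains I_K): {self.complete}",
            f"attribute counts: {list(map(int, self.attribute_counts))}",
            f"every attribute on >= 3 items: {self.min_count_ok}",
            f"Q* columns pairwise distinct: {self.distinct_columns_ok}",
            f"identifiable: {self.identifiable}",
        ]
        if self.identity_row_indices is not None:
            lines.insert(1, f"identity rows (0-based items): {list(self.identity_row_indices)}")
        return "\n".join(lines)


def check_completeness(Q: QMatrix) -> tuple[bool, tuple[int, ...] | None]:
    """Does Q contain every unit row e_k?  Returns the lowest such item per attribute."""
    rows = Q.entries
    indices = []
    for k in range(Q.K):
        unit = np.zeros(Q.K, dtype=np.int8)
        unit[k] = 1
        matches = np.flatnonzero((rows == unit).all(axis=1))
        if matches.size == 0:
            return False, None
        indices.append(int(matches[0]))
    return True, tuple(indices)


def check_attribute_counts(Q: QMatrix) -> tuple[bool, np.ndarray]:
    """Column sums of Q; OK iff every attribute is required by >= 3 items."""
    counts = Q.entries.sum(axis=0).astype(int)
    return bool(counts.min() >= 3), counts


def check_distinct_columns(Q: QMatrix, identity_rows) -> bool:
    """Are the columns of Q* (Q minus the identity rows) pairwise distinct?"""
    if identity_rows is None or len(identity_rows) != Q.K:
        raise ValueError("identity_rows must list one item index per attribute")
    idx = np.asarray(identity_rows, dtype=int)
    if idx.min() < 0 or idx.max() >= Q.J or len(set(idx.tolist())) != Q.K:
        raise ValueError("identity_rows must be distinct valid item indices")
    mask = np.ones(Q.J, dtype=bool)
    mask[idx] = False
    qstar = Q.entries[mask]
    for a in range(Q.K):
        for b in range(a + 1, Q.K):
            if (qstar[:, a] == qstar[:, b]).all():
                return False
    return True


def check_identifiability(Q: QMatrix, warn: bool = False) -> IdentifiabilityReport:
    """Run all three Gu-Xu checks and compose the verdict."""
    complete, identity_rows = check_completeness(Q)
    min_ok, counts = check_attribute_counts(Q)
    distinct_ok = check_distinct_columns(Q, identity_rows) if complete else False
    identifiable = complete and min_ok and distinct_ok
    if warn and not identifiable:
        warnings.warn(
            "Q-matrix fails the Gu-Xu identifiability conditions; "
            "estimates may not be uniquely determined",
            UserWarning,
            stacklevel=2,
        )
    return IdentifiabilityReport(
        complete=complete,
        attribute_counts=counts,
        min_count_ok=min_ok,
        distinct_columns_ok=distinct_ok,
        identifiable=identifiable,
        identity_row_indices=identity_rows,
    )
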