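"""Symptom taxonomy, Q-matrix, and latent-profile enumeration.

The screening instrument measures K binary symptom criteria (for ICD-10
depression, K = 10: C1–C3 "typical", C4–C10 "common"). A Q-matrix records
which criteria influence each item's response. Latent symptom profiles are
binary vectors alpha of length K; every module downstream indexes the 2^K
profiles in one fixed order (binary counting, first criterion least
significant), established here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "CriterionTaxonomy",
    "QMatrix",
    "enumerate_profiles",
    "reduced_profiles",
    "qmatrix_summary",
    "default_taxonomy",
]

#: Closed set of item content domains for depression instruments.
DOMAINS = ("mood", "cognition", "behavior", "somatic", "suicidality")

#: Hard cap on criteria count: profile space is 2^K.
MAX_CRITERIA = 16


class InvalidQMatrixError(ValueError):
    """Raised when a Q-matrix violates its structural invariants."""


@dataclass(frozen=True)
class CriterionTaxonomy:
    """Partition of symptom criteria into typical/common sets plus item domains.

    Parameters
    ----------
    criteria
        Ordered criterion identifiers, e.g. ``("C1", ..., "C10")``.
    typical
        Subset of `criteria` counted as typical symptoms (ICD-10: C1–C3).
    common
        Subset counted as common symptoms (ICD-10: C4–C10).
    domains
        Optional map item-id -> content domain (one of :data:`DOMAINS`).
    """

    criteria: tuple[str, ...]
    typical: tuple[str, ...]
    common: tuple[str, ...]
    domains: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.criteria) < 1:
            raise ValueError("need at least one criterion")
        if set(self.typical) | set(self.common) != set(self.criteria) or set(
            self.typical
        ) & set(self.common):
            raise ValueError("typical and common sets must partition the criteria")
        bad = {d for d in self.domains.values() if d not in DOMAINS}
        if bad:
            raise ValueError(f"unknown domain labels: {sorted(bad)}")

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    @property
    def typical_idx(self) -> np.ndarray:
        return np.array([self.criteria.index(c) for c in self.typical], dtype=int)

    @property
    def common_idx(self) -> np.ndarray:
        return np.array([self.criteria.index(c) for c in self.common], dtype=int)


def default_taxonomy(domains: dict[str, str] | None = None) -> CriterionTaxonomy:
    """ICD-10 depression taxonomy: C1–C3 typical, C4–C10 common."""
    crit = tuple(f"C{i}" for i in range(1, 11))
    return CriterionTaxonomy(
        criteria=crit, typical=crit[:3], common=crit[3:], domains=domains or {}
    )


@dataclass(frozen=True)
class QMatrix:
    """Items × criteria binary incidence matrix.

    Row j marks which symptom criteria influence responses to item j. Every
    item must measure at least one criterion and every criterion must be
    measured by at least one item.
    """

    entries: np.ndarray
    item_ids: tuple[str, ...]
    criteria: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=int)
        object.__setattr__(self, "entries", entries)
        if entries.ndim != 2:
            raise InvalidQMatrixError("Q-matrix must be 2-dimensional")
        if entries.shape != (len(self.item_ids), len(self.criteria)):
            raise InvalidQMatrixError("Q-matrix shape does not match labels")
        if not np.isin(entries, (0, 1)).all():
            raise InvalidQMatrixError("Q-matrix entries must be 0/1")
        if (entries.sum(axis=1) == 0).any():
            bad = [self.item_ids[j] for j in np.flatnonzero(entries.sum(axis=1) == 0)]
            raise InvalidQMatrixError(f"items measuring no criterion: {bad}")
        if (entries.sum(axis=0) == 0).any():
            bad = [self.criteria[k] for k in np.flatnonzero(entries.sum(axis=0) == 0)]
            raise InvalidQMatrixError(f"criteria measured by no item: {bad}")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.entries.shape[1]

    def required(self, item: int | str) -> np.ndarray:
        """Indices of the criteria measured by one item."""
        j = item if isinstance(item, int) else self.item_ids.index(item)
        return np.flatnonzero(self.entries[j])

    def subset(self, keep: list[str]) -> "QMatrix":
        """Restrict to a subset of items (validates column coverage)."""
        idx = [self.item_ids.index(i) for i in keep]
        return QMatrix(self.entries[idx], tuple(keep), self.criteria)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=list(self.item_ids), columns=list(self.criteria)
        )


def enumerate_profiles(n_criteria: int) -> np.ndarray:
    """All 2^K latent profiles in binary-counting order.

    Profile w has component k equal to bit k of w, so the first criterion is
    the least significant bit: for K=2 the order is (0,0),(1,0),(0,1),(1,1).
    Every posterior matrix in the package uses this indexing.

    Returns
    -------
    ndarray of shape (2**n_criteria, n_criteria), dtype int8.
    """
    if not 1 <= n_criteria <= MAX_CRITERIA:
        raise ValueError(
            f"number of criteria must be in [1, {MAX_CRITERIA}], got {n_criteria}"
        )
    w = np.arange(2**n_criteria)
    return ((w[:, None] >> np.arange(n_criteria)) & 1).astype(np.int8)


def reduced_profiles(q_row: np.ndarray) -> np.ndarray:
    """Sub-profiles over the criteria an item actually measures.

    For an item whose Q-row has K* ones, the 2^K* reduced profiles (same
    binary-counting order, restricted to the measured criteria) index the
    item's distinct endorsement probabilities.
    """
    q_row = np.asarray(q_row, dtype=int)
    k_star = int(q_row.sum())
    if k_star < 1:
        raise InvalidQMatrixError("item measures no criterion (all-zero Q-row)")
    return enumerate_profiles(k_star)


def profile_reduction_map(q_row: np.ndarray, n_criteria: int) -> np.ndarray:
    """Map each full-profile index w to its reduced-profile index for an item."""
    req = np.flatnonzero(np.asarray(q_row, dtype=int))
    if req.size == 0:
        raise InvalidQMatrixError("item measures no criterion (all-zero Q-row)")
    alpha = enumerate_profiles(n_criteria)
    return (alpha[:, req].astype(np.int64) @ (1 << np.arange(req.size))).astype(
        np.int64
    )


def qmatrix_summary(q: QMatrix) -> dict:
    """Descriptive Q-matrix moments.

    Reports the criteria-per-item histogram and mean, and the items-per-
    criterion range and mean. The two means satisfy the accounting identity
    mean_criteria_per_item * J == mean_items_per_criterion * K.
    """
    row_sums = q.entries.sum(axis=1)
    col_sums = q.entries.sum(axis=0)
    counts, freq = np.unique(row_sums, return_counts=True)
    return {
        "n_items": q.n_items,
        "n_criteria": q.n_criteria,
        "criteria_per_item_hist": dict(zip(counts.tolist(), freq.tolist())),
        "mean_criteria_per_item": float(row_sums.mean()),
        "items_per_criterion_min": int(col_sums.min()),
        "items_per_criterion_max": int(col_sums.max()),
        "mean_items_per_criterion": float(col_sums.mean()),
    }
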