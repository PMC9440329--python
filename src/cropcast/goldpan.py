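"""Stage 3 — pick each district's regression from a pool of globally and
locally well-performing combinations.

Per-district top picks ("local heroes") overfit single noisy series, so the
default mode builds a candidate pool from the combinations with the highest
mean correlation across all districts plus, for a grid of district fractions
down to 10%, the combination with the best mean over its own top-scoring
fraction of districts.  Each district then takes its best pool member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .workhorse import EvalTable

__all__ = [
    "PoolEntry",
    "SelectionResult",
    "global_heroes",
    "local_heroes_subsets",
    "build_pool",
    "assign_district_combos",
    "local_heroes_only",
]

DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(10, 0, -1))


@dataclass(frozen=True)
class PoolEntry:
    """A candidate combination with where it came from."""

    name: str
    provenance: str  # e.g. "global#1" or "top30%"
    score: float


@dataclass
class SelectionResult:
    """District -> combination assignment for one target year."""

    target_year: int
    pool: list[PoolEntry]
    assignment: dict[str, str]  # district -> combo name
    assigned_r: dict[str, float]

    @property
    def n_distinct(self) -> int:
        """c, the number of distinct combinations actually used."""
        return len(set(self.assignment.values()))

    @property
    def mean_assigned_r(self) -> float:
        vals = [v for v in self.assigned_r.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def _eligible(table: pd.DataFrame, min_coverage: float) -> pd.Series:
    cov = table.notna().mean(axis=1)
    return cov >= min_coverage


def global_heroes(
    eval_table: EvalTable, n_top: int = 5, min_coverage: float = 0.5
) -> list[PoolEntry]:
    """Combinations with the highest mean r across districts (missing cells
    excluded); rows with r in fewer than *min_coverage* of districts are not
    eligible.  Stable ties by row order."""
    t = eval_table.table
    elig = _eligible(t, min_coverage)
    means = t.mean(axis=1, skipna=True)[elig]
    means = means.dropna()
    order = np.argsort(-means.to_numpy(), kind="stable")[:n_top]
    return [
        PoolEntry(name=means.index[i], provenance=f"global#{rank + 1}",
                  score=float(means.iloc[i]))
        for rank, i in enumerate(order)
    ]


def local_heroes_subsets(
    eval_table: EvalTable,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    min_coverage: float = 0.5,
) -> list[PoolEntry]:
    """For each fraction f, the combination with the best mean over its own
    top ceil(f*D) district correlations."""
    t = eval_table.table
    D = t.shape[1]
    elig = _eligible(t, min_coverage)
    sub = t[elig]
    if sub.empty or D == 0:
        return []
    arr = sub.to_numpy(dtype=float)
    # per row, district r values sorted descending with NaN last
    srt = -np.sort(-np.where(np.isfinite(arr), arr, -np.inf), axis=1)
    out: list[PoolEntry] = []
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
        m = max(1, math.ceil(f * D))
        top = srt[:, :m]
        finite = np.isfinite(top)
        with np.errstate(invalid="ignore"):
            score = np.where(finite, top, 0.0).sum(axis=1) / finite.sum(axis=1)
        score = np.where(finite.any(axis=1), score, -np.inf)
        best = int(np.argmax(score))  # first max -> stable tie-break
        if np.isfinite(score[best]):
            out.append(
                PoolEntry(
                    name=sub.index[best],
                    provenance=f"top{round(f * 100)}%",
                    score=float(score[best]),
                )
            )
    return out


def build_pool(
    eval_table: EvalTable,
    n_global: int = 5,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    min_coverage: float = 0.5,
) -> list[PoolEntry]:
    """Merged candidate pool: global heroes first, then one subset hero per
    fraction (descending), duplicates kept once at first appearance."""
    entries = global_heroes(eval_table, n_global, min_coverage)
    entries += local_heroes_subsets(eval_table, fractions, min_coverage)
    seen: set[str] = set()
    pool = []
    for e in entries:
        if e.name not in seen:
            seen.add(e.name)
            pool.append(e)
    return pool


def assign_district_combos(
    pool: list[PoolEntry], eval_table: EvalTable
) -> SelectionResult:
    """Per district, the pool member with the highest r (ties to the earlier
    pool position).  Districts with no finite r over the pool are left
    unassigned."""
    if not pool:
        raise ValueError("empty candidate pool")
    t = eval_table.table
    rows = t.reindex([e.name for e in pool])
    assignment: dict[str, str] = {}
    assigned_r: dict[str, float] = {}
    arr = rows.to_numpy(dtype=float)
    for j, dist in enumerate(t.columns):
        col = arr[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            continue
        masked = np.where(finite, col, -np.inf)
        i = int(np.argmax(masked))  # argmax takes the first max
        assignment[dist] = pool[i].name
        assigned_r[dist] = float(col[i])
    return SelectionResult(
        target_year=eval_table.target_year,
        pool=pool,
        assignment=assignment,
        assigned_r=assigned_r,
    )


def local_heroes_only(eval_table: EvalTable) -> SelectionResult:
    """Alternative mode: per-district argmax over *all* evaluated rows."""
    t = eval_table.table
    assignment: dict[str, str] = {}
    assigned_r: dict[str, float] = {}
    arr = t.to_numpy(dtype=float)
    for j, dist in enumerate(t.columns):
        col = arr[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            continue
        i = int(np.argmax(np.where(finite, col, -np.inf)))
        assignment[dist] = t.index[i]
        assigned_r[dist] = float(col[i])
    pool = [
        PoolEntry(name=n, provenance="local", score=float("nan"))
        for n in dict.fromkeys(assignment.values())
    ]
    return SelectionResult(
        target_year=eval_table.target_year,
        pool=pool,
        assignment=assignment,
        assigned_r=assigned_r,
    )
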