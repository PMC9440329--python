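"""Stage 2 — out-of-sample skill of every valid combination of screened
features.

Every subset of the screened features of size 0..d_max (trend-only included,
same-variable windows must not overlap) is scored per district by the
Pearson correlation between observed yields and leave-one-out predictions.
In strict mode the target year is removed from the district's data entirely,
so the whole table is invariant to the target year's yields.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._ols import FIT_MARGIN, DistrictDesign, masked_pearson
from .features import FeatureWindow
from .prospector import compatibility_matrix

__all__ = [
    "EvalTable",
    "combo_name",
    "enumerate_valid_combos",
    "loo_predictions",
    "evaluate_combo",
    "build_eval_table",
]

TREND_ONLY = "trend"


def combo_name(features: Sequence[str]) -> str:
    """Row label for a feature subset: names joined by '+', 'trend' for d=0."""
    return "+".join(features) if features else TREND_ONLY


@dataclass
class EvalTable:
    """Combination x district table of out-of-sample Pearson correlations."""

    target_year: int
    table: pd.DataFrame  # index: combo name, columns: district ids
    combos: dict[str, tuple[str, ...]]  # combo name -> feature names

    @property
    def n_rows(self) -> int:
        """A_y, the number of evaluated combinations."""
        return len(self.table)

    @property
    def districts(self) -> list[str]:
        return list(self.table.columns)


def enumerate_valid_combos(
    screened: Sequence[str],
    windows_by_name: Mapping[str, tuple[str, FeatureWindow]],
    d_max: int = 4,
    enforce_nonoverlap: bool = True,
) -> list[tuple[str, ...]]:
    """All subsets of the screened features of size 0..d_max that satisfy the
    same-variable non-overlap constraint, ordered by size then feature order.

    The screened feature order is preserved inside each subset.
    """
    compat = (
        compatibility_matrix(screened, windows_by_name) if enforce_nonoverlap else None
    )
    out: list[tuple[str, ...]] = []
    for size in range(0, min(d_max, len(screened)) + 1):
        for idx in itertools.combinations(range(len(screened)), size):
            if compat is not None and not all(
                compat[a, b] for a, b in itertools.combinations(idx, 2)
            ):
                continue
            out.append(tuple(screened[i] for i in idx))
    return out


def loo_predictions(
    yields: pd.Series,
    district_features: pd.DataFrame,
    features: Sequence[str],
    target_year: int | None = None,
    strict: bool = True,
) -> pd.Series:
    """Leave-one-out predictions for one district and one feature subset.

    The prediction for year j comes from a fit that excludes y(j); with
    ``strict`` the target year is dropped from the data entirely (its pair
    does not enter downstream correlations).  Years with missing yield or
    missing feature values get no prediction.
    """
    obs = yields.dropna()
    if strict and target_year is not None:
        obs = obs[obs.index != target_year]
    feats = district_features.reindex(obs.index)[list(features)]
    ok = feats.notna().all(axis=1)
    years = obs.index[ok.to_numpy()]
    d = len(features)
    if len(years) < d + FIT_MARGIN + 1:
        return pd.Series(dtype=float)
    design = DistrictDesign(
        np.asarray(years, dtype=float),
        obs.loc[years].to_numpy(),
        feats.loc[years].to_numpy(dtype=float),
    )
    combo = np.arange(d, dtype=np.intp)[None, :]
    preds = design.batch_loo(combo)[0]
    return pd.Series(preds, index=years).dropna()


def evaluate_combo(
    observed: pd.Series, predicted: pd.Series, min_pairs: int = 3
) -> float:
    """Pearson r between observed and predicted, pairwise-complete; NaN when
    fewer than *min_pairs* pairs remain or either series is constant."""
    joined = pd.concat([observed, predicted], axis=1, join="inner").dropna()
    if len(joined) < min_pairs:
        return float("nan")
    o = joined.iloc[:, 0].to_numpy(dtype=float)
    p = joined.iloc[:, 1].to_numpy(dtype=float)
    return float(masked_pearson(p[None, :], o, min_pairs=min_pairs)[0])


def build_eval_table(
    feature_matrix,
    yields: pd.DataFrame,
    target_year: int,
    screened: Sequence[str],
    d_max: int = 4,
    strict: bool = True,
    min_pairs: int = 8,
    min_years: int = 17,
    enforce_nonoverlap: bool = True,
    combos: Sequence[tuple[str, ...]] | None = None,
) -> EvalTable:
    """Score every valid combination in every district for one target year."""
    if combos is None:
        combos = enumerate_valid_combos(
            screened, feature_matrix.windows_by_name(), d_max, enforce_nonoverlap
        )
    names = [combo_name(c) for c in combos]
    pool = list(screened)
    pos = {f: i for i, f in enumerate(pool)}
    combo_idx = [np.asarray([pos[f] for f in c], dtype=np.intp) for c in combos]
    by_size: dict[int, list[int]] = {}
    for i, c in enumerate(combos):
        by_size.setdefault(len(c), []).append(i)

    districts = [d_ for d_ in feature_matrix.districts if d_ in yields.index]
    table = pd.DataFrame(np.nan, index=names, columns=districts)

    for dist in districts:
        obs = yields.loc[dist].dropna()
        if strict:
            obs = obs[obs.index != target_year]
        feats = feature_matrix.district_frame(dist).reindex(obs.index)[pool]
        # group combos by their complete-row mask so each group is batched
        fmask = feats.notna().to_numpy()
        ymask = np.ones(len(obs), dtype=bool)
        col = np.full(len(names), np.nan)
        for size, members in by_size.items():
            groups: dict[bytes, list[int]] = {}
            for i in members:
                m = ymask & (
                    fmask[:, combo_idx[i]].all(axis=1) if size else ymask
                )
                groups.setdefault(m.tobytes(), []).append(i)
            for key, idxs in groups.items():
                m = np.frombuffer(key, dtype=bool)
                years = obs.index[m]
                if len(years) < max(min_years, size + FIT_MARGIN + 1):
                    continue
                design = DistrictDesign(
                    np.asarray(years, dtype=float),
                    obs.loc[years].to_numpy(),
                    feats.loc[years].to_numpy(dtype=float),
                )
                carr = (
                    np.asarray([combo_idx[i] for i in idxs], dtype=np.intp)
                    if size
                    else np.empty((len(idxs), 0), dtype=np.intp)
                )
                preds = design.batch_loo(carr)
                r = masked_pearson(preds, design.y, min_pairs=min_pairs)
                col[idxs] = r
        table[dist] = col
    return EvalTable(target_year=target_year, table=table, combos=dict(zip(names, combos)))
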