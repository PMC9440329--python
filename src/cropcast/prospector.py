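"""Stage 1 — exhaustive in-sample subset search and binomial feature screening.

For every district and target year, all d-feature regressions (trend always
included) are ranked by in-sample fit with the target year's yield censored.
The top K specs per district are pooled over districts; a feature whose
occurrence count exceeds the 99.9% binomial quantile of the pure-chance null
(each regression drawing d of the F features at random) survives screening.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._ols import FIT_MARGIN, DistrictDesign
from .features import FeatureWindow, windows_overlap

__all__ = [
    "ScreeningResult",
    "compatibility_matrix",
    "enumerate_full_combos",
    "combo_count",
    "top_k_regressions",
    "count_feature_frequencies",
    "binomial_cutoff",
    "screening_moments",
    "select_significant_features",
    "screen_features",
    "simulate_null_selection_rate",
]


@dataclass
class ScreeningResult:
    """Outcome of the occurrence-frequency screening for one target year."""

    target_year: int
    counts: pd.Series  # feature name -> occurrence count among retained specs
    n: int  # total retained regressions x slots base (districts x K)
    p: float  # per-slot null probability d / n_features
    expectation: float  # n * p
    sigma: float  # sqrt(n p (1-p))
    threshold: int  # 99.9% binomial quantile
    selected: list[str]  # features with count > threshold
    n_districts: int = 0
    fallback_used: bool = False

    @property
    def q(self) -> int:
        return len(self.selected)


def compatibility_matrix(
    feature_names: Sequence[str],
    windows_by_name: Mapping[str, tuple[str, FeatureWindow]],
) -> np.ndarray:
    """Boolean (F, F) matrix; entry is False iff two features of the *same*
    weather variable have overlapping windows (such pairs may not share a
    regression)."""
    F = len(feature_names)
    ok = np.ones((F, F), dtype=bool)
    for i, a in enumerate(feature_names):
        va, wa = windows_by_name[a]
        for j in range(i + 1, F):
            vb, wb = windows_by_name[feature_names[j]]
            if va == vb and windows_overlap(wa, wb):
                ok[i, j] = ok[j, i] = False
    return ok


def enumerate_full_combos(
    feature_names: Sequence[str],
    d: int,
    compat: np.ndarray | None = None,
) -> Iterator[tuple[int, ...]]:
    """All size-*d* feature subsets as index tuples, in lexicographic order
    over the given feature order, optionally filtered by the same-variable
    non-overlap constraint (*compat* from :func:`compatibility_matrix`)."""
    if d > len(feature_names):
        return iter(())
    idx = range(len(feature_names))
    if compat is None:
        return itertools.combinations(idx, d)

    def gen() -> Iterator[tuple[int, ...]]:
        for combo in itertools.combinations(idx, d):
            if all(compat[a, b] for a, b in itertools.combinations(combo, 2)):
                yield combo

    return gen()


def combo_count(
    n_features: int, d: int, feature_names: Sequence[str] | None = None,
    compat: np.ndarray | None = None,
) -> int:
    """Number of size-*d* subsets; closed form without the constraint,
    filtered enumeration with it."""
    if compat is None:
        return math.comb(n_features, d)
    names = feature_names if feature_names is not None else [str(i) for i in range(n_features)]
    return sum(1 for _ in enumerate_full_combos(names, d, compat))


def combos_array(
    feature_names: Sequence[str], d: int, compat: np.ndarray | None = None
) -> np.ndarray:
    """Materialised combos as an (C, d) index array (deterministic order)."""
    combos = list(enumerate_full_combos(feature_names, d, compat))
    if not combos:
        return np.empty((0, d), dtype=np.intp)
    return np.asarray(combos, dtype=np.intp)


def top_k_regressions(
    yields: pd.Series,
    district_features: pd.DataFrame,
    target_year: int,
    combos: np.ndarray,
    k: int,
    min_years: int = 17,
) -> list[tuple[float, tuple[int, ...]]] | None:
    """Top-*k* feature subsets for one district by in-sample R² with the
    target year censored.

    *yields* is indexed by harvest year; *district_features* holds the pool
    columns indexed by harvest year.  Returns ``None`` if the district has
    fewer than *min_years* usable observations.  Ties are broken by
    enumeration (lexicographic) order.
    """
    d = combos.shape[1] if combos.ndim == 2 else 0
    years = yields.dropna().index
    years = years[years != target_year]
    feats = district_features.reindex(years)
    row_ok = feats.notna().all(axis=1)
    years = years[row_ok.to_numpy()]
    if len(years) < max(min_years, d + FIT_MARGIN):
        return None
    design = DistrictDesign(
        np.asarray(years, dtype=float),
        yields.loc[years].to_numpy(),
        district_features.loc[years].to_numpy(dtype=float),
    )
    r2 = design.batch_r2(combos)
    order = np.argsort(-r2, kind="stable")[:k]
    return [(float(r2[i]), tuple(int(j) for j in combos[i])) for i in order
            if np.isfinite(r2[i])]


def count_feature_frequencies(
    top_lists: Iterable[Sequence[tuple[float, tuple[int, ...]]]],
    feature_names: Sequence[str],
) -> pd.Series:
    """Multiset tally of feature occurrences over all retained specs."""
    counts: Counter[int] = Counter()
    for lst in top_lists:
        for _, combo in lst:
            counts.update(combo)
    out = pd.Series(0, index=list(feature_names), dtype=int)
    for i, c in counts.items():
        out.iloc[i] = c
    return out


def binomial_cutoff(n: int, p: float, confidence: float = 0.999) -> int:
    """Smallest count k with binomial CDF(k; n, p) >= confidence."""
    if not 0 <= p <= 1:
        raise ValueError("p outside [0, 1]")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0 or p == 0:
        return 0
    return int(binom.ppf(confidence, n, p))


def screening_moments(n: int, p: float) -> tuple[float, float]:
    """Mean and standard deviation of the occurrence count under the null."""
    return n * p, math.sqrt(n * p * (1.0 - p))


def select_significant_features(counts: pd.Series, threshold: int) -> list[str]:
    """Features occurring strictly more often than the chance threshold,
    ordered by count (descending), ties by name."""
    sel = counts[counts > threshold]
    sel = sel.sort_index().sort_values(ascending=False, kind="stable")
    return list(sel.index)


def screen_features(
    feature_matrix,
    yields: pd.DataFrame,
    target_year: int,
    k: int = 23,
    d: int = 4,
    confidence: float = 0.999,
    min_years: int = 17,
    enforce_nonoverlap: bool = True,
    fallback_top_m: int = 10,
    combos: np.ndarray | None = None,
    n_jobs: int = 1,
) -> ScreeningResult:
    """Run the per-district searches for one target year and screen features.

    *yields* is a wide table (district index, year columns).  The null
    probability is ``d / F`` regardless of the actual retained spec sizes.
    Pass a precomputed *combos* array to reuse the enumeration across years.
    """
    names = feature_matrix.feature_names
    F = len(names)
    if combos is None:
        compat = (
            compatibility_matrix(names, feature_matrix.windows_by_name())
            if enforce_nonoverlap
            else None
        )
        combos = combos_array(names, d, compat)

    def one_district(dist: str):
        if dist not in yields.index:
            return None
        return top_k_regressions(
            yields.loc[dist],
            feature_matrix.district_frame(dist),
            target_year,
            combos,
            k,
            min_years,
        )

    districts = feature_matrix.districts
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one_district)(d_) for d_ in districts)
    else:
        results = [one_district(d_) for d_ in districts]

    top_lists = [r for r in results if r]
    counts = count_feature_frequencies(top_lists, names)
    n = sum(len(lst) for lst in top_lists)
    p = d / F if F else 0.0
    exp, sig = screening_moments(n, p)
    threshold = binomial_cutoff(n, p, confidence)
    selected = select_significant_features(counts, threshold)
    fallback = False
    if not selected and fallback_top_m > 0 and counts.sum() > 0:
        ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
        selected = list(ordered.index[:fallback_top_m])
        fallback = True
    return ScreeningResult(
        target_year=target_year,
        counts=counts,
        n=n,
        p=p,
        expectation=exp,
        sigma=sig,
        threshold=threshold,
        selected=selected,
        n_districts=len(top_lists),
        fallback_used=fallback,
    )


def simulate_null_selection_rate(
    n_samples: int,
    n_features: int,
    d: int,
    confidence: float = 0.999,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    mechanism: str = "binomial",
) -> float:
    """Monte-Carlo false-selection rate per feature under the pure-chance null.

    ``mechanism='binomial'`` draws each feature's count directly from
    Binomial(n, d/F); ``mechanism='draws'`` simulates n regressions each
    picking d distinct features uniformly (slower, exact mechanism).
    Returns the mean fraction of features exceeding the screening cutoff.
    """
    rng = rng or np.random.default_rng()
    p = d / n_features
    cutoff = binomial_cutoff(n_samples, p, confidence)
    if mechanism == "binomial":
        counts = rng.binomial(n_samples, p, size=(reps, n_features))
    elif mechanism == "draws":
        counts = np.zeros((reps, n_features), dtype=int)
        for r in range(reps):
            keys = rng.random((n_samples, n_features))
            picks = np.argpartition(keys, d - 1, axis=1)[:, :d]
            np.add.at(counts[r], picks.ravel(), 1)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return float((counts > cutoff).mean())
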