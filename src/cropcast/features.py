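"""Time-aggregated weather features from monthly district weather series.

A *feature* is the mean or sum of one weather variable over a contiguous
span of 2-6 calendar months ("window") inside the 12-month season that ends
at a crop-specific cut-off month.  Features are named by the variable id
followed by the zero-padded start and end months, e.g. ``tas0506`` is the
May-June temperature mean and ``pr1102`` the November-February precipitation
sum of the months preceding the harvest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MONTHS_PER_YEAR = 12

__all__ = [
    "FeatureWindow",
    "WeatherVariable",
    "FeatureMatrix",
    "season_months",
    "enumerate_windows",
    "windows_overlap",
    "feature_name",
    "parse_feature_name",
    "aggregate_feature",
    "build_feature_matrix",
]


@dataclass(frozen=True, order=True)
class FeatureWindow:
    """Contiguous span of calendar months, inclusive on both ends.

    The span may wrap the calendar-year boundary (e.g. start 11, end 2 is
    November through February).
    """

    start_month: int
    end_month: int

    def __post_init__(self) -> None:
        for m in (self.start_month, self.end_month):
            if not 1 <= m <= MONTHS_PER_YEAR:
                raise ValueError(f"month {m} outside 1..12")

    @property
    def length(self) -> int:
        if self.end_month >= self.start_month:
            return self.end_month - self.start_month + 1
        return MONTHS_PER_YEAR - self.start_month + 1 + self.end_month

    def months(self) -> tuple[int, ...]:
        """Calendar months covered, in span order."""
        return tuple(
            (self.start_month - 1 + i) % MONTHS_PER_YEAR + 1 for i in range(self.length)
        )


@dataclass(frozen=True)
class WeatherVariable:
    """A monthly weather variable and its window aggregation operator."""

    id: str
    units: str = ""
    op: str = "mean"

    def __post_init__(self) -> None:
        if self.op not in ("mean", "sum"):
            raise ValueError(f"aggregation op must be 'mean' or 'sum', got {self.op!r}")
        if not re.fullmatch(r"[A-Za-z]\w*?", self.id) or self.id[-1].isdigit():
            raise ValueError(f"variable id {self.id!r} must not end in a digit")


def season_months(cutoff_month: int, season_length: int = 12) -> list[int]:
    """Calendar months of the pre-harvest season, ending at *cutoff_month*."""
    if not 1 <= cutoff_month <= MONTHS_PER_YEAR:
        raise ValueError("cutoff_month outside 1..12")
    if not 1 <= season_length <= MONTHS_PER_YEAR:
        raise ValueError("season_length outside 1..12")
    first = cutoff_month - season_length  # zero-based, may be negative
    return [(first + i) % MONTHS_PER_YEAR + 1 for i in range(season_length)]


def enumerate_windows(
    season_length: int = 12,
    min_len: int = 2,
    max_len: int = 6,
    cutoff_month: int = 12,
) -> list[FeatureWindow]:
    """All contiguous windows of ``min_len..max_len`` months inside the season.

    Ordered by length, then by start position within the season; the count is
    ``sum(season_length + 1 - L for L in min_len..max_len)`` (45 for the
    default 2-6 month windows in a 12-month season).
    """
    if not 1 <= min_len <= max_len <= season_length:
        raise ValueError(
            f"need 1 <= min_len <= max_len <= season_length, "
            f"got ({min_len}, {max_len}, {season_length})"
        )
    season = season_months(cutoff_month, season_length)
    out = []
    for length in range(min_len, max_len + 1):
        for start in range(season_length - length + 1):
            out.append(FeatureWindow(season[start], season[start + length - 1]))
    return out


def windows_overlap(w1: FeatureWindow, w2: FeatureWindow) -> bool:
    """True iff the two windows share at least one calendar month."""
    return bool(set(w1.months()) & set(w2.months()))


def feature_name(variable_id: str, window: FeatureWindow) -> str:
    """Render e.g. ``('tas', May-Jun)`` as ``'tas0506'``."""
    return f"{variable_id}{window.start_month:02d}{window.end_month:02d}"


_NAME_RE = re.compile(r"^([A-Za-z]\w*?)(\d{2})(\d{2})$")


def parse_feature_name(
    name: str, variables: Iterable[str] | None = None
) -> tuple[str, FeatureWindow]:
    """Inverse of :func:`feature_name`; raises ``ValueError`` on bad input."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse feature name {name!r}")
    var, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if variables is not None and var not in set(variables):
        raise ValueError(f"unknown variable id {var!r} in feature {name!r}")
    return var, FeatureWindow(start, end)


def _month_year(month: int, harvest_year: int, cutoff_month: int) -> int:
    # months after the cut-off belong to the calendar year before harvest
    return harvest_year if month <= cutoff_month else harvest_year - 1


def aggregate_feature(
    panel: pd.DataFrame,
    district: str,
    harvest_year: int,
    variable: WeatherVariable,
    window: FeatureWindow,
    cutoff_month: int,
) -> float:
    """Aggregate one window for one district and harvest year.

    *panel* is a long table with columns ``district``, ``year``, ``month`` and
    one column per variable id.  Returns NaN if any month of the window is
    absent or missing (no silent imputation).
    """
    if window.length > MONTHS_PER_YEAR:
        raise ValueError("window longer than a year")
    sub = panel.loc[panel["district"] == district]
    keyed = sub.set_index(["year", "month"])[variable.id]
    vals = []
    for m in window.months():
        key = (_month_year(m, harvest_year, cutoff_month), m)
        if key not in keyed.index:
            return float("nan")
        vals.append(keyed.loc[key])
    arr = np.asarray(vals, dtype=float)
    if np.isnan(arr).any():
        return float("nan")
    return float(arr.mean() if variable.op == "mean" else arr.sum())


@dataclass
class FeatureMatrix:
    """District x harvest-year x feature table of aggregated weather values.

    ``data`` is indexed by ``(district, harvest_year)`` with one column per
    feature name; ``features`` maps each name to its variable and window.
    """

    data: pd.DataFrame
    features: dict[str, tuple[WeatherVariable, FeatureWindow]]
    cutoff_month: int = 12

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def districts(self) -> list[str]:
        return sorted(self.data.index.get_level_values("district").unique())

    def district_frame(self, district: str) -> pd.DataFrame:
        """Feature values for one district, indexed by harvest year."""
        return self.data.xs(district, level="district")

    def windows_by_name(self) -> dict[str, tuple[str, FeatureWindow]]:
        return {n: (v.id, w) for n, (v, w) in self.features.items()}


def build_feature_matrix(
    panel: pd.DataFrame,
    variables: Sequence[WeatherVariable],
    cutoff_month: int,
    window_bounds: tuple[int, int] = (2, 6),
    season_length: int = 12,
) -> FeatureMatrix:
    """Compute every (variable, window) aggregate for all districts and years.

    A cell is present iff every month of its window is present in the panel;
    harvest years whose season is not fully covered get missing cells.
    """
    min_len, max_len = window_bounds
    windows = enumerate_windows(season_length, min_len, max_len, cutoff_month)
    season = season_months(cutoff_month, season_length)
    pos_of_month = {m: i for i, m in enumerate(season)}

    sub = panel.loc[panel["month"].isin(season)].copy()
    sub["harvest_year"] = sub["year"] + (sub["month"] > cutoff_month).astype(int)
    sub["pos"] = sub["month"].map(pos_of_month)

    frames: list[pd.DataFrame] = []
    features: dict[str, tuple[WeatherVariable, FeatureWindow]] = {}
    for var in variables:
        if var.id not in panel.columns:
            raise KeyError(f"variable {var.id!r} not in weather panel")
        wide = sub.pivot(
            index=["district", "harvest_year"], columns="pos", values=var.id
        )
        wide = wide.reindex(columns=range(season_length))
        arr = wide.to_numpy(dtype=float)
        cols = {}
        for w in windows:
            p0 = pos_of_month[w.start_month]
            block = arr[:, p0 : p0 + w.length]
            agg = block.mean(axis=1) if var.op == "mean" else block.sum(axis=1)
            # numpy propagates NaN without skipping, which is what we want
            name = feature_name(var.id, w)
            cols[name] = agg
            features[name] = (var, w)
        frames.append(pd.DataFrame(cols, index=wide.index))

    data = pd.concat(frames, axis=1).sort_index()
    data.index = data.index.set_names(["district", "harvest_year"])
    return FeatureMatrix(data=data, features=features, cutoff_month=cutoff_month)
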