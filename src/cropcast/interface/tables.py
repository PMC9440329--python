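"""Readers and writers for the delimited ASCII table dialect.

All tables are header-first, tab-delimited by default, UTF-8, decimal point,
missing token ``NA``.  District ids are opaque strings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKEN = "NA"
FLOAT_FMT = "%.6f"


def _read(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False, dtype={"district": str}
    )
    return df


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _no_duplicates(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        line = int(dup.idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: duplicate {keys} key at line {line}")


def read_weather_table(path, sep: str = "\t", layout: str = "wide") -> pd.DataFrame:
    """Monthly weather panel.

    ``wide`` layout: one row per (district, year, month) with one column per
    variable; ``long`` layout: columns district, year, month, variable, value.
    Both parse to the same wide in-memory panel.
    """
    df = _read(path, sep)
    if layout == "long":
        _require(df, ["district", "year", "month", "variable", "value"], path)
        _no_duplicates(df, ["district", "year", "month", "variable"], path)
        df = (
            df.pivot(index=["district", "year", "month"], columns="variable", values="value")
            .reset_index()
        )
        df.columns.name = None
    elif layout == "wide":
        _require(df, ["district", "year", "month"], path)
        _no_duplicates(df, ["district", "year", "month"], path)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    for col in ("year", "month"):
        bad = df[col].isna() | (df[col].astype(float) % 1 != 0)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: malformed {col} at line {line}")
        df[col] = df[col].astype(int)
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        raise ValueError(f"{path}: month outside 1..12")
    return df.sort_values(["district", "year", "month"]).reset_index(drop=True)


def write_weather_table(panel: pd.DataFrame, path, sep: str = "\t") -> None:
    panel.to_csv(path, sep=sep, index=False, na_rep=NA_TOKEN, float_format=FLOAT_FMT)


def read_yield_table(path, sep: str = "\t") -> pd.DataFrame:
    """Annual yields (dt/ha) as a district x year wide table; missing years
    allowed, negative yields rejected."""
    df = _read(path, sep)
    _require(df, ["district", "year", "yield"], path)
    _no_duplicates(df, ["district", "year"], path)
    df["year"] = df["year"].astype(int)
    neg = df["yield"] < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ValueError(f"{path}: negative yield at line {line}")
    wide = df.pivot(index="district", columns="year", values="yield")
    wide.index.name = "district"
    return wide.sort_index()


def write_yield_table(yields: pd.DataFrame, path, sep: str = "\t") -> None:
    long = yields.stack(future_stack=True).rename("yield").reset_index()
    long = long.dropna(subset=["yield"])
    long.columns = ["district", "year", "yield"]
    long.to_csv(path, sep=sep, index=False, na_rep=NA_TOKEN, float_format=FLOAT_FMT)


def read_area_table(path, sep: str = "\t") -> pd.Series:
    """Growing areas (ha) used as aggregation weights."""
    df = _read(path, sep)
    _require(df, ["district", "area"], path)
    _no_duplicates(df, ["district"], path)
    if (df["area"] < 0).any():
        raise ValueError(f"{path}: negative growing area")
    s = df.set_index("district")["area"].astype(float)
    if not (s > 0).any():
        raise ValueError(f"{path}: no district with positive area")
    return s.sort_index()


def write_area_table(areas: pd.Series, path, sep: str = "\t") -> None:
    areas.rename("area").rename_axis("district").reset_index().to_csv(
        path, sep=sep, index=False, float_format=FLOAT_FMT
    )


def read_region_map(path, sep: str = "\t") -> pd.Series:
    df = _read(path, sep)
    _require(df, ["district", "region"], path)
    _no_duplicates(df, ["district"], path)
    return df.set_index("district")["region"].astype(str).sort_index()


def write_region_map(region_map: pd.Series, path, sep: str = "\t") -> None:
    region_map.rename("region").rename_axis("district").reset_index().to_csv(
        path, sep=sep, index=False
    )


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Generic labelled matrix (index kept) with NA for missing."""
    df.to_csv(path, sep=sep, na_rep=NA_TOKEN, float_format=FLOAT_FMT)


def read_matrix(path, sep: str = "\t", index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False, index_col=index_col
    )
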