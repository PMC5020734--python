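"""Effort standardization, proportional scaling and regression imputation.

Raw survey tables are unevenly sampled: transect effort differs between
years and some years were not surveyed at all. This module rescales counts
to a common reference effort, converts each annual vector to standardized
proportional contributions (percent x 100 scaling of the size-frequency
composition), and fills unsurveyed years by per-class ordinary
least-squares regression on year. Strata are always processed
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import EmptySampleError, SizeClassScheme

__all__ = [
    "ImputationConfig",
    "standardize_effort",
    "to_proportional",
    "to_proportional_frame",
    "impute_missing_years",
    "series_vectors",
]

PROPORTION_TOL = 1e-9


@dataclass(frozen=True)
class ImputationConfig:
    """Which years to fill and which observed years feed the regression."""

    target_years: tuple[int, ...]
    window_years: tuple[int, ...]
    clip_negative: bool = True

    def __post_init__(self) -> None:
        targets = set(self.target_years)
        window = set(self.window_years)
        if targets & window:
            raise ValueError("target years must not appear in the window")
        if len(window) < 2:
            raise ValueError("regression window needs at least 2 distinct years")


def _count_columns(df: pd.DataFrame,
                   scheme: SizeClassScheme | None = None) -> list[str]:
    if scheme is not None:
        return scheme.column_names()
    meta = {"year", "stratum", "transects", "unit", "imputed"}
    return [c for c in df.columns if c not in meta]


def standardize_effort(df: pd.DataFrame, reference_transects: int,
                       scheme: SizeClassScheme | None = None) -> pd.DataFrame:
    """Rescale counts to a common transect effort.

    Every class count is multiplied by reference_transects / transects for
    its row (e.g. a 3-transect year is doubled to match 6-transect years);
    the unit tag becomes ``standardized_count``.
    """
    if reference_transects < 1:
        raise ValueError("reference transect count must be >= 1")
    if (df["transects"] < 1).any():
        bad = df.loc[df["transects"] < 1, "year"].tolist()
        raise ValueError(f"rows with zero transects cannot be standardized: {bad}")
    cols = _count_columns(df, scheme)
    out = df.copy()
    factor = reference_transects / out["transects"].to_numpy(dtype=float)
    out[cols] = out[cols].to_numpy(dtype=float) * factor[:, np.newaxis]
    out["unit"] = "standardized_count"
    return out


def to_proportional(vector) -> np.ndarray:
    """Scale a stage vector to percent contributions (sums to 100).

    Raises :class:`EmptySampleError` on an all-zero vector rather than
    silently producing NaN.
    """
    x = np.asarray(vector, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise EmptySampleError("cannot take proportions of an all-zero vector")
    return 100.0 * x / total


def to_proportional_frame(df: pd.DataFrame,
                          scheme: SizeClassScheme | None = None) -> pd.DataFrame:
    """Row-wise proportional scaling of a survey table; unit becomes
    ``proportional``."""
    cols = _count_columns(df, scheme)
    out = df.copy()
    vals = out[cols].to_numpy(dtype=float)
    out[cols] = np.vstack([to_proportional(row) for row in vals])
    out["unit"] = "proportional"
    return out


def _ols_line(years: np.ndarray, values: np.ndarray):
    # closed-form degree-1 least squares; exact for >= 2 distinct years
    slope, intercept = np.polyfit(years, values, 1)
    return slope, intercept


def impute_missing_years(df: pd.DataFrame, config: ImputationConfig,
                         scheme: SizeClassScheme | None = None) -> pd.DataFrame:
    """Fill unsurveyed years by per-class linear regression on year.

    For every stratum and size class independently, an ordinary
    least-squares line value ~ year is fitted on the window years and
    evaluated at each target year. Negative fitted values are clipped to
    zero when ``clip_negative`` is set. Imputed rows carry imputed=True and
    a transect count of 0 (no field effort backs them).
    """
    cols = _count_columns(df, scheme)
    pieces = [df]
    for stratum, grp in df.groupby("stratum", sort=False):
        window = grp[grp["year"].isin(config.window_years)]
        if window["year"].nunique() < 2:
            raise ValueError(
                f"stratum {stratum!r}: fewer than 2 window years present")
        years = window["year"].to_numpy(dtype=float)
        fits = [_ols_line(years, window[c].to_numpy(dtype=float)) for c in cols]
        unit = grp["unit"].iloc[0] if "unit" in grp else "raw"
        new_rows = []
        for ty in config.target_years:
            if (grp["year"] == ty).any():
                continue  # already observed; nothing to fill
            row = {"year": ty, "stratum": stratum, "transects": 0,
                   "unit": unit, "imputed": True}
            for c, (slope, intercept) in zip(cols, fits):
                v = slope * ty + intercept
                if config.clip_negative and v < 0:
                    v = 0.0
                row[c] = v
            new_rows.append(row)
        if new_rows:
            pieces.append(pd.DataFrame(new_rows, columns=df.columns))
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["stratum", "year"], kind="stable").reset_index(drop=True)


def series_vectors(df: pd.DataFrame, stratum: str,
                   years=None,
                   scheme: SizeClassScheme | None = None) -> tuple[np.ndarray, list[int]]:
    """Extract the annual stage vectors of one stratum as an array.

    Returns (vectors, years) with vectors of shape (n_years, k) in
    ascending year order; ``years`` restricts the selection.
    """
    cols = _count_columns(df, scheme)
    sub = df[df["stratum"] == stratum]
    if years is not None:
        sub = sub[sub["year"].isin(list(years))]
    sub = sub.sort_values("year", kind="stable")
    if sub["year"].duplicated().any():
        raise ValueError(f"duplicate years in stratum {stratum!r}")
    return sub[cols].to_numpy(dtype=float), sub["year"].astype(int).tolist()
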