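"""Cross-table summaries of movement rates.

Per-quadrant regression rates are signed coordinates: under patch
expansion the boundary's northing rises in the N quadrant and falls in the
S quadrant, so the sign convention is flipped for S and W to obtain an
*oriented* rate in which positive always means expansion.  Oriented rates
are averaged by direction, pooled into an overall mean with a t-based 95%
margin of error, and placed alongside published forest-advance rates from
other ecotones (shipped as a packaged CSV; ranges enter as midpoints of
their printed bounds).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_quadrant_rates",
    "load_site_summary",
    "load_literature_rates",
    "orient_rates",
    "directional_means",
    "overall_mean_with_me",
    "literature_means",
    "compare_to_literature",
]

_SIGN = {"N": 1.0, "E": 1.0, "S": -1.0, "W": -1.0}


def _data(name: str) -> pd.DataFrame:
    with resources.files("monodom.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_quadrant_rates() -> pd.DataFrame:
    """Published per-quadrant boundary movement rates (m yr⁻¹, signed)."""
    return _data("quadrant_movement_rates.csv")


def load_site_summary() -> pd.DataFrame:
    """Published per-site gyration occupancy and expansion rates."""
    return _data("site_gyration_summary.csv")


def load_literature_rates() -> pd.DataFrame:
    """Published forest-advance rates from other ecotones."""
    return _data("literature_expansion_rates.csv")


def orient_rates(rates: pd.DataFrame) -> pd.DataFrame:
    """Add ``oriented_rate``: positive = expansion regardless of quadrant."""
    out = rates.copy()
    try:
        signs = out["quadrant"].map(_SIGN)
    except KeyError:
        raise ValueError("missing quadrant column")
    if signs.isna().any():
        bad = out.loc[signs.isna(), "quadrant"].unique()
        raise ValueError(f"unknown quadrant labels {list(bad)}")
    out["oriented_rate"] = out["rate"] * signs
    return out


def directional_means(
    oriented: pd.DataFrame, omit: list[float] | None = None
) -> dict[str, float]:
    """Arithmetic mean of oriented rates per cardinal direction.

    ``omit`` lists oriented-rate values to exclude (outlier handling).
    """
    out = {}
    for q in "NESW":
        vals = oriented.loc[oriented["quadrant"] == q, "oriented_rate"]
        if omit:
            vals = vals[~vals.isin(omit)]
        if len(vals) == 0:
            raise ValueError(f"no rates for direction {q}")
        out[q] = float(vals.mean())
    return out


def overall_mean_with_me(
    values, confidence: float = 0.95
) -> tuple[float, float]:
    """Mean and t-based margin of error (t quantile at df = n-1 times the
    standard error)."""
    values = np.asarray(values, float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = float(values.mean())
    se = values.std(ddof=1) / np.sqrt(n)
    me = float(stats.t.ppf((1 + confidence) / 2, n - 1) * se)
    return mean, me


def literature_means(
    rows: pd.DataFrame, study_directional: dict[str, float] | None = None
) -> dict[str, tuple[float, float]]:
    """Global mean advance rates over the flagged literature rows.

    Ranges enter as midpoints.  ``study_directional`` (direction -> rate)
    appends this study's four directional means to both flag sets.
    Returns ``{"a": (mean, me), "b": (mean, me)}``.
    """
    rows = rows.copy()
    rows["midpoint"] = (rows["rate_low"] + rows["rate_high"]) / 2
    out = {}
    for flag in ("a", "b"):
        vals = rows.loc[rows[f"in_mean_{flag}"] == 1, "midpoint"].tolist()
        if study_directional:
            vals += [study_directional[q] for q in "NESW"]
        if not vals:
            raise ValueError(f"no rows flagged for mean {flag}")
        out[flag] = overall_mean_with_me(vals)
    return out


def compare_to_literature(
    study_rates, literature_midpoints, alternative: str = "less",
    confidence: float = 0.95,
) -> dict[str, float]:
    """Welch two-sample comparison of study vs literature mean rates.

    One-sided by default (study slower than literature).  Returns the mean
    difference, the one-sided confidence bound on it, and the p-value.
    This is an interpretive comparison: the samples are neither independent
    draws from well-defined populations nor measured on identical scales.
    """
    a = np.asarray(study_rates, float)
    b = np.asarray(literature_midpoints, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    diff = float(a.mean() - b.mean())
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    tcrit = stats.t.ppf(confidence, res.df)
    bound = diff + tcrit * se if alternative == "less" else diff - tcrit * se
    return {"difference": diff, "bound": float(bound), "p": float(res.pvalue),
            "df": float(res.df), "kind": "interpretation"}
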