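"""Adiposity indices, descriptive tabulation and rank correlations.

Seven exposure variables characterise different patterns of fat
accumulation: BMI, waist circumference (WC), waist-to-hip ratio (WHR),
waist-to-height ratio (WHtR), A Body Shape Index (ABSI), hip circumference
(HC) and adult weight gain.  ABSI follows the Krakauer definition

    ABSI = WC / (BMI^(2/3) * height^(1/2))        [WC, height in metres]

which normalises waist size for overall body size and makes ABSI nearly
uncorrelated with BMI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: raw measurement columns expected by :func:`derive_indices`
RAW_COLUMNS = ("height_cm", "weight_kg", "wc_cm", "hc_cm")

#: the seven derived exposure variables, in canonical order
EXPOSURES = ("bmi", "wc", "whr", "whtr", "absi", "hc", "weight_gain")


def derive_indices(raw: pd.DataFrame, units: str = "cm") -> pd.DataFrame:
    """Derive the seven adiposity indices from raw anthropometrics.

    Parameters
    ----------
    raw : DataFrame with columns ``height_cm``, ``weight_kg``, ``wc_cm``,
        ``hc_cm`` and optionally ``weight_at_20_kg`` (may contain NaN).
        With ``units="m"`` the length columns are named ``height_m``,
        ``wc_m``, ``hc_m`` and given in metres.
    units : "cm" (default) or "m"; which length convention the input uses.

    Returns
    -------
    DataFrame indexed like ``raw`` with columns ``bmi``, ``wc``, ``whr``,
    ``whtr``, ``absi``, ``hc``, ``weight_gain``.  Lengths in the output are
    centimetres (``wc``, ``hc``); ``whr``/``whtr``/``absi`` are unit-consistent
    regardless of the input convention.  ``weight_gain`` is NaN where weight
    at age 20 is missing; all other indices are still computed for such rows.

    Raises
    ------
    ValueError on non-positive height, weight, WC or HC (the offending row
    labels are named in the message).
    """
    if units not in ("cm", "m"):
        raise ValueError(f"units must be 'cm' or 'm', got {units!r}")
    suffix = "_cm" if units == "cm" else "_m"
    factor = 1.0 if units == "cm" else 100.0

    def col(name: str) -> pd.Series:
        return pd.to_numeric(raw[name + suffix], errors="raise") * factor

    height_cm = col("height")
    wc_cm = col("wc")
    hc_cm = col("hc")
    weight = pd.to_numeric(raw["weight_kg"], errors="raise")

    bad = raw.index[
        (height_cm <= 0) | (weight <= 0) | (wc_cm <= 0) | (hc_cm <= 0)
    ]
    if len(bad):
        raise ValueError(
            f"non-positive raw anthropometrics in rows: {list(bad[:10])}"
        )

    height_m = height_cm / 100.0
    bmi = weight / height_m**2
    out = pd.DataFrame(index=raw.index)
    out["bmi"] = bmi
    out["wc"] = wc_cm
    out["whr"] = wc_cm / hc_cm
    out["whtr"] = wc_cm / height_cm
    out["absi"] = (wc_cm / 100.0) / (bmi ** (2.0 / 3.0) * np.sqrt(height_m))
    out["hc"] = hc_cm
    if "weight_at_20_kg" in raw.columns:
        w20 = pd.to_numeric(raw["weight_at_20_kg"], errors="coerce")
        out["weight_gain"] = weight - w20
    else:
        out["weight_gain"] = np.nan
    return out


def format_percent(count: int, total: int, decimals: int = 2) -> str:
    """``100*count/total`` rounded to ``decimals`` places, as a string."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{100.0 * count / total:.{decimals}f}%"


def describe(
    cohort: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    by: str = "is_case",
    skew_threshold: float = 1.0,
) -> pd.DataFrame:
    """Baseline-characteristics table split by case status.

    Continuous variables are shown as ``mean ± SD`` when roughly normal
    (|skewness| <= ``skew_threshold``) and as ``median [Q1; Q3]`` otherwise;
    categorical variables as ``count (percent)`` with the percent computed
    within each group and rounded to two decimals.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if continuous is None or categorical is None:
        auto_cont, auto_cat = [], []
        for c in cohort.columns:
            if c in (by, "pair_id"):
                continue
            s = cohort[c]
            if not pd.api.types.is_numeric_dtype(s):
                auto_cat.append(c)
            elif s.dropna().nunique() <= 5:
                auto_cat.append(c)
            else:
                auto_cont.append(c)
        continuous = continuous if continuous is not None else auto_cont
        categorical = categorical if categorical is not None else auto_cat

    groups = {str(k): g for k, g in cohort.groupby(by)}
    rows = []
    for var in continuous:
        row = {"variable": var, "type": "continuous"}
        for gname, g in groups.items():
            x = pd.to_numeric(g[var], errors="coerce").dropna()
            if len(x) == 0:
                row[gname] = ""
                continue
            if abs(stats.skew(x)) <= skew_threshold:
                row[gname] = f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
            else:
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                row[gname] = f"{med:.2f} [{q1:.2f}; {q3:.2f}]"
        rows.append(row)
    for var in categorical:
        levels = sorted(cohort[var].dropna().unique())
        for lev in levels:
            row = {"variable": f"{var}={lev}", "type": "categorical"}
            for gname, g in groups.items():
                n = int((g[var] == lev).sum())
                row[gname] = f"{n} ({format_percent(n, len(g))})"
            rows.append(row)
    return pd.DataFrame(rows)


def spearman_matrix(indices: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rank correlations with pairwise-complete handling.

    Weight-gain missingness (unavailable weight at age 20) makes complete-case
    deletion wasteful, so each pair of variables uses its own complete rows.
    Raises ValueError if any pair has fewer than ``min_n`` complete rows.
    """
    cols = list(indices.columns)
    k = len(cols)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sub = indices[[cols[i], cols[j]]].dropna()
            if len(sub) < min_n:
                raise ValueError(
                    f"fewer than {min_n} complete observations for "
                    f"({cols[i]}, {cols[j]})"
                )
            r = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=cols, columns=cols)
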