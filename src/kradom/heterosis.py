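"""Midparent heterosis of body weight from least-square line means.

Heterosis is the percent superiority of the crossbred mean over the
midparent value,

    H% = 100 * (LSM_cross - MP) / MP,   MP = (LSM_sire_line + LSM_dam_line) / 2,

where each least-square mean (LSM) adjusts for the fixed effects (sex and
hatch date) by fitting an additive linear model within the line and
averaging the cell predictions with equal weight over the observed
fixed-factor level combinations (classical LSMEANS over observed margins).
Missing parental means propagate to a missing H% rather than being imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HeterosisResult",
    "least_square_means",
    "heterosis_percent",
    "heterosis_table",
]

MISSING = float("nan")


@dataclass(frozen=True)
class HeterosisResult:
    """Per-age line LSMs (grams) and the midparent heterosis percentage.

    ``h_percent`` is NaN exactly when any of the three LSMs is NaN.
    """

    age_wk: int
    lsm_kr: float
    lsm_lk: float
    lsm_sut: float
    h_percent: float


def least_square_means(
    df: pd.DataFrame,
    trait: str = "bw_g",
    fixed: Sequence[str] = ("sex", "hatch"),
) -> tuple[float, float]:
    """Least-square mean and its SE for one group of records.

    Fits ``trait ~ sum of fixed factors`` (additive, reference coding) on
    the group and averages the model predictions with equal weight over
    every observed combination of fixed-factor levels.  Returns
    ``(nan, nan)`` for an empty group (with a warning) and an LSM with NaN
    SE when there are no residual degrees of freedom (e.g. one animal).
    """
    vals = pd.to_numeric(df[trait], errors="coerce") if len(df) else pd.Series(dtype=float)
    keep = vals.notna()
    df = df.loc[keep] if len(df) else df
    y = vals[keep].to_numpy(float) if len(df) else np.empty(0)
    if len(df) == 0:
        warnings.warn("least_square_means: empty group", stacklevel=2)
        return MISSING, MISSING

    factors = [f for f in fixed if f in df.columns]
    levels = {f: list(dict.fromkeys(df[f].astype(str))) for f in factors}
    blocks = [np.ones((len(df), 1))]
    for f in factors:
        col = df[f].astype(str)
        blocks.append(
            np.column_stack([(col == lev).to_numpy(float) for lev in levels[f][1:]])
            if len(levels[f]) > 1
            else np.empty((len(df), 0))
        )
    X = np.column_stack(blocks)

    # observed combinations of fixed-factor levels within the group
    if factors:
        combos = df[factors].astype(str).drop_duplicates()
    else:
        combos = pd.DataFrame(index=[0])
    crows = [np.ones((len(combos), 1))]
    for f in factors:
        col = combos[f]
        crows.append(
            np.column_stack([(col == lev).to_numpy(float) for lev in levels[f][1:]])
            if len(levels[f]) > 1
            else np.empty((len(combos), 0))
        )
    contrast = np.hstack(crows)
    c = contrast.mean(axis=0)

    res = sm.OLS(y, X).fit()
    lsm = float(c @ res.params)
    if res.df_resid < 1:
        return lsm, MISSING
    se = float(np.sqrt(c @ res.cov_params() @ c))
    return lsm, se


def heterosis_percent(lsm_kr: float, lsm_lk: float, lsm_sut: float) -> float:
    """Midparent heterosis in percent; NaN inputs propagate to NaN."""
    if any(not np.isfinite(v) for v in (lsm_kr, lsm_lk, lsm_sut)):
        return MISSING
    midparent = 0.5 * (lsm_lk + lsm_sut)
    if midparent <= 0:
        raise ValueError("midparent mean must be positive")
    return 100.0 * (lsm_kr - midparent) / midparent


def heterosis_table(
    pheno: pd.DataFrame,
    ped=None,
    trait: str = "bw_g",
    fixed: Sequence[str] = ("sex", "hatch"),
    ages: Sequence[int] | None = None,
    cross: str = "KR",
    sire_line: str = "LK",
    dam_line: str = "SUT",
) -> pd.DataFrame:
    """Per-age body-weight characteristics and heterosis percentage.

    ``pheno`` must carry a ``line`` column or a pedigree must be supplied
    to merge line labels from.  Output columns: age_wk, n, mean, cv_percent,
    min, max, the three line LSMs, and heterosis_percent (NaN where a
    parental LSM is unavailable).  Descriptives (n, mean, CV, min, max)
    summarise the cross only.
    """
    df = pheno.copy()
    if "line" not in df.columns:
        if ped is None:
            raise ValueError("phenotypes lack a 'line' column and no pedigree given")
        lines = pd.DataFrame({"animal": list(ped.ids), "line": [r.line for r in ped]})
        df = df.merge(lines, on="animal", how="left")
    df["age_wk"] = df["age_wk"].astype(int)
    if ages is None:
        ages = sorted(df["age_wk"].unique())

    rows = []
    for age in ages:
        sub = df[df["age_wk"] == age]
        lsm = {}
        for line in (cross, sire_line, dam_line):
            grp = sub[sub["line"] == line]
            if len(grp) == 0:
                warnings.warn(f"no {line} records at age {age}; LSM missing", stacklevel=2)
                lsm[line] = MISSING
            else:
                lsm[line], _ = least_square_means(grp, trait=trait, fixed=fixed)
        kr = pd.to_numeric(sub[sub["line"] == cross][trait], errors="coerce").dropna()
        rows.append(
            {
                "age_wk": age,
                "n": int(len(kr)),
                "mean": kr.mean() if len(kr) else MISSING,
                "cv_percent": 100.0 * kr.std(ddof=1) / kr.mean() if len(kr) > 1 else MISSING,
                "min": kr.min() if len(kr) else MISSING,
                "max": kr.max() if len(kr) else MISSING,
                "lsm_kr": lsm[cross],
                "lsm_lk": lsm[sire_line],
                "lsm_sut": lsm[dam_line],
                "heterosis_percent": heterosis_percent(
                    lsm[cross], lsm[sire_line], lsm[dam_line]
                ),
            }
        )
    return pd.DataFrame(rows)


def heterosis_result(
    pheno: pd.DataFrame, age: int, **kwargs
) -> HeterosisResult:
    """Single-age convenience wrapper around :func:`heterosis_table`."""
    tab = heterosis_table(pheno, ages=[age], **kwargs).iloc[0]
    return HeterosisResult(
        age_wk=age,
        lsm_kr=float(tab["lsm_kr"]),
        lsm_lk=float(tab["lsm_lk"]),
        lsm_sut=float(tab["lsm_sut"]),
        h_percent=float(tab["heterosis_percent"]),
    )
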