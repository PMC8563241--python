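"""Genotype–phenotype association and correlation analysis.

Tests the effect of a marker genotype (three-level factor) on any
per-animal quantity — body weight, a dominance BLUP, a normalised
expression level — with sex as a fixed covariate, compares genotype means
by the Tukey–Kramer studentized-range test (unequal group sizes), renders
the groupings as a compact letter display, and provides Pearson
correlation between paired per-animal quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GenotypeComparison",
    "TukeyPair",
    "TukeyResult",
    "CorrelationResult",
    "genotype_effect",
    "tukey_kramer",
    "pearson_correlation",
]


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    diff: float
    q: float
    p: float
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey–Kramer comparisons and the compact letter display."""

    pairs: tuple[TukeyPair, ...]
    letters: Mapping[str, str]
    alpha: float


@dataclass(frozen=True)
class GenotypeComparison:
    """Per-genotype adjusted means with Tukey letters and the overall F-test.

    Genotypes sharing no letter differ at level ``alpha``; genotypes
    sharing a letter do not.
    """

    trait: str
    genotypes: tuple[str, ...]
    lsm: Mapping[str, float]
    se: Mapping[str, float]
    n: Mapping[str, int]
    overall_p: float
    letters: Mapping[str, str]
    alpha: float
    age: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": list(self.genotypes),
                "lsm": [self.lsm[g] for g in self.genotypes],
                "se": [self.se[g] for g in self.genotypes],
                "n": [self.n[g] for g in self.genotypes],
                "letter": [self.letters[g] for g in self.genotypes],
            }
        ).assign(overall_p=self.overall_p)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value."""

    r: float
    p: float
    n: int


def _compact_letter_display(
    groups: Sequence[str],
    means: Mapping[str, float],
    significant: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Insert-and-absorb sweep building the compact letter display.

    Starts from one column holding every group; for each significantly
    different pair, columns containing both members are split in two (one
    without each member) and columns that became subsets of others are
    absorbed.  Letters are assigned in order of the best (largest-mean)
    group each column contains, so the display is invariant to group
    relabelling.
    """
    columns: list[set[str]] = [set(groups)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            ca, cb = col - {b}, col - {a}
            for new in (ca, cb):
                if not any(new <= other for other in columns):
                    columns.append(new)
            columns = [
                c for c in columns
                if not any(c < other for other in columns if c is not other)
            ]
    # drop exact duplicates, keep deterministic order by best member mean
    uniq: list[set[str]] = []
    for c in columns:
        if c and c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: (-max(means[g] for g in c), sorted(c)))
    labels = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, col in zip(labels, uniq):
        for g in sorted(col, key=lambda g: -means[g]):
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def tukey_kramer(
    group_means: Mapping[str, float],
    group_ns: Mapping[str, int],
    mse: float,
    df_resid: float,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey–Kramer all-pairs comparison from summary statistics.

    Uses the studentized range distribution with the Tukey–Kramer
    unequal-n standard error ``sqrt(mse/2 * (1/n_i + 1/n_j))``.  For two
    balanced groups this reduces exactly to the pooled two-sample t-test
    (``q = t * sqrt(2)``).
    """
    groups = list(group_means)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if mse <= 0:
        raise ValueError("mse must be positive")
    if df_resid < 1:
        raise ValueError("need at least one residual degree of freedom")
    k = len(groups)
    pairs = []
    significant: dict[tuple[str, str], bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = group_means[a] - group_means[b]
            se = np.sqrt(mse * 0.5 * (1.0 / group_ns[a] + 1.0 / group_ns[b]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
            sig = p <= alpha
            pairs.append(TukeyPair(a, b, float(diff), float(q), p, sig))
            significant[(a, b)] = sig
    letters = _compact_letter_display(groups, group_means, significant)
    return TukeyResult(pairs=tuple(pairs), letters=letters, alpha=alpha)


def genotype_effect(
    values: Sequence[float],
    genotype: Sequence[str],
    sex: Sequence[str] | None = None,
    alpha: float = 0.05,
    trait: str = "value",
    age: int | None = None,
    extra_factors: Mapping[str, Sequence[str]] | None = None,
) -> GenotypeComparison:
    """Linear-model test of a genotype effect with sex held fixed.

    Fits ``value ~ genotype + sex`` (reference coding), reports the
    genotype F-test p-value, per-genotype adjusted means (predictions
    averaged with equal weight over observed covariate levels) with their
    standard errors, and Tukey–Kramer letters computed from the model
    residual mean square.  Empty genotype groups are dropped with a
    warning; with all values identical the comparison degenerates to
    p = 1 and a single shared letter.
    """
    df = pd.DataFrame({"value": pd.to_numeric(pd.Series(values), errors="coerce"),
                       "genotype": pd.Series(genotype).astype(str).to_numpy()})
    if sex is not None:
        df["sex"] = pd.Series(sex).astype(str).to_numpy()
    for name, col in (extra_factors or {}).items():
        df[name] = pd.Series(col).astype(str).to_numpy()
    df = df[df["value"].notna()].reset_index(drop=True)

    counts = df["genotype"].value_counts()
    empty = [g for g in counts.index if counts[g] == 0]
    if empty:  # pragma: no cover - value_counts drops empties already
        warnings.warn(f"dropping empty genotype groups {empty}", stacklevel=2)
    genotypes = [g for g in dict.fromkeys(df["genotype"]) if counts.get(g, 0) > 0]
    if len(genotypes) < 2:
        raise ValueError("need at least two non-empty genotype groups")

    covariates = [c for c in df.columns if c not in ("value", "genotype")]
    y = df["value"].to_numpy(float)

    def design(cols: list[str]) -> np.ndarray:
        blocks = [np.ones((len(df), 1))]
        for c in cols:
            levels = list(dict.fromkeys(df[c]))
            if len(levels) > 1:
                blocks.append(
                    np.column_stack([(df[c] == lev).to_numpy(float) for lev in levels[1:]])
                )
        return np.hstack(blocks)

    X_full = design(["genotype"] + covariates)
    X_red = design(covariates)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_num = X_full.shape[1] - X_red.shape[1]
    df_den = full.df_resid
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")
    if full.ssr <= max(1e-12 * len(y) * np.var(y), 0.0) or np.allclose(y, y[0]):
        # degenerate: identical values within groups
        overall_p = 1.0
        mse = 0.0
    else:
        f_stat = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
        overall_p = float(stats.f.sf(f_stat, df_num, df_den))
        mse = full.ssr / df_den

    # adjusted genotype means: predictions averaged over observed covariate levels
    lsm: dict[str, float] = {}
    se: dict[str, float] = {}
    ns: dict[str, int] = {}
    cov_levels = {c: list(dict.fromkeys(df[c])) for c in covariates}
    geno_levels = list(dict.fromkeys(df["genotype"]))
    for g in genotypes:
        c_vec = [1.0]
        for lev in geno_levels[1:]:
            c_vec.append(1.0 if g == lev else 0.0)
        for c in covariates:
            levels = cov_levels[c]
            if len(levels) > 1:
                c_vec.extend([1.0 / len(levels)] * (len(levels) - 1))
        c_arr = np.array(c_vec)
        lsm[g] = float(c_arr @ full.params)
        se[g] = (
            float(np.sqrt(c_arr @ full.cov_params() @ c_arr)) if mse > 0 else 0.0
        )
        ns[g] = int(counts[g])

    if mse > 0:
        tukey = tukey_kramer(lsm, ns, mse, df_den, alpha=alpha)
        letters = dict(tukey.letters)
    else:
        letters = {g: "a" for g in genotypes}

    return GenotypeComparison(
        trait=trait,
        genotypes=tuple(genotypes),
        lsm=lsm,
        se=se,
        n=ns,
        overall_p=overall_p,
        letters=letters,
        alpha=alpha,
        age=age,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r between paired values with a two-sided t-based p-value.

    Incomplete pairs are dropped; at least three complete pairs are
    required.  Zero variance in either variable leaves r undefined (NaN).
    """
    xv = pd.to_numeric(pd.Series(x), errors="coerce").to_numpy(float)
    yv = pd.to_numeric(pd.Series(y), errors="coerce").to_numpy(float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    n = int(xv.size)
    if n < 3:
        raise ValueError("need at least three complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return CorrelationResult(float("nan"), float("nan"), n)
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(float(r), float(p), n)
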