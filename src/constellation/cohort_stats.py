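"""Comparative statistics over the per-gene property table.

Covers the compositional-bias machinery (chi-square against genome-wide
group frequencies, two-sample proportion tests, singleton/duplicate
ratios), Mann-Whitney comparisons of each constellation against solitary
genes, and the stepwise multivariate regression used to rank the relative
statistical effect of gene constellation against recombination rate,
chromosomal linkage and gene function.

All regressions operate on z-scored columns so coefficients are
standardized effects directly comparable across predictors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CONSTELLATION_ORDINAL",
    "RegressionModel",
    "composition_chisq",
    "proportion_test",
    "singleton_duplicate_ratio",
    "duplicate_ratio",
    "group_vs_sg_tests",
    "stepwise_fit",
    "encode_constellation",
]

#: Ordinal coding of the constellation label used as the single "Const."
#: regression feature; the order follows the classification scheme's
#: priority listing (solitary first).
CONSTELLATION_ORDINAL: dict[str, int] = {
    "SG": 0, "5PP": 1, "EE": 2, "5PI_EI": 3, "COS": 4, "CSS": 5,
}


def composition_chisq(
    observed: Sequence[int] | Mapping[str, int],
    background: Sequence[int] | Mapping[str, int],
) -> tuple[float, int, float]:
    """Chi-square test of group composition against background frequencies.

    Expected counts are the observed total distributed in background
    proportions.  Groups whose expected count falls below 1 are merged into
    the neighbouring group with the smallest expected count (logged).
    """
    if isinstance(observed, Mapping):
        keys = list(observed)
        obs = np.array([observed[k] for k in keys], dtype=float)
        bg = np.array([background[k] for k in keys], dtype=float)
    else:
        obs = np.asarray(observed, dtype=float)
        bg = np.asarray(background, dtype=float)
    if obs.shape != bg.shape:
        raise ValueError("observed and background must align")
    if (bg <= 0).any():
        raise ValueError("background counts must be positive")
    total = obs.sum()
    if total == 0:
        raise ValueError("no observed genes")

    obs_list, bg_list = list(obs), list(bg)
    expected = [total * b / sum(bg_list) for b in bg_list]
    while len(obs_list) > 1 and min(expected) < 1.0:
        i = int(np.argmin(expected))
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(obs_list)]
        j = min(neighbours, key=lambda j: expected[j])
        lo, hi = sorted((i, j))
        log.info("merging composition cell %d into %d (expected %.3f < 1)", i, j, expected[i])
        obs_list[lo] += obs_list.pop(hi)
        bg_list[lo] += bg_list.pop(hi)
        expected = [total * b / sum(bg_list) for b in bg_list]

    chi2, p = stats.chisquare(obs_list, f_exp=expected)
    df = len(obs_list) - 1
    return float(chi2), df, float(p)


def proportion_test(k: int, n: int, big_k: int, big_n: int) -> float:
    """Two-sample proportion z-test (pooled variance), two-sided p-value."""
    if n == 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < big_k < big_n):
        raise ValueError("need 0 < K < N")
    from statsmodels.stats.proportion import proportions_ztest

    _, p = proportions_ztest([k, big_k], [n, big_n], alternative="two-sided")
    return float(p)


def singleton_duplicate_ratio(n_genes: int, n_duplicates: int) -> float:
    """(genes without a duplicate) / (duplicated genes)."""
    if n_duplicates <= 0:
        raise ValueError("no duplicated genes: ratio undefined")
    return (n_genes - n_duplicates) / n_duplicates


def duplicate_ratio(
    table: pd.DataFrame,
    group: str | None = None,
    group_col: str = "group",
    flag_col: str = "duplicate",
) -> tuple[float | None, float | None]:
    """Singleton/duplicate ratio, optionally per group with a 2x2 chi-square.

    With a group, the ratio is computed within that group and the p-value
    tests its duplicate composition against the rest of the genome.
    Returns (ratio, p); ratio is None when the group has no duplicates,
    p is None when no group is given.
    """
    if flag_col not in table:
        raise KeyError(f"property table lacks a {flag_col!r} column")
    flags = table[flag_col].astype(int)
    if group is None:
        dup = int(flags.sum())
        ratio = None if dup == 0 else (len(flags) - dup) / dup
        return ratio, None
    in_group = table[group_col] == group
    a_dup = int(flags[in_group].sum())
    a_single = int((~flags[in_group].astype(bool)).sum())
    b_dup = int(flags[~in_group].sum())
    b_single = int((~flags[~in_group].astype(bool)).sum())
    ratio = None if a_dup == 0 else a_single / a_dup
    contingency = np.array([[a_single, a_dup], [b_single, b_dup]])
    if contingency.sum(axis=0).min() == 0 or contingency.sum(axis=1).min() == 0:
        return ratio, None
    _, p, _, _ = stats.chi2_contingency(contingency)
    return ratio, float(p)


def group_vs_sg_tests(
    table: pd.DataFrame,
    property_col: str,
    group_col: str = "group",
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Mann-Whitney U of each constellation against solitary genes.

    Two-sided, uncorrected for multiple comparisons (a deliberate default);
    the 95% CI is the normal approximation mean +/- 1.96 SEM.
    """
    sg = table.loc[table[group_col] == "SG", property_col].dropna()
    if sg.empty:
        raise ValueError("no solitary (SG) genes in the table")

    def summary(x: pd.Series) -> dict:
        sem = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
        return {
            "n": len(x),
            "mean": float(x.mean()),
            "ci_low": float(x.mean() - 1.96 * sem),
            "ci_high": float(x.mean() + 1.96 * sem),
        }

    rows = [{"group": "SG", **summary(sg), "U": np.nan, "p": np.nan}]
    for grp in sorted(set(table[group_col]) - {"SG", "CONFLICT"}):
        x = table.loc[table[group_col] == grp, property_col].dropna()
        if len(x) < min_group_size:
            warnings.warn(f"group {grp}: fewer than {min_group_size} values; skipped")
            continue
        if x.nunique() == 1 and sg.nunique() == 1 and x.iloc[0] == sg.iloc[0]:
            u, p = len(x) * len(sg) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(x, sg, alternative="two-sided")
        rows.append({"group": grp, **summary(x), "U": float(u), "p": float(p)})
    return pd.DataFrame(rows)


def encode_constellation(groups: pd.Series, scheme: str = "ordinal") -> pd.DataFrame:
    """Encode the group label for regression.

    ``ordinal`` yields a single 0-5 column (the default, matching the
    single constellation coefficient in the fitted models); ``onehot``
    yields one indicator per non-solitary group.
    """
    if scheme == "ordinal":
        codes = groups.map(CONSTELLATION_ORDINAL)
        if codes.isna().any():
            bad = sorted(set(groups[codes.isna()]))
            raise ValueError(f"unencodable group labels: {bad}")
        return codes.astype(float).to_frame("const_code")
    if scheme == "onehot":
        dummies = pd.get_dummies(groups).astype(float)
        return dummies.drop(columns=[c for c in ("SG",) if c in dummies])
    raise ValueError(f"unknown encoding scheme {scheme!r}")


@dataclass
class RegressionModel:
    """Result of a stepwise fit on z-scored data."""

    predictors: list[str]
    coefficients: dict[str, float]
    r: float
    p_value: float
    n: int
    standard_errors: dict[str, float] = field(default_factory=dict)

    @property
    def fitted(self) -> bool:
        return bool(self.predictors)

    def formula(self, y_name: str = "y") -> str:
        if not self.fitted:
            return "No fitting model"
        terms = " + ".join(f"{self.coefficients[p]:+.3f} {p}" for p in self.predictors)
        return f"z({y_name}) = {terms}"


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"column {x.name!r} is constant; cannot standardize")
    return (x - x.mean()) / sd


def stepwise_fit(
    y: pd.Series,
    predictors: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionModel:
    """Forward selection with backward elimination on z-scored columns.

    At each step the candidate with the smallest partial-F p-value enters
    if below ``p_enter``; included predictors whose p-value rises above
    ``p_remove`` are dropped.  Returns an explicit no-fitting-model result
    (empty predictor list) when nothing passes the entry criterion.
    """
    data = pd.concat([y.rename("__y__"), predictors], axis=1).dropna()
    n = len(data)
    if n <= predictors.shape[1] + 2:
        raise ValueError("too few complete cases for the candidate set")
    z = data.apply(_zscore)
    yz = z["__y__"]
    xz = z.drop(columns="__y__")

    selected: list[str] = []
    while True:
        changed = False
        remaining = [c for c in xz.columns if c not in selected]
        if remaining:
            pvals = {}
            for cand in remaining:
                model = sm.OLS(yz, sm.add_constant(xz[selected + [cand]])).fit()
                pvals[cand] = model.pvalues[cand]
            best = min(pvals, key=lambda c: (pvals[c], c))
            if pvals[best] < p_enter:
                selected.append(best)
                changed = True
        if selected:
            model = sm.OLS(yz, sm.add_constant(xz[selected])).fit()
            worst = max(selected, key=lambda c: (model.pvalues[c], c))
            if model.pvalues[worst] > p_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    if not selected:
        return RegressionModel(predictors=[], coefficients={}, r=0.0, p_value=1.0, n=n)
    model = sm.OLS(yz, sm.add_constant(xz[selected])).fit()
    return RegressionModel(
        predictors=list(selected),
        coefficients={c: float(model.params[c]) for c in selected},
        r=float(np.sqrt(max(0.0, model.rsquared))),
        p_value=float(model.f_pvalue),
        n=n,
        standard_errors={c: float(model.bse[c]) for c in selected},
    )
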