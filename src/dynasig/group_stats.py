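"""Between-category comparisons of forecast skill and nonlinearity.

Given the per-series verdict table, this module reproduces the standard
battery of group-level statistics for this kind of audit: per-category
mean (+/- sd) forecast skill, one-way ANOVA with Tukey's HSD pairwise
comparisons of rho, logistic regression with Wald tests for differences in
nonlinearity prevalence (data categories vs pooled model outputs), and a
one-way ANOVA on series lengths.

Conventions: all series with a defined forecast rho enter the skill
summaries and rho comparisons; only series passing the forecast-skill
screen enter nonlinearity prevalence denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError


@dataclass(frozen=True)
class AnovaResult:
    groups: tuple[str, ...]
    group_n: tuple[int, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    F: float
    p: float


@dataclass(frozen=True)
class RhoComparison:
    anova: AnovaResult
    tukey: pd.DataFrame  # columns: group_a, group_b, diff, p_adj


@dataclass(frozen=True)
class PrevalenceComparison:
    """Logistic-regression contrasts of nonlinearity prevalence.

    ``table`` has one row per comparison category: coefficient (log odds
    ratio vs the pooled reference), standard error, Wald z, two-sided p,
    and odds ratio.  Under complete separation the Wald machinery breaks
    down; ``separation`` flags it and ``fisher_p`` carries an exact-test
    fallback on the collapsed 2x2 table.
    """

    table: pd.DataFrame
    reference_categories: tuple[str, ...]
    separation: bool
    fisher_p: float | None


def _retained(df: pd.DataFrame) -> pd.DataFrame:
    return df[(~df["excluded"]) & (~df["screened_out"])]


def summarize_categories(verdicts: pd.DataFrame) -> pd.DataFrame:
    """Per-category skill and nonlinearity summary.

    Skill (mean/sd rho) is computed over all series with a defined rho;
    percent nonlinear over series that passed the screen.  Categories with
    no analyzable series are omitted.
    """
    rows = []
    for cat, grp in verdicts.groupby("category", sort=True):
        with_rho = grp[grp["rho"].notna()]
        retained = _retained(grp)
        if len(with_rho) == 0 and len(retained) == 0:
            continue
        n_nl = int(retained["is_nonlinear"].sum())
        rows.append(
            {
                "category": cat,
                "n_total": len(grp),
                "n_with_skill": len(with_rho),
                "mean_rho": float(with_rho["rho"].mean()) if len(with_rho) else np.nan,
                "sd_rho": (
                    float(with_rho["rho"].std(ddof=1))
                    if len(with_rho) > 1
                    else np.nan
                ),
                "n_retained": len(retained),
                "n_nonlinear": n_nl,
                "percent_nonlinear": (
                    100.0 * n_nl / len(retained) if len(retained) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def _oneway(groups: dict[str, np.ndarray]) -> AnovaResult:
    names = tuple(groups)
    arrays = [np.asarray(groups[g], dtype=np.float64) for g in names]
    if len(arrays) < 2:
        raise ParameterError("ANOVA needs at least two groups of size >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*arrays)
    if np.isnan(F):  # zero variance everywhere: identical constant groups
        F, p = 0.0, 1.0
    return AnovaResult(
        groups=names,
        group_n=tuple(len(a) for a in arrays),
        group_means=tuple(float(a.mean()) for a in arrays),
        group_sds=tuple(
            float(a.std(ddof=1)) if len(a) > 1 else 0.0 for a in arrays
        ),
        F=float(F),
        p=float(p),
    )


def compare_rho(
    verdicts: pd.DataFrame, categories: Sequence[str] | None = None
) -> RhoComparison:
    """One-way ANOVA on forecast rho by category, with Tukey's HSD.

    Categories with fewer than two series with defined rho are dropped
    (with at least two remaining required).  Tukey adjusted p-values come
    from the studentized-range distribution with classical pooled
    variance.
    """
    df = verdicts[verdicts["rho"].notna()]
    if categories is not None:
        df = df[df["category"].isin(categories)]
    groups = {
        cat: grp["rho"].to_numpy()
        for cat, grp in df.groupby("category", sort=True)
        if len(grp) >= 2
    }
    if len(groups) < 2:
        raise ParameterError("compare_rho needs >= 2 categories with >= 2 series")
    anova = _oneway(groups)
    names = list(groups)
    res = stats.tukey_hsd(*[groups[g] for g in names])
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return RhoComparison(anova=anova, tukey=pd.DataFrame(rows))


def compare_nonlinearity_prevalence(
    verdicts: pd.DataFrame,
    reference_categories: Sequence[str],
    comparison_categories: Sequence[str],
) -> PrevalenceComparison:
    """Logistic regression of nonlinearity on category contrasts.

    The reference categories (typically the pooled model outputs) form the
    baseline; each comparison category gets an indicator column.  The
    model is fit by Newton-type iteratively reweighted least squares and
    each contrast is tested with a Wald z.  Only screened-in series enter.
    """
    df = _retained(verdicts)
    df = df[df["category"].isin(list(reference_categories) + list(comparison_categories))]
    if df.empty:
        raise ParameterError("no retained series in the requested categories")
    y = df["is_nonlinear"].astype(float).to_numpy()
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for cat in comparison_categories:
        X[cat] = (df["category"] == cat).astype(float)
    separation = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 15):
            separation = True
    except Exception:  # PerfectSeparationError or convergence failure
        separation = True
        fit = None
    if not separation and fit is not None:
        table = pd.DataFrame(
            {
                "contrast": X.columns,
                "coef": fit.params,
                "se": fit.bse,
                "wald_z": fit.params / fit.bse,
                "p": 2 * stats.norm.sf(np.abs(fit.params / fit.bse)),
                "odds_ratio": np.exp(fit.params),
            }
        ).reset_index(drop=True)
        fisher_p = None
    else:
        table = pd.DataFrame(
            columns=["contrast", "coef", "se", "wald_z", "p", "odds_ratio"]
        )
        in_comp = df["category"].isin(comparison_categories)
        a = int((y == 1)[in_comp].sum())
        b = int((y == 0)[in_comp].sum())
        c = int((y == 1)[~in_comp].sum())
        d = int((y == 0)[~in_comp].sum())
        _, fisher_p = stats.fisher_exact([[a, b], [c, d]])
        fisher_p = float(fisher_p)
    return PrevalenceComparison(
        table=table,
        reference_categories=tuple(reference_categories),
        separation=separation,
        fisher_p=fisher_p,
    )


def compare_lengths(
    lengths: Sequence[float], groups: Sequence[str]
) -> AnovaResult:
    """One-way ANOVA on series lengths by group label.

    Typical use: test whether series classified nonlinear are longer or
    shorter than series classified linear.
    """
    lengths = np.asarray(lengths, dtype=np.float64)
    groups = np.asarray(groups)
    if len(lengths) != len(groups):
        raise ParameterError("lengths and groups must align")
    by = {
        g: lengths[groups == g]
        for g in pd.unique(groups)
        if (groups == g).sum() >= 2
    }
    if len(by) < 2:
        raise ParameterError("compare_lengths needs >= 2 groups with >= 2 members")
    return _oneway(by)
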