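"""Treatment-level inference for serial-passage suppression experiments.

The response variable is each replicate population's mean OD600 across the
experiment (censored days entering at the detection limit).  Because the
response deviates strongly from normality, all regressions run on the
rank-transformed response with treatment-coded categorical predictors; model
selection uses Gaussian-likelihood AIC with adjusted R^2 as a tiebreak.
Pairwise treatment contrasts use Mann-Whitney U tests (exact by full
enumeration for small tie-free samples) with Holm adjustment within a family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionFit",
    "TestResult",
    "AliasedTermsError",
    "mean_density_response",
    "rank_transform",
    "fit_rank_regression",
    "select_model",
    "mannwhitney_u",
    "pairwise_family",
    "response_24h_after_second_dose",
]


class AliasedTermsError(ValueError):
    """The requested design matrix is rank deficient."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (U or F statistic)."""

    name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    adjusted_p: float | None = None
    method: str = ""
    comparison: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class RegressionFit:
    """An OLS fit on the rank-transformed response."""

    terms: tuple[str, ...]
    formula: str
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    aic: float
    r_squared: float
    adj_r_squared: float
    n: int
    df_resid: float
    result: object = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.params)


def mean_density_response(
    od_table: pd.DataFrame,
    design: pd.DataFrame,
    experiment_run: str | None = None,
) -> pd.DataFrame:
    """Per-population mean OD600 response joined with the design factors.

    Every population must have an OD value for every day of the experiment
    (censored values are already stored at the detection limit).  Returns one
    row per population with the design's factor columns and ``response``.
    """
    required = {"population_id", "day", "od600"}
    missing = required - set(od_table.columns)
    if missing:
        raise ValueError(f"OD table missing columns: {sorted(missing)}")
    all_days = set(od_table["day"].unique())
    incomplete = [
        pid
        for pid, sub in od_table.groupby("population_id", sort=False)
        if set(sub["day"]) != all_days
    ]
    if incomplete:
        raise ValueError(f"populations with missing days: {sorted(incomplete)}")

    means = (
        od_table.groupby("population_id", sort=False)["od600"]
        .mean()
        .rename("response")
        .reset_index()
    )
    out = design.merge(means, on="population_id", how="inner", validate="1:1")
    if experiment_run is not None:
        out.insert(1, "experiment_run", experiment_run)
    return out


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n over the pooled values; ties receive average ranks."""
    return sps.rankdata(np.asarray(values, dtype=float), method="average")


def _formula(terms: Sequence[str], categorical: set[str]) -> str:
    parts = []
    for term in terms:
        factors = [
            f"C({f})" if f in categorical else f for f in term.split(":")
        ]
        parts.append(":".join(factors))
    rhs = " + ".join(parts) if parts else "1"
    return f"rank_response ~ {rhs}"


def fit_rank_regression(
    table: pd.DataFrame, terms: Sequence[str], response: str = "response"
) -> RegressionFit:
    """OLS on the rank-transformed response with treatment-coded factors.

    ``terms`` name columns of ``table`` (``"a:b"`` for interactions); string
    columns are dummy-coded with treatment contrasts.  Raises
    :class:`AliasedTermsError` naming the aliased columns if the design
    matrix is rank deficient.
    """
    data = table.copy()
    data["rank_response"] = rank_transform(data[response])
    categorical = {
        c for c in data.columns if data[c].dtype == object or str(data[c].dtype) == "category"
    }
    formula = _formula(terms, categorical)
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        aliased = []
        for j in range(1, exog.shape[1]):
            if np.linalg.matrix_rank(exog[:, : j + 1]) == np.linalg.matrix_rank(exog[:, :j]):
                aliased.append(model.exog_names[j])
        raise AliasedTermsError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    return RegressionFit(
        terms=tuple(terms),
        formula=formula,
        params=res.params,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        aic=float(res.aic),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        result=res,
    )


def select_model(
    table: pd.DataFrame,
    candidate_terms: Sequence[Sequence[str]],
    response: str = "response",
) -> tuple[RegressionFit, pd.DataFrame]:
    """Fit all candidate term sets and select the best by AIC.

    The minimum-AIC candidate wins.  A candidate within 2 AIC of it (an
    effective tie) replaces it only when unambiguously preferable: higher
    adjusted R^2 with no more parameters.  This keeps the conventional AIC
    parsimony penalty decisive on noise while letting adjusted R^2 break
    genuine ties.  Returns the winning fit and the full comparison table.
    """
    if not candidate_terms:
        raise ValueError("candidate term list is empty")
    fits = [fit_rank_regression(table, terms, response=response) for terms in candidate_terms]
    aics = np.array([f.aic for f in fits])
    best_i = int(np.argmin(aics))
    for i in np.flatnonzero(aics < aics.min() + 2.0):
        if (
            i != best_i
            and fits[i].adj_r_squared > fits[best_i].adj_r_squared
            and fits[i].n_params <= fits[best_i].n_params
        ):
            best_i = int(i)
    comparison = pd.DataFrame(
        {
            "terms": [" + ".join(f.terms) if f.terms else "(intercept)" for f in fits],
            "aic": [f.aic for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "adj_r_squared": [f.adj_r_squared for f in fits],
            "n_params": [f.n_params for f in fits],
            "selected": [i == best_i for i in range(len(fits))],
        }
    )
    return fits[best_i], comparison


def _exact_mannwhitney_p(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of rank assignments (no ties)."""
    n = len(ranks)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - offset
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, n + 1), n_a):
        u = sum(combo) - offset
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def mannwhitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact by full enumeration of the C(n_a+n_b, n_a) rank assignments when the
    pooled sample is small (<= 14) and tie free; otherwise the normal
    approximation with tie and continuity corrections.  The reported statistic
    is min(U_a, U_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    n_a, n_b = len(a), len(b)
    if n_a + n_b <= 14 and not ties:
        ranks = sps.rankdata(pooled)
        u_a, p = _exact_mannwhitney_p(ranks, n_a)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u_a, p = float(res.statistic), float(res.pvalue)
        method = "normal_approx"
    u = min(u_a, n_a * n_b - u_a)
    return TestResult(
        name="mannwhitney_u",
        statistic=float(u),
        p_value=min(float(p), 1.0),
        group_sizes=(n_a, n_b),
        method=method,
    )


def pairwise_family(
    groups: Mapping[str, Sequence[float]],
    comparisons: Iterable[tuple[str, str]],
) -> list[TestResult]:
    """Run a family of Mann-Whitney comparisons with Holm-adjusted p-values."""
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("no comparisons requested")
    raw = [mannwhitney_u(groups[a], groups[b]) for a, b in comparisons]
    adjusted = multipletests([t.p_value for t in raw], method="holm")[1]
    return [
        TestResult(
            name=t.name,
            statistic=t.statistic,
            p_value=t.p_value,
            group_sizes=t.group_sizes,
            adjusted_p=float(p_adj),
            method=t.method,
            comparison=(a, b),
        )
        for t, p_adj, (a, b) in zip(raw, adjusted, comparisons)
    ]


def response_24h_after_second_dose(
    od_table: pd.DataFrame, design: pd.DataFrame, timing_day: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """OD recorded 24 h after each population's second dose.

    The second dose lands at the start of day ``timing_day[timing]``; the OD
    recorded at the end of that day (recorded day index + 1) is the 24-h
    post-dose density used for pairwise treatment comparisons.  Populations
    without a second dose are omitted.
    """
    if timing_day is None:
        from .design import TIMING_DAY

        timing_day = {t.value: d for t, d in TIMING_DAY.items()}
    rows = []
    for _, row in design.iterrows():
        timing = row["timing"]
        if timing not in timing_day:
            continue
        day = timing_day[timing] + 1
        sub = od_table[
            (od_table["population_id"] == row["population_id"]) & (od_table["day"] == day)
        ]
        if sub.empty:
            raise ValueError(
                f"{row['population_id']}: no OD recorded for day {day}"
            )
        out = dict(row)
        out["day"] = day
        out["od600"] = float(sub["od600"].iloc[0])
        rows.append(out)
    return pd.DataFrame(rows)
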