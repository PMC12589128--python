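"""Accessible-region counting, Fisher-exact differential accessibility,
age-trend regression and multiple-testing helpers."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._types import FragmentTable
from .peaks import call_peaks


def count_regions_by_sample(
    fragments: FragmentTable,
    class_labels: dict[str, object],
    sample_labels: dict[str, object],
    genome_size: int,
    ages: dict[object, float] | None = None,
    caller_params: dict | None = None,
) -> pd.DataFrame:
    """Peaks called per (sample, class) pool of fragments.

    ``class_labels`` / ``sample_labels`` map barcode -> label.  Returns one
    row per sample x class with the called region count (0 for an empty
    pool) and, when ``ages`` maps sample -> post-conception weeks, an age
    column.
    """
    caller_params = caller_params or {}
    df = fragments.records
    cls = df["barcode"].map(class_labels)
    smp = df["barcode"].map(sample_labels)
    rows = []
    for (sample, klass), grp in df.groupby([smp, cls], observed=True):
        pool = FragmentTable(grp.reset_index(drop=True), fragments.sample_id)
        n = len(call_peaks(pool, genome_size, **caller_params)) if len(grp) else 0
        rows.append((sample, klass, n))
    out = pd.DataFrame(rows, columns=["sample_id", "class", "n_regions"])
    if ages is not None:
        out["age"] = out["sample_id"].map(ages)
    return out


def fisher_differential(
    counts_a: np.ndarray, counts_b: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact tests with BH correction.

    ``counts_a`` and ``counts_b`` are (n_regions, 2) arrays of
    (in_region, out_region) fragment counts per condition.  The
    alternative is that condition A's in-region proportion exceeds B's.
    Zero-margin tables get p = 1 by convention.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=np.int64))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=np.int64))
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("counts must be non-negative")
    ps, ors = [], []
    for (a_in, a_out), (b_in, b_out) in zip(counts_a, counts_b):
        table = [[a_in, a_out], [b_in, b_out]]
        if min(a_in + a_out, b_in + b_out, a_in + b_in, a_out + b_out) == 0:
            ps.append(1.0)
            ors.append(np.nan)
            continue
        odds, p = stats.fisher_exact(table, alternative="greater")
        ps.append(float(p))
        ors.append(float(odds))
    q = multiple_testing(np.array(ps), method="bh")
    return pd.DataFrame(
        {"odds_ratio": ors, "pvalue": ps, "qvalue": q, "significant": q < alpha}
    )


def age_trend(table: pd.DataFrame, group=None) -> dict:
    """OLS of region count on age: slope (regions/week), s.e., t, dof, p."""
    import statsmodels.api as sm

    df = table if group is None else table[table["class"].isin(set(group))]
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    age = df["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant")
    X = sm.add_constant(age)
    fit = sm.OLS(df["n_regions"].to_numpy(dtype=float), X).fit()
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    dof = int(fit.df_resid)
    t = coef / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
    return {"coefficient": coef, "se": se, "t": float(t), "dof": dof, "pvalue": p}


def multiple_testing(pvals, method: str = "bh", m: int | None = None,
                     alpha: float = 0.05):
    """Bonferroni threshold or BH step-up adjusted values.

    ``method='bonferroni'`` returns the significance threshold alpha / m;
    ``method='bh'`` returns BH-adjusted q-values (monotone step-up) for
    ``pvals``, with m defaulting to their number.
    """
    if method == "bonferroni":
        m = m if m is not None else len(np.atleast_1d(pvals))
        if m <= 0:
            raise ValueError("m must be positive")
        return alpha / m
    if method != "bh":
        raise ValueError("method must be 'bonferroni' or 'bh'")
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else len(p)
    if m <= 0:
        raise ValueError("m must be positive")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(ranked, 1.0)
    return q
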