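"""Group statistics: per-animal aggregation, reference normalization and
between-group tests.

The experimental unit for all between-group comparisons is the animal, not
the cell: per-cell endpoints are first averaged within each animal and
condition (the study design averages ~40 myocytes per animal), group
summaries are mean ± SEM over animal means, and normalization divides every
animal mean by a reference group mean — either the control mean at the same
pacing frequency ("per-frequency" mode) or the control mean at the same
frequency with 0% stimulus noise ("zero-noise" mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError, ParameterError

__all__ = ["GroupSummary", "StatTestResult", "per_animal_aggregate",
           "summarize_groups", "normalize_to_reference", "compare_groups",
           "anova_multi"]

CONDITION_COLS = ("group", "frequency_hz", "noise_fraction")


@dataclass
class GroupSummary:
    """Mean ± SEM of one endpoint over animal means in one condition."""

    endpoint: str
    group: str
    frequency_hz: float
    noise_fraction: float
    mean: float
    sem: float
    n_animals: int
    normalized_mean: float | None = None


def per_animal_aggregate(
    cell_rows: pd.DataFrame,
    endpoints: list[str],
    condition_cols: tuple[str, ...] = CONDITION_COLS,
    animal_col: str = "animal_id",
) -> pd.DataFrame:
    """Unweighted per-animal, per-condition means of per-cell endpoints.

    Rows where an endpoint is NaN (analysis errors) are excluded from that
    endpoint's mean and counted in ``n_excluded``.  Animals with zero valid
    cells for every endpoint are dropped with a warning.
    """
    if animal_col not in cell_rows.columns:
        raise ParameterError(f"every row must carry {animal_col!r}")
    keys = [c for c in condition_cols if c in cell_rows.columns] + [animal_col]
    grouped = cell_rows.groupby(keys, sort=True, dropna=False)
    out = grouped[endpoints].mean().reset_index()
    out["n_cells"] = grouped.size().to_numpy()
    out["n_excluded"] = grouped[endpoints].apply(
        lambda g: int(g.isna().any(axis=1).sum())).to_numpy()
    empty = out[endpoints].isna().all(axis=1)
    if empty.any():
        for _, row in out[empty].iterrows():
            warnings.warn(f"animal {row[animal_col]!r} has no valid cells "
                          "in one condition; excluded")
        out = out[~empty].reset_index(drop=True)
    return out


def summarize_groups(
    animal_df: pd.DataFrame,
    endpoints: list[str],
    condition_cols: tuple[str, ...] = CONDITION_COLS,
) -> pd.DataFrame:
    """Tidy mean/SEM/n table over animal means, one row per endpoint and
    condition (SEM = sd over animals / sqrt(n_animals), ddof=1)."""
    keys = [c for c in condition_cols if c in animal_df.columns]
    records = []
    for cond, g in animal_df.groupby(keys, sort=True):
        cond = cond if isinstance(cond, tuple) else (cond,)
        for ep in endpoints:
            vals = g[ep].dropna().to_numpy()
            rec = dict(zip(keys, cond))
            rec.update(endpoint=ep, mean=vals.mean() if len(vals) else np.nan,
                       sem=(vals.std(ddof=1) / np.sqrt(len(vals))
                            if len(vals) >= 2 else np.nan),
                       n_animals=len(vals))
            records.append(rec)
    return pd.DataFrame.from_records(records)


def normalize_to_reference(
    animal_df: pd.DataFrame,
    endpoints: list[str],
    reference: dict[str, object] | None = None,
    match_cols: tuple[str, ...] = ("frequency_hz",),
) -> pd.DataFrame:
    """Divide every animal mean by the reference group mean.

    ``reference`` fixes column values identifying the reference condition
    (default ``{"group": "CTRL", "noise_fraction": 0.0}`` — the zero-noise
    control); ``match_cols`` are matched between each row and its reference
    (default: same pacing frequency).  For the per-frequency mode without a
    noise axis, pass ``reference={"group": "CTRL"}``.  Returns a copy of
    ``animal_df`` with ``<endpoint>_norm`` columns; the reference group's
    normalized mean is 1 by construction.
    """
    if reference is None:
        reference = {"group": "CTRL", "noise_fraction": 0.0}
    for col in list(reference) + list(match_cols):
        if col not in animal_df.columns:
            raise ConfigurationError(f"reference/match column {col!r} not present")
    out = animal_df.copy()
    for ep in endpoints:
        out[f"{ep}_norm"] = np.nan
    ref_mask = np.ones(len(animal_df), dtype=bool)
    for col, val in reference.items():
        ref_mask &= (animal_df[col] == val).to_numpy()
    if not ref_mask.any():
        raise ConfigurationError(f"reference condition {reference} not present")
    groups = animal_df.groupby(list(match_cols), sort=False).indices if match_cols \
        else {(): np.arange(len(animal_df))}
    for _, idx in groups.items():
        idx = np.asarray(idx)
        ref_idx = idx[ref_mask[idx]]
        if len(ref_idx) == 0:
            raise ConfigurationError(
                f"reference condition {reference} missing for one level of "
                f"{match_cols}")
        for ep in endpoints:
            ref_mean = animal_df.loc[animal_df.index[ref_idx], ep].mean()
            out.loc[out.index[idx], f"{ep}_norm"] = (
                animal_df.loc[animal_df.index[idx], ep] / ref_mean)
    return out


@dataclass
class StatTestResult:
    test: str
    statistic: float
    p_value: float


def compare_groups(
    a_means,
    b_means,
    test: str = "student_t",
) -> StatTestResult:
    """Two-sided comparison of two samples of animal means.

    ``test`` is ``"student_t"`` (pooled variance, the default),
    ``"welch_t"`` or ``"mann_whitney_u"``.  The U statistic uses exact
    enumeration when min(n) <= 8 and there are no ties, otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(a_means, dtype=float)
    b = np.asarray(b_means, dtype=float)
    if test in ("student_t", "welch_t"):
        if len(a) < 2 or len(b) < 2:
            raise ParameterError("t-tests need n >= 2 per sample")
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                raise DegenerateInputError(
                    "both samples constant and equal: t undefined")
            raise DegenerateInputError("zero variance in both samples")
        res = sps.ttest_ind(a, b, equal_var=(test == "student_t"))
        return StatTestResult(test, float(res.statistic), float(res.pvalue))
    if test == "mann_whitney_u":
        if len(a) < 1 or len(b) < 1:
            raise ParameterError("U-test needs n >= 1 per sample")
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return StatTestResult(test, float(res.statistic), float(res.pvalue))
    raise ParameterError(f"unknown test {test!r}")


def anova_multi(
    df: pd.DataFrame,
    value: str,
    factors: list[str],
    design: str = "one_way",
    posthoc: bool = True,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame | None]:
    """Fixed-effects ANOVA with optional Tukey HSD post-hoc comparisons.

    ``design`` is ``"one_way"`` (one factor) or ``"two_way"`` (two factors
    with interaction, type-II sums of squares).  Returns ``{"anova":
    table, "posthoc": tukey table or None}``; the post-hoc compares the
    (combined) factor-level groups at significance level ``alpha``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if design == "one_way":
        if len(factors) != 1:
            raise ConfigurationError("one_way design needs exactly one factor")
    elif design == "two_way":
        if len(factors) != 2:
            raise ConfigurationError("two_way design needs exactly two factors")
    else:
        raise ParameterError(f"unknown design {design!r}")
    data = df[[value] + factors].dropna().copy()
    data = data.rename(columns={value: "_y"})
    for i, f in enumerate(factors):
        data[f"_f{i}"] = data[f].astype(str)
        levels = data[f"_f{i}"].nunique()
        if levels < 2:
            raise ConfigurationError(f"factor {f!r} needs >= 2 levels")
    cell_sizes = data.groupby([f"_f{i}" for i in range(len(factors))]).size()
    if (cell_sizes < 2).any():
        raise ConfigurationError("every design cell needs n >= 2")
    if design == "two_way":
        n_cells = int(np.prod([data[f"_f{i}"].nunique() for i in range(2)]))
        if len(cell_sizes) < n_cells:
            raise ConfigurationError(
                "two_way design with empty cells: interaction not estimable")
    within_var = data.groupby([f"_f{i}" for i in range(len(factors))])["_y"].var(ddof=1)
    if np.allclose(within_var.fillna(0), 0):
        raise DegenerateInputError("zero within-group variance: F undefined")

    formula = "_y ~ " + (" * " if design == "two_way" else " + ").join(
        f"C(_f{i})" for i in range(len(factors)))
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)

    tukey = None
    if posthoc:
        labels = data[[f"_f{i}" for i in range(len(factors))]].agg(":".join, axis=1)
        res = pairwise_tukeyhsd(data["_y"].to_numpy(), labels.to_numpy(), alpha=alpha)
        tukey = pd.DataFrame(res.summary().data[1:],
                             columns=res.summary().data[0])
    return {"anova": table, "posthoc": tukey}
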