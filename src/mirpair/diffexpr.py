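"""Rank-based two-group differential expression for small-sample designs.

The statistics follow the non-parametric screening approach used for small
clinical cohorts (here 7 cases vs 7 controls):

* present-calling by a log2 floor reached in a minimum fraction of samples of
  at least one group;
* the rank-sum difference between groups on midranks of the pooled values,
  with features attaining the *theoretical maximal* rank-sum difference
  flagged as distinctly expressed (complete separation: every value of one
  group exceeds every value of the other);
* two-sided Mann-Whitney U p-values (exact enumeration for small tie-free
  samples, tie-corrected normal approximation with continuity correction
  otherwise);
* signed fold changes from the ratio r of group means of the linear relative
  expression: +r for r >= 1, -1/r for r < 1.

No multiple-testing correction is applied by default (raw p <= alpha calls a
feature "regulated"); Benjamini-Hochberg is available behind ``adjust="bh"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import ExpressionDataset

__all__ = [
    "call_present", "rank_sum_difference", "mann_whitney_p",
    "signed_fold_change", "run_de", "max_rank_sum_diff", "RankSumResult",
]

EXACT_MAX_N = 16  # auto mode: exact enumeration up to this pooled size


@dataclass(frozen=True)
class RankSumResult:
    rank_sum_case: float
    rank_sum_control: float
    diff: float
    max_diff: float
    distinct: bool


def max_rank_sum_diff(n_case: int, n_control: int, direction: int = 1) -> float:
    """Theoretical extreme of the rank-sum difference (case - control).

    ``direction=+1``: every case value above every control value (case holds
    the top ranks); ``direction=-1``: the mirror image.  For n1 = n2 = 7 the
    extremes are +49 and -49 (ranks 8..14 vs 1..7).  With unequal group
    sizes the two extremes are not symmetric around zero (the rank-sum
    difference is centered at (n1 - n2)(n1 + n2 + 1)/2 under the null), so
    the extreme of the *relevant* direction must be compared against.
    """
    n1, n2 = n_case, n_control
    if direction >= 0:
        return n1 * (n1 + 2 * n2 + 1) / 2 - n2 * (n2 + 1) / 2
    return n1 * (n1 + 1) / 2 - n2 * (n2 + 2 * n1 + 1) / 2


def _null_mean_diff(n1: int, n2: int) -> float:
    return (n1 - n2) * (n1 + n2 + 1) / 2


def rank_sum_difference(case_values, control_values) -> RankSumResult:
    """Midrank sums over the pooled values and the distinctness flag.

    distinct <=> diff equals the theoretical extreme of its direction
    (direction taken relative to the null expectation of diff) <=> the two
    group value ranges do not overlap (any cross-group tie forbids
    distinctness).  For equal group sizes this reduces to
    |diff| = max_rank_sum_diff.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)  # midranks
    r_case = float(ranks[: case.size].sum())
    r_control = float(ranks[case.size:].sum())
    diff = r_case - r_control
    center = _null_mean_diff(case.size, control.size)
    max_diff = max_rank_sum_diff(case.size, control.size,
                                 1 if diff >= center else -1)
    distinct = bool(case.min() > control.max() or case.max() < control.min())
    return RankSumResult(r_case, r_control, diff, max_diff, distinct)


def _has_cross_ties(case: np.ndarray, control: np.ndarray) -> bool:
    return bool(np.intersect1d(case, control).size)


def mann_whitney_p(
    case_values, control_values,
    mode: Literal["exact", "normal", "auto"] = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of case vs control.

    ``exact`` enumerates the permutation distribution of U and is only valid
    without cross-group ties; ``normal`` is the tie-corrected normal
    approximation with continuity correction; ``auto`` picks exact when
    n1 + n2 <= 16 and there are no cross-group ties, else normal.

    Returns (U, p) with U the case-vs-control statistic.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    if mode not in ("exact", "normal", "auto"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    ties = _has_cross_ties(case, control)
    if mode == "exact" and ties:
        raise ConfigurationError(
            "exact Mann-Whitney is not defined with cross-group ties; "
            "use mode='normal'"
        )
    if mode == "auto":
        mode = "exact" if (case.size + control.size <= EXACT_MAX_N
                           and not ties) else "normal"
    if mode == "exact":
        res = stats.mannwhitneyu(case, control, alternative="two-sided",
                                 method="exact")
    else:
        res = stats.mannwhitneyu(case, control, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def signed_fold_change(case_values, control_values,
                       agg: Literal["mean", "median"] = "mean") -> float:
    """Signed fold change from the ratio of group aggregates (case/control).

    r >= 1 reports +r; r < 1 reports -1/r, so |FC| >= 1 always and the sign
    is the direction of the case group relative to controls.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    f = np.mean if agg == "mean" else np.median
    mc, mk = float(f(case)), float(f(control))
    if mc <= 0 or mk <= 0:
        raise ConfigurationError("group aggregates must be positive")
    r = mc / mk
    return r if r >= 1 else -1.0 / r


def _direction(fc: float) -> str:
    if fc > 1:
        return "up"
    if fc < 0:
        return "down"
    return "flat"


def call_present(dataset: ExpressionDataset, floor: float = 4.0,
                 min_frac: float = 0.5) -> pd.Series:
    """Present iff log2 expression > floor in >= min_frac of the samples of at
    least one group."""
    if not (0 < min_frac <= 1):
        raise ConfigurationError("min_frac must be in (0, 1]")
    log2 = dataset.log2()
    flags = {}
    for ids in (dataset.case_ids, dataset.control_ids):
        sub = log2[ids]
        flags[id(ids)] = (sub > floor).sum(axis=1) >= min_frac * len(ids)
    present = np.logical_or.reduce(list(flags.values()))
    return pd.Series(present, index=dataset.values.index, name="present")


DE_COLUMNS = [
    "present", "rank_sum_case", "rank_sum_control", "rank_sum_diff",
    "max_rank_sum_diff", "distinct", "U", "p_value", "fold_change_signed",
    "direction", "regulated",
]


def run_de(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    floor: float = 4.0,
    min_frac: float = 0.5,
    mode: Literal["exact", "normal", "auto"] = "auto",
    agg: Literal["mean", "median"] = "mean",
    adjust: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full differential-expression pass over a dataset.

    Returns (table, summary).  The table is indexed by feature id with the
    columns in ``DE_COLUMNS`` (absent features carry NaN statistics);
    ``regulated`` means present and p <= alpha (inclusive boundary).  The
    summary dict reports the counts present / regulated / up / down /
    distinct.

    The Mann-Whitney computation is vectorized: tie-free features go through
    exact enumeration (when the pooled size permits), features with
    cross-group ties through the tie-corrected normal approximation.
    """
    present = call_present(dataset, floor=floor, min_frac=min_frac)
    case = dataset.values[dataset.case_ids].to_numpy(float)
    control = dataset.values[dataset.control_ids].to_numpy(float)
    n1, n2 = case.shape[1], control.shape[1]
    n_feat = case.shape[0]

    pooled = np.concatenate([case, control], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    r_case = ranks[:, :n1].sum(axis=1)
    r_control = ranks[:, n1:].sum(axis=1)
    diff = r_case - r_control
    max_diff = np.where(diff >= _null_mean_diff(n1, n2),
                        max_rank_sum_diff(n1, n2, 1),
                        max_rank_sum_diff(n1, n2, -1))
    distinct_sep = (case.min(axis=1) > control.max(axis=1)) | (
        case.max(axis=1) < control.min(axis=1))

    # cross-group ties per feature
    cross_ties = np.array([
        _has_cross_ties(case[i], control[i]) for i in range(n_feat)
    ])
    U = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    use_exact = (
        np.zeros(n_feat, bool) if mode == "normal"
        else (~cross_ties if mode == "exact"
              else (~cross_ties & (n1 + n2 <= EXACT_MAX_N)))
    )
    if mode == "exact" and cross_ties.any():
        raise ConfigurationError(
            "exact Mann-Whitney requested but cross-group ties present; "
            "use mode='normal'"
        )
    if use_exact.any():
        res = stats.mannwhitneyu(case[use_exact], control[use_exact],
                                 axis=1, alternative="two-sided",
                                 method="exact")
        U[use_exact] = res.statistic
        p[use_exact] = res.pvalue
    rest = ~use_exact
    if rest.any():
        res = stats.mannwhitneyu(case[rest], control[rest], axis=1,
                                 alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        U[rest] = res.statistic
        p[rest] = res.pvalue
    p = np.minimum(p, 1.0)

    agg_f = np.mean if agg == "mean" else np.median
    mc = agg_f(case, axis=1)
    mk = agg_f(control, axis=1)
    r = mc / mk
    fc = np.where(r >= 1, r, -1.0 / r)

    table = pd.DataFrame(index=dataset.values.index.copy())
    table["present"] = present.to_numpy()
    table["rank_sum_case"] = r_case
    table["rank_sum_control"] = r_control
    table["rank_sum_diff"] = diff
    table["max_rank_sum_diff"] = max_diff
    table["distinct"] = distinct_sep
    table["U"] = U
    table["p_value"] = p
    table["fold_change_signed"] = fc
    table["direction"] = [_direction(v) for v in fc]

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        mask = table["present"].to_numpy()
        p_adj = np.full(n_feat, np.nan)
        if mask.any():
            p_adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
        table["p_adj"] = p_adj
        sig = table["p_adj"] <= alpha
    elif adjust is None:
        sig = table["p_value"] <= alpha
    else:
        raise ConfigurationError(f"unknown adjustment {adjust!r}")

    table["regulated"] = table["present"] & sig
    # statistics are only reported for present features
    absent = ~table["present"].to_numpy()
    float_cols = [c for c in table.columns
                  if c not in ("present", "regulated", "direction", "distinct")]
    table.loc[absent, float_cols] = np.nan
    table.loc[absent, "direction"] = ""
    table["distinct"] = table["regulated"] & table["distinct"]

    reg = table[table["regulated"]]
    summary = {
        "present": int(table["present"].sum()),
        "regulated": int(table["regulated"].sum()),
        "up": int((reg["direction"] == "up").sum()),
        "down": int((reg["direction"] == "down").sum()),
        "distinct": int(table["distinct"].sum()),
    }
    return table, summary
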