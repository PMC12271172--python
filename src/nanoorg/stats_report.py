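"""Group-comparison statistics: normality-gated tests, Grubbs outliers,
per-culture vehicle normalization, and tidy reports.

Policy: measurements are normalized to the vehicle-group mean of their own
culture (x100, so vehicle averages 100 per culture); group comparisons use a
two-tailed unpaired t-test when both groups pass every evaluable normality
test (D'Agostino-Pearson, Anderson-Darling, Shapiro-Wilk, Lilliefors-
corrected Kolmogorov-Smirnov) at alpha = 0.05, and a two-tailed Mann-Whitney
test otherwise.  Outliers can be removed beforehand by an iterated two-sided
Grubbs test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import (InsufficientDataError, NormalizationError,
                         ParameterError)

GROUP_VEHICLE = "vehicle"


# ---------------------------------------------------------------------------
# per-culture vehicle normalization
# ---------------------------------------------------------------------------

def normalize_to_vehicle(table: pd.DataFrame, variable: str | None = None,
                         vehicle_label: str = GROUP_VEHICLE) -> pd.DataFrame:
    """Normalize values to the vehicle average of each independent culture.

    ``table`` is tidy with columns ``culture_id, cell_id, group, variable,
    value``.  Each value becomes ``100 * value / mean(vehicle values of the
    same culture and variable)``, so every culture's vehicle mean is exactly
    100.  Cultures lacking vehicle rows for a variable raise
    :class:`NormalizationError` naming the culture.
    """
    required = {"culture_id", "group", "variable", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"measurement table missing column(s): {sorted(missing)}")
    out = table.copy()
    if variable is not None:
        out = out[out["variable"] == variable].copy()
    for (culture, var), sub in out.groupby(["culture_id", "variable"]):
        veh = sub.loc[sub["group"] == vehicle_label, "value"]
        if len(veh) == 0:
            raise NormalizationError(
                f"culture {culture!r} has no vehicle rows for variable {var!r}")
        out.loc[sub.index, "value"] = 100.0 * sub["value"] / veh.mean()
    return out


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

#: test name -> (minimum n, callable returning p-value or pass boolean)
def _dagostino_p(x):
    return stats.normaltest(x).pvalue


def _shapiro_p(x):
    return stats.shapiro(x).pvalue


def _lilliefors_p(x):
    return lilliefors(x, dist="norm")[1]


def _anderson_pass(x, alpha):
    res = stats.anderson(x, dist="norm", method="interpolate")
    return bool(res.pvalue > alpha)


NORMALITY_TESTS = ("dagostino_pearson", "anderson_darling", "shapiro_wilk",
                   "kolmogorov_smirnov")
_MIN_N = {"dagostino_pearson": 8, "anderson_darling": 8,
          "shapiro_wilk": 3, "kolmogorov_smirnov": 4}


def normality_report(values, alpha: float = 0.05) -> dict:
    """Outcome of each evaluable normality test for one sample.

    Tests whose minimum sample size is not met report ``None`` (skipped from
    the gate).  A sample with zero variance fails all evaluable tests.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    out: dict[str, bool | None] = {}
    degenerate = n > 0 and np.allclose(x, x[0])
    for name in NORMALITY_TESTS:
        if n < _MIN_N[name]:
            out[name] = None
        elif degenerate:
            out[name] = False
        elif name == "anderson_darling":
            out[name] = _anderson_pass(x, alpha)
        else:
            p = {"dagostino_pearson": _dagostino_p, "shapiro_wilk": _shapiro_p,
                 "kolmogorov_smirnov": _lilliefors_p}[name](x)
            out[name] = bool(p > alpha)
    return out


def normality_gate(values_a, values_b, alpha: float = 0.05) -> bool:
    """True (use the t-test) iff both groups pass all evaluable tests.

    Requires n >= 3 per group (the Shapiro-Wilk minimum); tests needing more
    observations are skipped rather than failed.
    """
    for vals in (values_a, values_b):
        if len(vals) < 3:
            raise InsufficientDataError("normality gate needs n >= 3 per group")
    for vals in (values_a, values_b):
        report = normality_report(vals, alpha)
        evaluated = [ok for ok in report.values() if ok is not None]
        if not evaluated or not all(evaluated):
            return False
    return True


# ---------------------------------------------------------------------------
# Grubbs outliers
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def remove_outliers_grubbs(values, alpha: float = 0.05):
    """Iterated two-sided Grubbs test; returns ``(kept, removed)`` arrays.

    At most one value (the most extreme) is removed per iteration; iteration
    stops when no value exceeds the critical G or fewer than 3 values remain.
    Zero-variance samples are returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("Grubbs test needs n >= 3")
    kept = x.copy()
    removed = []
    while len(kept) >= 3:
        sd = kept.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(kept - kept.mean()) / sd
        i = int(np.argmax(g))
        if g[i] > grubbs_critical(len(kept), alpha):
            removed.append(kept[i])
            kept = np.delete(kept, i)
        else:
            break
    return kept, np.asarray(removed)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonPolicy:
    """Switches for :func:`compare_groups`."""

    alpha_normality: float = 0.05
    remove_outliers: bool = False
    grubbs_alpha: float = 0.05
    paired: bool = False
    exact_mw_max_n: int = 8      # exact Mann-Whitney p up to this group size


@dataclass
class ComparisonResult:
    variable: str
    test_used: str               # unpaired_t | mann_whitney | paired_t
    statistic: float
    p_value: float
    descriptives: dict           # per-group mean/SEM or median/quartiles
    n: tuple[int, int]
    outliers_removed: list = field(default_factory=list)


def compare_groups(values_a, values_b, policy: ComparisonPolicy | None = None,
                   variable: str = "", labels=("a", "b")) -> ComparisonResult:
    """Two-group comparison under the normality-gated test policy.

    The descriptives follow the chosen test's convention: mean ± SEM for
    t-tests, median and quartiles for Mann-Whitney.
    """
    policy = policy or ComparisonPolicy()
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    removed: list[float] = []
    if policy.remove_outliers:
        a, rem_a = remove_outliers_grubbs(a, policy.grubbs_alpha)
        b, rem_b = remove_outliers_grubbs(b, policy.grubbs_alpha)
        removed = [*rem_a, *rem_b]

    if policy.paired:
        if len(a) != len(b):
            raise ParameterError("paired comparison needs equal-length groups")
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_rel(a, b)
        test = "paired_t"
        desc = _mean_sem(a, b, labels)
    else:
        gate = normality_gate(a, b, policy.alpha_normality)
        if gate:
            if np.allclose(a, a[0]) and np.allclose(b, b[0]) and a[0] == b[0]:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(a, b)
            test = "unpaired_t"
            desc = _mean_sem(a, b, labels)
        else:
            method = ("exact" if max(len(a), len(b)) <= policy.exact_mw_max_n
                      and not _has_ties(a, b) else "asymptotic")
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat, p = res.statistic, res.pvalue
            test = "mann_whitney"
            desc = {
                labels[0]: {"median": float(np.median(a)),
                            "q1": float(np.percentile(a, 25)),
                            "q3": float(np.percentile(a, 75))},
                labels[1]: {"median": float(np.median(b)),
                            "q1": float(np.percentile(b, 25)),
                            "q3": float(np.percentile(b, 75))},
            }
    return ComparisonResult(variable=variable, test_used=test, statistic=float(stat),
                            p_value=float(p), descriptives=desc,
                            n=(len(a), len(b)), outliers_removed=removed)


def _has_ties(a, b) -> bool:
    merged = np.concatenate([a, b])
    return len(np.unique(merged)) < len(merged)


def _mean_sem(a, b, labels):
    return {labels[0]: {"mean": float(a.mean()), "sem": float(stats.sem(a))},
            labels[1]: {"mean": float(b.mean()), "sem": float(stats.sem(b))}}


def percent_change(baseline: float, post: float) -> float:
    """100 * (post - baseline) / baseline."""
    if baseline == 0:
        raise ParameterError("baseline must be nonzero")
    return 100.0 * (post - baseline) / baseline


def compare_table(table: pd.DataFrame, variables=None, group_col: str = "group",
                  policy: ComparisonPolicy | None = None) -> pd.DataFrame:
    """Run :func:`compare_groups` for each variable of a tidy table.

    Returns one report row per variable with the test used, the statistic,
    the p-value and per-group descriptives.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ParameterError(f"need exactly two groups, found {groups}")
    variables = variables or sorted(table["variable"].unique())
    rows = []
    for var in variables:
        sub = table[table["variable"] == var]
        a = sub.loc[sub[group_col] == groups[0], "value"].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], "value"].to_numpy()
        res = compare_groups(a, b, policy, variable=var, labels=tuple(groups))
        row = {"variable": var, "test_used": res.test_used,
               "statistic": res.statistic, "p_value": res.p_value,
               f"n_{groups[0]}": res.n[0], f"n_{groups[1]}": res.n[1],
               "n_outliers_removed": len(res.outliers_removed)}
        for g, d in res.descriptives.items():
            for k, v in d.items():
                row[f"{k}_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
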