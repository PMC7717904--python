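"""Cohort-level statistics: mean ± s.e.m., Student's t-test, ratios.

The group comparison follows the classical recipe for small embryo
cohorts: per-group mean and standard error (unbiased s.d. / √n), a
pooled-variance two-tailed Student t-test between genotypes, and the
expression ratio reported as percent of the littermate-control mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero pooled variance with unequal means


def summarize(values) -> GroupSummary:
    """n, mean and s.e.m. (unbiased sample s.d. over √n); requires n ≥ 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a s.e.m.")
    return GroupSummary(n=int(v.size), mean=float(v.mean()),
                        sem=float(v.std(ddof=1) / np.sqrt(v.size)))


def t_test(a, b) -> TTestResult:
    """Pooled-variance two-sample Student t-test, two-tailed.

    df = n_a + n_b − 2.  Degenerate zero-variance cases follow the
    contract: equal means → t = 0, p = 1; unequal means → p = 0 with the
    ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = int(a.size + b.size - 2)
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, df=df)
        return TTestResult(t=float("inf") if a.mean() > b.mean() else float("-inf"),
                           p=0.0, df=df, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=df)


def expression_ratio(test, control) -> float:
    """Percent of control: ``100 × mean(test) / mean(control)``.

    Computed from group means (not per-pair ratios); scale-invariant.
    """
    test = np.asarray(test, dtype=float)
    control = np.asarray(control, dtype=float)
    mc = control.mean()
    if mc <= 0:
        raise ValueError("control mean must be positive")
    return float(100.0 * test.mean() / mc)


@dataclass
class CohortResult:
    """Per-genotype summaries plus pairwise comparisons against control."""

    control: str
    groups: dict[str, GroupSummary] = field(default_factory=dict)
    comparisons: dict[str, dict] = field(default_factory=dict)
    bin_comparisons: dict[str, dict] | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def compare_cohort(densities: dict[str, list[float]], control: str = "control") -> CohortResult:
    """Summaries, t-tests and percent-of-control for each non-control group."""
    if control not in densities:
        raise ValueError(f"control group {control!r} missing")
    result = CohortResult(control=control)
    for name, vals in densities.items():
        result.groups[name] = summarize(vals)
    for name, vals in densities.items():
        if name == control:
            continue
        tt = t_test(vals, densities[control])
        result.comparisons[name] = {
            "t": tt.t, "p": tt.p, "df": tt.df, "degenerate": tt.degenerate,
            "percent_of_control": expression_ratio(vals, densities[control]),
        }
    return result


def compare_spot_bins(
    fractions: dict[str, pd.DataFrame], control: str = "control"
) -> dict[str, dict]:
    """Per-bin t-tests of per-sample spot fractions between genotypes.

    ``fractions[genotype]`` is a (sample × bin) DataFrame of percentages.
    No multiple-testing correction is applied across bins (per-bin tests
    are reported as such).
    """
    if control not in fractions:
        raise ValueError(f"control group {control!r} missing")
    ctl = fractions[control]
    out: dict[str, dict] = {}
    for name, df in fractions.items():
        if name == control:
            continue
        per_bin = {}
        for col in ctl.columns:
            tt = t_test(df[col].to_numpy(), ctl[col].to_numpy())
            per_bin[col] = {
                "t": tt.t, "p": tt.p,
                "mean_test": float(df[col].mean()), "mean_control": float(ctl[col].mean()),
            }
        out[name] = per_bin
    return out


# ---------------------------------------------------------------------------
# summary-level density simulation (calibration / power studies)
# ---------------------------------------------------------------------------

def simulate_density_cohort(
    n: int, rng: np.random.Generator, factor: float = 1.0,
    mean_density: float = 500.0, cv: float = 0.08,
) -> np.ndarray:
    """Per-embryo densities drawn at summary level: normal with mean
    ``factor × mean_density`` and s.d. proportional to the mean (constant
    biological coefficient of variation)."""
    mu = factor * mean_density
    return rng.normal(mu, cv * mu, size=n)


def type_i_error_rate(
    n_pairs: int = 2000, n_per_group: int = 8, alpha: float = 0.05,
    seed: int = 0, mean_density: float = 500.0, cv: float = 0.08,
) -> float:
    """Empirical type-I error of the pipeline t-test under the null.

    Both groups are drawn from the same summary-level density
    distribution; returns the fraction of two-tailed pooled t-tests with
    p < alpha.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(mean_density, cv * mean_density, size=(n_pairs, n_per_group))
    b = rng.normal(mean_density, cv * mean_density, size=(n_pairs, n_per_group))
    res = sps.ttest_ind(a, b, axis=1, equal_var=True)
    return float(np.mean(res.pvalue < alpha))
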