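"""Per-feature two-group significance screening.

Each feature (texture or clinical) is compared between groups with three
two-sided tests: Welch's unequal-variance t-test, the two-sample
Kolmogorov-Smirnov test, and the Mann-Whitney-Wilcoxon rank-sum test.
A feature counts as significant only when all three agree (p < alpha).
Raw p-values are reported; a Benjamini-Hochberg column is emitted as
supplementary output but never gates significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

COMPARISONS = ("PA_vs_EH", "HTN_vs_C")


@dataclass
class StatTestResult:
    feature_name: str
    comparison: str
    p_welch: float
    p_ks: float
    p_mw: float
    alpha: float = 0.05
    flagged: bool = False  # degenerate Welch variance

    @property
    def significant_all(self) -> bool:
        return max(self.p_welch, self.p_ks, self.p_mw) < self.alpha


def split_groups(table: pd.DataFrame, comparison: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rows of the two arms: PA vs EH, or PA+EH (hypertensives) vs C."""
    g = table["group_label"]
    if comparison == "PA_vs_EH":
        return table[g == "PA"], table[g == "EH"]
    if comparison == "HTN_vs_C":
        return table[g.isin(["PA", "EH"])], table[g == "C"]
    raise ValueError(f"unknown comparison {comparison!r}")


def three_tests(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """(p_welch, p_ks, p_mw, degenerate_flag) for two samples.

    Mann-Whitney uses the exact null for small samples without ties and
    the tie-corrected normal approximation otherwise; KS follows the
    analogous auto rule.  When both samples have zero variance Welch's
    statistic is undefined and p=1 is returned, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    flagged = False
    if np.var(x) == 0 and np.var(y) == 0:
        p_welch, flagged = 1.0, True
    else:
        p_welch = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    p_ks = float(sps.ks_2samp(x, y, method="auto").pvalue)
    method = "exact" if (len(x) <= 20 and len(y) <= 20) else "asymptotic"
    try:
        p_mw = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    except ValueError:  # exact method refuses ties; fall back
        p_mw = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return p_welch, p_ks, p_mw, flagged


def feature_significance(
    table: pd.DataFrame,
    comparison: str,
    alpha: float = 0.05,
    feature_cols: list[str] | None = None,
    per_patient: bool = False,
) -> list[StatTestResult]:
    """Run the three tests for every feature column.

    ``table`` carries one row per image (or per patient for clinical
    covariates) with ``group_label`` and ``patient_id`` columns.  The
    default unit of analysis is the image; ``per_patient=True`` averages
    each patient's images first.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in ("image_id", "patient_id", "group_label")]
    if per_patient:
        table = (table.groupby(["patient_id", "group_label"], as_index=False)[feature_cols]
                 .mean())
    ga, gb = split_groups(table, comparison)
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError(f"a group is empty for comparison {comparison}")
    results = []
    for col in feature_cols:
        x = ga[col].dropna().to_numpy()
        y = gb[col].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"feature {col!r} has no data in one arm")
        pw, pk, pm, fl = three_tests(x, y)
        results.append(StatTestResult(col, comparison, pw, pk, pm, alpha=alpha, flagged=fl))
    return results


def count_significant(results: list[StatTestResult], alpha: float = 0.05) -> int:
    """Number of features significant by all three tests at ``alpha``."""
    if not results:
        raise ValueError("no test results")
    return sum(max(r.p_welch, r.p_ks, r.p_mw) < alpha for r in results)


def results_frame(results: list[StatTestResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"feature": r.feature_name, "comparison": r.comparison,
          "p_welch": r.p_welch, "p_ks": r.p_ks, "p_mw": r.p_mw,
          "significant_all": r.significant_all} for r in results]
    )
    # supplementary BH-adjusted Welch p-values (never gate significance)
    for comp in df["comparison"].unique():
        sel = df["comparison"] == comp
        df.loc[sel, "q_welch_bh"] = _bh_adjust(df.loc[sel, "p_welch"].to_numpy())
    return df


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def significance_report(
    results: list[StatTestResult],
    clinical_results: list[StatTestResult] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screening table with blank cells for non-significant entries.

    Rows sorted ascending by the Welch p-value; each p-value cell is
    printed only when below ``alpha``, otherwise left blank.
    """
    all_results = list(results) + list(clinical_results or [])
    rows = []
    for r in sorted(all_results, key=lambda r: r.p_welch):
        rows.append({
            "feature": r.feature_name,
            "comparison": r.comparison,
            "t_test": _fmt_p(r.p_welch, alpha),
            "ks_test": _fmt_p(r.p_ks, alpha),
            "mw_test": _fmt_p(r.p_mw, alpha),
        })
    return pd.DataFrame(rows, columns=["feature", "comparison", "t_test", "ks_test", "mw_test"])


def _fmt_p(p: float, alpha: float) -> str:
    if p >= alpha:
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"
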