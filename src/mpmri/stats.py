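"""Normality-gated group statistics and PCA over the ten study variables.

The gate follows the study convention: Shapiro-Wilk per group at alpha =
0.05; if any group fails, the comparison is nonparametric (Mann-Whitney U
between phenotypes, Kruskal-Wallis across days), otherwise parametric
(unpaired two-sided t-test, one-way ANOVA).  No multiple-testing
correction is applied — raw p-values are reported, matching the original
analysis convention.

PCA operates on the z-scored ten-variable feature table (correlation-
matrix PCA, appropriate for incommensurate units); the sign of each
component is fixed so its largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

#: the ten feature-table variables entering the PCA, in canonical order
FEATURE_COLUMNS = ("ADC_mean", "ADC_kurtosis", "ADC_range", "ADC_p90",
                   "delta_T1", "Ktrans", "AUC", "slope_max", "T1", "T2")
ID_COLUMNS = ("tumor_id", "phenotype", "day")


@dataclass
class GroupSample:
    label: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("a group needs at least 2 values")


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    gate_trace: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class PCAResult:
    loadings: np.ndarray       # (n_variables, k)
    scores: np.ndarray         # (n_rows, k)
    variance_ratio: np.ndarray  # (k,)
    columns: tuple[str, ...] = FEATURE_COLUMNS


def shapiro_gate(groups: list[GroupSample], alpha: float = 0.05):
    """Decide parametric vs. nonparametric testing.

    Returns ``(choice, p_per_group)`` with choice ``'nonparametric'`` iff
    any group's Shapiro-Wilk p-value falls below ``alpha``.
    """
    if any(g.values.size < 3 for g in groups):
        raise ValueError("Shapiro-Wilk needs at least 3 values per group")
    p_per_group = {g.label: float(sps.shapiro(g.values).pvalue) for g in groups}
    choice = "nonparametric" if any(p < alpha for p in p_per_group.values()) else "parametric"
    return choice, p_per_group


def _mwu_method(a: np.ndarray, b: np.ndarray) -> str:
    # exact when both groups are small; tie-corrected normal approximation otherwise
    return "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"


def compare_two_groups(a: GroupSample, b: GroupSample, alpha: float = 0.05,
                       force: str | None = None) -> TestResult:
    """Two-sided two-group comparison with the normality gate.

    ``force`` overrides the gate with ``'parametric'`` or ``'nonparametric'``.
    """
    if force is None:
        if min(a.values.size, b.values.size) < 3:
            # normality cannot be assessed; default to the rank test
            choice = "nonparametric"
            trace = {"gate": "skipped_small_n"}
        else:
            choice, p_sw = shapiro_gate([a, b], alpha)
            trace = {"shapiro_p": p_sw, "alpha": alpha}
    else:
        choice = force
        trace = {"forced": force}
    trace["choice"] = choice
    if choice == "parametric":
        res = sps.ttest_ind(a.values, b.values)
        return TestResult("t_test", float(res.statistic), float(res.pvalue), trace)
    res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided",
                           method=_mwu_method(a.values, b.values))
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue), trace)


def compare_over_time(groups: list[GroupSample], alpha: float = 0.05,
                      force: str | None = None) -> TestResult:
    """Gated one-way comparison across the three imaging days."""
    if len(groups) != 3:
        raise ValueError("expected samples for the 3 imaging days")
    if force is None:
        if min(g.values.size for g in groups) < 3:
            choice = "nonparametric"
            trace = {"gate": "skipped_small_n"}
        else:
            choice, p_sw = shapiro_gate(groups, alpha)
            trace = {"shapiro_p": p_sw, "alpha": alpha}
    else:
        choice = force
        trace = {"forced": force}
    trace["choice"] = choice
    arrays = [g.values for g in groups]
    if choice == "parametric":
        res = sps.f_oneway(*arrays)
        return TestResult("anova", float(res.statistic), float(res.pvalue), trace)
    res = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(res.statistic), float(res.pvalue), trace)


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with the two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return TestResult("pearson", float(res.statistic), float(res.pvalue))


def make_feature_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate the study feature table."""
    table = pd.DataFrame(rows)
    missing = [c for c in ID_COLUMNS + FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if table[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("feature table has missing values in PCA variables")
    return table[list(ID_COLUMNS + FEATURE_COLUMNS)]


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature column to mean 0, sd 1 (n-1)."""
    out = table.copy()
    for col in FEATURE_COLUMNS:
        values = out[col].to_numpy(dtype=float)
        sd = values.std(ddof=1)
        if sd == 0:
            raise ValueError(f"constant column {col!r} cannot be standardized")
        out[col] = (values - values.mean()) / sd
    return out


def run_pca(table: pd.DataFrame, n_components: int = 10) -> PCAResult:
    """PCA of the (z-scored) feature table via the singular decomposition.

    The sign of each component is fixed so that its largest-magnitude
    loading is positive, making scores reproducible across runs.
    """
    x = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    n_rows = x.shape[0]
    if n_rows < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_components > min(n_rows - 1, len(FEATURE_COLUMNS)):
        raise ValueError("n_components exceeds the table rank")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()          # (n_vars, k)
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(loadings=loadings, scores=scores,
                     variance_ratio=pca.explained_variance_ratio_.copy())


def pc1_threshold_accuracy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Separation of two classes by thresholding the first PC score.

    The threshold is the midpoint between the two class means on PC1;
    accuracy is the fraction of rows on their class's side.
    """
    pc1 = np.asarray(scores)[:, 0]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("PC1 threshold accuracy needs exactly 2 classes")
    m0 = pc1[labels == classes[0]].mean()
    m1 = pc1[labels == classes[1]].mean()
    threshold = 0.5 * (m0 + m1)
    if m0 <= m1:
        pred = np.where(pc1 <= threshold, classes[0], classes[1])
    else:
        pred = np.where(pc1 > threshold, classes[0], classes[1])
    return float(np.mean(pred == labels))
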