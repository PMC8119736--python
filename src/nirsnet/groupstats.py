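"""Group-level statistics: connection-wise and ROI-wise two-sample t-tests
with Benjamini–Hochberg FDR correction, metric comparisons across the
sparsity sweep, two-sample power analysis, and the classification feature
grid (4 metrics × 5 thresholds → 20 features per subject).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

from .connectivity import ConnectivityMatrix

FEATURE_METRICS = ("sigma", "eloc_gamma", "q", "cp_gamma")
FEATURE_THRESHOLDS = (0.30, 0.31, 0.32, 0.33, 0.34)


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    unit: str
    t: float
    df: int
    p: float
    p_fdr: float | None = None
    mean_a: float = np.nan
    sd_a: float = np.nan
    mean_b: float = np.nan
    sd_b: float = np.nan


def two_sample_t(
    group_a: np.ndarray, group_b: np.ndarray, unit: str = ""
) -> TestResult:
    """Pooled-variance (Student) two-sided t-test; df = n1 + n2 − 2.

    The pooled form is the one consistent with df = 24 for two groups of
    13 subjects.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs >= 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        unit=unit,
        t=float(t),
        df=a.size + b.size - 2,
        p=float(p),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
    )


def fdr_correct(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ConnectionTests:
    table: pd.DataFrame  # one row per unique pair
    n_sig_05: int  # uncorrected p < 0.05
    n_sig_01: int  # uncorrected p < 0.01
    n_sig_fdr_05: int
    n_sig_fdr_01: int


def connectionwise_tests(
    mats_a: list[ConnectivityMatrix], mats_b: list[ConnectivityMatrix]
) -> ConnectionTests:
    """Two-sample t-test per unique node pair across the two groups.

    For 45-channel matrices this is 990 tests. Significance counts are
    reported both before and after FDR, since either convention may be the
    one behind a printed count.
    """
    if not mats_a or not mats_b:
        raise StatsError("both groups need at least one matrix")
    labels = mats_a[0].labels
    for m in mats_a + mats_b:
        if m.labels != labels:
            raise StatsError("all matrices must share node labels")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    stack_a = np.stack([m.values[iu] for m in mats_a])  # subjects x pairs
    stack_b = np.stack([m.values[iu] for m in mats_b])
    rows = []
    for k, (i, j) in enumerate(zip(*iu)):
        res = two_sample_t(stack_a[:, k], stack_b[:, k], unit=f"{labels[i]}-{labels[j]}")
        rows.append(res)
    p = np.array([r.p for r in rows])
    p_fdr = fdr_correct(p)
    table = pd.DataFrame(
        {
            "unit": [r.unit for r in rows],
            "t": [r.t for r in rows],
            "df": [r.df for r in rows],
            "p": p,
            "p_fdr": p_fdr,
            "mean_a": [r.mean_a for r in rows],
            "sd_a": [r.sd_a for r in rows],
            "mean_b": [r.mean_b for r in rows],
            "sd_b": [r.sd_b for r in rows],
        }
    )
    return ConnectionTests(
        table=table,
        n_sig_05=int(np.sum(p < 0.05)),
        n_sig_01=int(np.sum(p < 0.01)),
        n_sig_fdr_05=int(np.sum(p_fdr < 0.05)),
        n_sig_fdr_01=int(np.sum(p_fdr < 0.01)),
    )


def power_two_sample(
    mean1: float,
    mean2: float,
    sd: float,
    n_per_group: int,
    alpha: float = 0.05,
    method: str = "normal",
) -> float:
    """Power of a two-sided two-sample comparison of means.

    ``method="normal"`` uses the normal approximation
    Φ(|δ|/(sd·√(2/n)) − z_{1−α/2}) + Φ(−|δ|/(sd·√(2/n)) − z_{1−α/2});
    ``method="nct"`` uses the noncentral-t calculation. The two can differ
    by a few percentage points at small n.
    """
    if sd <= 0:
        raise StatsError("sd must be positive")
    if n_per_group < 2:
        raise StatsError("n_per_group must be >= 2")
    if not 0 < alpha < 1:
        raise StatsError("alpha must lie in (0, 1)")
    delta = abs(mean1 - mean2)
    if method == "normal":
        se = sd * np.sqrt(2.0 / n_per_group)
        z_crit = sps.norm.ppf(1 - alpha / 2)
        shift = delta / se
        return float(sps.norm.cdf(shift - z_crit) + sps.norm.cdf(-shift - z_crit))
    if method == "nct":
        return float(
            TTestIndPower().power(
                effect_size=delta / sd, nobs1=n_per_group, ratio=1.0, alpha=alpha
            )
        )
    raise StatsError(f"unknown method {method!r}; use 'normal' or 'nct'")


@dataclass
class FeatureTable:
    """Subjects × 20 feature matrix (4 metrics × 5 thresholds) with labels."""

    features: pd.DataFrame  # index: subject ids; 20 columns, metric-major
    labels: pd.Series  # subject -> group

    @property
    def n_subjects(self) -> int:
        return len(self.features)


def feature_columns() -> list[str]:
    return [f"{m}@{s:.2f}" for m in FEATURE_METRICS for s in FEATURE_THRESHOLDS]


def extract_features(sweep: pd.DataFrame) -> FeatureTable:
    """Build the classification feature table from long-format sweep output.

    ``sweep`` needs columns (subject, group, sparsity, metric, value); every
    subject must have all four metrics at all five thresholds.
    """
    required = {"subject", "group", "sparsity", "metric", "value"}
    if not required.issubset(sweep.columns):
        raise StatsError(f"sweep table needs columns {sorted(required)}")
    sub = sweep[
        sweep["metric"].isin(FEATURE_METRICS)
        & np.isclose(sweep["sparsity"].to_numpy()[:, None], FEATURE_THRESHOLDS).any(axis=1)
    ].copy()
    sub["column"] = [
        f"{m}@{s:.2f}" for m, s in zip(sub["metric"], sub["sparsity"].round(2))
    ]
    wide = sub.pivot_table(index="subject", columns="column", values="value", aggfunc="first")
    cols = feature_columns()
    missing = [
        f"{subj}:{col}"
        for subj in wide.index
        for col in cols
        if col not in wide.columns or pd.isna(wide.loc[subj, col])
    ]
    if missing:
        raise StatsError(f"missing feature cells: {missing[:10]}" + ("..." if len(missing) > 10 else ""))
    wide = wide[cols]
    labels = sub.drop_duplicates("subject").set_index("subject")["group"].reindex(wide.index)
    return FeatureTable(features=wide, labels=labels)


def metric_group_table(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per metric × threshold group comparison over the feature grid.

    Mirrors the feature-table layout: 20 rows with t, df, p and per-group
    mean ± SD (patient group first).
    """
    table = extract_features(sweep)
    rows = []
    is_patient = (table.labels == "patient").to_numpy()
    if is_patient.all() or not is_patient.any():
        raise StatsError("need both groups for a group table")
    for metric in FEATURE_METRICS:
        for s in FEATURE_THRESHOLDS:
            col = f"{metric}@{s:.2f}"
            vals = table.features[col].to_numpy()
            res = two_sample_t(vals[is_patient], vals[~is_patient], unit=col)
            rows.append(
                {
                    "metric": metric,
                    "sparsity": s,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "mean_patient": res.mean_a,
                    "sd_patient": res.sd_a,
                    "mean_control": res.mean_b,
                    "sd_control": res.sd_b,
                }
            )
    return pd.DataFrame(rows)
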