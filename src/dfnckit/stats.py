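"""Group-level inference on temporal state metrics and connectivity.

The statistical layer of the analysis: independent two-sample t-tests
(pooled-variance by default, df = n1 + n2 - 2; Welch reported when
Levene's test rejects homogeneity), Pearson correlations between state
metrics and clinical covariates, Benjamini-Hochberg FDR within
pre-registered families, and per-state network-block connectivity
contrasts. The pooled t is also computable directly from printed
summary statistics (n, mean, sd per group), which is how the published
State-1 and State-4 dwell-time contrasts are recomputed exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import NetworkPartition, WindowedFNCSeries


@dataclass
class TestResult:
    statistic: float
    df: float
    pvalue: float
    n1: int | None = None
    n2: int | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def two_sample_t(
    group1,
    group2,
    variant: str = "pooled",
) -> TestResult:
    """Independent two-sample t-test from raw vectors or summaries.

    ``group1``/``group2`` are either 1-D arrays of raw observations or
    ``(n, mean, sd)`` summary triples. variant 'pooled' uses the
    equal-variance statistic with df = n1 + n2 - 2; 'welch' uses the
    Satterthwaite approximation.
    """
    if variant not in {"pooled", "welch"}:
        raise ValueError("variant must be 'pooled' or 'welch'")
    equal_var = variant == "pooled"

    def as_summary(g):
        if isinstance(g, tuple) and len(g) == 3:
            return int(g[0]), float(g[1]), float(g[2])
        arr = np.asarray(g, dtype=float)
        return arr.size, float(arr.mean()), float(arr.std(ddof=1))

    n1, m1, s1 = as_summary(group1)
    n2, m2, s2 = as_summary(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            raise ValueError("zero variance in both groups with equal means")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue), n1, n2)


def levene_test(x, y, center: str = "mean") -> TestResult:
    """Levene's homogeneity-of-variance test (mean-centered by default;
    'median' gives the Brown-Forsythe variant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return TestResult(0.0, x.size + y.size - 2, 1.0, x.size, y.size)
    stat, p = sps.levene(x, y, center=center)
    return TestResult(float(stat), x.size + y.size - 2, float(p), x.size, y.size)


def pearson_corr(x, y) -> TestResult:
    """Pearson r with two-sided p on n - 2 df; non-finite pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), x.size - 2, float(p), n1=x.size)


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags at q)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def state_block_connectivity(
    series: WindowedFNCSeries,
    labels: np.ndarray,
    state: int,
    partition: NetworkPartition | None = None,
) -> dict[str, float] | None:
    """Mean FNC per network block over one subject's windows in a state.

    Averages the subject's windowed FNC vectors over windows assigned to
    ``state``, then averages within the 6 network blocks. Returns None
    if the subject never visits the state (excluded downstream, which
    shrinks the group df accordingly).
    """
    partition = partition or series.partition
    labels = np.asarray(labels, dtype=int)
    if labels.size != series.n_windows:
        raise ValueError("label sequence length must match window count")
    mask = labels == state
    if not mask.any():
        return None
    mean_vec = series.data[mask].mean(axis=0)
    block_idx = partition.pair_block_index()
    names = partition.block_labels()
    return {name: float(mean_vec[block_idx == b].mean()) for b, name in enumerate(names)}


def block_connectivity_table(
    series_list: list[WindowedFNCSeries],
    labels: dict[str, np.ndarray],
    groups: dict[str, str],
    state: int,
    partition: NetworkPartition | None = None,
) -> pd.DataFrame:
    """Per-subject block means for one state; absent subjects dropped."""
    rows = []
    for s in series_list:
        blocks = state_block_connectivity(s, labels[s.subject_id], state, partition)
        if blocks is None:
            continue
        rows.append({"subject_id": s.subject_id, "group": groups[s.subject_id], **blocks})
    return pd.DataFrame(rows)


def _group_vectors(df: pd.DataFrame, col: str, group_order: tuple[str, str]):
    a = df.loc[df["group"] == group_order[0], col].to_numpy(dtype=float)
    b = df.loc[df["group"] == group_order[1], col].to_numpy(dtype=float)
    return a[np.isfinite(a)], b[np.isfinite(b)]


def run_group_analysis(
    profiles: pd.DataFrame,
    clinical: pd.DataFrame,
    n_states: int,
    group_order: tuple[str, str] = ("CD", "HC"),
    fdr_q: float = 0.05,
    correlation_columns: dict[str, str] | None = None,
    correlation_states: tuple[int, ...] = (1, 4),
    levene_alpha: float = 0.05,
) -> pd.DataFrame:
    """The full published battery on a temporal-metrics + clinical table.

    Families for FDR correction (each corrected separately):
      * dwell-time contrasts for each state plus the transitions contrast;
      * fraction-of-time contrasts per state;
      * for each correlated state metric, its row of clinical correlations.

    ``correlation_columns`` maps clinical column -> scope ('all' or
    'patients'); default scope is patients-only for endocrine-style
    columns absent in controls, 'all' otherwise (here: every numeric
    clinical column at 'all' unless specified). Patients are
    ``group_order[0]``.

    Returns a tidy frame: analysis, variable, statistic, df, p, p_fdr,
    reject, n1, n2, plus Welch columns where Levene rejects.
    """
    merged = profiles.merge(clinical.drop(columns=["group"], errors="ignore"),
                            on="subject_id", how="inner", validate="1:1")
    orphans = set(profiles["subject_id"]) ^ set(clinical["subject_id"])
    if len(merged) < len(profiles) or len(merged) < len(clinical):
        raise ValueError(f"subject_id mismatch between tables: {sorted(orphans)}")

    rows = []

    def finish_family(fam_rows: list[dict]):
        # FDR over the testable (finite-p) members of the family only
        finite = [i for i, r in enumerate(fam_rows) if np.isfinite(r["p"])]
        if finite:
            p_adj, rej = fdr_bh([fam_rows[i]["p"] for i in finite], fdr_q)
            for j, i in enumerate(finite):
                fam_rows[i]["p_fdr"] = float(p_adj[j])
                fam_rows[i]["reject"] = bool(rej[j])
        for r in fam_rows:
            r.setdefault("p_fdr", np.nan)
            r.setdefault("reject", False)
        rows.extend(fam_rows)

    def t_family(cols: list[str], family: str):
        fam_rows = []
        for col in cols:
            a, b = _group_vectors(merged, col, group_order)
            row = {"analysis": family, "variable": col,
                   "n1": a.size, "n2": b.size}
            try:
                res = two_sample_t(a, b, "pooled")
                lev = levene_test(a, b)
                row.update(statistic=res.statistic, df=res.df, p=res.pvalue,
                           levene_p=lev.pvalue)
                if lev.pvalue < levene_alpha:
                    w = two_sample_t(a, b, "welch")
                    row.update(welch_statistic=w.statistic, welch_df=w.df,
                               welch_p=w.pvalue)
            except ValueError:  # degenerate column (e.g. state never visited)
                row.update(statistic=np.nan, df=np.nan, p=np.nan,
                           levene_p=np.nan)
            fam_rows.append(row)
        finish_family(fam_rows)

    dwell_cols = [f"dwell_s{s}" for s in range(1, n_states + 1)]
    frac_cols = [f"frac_s{s}" for s in range(1, n_states + 1)]
    t_family(dwell_cols + ["n_transitions"], "dwell_and_transitions")
    t_family(frac_cols, "fraction_time")

    clin_cols = [
        c for c in clinical.columns
        if c not in ("subject_id", "group")
        and pd.api.types.is_numeric_dtype(clinical[c])
    ]
    scopes = correlation_columns or {}
    for s in correlation_states:
        metric = f"dwell_s{s}"
        fam_rows = []
        for col in clin_cols:
            sub = merged if scopes.get(col, "all") == "all" else merged[
                merged["group"] == group_order[0]
            ]
            row = {"analysis": f"correlation_{metric}", "variable": col,
                   "n2": None, "levene_p": np.nan}
            try:
                res = pearson_corr(sub[metric], sub[col])
                row.update(statistic=res.statistic, df=res.df, p=res.pvalue,
                           n1=res.n1)
            except ValueError:
                row.update(statistic=np.nan, df=np.nan, p=np.nan,
                           n1=len(sub))
            fam_rows.append(row)
        finish_family(fam_rows)

    return pd.DataFrame(rows)


def block_contrast_analysis(
    series_list: list[WindowedFNCSeries],
    labels: dict[str, np.ndarray],
    groups: dict[str, str],
    states: tuple[int, ...],
    partition: NetworkPartition | None = None,
    group_order: tuple[str, str] = ("CD", "HC"),
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-state network-block group contrasts (one FDR family per state)."""
    partition = partition or series_list[0].partition
    out = []
    for state in states:
        table = block_connectivity_table(series_list, labels, groups, state, partition)
        fam_rows = []
        for block in partition.block_labels():
            a, b = _group_vectors(table, block, group_order) if len(table) else (
                np.array([]), np.array([])
            )
            row = {"analysis": f"block_state{state}", "variable": block,
                   "n1": a.size, "n2": b.size}
            try:
                res = two_sample_t(a, b, "pooled")
                row.update(statistic=res.statistic, df=res.df, p=res.pvalue)
            except ValueError:
                row.update(statistic=np.nan, df=np.nan, p=np.nan)
            fam_rows.append(row)
        finite = [i for i, r in enumerate(fam_rows) if np.isfinite(r["p"])]
        if finite:
            p_adj, rej = fdr_bh([fam_rows[i]["p"] for i in finite], fdr_q)
            for j, i in enumerate(finite):
                fam_rows[i]["p_fdr"] = float(p_adj[j])
                fam_rows[i]["reject"] = bool(rej[j])
        for r in fam_rows:
            r.setdefault("p_fdr", np.nan)
            r.setdefault("reject", False)
        out.extend(fam_rows)
    return pd.DataFrame(out)
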