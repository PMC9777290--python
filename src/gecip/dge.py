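"""Two-group differential expression: per-gene t-test, FDR, fold change.

The operative DEG rule is q < alpha after Benjamini-Hochberg adjustment of
two-tailed two-sample t-test p-values; log2 fold change (target minus
control on the log2 scale) is reported alongside and can optionally gate
the call via ``fc_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import CONTROL, TARGET, ExpressionDataset

_TINY_P = float(np.nextafter(0, 1))


@dataclass
class DGEResult:
    """Per-gene test results with the thresholds that produced the calls."""

    table: pd.DataFrame        # index gene; t, p, q, log2_fold_change, is_deg, flagged
    alpha: float
    fc_min: float
    variance: str
    fdr_method: str

    @property
    def degs(self) -> list[str]:
        """DEG symbols ordered by ascending q, ties by symbol."""
        hits = self.table[self.table["is_deg"]]
        return list(hits.assign(_gene=hits.index).sort_values(["q", "_gene"]).index)


def t_test_per_gene(
    data: ExpressionDataset, variance: str = "pooled"
) -> pd.DataFrame:
    """Two-tailed two-sample t-test per gene; t > 0 means higher in target.

    ``variance`` selects the pooled-variance test (default) or Welch's.
    Genes where both groups have zero variance are degenerate: equal means
    give (t=0, p=1), unequal means the smallest representable positive p;
    both are flagged.
    """
    if variance not in ("pooled", "welch"):
        raise ValueError(f"unknown variance model {variance!r}")
    target = data.group_matrix(TARGET)
    control = data.group_matrix(CONTROL)
    n_t, n_c = target.shape[1], control.shape[1]
    res = stats.ttest_ind(target, control, axis=1, equal_var=(variance == "pooled"))
    t = np.array(res.statistic, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    df = np.array(res.df, dtype=float)

    mean_diff = target.mean(axis=1) - control.mean(axis=1)
    var_t = target.var(axis=1, ddof=1)
    var_c = control.var(axis=1, ddof=1)
    degenerate = (var_t == 0) & (var_c == 0)
    flagged = degenerate.copy()
    eq = degenerate & (mean_diff == 0)
    ne = degenerate & (mean_diff != 0)
    t[eq], p[eq] = 0.0, 1.0
    t[ne] = np.sign(mean_diff[ne]) * np.inf
    p[ne] = _TINY_P
    df[degenerate] = n_t + n_c - 2
    p = np.clip(p, _TINY_P, 1.0)
    return pd.DataFrame(
        {"t": t, "p": p, "df": df, "flagged": flagged}, index=data.values.index
    )


def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Adjust p-values for multiple testing.

    ``bh`` is the Benjamini-Hochberg step-up q-value; ``storey`` is the
    pFDR-style q-value that first estimates the null proportion pi0 from
    the p-value histogram (lambda = 0.5) and scales the BH value by it.
    All p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
        pi0 = max(pi0, 1.0 / p.size)  # guard against a zero estimate
        return np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def fold_change(data: ExpressionDataset) -> pd.Series:
    """log2 fold change per gene: mean(target) - mean(control) on log2 values."""
    diff = data.group_matrix(TARGET).mean(axis=1) - data.group_matrix(CONTROL).mean(axis=1)
    return pd.Series(diff, index=data.values.index, name="log2_fold_change")


def run_dge(
    data: ExpressionDataset,
    alpha: float = 0.05,
    fdr_method: str = "bh",
    variance: str = "pooled",
    fc_min: float = 0.0,
) -> DGEResult:
    """Full differential-expression pass: test, adjust, call DEGs."""
    tested = t_test_per_gene(data, variance=variance)
    q = fdr_adjust(tested["p"].to_numpy(), method=fdr_method)
    lfc = fold_change(data)
    table = tested.assign(q=q, log2_fold_change=lfc)
    table["is_deg"] = (table["q"] < alpha) & (table["log2_fold_change"].abs() >= fc_min)
    return DGEResult(
        table=table,
        alpha=alpha,
        fc_min=fc_min,
        variance=variance,
        fdr_method=fdr_method,
    )


def call_degs(result: DGEResult, alpha: float | None = None, fc_min: float | None = None) -> list[str]:
    """Re-threshold an existing result; returns DEGs by ascending q then symbol."""
    alpha = result.alpha if alpha is None else alpha
    fc_min = result.fc_min if fc_min is None else fc_min
    t = result.table
    hits = t[(t["q"] < alpha) & (t["log2_fold_change"].abs() >= fc_min)]
    return list(hits.assign(_gene=hits.index).sort_values(["q", "_gene"]).index)


def write_dge_table(result: DGEResult, path) -> None:
    cols = ["t", "p", "q", "log2_fold_change", "is_deg", "flagged"]
    result.table[cols].to_csv(path, sep="\t", index_label="gene")
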