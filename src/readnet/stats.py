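"""Two-sample group statistics and multiple-comparison handling.

The pooled-variance Student's t (df = n_a + n_b - 2) is used everywhere:
with 16 subjects per group that is the df = 30 statistic the design calls
for.  The sign convention is mean_a - mean_b, with the group ordering of
every table recorded in its metadata.  Bonferroni correction uses families
defined per metric and session (the sparsity ladder) for global metrics
and per measure (the 90 nodes) for nodal tests; both uncorrected and
corrected flags are always emitted.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "two_sample_t",
    "t_from_summary",
    "bonferroni_threshold",
    "compare_global_metrics",
    "compare_nodal",
    "compare_behavior",
]


def two_sample_t(
    values_a: Sequence[float] | np.ndarray, values_b: Sequence[float] | np.ndarray
):
    """Pooled-variance two-sample t; sign is mean_a - mean_b.

    Accepts 1-D samples or [n_subjects, m] arrays (m simultaneous tests
    sharing subjects).  Returns (t, df, p); zero pooled variance yields
    t = 0, p = 1 when the means agree and a flagged infinite t otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim not in (1, 2) or b.ndim != a.ndim:
        raise ValueError("inputs must both be 1-D or both 2-D")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    return t_from_summary(
        a.mean(axis=0),
        a.std(axis=0, ddof=1),
        n_a,
        b.mean(axis=0),
        b.std(axis=0, ddof=1),
        n_b,
    )


def t_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    """Pooled-variance t from printed summary statistics.

    df = n_a + n_b - 2; two-sided p.  Works elementwise on arrays.
    """
    mean_a, sd_a = np.asarray(mean_a, float), np.asarray(sd_a, float)
    mean_b, sd_b = np.asarray(mean_b, float), np.asarray(sd_b, float)
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if np.any(sd_a < 0) or np.any(sd_b < 0):
        raise ValueError("standard deviations must be non-negative")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = np.sqrt(pooled_var * (1 / n_a + 1 / n_b))
    diff = mean_a - mean_b
    zero = se == 0
    if np.any(zero & (diff != 0)):
        warnings.warn("zero pooled variance with unequal means: t set to +/-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, np.sign(diff) * np.inf, diff / np.where(se, se, 1))
    t = np.where(zero & (diff == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2 * sps.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    if t.ndim == 0:
        return float(t), df, float(p)
    return t, df, p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def _group_frames(
    records: pd.DataFrame, group_order: tuple[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = set(group_order) - set(records["group"].unique())
    if missing:
        raise ValueError(f"records lack group(s) {sorted(missing)}")
    a = records[records["group"] == group_order[0]]
    b = records[records["group"] == group_order[1]]
    return a, b


def compare_global_metrics(
    records: pd.DataFrame,
    metrics: tuple[str, ...] | None = None,
    group_order: tuple[str, str] = ("good", "poor"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t per (metric, session, sparsity) over subjects.

    `records` is the long metric table: one row per subject-session-
    sparsity with columns subject_id, group, session, sparsity and one
    column per metric.  The Bonferroni family is the number of sparsity
    levels actually tested for that metric and session; levels where any
    subject's value is missing (e.g. Lp on a fully disconnected graph) are
    dropped with a warning, shrinking the family.
    """
    id_cols = {"subject_id", "group", "session", "sparsity", "reachable_fraction"}
    if metrics is None:
        metrics = tuple(c for c in records.columns if c not in id_cols)
    rows = []
    for session in sorted(records["session"].unique()):
        sess = records[records["session"] == session]
        sparsities = sorted(sess["sparsity"].unique())
        for metric in metrics:
            tested = []
            for s in sparsities:
                cell = sess[sess["sparsity"] == s]
                a, b = _group_frames(cell, group_order)
                va, vb = a[metric].to_numpy(), b[metric].to_numpy()
                if np.isnan(va).any() or np.isnan(vb).any():
                    warnings.warn(
                        f"{metric} missing for some subjects at session={session}, "
                        f"sparsity={s}; row dropped and family reduced"
                    )
                    continue
                t, df, p = two_sample_t(va, vb)
                tested.append(
                    {
                        "target": metric,
                        "session": session,
                        "sparsity": s,
                        "mean_a": va.mean(),
                        "sd_a": va.std(ddof=1),
                        "mean_b": vb.mean(),
                        "sd_b": vb.std(ddof=1),
                        "t": t,
                        "df": df,
                        "p": p,
                    }
                )
            family = len(tested)
            for row in tested:
                row["family_size"] = family
                row["significant_uncorrected"] = row["p"] < alpha
                row["significant_bonferroni"] = row["p"] < bonferroni_threshold(
                    alpha, family
                )
                rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["group_order"] = group_order
    table.attrs["alpha"] = alpha
    return table


def compare_nodal(
    records: pd.DataFrame,
    measures: tuple[str, ...] = ("degree", "betweenness"),
    group_order: tuple[str, str] = ("good", "poor"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-node two-sample t at a single sparsity.

    `records` is long nodal data: one row per subject-session-node with
    columns subject_id, group, session, sparsity, node, degree,
    betweenness.  The Bonferroni family is the node count, separately per
    measure (and session).
    """
    if records["sparsity"].nunique() != 1:
        raise ValueError("nodal comparisons require a single sparsity")
    rows = []
    for session in sorted(records["session"].unique()):
        sess = records[records["session"] == session]
        nodes = list(dict.fromkeys(sess["node"]))  # preserve atlas order
        m = len(nodes)
        a_all, b_all = _group_frames(sess, group_order)
        a_wide = {
            meas: a_all.pivot(index="subject_id", columns="node", values=meas)[nodes]
            for meas in measures
        }
        b_wide = {
            meas: b_all.pivot(index="subject_id", columns="node", values=meas)[nodes]
            for meas in measures
        }
        for meas in measures:
            va, vb = a_wide[meas].to_numpy(float), b_wide[meas].to_numpy(float)
            t, df, p = two_sample_t(va, vb)
            for k, node in enumerate(nodes):
                rows.append(
                    {
                        "target": node,
                        "measure": meas,
                        "session": session,
                        "sparsity": records["sparsity"].iloc[0],
                        "mean_a": va[:, k].mean(),
                        "sd_a": va[:, k].std(ddof=1),
                        "mean_b": vb[:, k].mean(),
                        "sd_b": vb[:, k].std(ddof=1),
                        "t": t[k] if np.ndim(t) else t,
                        "df": df,
                        "p": p[k] if np.ndim(p) else p,
                        "family_size": m,
                        "significant_uncorrected": (p[k] if np.ndim(p) else p) < alpha,
                        "significant_bonferroni": (p[k] if np.ndim(p) else p)
                        < bonferroni_threshold(alpha, m),
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["group_order"] = group_order
    table.attrs["alpha"] = alpha
    return table


def compare_behavior(
    behavior: pd.DataFrame,
    group_order: tuple[str, str] = ("good", "poor"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t on reading and Raven scores (columns *_score)."""
    a, b = _group_frames(behavior, group_order)
    rows = []
    for col in [c for c in behavior.columns if c.endswith("_score")]:
        t, df, p = two_sample_t(a[col], b[col])
        rows.append(
            {
                "target": col,
                "mean_a": a[col].mean(),
                "sd_a": a[col].std(ddof=1),
                "mean_b": b[col].mean(),
                "sd_b": b[col].std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
                "significant_uncorrected": p < alpha,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["group_order"] = group_order
    table.attrs["alpha"] = alpha
    return table
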