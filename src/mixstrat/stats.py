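"""Nonparametric group statistics and the clinical-vs-biological cross-tab.

Group comparisons follow the study's analysis plan: per-group mean±SD
summaries, a Kruskal–Wallis omnibus test per variable, and two-sided
pairwise Mann–Whitney U-tests with family-wise correction over the pairs
within each variable (Holm step-down by default, Bonferroni available).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .labels import TABLE_LABEL_ORDER, DiagnosisLabel

__all__ = [
    "GroupSummary",
    "PairwiseResult",
    "CrossTab",
    "summarize_groups",
    "kruskal_wallis",
    "pairwise_mannwhitney",
    "crosstab",
    "summary_frame",
    "pairwise_frame",
]

logger = logging.getLogger(__name__)

CORRECTIONS = {"holm": "holm", "bonferroni": "bonferroni"}


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics and the omnibus test for one variable."""

    variable: str
    groups: tuple[str, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    h_statistic: float
    p_value: float


@dataclass(frozen=True)
class PairwiseResult:
    """One two-sided Mann–Whitney comparison within a correction family."""

    variable: str
    group_a: str
    group_b: str
    u_statistic: float
    p_raw: float
    p_corrected: float
    correction: str


@dataclass(frozen=True)
class CrossTab:
    """Clinical x biological contingency table with margins."""

    labels: tuple[str, ...]
    counts: pd.DataFrame  # index=clinical, columns=biological
    row_margins: pd.Series
    col_margins: pd.Series
    total: int

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_margins
        bottom = self.col_margins.copy()
        bottom["Total"] = self.total
        out.loc["Total"] = bottom
        return out


def kruskal_wallis(samples: list[np.ndarray | list[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value.

    Requires at least two groups with one value each and a total of three
    observations. When every observation is identical the statistic is 0
    and p is reported as 1.0 (documented convention; the chi-square
    approximation is undefined there).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays) or sum(a.size for a in arrays) < 3:
        raise InputError("kruskal_wallis needs >= 2 non-empty groups and total n >= 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided U-test; exact when both n <= 20 and tie-free, else normal approx.

    U is oriented to the first sample (number of (a > b) pairs, ties
    counted half).
    """
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if a.size <= 20 and b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pairwise_mannwhitney(
    samples: list[np.ndarray | list[float]],
    labels: list[str] | None = None,
    correction: str = "holm",
) -> list[PairwiseResult]:
    """All unordered pairwise Mann–Whitney tests with family-wise correction.

    The family is the set of pairs passed in one call (pairs within one
    variable). Groups with no values are skipped with a log entry.
    """
    if correction not in CORRECTIONS:
        raise InputError(f"correction must be one of {sorted(CORRECTIONS)}, got {correction!r}")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise InputError("labels and samples must have equal length")
    usable = []
    for lab, arr in zip(labels, arrays):
        if arr.size < 1:
            logger.warning("group %s has no values; skipped from pairwise tests", lab)
            continue
        usable.append((lab, arr))
    if len(usable) < 2:
        raise InputError("need >= 2 non-empty groups for pairwise tests")

    pairs = list(itertools.combinations(usable, 2))
    stats_p = [_mannwhitney(a, b) for (_, a), (_, b) in pairs]
    raw = [p for _, p in stats_p]
    corrected = multipletests(raw, method=CORRECTIONS[correction])[1]
    results = []
    for ((la, _), (lb, _)), (u, p_raw), p_corr in zip(pairs, stats_p, corrected):
        results.append(
            PairwiseResult(
                variable="",
                group_a=la,
                group_b=lb,
                u_statistic=u,
                p_raw=p_raw,
                p_corrected=float(max(p_corr, p_raw)),
                correction=correction,
            )
        )
    return results


def summarize_groups(
    table: pd.DataFrame,
    variables: list[str],
    group_column: str = "biological_label",
    group_order: list[str] | None = None,
) -> list[GroupSummary]:
    """Per-variable, per-group n/mean/SD (n-1) plus the Kruskal–Wallis omnibus.

    Missing values are excluded variable-wise; groups are compared in the
    order of first appearance unless ``group_order`` is given.
    """
    if group_column not in table.columns:
        raise InputError(f"group column {group_column!r} not in table")
    for v in variables:
        if v not in table.columns:
            raise InputError(f"unknown variable {v!r}")
    if group_order is None:
        group_order = list(dict.fromkeys(table[group_column]))
    summaries = []
    for v in variables:
        ns, means, sds, omnibus = [], [], [], []
        for g in group_order:
            vals = pd.to_numeric(table.loc[table[group_column] == g, v], errors="coerce").dropna()
            ns.append(int(vals.size))
            means.append(float(vals.mean()) if vals.size else float("nan"))
            sds.append(float(vals.std(ddof=1)) if vals.size >= 2 else float("nan"))
            if vals.size >= 1:
                omnibus.append(vals.to_numpy())
        if len(omnibus) >= 2 and sum(a.size for a in omnibus) >= 3:
            h, p = kruskal_wallis(omnibus)
        else:
            h, p = float("nan"), float("nan")
        summaries.append(
            GroupSummary(
                variable=v,
                groups=tuple(str(g) for g in group_order),
                n=tuple(ns),
                mean=tuple(means),
                sd=tuple(sds),
                h_statistic=h,
                p_value=p,
            )
        )
    return summaries


def pairwise_by_variable(
    table: pd.DataFrame,
    variables: list[str],
    group_column: str = "biological_label",
    correction: str = "holm",
    group_order: list[str] | None = None,
) -> list[PairwiseResult]:
    """Pairwise Mann–Whitney tests for each variable, corrected per variable."""
    if group_order is None:
        group_order = list(dict.fromkeys(table[group_column]))
    results: list[PairwiseResult] = []
    for v in variables:
        samples, labels = [], []
        for g in group_order:
            vals = pd.to_numeric(table.loc[table[group_column] == g, v], errors="coerce").dropna()
            samples.append(vals.to_numpy())
            labels.append(str(g))
        for r in pairwise_mannwhitney(samples, labels, correction=correction):
            results.append(
                PairwiseResult(
                    variable=v,
                    group_a=r.group_a,
                    group_b=r.group_b,
                    u_statistic=r.u_statistic,
                    p_raw=r.p_raw,
                    p_corrected=r.p_corrected,
                    correction=r.correction,
                )
            )
    return results


def crosstab(
    clinical_labels,
    biological_labels,
    label_order: tuple[DiagnosisLabel, ...] | tuple[str, ...] = TABLE_LABEL_ORDER,
) -> CrossTab:
    """Clinical x biological contingency table with margins and grand total."""
    order = [l.value if isinstance(l, DiagnosisLabel) else str(l) for l in label_order]
    clin = [l.value if isinstance(l, DiagnosisLabel) else str(l) for l in clinical_labels]
    bio = [l.value if isinstance(l, DiagnosisLabel) else str(l) for l in biological_labels]
    if len(clin) != len(bio):
        raise InputError("clinical and biological label sequences must have equal length")
    outside = sorted(set(clin + bio) - set(order))
    if outside:
        raise InputError(f"labels outside the configured order: {outside}")
    counts = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for c, b in zip(clin, bio):
        counts.loc[c, b] += 1
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    return CrossTab(
        labels=tuple(order),
        counts=counts,
        row_margins=row_margins,
        col_margins=col_margins,
        total=int(counts.to_numpy().sum()),
    )


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Wide report table: one row per variable, 'mean ± sd (n)' per group."""
    rows = {}
    for s in summaries:
        row = {}
        for g, n, m, sd in zip(s.groups, s.n, s.mean, s.sd):
            row[g] = f"{m:.2f} ± {sd:.2f} (n={n})" if n else "—"
        row["H"] = round(s.h_statistic, 3)
        row["p"] = s.p_value
        rows[s.variable] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def pairwise_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "U": r.u_statistic,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "correction": r.correction,
            }
            for r in results
        ]
    )
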