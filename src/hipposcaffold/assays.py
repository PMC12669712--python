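"""Relative-expression and array-based differential analysis.

Implements the comparative-CT (ddCT) method for qPCR tables, percent-change
arithmetic, the RPPA two-fold / p < 0.05 differential filter with
|log2 fold-change| ranking, and a thin group-comparison layer over the
standard two-sample and k-group tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VALID_TESTS = ("t", "rank-sum-2", "rank-multi", "anova")


@dataclass
class RelExpr:
    """Relative expression of one gene across conditions by the ddCT method.

    ``summary`` has one row per condition: fold (2^(-mean ddCT), i.e. the
    geometric mean of per-sample folds, so the calibrator's fold is exactly
    1), se (standard error of per-sample folds over biological samples) and
    n (biological samples).  ``per_sample`` keeps the sample-level ddCT and
    fold values.
    """

    gene: str
    reference_gene: str
    calibrator: str
    summary: pd.DataFrame
    per_sample: pd.DataFrame

    def fold(self, condition: str) -> float:
        return float(self.summary.loc[condition, "fold"])


@dataclass
class GroupEffect:
    """Result of a standard group comparison: statistic, p-value, and (for
    two groups) the percent change of the means."""

    test: str
    statistic: float
    p_value: float
    percent_change: float | None
    group_means: dict[str, float]
    group_ns: dict[str, int]


@dataclass
class RPPATable:
    """Proteins x samples matrix of normalized log2 expression with group
    labels per sample column."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not set(self.groups.index) == set(self.values.columns):
            raise ValueError("group labels must cover exactly the sample columns")
        counts = self.groups.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 samples: {small}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")


def ddct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator: str,
) -> RelExpr:
    """Comparative-CT relative expression of ``target_gene``.

    Technical replicates are averaged per (sample, gene); dCT = CT(target) -
    CT(reference) per sample; ddCT subtracts the mean calibrator dCT; fold =
    2^(-ddCT).  Biological samples are the qPCR runs.  A sample lacking the
    reference gene is an error naming the sample.
    """
    required = {"sample_id", "condition", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    for gene in (target_gene, reference_gene):
        if gene not in set(table["gene"]):
            raise ValueError(f"gene {gene!r} not present in CT table")
    if calibrator not in set(table["condition"]):
        raise ValueError(f"calibrator condition {calibrator!r} not in CT table")

    mean_ct = (
        table.groupby(["sample_id", "condition", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    wide = mean_ct.pivot_table(
        index=["sample_id", "condition"], columns="gene", values="ct"
    )
    if reference_gene not in wide.columns or wide[reference_gene].isna().any():
        bad = (
            wide.index.get_level_values("sample_id")[
                wide.get(reference_gene, pd.Series(np.nan, index=wide.index)).isna()
            ].tolist()
            if reference_gene in wide.columns
            else wide.index.get_level_values("sample_id").tolist()
        )
        raise ValueError(f"reference gene missing for sample(s): {bad}")
    sub = wide[[target_gene, reference_gene]].dropna(subset=[target_gene]).copy()
    sub["dct"] = sub[target_gene] - sub[reference_gene]
    cal = sub.xs(calibrator, level="condition")["dct"]
    if cal.empty:
        raise ValueError(f"no calibrator samples for condition {calibrator!r}")
    sub["ddct"] = sub["dct"] - cal.mean()
    sub["fold"] = 2.0 ** (-sub["ddct"])

    per_sample = sub.reset_index()[
        ["sample_id", "condition", "dct", "ddct", "fold"]
    ]
    grouped = per_sample.groupby("condition", sort=False)
    summary = pd.DataFrame({
        "fold": 2.0 ** (-grouped["ddct"].mean()),
        "se": grouped["fold"].sem(),
        "n": grouped["fold"].size(),
    })
    return RelExpr(
        gene=target_gene,
        reference_gene=reference_gene,
        calibrator=calibrator,
        summary=summary,
        per_sample=per_sample,
    )


def percent_change(fold_alt: float, fold_ref: float) -> float:
    """Percent change of ``fold_alt`` relative to ``fold_ref``:
    100 * (alt - ref) / ref."""
    if fold_ref <= 0:
        raise ValueError("reference fold must be positive")
    return 100.0 * (fold_alt - fold_ref) / fold_ref


def rppa_filter_rank(
    table: RPPATable,
    control_group: str = "control",
    fc_min: float = 2.0,
    alpha: float = 0.05,
    top_n: int = 100,
    bh_adjust: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Differential filter and |log2FC| ranking of an RPPA table.

    Per protein: mean log2 difference of each non-control group pooled vs
    control and a two-sided two-sample t-test (unadjusted by default; set
    ``bh_adjust`` for Benjamini-Hochberg).  The differential set holds
    proteins with |log2FC| >= log2(fc_min) and p < alpha.  The ranked list
    is the top ``top_n`` by |log2FC| among passing proteins, padded in score
    order with non-passing proteins (``passed`` column False) when fewer
    pass.  Ties break by protein id.
    """
    if control_group not in set(table.groups):
        raise ValueError(f"control group {control_group!r} not present")
    ctrl_cols = table.groups.index[table.groups == control_group]
    trt_cols = table.groups.index[table.groups != control_group]
    if len(trt_cols) < 2:
        raise ValueError("need >= 2 non-control samples")
    ctrl = table.values[ctrl_cols].to_numpy()
    trt = table.values[trt_cols].to_numpy()

    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    tres = stats.ttest_ind(trt, ctrl, axis=1)
    pvals = np.asarray(tres.pvalue, dtype=float)
    if bh_adjust:
        pvals = stats.false_discovery_control(pvals, method="bh")

    frame = pd.DataFrame({
        "protein": table.values.index,
        "log2fc": log2fc,
        "fold_change": 2.0 ** log2fc,
        "p_value": pvals,
    })
    frame["score"] = frame["log2fc"].abs()
    frame["passed"] = (frame["score"] >= np.log2(fc_min)) & (frame["p_value"] < alpha)
    frame = frame.sort_values(
        ["passed", "score", "protein"], ascending=[False, False, True]
    ).reset_index(drop=True)
    ranked = frame.head(top_n).copy()
    ranked.attrs["padded"] = bool((~ranked["passed"]).any())
    differential = frame.loc[frame["passed"], "protein"].tolist()
    return differential, ranked


def compare_groups(
    values_by_group: dict[str, list[float]],
    test: str = "rank-sum-2",
) -> GroupEffect:
    """Standard two-sample or k-group comparison.

    ``test``: ``t`` (two-sided Student's t), ``rank-sum-2`` (Mann-Whitney U,
    exact for small untied samples), ``rank-multi`` (Kruskal-Wallis) or
    ``anova`` (one-way).  Percent change of means is reported for exactly
    two groups, in insertion order (second vs first).
    """
    if test not in VALID_TESTS:
        raise ValueError(f"unknown test {test!r}; valid tests: {list(VALID_TESTS)}")
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise ValueError("need at least 2 values per group")
    samples = list(arrays.values())
    if test in ("t", "rank-sum-2") and len(samples) != 2:
        raise ValueError(f"test {test!r} requires exactly 2 groups")
    if test == "t":
        res = stats.ttest_ind(samples[1], samples[0])
    elif test == "rank-sum-2":
        res = stats.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided", method="auto"
        )
    elif test == "rank-multi":
        res = stats.kruskal(*samples)
    else:
        res = stats.f_oneway(*samples)
    means = {g: float(a.mean()) for g, a in arrays.items()}
    pct = None
    if len(samples) == 2:
        m0, m1 = means[list(arrays)[0]], means[list(arrays)[1]]
        if m0 != 0:
            pct = 100.0 * (m1 - m0) / m0
    return GroupEffect(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        percent_change=pct,
        group_means=means,
        group_ns={g: int(len(a)) for g, a in arrays.items()},
    )
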