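"""Relative qPCR quantification (Livak 2^-dCt and 2^-ddCt).

Technical replicates are averaged to one Ct per sample x gene before any
delta is taken; dCt is target minus reference gene, and ddCt normalizes
against the mean dCt of a designated control group.  The two-sample
comparison mirrors the normality-gated protocol: Shapiro-Wilk on each
group at alpha = 0.05, then either Welch's t-test (both normal) or the
Mann-Whitney U-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtSchemaError",
    "InsufficientDataError",
    "ExpressionResult",
    "ComparisonResult",
    "validate_ct_table",
    "relative_expression",
    "compare_groups",
]

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


class CtSchemaError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class ExpressionResult:
    method: str
    reference_gene: str
    control_group: str | None
    per_sample: pd.DataFrame     # sample_id, group, gene, dct, rel_2dct [, ddct, fold]
    per_group: pd.DataFrame      # group, gene, mean dct [, mean ddct, fold of mean]


class ComparisonResult(NamedTuple):
    test_used: str               # "welch-t" or "mann-whitney"
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float


def validate_ct_table(ct: pd.DataFrame, reference_gene: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise CtSchemaError(f"Ct table missing columns {missing}")
    if ct.empty:
        raise CtSchemaError("Ct table is empty")
    if (ct["ct"] <= 0).any():
        raise CtSchemaError("Ct values must be > 0")
    samples = set(ct["sample_id"])
    with_ref = set(ct.loc[ct["gene"] == reference_gene, "sample_id"])
    orphans = samples - with_ref
    if orphans:
        raise CtSchemaError(
            f"samples without reference gene {reference_gene!r} rows: {sorted(orphans)}"
        )


def relative_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    method: str = "dct",
    control_group: str | None = None,
) -> ExpressionResult:
    """Per-sample relative expression for every non-reference gene.

    ``method="dct"`` reports ``2^-dCt``; ``method="ddct"`` additionally
    normalizes each sample's dCt by the control group's mean dCt for that
    gene, reporting ``2^-ddCt`` fold changes (control group averages to a
    fold change of exactly 1).
    """
    if method not in ("dct", "ddct"):
        raise ValueError(f"unknown method {method!r}")
    validate_ct_table(ct, reference_gene)
    if method == "ddct":
        if control_group is None:
            raise ValueError("ddct requires a control_group")
        if control_group not in set(ct["group"]):
            raise CtSchemaError(f"control group {control_group!r} not in table")

    mean_ct = (
        ct.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene][["sample_id", "ct"]].rename(
        columns={"ct": "ct_ref"}
    )
    targets = mean_ct[mean_ct["gene"] != reference_gene].merge(ref, on="sample_id")
    if targets.empty:
        raise CtSchemaError("no target-gene rows in the Ct table")
    targets = targets.copy()
    targets["dct"] = targets["ct"] - targets["ct_ref"]
    targets["rel_2dct"] = 2.0 ** (-targets["dct"])

    if method == "ddct":
        ctrl = (
            targets[targets["group"] == control_group]
            .groupby("gene")["dct"]
            .mean()
            .rename("dct_control")
        )
        missing = set(targets["gene"]) - set(ctrl.index)
        if missing:
            raise CtSchemaError(
                f"control group has no rows for genes {sorted(missing)}"
            )
        targets = targets.merge(ctrl, on="gene")
        targets["ddct"] = targets["dct"] - targets["dct_control"]
        targets["fold"] = 2.0 ** (-targets["ddct"])

    group_cols = {"dct": "mean"} | ({"ddct": "mean"} if method == "ddct" else {})
    per_group = targets.groupby(["group", "gene"], sort=False).agg(group_cols).reset_index()
    if method == "ddct":
        per_group["fold_of_mean"] = 2.0 ** (-per_group["ddct"])

    keep = ["sample_id", "group", "gene", "dct", "rel_2dct"]
    if method == "ddct":
        keep += ["ddct", "fold"]
    return ExpressionResult(
        method=method,
        reference_gene=reference_gene,
        control_group=control_group,
        per_sample=targets[keep].reset_index(drop=True),
        per_group=per_group,
    )


def _shapiro_p(values: np.ndarray) -> float:
    # zero-range input has no defined W statistic; route it to the rank branch
    if np.ptp(values) == 0.0:
        return 0.0
    return float(stats.shapiro(values).pvalue)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Normality-gated two-sample comparison.

    Both groups normal by Shapiro-Wilk at ``alpha`` -> Welch's unequal
    variance t-test; otherwise the Mann-Whitney U-test.  Requires at
    least three values per group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("need >= 3 values per group")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa > alpha and pb > alpha:
        stat = stats.ttest_ind(a, b, equal_var=False)
        return ComparisonResult("welch-t", float(stat.pvalue), pa, pb)
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult("mann-whitney", float(stat.pvalue), pa, pb)
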