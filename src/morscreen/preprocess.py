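"""Detection census, abundance stratification, normalization and fold changes.

Stages between raw Cq values and the screening statistics:

* a per-assay detection census (FOC = frequency of occurrence, the number of
  samples per group with a detected well) and the resulting stratification
  into an abundant set A, a less-abundant set B, and excluded assays;
* reference-assay (normalizer) selection by a stability score combining
  intergroup bias and intragroup variance;
* delta-Cq normalization against the arithmetic mean of the reference Cq
  values in each sample;
* per-assay fold changes ``2**(-ddCq)`` with two-sample t-tests and
  up/down/flat calls for a volcano summary;
* group-mean substitution of missing expression values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    Cohort,
    CqMatrix,
    ExpressionMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

MIN_FOC = 3
# Detection fractions defining the abundant stratum; equal to the absolute
# counts 19-of-28 controls and 17-of-22 cases at the default cohort size.
SET_A_CONTROL_FRACTION = 19 / 28
SET_A_CASE_FRACTION = 17 / 22

SET_A = "A"
SET_B = "B"
EXCLUDED = "excluded"
UNDETECTED = "undetected"


# ---------------------------------------------------------------------------
# Detection census
# ---------------------------------------------------------------------------

@dataclass
class CensusSummary:
    panel_size: int
    n_detected: int
    n_undetected: int
    percent_detected: int  # floor of 100 * detected / panel
    n_set_a: int
    n_set_b: int
    n_excluded: int


@dataclass
class MarkerCensus:
    """Per-assay FOC bookkeeping and set assignment.

    ``table`` columns: ``foc_control``, ``foc_case``, ``detected_anywhere``,
    ``set_label`` in {A, B, excluded, undetected}.
    """

    table: pd.DataFrame
    summary: CensusSummary

    def set_members(self, label: str) -> list[str]:
        return list(self.table.index[self.table["set_label"] == label])


def detection_percent(n_detected: int, panel_size: int) -> int:
    """Panel detection rate as the floor of the percentage ("at least X%")."""
    if panel_size <= 0:
        raise ValidationError("panel size must be positive")
    return math.floor(100 * n_detected / panel_size)


def _set_a_thresholds(n_control: int, n_case: int,
                      control_fraction: float, case_fraction: float,
                      ) -> tuple[int, int]:
    # ceil with a fuzz guard so 19/28 of 28 is exactly 19, not 20
    t_c = math.ceil(control_fraction * n_control - 1e-9)
    t_a = math.ceil(case_fraction * n_case - 1e-9)
    return t_c, t_a


def detection_census(
    cohort: Cohort,
    min_foc: int = MIN_FOC,
    set_a_control_fraction: float = SET_A_CONTROL_FRACTION,
    set_a_case_fraction: float = SET_A_CASE_FRACTION,
) -> MarkerCensus:
    """Count detected samples per assay and group; stratify into sets.

    An assay is *excluded* if its FOC is below ``min_foc`` in either group;
    otherwise it joins set A when its FOC reaches the abundant-stratum
    thresholds in both groups (19 controls / 17 cases at the default 28/22
    cohort), else set B.  Assays never detected anywhere are labelled
    separately so the partition covers the whole panel.
    """
    group = cohort.group
    n_ctrl, n_case = cohort.group_sizes()
    if n_ctrl == 0 or n_case == 0:
        raise ValidationError("both groups must be non-empty")
    det = cohort.cq.detection()
    foc_c = det.loc[:, group == cohort.control_label].sum(axis=1).astype(int)
    foc_a = det.loc[:, group == cohort.case_label].sum(axis=1).astype(int)
    anywhere = (foc_c + foc_a) > 0

    t_c, t_a = _set_a_thresholds(n_ctrl, n_case,
                                 set_a_control_fraction, set_a_case_fraction)
    passes = (foc_c >= min_foc) & (foc_a >= min_foc)
    in_a = passes & (foc_c >= t_c) & (foc_a >= t_a)

    label = pd.Series(EXCLUDED, index=det.index, dtype=object)
    label[~anywhere] = UNDETECTED
    label[passes & ~in_a] = SET_B
    label[in_a] = SET_A

    table = pd.DataFrame({
        "foc_control": foc_c,
        "foc_case": foc_a,
        "detected_anywhere": anywhere,
        "set_label": label,
    })
    n_det = int(anywhere.sum())
    summary = CensusSummary(
        panel_size=len(det.index),
        n_detected=n_det,
        n_undetected=len(det.index) - n_det,
        percent_detected=detection_percent(n_det, len(det.index)),
        n_set_a=int((label == SET_A).sum()),
        n_set_b=int((label == SET_B).sum()),
        n_excluded=int((label == EXCLUDED).sum()),
    )
    logger.info("census: %d/%d assays detected (%d%%); set A %d, set B %d, "
                "excluded %d", n_det, summary.panel_size,
                summary.percent_detected, summary.n_set_a, summary.n_set_b,
                summary.n_excluded)
    return MarkerCensus(table, summary)


# ---------------------------------------------------------------------------
# Reference (normalizer) selection
# ---------------------------------------------------------------------------

def select_references(cohort: Cohort, n_refs: int = 2) -> pd.DataFrame:
    """Rank fully detected assays by expression stability.

    Stability of a candidate is ``sqrt(bias^2 + mean within-group variance)``
    where bias is the root-mean-square deviation of the group means from the
    grand mean — a two-way (group x sample) decomposition in the spirit of
    model-based normalizer selection: an ideal reference has no group effect
    and no residual scatter, hence stability 0.  Lower is more stable.

    Returns the full ranked table (columns ``stability``, ``bias``,
    ``within_sd``, ``selected``); ties break deterministically by assay id.
    """
    det = cohort.cq.detection()
    full = det.all(axis=1)
    if not full.any():
        raise ValidationError(
            "no assay is detected in every sample; supply an explicit "
            "reference list instead")
    group = cohort.group.to_numpy()
    vals = cohort.cq.values.loc[full]
    labels = (cohort.control_label, cohort.case_label)
    means = {g: vals.loc[:, group == g].mean(axis=1) for g in labels}
    variances = {g: vals.loc[:, group == g].var(axis=1, ddof=1) for g in labels}
    grand = sum(means.values()) / 2.0
    bias_sq = sum((means[g] - grand) ** 2 for g in labels) / 2.0
    within = sum(variances.values()) / 2.0
    stability = np.sqrt(bias_sq + within)

    table = pd.DataFrame({
        "stability": stability,
        "bias": np.sqrt(bias_sq),
        "within_sd": np.sqrt(within),
    })
    # stable sort after an index sort => ties break by assay id
    table = table.sort_index(kind="mergesort").sort_values(
        "stability", kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["rank"] <= n_refs
    return table


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(cq: CqMatrix, references: list[str],
              strict: bool = True, mask_undetected: bool = True,
              ) -> ExpressionMatrix:
    """Delta-Cq normalization against the mean reference Cq of each sample.

    ``dCq(assay, sample) = Cq(assay, sample) − mean(reference Cq in sample)``.
    Missing target wells stay missing.  In strict mode a reference missing in
    any sample is an error; in lenient mode the per-sample mean runs over the
    available references (with a warning).
    """
    if not references:
        raise ValidationError("at least one reference assay is required")
    missing = [r for r in references if r not in cq.values.index]
    if missing:
        raise ValidationError(f"reference assays not in matrix: {missing}")
    base = cq.detected_values() if mask_undetected else cq.values
    ref_vals = base.loc[references]
    absent = ref_vals.isna()
    if absent.to_numpy().any():
        bad = {s: list(ref_vals.index[absent[s]])
               for s in ref_vals.columns if absent[s].any()}
        if strict:
            raise ValidationError(
                f"references undetected in some samples: {bad}")
        logger.warning("references missing in %d samples; using per-sample "
                       "mean over available references", len(bad))
    ref_mean = ref_vals.mean(axis=0, skipna=True)
    if ref_mean.isna().any():
        bad_samples = list(ref_mean.index[ref_mean.isna()])
        raise ValidationError(f"no reference detected in samples: {bad_samples}")
    dcq = base.sub(ref_mean, axis=1)
    return ExpressionMatrix(dcq, "delta_cq", list(references))


# ---------------------------------------------------------------------------
# Fold changes / volcano summary
# ---------------------------------------------------------------------------

UP = "up"
DOWN = "down"
FLAT = "flat"


@dataclass
class FoldChangeTable:
    """Per-assay case-vs-control fold change, t-test p and regulation call.

    ``table`` columns: ``n_control``, ``n_case``, ``delta_delta_cq``,
    ``fold_change`` (= 2**(−ddCq)), ``log2_fc``, ``p_value``, ``call``.
    """

    table: pd.DataFrame
    threshold: float

    def counts(self) -> dict[str, int]:
        c = self.table["call"].value_counts()
        return {k: int(c.get(k, 0)) for k in (UP, DOWN, FLAT)}


def fold_changes(expr: ExpressionMatrix | pd.DataFrame, group: pd.Series,
                 control_label: str, case_label: str,
                 threshold: float = 1.5, equal_var: bool = True,
                 ) -> FoldChangeTable:
    """Fold change ``2**(-ddCq)`` and two-sided t-test per assay.

    ddCq is the difference of group mean dCq (case − control), so a lower
    case Cq (more abundant) gives FC > 1 = up-regulated.  The call is ``up``
    when FC >= threshold, ``down`` when FC <= 1/threshold, else ``flat``.
    The t-test uses pooled variance by default (Welch via ``equal_var=False``).
    """
    if threshold < 1.0:
        raise ValidationError("fold-change threshold must be >= 1")
    if isinstance(expr, pd.DataFrame):
        expr = ExpressionMatrix(expr, "delta_cq")
    dcq = expr.as_scale("delta_cq").values
    group = group.reindex(dcq.columns)
    mask_c = (group == control_label).to_numpy()
    mask_a = (group == case_label).to_numpy()
    rows = []
    for assay, row in dcq.iterrows():
        x = row.to_numpy()[mask_c]
        y = row.to_numpy()[mask_a]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0:
            raise ValidationError(
                f"assay {assay!r} has no detected value in one group")
        ddcq = float(np.mean(y) - np.mean(x))
        fc = float(2.0 ** (-ddcq))
        if len(x) < 2 or len(y) < 2:
            p = np.nan
        elif np.var(x) == 0 and np.var(y) == 0:
            p = 1.0 if np.mean(x) == np.mean(y) else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
        # tiny relative guard so an exact-threshold ddCq is not misclassified
        # by floating-point roundoff of 2**(-ddCq)
        if fc >= threshold * (1.0 - 1e-12):
            call = UP
        elif fc <= (1.0 / threshold) * (1.0 + 1e-12):
            call = DOWN
        else:
            call = FLAT
        rows.append((assay, len(x), len(y), ddcq, fc, -ddcq, p, call))
    table = pd.DataFrame(
        rows, columns=["assay", "n_control", "n_case", "delta_delta_cq",
                       "fold_change", "log2_fc", "p_value", "call"],
    ).set_index("assay")
    out = FoldChangeTable(table, threshold)
    logger.info("fold changes: %s at threshold %.2f", out.counts(), threshold)
    return out


# ---------------------------------------------------------------------------
# Group-mean substitution
# ---------------------------------------------------------------------------

def substitute_missing(expr: ExpressionMatrix, group: pd.Series,
                       ) -> ExpressionMatrix:
    """Replace each missing cell by its assay's within-group mean.

    Group means over detected values are unchanged by the substitution.
    An assay with zero detected values in some group cannot be substituted
    there and raises an error naming the assay.
    """
    vals = expr.values.copy()
    n_subst = 0
    for lab in pd.unique(group):
        cols = group.index[group == lab]
        block = vals[cols]
        means = block.mean(axis=1, skipna=True)
        empty = means.isna() & block.isna().any(axis=1)
        if empty.any():
            raise ValidationError(
                f"group {lab!r} has no detected values for assays "
                f"{list(vals.index[empty])}")
        filled = block.apply(lambda col: col.fillna(means))
        n_subst += int(block.isna().sum().sum())
        vals[cols] = filled
    logger.info("substituted %d missing cells with group means", n_subst)
    return ExpressionMatrix(vals, expr.scale, list(expr.references))
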