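"""Measure-of-Relevance (MoR) screening and subsampling reliability.

The MoR of a variable in a two-group comparison is a rank-scale
standardized mean difference: pool both groups, assign mid-ranks, and take

    MoR = |mean rank in group 1 − mean rank in group 2| / SD(pooled ranks)

with the population SD of the pooled mid-ranks in the denominator.  Being
rank-based it is invariant under any strictly monotone transformation of
the values, nonnegative and symmetric in the group order; for completely
separated groups of 5 vs 5 it equals 5 / sqrt(99/12) ≈ 1.74.  Variables are
sorted by MoR into an ascending *information chain*; those above a critical
value ``d`` (default 0.57, a medium-to-large standardized effect) are
declared *informative*.  No test decisions or multiplicity corrections are
involved — the screen reduces dimensionality before confirmatory testing.

The *reliability* stage repeats the screen on ``B`` random subsamples
(``m`` per group, drawn without replacement) and reports per variable the
relative frequency RF of being informative; variables with RF at or above a
threshold (default 0.8) are *reliable* candidates.  Missing values are
either left out per subsample (a variable is only evaluable with at least
two detected values per group) or substituted by full-data group means
beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CRITICAL_VALUE = 0.57
DEFAULT_REPEATS = 800
DEFAULT_SUBSAMPLE_SIZE = 15
DEFAULT_RF_THRESHOLD = 0.8

SUBSTITUTION_MODES = ("none", "group_mean")

#: signature of a pluggable two-sample relevance statistic
RelevanceStatistic = Callable[[np.ndarray, np.ndarray], float]


# ---------------------------------------------------------------------------
# The statistic
# ---------------------------------------------------------------------------

def mor_value(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-scale standardized mean difference between two samples.

    Requires at least two non-missing values per group.  If every pooled
    value is identical the rank dispersion is zero and the variable carries
    no discriminating information: MoR = 0 (not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("MoR needs >= 2 non-missing values per group")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    sd = ranks.std()  # population SD of the pooled ranks
    if sd == 0.0:
        return 0.0
    return float(abs(ranks[: len(x)].mean() - ranks[len(x):].mean()) / sd)


def _mor_columns(block: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized MoR over the rows of ``block`` (variables x samples).

    No missing values allowed; columns [0, n1) are group 1.
    """
    ranks = stats.rankdata(block, axis=1)
    sd = ranks.std(axis=1)
    diff = np.abs(ranks[:, :n1].mean(axis=1) - ranks[:, n1:].mean(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, diff / sd, 0.0)
    return out


# ---------------------------------------------------------------------------
# Information chain
# ---------------------------------------------------------------------------

@dataclass
class RelevanceResult:
    """Per-variable MoR values on the ascending information chain.

    ``table`` columns: ``mor``, ``chain_position`` (1 = smallest MoR),
    ``informative``; plus ``n_control``/``n_case`` actually used.
    """

    table: pd.DataFrame
    critical_value: float

    @property
    def informative(self) -> list[str]:
        t = self.table[self.table["informative"]]
        return list(t.index)

    @property
    def n_informative(self) -> int:
        return int(self.table["informative"].sum())


def information_chain(mor_values: pd.Series,
                      d: float = DEFAULT_CRITICAL_VALUE) -> pd.DataFrame:
    """Sort MoR values ascending and flag those strictly above ``d``.

    Ties break deterministically by variable id (stable sort).  If ``d``
    exceeds the maximum MoR no variable is informative.
    """
    if d <= 0:
        raise ValidationError("critical value d must be positive")
    ordered = mor_values.sort_index(kind="mergesort").sort_values(
        kind="mergesort")
    table = pd.DataFrame({"mor": ordered})
    table["chain_position"] = np.arange(1, len(table) + 1)
    table["informative"] = table["mor"] > d
    return table


def screen(table: pd.DataFrame, group: pd.Series,
           control_label: str, case_label: str,
           d: float = DEFAULT_CRITICAL_VALUE,
           statistic: RelevanceStatistic = mor_value) -> RelevanceResult:
    """One MoR screen of a variables x samples table.

    Missing values are left out per variable; a variable needs at least two
    detected values per group.  ``statistic`` may swap in an alternative
    two-sample relevance measure with the same contract.
    """
    group = group.reindex(table.columns)
    mask_c = (group == control_label).to_numpy()
    mask_a = (group == case_label).to_numpy()
    mors, n_c, n_a = {}, {}, {}
    for var, row in table.iterrows():
        vals = row.to_numpy(dtype=float)
        x, y = vals[mask_c], vals[mask_a]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(
                f"variable {var!r} has fewer than 2 detected values in a group")
        mors[var] = statistic(x, y)
        n_c[var], n_a[var] = len(x), len(y)
    chain = information_chain(pd.Series(mors), d)
    chain["n_control"] = pd.Series(n_c)
    chain["n_case"] = pd.Series(n_a)
    result = RelevanceResult(chain, d)
    logger.info("MoR screen: %d of %d variables informative at d = %.2f",
                result.n_informative, len(chain), d)
    return result


def largest_gap_critical_value(mor_values: pd.Series,
                               minimum: float = DEFAULT_CRITICAL_VALUE,
                               ) -> float:
    """Alternative, non-canonical stop criterion: the largest gap rule.

    Returns the midpoint of the widest gap in the ascending chain at or
    above ``minimum``; falls back to ``minimum`` when no gap lies there.
    The canonical criterion is the fixed critical value.
    """
    ordered = np.sort(mor_values.to_numpy())
    gaps = np.diff(ordered)
    mids = (ordered[:-1] + ordered[1:]) / 2.0
    eligible = mids >= minimum
    if not eligible.any():
        return minimum
    k = np.argmax(np.where(eligible, gaps, -np.inf))
    return float(mids[k])


# ---------------------------------------------------------------------------
# Reliability by subsampling
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    """RF of being informative across ``repeats`` subsampled screens.

    ``table`` columns: ``informative_count``, ``evaluable_count``, ``rf``,
    ``reliable``; RF = informative_count / repeats exactly.
    """

    table: pd.DataFrame
    repeats: int
    subsample_size: int
    critical_value: float
    rf_threshold: float
    substitution: str
    seed: int

    @property
    def reliable(self) -> list[str]:
        return list(self.table.index[self.table["reliable"]])


def reliability(table: pd.DataFrame, group: pd.Series,
                control_label: str, case_label: str,
                repeats: int = DEFAULT_REPEATS,
                subsample_size: int = DEFAULT_SUBSAMPLE_SIZE,
                d: float = DEFAULT_CRITICAL_VALUE,
                rf_threshold: float = DEFAULT_RF_THRESHOLD,
                substitution: str = "none",
                seed: int = 0) -> ReliabilityResult:
    """Repeat the MoR screen on random subgroups and count informative calls.

    Each repeat draws ``subsample_size`` samples per group without
    replacement (an independent, reproducible stream keyed on
    ``(seed, repeat)``), screens all variables at the fixed critical value
    ``d``, and accumulates how often each variable lands above it.  With
    ``substitution="group_mean"`` missing cells are first replaced by the
    full-data within-group means; with ``"none"`` a variable is evaluated
    per subsample on its detected values only and counts as not informative
    whenever either group retains fewer than two.
    """
    if substitution not in SUBSTITUTION_MODES:
        raise ValidationError(
            f"substitution must be one of {SUBSTITUTION_MODES}")
    if repeats <= 0:
        raise ValidationError("repeats must be positive")
    group = group.reindex(table.columns)
    # draw over sample ids in sorted order so the subsample stream does not
    # depend on the column order of the input table
    ctrl_ids = sorted(group.index[(group == control_label).to_numpy()])
    case_ids = sorted(group.index[(group == case_label).to_numpy()])
    ctrl_cols = table.columns.get_indexer(ctrl_ids)
    case_cols = table.columns.get_indexer(case_ids)
    m = subsample_size
    if m < 2:
        raise ValidationError("subsample size must be >= 2")
    if m > len(ctrl_cols) or m > len(case_cols):
        raise ValidationError(
            f"subsample size {m} exceeds a group size "
            f"({len(ctrl_cols)}/{len(case_cols)})")

    data = table.to_numpy(dtype=float)
    if substitution == "group_mean":
        data = data.copy()
        for cols in (ctrl_cols, case_cols):
            block = data[:, cols]
            means = np.nanmean(block, axis=1)
            if np.isnan(means).any():
                bad = list(table.index[np.isnan(means)])
                raise ValidationError(
                    f"no detected values in one group for {bad}")
            idx = np.where(np.isnan(block))
            block[idx] = means[idx[0]]
            data[:, cols] = block

    n_vars = data.shape[0]
    informative = np.zeros(n_vars, dtype=int)
    evaluable = np.zeros(n_vars, dtype=int)
    complete = not np.isnan(data).any()

    for b in range(repeats):
        rng = np.random.default_rng((seed, b))
        sub_c = rng.choice(ctrl_cols, size=m, replace=False)
        sub_a = rng.choice(case_cols, size=m, replace=False)
        block = data[:, np.concatenate([sub_c, sub_a])]
        if complete:
            mors = _mor_columns(block, m)
            evaluable += 1
            informative += mors > d
        else:
            xs = block[:, :m]
            ys = block[:, m:]
            ok = ((~np.isnan(xs)).sum(axis=1) >= 2) & \
                 ((~np.isnan(ys)).sum(axis=1) >= 2)
            evaluable += ok
            for i in np.flatnonzero(ok):
                if mor_value(xs[i], ys[i]) > d:
                    informative[i] += 1

    rf = informative / repeats
    out = pd.DataFrame({
        "informative_count": informative,
        "evaluable_count": evaluable,
        "rf": rf,
        "reliable": rf >= rf_threshold,
    }, index=table.index)
    result = ReliabilityResult(out, repeats, m, d, rf_threshold,
                               substitution, seed)
    logger.info("reliability: %d of %d variables reliable (RF >= %.2f) over "
                "%d repeats of %d+%d samples", len(result.reliable), n_vars,
                rf_threshold, repeats, m, m)
    return result
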