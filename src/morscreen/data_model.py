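"""Domain types and delimited-text IO for Cq matrices and cohort metadata.

The central container is :class:`CqMatrix`: an assay x sample grid of
quantification cycles (Cq) with explicit detection semantics.  A well is
*detected* iff a Cq value is present and lies at or below the positivity
cutoff (default 34 cycles); absent wells and wells above the cutoff are
treated as "not detected".  Normalized expression lives in
:class:`ExpressionMatrix` as delta-Cq (target Cq minus the per-sample mean
Cq of the reference assays), convertible to linear relative expression
``2**(-dCq)`` or its log2 (which is simply ``-dCq``).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 34.0
#: Tokens accepted (case-insensitively) as "well not detected" on read.
MISSING_TOKENS = frozenset({"", "nd", "na", "n/a", "nan"})
#: Token written for missing wells.
MISSING_OUT = "ND"

POOL_COLUMN_NAMES = frozenset({"pool", "assay_pool", "set"})

CONTROL = "control"
CASE = "case"


class ValidationError(ValueError):
    """Input violates a structural contract (duplicate ids, bad shapes...)."""


class ParseError(ValueError):
    """A delimited file could not be interpreted as a Cq or metadata table."""


class NumericalError(ArithmeticError):
    """A numerical operation failed (singular matrices, undefined statistics)."""


# ---------------------------------------------------------------------------
# CqMatrix
# ---------------------------------------------------------------------------

@dataclass
class CqMatrix:
    """Assay x sample grid of Cq values with detection semantics.

    Parameters
    ----------
    values
        DataFrame indexed by assay id, columns = sample ids, float Cq in
        cycles; ``NaN`` marks a missing (undetected) well.
    pool
        Optional per-assay pool label (e.g. ``A``/``B``/``C``/``D``); aligned
        to ``values.index``.  Empty string where unknown.
    cutoff
        Cq positivity threshold in cycles: a well is detected iff its value
        is present and ``<= cutoff``.
    """

    values: pd.DataFrame
    pool: pd.Series | None = None
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate assay ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() <= 0).any():
                raise ValidationError("Cq values must be positive cycles")
        if self.pool is None:
            self.pool = pd.Series("", index=self.values.index, dtype=object)
        else:
            self.pool = self.pool.reindex(self.values.index).fillna("").astype(object)
        self.cutoff = float(self.cutoff)

    # -- basic introspection ------------------------------------------------
    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        """Number of missing (absent) wells."""
        return int(self.values.isna().sum().sum())

    def detection(self) -> pd.DataFrame:
        """Boolean grid: True iff the well has a Cq value <= cutoff."""
        return self.values.notna() & (self.values <= self.cutoff)

    def detected_values(self) -> pd.DataFrame:
        """Cq grid with undetected wells (absent or above cutoff) set to NaN."""
        return self.values.where(self.detection())

    # -- transforms ---------------------------------------------------------
    def subset_assays(self, assays: list[str]) -> "CqMatrix":
        missing = [a for a in assays if a not in self.values.index]
        if missing:
            raise ValidationError(f"unknown assay ids: {missing}")
        return CqMatrix(self.values.loc[assays].copy(), self.pool.loc[assays].copy(),
                        self.cutoff)

    def subset_samples(self, samples: list[str]) -> "CqMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return CqMatrix(self.values[samples].copy(), self.pool.copy(), self.cutoff)

    def equals(self, other: "CqMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.pool.equals(other.pool)
            and self.cutoff == other.cutoff
        )


# ---------------------------------------------------------------------------
# CohortMetadata
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ("age", "tau", "p_tau", "abeta42", "rna_yield")


@dataclass
class CohortMetadata:
    """Per-sample clinical annotations: group, sex, age and CSF proteins.

    ``table`` is indexed by sample id with at least columns ``group`` (two
    levels) and optionally ``sex`` ({f, m}), ``age`` (years) and protein
    markers ``tau``/``p_tau``/``abeta42`` (pg/ml).
    """

    table: pd.DataFrame
    control_label: str = CONTROL
    case_label: str = CASE

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
        if "group" not in self.table.columns:
            raise ValidationError("metadata requires a 'group' column")
        levels = set(self.table["group"].unique())
        expected = {self.control_label, self.case_label}
        if not levels <= expected:
            raise ValidationError(
                f"group levels {sorted(levels)} not in {sorted(expected)}")
        counts = self.table["group"].value_counts()
        for lab in expected:
            if counts.get(lab, 0) < 2:
                raise ValidationError(
                    f"group '{lab}' needs >= 2 samples, found {counts.get(lab, 0)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def group_sizes(self) -> tuple[int, int]:
        g = self.table["group"]
        return (int((g == self.control_label).sum()), int((g == self.case_label).sum()))


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

SCALES = ("delta_cq", "rel_linear", "rel_log2")


@dataclass
class ExpressionMatrix:
    """Normalized expression on one of three interchangeable scales.

    ``delta_cq`` is the native scale (cycles); ``rel_linear`` is
    ``2**(-dCq)`` and ``rel_log2`` is ``log2`` of that, i.e. ``-dCq``.
    """

    values: pd.DataFrame
    scale: str = "delta_cq"
    references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        self.values = self.values.astype(float)

    def as_scale(self, scale: str) -> "ExpressionMatrix":
        if scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {scale!r}")
        if scale == self.scale:
            return self
        dcq = self._to_delta_cq()
        if scale == "delta_cq":
            out = dcq
        elif scale == "rel_linear":
            out = np.exp2(-dcq)
        else:  # rel_log2
            out = -dcq
        return ExpressionMatrix(out, scale, list(self.references))

    def _to_delta_cq(self) -> pd.DataFrame:
        if self.scale == "delta_cq":
            return self.values
        if self.scale == "rel_log2":
            return -self.values
        return -np.log2(self.values)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _sniff_sep(path: str) -> str:
    import os
    if not os.path.exists(path):
        raise ValidationError(f"input path does not exist: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _parse_cq_cell(raw: object, row: str, col: str) -> float:
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"non-numeric Cq value {text!r} at assay {row!r}, sample {col!r}"
        ) from None


def read_cq_table(path: str, cutoff: float = DEFAULT_CUTOFF,
                  sep: str | None = None) -> CqMatrix:
    """Read a delimited Cq table into a validated :class:`CqMatrix`.

    First column holds assay ids; an optional column named ``pool`` (or
    ``assay_pool``/``set``) holds pool labels; every remaining column is a
    sample.  Blank, ``ND`` or ``NA`` cells (any case) mean "not detected".
    """
    sep = sep or _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate assay ids in {path}: {dupes}")
    if raw.columns.has_duplicates:
        dupes = [c.split(".")[0] for c in raw.columns[raw.columns.duplicated()]]
        raise ValidationError(f"duplicate sample columns in {path}: {dupes}")
    # pandas mangles duplicate header names to 'x.1'; detect those too
    bases = pd.Index([c.rsplit(".", 1)[0] for c in raw.columns])
    if bases.has_duplicates:
        dupes = bases[bases.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample columns in {path}: {dupes}")

    pool = None
    pool_cols = [c for c in raw.columns if c.lower() in POOL_COLUMN_NAMES]
    if pool_cols:
        pool = raw[pool_cols[0]].astype(object)
        raw = raw.drop(columns=pool_cols)

    values = pd.DataFrame(
        [[_parse_cq_cell(raw.iat[i, j], raw.index[i], raw.columns[j])
          for j in range(raw.shape[1])] for i in range(raw.shape[0])],
        index=raw.index, columns=raw.columns, dtype=float,
    )
    cq = CqMatrix(values, pool, cutoff)
    logger.info("read %d assays x %d samples from %s (%d missing wells)",
                len(cq.assay_ids), len(cq.sample_ids), path, cq.n_missing)
    return cq


def write_cq_table(cq: CqMatrix, path: str, sep: str = "\t") -> None:
    """Write a Cq table; missing wells are emitted as ``ND``."""
    out = cq.values.copy()
    body = out.astype(object).where(out.notna(), MISSING_OUT)
    if (cq.pool != "").any():
        body.insert(0, "pool", cq.pool)
    body.index.name = "assay"
    body.to_csv(path, sep=sep)


def read_metadata(path: str, sep: str | None = None,
                  control_label: str = CONTROL,
                  case_label: str = CASE) -> CohortMetadata:
    """Read the sample-metadata table (sample id, group, sex, age, proteins)."""
    sep = sep or _sniff_sep(path)
    table = pd.read_csv(path, sep=sep, index_col=0)
    for col in METRIC_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return CohortMetadata(table, control_label, case_label)


def write_metadata(meta: CohortMetadata, path: str, sep: str = "\t") -> None:
    out = meta.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A CqMatrix joined with its metadata; samples aligned and ordered."""

    cq: CqMatrix
    meta: CohortMetadata

    @property
    def group(self) -> pd.Series:
        return self.meta.group

    def group_sizes(self) -> tuple[int, int]:
        return self.meta.group_sizes()

    @property
    def control_label(self) -> str:
        return self.meta.control_label

    @property
    def case_label(self) -> str:
        return self.meta.case_label


def join_metadata(cq: CqMatrix, meta: CohortMetadata) -> Cohort:
    """Align a Cq matrix with cohort metadata into a :class:`Cohort`.

    Metadata must cover every sample of the matrix.  Samples present only in
    the metadata are dropped with a warning; an empty intersection or a Cq
    sample without metadata is an error.
    """
    cq_samples = set(cq.sample_ids)
    meta_samples = set(meta.sample_ids)
    unmatched = sorted(cq_samples - meta_samples)
    if unmatched:
        raise ValidationError(f"samples without metadata: {unmatched}")
    common = [s for s in meta.sample_ids if s in cq_samples]
    if not common:
        raise ValidationError("no overlap between Cq samples and metadata")
    extra = sorted(meta_samples - cq_samples)
    if extra:
        logger.warning("dropping %d metadata-only samples: %s", len(extra), extra)
    meta_aligned = CohortMetadata(meta.table.loc[common].copy(),
                                  meta.control_label, meta.case_label)
    cq_aligned = cq.subset_samples(common)
    n_ctrl, n_case = meta_aligned.group_sizes()
    logger.info("joined cohort: %d %s / %d %s samples",
                n_ctrl, meta.control_label, n_case, meta.case_label)
    return Cohort(cq_aligned, meta_aligned)
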