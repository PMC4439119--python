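"""End-to-end orchestration: census → normalization → fold changes →
MoR screen → reliability → substitution → MANCOVA → classification →
correlations, with every stage output written as TSV and a single
structured, reproducible run report.

The pipeline mirrors a two-stage biomarker study: an abundant stratum
(set A, plus the classical CSF proteins) goes through the subsampling
reliability analysis, the less-abundant stratum (set B) through a single
MoR screen; survivors of either route are confirmed by MANCOVA with age
and sex as covariates and finally evaluated by discriminant analysis and
per-marker ROC.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classification as cls
from . import confirmatory as conf
from . import preprocess as prep
from . import relevance as rel
from .data_model import (
    Cohort,
    CohortMetadata,
    DEFAULT_CUTOFF,
    ValidationError,
    join_metadata,
    read_cq_table,
    read_metadata,
)

logger = logging.getLogger(__name__)

PROTEIN_COLUMNS = ("tau", "p_tau", "abeta42")


@dataclass
class RunConfig:
    """Every knob of a pipeline run; fully serialized into the run report."""

    cq_path: str = ""
    metadata_path: str = ""
    cutoff: float = DEFAULT_CUTOFF
    min_foc: int = prep.MIN_FOC
    set_a_control_fraction: float = prep.SET_A_CONTROL_FRACTION
    set_a_case_fraction: float = prep.SET_A_CASE_FRACTION
    fc_threshold: float = 1.5
    references: list[str] = field(default_factory=list)  # empty = auto-select
    n_refs: int = 2
    strict_normalization: bool = False
    include_proteins: bool = True
    d: float = rel.DEFAULT_CRITICAL_VALUE
    repeats: int = rel.DEFAULT_REPEATS
    subsample_size: int = rel.DEFAULT_SUBSAMPLE_SIZE
    rf_threshold: float = rel.DEFAULT_RF_THRESHOLD
    alpha: float = conf.DEFAULT_ALPHA
    classification_markers: list[str] = field(default_factory=list)
    correlation_cq_cutoff: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls_, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls_(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write(df: pd.DataFrame, outdir: str, name: str, index_label: str) -> str:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path


def _protein_rows(meta: CohortMetadata) -> pd.DataFrame:
    cols = [c for c in PROTEIN_COLUMNS if c in meta.table.columns]
    return meta.table[cols].T.astype(float)


def assemble_marker_table(expr_values: pd.DataFrame, assays: list[str],
                          proteins: pd.DataFrame | None = None,
                          ) -> pd.DataFrame:
    """Stack selected assay expression rows with protein-marker rows.

    Proteins bypass the Cq machinery and enter on their native scale (the
    screen is rank-based, hence scale-free); their row ids must not collide
    with assay ids.
    """
    parts = [expr_values.loc[assays]]
    if proteins is not None and len(proteins):
        clash = set(proteins.index) & set(assays)
        if clash:
            raise ValidationError(f"protein names collide with assays: {sorted(clash)}")
        parts.append(proteins.reindex(columns=expr_values.columns))
    return pd.concat(parts, axis=0)


def run_pipeline(config: RunConfig, outdir: str,
                 cohort: Cohort | None = None) -> dict:
    """Execute every stage and return the (JSON-serializable) run report.

    ``cohort`` may be passed directly (e.g. fresh from the simulator);
    otherwise ``config.cq_path``/``metadata_path`` are read.  Every stage
    writes its TSV into ``outdir``; the report is written as
    ``report.json`` and is byte-identical across reruns of the same inputs.
    """
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    notices: list[str] = []

    def stage(name: str, **payload) -> None:
        report["stages"][name] = payload

    # ---- load -------------------------------------------------------------
    if cohort is None:
        for p in (config.cq_path, config.metadata_path):
            if not p:
                raise ValidationError("cq_path and metadata_path are required")
            if not os.path.exists(p):
                raise ValidationError(f"input path does not exist: {p}")
        cq = read_cq_table(config.cq_path, cutoff=config.cutoff)
        meta = read_metadata(config.metadata_path)
        cohort = join_metadata(cq, meta)
    n_ctrl, n_case = cohort.group_sizes()
    stage("load", n_control=n_ctrl, n_case=n_case,
          n_assays=len(cohort.cq.assay_ids),
          n_missing_wells=cohort.cq.n_missing)

    # ---- census -----------------------------------------------------------
    census = prep.detection_census(
        cohort, config.min_foc,
        config.set_a_control_fraction, config.set_a_case_fraction)
    _write(census.table, outdir, "census.tsv", "assay")
    stage("census", **dataclasses.asdict(census.summary))

    # ---- references & normalization ---------------------------------------
    if config.references:
        references = list(config.references)
        ref_table = None
    else:
        ref_table = prep.select_references(cohort, config.n_refs)
        _write(ref_table, outdir, "reference_stability.tsv", "assay")
        references = list(ref_table.index[ref_table["selected"]])
    expr = prep.normalize(cohort.cq, references,
                          strict=config.strict_normalization)
    stage("normalize", references=references)

    # ---- fold changes on FOC-passing assays --------------------------------
    evaluated = census.set_members(prep.SET_A) + census.set_members(prep.SET_B)
    fc = prep.fold_changes(
        expr.as_scale("delta_cq").values.loc[evaluated] if evaluated
        else expr.values.iloc[:0],
        cohort.group, cohort.control_label, cohort.case_label,
        config.fc_threshold) if evaluated else None
    if fc is not None:
        _write(fc.table, outdir, "fold_changes.tsv", "assay")
        stage("fold_changes", threshold=config.fc_threshold, **fc.counts())
    else:
        notices.append("no assay passed the FOC filter; volcano skipped")

    proteins = _protein_rows(cohort.meta) if config.include_proteins else None
    dcq = expr.as_scale("delta_cq").values

    # ---- set B: single MoR screen ------------------------------------------
    informative_b: list[str] = []
    set_b = census.set_members(prep.SET_B)
    if set_b:
        table_b = assemble_marker_table(dcq, set_b)
        # drop rows not evaluable (fewer than 2 detected per group)
        screen_b = rel.screen(table_b, cohort.group, cohort.control_label,
                              cohort.case_label, config.d)
        _write(screen_b.table, outdir, "screen_set_b.tsv", "variable")
        informative_b = screen_b.informative
        stage("screen_set_b", n_variables=len(table_b),
              n_informative=screen_b.n_informative, d=config.d)
    else:
        notices.append("set B is empty; screen skipped")

    # ---- set A (+ proteins): reliability, both substitution modes ----------
    reliable_a: list[str] = []
    set_a = census.set_members(prep.SET_A)
    if set_a or (proteins is not None and len(proteins)):
        table_a = assemble_marker_table(dcq, set_a, proteins)
        m = min(config.subsample_size, n_ctrl, n_case)
        if m < config.subsample_size:
            notices.append(f"subsample size reduced to {m} (group sizes)")
        rel_results = {}
        for mode in ("none", "group_mean"):
            res = rel.reliability(
                table_a, cohort.group, cohort.control_label,
                cohort.case_label, repeats=config.repeats,
                subsample_size=m, d=config.d,
                rf_threshold=config.rf_threshold, substitution=mode,
                seed=config.seed)
            _write(res.table, outdir, f"reliability_{mode}.tsv", "variable")
            rel_results[mode] = res
        reliable_a = sorted(set(rel_results["none"].reliable)
                            | set(rel_results["group_mean"].reliable))
        stage("reliability", n_variables=len(table_a),
              subsample_size=m, repeats=config.repeats,
              reliable_without_substitution=rel_results["none"].reliable,
              reliable_with_substitution=rel_results["group_mean"].reliable,
              reliable_union=reliable_a)
    else:
        notices.append("set A is empty; reliability skipped")

    # ---- substitution + MANCOVA per family ---------------------------------
    covariates = cohort.meta.table[
        [c for c in ("age", "sex") if c in cohort.meta.table.columns]]
    significant: list[str] = []
    families = {"set_a_reliable": reliable_a, "set_b_informative": informative_b}
    for fam_name, members in families.items():
        if not members:
            notices.append(f"no candidates in family {fam_name}; "
                           "confirmatory stage skipped")
            stage(f"mancova_{fam_name}", skipped=True)
            continue
        assay_members = [m for m in members if m in dcq.index]
        prot_members = ([m for m in members if m in proteins.index]
                        if proteins is not None else [])
        table_fam = assemble_marker_table(
            dcq, assay_members,
            proteins.loc[prot_members] if prot_members else None)
        filled = prep.substitute_missing(
            type(expr)(table_fam, "delta_cq"), cohort.group)
        responses = filled.values.T  # samples x markers
        try:
            res = conf.mancova(responses, cohort.group, covariates,
                               cohort.control_label, cohort.case_label,
                               alpha=config.alpha)
        except (ValidationError, conf.NumericalError) as exc:
            notices.append(f"MANCOVA for {fam_name} failed: {exc}")
            stage(f"mancova_{fam_name}", skipped=True, reason=str(exc))
            continue
        _write(res.univariate, outdir, f"mancova_{fam_name}.tsv", "marker")
        significant += [m for m in res.univariate.index[
            res.univariate["significant"]]]
        stage(f"mancova_{fam_name}",
              wilks_lambda=res.group_test.wilks_lambda,
              F=res.group_test.F, df1=res.group_test.df1,
              df2=res.group_test.df2, p=res.group_test.p_value,
              covariate_F=None if res.covariate_test is None
              else res.covariate_test.F,
              covariate_p=None if res.covariate_test is None
              else res.covariate_test.p_value,
              significant=[m for m in res.univariate.index[
                  res.univariate["significant"]]])

    # ---- classification -----------------------------------------------------
    markers = config.classification_markers or [
        m for m in significant if m in dcq.index][:3]
    if markers:
        feats = prep.substitute_missing(
            type(expr)(dcq.loc[markers], "delta_cq"), cohort.group)
        report_cls = cls.lda_classify(feats.values.T, cohort.group,
                                      cohort.control_label, cohort.case_label)
        roc_rows = []
        for mk in markers:
            rr = cls.roc_auc(feats.values.loc[mk].to_numpy(),
                             (cohort.group == cohort.case_label).to_numpy())
            rr.curve.insert(0, "marker", mk)
            roc_rows.append(rr.curve)
        pd.concat(roc_rows).to_csv(os.path.join(outdir, "roc_curves.tsv"),
                                   sep="\t", index=False)
        stage("classification", markers=markers,
              accuracy_control=report_cls.accuracy_control,
              accuracy_case=report_cls.accuracy_case,
              accuracy_overall=report_cls.accuracy_overall,
              auc={k: float(v) for k, v in report_cls.marker_auc.items()})
    else:
        notices.append("no significant marker for classification; skipped")

    # ---- correlations with protein markers ----------------------------------
    prot_cols = [c for c in PROTEIN_COLUMNS if c in cohort.meta.table.columns]
    corr_rows = []
    case_mask = (cohort.group == cohort.case_label).to_numpy()
    for mk in [m for m in significant if m in dcq.index]:
        log2_expr = -dcq.loc[mk].to_numpy()
        raw_cq = cohort.cq.values.loc[mk].to_numpy()
        for pc in prot_cols:
            prot = cohort.meta.table[pc].to_numpy(dtype=float)
            try:
                r = conf.pearson(log2_expr[case_mask], prot[case_mask],
                                 ci_level=0.98,
                                 cq=raw_cq[case_mask],
                                 cq_cutoff=config.correlation_cq_cutoff)
            except (ValidationError, conf.NumericalError):
                continue
            corr_rows.append((mk, pc, r.n, r.r, r.ci_low, r.ci_high,
                              r.r_squared_percent, r.p_value))
    if corr_rows:
        corr = pd.DataFrame(corr_rows, columns=[
            "marker", "protein", "n", "r", "ci_low", "ci_high",
            "r2_percent", "p_value"])
        corr.to_csv(os.path.join(outdir, "correlations.tsv"), sep="\t",
                    index=False)
        stage("correlations", n_pairs=len(corr_rows))

    # ---- demographics -------------------------------------------------------
    demo = conf.demographics_tests(cohort.meta.table, cohort.control_label,
                                   cohort.case_label)
    _write(demo, outdir, "demographics.tsv", "variable")

    report["notices"] = notices
    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
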