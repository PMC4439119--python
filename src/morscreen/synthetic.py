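"""Synthetic RT-qPCR cohorts with the structure the analysis assumes.

The generator emulates a two-group CSF miRNA profiling study: a large assay
panel of which only a fraction is expressed in the fluid at all, Gaussian
per-assay abundance on the Cq scale, a per-sample technical offset (library
loading / efficiency), designated stable reference assays, planted
case-vs-control effects on chosen assays (in delta-delta-Cq cycles),
abundance-driven or completely-random dropout, and clinical covariates
(age, stratified sex, CSF protein markers) with configurable group
means/SDs.  A truth table records planted effects and reference status so
downstream screens can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    CASE,
    CONTROL,
    CohortMetadata,
    CqMatrix,
    DEFAULT_CUTOFF,
    ValidationError,
)

__all__ = [
    "GroupGaussian",
    "DropoutModel",
    "CorrelationHook",
    "SimulationConfig",
    "simulate_cohort",
    "inject_dropout",
]


@dataclass(frozen=True)
class GroupGaussian:
    """Per-group Gaussian for a clinical variable (mean/SD per group)."""

    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float

    def draw(self, rng: np.random.Generator, n_control: int, n_case: int,
             lower: float | None = None) -> np.ndarray:
        vals = np.concatenate([
            rng.normal(self.control_mean, self.control_sd, n_control),
            rng.normal(self.case_mean, self.case_sd, n_case),
        ])
        if lower is not None:
            vals = np.maximum(vals, lower)
        return vals


@dataclass(frozen=True)
class DropoutModel:
    """How wells go missing.

    ``mode``:
      * ``"abundance"`` — probability of losing a well is logistic in
        (true Cq − cutoff) with slope ``slope`` per cycle, so low-abundance
        (high-Cq) wells drop out more.  This reproduces the abundant
        high-detection stratum vs the sparse low-abundance stratum.
      * ``"mar"`` — missing completely at random at probability ``rate``.
      * ``"none"`` — no dropout beyond the cutoff itself.
    """

    mode: str = "abundance"
    slope: float = 0.7
    rate: float = 0.0

    def probabilities(self, true_cq: np.ndarray, cutoff: float) -> np.ndarray:
        if self.mode == "none":
            return np.zeros_like(true_cq)
        if self.mode == "mar":
            if not 0.0 <= self.rate <= 1.0:
                raise ValidationError(f"dropout rate must be in [0, 1]: {self.rate}")
            return np.full_like(true_cq, self.rate)
        if self.mode == "abundance":
            return 1.0 / (1.0 + np.exp(-self.slope * (true_cq - cutoff)))
        raise ValidationError(f"unknown dropout mode {self.mode!r}")


@dataclass(frozen=True)
class CorrelationHook:
    """Couple one marker's expression to one protein at a target Pearson r.

    The protein is rebuilt from a latent factor shared with the marker's
    standardized within-group log2 expression (−Cq residual), so the
    realized within-group correlation approaches ``r`` for large n.
    """

    assay: str
    protein: str
    r: float


# Table-driven defaults emulate the study cohort: group sizes, age structure,
# stratified sex, and CSF protein markers (pg/ml).
_DEFAULT_AGE = GroupGaussian(61.0, 12.7, 72.1, 8.5)
_DEFAULT_PROTEINS = {
    "tau": GroupGaussian(308.9, 227.7, 708.5, 282.9),
    "p_tau": GroupGaussian(52.6, 28.5, 92.0, 93.3),
    "abeta42": GroupGaussian(719.9, 406.7, 446.7, 164.1),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated cohort.

    Defaults describe a 28-control / 22-case CSF cohort over a 1178-assay
    panel with six stable reference assays, an abundant fully-detectable
    tier of ~60 assays (mean Cq 26) and a long tail of dilute assays whose
    abundance-driven dropout around the Cq-34 cutoff yields roughly 37% of
    the panel detected at all and a large less-abundant ("set B") stratum.
    """

    n_control: int = 28
    n_case: int = 22
    n_assays: int = 1178
    n_reference: int = 6
    #: assays right after the references form an abundant, fully detectable
    #: tier (the "set A" stratum); plant effects there to study recovery.
    n_abundant: int = 50
    #: (assay id, effect in delta-delta-Cq cycles); negative = up-regulated
    #: in cases (lower Cq = more abundant).
    planted: tuple[tuple[str, float], ...] = ()
    expressed_fraction: float = 1.0
    baseline_mean: float = 37.5
    baseline_sd: float = 3.0
    abundant_mean: float = 26.0
    abundant_sd: float = 2.0
    reference_mean: float = 24.0
    reference_sd: float = 0.5
    noise_sd: float = 1.0
    sample_offset_sd: float = 0.5
    cutoff: float = DEFAULT_CUTOFF
    dropout: DropoutModel = field(default_factory=DropoutModel)
    age: GroupGaussian = _DEFAULT_AGE
    stratify_sex: bool = True
    proteins: dict[str, GroupGaussian] = field(
        default_factory=lambda: dict(_DEFAULT_PROTEINS))
    correlation_hooks: tuple[CorrelationHook, ...] = ()
    seed: int = 0

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _assay_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"mir-{i + 1:0{width}d}" for i in range(n)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CqMatrix, CohortMetadata, pd.DataFrame]:
    """Draw one cohort; returns (CqMatrix, CohortMetadata, truth table).

    The truth table has one row per assay: ``planted_effect`` (cycles,
    0 for null assays), ``is_reference`` and ``is_expressed``; plus realized
    per-group detection counts ``foc_control``/``foc_case``.  The same seed
    yields a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n_c, n_a = config.n_control, config.n_case
    n = n_c + n_a
    assays = _assay_names(config.n_assays)
    assay_index = pd.Index(assays, name="assay")
    samples = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array([CONTROL] * n_c + [CASE] * n_a)

    planted = dict(config.planted)
    unknown = sorted(set(planted) - set(assays))
    if unknown:
        raise ValidationError(f"planted assay ids outside panel: {unknown}")

    # Expression status and abundance tier are positional properties of the
    # panel, independent of planting, so a planted effect of zero leaves an
    # assay distributionally identical to a non-planted one.
    n_ref = config.n_reference
    if n_ref > config.n_assays:
        raise ValidationError("more reference assays than panel assays")
    n_ab = min(config.n_abundant, config.n_assays - n_ref)
    refs = assays[:n_ref]
    expressed = rng.random(config.n_assays) < config.expressed_fraction
    expressed[: n_ref + n_ab] = True

    mu = rng.normal(config.baseline_mean, config.baseline_sd, config.n_assays)
    mu[n_ref: n_ref + n_ab] = rng.normal(config.abundant_mean,
                                         config.abundant_sd, n_ab)
    mu[:n_ref] = rng.normal(config.reference_mean, config.reference_sd, n_ref)

    sample_offset = rng.normal(0.0, config.sample_offset_sd, n)
    eps = rng.normal(0.0, config.noise_sd, (config.n_assays, n))

    effect = np.zeros(config.n_assays)
    for a, delta in planted.items():
        effect[assays.index(a)] = delta

    is_case = (group == CASE).astype(float)
    true_cq = (mu[:, None] + sample_offset[None, :]
               + effect[:, None] * is_case[None, :] + eps)

    # Dropout: unexpressed assays are missing everywhere; expressed wells
    # drop out per the configured model.
    p_drop = config.dropout.probabilities(true_cq, config.cutoff)
    dropped = rng.random(true_cq.shape) < p_drop
    observed = np.where(expressed[:, None] & ~dropped, true_cq, np.nan)
    observed = np.maximum(observed, 1e-6)  # Cq must stay positive

    values = pd.DataFrame(observed, index=assay_index, columns=samples)
    pools = pd.Series([("ABCD")[i % 4] for i in range(config.n_assays)],
                      index=assay_index, dtype=object)
    cq = CqMatrix(values, pools, config.cutoff)

    # --- metadata ----------------------------------------------------------
    meta = pd.DataFrame(index=pd.Index(samples, name="sample"))
    meta["group"] = group
    if config.stratify_sex:
        # alternate within each group: balanced controls (14/14 at n=28) and a
        # mild female excess among cases (13/9 at n=22), as in memory-clinic
        # cohorts
        sex = np.concatenate([
            np.array(["f", "m"] * n_c)[:n_c],
            np.array(["f", "f", "m"] * n_a)[:n_a],
        ])
    else:
        sex = np.where(rng.random(n) < 0.5, "f", "m")
    meta["sex"] = sex
    meta["age"] = config.age.draw(rng, n_c, n_a, lower=18.0)
    for name, model in config.proteins.items():
        meta[name] = model.draw(rng, n_c, n_a, lower=1.0)

    # --- correlation hooks -------------------------------------------------
    for hook in config.correlation_hooks:
        if hook.assay not in assays:
            raise ValidationError(f"correlation hook assay {hook.assay!r} not in panel")
        if hook.protein not in meta.columns:
            raise ValidationError(f"correlation hook protein {hook.protein!r} unknown")
        if not -1.0 <= hook.r <= 1.0:
            raise ValidationError(f"target correlation must be in [-1, 1]: {hook.r}")
        expr = -values.loc[hook.assay].to_numpy()  # log2 expression direction
        z = np.empty(n)
        new = np.empty(n)
        model = config.proteins[hook.protein]
        for lab, mean_, sd_ in ((CONTROL, model.control_mean, model.control_sd),
                                (CASE, model.case_mean, model.case_sd)):
            mask = group == lab
            e = expr[mask]
            mu_e, sd_e = np.nanmean(e), np.nanstd(e)
            zg = np.where(np.isnan(e), 0.0, (e - mu_e) / (sd_e if sd_e else 1.0))
            indep = rng.normal(0.0, 1.0, mask.sum())
            latent = hook.r * zg + np.sqrt(1.0 - hook.r**2) * indep
            new[mask] = np.maximum(mean_ + sd_ * latent, 1.0)
        meta[hook.protein] = new

    metadata = CohortMetadata(meta)

    detection = cq.detection()
    truth = pd.DataFrame(index=assay_index)
    truth["planted_effect"] = effect
    truth["is_reference"] = [a in set(refs) for a in assays]
    truth["is_expressed"] = expressed
    truth["foc_control"] = detection.loc[:, group == CONTROL].sum(axis=1)
    truth["foc_case"] = detection.loc[:, group == CASE].sum(axis=1)
    return cq, metadata, truth


def inject_dropout(cq: CqMatrix, model: DropoutModel, seed: int) -> CqMatrix:
    """Remove wells i.i.d. according to ``model``; returns a new matrix."""
    rng = np.random.default_rng(seed)
    vals = cq.values.to_numpy(copy=True)
    with np.errstate(invalid="ignore"):
        p = model.probabilities(np.nan_to_num(vals, nan=np.inf), cq.cutoff)
    p = np.where(np.isnan(vals), 0.0, p)
    dropped = rng.random(vals.shape) < p
    vals[dropped] = np.nan
    out = CqMatrix(pd.DataFrame(vals, index=cq.values.index,
                                columns=cq.values.columns),
                   cq.pool.copy(), cq.cutoff)
    return out
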