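"""Sex-specific schizophrenia signal: stringent filtering and a subsampling null.

Two bespoke procedures:

* **Stringent sex-specific filter** — starting from each sex's diagnosis
  DEGs (FDR < 0.05), remove (b) genes that are also DEGs in the opposite
  sex, then (c) genes whose residualized expression (covariate-only null,
  diagnosis excluded) still differs between diagnosis groups *in the
  opposite sex* by Mann-Whitney at p < 0.05.  What survives is a gene whose
  diagnosis signal is demonstrably confined to one sex.

* **Male-subsampling permutation null** — female cohorts are far smaller
  than male cohorts, so a smaller female DEG count could be pure power
  loss.  Repeatedly subsample males down to the female sample size, rerun
  the diagnosis DE pipeline, and compare the observed female DEG count to
  the distribution of male-at-female-n DEG counts with an add-one
  two-sided empirical p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffexpr, quantnorm
from .diffexpr import DEResult, DesignSpec
from .dosage import mann_whitney
from .quantnorm import ExprMatrix


@dataclass
class FilterReport:
    """Nested gene sets of the stringent filter, with per-gene removal reasons."""

    sex: str
    stage_a: set  # sex-specific diagnosis DEGs at FDR < 0.05
    stage_b: set  # after removing genes shared with the opposite sex
    stage_c: set  # after removing genes with opposite-sex residualized signal
    removal_reason: dict  # gene -> "shared" | "opposite-sex signal"

    def __post_init__(self):
        if not (self.stage_c <= self.stage_b <= self.stage_a):
            raise ValueError("filter stages must be nested: (c) <= (b) <= (a)")

    @property
    def counts(self):
        return {"a": len(self.stage_a), "b": len(self.stage_b), "c": len(self.stage_c)}


@dataclass
class NullDistribution:
    counts: np.ndarray  # DEG count per subsample draw (length B)
    observed: int  # observed female DEG count
    p_two_sided: float
    p_lower: float  # P(null <= observed)
    p_upper: float  # P(null >= observed)
    seed: int
    subsample_size: int


def _one_sex_filter(
    own: DEResult,
    other: DEResult,
    resid_expr: ExprMatrix,
    meta: pd.DataFrame,
    opposite_sex: str,
    fdr: float,
    mwu_alpha: float,
) -> FilterReport:
    a = set(own.table.index[own.table["adj.P.Val"] < fdr])
    other_sig = set(other.table.index[other.table["adj.P.Val"] < fdr])
    reasons = {g: "shared" for g in a & other_sig}
    b = a - other_sig

    opp = meta.index[meta["sex"] == opposite_sex]
    opp = [s for s in opp if s in resid_expr.samples]
    sz = [s for s in opp if meta.loc[s, "diagnosis"] == "SZ"]
    ctl = [s for s in opp if meta.loc[s, "diagnosis"] == "CTL"]
    missing = sorted(g for g in b if g not in resid_expr.genes)
    if missing:
        raise ValueError(f"genes absent from residualized expression: {missing[:10]}")
    c = set()
    for g in sorted(b):
        _, p = mann_whitney(
            resid_expr.values.loc[g, sz].to_numpy(),
            resid_expr.values.loc[g, ctl].to_numpy(),
        )
        if p < mwu_alpha:
            reasons[g] = "opposite-sex signal"
        else:
            c.add(g)
    sex = "F" if opposite_sex == "M" else "M"
    return FilterReport(sex=sex, stage_a=a, stage_b=b, stage_c=c, removal_reason=reasons)


def stringent_sex_filter(
    de_female: DEResult,
    de_male: DEResult,
    resid_expr: ExprMatrix,
    meta: pd.DataFrame,
    fdr: float = 0.05,
    mwu_alpha: float = 0.05,
):
    """Apply the stringent sex-specific DEG filter in both directions.

    ``resid_expr`` must be residualized under the covariate-only null
    (diagnosis excluded) so a diagnosis difference is still visible in the
    residuals.  Returns ``(female_report, male_report)``.
    """
    female = _one_sex_filter(de_female, de_male, resid_expr, meta, "M", fdr, mwu_alpha)
    male = _one_sex_filter(de_male, de_female, resid_expr, meta, "F", fdr, mwu_alpha)
    return female, male


@dataclass
class SubsampleDEConfig:
    """Diagnosis DE pipeline applied inside each subsample draw.

    With ``reuse_normalization`` (default) the filter, TMM factors, log-CPM
    and precision weights are computed once on the full male cohort and
    re-used per draw (only the model refits); otherwise the whole pipeline,
    including hidden-factor estimation, reruns on every draw.
    """

    covariates: list = field(default_factory=list)
    cpm_threshold: float = 10.0
    group_fraction: float = 0.7
    n_hidden: int | str = 0
    fdr: float = 0.05
    reuse_normalization: bool = True


def _dx_deg_count(logcpm, weights, meta_sub, cfg) -> int:
    spec = DesignSpec(model="diagnosis_by_sex", covariates=cfg.covariates)
    factors = None
    if cfg.n_hidden not in (0, None):
        null_spec = DesignSpec(model="null_minimal", covariates=cfg.covariates)
        null_design, _ = diffexpr.build_design(meta_sub, null_spec, None)
        factors = diffexpr.estimate_hidden_factors(logcpm, null_design, k=cfg.n_hidden)
    design, contrast = diffexpr.build_design(meta_sub, spec, factors)
    res = diffexpr.fit_moderated(logcpm, weights, design, contrast)
    return int((res.table["adj.P.Val"] < cfg.fdr).sum())


def _full_pipeline_count(counts, meta_sub, cfg) -> int:
    kept = quantnorm.filter_by_expression(
        counts, meta_sub, cfg.cpm_threshold, cfg.group_fraction, group="diagnosis"
    )
    sub = counts.loc[kept]
    factors = quantnorm.tmm_factors(sub)
    logcpm = quantnorm.log_cpm(sub, factors)
    spec = DesignSpec(model="diagnosis_by_sex", covariates=cfg.covariates)
    design, _ = diffexpr.build_design(meta_sub, spec, None)
    weights = quantnorm.voom_weights(logcpm, design)
    return _dx_deg_count(logcpm, weights, meta_sub, cfg)


def empirical_p(null_counts: np.ndarray, observed: float):
    """Add-one two-sided empirical p from a permutation null.

    p_lower = (1 + #{null <= obs}) / (B + 1), p_upper analogous;
    two-sided = min(1, 2 * min(p_lower, p_upper)).  Never returns 0.
    """
    B = len(null_counts)
    p_lo = (1 + int(np.sum(null_counts <= observed))) / (B + 1)
    p_hi = (1 + int(np.sum(null_counts >= observed))) / (B + 1)
    return min(1.0, 2.0 * min(p_lo, p_hi)), p_lo, p_hi


def subsampling_null(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    target_n: int,
    observed: int,
    B: int = 1000,
    seed: int = 13,
    de_config: SubsampleDEConfig | None = None,
    stratify: str | None = None,
) -> NullDistribution:
    """Male-subsampling null for the diagnosis DEG count at female n.

    Draws ``B`` simple random subsamples (without replacement) of the male
    samples at size ``target_n``, runs the diagnosis DE pipeline per draw
    and records the DEG count.  ``observed`` is the female DEG count being
    calibrated.  ``stratify="diagnosis"`` balances draws within diagnosis
    (off by default: the draw is unrestricted random sampling).
    """
    cfg = de_config or SubsampleDEConfig()
    males = meta.index[meta["sex"] == "M"]
    males = [s for s in males if s in counts.columns]
    if target_n >= len(males):
        raise ValueError(
            f"target_n={target_n} must be smaller than the male sample count ({len(males)})"
        )
    rng = np.random.default_rng(seed)

    logcpm = weights = None
    if cfg.reuse_normalization:
        male_counts = counts[males]
        meta_m = meta.loc[males]
        kept = quantnorm.filter_by_expression(
            male_counts, meta_m, cfg.cpm_threshold, cfg.group_fraction, group="diagnosis"
        )
        male_counts = male_counts.loc[kept]
        factors = quantnorm.tmm_factors(male_counts)
        logcpm = quantnorm.log_cpm(male_counts, factors)
        spec = DesignSpec(model="diagnosis_by_sex", covariates=cfg.covariates)
        design, _ = diffexpr.build_design(meta_m, spec, None)
        weights = quantnorm.voom_weights(logcpm, design)

    null_counts = np.empty(B, dtype=int)
    for b in range(B):
        if stratify is not None:
            chosen = []
            strata = meta.loc[males, stratify]
            for level in sorted(set(strata)):
                pool = [s for s in males if strata[s] == level]
                n_level = int(round(target_n * len(pool) / len(males)))
                chosen.extend(rng.choice(pool, size=n_level, replace=False))
        else:
            chosen = list(rng.choice(males, size=target_n, replace=False))
        meta_sub = meta.loc[chosen]
        if cfg.reuse_normalization:
            lc = ExprMatrix(logcpm.values[chosen], kind="logCPM", note=logcpm.note)
            wt = quantnorm.WeightMatrix(weights.values[chosen])
            null_counts[b] = _dx_deg_count(lc, wt, meta_sub, cfg)
        else:
            null_counts[b] = _full_pipeline_count(counts[chosen], meta_sub, cfg)

    p2, p_lo, p_hi = empirical_p(null_counts, observed)
    return NullDistribution(
        counts=null_counts,
        observed=observed,
        p_two_sided=p2,
        p_lower=p_lo,
        p_upper=p_hi,
        seed=seed,
        subsample_size=target_n,
    )
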