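"""End-to-end orchestration of the sex-informed expression pipeline.

One configured run chains: synthetic data (or user tables) -> filtering and
normalization -> per-region sex DE and diagnosis-by-sex DE -> RXE dosage and
XCI enrichment -> stringent sex-specific filter -> male-subsampling null ->
cross-region concordance.  Every stage writes a stable-named TSV into the
output directory, the resolved configuration (seeds included) is captured as
YAML, and a run log records feature counts in/out at each filter.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import concord, diffexpr, dosage, quantnorm, sexspec, synth
from .diffexpr import DesignSpec
from .synth import SimConfig


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run; every seed is explicit."""

    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None  # read counts/meta/annotation instead of simulating
    out_dir: str = "pipeline_out"
    cpm_threshold: float = 10.0
    group_fraction: float = 0.7
    prior_count: float = 0.5
    n_hidden: int | str = "auto"
    covariates: list = field(default_factory=lambda: ["snpPC1", "snpPC2", "snpPC3"])
    fdr: float = 0.05
    presence_fraction: float = 0.2
    subsample_B: int = 100
    subsample_seed: int = 13
    hidden_seed: int = 1
    run_subsampling: bool = True
    run_dosage: bool = True
    run_sexspec: bool = True
    run_concordance: bool = True

    def validate(self):
        if self.input_dir is not None and not os.path.isdir(self.input_dir):
            raise ValueError(f"input_dir {self.input_dir!r} does not exist")
        if self.subsample_B < 1:
            raise ValueError("subsample_B must be >= 1")


def _region_de(counts, meta, annotation, cfg, log):
    """Per-region normalization, sex DE, diagnosis-by-sex DE and residuals."""
    results = {}
    for region in sorted(set(meta["region"])):
        meta_r = meta[meta["region"] == region]
        counts_r = counts[meta_r.index]
        kept = quantnorm.filter_by_expression(
            counts_r, meta_r, cfg.cpm_threshold, cfg.group_fraction, group="sex"
        )
        log.append(
            f"[{region}] expression filter: {len(kept)}/{counts_r.shape[0]} genes kept"
        )
        counts_r = counts_r.loc[kept]
        factors = quantnorm.tmm_factors(counts_r)
        logcpm = quantnorm.log_cpm(counts_r, factors, cfg.prior_count)

        qc_covs = [c for c in meta_r.columns if c.startswith("qc")]
        screened = diffexpr.screen_covariates(
            logcpm, meta_r, candidates=qc_covs + cfg.covariates
        )
        covs = [c for c in cfg.covariates if c in meta_r.columns]
        covs += [c for c in screened if c not in covs]
        log.append(f"[{region}] covariates used: {covs}")

        null_spec = DesignSpec(model="null_minimal", covariates=covs)
        null_design, _ = diffexpr.build_design(meta_r, null_spec, None)
        factors_sv = diffexpr.estimate_hidden_factors(
            logcpm, null_design, k=cfg.n_hidden, seed=cfg.hidden_seed
        )
        log.append(f"[{region}] hidden factors: k={factors_sv.shape[1]}")

        sex_spec = DesignSpec(model="sex", covariates=covs)
        design, contrast = diffexpr.build_design(meta_r, sex_spec, factors_sv)
        weights = quantnorm.voom_weights(logcpm, design)
        de_sex = diffexpr.fit_moderated(logcpm, weights, design, contrast)
        log.append(
            f"[{region}] sex DE: {int((de_sex.table['adj.P.Val'] < cfg.fdr).sum())} DEGs"
        )

        de_dx = {}
        for sex in ("F", "M"):
            meta_s = meta_r[meta_r["sex"] == sex]
            lc_s = quantnorm.ExprMatrix(logcpm.values[meta_s.index], "logCPM")
            spec_s = DesignSpec(model="diagnosis_by_sex", covariates=covs)
            null_s, _ = diffexpr.build_design(
                meta_s, DesignSpec(model="null_minimal", covariates=covs), None
            )
            sv_s = diffexpr.estimate_hidden_factors(
                lc_s, null_s, k=cfg.n_hidden, seed=cfg.hidden_seed
            )
            d_s, c_s = diffexpr.build_design(meta_s, spec_s, sv_s)
            w_s = quantnorm.voom_weights(lc_s, d_s)
            de_dx[sex] = diffexpr.fit_moderated(lc_s, w_s, d_s, c_s)
            log.append(
                f"[{region}] diagnosis DE ({sex}): "
                f"{int((de_dx[sex].table['adj.P.Val'] < cfg.fdr).sum())} DEGs"
            )

        # residualized expression under the minimal null (no sex, no diagnosis)
        null_min, _ = diffexpr.build_design(meta_r, null_spec, factors_sv)
        resid, flagged = diffexpr.residualize(logcpm, null_min)
        if flagged:
            log.append(f"[{region}] residualization flagged {len(flagged)} genes")

        results[region] = {
            "counts": counts_r,
            "meta": meta_r,
            "logcpm": logcpm,
            "de_sex": de_sex,
            "de_dx": de_dx,
            "resid": resid,
            "covs": covs,
        }
    return results


def run_pipeline(cfg: PipelineConfig):
    """Run the configured pipeline; returns the output directory path."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    log: list[str] = []

    if cfg.input_dir is not None:
        counts, meta, annotation = synth.read_dataset(cfg.input_dir)
        truth = None
        log.append(f"loaded dataset from {cfg.input_dir}")
    else:
        counts, meta, annotation, truth = synth.simulate_dataset(cfg.sim)
        log.append(
            f"simulated dataset: {counts.shape[0]} genes x {counts.shape[1]} samples, "
            f"seed={cfg.sim.seed}"
        )

    regions = _region_de(counts, meta, annotation, cfg, log)
    for region, r in regions.items():
        r["de_sex"].table.to_csv(
            os.path.join(cfg.out_dir, f"de_sex_{region}.tsv"), sep="\t"
        )
        for sex, de in r["de_dx"].items():
            de.table.to_csv(
                os.path.join(cfg.out_dir, f"de_dx_{region}_{sex}.tsv"), sep="\t"
            )

    if cfg.run_dosage:
        eff, retained = quantnorm.effective_lengths(
            annotation, cfg.sim.mean_fragment_length
        )
        log.append(f"effective lengths: {int(retained.sum())}/{len(retained)} genes kept")
        rxe_tables = []
        for region, r in regions.items():
            genes = [g for g in r["counts"].index if retained.get(g, False)]
            tpm = quantnorm.compute_tpm(r["counts"].loc[genes], eff)
            rxe = dosage.compute_rxe(
                tpm, annotation, meta=r["meta"], presence_fraction=cfg.presence_fraction
            )
            rxe_tables.append(rxe)
        rxe_all = pd.concat(rxe_tables)
        rxe_all.to_csv(os.path.join(cfg.out_dir, "rxe.tsv"), sep="\t")

        # XCI enrichment over X-linked tested genes, pooled across regions
        x_genes = set(
            annotation.index[(annotation["chromosome"] == "X")]
        )
        tested_x = set().union(*(set(r["counts"].index) for r in regions.values())) & x_genes
        if tested_x:
            fem, mal = set(), set()
            for r in regions.values():
                sig = r["de_sex"].table[r["de_sex"].table["adj.P.Val"] < cfg.fdr]
                fem |= set(sig.index[sig["logFC"] < 0]) & tested_x
                mal |= set(sig.index[sig["logFC"] > 0]) & tested_x
            enrich = dosage.xci_enrichment(
                {"female-bias": fem, "male-bias": mal, "all": fem | mal},
                annotation,
                tested_x,
            )
            enrich.to_csv(os.path.join(cfg.out_dir, "xci_enrichment.tsv"), index=False, sep="\t")
            log.append(f"XCI enrichment over {len(tested_x)} tested X genes")

    if cfg.run_sexspec:
        for region, r in regions.items():
            fem_rep, mal_rep = sexspec.stringent_sex_filter(
                r["de_dx"]["F"], r["de_dx"]["M"], r["resid"], r["meta"], fdr=cfg.fdr
            )
            rows = []
            for rep in (fem_rep, mal_rep):
                for g in sorted(rep.stage_a):
                    rows.append(
                        {
                            "region": region,
                            "sex": rep.sex,
                            "gene_id": g,
                            "kept": g in rep.stage_c,
                            "removal_reason": rep.removal_reason.get(g, ""),
                        }
                    )
            pd.DataFrame(
                rows, columns=["region", "sex", "gene_id", "kept", "removal_reason"]
            ).to_csv(
                os.path.join(cfg.out_dir, f"sexspec_filter_{region}.tsv"),
                sep="\t",
                index=False,
            )
            log.append(
                f"[{region}] stringent filter F: {fem_rep.counts}, M: {mal_rep.counts}"
            )

    do_subsampling = cfg.run_subsampling
    if do_subsampling:
        region = sorted(regions)[0]
        r = regions[region]
        n_f = int((r["meta"]["sex"] == "F").sum())
        n_m = int((r["meta"]["sex"] == "M").sum())
        if n_f >= n_m:
            log.append(
                f"[{region}] subsampling skipped: female n ({n_f}) not smaller "
                f"than male n ({n_m})"
            )
            do_subsampling = False
    if do_subsampling:
        obs = int((r["de_dx"]["F"].table["adj.P.Val"] < cfg.fdr).sum())
        null = sexspec.subsampling_null(
            counts[r["meta"].index],
            r["meta"],
            target_n=n_f,
            observed=obs,
            B=cfg.subsample_B,
            seed=cfg.subsample_seed,
            de_config=sexspec.SubsampleDEConfig(covariates=r["covs"]),
        )
        pd.DataFrame({"deg_count": null.counts}).to_csv(
            os.path.join(cfg.out_dir, "subsample_null.tsv"), sep="\t", index=False
        )
        log.append(
            f"[{region}] subsampling null: observed={obs}, "
            f"median null={int(np.median(null.counts))}, p={null.p_two_sided:.3f}"
        )

    if cfg.run_concordance and len(regions) >= 2:
        rows = []
        names = sorted(regions)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = regions[names[i]], regions[names[j]]
                universe = set(a["de_sex"].table.index) | set(b["de_sex"].table.index)
                try:
                    rep = concord.replication_stats(
                        a["de_sex"], b["de_sex"], universe
                    )
                except ValueError as exc:
                    log.append(f"concordance {names[i]} vs {names[j]} skipped: {exc}")
                    continue
                rows.append(
                    {
                        "region_a": names[i],
                        "region_b": names[j],
                        "pi1": rep.pi1,
                        "spearman_rho": rep.spearman_rho,
                        "sign_concordance": rep.sign_concordance,
                        "overlap_odds_ratio": rep.overlap_odds_ratio,
                        "overlap_p": rep.overlap_p,
                        "n_features": rep.n_features,
                    }
                )
        pd.DataFrame(rows).to_csv(
            os.path.join(cfg.out_dir, "concordance.tsv"), sep="\t", index=False
        )

    with open(os.path.join(cfg.out_dir, "resolved_config.yaml"), "w") as fh:
        d = dataclasses.asdict(cfg)
        yaml.safe_dump(d, fh, default_flow_style=False)
    with open(os.path.join(cfg.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return cfg.out_dir
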