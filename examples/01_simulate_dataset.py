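"""Generate a synthetic brain-cohort dataset with planted ground truth.

A two-region cohort with male-majority sampling, X/Y/PAR gene geography,
XCI classes, planted sex effects and a hidden batch factor.
"""

from sexdimorph import SimConfig, simulate_dataset

cfg = SimConfig(
    n_genes=1000,
    n_per_cell={"F": 12, "M": 27},
    regions=("caudate", "hippocampus"),
    rxe_factor=0.8,  # male-SZ X dosage reduced in the hippocampus
    seed=1,
)
counts, meta, annotation, truth = simulate_dataset(cfg)

print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples")
print("samples per (region, sex, diagnosis):")
print(meta.groupby(["region", "sex", "diagnosis"]).size())
print("gene geography:", annotation["chromosome"].value_counts().to_dict())
print("XCI classes on X:", annotation.loc[annotation["chromosome"] == "X",
                                          "xci_status"].value_counts().to_dict())
print(f"{len(truth.sex_biased_genes)} genes carry a true sex effect "
      "(planted autosomal log-fold-changes plus escape/variable/Y genes)")
print("planted X-dosage shifts:", truth.rxe_shift)
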