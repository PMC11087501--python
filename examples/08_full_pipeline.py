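"""One configured end-to-end run.

Chains simulation -> normalization -> per-region sex and diagnosis DE ->
RXE dosage and XCI enrichment -> stringent sex-specific filter ->
subsampling null -> cross-region concordance, writing TSV artifacts, a run
log and the resolved configuration.  Equivalent shell command:

    sexdimorph run --seed 8 --out pipeline_out
"""

from sexdimorph import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimConfig(
        n_genes=800,
        n_per_cell={"F": 12, "M": 24},
        regions=("caudate", "hippocampus"),
        rxe_factor=0.8,
        seed=8,
    ),
    out_dir="scratch/example_pipeline",
    subsample_B=49,
    n_hidden="auto",
)
out = run_pipeline(cfg)

print(f"artifacts in {out}:")
import os

for name in sorted(os.listdir(out)):
    print(" ", name)
print()
print("run log:")
with open(os.path.join(out, "run_log.txt")) as fh:
    print(fh.read())
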