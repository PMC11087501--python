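"""Synthetic bulk RNA-seq datasets with sex-structured expression.

Generates gene-level count matrices, sample metadata, gene annotation and a
ground-truth record emulating a postmortem brain cohort with two sexes, two
diagnosis groups (control / schizophrenia) and several brain regions sampled
from overlapping donors.  The generative model is negative binomial
(gamma-Poisson) on a log2 mean that stacks:

* a per-gene baseline (log-normal spread around a global scale),
* chromosome geography: autosomes, X (with pseudoautosomal PAR genes), Y,
* X-inactivation classes on X: *escape* genes expressed from both female X
  copies (female-biased), *variable escape* (weaker female bias), *inactive*
  (dosage compensated, no sex difference),
* Y genes expressed in males only; PAR genes expressed equally in both sexes,
* planted sex effects on a minority of autosomal genes,
* sex-specific diagnosis effects per region,
* an optional multiplicative X-dosage reduction in one (sex, diagnosis,
  region) group — the "relative X expression" shift,
* a hidden batch factor and log-normal library-size variation.

Everything planted is recorded in :class:`GroundTruth` so downstream stages
can be scored against the truth.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

AUTOSOMES = tuple(str(c) for c in range(1, 23))
XCI_CLASSES = ("escape", "variable", "inactive")

_REQUIRED_META_COLS = ("sample_id", "donor_id", "sex", "diagnosis", "region", "age")
_REQUIRED_ANNOT_COLS = ("gene_id", "chromosome", "gene_length", "par_flag", "xci_status")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Fractions: ``chrom_props`` over all genes, ``xci_class_probs`` over
    non-PAR X genes; both must sum to 1.  ``n_per_cell`` is the number of
    samples in every (sex x diagnosis x region) cell; donors are shared
    across regions (one sample per donor per region), as in repeated-measures
    brain cohorts.  ``dispersion`` is the NB dispersion phi with
    Var = mu + phi * mu^2.  Effect sizes are log2 fold changes.
    """

    n_genes: int = 2000
    chrom_props: dict = field(
        default_factory=lambda: {"autosome": 0.90, "X": 0.06, "Y": 0.02, "PAR": 0.02}
    )
    # close to the published XCI catalogue proportions 99/101/431 of 631
    xci_class_probs: dict = field(
        default_factory=lambda: {"escape": 0.157, "variable": 0.160, "inactive": 0.683}
    )
    regions: tuple = ("caudate", "dlpfc", "hippocampus")
    # samples per (sex x diagnosis x region) cell; a dict keyed by sex
    # ({"F": 12, "M": 27}) emulates male-majority cohorts
    n_per_cell: int | dict = 25
    baseline_mean: float = 200.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.1
    sex_frac: float = 0.05
    sex_logfc: float = 1.0
    escape_shift: float = 0.4
    variable_shift: float = 0.2
    dx_frac_female: float = 0.01
    dx_frac_male: float = 0.01
    dx_frac_shared: float = 0.01
    dx_logfc: float = 1.0
    rxe_factor: float = 1.0
    rxe_region: str = "hippocampus"
    rxe_sex: str = "M"
    rxe_diagnosis: str = "SZ"
    batch_scale: float = 0.3
    library_size_log_sd: float = 0.3
    mean_fragment_length: float = 200.0
    n_covariates: int = 4
    seed: int = 0

    def validate(self) -> None:
        for name, fracs in (("chrom_props", self.chrom_props), ("xci_class_probs", self.xci_class_probs)):
            vals = np.array(list(fracs.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{name}: fractions must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name}: fractions must sum to 1 (got {vals.sum()!r})")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.library_size_log_sd < 0:
            raise ValueError("library_size_log_sd must be >= 0")
        if not 0 <= self.sex_frac <= 1:
            raise ValueError("sex_frac must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        cells = (
            self.n_per_cell.values()
            if isinstance(self.n_per_cell, dict)
            else [self.n_per_cell]
        )
        if any(n < 1 for n in cells):
            raise ValueError(
                "n_per_cell must be >= 1: every (sex x diagnosis x region) cell "
                "needs samples for the downstream designs"
            )
        if isinstance(self.n_per_cell, dict) and set(self.n_per_cell) != {"F", "M"}:
            raise ValueError("n_per_cell dict must have exactly the keys 'F' and 'M'")
        if self.rxe_factor != 1.0 and self.rxe_region not in self.regions:
            raise ValueError(f"rxe_region {self.rxe_region!r} not among regions {self.regions}")


@dataclass
class GroundTruth:
    """Planted effects, one record per gene plus per-sample factors."""

    sex_logfc: pd.Series  # log2(male/female), per gene
    dx_logfc: pd.DataFrame  # long: gene_id, region, sex, logfc
    sex_biased_genes: set
    rxe_shift: dict  # (sex, diagnosis, region) -> log2 shift of X-gene means
    hidden_factor: pd.Series  # per sample


def _largest_remainder(total: int, props: dict) -> dict:
    keys = list(props)
    raw = np.array([props[k] for k in keys]) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base))


def simulate_dataset(config: SimConfig):
    """Draw one dataset; bit-identical for a fixed config (seed included).

    Returns ``(counts, meta, annotation, truth)`` where counts is a
    genes x samples integer DataFrame, meta and annotation are DataFrames
    (one row per sample / gene), and truth is a :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    # --- gene annotation ---------------------------------------------------
    n_by_class = _largest_remainder(G, config.chrom_props)
    gene_ids = [f"G{i:05d}" for i in range(G)]
    chrom = np.empty(G, dtype=object)
    par = np.zeros(G, dtype=bool)
    xci = np.full(G, "not_applicable", dtype=object)
    i = 0
    n_aut = n_by_class.get("autosome", 0)
    chrom[i : i + n_aut] = [AUTOSOMES[j % 22] for j in range(n_aut)]
    i += n_aut
    n_x = n_by_class.get("X", 0)
    chrom[i : i + n_x] = "X"
    if n_x:
        xci[i : i + n_x] = rng.choice(
            XCI_CLASSES, size=n_x, p=[config.xci_class_probs[c] for c in XCI_CLASSES]
        )
    x_slice = slice(i, i + n_x)
    i += n_x
    n_par = n_by_class.get("PAR", 0)
    chrom[i : i + n_par] = "X"
    par[i : i + n_par] = True
    xci[i : i + n_par] = "escape"  # PAR loci escape inactivation by construction
    i += n_par
    n_y = n_by_class.get("Y", 0)
    chrom[i : i + n_y] = "Y"
    i += n_y
    assert i == G

    gene_length = np.maximum(
        np.round(rng.lognormal(mean=np.log(2500.0), sigma=0.6, size=G)).astype(int), 250
    )
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chrom,
            "gene_length": gene_length,
            "par_flag": par,
            "xci_status": xci,
        }
    ).set_index("gene_id")

    # --- samples and donors ------------------------------------------------
    rows = []
    if isinstance(config.n_per_cell, dict):
        n_of = dict(config.n_per_cell)
    else:
        n_of = {"F": config.n_per_cell, "M": config.n_per_cell}
    donor_age = {}
    donor_snp = {}
    for sex in ("F", "M"):
        for dx in ("CTL", "SZ"):
            for d in range(n_of[sex]):
                donor = f"D{sex}{dx}{d:03d}"
                donor_age[donor] = rng.uniform(17.0, 80.0)
                donor_snp[donor] = rng.normal(size=3)
    for region in config.regions:
        for sex in ("F", "M"):
            for dx in ("CTL", "SZ"):
                for d in range(n_of[sex]):
                    donor = f"D{sex}{dx}{d:03d}"
                    rows.append(
                        {
                            "sample_id": f"{donor}_{region}",
                            "donor_id": donor,
                            "sex": sex,
                            "diagnosis": dx,
                            "region": region,
                            "age": donor_age[donor],
                            **{f"snpPC{k+1}": donor_snp[donor][k] for k in range(3)},
                        }
                    )
    meta = pd.DataFrame(rows).set_index("sample_id")
    S = len(meta)
    for c in range(config.n_covariates):
        meta[f"qc{c+1}"] = rng.normal(size=S)

    # --- planted effects ----------------------------------------------------
    is_aut = annotation["chromosome"].isin(AUTOSOMES).to_numpy()
    is_y = (annotation["chromosome"] == "Y").to_numpy()
    is_x_npar = ((annotation["chromosome"] == "X") & ~annotation["par_flag"]).to_numpy()

    sex_lfc = np.zeros(G)  # log2(male / female)
    aut_idx = np.flatnonzero(is_aut)
    n_sex = int(round(config.sex_frac * len(aut_idx)))
    planted_sex = rng.choice(aut_idx, size=n_sex, replace=False) if n_sex else np.array([], int)
    sex_lfc[planted_sex] = config.sex_logfc * rng.choice([-1.0, 1.0], size=n_sex)
    # escape genes expressed from both female X copies -> female bias
    esc = is_x_npar & (xci == "escape")
    var = is_x_npar & (xci == "variable")
    sex_lfc[esc] -= config.escape_shift
    sex_lfc[var] -= config.variable_shift
    y_female_log2_drop = np.log2(1e-4)  # Y genes effectively silent in females
    sex_lfc[is_y] = -y_female_log2_drop

    dx_records = []
    dx_lfc = {}  # (region, sex) -> per-gene array
    for region in config.regions:
        free = aut_idx.copy()
        rng.shuffle(free)
        n_sh = int(round(config.dx_frac_shared * len(aut_idx)))
        n_f = int(round(config.dx_frac_female * len(aut_idx)))
        n_m = int(round(config.dx_frac_male * len(aut_idx)))
        shared, fem, mal = free[:n_sh], free[n_sh : n_sh + n_f], free[n_sh + n_f : n_sh + n_f + n_m]
        for sex in ("F", "M"):
            arr = np.zeros(G)
            own = fem if sex == "F" else mal
            for idx_set in (shared, own):
                if len(idx_set):
                    arr[idx_set] = config.dx_logfc * rng.choice([-1.0, 1.0], size=len(idx_set))
            dx_lfc[(region, sex)] = arr
            for g in np.flatnonzero(arr):
                dx_records.append(
                    {"gene_id": gene_ids[g], "region": region, "sex": sex, "logfc": arr[g]}
                )

    hidden = rng.normal(size=S)
    batch_loadings = rng.normal(scale=config.batch_scale, size=G) if config.batch_scale > 0 else np.zeros(G)
    lib_factor = np.exp(rng.normal(scale=config.library_size_log_sd, size=S))

    # --- log2 mean matrix ---------------------------------------------------
    base = np.log2(config.baseline_mean) + rng.normal(scale=config.baseline_log2_sd, size=G)
    log2mu = np.tile(base[:, None], (1, S)).astype(float)
    male = (meta["sex"] == "M").to_numpy()
    sz = (meta["diagnosis"] == "SZ").to_numpy()
    applied_sex = np.where(is_y, 0.0, sex_lfc)  # Y handled by silencing females
    log2mu[:, male] += applied_sex[:, None]
    log2mu[np.ix_(is_y, ~male)] += y_female_log2_drop
    for region in config.regions:
        in_r = (meta["region"] == region).to_numpy()
        for sex, sex_mask in (("F", ~male), ("M", male)):
            cols = in_r & sex_mask & sz
            if cols.any():
                log2mu[:, cols] += dx_lfc[(region, sex)][:, None]
    rxe_shift = {}
    if config.rxe_factor != 1.0:
        cols = (
            (meta["region"] == config.rxe_region)
            & (meta["sex"] == config.rxe_sex)
            & (meta["diagnosis"] == config.rxe_diagnosis)
        ).to_numpy()
        log2mu[np.ix_(is_x_npar, cols)] += np.log2(config.rxe_factor)
        rxe_shift[(config.rxe_sex, config.rxe_diagnosis, config.rxe_region)] = np.log2(
            config.rxe_factor
        )
    log2mu += batch_loadings[:, None] * hidden[None, :]

    mu = np.exp2(log2mu) * lib_factor[None, :]
    # gamma-Poisson: Var = mu + phi mu^2
    lam = rng.gamma(shape=1.0 / config.dispersion, scale=mu * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=meta.index)

    truth = GroundTruth(
        sex_logfc=pd.Series(sex_lfc, index=counts_df.index, name="sex_logfc"),
        dx_logfc=pd.DataFrame(dx_records, columns=["gene_id", "region", "sex", "logfc"]),
        sex_biased_genes={gene_ids[g] for g in np.flatnonzero(sex_lfc != 0.0)},
        rxe_shift=rxe_shift,
        hidden_factor=pd.Series(hidden, index=meta.index, name="hidden_factor"),
    )
    return counts_df, meta, annotation, truth


# --- I/O -------------------------------------------------------------------

def write_dataset(path, counts, meta, annotation, truth=None, config=None, counts_format="tsv"):
    """Write the dataset as plain-text tables under ``path``.

    Counts as TSV (gene rows, sample columns) or MatrixMarket with row/column
    name sidecars.  The resolved config (including the seed) is written as
    YAML when given.
    """
    os.makedirs(path, exist_ok=True)
    if counts_format == "tsv":
        counts.to_csv(os.path.join(path, "counts.tsv"), sep="\t")
    elif counts_format == "mtx":
        scipy.io.mmwrite(
            os.path.join(path, "counts.mtx"), scipy.sparse.csr_matrix(counts.to_numpy())
        )
        with open(os.path.join(path, "counts.mtx.rownames"), "w") as fh:
            fh.write("\n".join(counts.index) + "\n")
        with open(os.path.join(path, "counts.mtx.colnames"), "w") as fh:
            fh.write("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown counts_format {counts_format!r}")
    meta.reset_index().to_csv(os.path.join(path, "meta.tsv"), sep="\t", index=False)
    annotation.reset_index().to_csv(os.path.join(path, "annotation.tsv"), sep="\t", index=False)
    if truth is not None:
        truth.sex_logfc.to_csv(os.path.join(path, "truth_sex_logfc.tsv"), sep="\t")
        truth.dx_logfc.to_csv(os.path.join(path, "truth_dx_logfc.tsv"), sep="\t", index=False)
        truth.hidden_factor.to_csv(os.path.join(path, "truth_hidden_factor.tsv"), sep="\t")
        with open(os.path.join(path, "truth_rxe_shift.tsv"), "w") as fh:
            fh.write("sex\tdiagnosis\tregion\tlog2_shift\n")
            for (sex, dx, region), shift in truth.rxe_shift.items():
                fh.write(f"{sex}\t{dx}\t{region}\t{shift}\n")
    if config is not None:
        with open(os.path.join(path, "config.yaml"), "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, default_flow_style=False)


def read_counts(path):
    """Read a counts table (TSV or MatrixMarket with name sidecars)."""
    if str(path).endswith(".mtx"):
        mat = scipy.io.mmread(path).toarray().astype(np.int64)
        with open(str(path) + ".rownames") as fh:
            genes = [line.strip() for line in fh if line.strip()]
        with open(str(path) + ".colnames") as fh:
            samples = [line.strip() for line in fh if line.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(
                f"counts matrix {mat.shape} does not match sidecar names "
                f"({len(genes)} genes x {len(samples)} samples)"
            )
        return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in counts: {dup!r}")
    return df


def read_meta(path):
    meta = pd.read_csv(path, sep="\t")
    for col in _REQUIRED_META_COLS:
        if col not in meta.columns:
            raise ValueError(f"metadata file {path}: missing required column {col!r}")
    bad = set(meta["sex"]) - {"F", "M"}
    if bad:
        raise ValueError(f"metadata: sex must be F or M, got {sorted(bad)}")
    bad = set(meta["diagnosis"]) - {"CTL", "SZ"}
    if bad:
        raise ValueError(f"metadata: diagnosis must be CTL or SZ, got {sorted(bad)}")
    return meta.set_index("sample_id")


def read_annotation(path):
    annot = pd.read_csv(path, sep="\t")
    for col in _REQUIRED_ANNOT_COLS:
        if col not in annot.columns:
            raise ValueError(f"annotation file {path}: missing required column {col!r}")
    annot["chromosome"] = annot["chromosome"].astype(str)
    annot["par_flag"] = annot["par_flag"].astype(bool)
    if (annot["gene_length"] < 1).any():
        bad = annot.loc[annot["gene_length"] < 1, "gene_id"].iloc[0]
        raise ValueError(f"annotation: gene_length < 1 for {bad!r}")
    off_x = (annot["xci_status"] != "not_applicable") & (annot["chromosome"] != "X")
    if off_x.any():
        bad = annot.loc[off_x, "gene_id"].iloc[0]
        raise ValueError(f"annotation: xci_status set for non-X gene {bad!r}")
    return annot.set_index("gene_id")


def read_dataset(path, counts_format="tsv"):
    """Inverse of :func:`write_dataset` for the three primary tables."""
    counts_file = os.path.join(path, "counts.mtx" if counts_format == "mtx" else "counts.tsv")
    counts = read_counts(counts_file)
    meta = read_meta(os.path.join(path, "meta.tsv"))
    annotation = read_annotation(os.path.join(path, "annotation.tsv"))
    return counts, meta, annotation
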