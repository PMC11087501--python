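"""Expression units and preprocessing.

Effective gene lengths, TPM, the CPM-based low-expression filter, TMM
library-size normalization, log-CPM and mean-variance precision weights
(the voom approach: model the square-root residual standard deviation as a
smooth function of log-count abundance and weight each observation by the
inverse fourth power of its predicted square-root sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class ExprMatrix:
    """A genes x samples real-valued matrix with a unit tag.

    ``kind`` is one of ``TPM``, ``logCPM``, ``residual_z``; ``note`` records
    the filter/normalization provenance.
    """

    values: pd.DataFrame
    kind: str
    note: str = ""

    @property
    def genes(self):
        return self.values.index

    @property
    def samples(self):
        return self.values.columns


@dataclass
class NormFactors:
    factors: pd.Series  # per-sample TMM factor, geometric mean 1
    reference: str  # reference sample id


@dataclass
class WeightMatrix:
    values: pd.DataFrame  # genes x samples, positive precision weights


def effective_lengths(annotation: pd.DataFrame, mean_fragment_length: float):
    """Effective length = gene length - mean fragment length + 1.

    Genes whose effective length is <= 1 are masked out (they cannot be
    quantified at this fragment length).  Returns ``(eff_len, retained)``
    as aligned Series over the annotation index.
    """
    if mean_fragment_length <= 0:
        raise ValueError("mean_fragment_length must be > 0")
    eff = annotation["gene_length"].astype(float) - mean_fragment_length + 1.0
    retained = eff > 1.0
    return eff, retained


def compute_tpm(counts: pd.DataFrame, eff_len: pd.Series) -> ExprMatrix:
    """Transcripts per million from counts and effective lengths.

    Per sample: rate_g = count_g / eff_len_g, TPM_g = 1e6 * rate_g / sum(rate).
    Every column of the result sums to 1e6 over the retained genes.
    """
    eff = eff_len.reindex(counts.index)
    if eff.isna().any():
        missing = counts.index[eff.isna()][0]
        raise ValueError(f"no effective length for gene {missing!r}")
    if (eff <= 1.0).any():
        bad = counts.index[eff <= 1.0][0]
        raise ValueError(f"gene {bad!r} has effective length <= 1; mask it out first")
    rate = counts.to_numpy(dtype=float) / eff.to_numpy()[:, None]
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        bad = counts.columns[np.flatnonzero(denom <= 0)[0]]
        raise ValueError(f"sample {bad!r} has zero total expression; TPM undefined")
    tpm = 1e6 * rate / denom[None, :]
    return ExprMatrix(
        pd.DataFrame(tpm, index=counts.index, columns=counts.columns), kind="TPM"
    )


def cpm(counts: pd.DataFrame, lib_sizes=None) -> pd.DataFrame:
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    return counts / lib * 1e6


def filter_by_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    cpm_threshold: float = 10.0,
    group_fraction: float = 0.7,
    group: str = "sex",
) -> pd.Index:
    """Low-expression filter: keep genes above a CPM floor in enough samples.

    A gene is retained iff the number of samples (across *all* samples) with
    CPM >= ``cpm_threshold`` is at least ``ceil(group_fraction * smallest
    group size)``, the smallest group taken over the levels of ``group``
    (default sex, i.e. the female sample size in male-majority cohorts).
    """
    if group not in meta.columns:
        raise ValueError(f"grouping column {group!r} not in metadata")
    sizes = meta.loc[counts.columns, group].value_counts()
    if (sizes == 0).any() or sizes.empty:
        raise ValueError(f"empty group level for {group!r}")
    quota = math.ceil(group_fraction * sizes.min())
    c = cpm(counts)
    n_ok = (c.to_numpy() >= cpm_threshold).sum(axis=1)
    return counts.index[n_ok >= quota]


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m=0.30, trim_a=0.05):
    """Trimmed weighted mean of M-values for one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return None
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    n = len(m)
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any():
        return 0.0
    # inverse asymptotic variance of M (delta method)
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    return float(np.sum(w[sel] * m[sel]) / np.sum(w[sel]))


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Reference sample: the one whose 75th-percentile CPM is closest to the
    mean 75th percentile.  Genes with a zero count in either member of a
    pair are excluded from that pair's M/A values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.columns[np.flatnonzero(lib <= 0)[0]]
        raise ValueError(f"sample {bad!r} has zero library size")
    mat = counts.to_numpy()
    q75 = np.percentile(mat / lib[None, :] * 1e6, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = mat[:, ref_idx]
    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        val = _tmm_pair(mat[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        if val is None:
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no co-expressed genes with the reference"
            )
        logf[j] = val
    factors = np.exp2(logf)
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        pd.Series(factors, index=counts.columns, name="tmm_factor"),
        reference=counts.columns[ref_idx],
    )


def log_cpm(counts: pd.DataFrame, factors: NormFactors | None = None, prior_count: float = 0.5) -> ExprMatrix:
    """log2 counts per million on TMM-effective library sizes.

    log2((count + prior) / (effective library + 2 * prior) * 1e6), effective
    library = raw library size x TMM factor.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if factors is not None:
        lib = lib * factors.factors.reindex(counts.columns).to_numpy()
    with np.errstate(divide="ignore"):  # prior_count=0 maps zero counts to -inf
        vals = np.log2(
            (counts.to_numpy(dtype=float) + prior_count) / (lib[None, :] + 2.0 * prior_count) * 1e6
        )
    return ExprMatrix(
        pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        kind="logCPM",
        note=f"prior_count={prior_count}, tmm={'yes' if factors is not None else 'no'}",
    )


def voom_weights(logcpm: ExprMatrix, design: pd.DataFrame, span: float = 0.5) -> WeightMatrix:
    """Mean-variance precision weights from the lowess sd trend.

    Per gene, an OLS fit of log-CPM on the design gives a residual sd; the
    lowess trend of sqrt(sd) against average log-CPM, evaluated at each
    observation's fitted value (clamped to the trend's range), yields the
    predicted sqrt-sd whose inverse fourth power is the weight.
    """
    if logcpm.kind != "logCPM":
        raise ValueError(f"expected logCPM input, got kind={logcpm.kind!r}")
    Y = logcpm.values.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    df = n - p
    if df < 2:
        raise ValueError(f"need >= 2 residual degrees of freedom, have {df}")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    sigma = np.sqrt(((Y - fitted) ** 2).sum(axis=1) / df)
    sqrt_sd = np.sqrt(sigma)
    avg = Y.mean(axis=1)
    trend = lowess(sqrt_sd, avg, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.clip(trend[:, 1], 1e-4, None)
    # np.interp clamps to the endpoints outside the trend's x-range
    pred = np.interp(fitted, tx, ty)
    w = pred ** -4.0
    return WeightMatrix(pd.DataFrame(w, index=logcpm.values.index, columns=logcpm.values.columns))
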