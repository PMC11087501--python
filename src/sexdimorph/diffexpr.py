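"""Linear-model differential expression with empirical-Bayes moderation.

Implements the four designs used for sex-informed brain transcriptomics:

* ``sex`` — sex + diagnosis + age + quality covariates + SNP PCs + hidden
  factors; the sex coefficient is the test target (male-bias positive).
* ``sex_x_region`` — sex x region interaction with main effects, diagnosis,
  age, covariates and SNP PCs (no hidden factors); repeated donors across
  regions are handled with donor-clustered robust standard errors.
* ``sex_x_diagnosis`` — sex x diagnosis interaction plus covariates and
  hidden factors.
* ``diagnosis_by_sex`` — the diagnosis model fit within one sex.

plus the matching null designs used for residualization:

* ``null_with_diagnosis`` — diagnosis + age + covariates + SNP PCs (no sex).
* ``null_minimal`` — age + covariates + SNP PCs + hidden factors (no sex,
  no diagnosis).

Per-gene fits are weighted least squares; residual variances are shrunk
toward a pooled prior by moment-matching a scaled-F distribution across
genes (the eBayes moderated t), p-values use the augmented degrees of
freedom, and BH FDR is appended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .quantnorm import ExprMatrix, WeightMatrix

MODELS = (
    "sex",
    "sex_x_region",
    "sex_x_diagnosis",
    "diagnosis_by_sex",
    "null_with_diagnosis",
    "null_minimal",
)


@dataclass
class DesignSpec:
    model: str
    covariates: list = field(default_factory=list)  # numeric metadata columns
    n_hidden: int | str = 0  # fixed k, or "auto" (resolved before build_design)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")


@dataclass
class ModerationParams:
    s0_squared: float  # prior residual variance
    d0: float  # prior degrees of freedom (may be inf)


@dataclass
class DEResult:
    """Per-feature table: logFC, AveExpr, t (or F), P.Value, adj.P.Val, direction."""

    table: pd.DataFrame
    moderation: ModerationParams | None
    contrast: list

    @property
    def significant(self):
        return self.table.index[self.table["adj.P.Val"] < 0.05]


# --- covariate screening ---------------------------------------------------

def _sample_pcs(values: np.ndarray, n_pcs: int) -> np.ndarray:
    """Principal-component scores per sample of a genes x samples matrix."""
    X = values.T - values.T.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s))
    return u[:, :k] * s[:k]


def screen_covariates(
    expr: ExprMatrix,
    meta: pd.DataFrame,
    candidates: list | None = None,
    n_pcs: int = 10,
    corr_threshold: float = 0.95,
    alpha: float = 0.05,
) -> list:
    """Select covariates correlated with expression in either sex.

    Candidates that are pairwise Pearson-correlated above ``corr_threshold``
    are reduced to the first of each correlated pair before testing.  Each
    survivor is correlated with the top expression PCs within each sex;
    covariates reaching Bonferroni-corrected p < ``alpha`` in either sex are
    selected.  Constant covariates are excluded with a warning.
    """
    if candidates is None:
        candidates = [
            c
            for c in meta.columns
            if pd.api.types.is_numeric_dtype(meta[c]) and c not in ("age",)
        ]
    meta = meta.loc[expr.samples]
    kept = []
    for c in candidates:
        v = meta[c].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            warnings.warn(f"covariate {c!r} is constant; excluded from screening")
            continue
        kept.append(c)
    # drop near-duplicates, keeping the first occurrence
    dedup = []
    for c in kept:
        if any(
            abs(np.corrcoef(meta[c], meta[d])[0, 1]) > corr_threshold for d in dedup
        ):
            continue
        dedup.append(c)
    if not dedup:
        return []
    pvals = {c: [] for c in dedup}
    for sex in ("F", "M"):
        idx = meta.index[meta["sex"] == sex]
        if len(idx) < 3:
            raise ValueError(f"need >= 3 samples of sex {sex!r} for covariate screening")
        pcs = _sample_pcs(expr.values[idx].to_numpy(dtype=float), n_pcs)
        for c in dedup:
            v = meta.loc[idx, c].to_numpy(dtype=float)
            for k in range(pcs.shape[1]):
                if np.std(pcs[:, k]) == 0:
                    continue
                _, p = stats.pearsonr(v, pcs[:, k])
                pvals[c].append(p)
    n_tests = sum(len(v) for v in pvals.values())
    return [c for c in dedup if min(pvals[c], default=1.0) * n_tests < alpha]


# --- hidden factors --------------------------------------------------------

def _residual_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def estimate_hidden_factors(
    expr: ExprMatrix,
    null_design: pd.DataFrame,
    k: int | str = "auto",
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Surrogates for unmodeled variation: PCs of the null-model residuals.

    With ``k="auto"`` the number of factors is chosen by parallel analysis
    (Buja-Eyuboglu): keep the leading PCs whose variance exceeds the
    ``quantile`` of the matched PC variance under independent within-gene
    permutation of the residuals; stop at the first failure.
    """
    X = null_design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("null design is rank deficient")
    df = n - p
    if isinstance(k, int) and k >= df:
        raise ValueError(f"k={k} >= residual degrees of freedom ({df})")
    R = _residual_matrix(expr.values.to_numpy(dtype=float), X)
    Rc = R - R.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(Rc.T, full_matrices=False)
    ev = s**2 / (Rc.shape[0] * max(Rc.shape[1] - 1, 1))
    if k == "auto":
        rng = np.random.default_rng(seed)
        kmax = min(df - 1, len(s), 10)
        null_ev = np.empty((n_perm, kmax))
        for b in range(n_perm):
            P = rng.permuted(Rc, axis=1)
            P -= P.mean(axis=1, keepdims=True)
            sp = np.linalg.svd(P.T, compute_uv=False)
            null_ev[b] = (sp**2 / (P.shape[0] * max(P.shape[1] - 1, 1)))[:kmax]
        thresh = np.quantile(null_ev, quantile, axis=0)
        k_res = 0
        for i in range(kmax):
            if ev[i] > thresh[i]:
                k_res += 1
            else:
                break
        k = k_res
    cols = [f"SV{i+1}" for i in range(k)]
    if k == 0:
        return pd.DataFrame(index=expr.samples, columns=cols, dtype=float)
    scores = u[:, :k] * s[:k]
    scores = scores / scores.std(axis=0, ddof=1)
    return pd.DataFrame(scores, index=expr.samples, columns=cols)


# --- design construction ---------------------------------------------------

def _dummies(series: pd.Series, reference: str, name: str) -> pd.DataFrame:
    levels = [reference] + sorted(set(series) - {reference})
    out = {}
    for lv in levels[1:]:
        out[f"{name}_{lv}"] = (series == lv).astype(float)
    return pd.DataFrame(out, index=series.index)


def build_design(
    meta: pd.DataFrame, spec: DesignSpec, factors: pd.DataFrame | None = None
):
    """Treatment-coded design matrix with intercept, plus contrast columns.

    References: female sex, CTL diagnosis and the alphabetically first
    region, so the sex coefficient is log2(male/female) — male-bias
    positive.  For interaction models the product columns are the test
    target.  Raises on rank deficiency, listing the aliased columns.
    """
    model = spec.model
    parts = [pd.DataFrame({"Intercept": np.ones(len(meta))}, index=meta.index)]
    contrast: list[str] = []

    needs_sex = model in ("sex", "sex_x_region", "sex_x_diagnosis")
    if model == "diagnosis_by_sex":
        sexes = set(meta["sex"])
        if len(sexes) != 1:
            raise ValueError(
                f"diagnosis_by_sex requires single-sex input; got sexes {sorted(sexes)}"
            )
    if needs_sex:
        parts.append(_dummies(meta["sex"], "F", "sex"))
    if model in ("sex", "sex_x_region", "diagnosis_by_sex", "null_with_diagnosis"):
        parts.append(_dummies(meta["diagnosis"], "CTL", "diagnosis"))
    if model == "sex_x_region":
        regions = _dummies(meta["region"], sorted(set(meta["region"]))[0], "region")
        parts.append(regions)
        inter = regions.mul(parts[1]["sex_M"], axis=0)
        inter.columns = [f"sex_M:{c}" for c in regions.columns]
        parts.append(inter)
        contrast = list(inter.columns)
    elif model == "sex_x_diagnosis":
        dx = _dummies(meta["diagnosis"], "CTL", "diagnosis")
        parts.append(dx)
        inter = dx.mul(parts[1]["sex_M"], axis=0)
        inter.columns = [f"sex_M:{c}" for c in dx.columns]
        parts.append(inter)
        contrast = list(inter.columns)
    elif model == "sex":
        contrast = ["sex_M"]
    elif model == "diagnosis_by_sex":
        contrast = ["diagnosis_SZ"]

    parts.append(meta[["age"]].astype(float))  # age enters every design
    for c in spec.covariates:
        if c not in meta.columns:
            raise ValueError(f"covariate {c!r} not in metadata")
        parts.append(meta[[c]].astype(float))
    if model in ("sex", "sex_x_diagnosis", "diagnosis_by_sex", "null_minimal"):
        if factors is not None and factors.shape[1] > 0:
            parts.append(factors.loc[meta.index].astype(float))
    design = pd.concat(parts, axis=1)

    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, r = np.linalg.qr(X)
        aliased = [design.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    return design, contrast


# --- moderated fits --------------------------------------------------------

def _wls_batch(Y: np.ndarray, W: np.ndarray, X: np.ndarray):
    """Batched per-gene weighted least squares.

    Returns (beta G x p, s2 residual variances, cov_unscaled G x p x p, df).
    """
    n, p = X.shape
    XtWX = np.einsum("sp,gs,sq->gpq", X, W, X, optimize=True)
    XtWy = np.einsum("sp,gs->gp", X, W * Y, optimize=True)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    fitted = beta @ X.T
    rss = (W * (Y - fitted) ** 2).sum(axis=1)
    df = n - p
    s2 = rss / df
    cov_unscaled = np.linalg.inv(XtWX)
    return beta, s2, cov_unscaled, df


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the limma recipe)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_prior(s2: np.ndarray, df: int) -> ModerationParams:
    """Moment-match a scaled-F prior to the residual variances (eBayes).

    Works on log(s^2); the spread in excess of the chi-square sampling
    variance determines the prior degrees of freedom d0, the location the
    prior variance s0^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return ModerationParams(float(np.median(s2[ok])) if ok.any() else 1.0, np.inf)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    evar = e.var(ddof=1) * (1.0 - 1.0 / len(e))  # slight shrink, as n -> inf irrelevant
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return ModerationParams(float(np.exp(ebar)), np.inf)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(s0sq, d0)


def posterior_variance(s2: np.ndarray, df: float, prior: ModerationParams) -> np.ndarray:
    """(d0 * s0^2 + d * s^2) / (d0 + d); collapses to s^2 at d0=0, s0^2 at d0=inf."""
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0_squared)
    if prior.d0 == 0:
        return np.asarray(s2, dtype=float)
    return (prior.d0 * prior.s0_squared + df * s2) / (prior.d0 + df)


def _cluster_robust_cov(Y, W, X, beta, cov_unscaled, clusters):
    """CR1 sandwich covariance per gene, clustered on donor."""
    n, p = X.shape
    resid = Y - beta @ X.T
    labels = pd.factorize(clusters)[0]
    G = labels.max() + 1
    meat = np.zeros((Y.shape[0], p, p))
    for c in range(G):
        idx = labels == c
        Xc = X[idx]
        u = np.einsum("sp,gs->gp", Xc, (W[:, idx] * resid[:, idx]), optimize=True)
        meat += u[:, :, None] * u[:, None, :]
    corr = (G / (G - 1.0)) * ((n - 1.0) / (n - p))
    V = cov_unscaled @ meat @ cov_unscaled * corr
    return V, G - 1


def fit_moderated(
    expr: ExprMatrix,
    weights: WeightMatrix | None,
    design: pd.DataFrame,
    contrast: list | str,
    d0: float | None = None,
    clusters: pd.Series | None = None,
) -> DEResult:
    """Weighted per-gene fits with moderated t (or F for multi-term contrasts).

    ``d0=None`` estimates the prior from the data; ``d0=0`` disables
    moderation (ordinary WLS t); ``d0=inf`` shrinks fully to the pooled
    prior variance.  With ``clusters`` given (donor ids), standard errors
    are donor-clustered CR1 sandwich estimates with n_clusters - 1 degrees
    of freedom and no variance moderation.
    """
    if isinstance(contrast, str):
        contrast = [contrast]
    for c in contrast:
        if c not in design.columns:
            raise ValueError(f"contrast column {c!r} not in design")
    Y = expr.values.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("zero residual degrees of freedom")
    W = np.ones_like(Y) if weights is None else weights.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(W)) or np.any(W <= 0):
        raise ValueError("weights must be finite and positive")
    beta, s2, cov_unscaled, df = _wls_batch(Y, W, X)
    cidx = [design.columns.get_loc(c) for c in contrast]

    if clusters is not None:
        V, df_t = _cluster_robust_cov(Y, W, X, beta, cov_unscaled, clusters.loc[design.index])
        prior = None
        if len(cidx) == 1:
            se = np.sqrt(V[:, cidx[0], cidx[0]])
            tstat = beta[:, cidx[0]] / se
            pval = 2.0 * stats.t.sf(np.abs(tstat), df_t)
            stat_col = tstat
        else:
            r = len(cidx)
            bc = beta[:, cidx]
            Vc = V[np.ix_(np.arange(len(beta)), cidx, cidx)]
            Fstat = np.einsum(
                "gi,gij,gj->g", bc, np.linalg.inv(Vc), bc, optimize=True
            ) / r
            pval = stats.f.sf(Fstat, r, df_t)
            stat_col = Fstat
    else:
        prior = estimate_prior(s2, df) if d0 is None else _fixed_prior(s2, df, d0)
        post = posterior_variance(s2, df, prior)
        total_df = df + (0.0 if np.isinf(prior.d0) else prior.d0)
        if len(cidx) == 1:
            se = np.sqrt(cov_unscaled[:, cidx[0], cidx[0]] * post)
            tstat = beta[:, cidx[0]] / se
            pval = 2.0 * stats.t.sf(np.abs(tstat), np.inf if np.isinf(prior.d0) else total_df)
            stat_col = tstat
        else:
            r = len(cidx)
            bc = beta[:, cidx]
            Vc = cov_unscaled[np.ix_(np.arange(len(beta)), cidx, cidx)]
            quad = np.einsum("gi,gij,gj->g", bc, np.linalg.inv(Vc), bc, optimize=True)
            Fstat = quad / (r * post)
            pval = stats.f.sf(Fstat, r, 1e12 if np.isinf(prior.d0) else total_df)
            stat_col = Fstat

    logfc = beta[:, cidx[0]] if len(cidx) == 1 else beta[:, cidx][
        np.arange(len(beta)), np.argmax(np.abs(beta[:, cidx]), axis=1)
    ]
    fdr = adjust_bh(pd.Series(pval, index=expr.genes)).to_numpy()
    direction = _direction_labels(contrast[0], logfc)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": Y.mean(axis=1),
            "t": stat_col,
            "P.Value": pval,
            "adj.P.Val": fdr,
            "direction": direction,
            "df.residual": df,
        },
        index=expr.genes,
    )
    return DEResult(table=table, moderation=prior, contrast=contrast)


def _fixed_prior(s2, df, d0):
    if d0 == 0:
        return ModerationParams(0.0, 0.0)
    est = estimate_prior(s2, df)
    return ModerationParams(est.s0_squared, d0)


def _direction_labels(contrast_name: str, logfc: np.ndarray) -> np.ndarray:
    if contrast_name.startswith("sex"):
        pos, neg = "male-biased", "female-biased"
    elif contrast_name.startswith("diagnosis"):
        pos, neg = "up_SZ", "down_SZ"
    else:
        pos, neg = "up", "down"
    return np.where(logfc > 0, pos, neg)


def adjust_bh(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up FDR; NaN p-values propagate with a warning."""
    s = pd.Series(np.asarray(p, dtype=float)) if not isinstance(p, pd.Series) else p
    vals = s.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(vals, np.nan)
    ok = ~np.isnan(vals)
    if (~ok).any():
        warnings.warn("NaN p-values propagated through BH adjustment")
    if ok.any():
        out[ok] = multipletests(vals[ok], method="fdr_bh")[1]
    return pd.Series(out, index=s.index, name="adj.P.Val")


def residualize(expr: ExprMatrix, null_design: pd.DataFrame):
    """Regress the null design out of each gene, then z-score across samples.

    Returns ``(ExprMatrix(residual_z), flagged)`` where ``flagged`` lists
    genes with zero residual variance (excluded from the output).
    """
    X = null_design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("null design is rank deficient")
    R = _residual_matrix(expr.values.to_numpy(dtype=float), X)
    sd = R.std(axis=1, ddof=1)
    flagged = list(expr.genes[sd == 0])
    keep = sd > 0
    Z = (R[keep] - R[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    out = ExprMatrix(
        pd.DataFrame(Z, index=expr.genes[keep], columns=expr.samples),
        kind="residual_z",
        note="null-design residuals, per-gene z-scored",
    )
    return out, flagged
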