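"""X-chromosome dosage: relative X expression and XCI-status enrichment.

Relative X expression (RXE) summarizes chromosome-wide X dosage per sample
as log2(mean TPM over X genes) - log2(mean TPM over autosomal genes); a
fully dosage-compensated male and a female should sit at similar RXE, so a
group shift flags a chromosome-wide dosage change.  Pseudoautosomal genes
are excluded from the X set and chrY from both sets by default (neither is
informative for X inactivation dosage).

XCI enrichment asks whether sex-biased genes over-represent the escape /
variable-escape / inactive inactivation classes, via two-sided Fisher exact
tests with Bonferroni correction across all tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantnorm import ExprMatrix
from .synth import AUTOSOMES


@dataclass
class EnrichResult:
    category: str
    stratum: str
    table: np.ndarray  # 2x2: [[set&cat, set&~cat], [~set&cat, ~set&~cat]]
    odds_ratio: float
    p_value: float
    p_bonferroni: float


def compute_rxe(
    tpm: ExprMatrix,
    annotation: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    presence_fraction: float = 0.2,
    method: str = "log_of_mean",
    include_par: bool = False,
    include_y: bool = False,
    restrict_xci_class: str | None = None,
) -> pd.DataFrame:
    """Per-sample relative X expression from a TPM matrix.

    Genes with TPM > 0 in fewer than ``presence_fraction`` of samples are
    dropped first.  ``method="log_of_mean"`` is log2(mean TPM_X) -
    log2(mean TPM_autosome); ``"mean_of_log"`` averages log2(TPM + 1)
    within each set instead.  ``restrict_xci_class`` limits the X set to
    one inactivation class (e.g. ``"inactive"``).
    """
    if tpm.kind != "TPM":
        raise ValueError(f"RXE requires a TPM matrix, got kind={tpm.kind!r}")
    if method not in ("log_of_mean", "mean_of_log"):
        raise ValueError(f"unknown method {method!r}")
    vals = tpm.values
    annot = annotation.reindex(vals.index)
    if annot["chromosome"].isna().any():
        missing = vals.index[annot["chromosome"].isna()][0]
        raise ValueError(f"gene {missing!r} missing from annotation")
    present = (vals.to_numpy() > 0).sum(axis=1) >= presence_fraction * vals.shape[1]
    chrom = annot["chromosome"].astype(str)
    x_mask = (chrom == "X") & present
    if not include_par:
        x_mask &= ~annot["par_flag"].astype(bool)
    if restrict_xci_class is not None:
        x_mask &= annot["xci_status"] == restrict_xci_class
    aut_mask = chrom.isin(AUTOSOMES) & present
    if include_y:
        aut_mask |= (chrom == "Y") & present
    if x_mask.sum() == 0 or aut_mask.sum() == 0:
        raise ValueError("no X or no autosomal genes survive the presence filter")

    X = vals.loc[x_mask.to_numpy()].to_numpy()
    A = vals.loc[aut_mask.to_numpy()].to_numpy()
    if method == "log_of_mean":
        mx, ma = X.mean(axis=0), A.mean(axis=0)
        for j in np.flatnonzero((mx <= 0) | (ma <= 0)):
            raise ValueError(
                f"sample {vals.columns[j]!r}: zero mean TPM in the X or autosomal set"
            )
        rxe = np.log2(mx) - np.log2(ma)
    else:
        rxe = np.log2(X + 1.0).mean(axis=0) - np.log2(A + 1.0).mean(axis=0)

    out = pd.DataFrame(
        {
            "rxe": rxe,
            "n_x_genes": int(x_mask.sum()),
            "n_autosomal_genes": int(aut_mask.sum()),
        },
        index=vals.columns,
    )
    if meta is not None:
        out = out.join(meta[["sex", "diagnosis", "region"]])
    return out


def mann_whitney(x, y):
    """Mann-Whitney U with exact p when feasible.

    Exact enumeration when both groups have <= 8 observations and the pooled
    values are tie-free; otherwise the tie-corrected normal approximation
    with continuity correction.  Returns ``(U, two-sided p)`` with U counted
    for the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def xci_enrichment(
    deg_sets: dict,
    annotation: pd.DataFrame,
    universe,
    categories=("escape", "variable", "inactive"),
) -> pd.DataFrame:
    """Fisher enrichment of XCI classes within sex-biased gene sets.

    ``deg_sets`` maps a stratum label (``female-bias``, ``male-bias``,
    ``all``) to a gene set; the universe is all tested X-annotated genes.
    One 2x2 table per (class x stratum), two-sided Fisher exact p, and
    Bonferroni over every table computed.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    for name, s in deg_sets.items():
        extra = set(s) - universe
        if extra:
            raise ValueError(f"deg set {name!r} contains genes outside the universe: "
                             f"{sorted(extra)[:5]}")
    status = annotation["xci_status"].reindex(sorted(universe))
    results = []
    for stratum, genes in deg_sets.items():
        genes = set(genes)
        for cat in categories:
            cat_genes = set(status.index[status == cat])
            a = len(genes & cat_genes)
            b = len(genes - cat_genes)
            c = len(cat_genes - genes)
            d = len(universe) - a - b - c
            table = np.array([[a, b], [c, d]])
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            results.append(
                EnrichResult(cat, stratum, table, float(odds), float(p), p)
            )
    n_tests = len(results)
    rows = []
    for r in results:
        r.p_bonferroni = min(1.0, r.p_value * n_tests)
        rows.append(
            {
                "category": r.category,
                "stratum": r.stratum,
                "n_in_set_in_cat": int(r.table[0, 0]),
                "n_in_set_not_cat": int(r.table[0, 1]),
                "n_not_set_in_cat": int(r.table[1, 0]),
                "n_not_set_not_cat": int(r.table[1, 1]),
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "p_bonferroni": r.p_bonferroni,
            }
        )
    return pd.DataFrame(rows)
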