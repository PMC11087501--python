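"""Cross-dataset replication statistics: pi1, effect concordance, set overlap.

pi1 = 1 - pi0 estimates the fraction of true signals among one dataset's
hits when their p-values are recomputed in a second dataset (Storey's pi0
with the smoother).  Effect concordance is the Spearman correlation and
sign-agreement of shared log fold changes; overlap enrichment is a
two-sided Fisher exact test of the DEG-set intersection against the tested
universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diffexpr import DEResult


@dataclass
class ReplicationStats:
    pi0: float
    pi1: float
    lambda_grid: np.ndarray
    spearman_rho: float
    spearman_p: float
    sign_concordance: float
    overlap_table: np.ndarray
    overlap_odds_ratio: float
    overlap_p: float
    n_features: int


def pi1(
    p_values,
    method: str = "smoother",
    lambda_grid=None,
    fixed_lambda: float = 0.5,
):
    """Storey pi0/pi1 from replication p-values.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)).  ``smoother`` fits a
    low-df cubic smoother (a precision-weighted cubic fit, the stiff limit
    of a natural cubic smoothing spline at ~4 effective df) to pi0(lambda)
    over the grid and evaluates it at the largest lambda, clamped to
    [0, 1]; the weights are the inverse sampling sd of each pi0(lambda),
    which damps the increasingly noisy tail estimates.  With fewer than 20
    p-values, or ``method="fixed"``, the single-lambda estimate at
    ``fixed_lambda`` is used.  Returns ``(pi0, pi1)``.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values given")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    n = len(p)
    if method == "fixed" or n < 20:
        pi0 = np.sum(p > fixed_lambda) / (n * (1.0 - fixed_lambda))
    elif method == "smoother":
        pi0_lam = np.array([np.sum(p > l) / (n * (1.0 - l)) for l in lam])
        # var(pi0(lambda)) scales as 1/(1 - lambda): downweight the tail
        weights = np.sqrt(1.0 - lam)
        coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, 3, w=weights)
        pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
    else:
        raise ValueError(f"unknown method {method!r}")
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return pi0, 1.0 - pi0


def effect_concordance(de_a: DEResult, de_b: DEResult, restrict: str = "all"):
    """Spearman rho and sign agreement of logFC over shared features.

    ``restrict="significant"`` limits to features with adjusted p < 0.05 in
    both results.  Requires at least 3 shared features.
    """
    ta, tb = de_a.table, de_b.table
    shared = ta.index.intersection(tb.index)
    if restrict == "significant":
        shared = shared[
            (ta.loc[shared, "adj.P.Val"] < 0.05) & (tb.loc[shared, "adj.P.Val"] < 0.05)
        ]
    elif restrict != "all":
        raise ValueError(f"unknown restrict {restrict!r}")
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared features, have {len(shared)}")
    a = ta.loc[shared, "logFC"].to_numpy()
    b = tb.loc[shared, "logFC"].to_numpy()
    rho, p = stats.spearmanr(a, b)
    concord = float(np.mean(np.sign(a) == np.sign(b)))
    return float(rho), float(p), concord, len(shared)


def overlap_enrichment(set_a, set_b, universe):
    """Two-sided Fisher exact test of two gene sets' overlap in a universe.

    Table: [[|A&B|, |A\\B|], [|B\\A|, |universe \\ (A|B)|]].  Returns
    ``(table, odds_ratio, p)``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    t11 = len(a & b)
    t12 = len(a - b)
    t21 = len(b - a)
    t22 = len(universe) - t11 - t12 - t21
    table = np.array([[t11, t12], [t21, t22]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def replication_stats(de_a: DEResult, de_b: DEResult, universe, select_p: float = 0.05):
    """Full replication summary of dataset A's hits evaluated in dataset B.

    Features nominally significant in A (p < ``select_p``) contribute their
    B p-values to the pi1 estimate; concordance and overlap use the shared
    tested features and FDR < 0.05 DEG sets respectively.
    """
    shared = de_a.table.index.intersection(de_b.table.index)
    hits_a = shared[de_a.table.loc[shared, "P.Value"] < select_p]
    if len(hits_a) == 0:
        raise ValueError("no nominally significant features in dataset A")
    pi0, p1 = pi1(de_b.table.loc[hits_a, "P.Value"].to_numpy())
    rho, rho_p, concord, n = effect_concordance(de_a, de_b)
    table, odds, fp = overlap_enrichment(
        de_a.significant, de_b.significant, universe
    )
    return ReplicationStats(
        pi0=pi0,
        pi1=p1,
        lambda_grid=np.arange(0.05, 0.951, 0.05),
        spearman_rho=rho,
        spearman_p=rho_p,
        sign_concordance=concord,
        overlap_table=table,
        overlap_odds_ratio=odds,
        overlap_p=fp,
        n_features=n,
    )
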