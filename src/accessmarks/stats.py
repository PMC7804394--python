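"""Shared statistical engines: the moderated two-sample t and rank-sum tests.

The moderated t shrinks each row's pooled variance toward the grand mean of
row variances with a fixed prior degrees of freedom ``d0`` (default 4):

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),   s0^2 = mean_g(s_g^2)

and refers t = delta / (s_tilde * sqrt(1/n_a + 1/n_b)) to a t distribution on
``d0 + d_g`` degrees of freedom.  At ``d0 = 0`` this is exactly the ordinary
pooled-variance two-sample t; as ``d0`` grows every row is judged against the
common variance.  The fixed prior keeps the statistic deterministic and well
behaved at the 2-3 replicates typical of ChIP/ATAC designs, at the cost of not
adapting ``d0`` to the data the way an empirical-Bayes fit would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ModeratedResult:
    log2fc: pd.Series
    t: pd.Series
    p: pd.Series
    s0_sq: float
    prior_df: float


def log2_cpm(values, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2(x + pseudocount); bounds fold changes on zero entries."""
    return np.log2(np.asarray(values, dtype=float) + pseudocount)


def moderated_diff(
    table: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    prior_df: float = 4.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    already_log: bool = False,
) -> ModeratedResult:
    """Moderated t per row of ``table`` for group_a vs group_b (a minus b).

    ``table`` holds linear CPM unless ``already_log``.  Rows where both groups
    have zero variance and equal means get p = 1 (no evidence either way).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    if prior_df < 0:
        raise ValueError("prior_df must be >= 0")
    a = table[list(group_a)].to_numpy(dtype=float)
    b = table[list(group_b)].to_numpy(dtype=float)
    if not already_log:
        a = log2_cpm(a, pseudocount)
        b = log2_cpm(b, pseudocount)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta = mean_a - mean_b
    d_g = na + nb - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d_g
    s0_sq = float(s_sq.mean()) if len(s_sq) else 0.0
    denom_df = prior_df + d_g
    s_tilde_sq = (prior_df * s0_sq + d_g * s_sq) / denom_df
    se = np.sqrt(s_tilde_sq * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    p = 2.0 * sps.t.sf(np.abs(t), df=denom_df)
    p = np.where((se == 0) & (delta == 0), 1.0, p)
    p = np.where(np.isinf(t), 0.0, p)
    idx = table.index
    return ModeratedResult(
        log2fc=pd.Series(delta, index=idx, name="log2fc"),
        t=pd.Series(t, index=idx, name="t"),
        p=pd.Series(p, index=idx, name="p"),
        s0_sq=s0_sq,
        prior_df=prior_df,
    )


def rank_sum_one_sided(
    other: np.ndarray,
    reference: np.ndarray,
    direction: str = "greater",
    exact_max_n: int = 8,
) -> float:
    """One-sided Mann-Whitney-Wilcoxon p for ``other`` vs ``reference``.

    ``direction='greater'`` tests whether ``other`` is stochastically greater
    than ``reference``.  Exact enumeration is used when the smaller group has
    at most ``exact_max_n`` observations and there are no ties; otherwise the
    tie-corrected normal approximation applies.
    """
    other = np.asarray(other, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if len(other) == 0 or len(reference) == 0:
        raise ValueError("both groups must be non-empty")
    small = min(len(other), len(reference))
    has_ties = len(np.unique(np.concatenate([other, reference]))) < len(other) + len(reference)
    method = "exact" if (small <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(other, reference, alternative=direction, method=method)
    return float(res.pvalue)
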