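"""Link-centric differential co-expression (DCe).

Differentially co-expressed links (DCLs) are selected with a limit-fold-change
(LFC) style model: among links whose correlations keep the same sign, the
fold change FC = max(|r1|, |r2|) / (min(|r1|, |r2|) + eps) is ranked within
equal-count bins of the signal magnitude max(|r1|, |r2|), and the top ``delta``
fraction of each bin is flagged — a magnitude-dependent fold-change threshold.
Links whose correlations change sign between conditions (co-expression
reversal) are categorically different: they are ranked globally by |r1 - r2|
and the top ``delta`` fraction flagged, bypassing the fold-change envelope.

Genes are then scored by enrichment of DCLs among their links with an
upper-tail binomial probability: a gene with n_i links of which k_i are DCLs,
in a network of N links with K DCLs overall, gets

    P(g_i) = sum_{x=k_i}^{n_i} C(n_i, x) (K/N)^x (1 - K/N)^(n_i - x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CoexpressionNetworkPair
from .expression import ValidationError

__all__ = [
    "DCeCounts",
    "reversal_type",
    "lfc_select_dcls",
    "dce_counts",
    "binomial_enrichment",
    "dce_dcg_pvalues",
    "call_dce_dcgs",
]

log = logging.getLogger(__name__)

#: Bin index recorded for reversal (opposite-sign) links, which are ranked in
#: one global pool rather than per magnitude bin.
REVERSAL_POOL = -1


def reversal_type(r1: float, r2: float) -> int:
    """1 if the link's correlation changes sign between conditions, else 0.

    A product of exactly zero is typed 0: with one coefficient at zero no sign
    change is demonstrable.
    """
    for r in (r1, r2):
        if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
            raise ValidationError(f"correlation {r} outside [-1, 1]")
    return 1 if r1 * r2 < 0 else 0


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def lfc_select_dcls(
    net: CoexpressionNetworkPair,
    delta: float = 0.25,
    n_bins: int = 20,
    epsilon: float = 1e-8,
    min_bin_count: int = 10,
) -> pd.DataFrame:
    """Flag DCLs with the limit-fold-change model.

    Returns one row per network link with columns gene_a, gene_b, r1, r2,
    reversal_type, score, selection_bin and is_dcl. Same-sign links carry
    their magnitude-bin index; reversal links carry ``REVERSAL_POOL``.

    ``n_bins`` is an upper bound: bins are equal-count and never smaller than
    ``min_bin_count`` links, so small networks fall back to fewer (ultimately
    one) bins instead of degenerate singleton bins. Per-bin selection counts
    are delta × bin size rounded half up; links with no differential signal
    (FC at its floor of 1, i.e. |r1| = |r2|) are never flagged, so a network
    with identical correlations in both conditions yields no DCLs.
    """
    if not 0.0 < delta < 1.0:
        raise ValidationError("delta must lie in (0, 1)")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if net.n_links == 0:
        raise ValidationError("network pair has no links")

    r1, r2 = net.r1, net.r2
    abs1, abs2 = np.abs(r1), np.abs(r2)
    absmax = np.maximum(abs1, abs2)
    absmin = np.minimum(abs1, abs2)
    fc = absmax / (absmin + epsilon)
    rtype = np.where(r1 * r2 < 0, 1, 0)
    score = np.where(rtype == 1, np.abs(r1 - r2), fc)
    is_dcl = np.zeros(net.n_links, dtype=bool)
    sel_bin = np.full(net.n_links, REVERSAL_POOL, dtype=int)

    # Same-sign group: equal-count magnitude bins, top-delta by FC per bin.
    same_idx = np.flatnonzero(rtype == 0)
    if same_idx.size:
        by_mag = same_idx[np.argsort(absmax[same_idx], kind="stable")]
        eff_bins = max(1, min(n_bins, by_mag.size // max(1, min_bin_count)))
        for b, members in enumerate(np.array_split(by_mag, eff_bins)):
            sel_bin[members] = b
            n_take = _round_half_up(delta * members.size)
            eligible = members[fc[members] > 1.0 + 1e-9]
            if n_take == 0 or eligible.size == 0:
                continue
            order = eligible[np.argsort(-fc[eligible], kind="stable")]
            is_dcl[order[:n_take]] = True

    # Opposite-sign group: one pool ranked by the correlation difference.
    opp_idx = np.flatnonzero(rtype == 1)
    if opp_idx.size:
        n_take = _round_half_up(delta * opp_idx.size)
        order = opp_idx[np.argsort(-score[opp_idx], kind="stable")]
        is_dcl[order[:n_take]] = True

    if not is_dcl.any():
        log.warning("LFC selection flagged zero DCLs (delta=%.3g)", delta)

    return pd.DataFrame(
        {
            "gene_a": [a for a, _ in net.links],
            "gene_b": [b for _, b in net.links],
            "r1": r1,
            "r2": r2,
            "reversal_type": rtype,
            "score": score,
            "selection_bin": sel_bin,
            "is_dcl": is_dcl,
        }
    )


@dataclass
class DCeCounts:
    """Link/DCL bookkeeping behind the binomial enrichment.

    N = total links, K = flagged DCLs; ``table`` holds per-gene degree n_i and
    incident-DCL count k_i. Invariant: sum of k_i over genes equals 2K.
    """

    N: int
    K: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0 <= self.K <= self.N:
            raise ValidationError("need 0 <= K <= N")
        if ((self.table["k_i"] < 0) | (self.table["k_i"] > self.table["n_i"])).any():
            raise ValidationError("need 0 <= k_i <= n_i for every gene")
        if int(self.table["k_i"].sum()) != 2 * self.K:
            raise ValidationError("sum of k_i must equal 2K")


def dce_counts(dcl_table: pd.DataFrame) -> DCeCounts:
    """Aggregate a DCL table into the per-gene (n_i, k_i) counts."""
    ends = pd.concat(
        [
            dcl_table[["gene_a", "is_dcl"]].rename(columns={"gene_a": "gene"}),
            dcl_table[["gene_b", "is_dcl"]].rename(columns={"gene_b": "gene"}),
        ]
    )
    per_gene = (
        ends.groupby("gene")["is_dcl"]
        .agg(n_i="size", k_i="sum")
        .reset_index()
        .sort_values("gene", ignore_index=True)
    )
    per_gene["k_i"] = per_gene["k_i"].astype(int)
    return DCeCounts(
        N=len(dcl_table), K=int(dcl_table["is_dcl"].sum()), table=per_gene
    )


def binomial_enrichment(n_i: int, k_i: int, K: int, N: int) -> float:
    """Upper-tail binomial probability that >= k_i of n_i links are DCLs.

    Computed with the binomial survival function (numerically stable for the
    small tail probabilities of hub genes); equals 1.0 exactly at k_i = 0.
    """
    if N < 1 or not 0 <= K <= N:
        raise ValidationError("need N >= 1 and 0 <= K <= N")
    if not 0 <= k_i <= n_i:
        raise ValidationError("need 0 <= k_i <= n_i")
    if k_i == 0:
        return 1.0
    p = float(stats.binom.sf(k_i - 1, n_i, K / N))
    return min(max(p, 0.0), 1.0)


def dce_dcg_pvalues(counts: DCeCounts) -> pd.DataFrame:
    """Per-gene enrichment table: gene, n_i, k_i, p_value."""
    table = counts.table.copy()
    table["p_value"] = [
        binomial_enrichment(int(n), int(k), counts.K, counts.N)
        for n, k in zip(table["n_i"], table["k_i"])
    ]
    return table


def call_dce_dcgs(counts: DCeCounts, p_threshold: float = 0.05) -> frozenset[str]:
    """Genes whose links are significantly enriched for DCLs."""
    if not 0.0 <= p_threshold <= 1.0:
        raise ValidationError("p threshold must lie in [0, 1]")
    table = dce_dcg_pvalues(counts)
    return frozenset(table.loc[table["p_value"] <= p_threshold, "gene"])
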