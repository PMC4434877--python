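"""Condition-specific co-expression networks over a shared link set.

Two correlation maps (one per condition) are thresholded jointly so that both
networks share exactly the same topology and differ only in the correlation
coefficient attached to each link. A gene's "neighbor vectors" — the per-link
coefficients in each condition, in a fixed canonical order — are the substrate
of the per-gene differential co-expression statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ValidationError

__all__ = [
    "LinkCutoff",
    "CoexpressionNetworkPair",
    "NoLinksError",
    "pairwise_correlations",
    "build_network_pair",
    "neighbor_vectors",
    "canonical_link",
]

log = logging.getLogger(__name__)


class NoLinksError(ValueError):
    """Raised when the link cutoff retains no gene pairs."""


def canonical_link(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair in canonical (lexicographically sorted) order."""
    if a == b:
        raise ValidationError(f"self-link {a!r} is not a valid gene pair")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class LinkCutoff:
    """Rule deciding which gene pairs enter the shared link set.

    mode="threshold": keep a pair iff max(|r1|, |r2|) >= value.
    mode="quantile":  keep the top ``value`` fraction of pairs by max(|r1|, |r2|)
    (at least one pair). The original analyses in this field apply a hard
    correlation cutoff; 0.8 is a common choice for small-sample microarray work.
    """

    mode: str = "threshold"
    value: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "quantile"):
            raise ValidationError(f"unknown cutoff mode {self.mode!r}")
        if self.mode == "threshold" and not 0.0 <= self.value <= 1.0:
            raise ValidationError("threshold cutoff must lie in [0, 1]")
        if self.mode == "quantile" and not 0.0 < self.value <= 1.0:
            raise ValidationError("quantile cutoff must lie in (0, 1]")

    def mask(self, score: np.ndarray) -> np.ndarray:
        """Boolean retention mask over an array of per-pair max-|r| scores."""
        if self.mode == "threshold":
            return score >= self.value
        n_keep = max(1, int(np.ceil(self.value * score.size)))
        if n_keep >= score.size:
            return np.ones(score.size, dtype=bool)
        order = np.argsort(score, kind="stable")
        keep = np.zeros(score.size, dtype=bool)
        keep[order[score.size - n_keep:]] = True
        return keep


def pairwise_correlations(
    expr: ExpressionMatrix, condition: str, method: str = "pearson"
) -> pd.DataFrame:
    """All gene pair-wise correlation coefficients within one condition.

    Returns a symmetric genes × genes DataFrame; the diagonal (self pairs) is
    NaN, as are all pairs touching a zero-variance gene (such genes cannot
    carry a defined correlation and are excluded downstream with a warning).

    Raises a :class:`ValidationError` naming the condition when it has fewer
    than the three samples a correlation coefficient needs.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    block = expr.submatrix(condition)
    if block.shape[1] < 3:
        raise ValidationError(
            f"condition {condition!r} has {block.shape[1]} samples; "
            "correlation requires at least 3"
        )
    x = block.to_numpy(dtype=float)
    if method == "spearman":
        x = np.apply_along_axis(lambda row: pd.Series(row).rank().to_numpy(), 1, x)
    sd = x.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        bad = [g for g, d in zip(block.index, degenerate) if d]
        log.warning(
            "condition %s: %d zero-variance gene(s) excluded from the pair "
            "universe: %s", condition, len(bad), bad[:10],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.clip(corr, -1.0, 1.0)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.nan)
    return pd.DataFrame(corr, index=block.index, columns=block.index)


@dataclass
class CoexpressionNetworkPair:
    """One shared link set carrying two correlations per link.

    ``links`` are canonical (lexicographically ordered) gene pairs; ``r1`` and
    ``r2`` hold the coefficient of each link under condition 1 and condition 2
    respectively. ``condition_labels`` and ``cutoff`` record provenance so the
    permutation test can rebuild networks from permuted data the same way.
    """

    links: list[tuple[str, str]]
    r1: np.ndarray
    r2: np.ndarray
    condition_labels: tuple[str, str]
    cutoff: LinkCutoff

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        if not (len(self.links) == self.r1.size == self.r2.size):
            raise ValidationError("links, r1 and r2 must have identical length")
        for a, b in self.links:
            if not a < b:
                raise ValidationError(f"link ({a!r}, {b!r}) is not canonical")
        for r in (self.r1, self.r2):
            if r.size and (np.abs(r) > 1 + 1e-12).any():
                raise ValidationError("correlations must lie in [-1, 1]")
        self._neighbors: dict[str, list[tuple[str, int]]] = {}
        for idx, (a, b) in enumerate(self.links):
            self._neighbors.setdefault(a, []).append((b, idx))
            self._neighbors.setdefault(b, []).append((a, idx))
        for lst in self._neighbors.values():
            lst.sort()  # canonical neighbor order

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def genes(self) -> list[str]:
        """Genes with at least one incident link, sorted."""
        return sorted(self._neighbors)

    def degree(self, gene: str) -> int:
        return len(self._neighbors.get(gene, ()))

    def link_correlations(self, a: str, b: str) -> tuple[float, float]:
        link = canonical_link(a, b)
        for nb, idx in self._neighbors.get(link[0], ()):
            if nb == link[1]:
                return float(self.r1[idx]), float(self.r2[idx])
        raise KeyError(f"link {link} not present in the network pair")

    def neighbor_vectors(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-neighbor correlation vectors (x, y) in canonical neighbor order.

        Returns a pair of empty arrays for a gene without incident links —
        the empty-neighborhood marker; the per-gene statistic is undefined
        there and such genes are skipped (and logged) downstream.
        """
        entries = self._neighbors.get(gene, [])
        idx = np.array([i for _, i in entries], dtype=int)
        return self.r1[idx], self.r2[idx]

    def swap_conditions(self) -> "CoexpressionNetworkPair":
        """The same network with the two condition labels exchanged."""
        return CoexpressionNetworkPair(
            links=list(self.links),
            r1=self.r2.copy(),
            r2=self.r1.copy(),
            condition_labels=(self.condition_labels[1], self.condition_labels[0]),
            cutoff=self.cutoff,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [a for a, _ in self.links],
                "gene_b": [b for _, b in self.links],
                "r1": self.r1,
                "r2": self.r2,
            }
        )


def build_network_pair(
    corr1: pd.DataFrame,
    corr2: pd.DataFrame,
    cutoff: LinkCutoff = LinkCutoff(),
    condition_labels: tuple[str, str] = ("cond1", "cond2"),
) -> CoexpressionNetworkPair:
    """Joint thresholding of two correlation maps into a shared link set.

    A pair is retained iff max(|r1|, |r2|) passes the cutoff rule, so a link
    strongly co-expressed in either condition enters both networks and both
    coefficients are preserved. Pairs undefined in either condition
    (zero-variance genes) are dropped before thresholding.
    """
    if list(corr1.index) != list(corr2.index):
        raise ValidationError("corr1 and corr2 must cover the same gene universe")
    genes = np.asarray(corr1.index)
    c1 = corr1.to_numpy(dtype=float)
    c2 = corr2.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    v1, v2 = c1[iu, ju], c2[iu, ju]
    defined = ~(np.isnan(v1) | np.isnan(v2))
    n_undefined = int((~defined).sum())
    if n_undefined:
        log.warning("dropping %d gene pair(s) with undefined correlations", n_undefined)
    iu, ju, v1, v2 = iu[defined], ju[defined], v1[defined], v2[defined]
    score = np.maximum(np.abs(v1), np.abs(v2))
    keep = cutoff.mask(score) if score.size else np.zeros(0, dtype=bool)
    if not keep.any():
        raise NoLinksError(
            f"cutoff {cutoff} retained zero links out of {score.size} pairs; "
            "consider a looser threshold"
        )
    links, r1, r2 = [], [], []
    for i, j, a, b in zip(iu[keep], ju[keep], v1[keep], v2[keep]):
        ga, gb = genes[i], genes[j]
        if ga < gb:
            links.append((ga, gb))
        else:
            links.append((gb, ga))
        r1.append(a)
        r2.append(b)
    order = np.argsort(np.array([f"{a}\t{b}" for a, b in links]))
    return CoexpressionNetworkPair(
        links=[links[k] for k in order],
        r1=np.array(r1)[order],
        r2=np.array(r2)[order],
        condition_labels=condition_labels,
        cutoff=cutoff,
    )


def neighbor_vectors(
    net: CoexpressionNetworkPair, gene: str
) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`CoexpressionNetworkPair.neighbor_vectors`."""
    return net.neighbor_vectors(gene)
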