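"""Differential regulation analysis (DRA).

The two DCG calls (per-gene dC statistic and link-enrichment) are intersected
into "true" DCGs; DCLs touching a true DCG become "true" DCLs; both are then
projected onto a transcription-factor→target library. A true DCG that is a
known TF is a differentially regulated gene (DRG); a true DCL that matches a
library relation is a TF→target DCL (DRL), carrying the regulator, target,
both correlations, the reversal type and the dC p-value of its DCG endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coexpression import CoexpressionNetworkPair, canonical_link
from .dce import reversal_type
from .dcp import DcpResult
from .expression import ValidationError

__all__ = [
    "TF2TargetLibrary",
    "DifferentialRegulationReport",
    "true_dcgs",
    "true_dcls",
    "annotate_drgs",
    "annotate_drls",
]

DRL_COLUMNS = ["tf", "target", "p_dcg", "r1", "r2", "reversal_type", "starred"]


@dataclass(frozen=True)
class TF2TargetLibrary:
    """Set of ordered regulator→target relations.

    A gene may act as both a TF and a target; duplicate pairs collapse.
    """

    relations: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs) -> "TF2TargetLibrary":
        rels = set()
        for tf, target in pairs:
            if tf == target:
                raise ValidationError(f"self-regulation tuple ({tf!r}) not supported")
            rels.add((str(tf), str(target)))
        return cls(relations=frozenset(rels))

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.relations)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.relations)

    def __len__(self) -> int:
        return len(self.relations)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.relations


def true_dcgs(dcp_set: frozenset[str], dce_set: frozenset[str]) -> frozenset[str]:
    """Genes called differentially co-expressed by both methods (intersection)."""
    return frozenset(dcp_set) & frozenset(dce_set)


def true_dcls(
    dcls: frozenset[tuple[str, str]], true_dcg_set: frozenset[str]
) -> frozenset[tuple[str, str]]:
    """DCLs with at least one endpoint among the true DCGs."""
    out = set()
    for a, b in dcls:
        link = canonical_link(a, b)
        if link[0] in true_dcg_set or link[1] in true_dcg_set:
            out.add(link)
    return frozenset(out)


def annotate_drgs(true_dcg_set: frozenset[str], lib: TF2TargetLibrary) -> frozenset[str]:
    """True DCGs that are known transcription factors."""
    return frozenset(true_dcg_set) & lib.tfs


def annotate_drls(
    links: frozenset[tuple[str, str]],
    lib: TF2TargetLibrary,
    dcp_results: DcpResult | pd.DataFrame,
    net: CoexpressionNetworkPair,
    dcg_set: frozenset[str],
) -> pd.DataFrame:
    """Project true DCLs onto the TF→target library.

    Each link yields one record per matching orientation — a link present in
    the library both ways emits two records. The DCG endpoint(s) are starred;
    ``p_dcg`` is the dC p-value of the starred gene, and the smaller of the
    two when both endpoints are DCGs. Output is sorted by (tf, target) for
    reproducible diffs.
    """
    table = dcp_results.table if isinstance(dcp_results, DcpResult) else dcp_results
    pmap = dict(zip(table["gene"], table["p_value"]))
    rows = []
    for link in sorted(canonical_link(*lk) for lk in links):
        a, b = link
        r1, r2 = net.link_correlations(a, b)  # KeyError if link not in net
        starred = sorted(g for g in link if g in dcg_set)
        if not starred:
            raise ValidationError(f"link {link} has no DCG endpoint")
        ps = [pmap[g] for g in starred if g in pmap]
        if not ps:
            raise ValidationError(f"no dC p-value for starred gene(s) of {link}")
        p_dcg = float(min(ps))
        for tf, target in ((a, b), (b, a)):
            if (tf, target) in lib:
                rows.append(
                    (tf, target, p_dcg, r1, r2, reversal_type(r1, r2), ",".join(starred))
                )
    out = pd.DataFrame(rows, columns=DRL_COLUMNS)
    return out.sort_values(["tf", "target"], ignore_index=True)


@dataclass
class DifferentialRegulationReport:
    """Everything DRA derives for one two-condition comparison."""

    comparison_label: str
    true_dcgs: frozenset[str] = frozenset()
    true_dcls: frozenset[tuple[str, str]] = frozenset()
    drgs: frozenset[str] = frozenset()
    drls: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DRL_COLUMNS))
    dcp_result: DcpResult | None = field(default=None, repr=False)
    dcl_table: pd.DataFrame | None = field(default=None, repr=False)
    dce_table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.drgs <= self.true_dcgs:
            raise ValidationError("DRGs must be a subset of the true DCGs")
        for tf, target in zip(self.drls["tf"], self.drls["target"]):
            if canonical_link(tf, target) not in self.true_dcls:
                raise ValidationError(f"DRL ({tf}, {target}) outside the true DCLs")

    @property
    def drl_ids(self) -> frozenset[tuple[str, str]]:
        """Ordered (tf, target) identities used for set operations on DRLs."""
        return frozenset(zip(self.drls["tf"], self.drls["target"]))

    @property
    def is_empty(self) -> bool:
        """True when the comparison detected nothing (a valid outcome)."""
        return not self.true_dcgs and len(self.drls) == 0

    def counts(self) -> dict[str, int]:
        return {
            "true_dcgs": len(self.true_dcgs),
            "true_dcls": len(self.true_dcls),
            "drgs": len(self.drgs),
            "drls": int(len(self.drls)),
        }
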