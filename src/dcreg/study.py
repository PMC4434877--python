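"""Three-comparison study design with individual-effect exclusion.

One study arm compares a patient group before and after treatment against a
shared healthy control group:

* ``pre_vs_control``  — untreated disease signal plus individual effects,
* ``post_vs_control`` — treated disease signal plus individual effects,
* ``pre_vs_post``     — the treatment effect itself.

Regulators and regulatory links found both before and after treatment are
attributed to individual differences rather than disease and excluded by set
difference; disease DRGs and DRLs then overlap into "key" regulators — the
DRLs whose TF is itself a disease DRG, and the TFs of those DRLs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import NoLinksError, build_network_pair, pairwise_correlations
from .config import RunConfig
from .dce import call_dce_dcgs, dce_counts, dce_dcg_pvalues, lfc_select_dcls
from .dcp import PermutationPlan, call_dcp_dcgs, permutation_pvalues
from .dra import (
    DRL_COLUMNS,
    DifferentialRegulationReport,
    TF2TargetLibrary,
    annotate_drgs,
    annotate_drls,
    true_dcgs,
    true_dcls,
)
from .expression import ExpressionMatrix, ValidationError

__all__ = [
    "StudyArm",
    "KeyRegulationSummary",
    "exclude_shared",
    "key_overlap",
    "run_comparison",
    "run_arm",
]

log = logging.getLogger(__name__)

COMPARISON_NAMES = ("pre_vs_control", "post_vs_control", "pre_vs_post")


def exclude_shared(primary: frozenset, confound: frozenset) -> frozenset:
    """primary − (primary ∩ confound): drop elements also seen in the confound.

    Applied identically to DRG sets (gene identities) and DRL sets (ordered
    (tf, target) identities — correlation values necessarily differ between
    comparisons and play no role in the identity).
    """
    primary = frozenset(primary)
    return primary - (primary & frozenset(confound))


def key_overlap(
    drgs: frozenset[str], drls: pd.DataFrame
) -> tuple[frozenset[str], pd.DataFrame]:
    """Overlap DRGs with DRLs into the key regulators.

    A DRL is key iff its TF is itself a DRG; a DRG is key iff it is the TF of
    at least one key DRL. Returns (key_drgs, key_drls).
    """
    if len(drls) == 0:
        return frozenset(), drls.copy()
    keep = drls["tf"].isin(set(drgs))
    key_drls = drls.loc[keep].reset_index(drop=True)
    return frozenset(key_drls["tf"]), key_drls


@dataclass
class StudyArm:
    """The three comparison reports of one arm (e.g. one disease subtype)."""

    label: str
    reports: dict[str, DifferentialRegulationReport]

    def __post_init__(self) -> None:
        if set(self.reports) != set(COMPARISON_NAMES):
            raise ValidationError(
                f"reports must cover exactly {COMPARISON_NAMES}, got {sorted(self.reports)}"
            )


@dataclass
class KeyRegulationSummary:
    """Disease-specific and key regulation after individual-effect exclusion."""

    disease_drgs: frozenset[str]
    disease_drls: pd.DataFrame
    key_drgs: frozenset[str]
    key_drls: pd.DataFrame
    treatment_drgs: frozenset[str]
    treatment_drls: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.key_drgs <= self.disease_drgs:
            raise ValidationError("key DRGs must be a subset of the disease DRGs")

    @property
    def treatment_effect_detected(self) -> bool:
        """False means "no significant treatment effect" — a valid outcome."""
        return bool(self.treatment_drgs) or len(self.treatment_drls) > 0

    def counts(self) -> dict[str, int]:
        return {
            "disease_drgs": len(self.disease_drgs),
            "disease_drls": int(len(self.disease_drls)),
            "key_drgs": len(self.key_drgs),
            "key_drls": int(len(self.key_drls)),
            "treatment_drgs": len(self.treatment_drgs),
            "treatment_drls": int(len(self.treatment_drls)),
        }


def run_comparison(
    expr: ExpressionMatrix,
    cond1: str,
    cond2: str,
    lib: TF2TargetLibrary,
    config: RunConfig | None = None,
    seed: int | None = None,
    label: str | None = None,
) -> DifferentialRegulationReport:
    """Full DCEA + DRA for one two-condition comparison.

    Pipeline: pair-wise correlations per condition → joint cutoff into a
    shared link set → dC permutation test (DCp) → LFC link selection and
    binomial enrichment (DCe) → true DCGs (intersection) and true DCLs →
    DRG/DRL annotation against the library. A cutoff retaining no links
    yields an empty report (logged), not an error: it means no co-expression
    signal at the chosen threshold.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    label = label or f"{cond1}_vs_{cond2}"
    corr1 = pairwise_correlations(expr, cond1, config.correlation_method)
    corr2 = pairwise_correlations(expr, cond2, config.correlation_method)
    try:
        net = build_network_pair(corr1, corr2, config.cutoff, (cond1, cond2))
    except NoLinksError:
        log.warning("comparison %s: cutoff retained no links; empty report", label)
        return DifferentialRegulationReport(comparison_label=label)

    plan = PermutationPlan(
        n_permutations=config.n_permutations, seed=seed, scheme=config.permutation_scheme
    )
    dcp_res = permutation_pvalues(expr, net, plan)
    dcp_set = call_dcp_dcgs(dcp_res, config.dcp_p_threshold, config.dcp_fdr_threshold)

    dcl_table = lfc_select_dcls(
        net,
        delta=config.dce_delta,
        n_bins=config.dce_bins,
        epsilon=config.dce_epsilon,
        min_bin_count=config.dce_min_bin_count,
    )
    counts = dce_counts(dcl_table)
    dce_table = dce_dcg_pvalues(counts)
    dce_set = call_dce_dcgs(counts, config.dce_p_threshold)

    tdcg = true_dcgs(dcp_set, dce_set)
    flagged = frozenset(
        zip(dcl_table.loc[dcl_table["is_dcl"], "gene_a"],
            dcl_table.loc[dcl_table["is_dcl"], "gene_b"])
    )
    tdcl = true_dcls(flagged, tdcg)
    drgs = annotate_drgs(tdcg, lib)
    drls = (
        annotate_drls(tdcl, lib, dcp_res, net, tdcg)
        if tdcl
        else pd.DataFrame(columns=DRL_COLUMNS)
    )
    return DifferentialRegulationReport(
        comparison_label=label,
        true_dcgs=tdcg,
        true_dcls=tdcl,
        drgs=drgs,
        drls=drls,
        dcp_result=dcp_res,
        dcl_table=dcl_table,
        dce_table=dce_table,
    )


def run_arm(
    expr: ExpressionMatrix,
    conditions: dict[str, str],
    lib: TF2TargetLibrary,
    config: RunConfig | None = None,
    label: str = "arm",
) -> tuple[StudyArm, KeyRegulationSummary]:
    """Run the full three-comparison design on one arm.

    ``conditions`` maps the roles ``pre``, ``post`` and ``control`` to the
    condition labels of the sample sheet. Per-comparison permutation seeds are
    spawned deterministically from ``config.seed``.
    """
    config = config or RunConfig()
    for role in ("pre", "post", "control"):
        if role not in conditions:
            raise ValidationError(f"missing condition role {role!r}")
        cond = conditions[role]
        if cond not in set(expr.conditions):
            raise ValidationError(f"condition {cond!r} (role {role!r}) not in sample sheet")
        if expr.n_samples(cond) < 3:
            raise ValidationError(
                f"condition {cond!r} has {expr.n_samples(cond)} samples; need >= 3"
            )
    seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(config.seed).generate_state(3)
    ]
    pre, post, control = conditions["pre"], conditions["post"], conditions["control"]
    pairs = {
        "pre_vs_control": (pre, control),
        "post_vs_control": (post, control),
        "pre_vs_post": (pre, post),
    }
    reports = {
        name: run_comparison(expr, a, b, lib, config, seed=s, label=name)
        for (name, (a, b)), s in zip(pairs.items(), seeds)
    }
    arm = StudyArm(label=label, reports=reports)

    r_pre, r_post = reports["pre_vs_control"], reports["post_vs_control"]
    disease_drgs = exclude_shared(r_pre.drgs, r_post.drgs)
    keep_ids = exclude_shared(r_pre.drl_ids, r_post.drl_ids)
    mask = [
        (tf, tg) in keep_ids for tf, tg in zip(r_pre.drls["tf"], r_pre.drls["target"])
    ]
    disease_drls = r_pre.drls.loc[mask].reset_index(drop=True)
    key_drgs, key_drls = key_overlap(disease_drgs, disease_drls)
    summary = KeyRegulationSummary(
        disease_drgs=disease_drgs,
        disease_drls=disease_drls,
        key_drgs=key_drgs,
        key_drls=key_drls,
        treatment_drgs=reports["pre_vs_post"].drgs,
        treatment_drls=reports["pre_vs_post"].drls,
    )
    if not summary.treatment_effect_detected:
        log.info("arm %s: no significant treatment effect detected", label)
    return arm, summary
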