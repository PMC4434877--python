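"""Synthetic two-condition (or multi-group) expression data with planted
differential co-expression structure.

Each regulator "hub" gene and its targets form a factor block: targets load on
the hub's latent factor with loading equal to the desired hub–target
correlation, which makes every block correlation matrix positive
semi-definite by construction. Between the baseline and the altered condition
a configurable fraction of hub links flips sign (co-expression reversal,
+r → −r) and a further fraction collapses to the background level
(correlation shift). Remaining genes form an equicorrelated background.
Samples are drawn from the implied multivariate normal on a log2-like scale
(mean 8, standard deviation ``noise_sd``), echoing RMA-normalized microarray
intensities with small per-group sample counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dra import TF2TargetLibrary
from .expression import ExpressionMatrix, ValidationError

__all__ = ["SimulationConfig", "GroundTruth", "RecoveryScore", "simulate", "recovery_score"]

log = logging.getLogger(__name__)


def _default_groups() -> dict[str, int]:
    # Disease-vs-control contrast at the small group sizes typical of the
    # microarray studies this emulates (8 patients, 8 controls).
    return {"disease": 8, "control": 8}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a detectable desk-scale dataset."""

    n_genes: int = 120
    samples_per_group: dict[str, int] = field(default_factory=_default_groups)
    altered_groups: tuple[str, ...] = ("disease",)
    n_tf_hubs: int = 3
    targets_per_hub: int = 10
    reversal_fraction: float = 1.0
    shift_fraction: float = 0.0
    base_correlation: float = 0.9
    background_correlation: float = 0.0
    noise_sd: float = 1.0
    n_decoy_targets: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reversal_fraction", "shift_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.reversal_fraction + self.shift_fraction > 1.0 + 1e-12:
            raise ValidationError("reversal_fraction + shift_fraction must be <= 1")
        if not 0.0 < self.base_correlation < 1.0:
            raise ValidationError("base_correlation must lie in (0, 1)")
        if not 0.0 <= self.background_correlation < 1.0:
            raise ValidationError("background_correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for g, n in self.samples_per_group.items():
            if n < 3:
                raise ValidationError(f"group {g!r} has {n} samples; need >= 3")
        for g in self.altered_groups:
            if g not in self.samples_per_group:
                raise ValidationError(f"altered group {g!r} not among the sample groups")
        n_planted = self.n_tf_hubs * (1 + self.targets_per_hub)
        if n_planted > self.n_genes:
            raise ValidationError(
                f"planted structure ({n_planted} genes) does not fit in n_genes={self.n_genes}"
            )


@dataclass
class GroundTruth:
    """What was planted: affected regulators, altered links, and the library."""

    planted_dcg_genes: frozenset[str]
    planted_dcl_links: frozenset[tuple[str, str]]
    link_types: dict[tuple[str, str], str]  # link -> "reversal" | "shift"
    planted_library: TF2TargetLibrary


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _hub_layout(config: SimulationConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    hubs = [f"TF{h+1:02d}" for h in range(config.n_tf_hubs)]
    targets = {
        hub: [f"T{h+1:02d}G{j+1:02d}" for j in range(config.targets_per_hub)]
        for h, hub in enumerate(hubs)
    }
    n_bg = config.n_genes - config.n_tf_hubs * (1 + config.targets_per_hub)
    background = [f"BG{i+1:03d}" for i in range(n_bg)]
    return hubs, targets, background


def _correlation_matrix(
    genes: list[str],
    hubs: list[str],
    targets: dict[str, list[str]],
    background: list[str],
    loadings: dict[tuple[str, str], float],
    bg_corr: float,
) -> np.ndarray:
    """Assemble the full implied correlation matrix of one condition."""
    pos = {g: i for i, g in enumerate(genes)}
    corr = np.eye(len(genes))
    for hub in hubs:
        tg = targets[hub]
        lam = np.array([loadings[(hub, t)] for t in tg])
        hi = pos[hub]
        ti = np.array([pos[t] for t in tg])
        corr[hi, ti] = corr[ti, hi] = lam
        # Targets share only the hub factor: corr(t_i, t_j) = lam_i * lam_j.
        corr[np.ix_(ti, ti)] = np.outer(lam, lam)
        corr[ti, ti] = 1.0
    if background and bg_corr > 0:
        bi = np.array([pos[g] for g in background])
        corr[np.ix_(bi, bi)] = bg_corr
        corr[bi, bi] = 1.0
    return corr


def _ensure_psd(corr: np.ndarray) -> np.ndarray:
    """Validate positive semi-definiteness; nearest-PSD repair if violated."""
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() >= -1e-10:
        return corr
    repaired = (eigvec * np.clip(eigval, 1e-10, None)) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    magnitude = float(np.abs(repaired - corr).max())
    log.warning("correlation matrix repaired to nearest PSD (max change %.3g)", magnitude)
    if magnitude > 0.1:
        raise ValidationError(
            f"correlation structure infeasible: PSD repair changed entries by {magnitude:.3g}"
        )
    return repaired


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a multi-group expression matrix with planted structure.

    Link alteration is deterministic given the config: within each hub the
    first ``round(reversal_fraction * m)`` targets reverse sign and the next
    ``round(shift_fraction * m)`` shift to background, so ground truth is
    reproducible independent of the sampling RNG. The TF→target library
    contains every planted hub→target relation plus ``n_decoy_targets``
    background-gene relations per hub (library entries without a planted
    co-expression change).
    """
    hubs, targets, background = _hub_layout(config)
    genes = hubs.copy()
    for hub in hubs:
        genes.extend(targets[hub])
    genes.extend(background)

    m = config.targets_per_hub
    n_rev = _round_half_up(config.reversal_fraction * m)
    n_shift = min(_round_half_up(config.shift_fraction * m), m - n_rev)
    base, bg = config.base_correlation, config.background_correlation

    baseline: dict[tuple[str, str], float] = {}
    altered: dict[tuple[str, str], float] = {}
    link_types: dict[tuple[str, str], str] = {}
    for hub in hubs:
        for j, t in enumerate(targets[hub]):
            baseline[(hub, t)] = base
            if j < n_rev:
                altered[(hub, t)] = -base
                link_types[tuple(sorted((hub, t)))] = "reversal"
            elif j < n_rev + n_shift:
                altered[(hub, t)] = bg
                link_types[tuple(sorted((hub, t)))] = "shift"
            else:
                altered[(hub, t)] = base

    structures = {
        "baseline": _ensure_psd(
            _correlation_matrix(genes, hubs, targets, background, baseline, bg)
        ),
        "altered": _ensure_psd(
            _correlation_matrix(genes, hubs, targets, background, altered, bg)
        ),
    }
    chol = {
        name: np.linalg.cholesky(corr + 1e-10 * np.eye(len(genes)))
        for name, corr in structures.items()
    }

    rng = np.random.default_rng(config.seed)
    columns, blocks, cond_of = [], [], {}
    for group in config.samples_per_group:  # insertion order: deterministic
        n = config.samples_per_group[group]
        which = "altered" if group in config.altered_groups else "baseline"
        z = rng.standard_normal((len(genes), n))
        blocks.append(8.0 + config.noise_sd * (chol[which] @ z))
        for k in range(n):
            sample = f"{group}_{k+1:02d}"
            columns.append(sample)
            cond_of[sample] = group
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    expr = ExpressionMatrix(values=values, conditions=pd.Series(cond_of))

    relations = [(hub, t) for hub in hubs for t in targets[hub]]
    for h, hub in enumerate(hubs):
        for d in range(min(config.n_decoy_targets, len(background))):
            relations.append((hub, background[(h * config.n_decoy_targets + d) % len(background)]))
    planted_dcgs = frozenset(
        hub
        for hub in hubs
        if any(link_types.get(tuple(sorted((hub, t)))) for t in targets[hub])
    )
    truth = GroundTruth(
        planted_dcg_genes=planted_dcgs,
        planted_dcl_links=frozenset(link_types),
        link_types=link_types,
        planted_library=TF2TargetLibrary.from_pairs(relations),
    )
    return expr, truth


@dataclass
class RecoveryScore:
    """Sensitivity and false-discovery fraction for DCGs and DCLs.

    NaN marks undefined entries (empty truth, or an empty report for the
    false-discovery fraction).
    """

    dcg_sensitivity: float
    dcg_false_discovery: float
    dcl_sensitivity: float
    dcl_false_discovery: float


def _sens_fdr(reported: frozenset, planted: frozenset) -> tuple[float, float]:
    sens = len(reported & planted) / len(planted) if planted else float("nan")
    fdr = (
        len(reported - planted) / len(reported) if reported else float("nan")
    )
    return sens, fdr


def recovery_score(report, truth: GroundTruth) -> RecoveryScore:
    """Score a comparison report against the planted ground truth.

    DCGs are compared on ``report.true_dcgs``; DCLs on the canonical
    unordered pairs of ``report.true_dcls``.
    """
    if not truth.planted_dcg_genes and not truth.planted_dcl_links:
        log.warning("recovery_score against empty ground truth is undefined")
    dcg_s, dcg_f = _sens_fdr(frozenset(report.true_dcgs), truth.planted_dcg_genes)
    links = frozenset(tuple(sorted(l)) for l in report.true_dcls)
    dcl_s, dcl_f = _sens_fdr(links, truth.planted_dcl_links)
    return RecoveryScore(dcg_s, dcg_f, dcl_s, dcl_f)
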