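"""Run configuration: every tunable of the pipeline in one validated object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .coexpression import LinkCutoff
from .dcp import SCHEME_FIXED, SCHEME_RESELECT
from .expression import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All analysis knobs; serialized verbatim into every run manifest.

    Defaults: hard correlation cutoff 0.8 on max(|r1|, |r2|); 500 label
    permutations with network re-selection; DCG calls at p <= 0.05 for both
    the dC permutation test and the binomial enrichment (FDR filtering off
    unless a threshold is supplied); LFC selection with delta = 0.25 over at
    most 20 equal-count magnitude bins.
    """

    cutoff: LinkCutoff = field(default_factory=LinkCutoff)
    correlation_method: str = "pearson"
    n_permutations: int = 500
    permutation_scheme: str = SCHEME_RESELECT
    seed: int = 0
    dcp_p_threshold: float = 0.05
    dcp_fdr_threshold: float | None = None
    dce_p_threshold: float = 0.05
    dce_delta: float = 0.25
    dce_bins: int = 20
    dce_epsilon: float = 1e-8
    dce_min_bin_count: int = 10

    def __post_init__(self) -> None:
        if isinstance(self.cutoff, dict):
            self.cutoff = LinkCutoff(**self.cutoff)
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError(f"unknown correlation method {self.correlation_method!r}")
        if self.permutation_scheme not in (SCHEME_RESELECT, SCHEME_FIXED):
            raise ValidationError(f"unknown permutation scheme {self.permutation_scheme!r}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 <= self.seed < 2**31:
            raise ValidationError("seed must lie in [0, 2^31)")
        for name in ("dcp_p_threshold", "dce_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.dcp_fdr_threshold is not None and not 0.0 < self.dcp_fdr_threshold <= 1.0:
            raise ValidationError("dcp_fdr_threshold must lie in (0, 1]")
        if not 0.0 < self.dce_delta < 1.0:
            raise ValidationError("dce_delta must lie in (0, 1)")
        if self.dce_bins < 1 or self.dce_min_bin_count < 1:
            raise ValidationError("dce_bins and dce_min_bin_count must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
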