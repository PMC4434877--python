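"""Gene-by-sample expression matrices with per-sample condition labels.

The container wraps a pandas DataFrame (rows = genes, columns = samples) of
continuous log2-scale intensities together with a sample→condition mapping.
It is the raw input of every two-condition comparison in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates the container invariants."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values for genes × samples plus condition labels.

    Parameters
    ----------
    values
        DataFrame with unique gene identifiers as the index and unique sample
        identifiers as columns. Must be fully numeric with no missing values.
    conditions
        Series mapping every sample identifier (index) to a condition label.

    Notes
    -----
    Group sizes are validated where they matter: correlation requires at least
    three samples per condition and that check happens (with the condition
    named) when correlations are computed, not at construction, so a matrix
    holding unused small groups can still be loaded and inspected.
    """

    values: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = sorted(set(v.index[v.index.duplicated()]))
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if v.columns.has_duplicates:
            dupes = sorted(set(v.columns[v.columns.duplicated()]))
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        try:
            v = v.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if v.isna().any().any():
            bad = v.columns[v.isna().any(axis=0)].tolist()
            raise ValidationError(f"missing expression values in samples {bad}")
        self.values = v
        cond = pd.Series(self.conditions)
        missing = set(v.columns) - set(cond.index)
        if missing:
            raise ValidationError(f"samples without a condition label: {sorted(missing)}")
        # Restrict and align the sheet to the samples actually present.
        self.conditions = cond.reindex(v.columns)

    # -- basic views ------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def condition_of(self) -> dict[str, str]:
        return dict(self.conditions)

    @property
    def condition_labels(self) -> list[str]:
        return sorted(set(self.conditions))

    def n_samples(self, condition: str) -> int:
        return int((self.conditions == condition).sum())

    def samples_in(self, condition: str) -> list[str]:
        """Sample ids of one condition, sorted for order-invariant downstream use."""
        if condition not in set(self.conditions):
            raise ValidationError(f"condition {condition!r} not present in sample sheet")
        return sorted(self.conditions.index[self.conditions == condition])

    def submatrix(self, condition: str) -> pd.DataFrame:
        """Genes × samples block for one condition (samples in sorted order)."""
        return self.values[self.samples_in(condition)]
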