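"""Plain-text readers and writers: expression TSV, sample sheets, TF→target
libraries, result tables and run manifests. Everything is tab-separated text."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dra import TF2TargetLibrary
from .expression import ExpressionMatrix, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_tf2target",
    "write_tf2target",
    "write_dcp_table",
    "write_dcl_table",
    "write_drl_table",
    "write_manifest",
]


def read_expression(path: str | Path, sample_sheet: str | Path | None = None) -> ExpressionMatrix:
    """Load a gene × sample TSV (first column = gene id, header = sample ids).

    Rejects duplicate gene ids (naming the gene and its line numbers), ragged
    rows and non-numeric cells with the offending location.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed table: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated(keep=False)]
        lines = {g: [int(i) + 2 for i in np.flatnonzero(frame.index == g)] for g in set(dupes)}
        raise ValidationError(f"{path}: duplicate gene id(s) at lines: {lines}")
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            gene = frame.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value for gene {gene!r} in sample {col!r}"
            )
    frame.index.name = None
    if sample_sheet is not None:
        conditions = read_sample_sheet(sample_sheet)
    else:
        conditions = pd.Series("all", index=frame.columns)
    return ExpressionMatrix(values=frame.astype(float), conditions=conditions)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.values.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Two-column TSV (sample id, condition label) → sample→condition Series."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] != 2:
        raise ValidationError(f"{path}: sample sheet must have exactly 2 columns")
    if frame[0].duplicated().any():
        dupes = sorted(set(frame.loc[frame[0].duplicated(), 0]))
        raise ValidationError(f"{path}: duplicate sample id(s): {dupes}")
    return pd.Series(frame[1].values, index=frame[0].values)


def write_sample_sheet(conditions: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": conditions.index, "condition": conditions.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tf2target(path: str | Path) -> TF2TargetLibrary:
    """Two-column TSV (TF, target), one relation per line, '#' comments."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] != 2:
        raise ValidationError(f"{path}: TF2target library must have exactly 2 columns")
    return TF2TargetLibrary.from_pairs(frame.itertuples(index=False, name=None))


def write_tf2target(lib: TF2TargetLibrary, path: str | Path) -> None:
    rows = sorted(lib.relations)
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_dcp_table(result, path: str | Path) -> None:
    """Per-gene dC results: gene, dC, n_neighbors, p, fdr."""
    table = result.table if hasattr(result, "table") else result
    table.to_csv(path, sep="\t", index=False)


def write_dcl_table(dcl_table: pd.DataFrame, path: str | Path) -> None:
    """DCL table mirroring the published layout: gene pair, both correlations,
    reversal type, DCL flag and selection bin."""
    out = dcl_table.rename(
        columns={
            "gene_a": "gene A",
            "gene_b": "gene B",
            "r1": "Cor.1",
            "r2": "Cor.2",
            "reversal_type": "Type",
            "selection_bin": "bin",
        }
    )[["gene A", "gene B", "Cor.1", "Cor.2", "Type", "is_dcl", "bin"]]
    out.insert(0, "NO.", np.arange(1, len(out) + 1))
    out.to_csv(path, sep="\t", index=False)


def write_drl_table(drls: pd.DataFrame, path: str | Path) -> None:
    """TF→target DCL table: NO., TF, Target, p.DCG, Cor.1, Cor.2, Type."""
    out = drls.rename(
        columns={
            "tf": "TF",
            "target": "Target",
            "p_dcg": "p.DCG",
            "r1": "Cor.1",
            "r2": "Cor.2",
            "reversal_type": "Type",
        }
    )[["TF", "Target", "p.DCG", "Cor.1", "Cor.2", "Type"]]
    out.insert(0, "NO.", np.arange(1, len(out) + 1))
    out.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, payload: dict) -> None:
    """Machine-readable run manifest (JSON) with package/runtime versions."""
    manifest = {
        "dcreg_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        **payload,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
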