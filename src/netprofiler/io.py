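"""Reading and writing the TSV interchange formats.

Expression tables are samples x genes with a header row of gene ids and a
first column of sample ids (an orientation flag accepts genes x samples).
Sample-specific coefficient tensors are persisted as long-format edge lists
(sample, regulator, target, coefficient) holding only nonzero entries.
All tables round-trip at full float precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionPanel, ModulatorTable
from .exceptions import InvalidParameterError
from .network import SampleSpecificNetwork

__all__ = [
    "read_expression_table",
    "read_modulator_table",
    "write_edge_list",
    "read_edge_list",
    "network_from_edges",
    "write_loadings",
    "read_loadings",
    "write_similarity",
    "read_similarity",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_numeric_table(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    sep = _sep_for(path)
    # pandas silently renames duplicate header ids, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise InvalidParameterError(
                f"duplicate column id {name!r} in {path}"
            )
        seen.add(name)
    try:
        frame = pd.read_csv(
            path, sep=sep, index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # parse errors carry pandas' line info
        raise InvalidParameterError(f"cannot parse {what} {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise InvalidParameterError(f"duplicate row id {dup!r} in {path}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[int(np.argmax(bad.to_numpy()))]
            raise InvalidParameterError(
                f"non-numeric value {frame.loc[row, col]!r} at row {row!r}, "
                f"column {col!r} in {path}"
            )
        frame[col] = converted
    if frame.isna().any().any():
        arr = frame.isna().to_numpy()
        i, j = np.argwhere(arr)[0]
        raise InvalidParameterError(
            f"missing value at row {frame.index[i]!r}, column "
            f"{frame.columns[j]!r} in {path}"
        )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_expression_table(
    path: str | Path, orientation: str = "samples_by_genes"
) -> pd.DataFrame:
    """Read an expression TSV/CSV as a samples x genes frame.

    ``orientation="genes_by_samples"`` transposes the file on input.
    Duplicate ids and non-numeric cells are rejected with coordinates.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    frame = _read_numeric_table(path, "expression table")
    if orientation == "genes_by_samples":
        frame = frame.T
    return frame


def read_modulator_table(path: str | Path) -> ModulatorTable:
    """Read a modulator TSV (first column sample id, named characteristics)."""
    return ModulatorTable.from_frame(_read_numeric_table(path, "modulator table"))


def write_edge_list(network: SampleSpecificNetwork, path: str | Path) -> None:
    """Persist the nonzero coefficients as a long-format edge list."""
    network.to_edges().to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip",
                        dtype={"sample": str, "regulator": str, "target": str})
    required = {"sample", "regulator", "target", "coefficient"}
    if not required <= set(frame.columns):
        raise InvalidParameterError(
            f"edge list {path} must have columns {sorted(required)}"
        )
    return frame


def network_from_edges(
    edges: pd.DataFrame,
    sample_ids: Sequence[str],
    regulator_ids: Sequence[str],
    target_ids: Sequence[str],
) -> SampleSpecificNetwork:
    """Rebuild a coefficient tensor from a long-format edge list."""
    sample_ids = [str(s) for s in sample_ids]
    regulator_ids = [str(s) for s in regulator_ids]
    target_ids = [str(s) for s in target_ids]
    spos = {s: i for i, s in enumerate(sample_ids)}
    rpos = {s: i for i, s in enumerate(regulator_ids)}
    tpos = {s: i for i, s in enumerate(target_ids)}
    coef = np.zeros((len(sample_ids), len(regulator_ids), len(target_ids)))
    for row in edges.itertuples(index=False):
        try:
            coef[spos[row.sample], rpos[row.regulator], tpos[row.target]] = (
                row.coefficient
            )
        except KeyError as exc:
            raise InvalidParameterError(
                f"edge list references unknown id {exc.args[0]!r}"
            ) from None
    return SampleSpecificNetwork(
        coef, np.zeros((len(sample_ids), len(target_ids))),
        regulator_ids, target_ids, sample_ids,
    )


def write_loadings(
    loadings: np.ndarray, regulator_ids: Sequence[str], path: str | Path
) -> None:
    """Loadings TSV: rows = regulator genes, columns = components."""
    frame = pd.DataFrame(
        loadings,
        index=[str(g) for g in regulator_ids],
        columns=[f"component_{k + 1}" for k in range(loadings.shape[1])],
    )
    frame.index.name = "regulator"
    frame.to_csv(path, sep="\t")


def read_loadings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")


def write_similarity(
    W: np.ndarray, regulator_ids: Sequence[str], path: str | Path
) -> None:
    ids = [str(g) for g in regulator_ids]
    frame = pd.DataFrame(W, index=ids, columns=ids)
    frame.index.name = "regulator"
    frame.to_csv(path, sep="\t")


def read_similarity(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")
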