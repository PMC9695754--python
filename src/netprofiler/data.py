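"""In-memory containers for expression panels and modulator tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .exceptions import AlignmentError, InvalidParameterError


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise InvalidParameterError(f"duplicate {what} id {dup!r}")
    return ids


@dataclass
class ModulatorTable:
    """Per-sample cancer characteristics M (n samples x h characteristics).

    A characteristic ("modulator") is any per-sample quantity indexing the
    varying coefficients, e.g. the sensitivity of each cell line to a drug.
    """

    values: NDArray[np.float64]
    sample_ids: list[str]
    characteristic_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise InvalidParameterError("modulator values must be 2-d")
        if self.values.shape[0] == 1 and len(self.sample_ids) > 1:
            self.values = self.values.T
        n, h = self.values.shape
        if n < 2:
            raise InvalidParameterError("need at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise InvalidParameterError(
                f"missing/non-finite modulator value at sample "
                f"{self.sample_ids[i]!r}, characteristic "
                f"{self.characteristic_names[j]!r}"
            )
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.characteristic_names = [str(c) for c in self.characteristic_names]
        if len(self.sample_ids) != n or len(self.characteristic_names) != h:
            raise InvalidParameterError("id lists do not match value shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_characteristics(self) -> int:
        return self.values.shape[1]

    def column(self, name: str | None = None) -> NDArray[np.float64]:
        """One characteristic as a vector (default: the first)."""
        if name is None:
            return self.values[:, 0]
        try:
            j = self.characteristic_names.index(str(name))
        except ValueError:
            raise InvalidParameterError(
                f"unknown characteristic {name!r}; have {self.characteristic_names}"
            ) from None
        return self.values[:, j]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ModulatorTable":
        return cls(
            frame.to_numpy(dtype=float),
            list(frame.index.astype(str)),
            list(frame.columns.astype(str)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.characteristic_names
        )


@dataclass
class ExpressionPanel:
    """Regulator matrix X (n x p) and target matrix Y (n x q) with identifiers.

    Regulator and target gene sets may overlap (or coincide); downstream
    fitting excludes the self-loop of a gene onto itself.
    """

    X: NDArray[np.float64]
    Y: NDArray[np.float64]
    regulator_ids: list[str]
    target_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise InvalidParameterError("X and Y must be 2-d")
        if self.X.shape[0] != self.Y.shape[0]:
            raise AlignmentError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        for name, arr in (("X", self.X), ("Y", self.Y)):
            if not np.all(np.isfinite(arr)):
                i, j = np.argwhere(~np.isfinite(arr))[0]
                raise InvalidParameterError(
                    f"missing/non-finite value in {name} at row {i}, column {j}"
                )
        self.regulator_ids = _check_ids(self.regulator_ids, "regulator")
        self.target_ids = _check_ids(self.target_ids, "target")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.X.shape != (len(self.sample_ids), len(self.regulator_ids)):
            raise AlignmentError("X shape does not match sample/regulator ids")
        if self.Y.shape != (len(self.sample_ids), len(self.target_ids)):
            raise AlignmentError("Y shape does not match sample/target ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_regulators(self) -> int:
        return self.X.shape[1]

    @property
    def n_targets(self) -> int:
        return self.Y.shape[1]

    @classmethod
    def from_expression(
        cls,
        expression: pd.DataFrame,
        regulators: Sequence[str] | None = None,
        targets: Sequence[str] | None = None,
    ) -> "ExpressionPanel":
        """Split one samples-x-genes expression frame into regulators/targets.

        With no gene lists every gene plays both roles (self-loops are
        excluded at fit time).
        """
        genes = list(expression.columns.astype(str))
        regulators = list(map(str, regulators)) if regulators is not None else genes
        targets = list(map(str, targets)) if targets is not None else genes
        for g in list(regulators) + list(targets):
            if g not in set(genes):
                raise AlignmentError(f"gene {g!r} not present in expression table")
        return cls(
            expression.loc[:, regulators].to_numpy(dtype=float),
            expression.loc[:, targets].to_numpy(dtype=float),
            regulators,
            targets,
            list(expression.index.astype(str)),
        )


def check_sample_alignment(
    panel: ExpressionPanel, modulators: ModulatorTable
) -> None:
    if panel.sample_ids != modulators.sample_ids:
        raise AlignmentError(
            "expression panel and modulator table have different sample ids"
        )
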