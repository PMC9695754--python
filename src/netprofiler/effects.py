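"""Regulatory effects and consensus edge summaries.

The *regulatory effect* of regulator j on target l in sample alpha is the
fitted coefficient times that sample's regulator expression,

    r_{a l j} = beta_hat_{jl}(m_a) * x_{a j},

so for each target gene l the effects over all samples form an n x p matrix
R_l.  These matrices are the input both of the common-component analysis
(:mod:`netprofiler.netscca`) and of the edge-knockout importance procedure
(:mod:`netprofiler.xprediction`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .data import ExpressionPanel
from .exceptions import AlignmentError, InvalidParameterError
from .network import SampleSpecificNetwork

__all__ = ["RegulatoryEffectSet", "regulatory_effects", "consensus_edges"]


@dataclass
class RegulatoryEffectSet:
    """Per-target regulatory-effect matrices R_l (each n samples x p regulators)."""

    matrices: list[NDArray[np.float64]]
    target_ids: list[str]
    regulator_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n, p = len(self.sample_ids), len(self.regulator_ids)
        if len(self.matrices) != len(self.target_ids):
            raise AlignmentError("one matrix per target is required")
        for l, R in enumerate(self.matrices):
            R = np.asarray(R, dtype=float)
            if R.shape != (n, p):
                raise AlignmentError(
                    f"effect matrix for target {self.target_ids[l]!r} has "
                    f"shape {R.shape}, expected {(n, p)}"
                )
            self.matrices[l] = R

    @property
    def n_targets(self) -> int:
        return len(self.matrices)

    def feature_matrix(self) -> tuple[NDArray[np.float64], list[tuple[str, str]]]:
        """Flatten to (n, E): one column per edge nonzero in >= 1 sample.

        Returns the matrix and the edge index, a list of
        (target_id, regulator_id) pairs aligned with the columns.
        """
        cols, index = [], []
        for l, R in enumerate(self.matrices):
            nz = np.any(R != 0, axis=0)
            for j in np.nonzero(nz)[0]:
                cols.append(R[:, j])
                index.append((self.target_ids[l], self.regulator_ids[j]))
        if not cols:
            raise InvalidParameterError("no nonzero regulatory effects")
        return np.column_stack(cols), index

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table of nonzero effects."""
        rows = []
        for l, R in enumerate(self.matrices):
            a, j = np.nonzero(R)
            rows.append(
                pd.DataFrame(
                    {
                        "sample": [self.sample_ids[i] for i in a],
                        "regulator": [self.regulator_ids[i] for i in j],
                        "target": self.target_ids[l],
                        "effect": R[a, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["sample", "regulator", "target", "effect"]
        )


def regulatory_effects(
    network: SampleSpecificNetwork, panel: ExpressionPanel
) -> RegulatoryEffectSet:
    """Compute r_{alj} = beta_hat_{jl}(m_a) * x_{aj} for every edge.

    Coefficients are already on the original expression scale, so the
    product uses raw expression values.  Effects inherit the sparsity
    pattern of the coefficients exactly.
    """
    if (
        network.sample_ids != panel.sample_ids
        or network.regulator_ids != panel.regulator_ids
        or network.target_ids != panel.target_ids
    ):
        raise AlignmentError("network and panel identifiers do not align")
    matrices = [
        network.coefficients[:, :, l] * panel.X
        for l in range(len(network.target_ids))
    ]
    return RegulatoryEffectSet(
        matrices,
        list(network.target_ids),
        list(network.regulator_ids),
        list(network.sample_ids),
    )


def consensus_edges(
    network: SampleSpecificNetwork,
    sample_subset=None,
    statistic: str = "median",
) -> pd.DataFrame:
    """Summarize each edge over a subset of samples (default: all).

    Per (regulator, target) pair the ``statistic`` (median by default, mean
    behind the flag) of the coefficients over the subset is reported, along
    with the number of subset samples in which the edge is present.  Edges
    zero in every subset sample are omitted.
    """
    if statistic not in ("median", "mean"):
        raise InvalidParameterError(f"unknown statistic {statistic!r}")
    n = network.coefficients.shape[0]
    if sample_subset is None:
        idx = np.arange(n)
    else:
        subset = list(sample_subset)
        if len(subset) == 0:
            raise InvalidParameterError("sample subset is empty")
        if all(isinstance(s, (int, np.integer)) for s in subset):
            idx = np.asarray(subset, dtype=int)
        else:
            pos = {s: i for i, s in enumerate(network.sample_ids)}
            try:
                idx = np.asarray([pos[str(s)] for s in subset], dtype=int)
            except KeyError as exc:
                raise InvalidParameterError(
                    f"unknown sample id {exc.args[0]!r}"
                ) from None
    sub = network.coefficients[idx]  # (m, p, q)
    stat = np.median(sub, axis=0) if statistic == "median" else sub.mean(axis=0)
    n_nonzero = np.count_nonzero(sub != 0, axis=0)
    j, l = np.nonzero(n_nonzero)
    return pd.DataFrame(
        {
            "regulator": [network.regulator_ids[i] for i in j],
            "target": [network.target_ids[i] for i in l],
            f"{statistic}_coefficient": stat[j, l],
            "n_nonzero_samples": n_nonzero[j, l],
        }
    )
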