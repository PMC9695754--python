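"""End-to-end pipeline: filter -> fit networks -> effects -> NetSCCA -> Xprediction.

The pipeline is driven by a JSON configuration (validated strictly: unknown
keys are rejected, referenced paths must exist) and writes TSV outputs plus
a JSON run manifest holding the full parameterization, seed and library
versions — enough to re-run identically.  Outputs are written as each stage
completes, so a failing stage leaves earlier results on disk and aborts
with the stage name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .data import ExpressionPanel, ModulatorTable
from .effects import consensus_edges, regulatory_effects
from .exceptions import InvalidParameterError, PipelineStageError
from .io import (
    read_expression_table,
    read_modulator_table,
    write_edge_list,
    write_loadings,
    write_similarity,
)
from .kernels import KernelConfig
from .netscca import jaccard_similarity, neighbor_sets_from_network, netscca_fit
from .network import (
    PenaltySpec,
    fit_sample_specific_network,
    variance_filter,
)
from .xprediction import PredictorSpec, xprediction

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KernelBlock(_Strict):
    mode: Literal["constant", "adaptive_knn", "multivariate"] = "adaptive_knn"
    bandwidth: Optional[float] = None
    k: Optional[int] = None
    range_factor: float | Literal["auto"] = "auto"
    epsilon_floor: float = 1e-8


class PenaltyBlock(_Strict):
    family: Literal["ridge", "lasso", "elastic_net"] = "lasso"
    reg_lambda: float | Literal["auto"] = "auto"
    gamma: Optional[float] = None
    selection: Literal["weighted_bic", "weighted_cv"] = "weighted_bic"
    per_sample_lambda: bool = False


class NetsccaBlock(_Strict):
    enabled: bool = True
    n_components: int | Literal["auto"] = "auto"
    lambda1: float = 0.0
    lambda2: float = 0.0
    tol: float = 1e-4
    max_iter: int = 200


class XpredictionBlock(_Strict):
    enabled: bool = True
    model: Literal["kernel_svm", "random_forest", "feedforward_nn"] = (
        "feedforward_nn"
    )
    hyperparameters: dict = {}
    cv_folds: int = 10
    n_repeats: int = 20
    alpha: float = 0.05
    low_percentile: float = 5.0
    high_percentile: float = 95.0
    adjust: Optional[Literal["bh"]] = None


class PipelineConfig(_Strict):
    """Validated configuration of one pipeline run."""

    expression_path: str
    modulator_path: str
    output_dir: str
    orientation: Literal["samples_by_genes", "genes_by_samples"] = (
        "samples_by_genes"
    )
    modulator_column: Optional[str] = None
    sensitivity_column: Optional[str] = None
    regulators_path: Optional[str] = None
    targets_path: Optional[str] = None
    variance_top_fraction: float = 1.0
    kernel: KernelBlock = KernelBlock()
    penalty: PenaltyBlock = PenaltyBlock()
    netscca: NetsccaBlock = NetsccaBlock()
    xprediction: XpredictionBlock = XpredictionBlock()
    seed: int = 0
    threads: int = 1
    log_level: str = "INFO"

    @field_validator("variance_top_fraction")
    @classmethod
    def _check_fraction(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("variance_top_fraction must lie in (0, 1]")
        return v

    def validate_paths(self) -> None:
        for name in ("expression_path", "modulator_path", "regulators_path",
                     "targets_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise InvalidParameterError(f"{name} does not exist: {value}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        config = cls.model_validate(raw)
        config.validate_paths()
        return config


def _read_gene_list(path: str | None) -> list[str] | None:
    if path is None:
        return None
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns a dict of output paths.

    Stages: variance filter -> sample-specific network fit -> regulatory
    effects (+ consensus edges) -> optional NetSCCA -> optional Xprediction.
    The run is deterministic given (config, seed) and independent of the
    thread count.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "read_inputs"
    try:
        expression = read_expression_table(
            config.expression_path, config.orientation
        )
        modulators_full = read_modulator_table(config.modulator_path)
        regulators = _read_gene_list(config.regulators_path)
        targets = _read_gene_list(config.targets_path)

        stage = "variance_filter"
        if config.variance_top_fraction < 1.0:
            keep = variance_filter(
                expression.to_numpy(), config.variance_top_fraction
            )
            expression = expression.iloc[:, keep]
            kept = set(expression.columns)
            if regulators is not None:
                regulators = [g for g in regulators if g in kept]
            if targets is not None:
                targets = [g for g in targets if g in kept]
        panel = ExpressionPanel.from_expression(expression, regulators, targets)

        mcol = config.modulator_column
        if config.kernel.mode == "multivariate":
            modulators = modulators_full
        else:
            modulators = ModulatorTable(
                modulators_full.column(mcol)[:, None],
                modulators_full.sample_ids,
                [mcol or modulators_full.characteristic_names[0]],
            )

        stage = "fit_network"
        kernel = KernelConfig(
            mode=config.kernel.mode,
            bandwidth=config.kernel.bandwidth,
            k=config.kernel.k,
            range_factor=config.kernel.range_factor,
            epsilon_floor=config.kernel.epsilon_floor,
        )
        penalty = PenaltySpec(
            family=config.penalty.family,
            lam=config.penalty.reg_lambda,
            gamma=config.penalty.gamma,
            selection=config.penalty.selection,
        )
        network = fit_sample_specific_network(
            panel, modulators, kernel, penalty,
            per_sample_lambda=config.penalty.per_sample_lambda,
            seed=config.seed, threads=config.threads,
        )
        write_edge_list(network, out / "edges.tsv")
        outputs["edges"] = str(out / "edges.tsv")
        consensus_edges(network).to_csv(
            out / "consensus.tsv", sep="\t", index=False
        )
        outputs["consensus"] = str(out / "consensus.tsv")

        stage = "regulatory_effects"
        effects = regulatory_effects(network, panel)
        effects.to_long_frame().to_csv(
            out / "effects.tsv", sep="\t", index=False
        )
        outputs["effects"] = str(out / "effects.tsv")

        if config.netscca.enabled:
            stage = "netscca"
            similarity = jaccard_similarity(neighbor_sets_from_network(network))
            write_similarity(
                similarity.W, panel.regulator_ids, out / "similarity.tsv"
            )
            outputs["similarity"] = str(out / "similarity.tsv")
            model = netscca_fit(
                effects, W=similarity, K=config.netscca.n_components,
                lambda1=config.netscca.lambda1, lambda2=config.netscca.lambda2,
                tol=config.netscca.tol, max_iter=config.netscca.max_iter,
            )
            write_loadings(model.loadings, panel.regulator_ids,
                           out / "loadings.tsv")
            outputs["loadings"] = str(out / "loadings.tsv")

        if config.xprediction.enabled:
            stage = "xprediction"
            scol = config.sensitivity_column
            sensitivity = modulators_full.column(scol)
            xb = config.xprediction
            spec = PredictorSpec(
                model=xb.model, hyperparameters=xb.hyperparameters,
                cv_folds=xb.cv_folds, n_repeats=xb.n_repeats, seed=config.seed,
            )
            table = xprediction(
                effects, sensitivity, spec, alpha=xb.alpha,
                low_p=xb.low_percentile, high_p=xb.high_percentile,
                adjust=xb.adjust, threads=config.threads,
            )
            table.to_csv(out / "importance.tsv", sep="\t", index=False)
            outputs["importance"] = str(out / "importance.tsv")

        stage = "manifest"
        manifest = {
            "package": "netprofiler",
            "version": __version__,
            "config": config.model_dump(),
            "seed": config.seed,
            "library_versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": __import__("sklearn").__version__,
                "scipy": __import__("scipy").__version__,
            },
            "outputs": outputs,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest"] = str(out / "manifest.json")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    return outputs
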