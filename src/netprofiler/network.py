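"""Kernel-weighted L1-type regression for sample-specific network inference.

For each target gene ``y_l`` and each target sample ``alpha`` the model

    y_il = sum_j beta_jl(m_alpha) x_ij + eps_il

is fitted by minimizing

    1/2 sum_i w_i(alpha) (y_il - b0 - sum_j beta_jl x_ij)^2 + P(beta_l)

where ``w_i(alpha)`` are kernel weights over the modulator values (see
:mod:`netprofiler.kernels`) and ``P`` is a ridge, lasso or elastic-net
penalty ``P = lam * sum_j (gamma beta_j^2 + (1-gamma)|beta_j|)``.  A nonzero
``beta_jl(m_alpha)`` is a directed edge regulator j -> target l in sample
alpha's network.

Implementation notes
--------------------
* The solver is cyclic coordinate descent on the weighted objective.  Before
  fitting, kernel weights are rescaled to sum to n so one lambda grid is
  comparable across target samples, predictors are standardized to weighted
  unit variance and the response is weighted-centred; coefficients are
  returned on the original scale.  An intercept is always fitted implicitly.
* lambda is selected on a grid by weighted BIC (default) or weighted k-fold
  cross-validation; by default one lambda per target gene, shared across
  target samples, with per-sample selection behind a flag.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from joblib import Parallel, delayed
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator

from .data import ExpressionPanel, ModulatorTable, check_sample_alignment
from .exceptions import (
    DegenerateWeightsError,
    InvalidParameterError,
    NetprofilerError,
)
from .kernels import KernelConfig, SampleWeights, kernel_weights

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "SampleSpecificNetwork",
    "fit_penalized_regression",
    "select_lambda",
    "fit_sample_specific_network",
    "variance_filter",
    "NetworkProfiler",
]

#: below this weighted sample size a per-sample fit is flagged as unreliable
EFFECTIVE_SIZE_WARNING = 10.0


@dataclass
class PenaltySpec:
    """Penalty family and regularization strength.

    ``lam`` may be a number or ``"auto"``, in which case it is chosen on
    ``lambda_grid`` (auto-generated when omitted) by ``selection``.
    ``gamma`` mixes ridge (gamma=1) and lasso (gamma=0) parts of the elastic
    net penalty ``lam * sum(gamma b^2 + (1-gamma)|b|)``.
    """

    family: Literal["ridge", "lasso", "elastic_net"] = "lasso"
    lam: float | Literal["auto"] = "auto"
    gamma: float | None = None
    lambda_grid: NDArray[np.float64] | None = None
    selection: Literal["weighted_bic", "weighted_cv"] = "weighted_bic"

    def __post_init__(self) -> None:
        if self.family not in ("ridge", "lasso", "elastic_net"):
            raise InvalidParameterError(f"unknown penalty family {self.family!r}")
        if self.family == "elastic_net":
            if self.gamma is None or not 0 <= self.gamma <= 1:
                raise InvalidParameterError(
                    "elastic_net requires gamma in [0, 1]"
                )
        if isinstance(self.lam, str):
            if self.lam != "auto":
                raise InvalidParameterError(f"lam must be a number or 'auto'")
        elif not self.lam >= 0:
            raise InvalidParameterError("lam must be nonnegative")
        if self.selection not in ("weighted_bic", "weighted_cv"):
            raise InvalidParameterError(f"unknown selection {self.selection!r}")

    def l1_l2(self, lam: float) -> tuple[float, float]:
        """Split lam into (l1, l2) coefficients of sum|b| and sum b^2."""
        if self.family == "lasso":
            return lam, 0.0
        if self.family == "ridge":
            return 0.0, lam
        return lam * (1.0 - self.gamma), lam * self.gamma


def _resolve_weights(
    weights: SampleWeights | ArrayLike | None, n: int
) -> NDArray[np.float64]:
    if weights is None:
        return np.ones(n)
    if isinstance(weights, SampleWeights):
        w = np.asarray(weights.weights, dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise InvalidParameterError(f"weights must have shape ({n},)")
    if np.any(w < 0):
        raise InvalidParameterError("weights must be nonnegative")
    if not np.any(w > 0):
        raise DegenerateWeightsError("all kernel weights are zero")
    if np.count_nonzero(w > 0) < 2:
        raise DegenerateWeightsError("fewer than 2 samples with positive weight")
    return w


def _coordinate_descent(
    X: NDArray,
    y: NDArray,
    w: NDArray,
    l1: float,
    l2: float,
    tol: float,
    max_iter: int,
    beta_init: NDArray | None = None,
) -> tuple[NDArray, bool, int]:
    """Cyclic CD for 1/2 sum w (y - X b)^2 + l1 ||b||_1 + l2 ||b||_2^2.

    X and y are assumed already centred/scaled; no intercept here.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta_init is None else beta_init.copy()
    wX = w[:, None] * X
    z = np.einsum("ij,ij->j", wX, X)  # sum_i w_i x_ij^2
    r = y - X @ beta
    active = z > 0
    denom = z + 2.0 * l2
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            if not active[j]:
                continue
            bj = beta[j]
            rho = wX[:, j] @ r + z[j] * bj
            if l1 > 0:
                new = math.copysign(max(abs(rho) - l1, 0.0), rho) / denom[j]
            else:
                new = rho / denom[j]
            if new != bj:
                r += X[:, j] * (bj - new)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        if max_delta < tol:
            converged = True
            break
    return beta, converged, it


@dataclass
class _FitResult:
    coef: NDArray[np.float64]
    intercept: float
    lam: float
    converged: bool
    n_iter: int
    effective_size: float


def fit_penalized_regression(
    X: ArrayLike,
    y: ArrayLike,
    penalty: PenaltySpec | None = None,
    weights: SampleWeights | ArrayLike | None = None,
    standardize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    seed: int = 0,
) -> _FitResult:
    """Fit one weighted penalized regression; coefficients on the raw scale.

    Minimizes ``1/2 sum_i w_i (y_i - b0 - x_i . b)^2 + P(b)``.  With uniform
    weights and ``standardize=False`` this is the standard lasso / ridge /
    elastic net on the raw predictors.

    Returns an object with ``coef``, ``intercept``, the ``lam`` actually
    used, convergence information and the effective (pre-rescaling) weight
    sum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise InvalidParameterError("X must be (n, p) and y length n")
    n, p = X.shape
    w = _resolve_weights(weights, n)
    penalty = penalty or PenaltySpec()

    effective = float(w.sum())
    wsum = effective
    mu_x = (w @ X) / wsum
    mu_y = float(w @ y) / wsum
    Xc = X - mu_x
    yc = y - mu_y

    var_y = float(w @ yc**2) / wsum
    if var_y <= 1e-300:
        warnings.warn(
            "response is constant under the weights; returning an "
            "intercept-only model",
            RuntimeWarning,
            stacklevel=2,
        )
        lamv = penalty.lam if not isinstance(penalty.lam, str) else 0.0
        return _FitResult(np.zeros(p), mu_y, float(lamv), True, 0, effective)

    if standardize:
        scale = np.sqrt((w @ Xc**2) / wsum)
        scale = np.where(scale > 1e-300, scale, 1.0)
    else:
        scale = np.ones(p)
    Xs = Xc / scale

    lam = penalty.lam
    if isinstance(lam, str):
        lam = select_lambda(X, y, weights=w, penalty=penalty, seed=seed,
                            standardize=standardize, tol=tol, max_iter=max_iter)
    l1, l2 = penalty.l1_l2(float(lam))
    beta_s, converged, n_iter = _coordinate_descent(
        Xs, yc, w, l1, l2, tol, max_iter
    )
    # floating-point dust at the soft-threshold boundary is not an edge
    if np.any(beta_s != 0):
        beta_s[np.abs(beta_s) < 1e-10 * max(1.0, np.abs(beta_s).max())] = 0.0
    coef = beta_s / scale
    intercept = mu_y - float(coef @ mu_x)
    return _FitResult(coef, intercept, float(lam), converged, n_iter, effective)


def default_lambda_grid(
    X: ArrayLike,
    y: ArrayLike,
    weights: ArrayLike | None = None,
    n_points: int = 30,
    ratio: float = 1e-3,
    standardize: bool = True,
) -> NDArray[np.float64]:
    """Geometric lambda grid from the smallest all-zero lambda downwards."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = _resolve_weights(weights, X.shape[0])
    wsum = w.sum()
    mu_x = (w @ X) / wsum
    mu_y = float(w @ y) / wsum
    Xc, yc = X - mu_x, y - mu_y
    if standardize:
        scale = np.sqrt((w @ Xc**2) / wsum)
        scale = np.where(scale > 1e-300, scale, 1.0)
        Xc = Xc / scale
    lam_max = float(np.max(np.abs((w * yc) @ Xc)))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_points)


def _effective_sample_size(w: NDArray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    return float(w.sum() ** 2 / (w**2).sum())


def _refit_rss(X: NDArray, y: NDArray, w: NDArray, support: NDArray) -> float:
    """Weighted RSS of the OLS refit (with intercept) on the active set.

    Scoring candidate active sets by their relaxed (unshrunken) fit removes
    the lasso shrinkage bias from information-criterion model selection.
    """
    Xa = np.column_stack([np.ones(len(y)), X[:, support]])
    A = Xa.T @ (w[:, None] * Xa)
    b = Xa.T @ (w * y)
    beta = np.linalg.lstsq(A, b, rcond=None)[0]
    resid = y - Xa @ beta
    return float(w @ resid**2)


def _weighted_bic(rss: float, nnz: int, wsum: float, ess: float) -> float:
    """BIC of a weighted fit on the effective-sample-size scale.

    Kernel weights overstate the information in a local fit when the
    nominal n is used; the Kish effective size is the honest sample size
    for both the likelihood term and the complexity penalty.
    """
    rss = max(rss, 1e-300)
    ess = max(ess, 2.0)
    return ess * math.log(rss / wsum) + nnz * math.log(ess)


def select_lambda(
    X: ArrayLike,
    y: ArrayLike,
    weights: SampleWeights | ArrayLike | None = None,
    penalty: PenaltySpec | None = None,
    seed: int = 0,
    standardize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    cv_folds: int = 5,
) -> float:
    """Choose lambda on a grid by weighted BIC or weighted k-fold CV.

    Deterministic given ``seed`` (the seed only shuffles CV folds).  Ties
    are broken toward the larger (sparser) lambda.
    """
    penalty = penalty or PenaltySpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    w = _resolve_weights(weights, n)
    grid = penalty.lambda_grid
    if grid is None:
        grid = default_lambda_grid(X, y, w, standardize=standardize)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]  # large -> small
    if grid.size == 0:
        raise InvalidParameterError("lambda grid is empty")
    if grid.size == 1:
        return float(grid[0])

    if penalty.selection == "weighted_bic":
        ess = _effective_sample_size(w)
        scores = []
        for lam in grid:
            fit = fit_penalized_regression(
                X, y, replace(penalty, lam=float(lam)), weights=w,
                standardize=standardize, tol=tol, max_iter=max_iter,
            )
            support = np.nonzero(fit.coef)[0]
            rss = _refit_rss(X, y, w, support)
            scores.append(_weighted_bic(rss, len(support), float(w.sum()), ess))
        return float(grid[int(np.argmin(scores))])

    # weighted k-fold CV on samples with positive weight
    rng = np.random.default_rng(seed)
    idx = np.nonzero(w > 0)[0]
    rng.shuffle(idx)
    folds = np.array_split(idx, min(cv_folds, len(idx)))
    errors = np.zeros(len(grid))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if np.count_nonzero(w[mask] > 0) < 2:
            continue
        for gi, lam in enumerate(grid):
            fit = fit_penalized_regression(
                X[mask], y[mask], replace(penalty, lam=float(lam)),
                weights=w[mask], standardize=standardize, tol=tol,
                max_iter=max_iter,
            )
            resid = y[fold] - fit.intercept - X[fold] @ fit.coef
            errors[gi] += float(w[fold] @ resid**2)
    return float(grid[int(np.argmin(errors))])


def variance_filter(
    expression: ArrayLike, top_fraction: float
) -> NDArray[np.intp]:
    """Indices of the ceil(top_fraction * G) highest-variance genes.

    Ties in variance are broken by gene order; the returned indices are
    sorted ascending.
    """
    if not 0 < top_fraction <= 1:
        raise InvalidParameterError("top_fraction must lie in (0, 1]")
    arr = np.asarray(expression, dtype=float)
    var = arr.var(axis=0, ddof=1)
    order = np.argsort(-var, kind="stable")
    m = math.ceil(top_fraction * arr.shape[1])
    return np.sort(order[:m])


@dataclass
class SampleSpecificNetwork:
    """Fitted sample-specific networks: one p x q coefficient matrix per sample.

    ``coefficients[alpha, j, l]`` is the estimated effect of regulator j on
    target l in sample alpha's network; a nonzero entry is an edge.
    ``diagnostics`` records per-(sample, target) effective kernel size and
    the lambda used; ``failures`` lists (alpha, l, reason) for fits that
    could not be performed.
    """

    coefficients: NDArray[np.float64]  # (n, p, q)
    intercepts: NDArray[np.float64]  # (n, q)
    regulator_ids: list[str]
    target_ids: list[str]
    sample_ids: list[str]
    kernel: KernelConfig | None = None
    penalty: PenaltySpec | None = None
    diagnostics: "object | None" = None  # pandas DataFrame
    failures: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.coefficients.shape[0]

    def to_edges(self):
        """Long-format table of nonzero coefficients (one row per edge)."""
        import pandas as pd

        a, j, l = np.nonzero(self.coefficients)
        return pd.DataFrame(
            {
                "sample": [self.sample_ids[i] for i in a],
                "regulator": [self.regulator_ids[i] for i in j],
                "target": [self.target_ids[i] for i in l],
                "coefficient": self.coefficients[a, j, l],
            }
        )


def _anchor_indices(M: NDArray, n_anchors: int) -> NDArray[np.intp]:
    """Samples spread over the modulator distribution (lambda selection)."""
    n = M.shape[0]
    if n <= n_anchors:
        return np.arange(n)
    key = M[:, 0] if M.ndim == 2 else M
    order = np.argsort(key, kind="stable")
    pos = np.linspace(0, n - 1, n_anchors).round().astype(int)
    return order[pos]


def fit_sample_specific_network(
    panel: ExpressionPanel,
    modulators: ModulatorTable | ArrayLike,
    kernel: KernelConfig | None = None,
    penalty: PenaltySpec | None = None,
    per_sample_lambda: bool = False,
    standardize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    seed: int = 0,
    threads: int = 1,
    n_anchors: int = 10,
) -> SampleSpecificNetwork:
    """Fit the full stack of sample-specific networks.

    For every target gene l and target sample alpha, kernel weights are
    computed from the modulator, rescaled to sum to n, and a weighted
    penalized regression of y_l on the regulators is fitted.  When the
    regulator and target identifier of a gene coincide, the self-loop is
    excluded from that target's predictors.

    lambda is selected per target gene on a common grid (weighted BIC
    averaged over ``n_anchors`` anchor samples spread across the modulator
    range) and shared across samples, unless ``per_sample_lambda=True``.
    Per-fit failures are recorded in ``failures`` rather than raised; a run
    in which every fit failed raises.  Results are independent of
    ``threads``.
    """
    import pandas as pd

    kernel = kernel or KernelConfig()
    penalty = penalty or PenaltySpec()
    if isinstance(modulators, ModulatorTable):
        check_sample_alignment(panel, modulators)
        M = modulators.values
    else:
        M = np.asarray(modulators, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        if M.shape[0] != panel.n_samples:
            raise InvalidParameterError("modulator rows must match panel samples")
    if kernel.mode != "multivariate" and M.shape[1] != 1:
        raise InvalidParameterError(
            f"kernel mode {kernel.mode!r} is univariate but modulator has "
            f"{M.shape[1]} characteristics"
        )

    n, p, q = panel.n_samples, panel.n_regulators, panel.n_targets
    X, Y = panel.X, panel.Y
    reg_pos = {g: j for j, g in enumerate(panel.regulator_ids)}

    # precompute weights once per target sample (shared across targets)
    all_weights = [kernel_weights(M, a, kernel) for a in range(n)]

    def fit_target(l: int):
        tid = panel.target_ids[l]
        keep = np.arange(p)
        if tid in reg_pos:  # exclude the self-loop
            keep = keep[keep != reg_pos[tid]]
        Xl = X[:, keep]
        y = Y[:, l]
        pen_l = penalty
        if isinstance(penalty.lam, str) and not per_sample_lambda:
            grid = penalty.lambda_grid
            if grid is None:
                grid = default_lambda_grid(Xl, y, standardize=standardize)
            anchors = _anchor_indices(M, n_anchors)
            bic = np.zeros(len(grid))
            for a in anchors:
                w = all_weights[a].weights
                if w.sum() <= 0:
                    continue
                ess = _effective_sample_size(w)
                wr = w * (n / w.sum())
                for gi, lam in enumerate(grid):
                    fit = fit_penalized_regression(
                        Xl, y, replace(penalty, lam=float(lam)), weights=wr,
                        standardize=standardize, tol=tol, max_iter=max_iter,
                    )
                    support = np.nonzero(fit.coef)[0]
                    bic[gi] += _weighted_bic(
                        _refit_rss(Xl, y, wr, support),
                        len(support),
                        float(wr.sum()),
                        ess,
                    )
            # ties toward the sparser (larger) lambda
            order = np.argsort(-np.asarray(grid, dtype=float), kind="stable")
            best = order[int(np.argmin(bic[order]))]
            pen_l = replace(penalty, lam=float(grid[best]))

        coefs = np.zeros((n, p))
        icepts = np.zeros(n)
        diag_rows = []
        fails = []
        for a in range(n):
            sw = all_weights[a]
            eff = float(sw.weights.sum())
            try:
                if eff <= 0:
                    raise DegenerateWeightsError("all kernel weights are zero")
                wr = sw.weights * (n / eff)
                fit = fit_penalized_regression(
                    Xl, y, pen_l, weights=wr, standardize=standardize,
                    tol=tol, max_iter=max_iter, seed=seed,
                )
                coefs[a, keep] = fit.coef
                icepts[a] = fit.intercept
                if eff < EFFECTIVE_SIZE_WARNING:
                    logger.debug(
                        "effective kernel size %.2f < %.0f for sample %s, "
                        "target %s", eff, EFFECTIVE_SIZE_WARNING,
                        panel.sample_ids[a], tid,
                    )
                diag_rows.append((panel.sample_ids[a], tid, eff, fit.lam,
                                  fit.converged))
            except NetprofilerError as exc:
                fails.append((a, l, str(exc)))
                diag_rows.append((panel.sample_ids[a], tid, eff,
                                  float("nan"), False))
        return coefs, icepts, diag_rows, fails

    results = Parallel(n_jobs=threads, prefer="threads")(
        delayed(fit_target)(l) for l in range(q)
    )

    coefficients = np.zeros((n, p, q))
    intercepts = np.zeros((n, q))
    diag_rows: list = []
    failures: list = []
    for l, (coefs, icepts, rows, fails) in enumerate(results):
        coefficients[:, :, l] = coefs
        intercepts[:, l] = icepts
        diag_rows.extend(rows)
        failures.extend(fails)
    if len(failures) == n * q:
        raise NetprofilerError("every per-(sample, target) fit failed")

    diagnostics = pd.DataFrame(
        diag_rows,
        columns=["sample", "target", "effective_size", "lambda", "converged"],
    )
    return SampleSpecificNetwork(
        coefficients, intercepts, list(panel.regulator_ids),
        list(panel.target_ids), list(panel.sample_ids), kernel, penalty,
        diagnostics, failures,
    )


class NetworkProfiler(BaseEstimator):
    """Sample-characteristic-specific network estimator (scikit-learn style).

    Fits, per target gene and per sample, a kernel-weighted penalized
    regression of target expression on regulator expression, where the
    kernel weights samples by modulator similarity.  The fitted attribute
    ``coef_`` has shape (n_samples, n_regulators, n_targets).

    Parameters
    ----------
    kernel : {"constant", "adaptive_knn", "multivariate"}
        Weighting kernel over modulator values.
    bandwidth : float, constant-kernel bandwidth b.
    k : int or None, neighbour count of the adaptive kernel
        (None = ceil(sqrt(n))).
    range_factor : float or "auto", dispersion factor r(M).
    bandwidth_matrix : array or "auto", multivariate bandwidth H.
    penalty : {"lasso", "ridge", "elastic_net"}
    reg_lambda : float or "auto" — regularization strength.
    gamma : elastic-net mixing in [0, 1] (ridge share).
    per_sample_lambda : bool, select lambda per (sample, target) instead of
        per target.
    """

    def __init__(
        self,
        kernel: str = "adaptive_knn",
        bandwidth: float | None = None,
        k: int | None = None,
        range_factor: float | str = "auto",
        bandwidth_matrix: ArrayLike | str = "auto",
        epsilon_floor: float = 1e-8,
        penalty: str = "lasso",
        reg_lambda: float | str = "auto",
        gamma: float | None = None,
        lambda_grid: ArrayLike | None = None,
        selection: str = "weighted_bic",
        per_sample_lambda: bool = False,
        standardize: bool = True,
        tol: float = 1e-7,
        max_iter: int = 100_000,
        seed: int = 0,
        threads: int = 1,
    ):
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.k = k
        self.range_factor = range_factor
        self.bandwidth_matrix = bandwidth_matrix
        self.epsilon_floor = epsilon_floor
        self.penalty = penalty
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.lambda_grid = lambda_grid
        self.selection = selection
        self.per_sample_lambda = per_sample_lambda
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.threads = threads

    def _kernel_config(self) -> KernelConfig:
        return KernelConfig(
            mode=self.kernel,
            bandwidth=self.bandwidth,
            k=self.k,
            range_factor=self.range_factor,
            bandwidth_matrix=self.bandwidth_matrix,
            epsilon_floor=self.epsilon_floor,
        )

    def _penalty_spec(self) -> PenaltySpec:
        grid = None
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
        return PenaltySpec(
            family=self.penalty, lam=self.reg_lambda, gamma=self.gamma,
            lambda_grid=grid, selection=self.selection,
        )

    def fit(self, X, Y=None, *, modulators=None, regulator_ids=None,
            target_ids=None, sample_ids=None):
        """Fit sample-specific networks.

        ``X`` may be an :class:`ExpressionPanel` (then ``Y`` is ignored) or
        an (n, p) regulator matrix with ``Y`` the (n, q) target matrix.
        ``modulators`` is a :class:`ModulatorTable` or an (n,) / (n, h)
        array and is required.
        """
        if isinstance(X, ExpressionPanel):
            panel = X
        else:
            X = np.asarray(X, dtype=float)
            Y = np.asarray(Y, dtype=float)
            if Y.ndim == 1:
                Y = Y[:, None]
            n, p = X.shape
            q = Y.shape[1]
            panel = ExpressionPanel(
                X, Y,
                regulator_ids or [f"R{j}" for j in range(p)],
                target_ids or [f"T{l}" for l in range(q)],
                sample_ids or [f"S{i}" for i in range(n)],
            )
        if modulators is None:
            raise InvalidParameterError("modulators are required")
        net = fit_sample_specific_network(
            panel, modulators, self._kernel_config(), self._penalty_spec(),
            per_sample_lambda=self.per_sample_lambda,
            standardize=self.standardize, tol=self.tol,
            max_iter=self.max_iter, seed=self.seed, threads=self.threads,
        )
        self.network_ = net
        self.coef_ = net.coefficients
        self.intercept_ = net.intercepts
        self.n_features_in_ = panel.n_regulators
        return self
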