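"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and seed, and together
they produce every input the pipeline consumes:

* a non-uniformly distributed modulator (Gaussian mixture with a dense and
  a sparse region, mimicking real anti-cancer drug-sensitivity profiles);
* expression data from a varying-coefficient linear model
  y_l = sum_j beta_jl(m) x_j + eps with sparse, modulator-dependent
  coefficients and Gaussian noise;
* stacks of regulatory-effect matrices sharing a sparse low-rank common
  structure (for testing the common-component analysis);
* drug-sensitivity vectors driven by designated causal edges (for testing
  the knockout-importance procedure).

The default varying-network scenario has, per target, a linear-in-m edge
(beta = 0.5 m), a threshold edge that vanishes above the modulator cutoff 6
(between the two mixture components), and a constant edge; the noise level
sigma = 1.8 puts the signal-to-noise ratio near 3 under the default
modulator mixture.  The mixture is located away from zero so every true
edge coefficient is bounded away from zero over the modulator's range —
otherwise "support recovery" would count fundamentally undetectable
near-zero coefficients as misses and stop being a meaningful benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .data import ExpressionPanel, ModulatorTable
from .effects import RegulatoryEffectSet
from .exceptions import InvalidParameterError

__all__ = [
    "SimulationTruth",
    "simulate_modulator",
    "default_truth",
    "simulate_varying_network",
    "simulate_common_structure",
    "simulate_drug_response",
    "recovery_metrics",
]

#: default Gaussian-mixture modulator: a dense region near 4 and a sparse,
#: wide region near 8
DEFAULT_MIXTURE = {"means": (4.0, 8.0), "sds": (0.5, 1.5), "weights": (0.75, 0.25)}

DEFAULT_SIGMA = 1.8  # noise sd giving SNR ~ 3 under the default truth/mixture
DEFAULT_THRESHOLD = 6.0  # modulator cutoff of the threshold edge


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``beta`` maps (regulator j, target l, modulator value m) to the true
    coefficient; ``causal_edges`` lists (target_id, regulator_id) pairs that
    drive the simulated drug response; ``true_loadings`` holds the shared
    sparse loadings of the common-structure scenario.
    """

    beta: Callable[[int, int, float], float]
    noise_sd: float
    seed: int
    causal_edges: list[tuple[str, str]] = field(default_factory=list)
    true_loadings: NDArray[np.float64] | None = None

    def coefficient_tensor(
        self, m: ArrayLike, p: int, q: int
    ) -> NDArray[np.float64]:
        """Evaluate the true coefficients on a modulator vector: (n, p, q)."""
        m = np.asarray(m, dtype=float)
        out = np.zeros((len(m), p, q))
        for a, ma in enumerate(m):
            for l in range(q):
                for j in range(p):
                    out[a, j, l] = self.beta(j, l, float(ma))
        return out


def simulate_modulator(
    n: int,
    means: Sequence[float] | None = None,
    sds: Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
    seed: int = 0,
) -> NDArray[np.float64]:
    """Draw n modulator values from a Gaussian mixture.

    The default two-component mixture has a dominant narrow component and a
    minor wide one, producing dense and sparse regions of the modulator
    distribution.
    """
    means = np.asarray(
        means if means is not None else DEFAULT_MIXTURE["means"], dtype=float
    )
    sds = np.asarray(
        sds if sds is not None else DEFAULT_MIXTURE["sds"], dtype=float
    )
    weights = np.asarray(
        weights if weights is not None else DEFAULT_MIXTURE["weights"],
        dtype=float,
    )
    if not (len(means) == len(sds) == len(weights)):
        raise InvalidParameterError("mixture component lists disagree in length")
    if np.any(sds < 0) or np.any(weights < 0):
        raise InvalidParameterError("sds and weights must be nonnegative")
    if not np.isclose(weights.sum(), 1.0):
        raise InvalidParameterError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), size=n, p=weights)
    return rng.normal(means[comp], sds[comp])


def default_truth(
    p: int,
    q: int,
    noise_sd: float = DEFAULT_SIGMA,
    seed: int = 0,
    linear_slope: float = 0.5,
    threshold_level: float = 1.5,
    threshold_cutoff: float = DEFAULT_THRESHOLD,
    constant_level: float = 1.0,
) -> SimulationTruth:
    """Default varying-coefficient truth: per target, three kinds of edge.

    Regulator 0 -> linear in m (slope * m); regulator 1 -> threshold
    (level for m <= cutoff, else 0); regulator 2 -> constant; all other
    coefficients are 0.
    """
    if p < 3:
        raise InvalidParameterError("default truth needs p >= 3")

    def beta(j: int, l: int, m: float) -> float:
        if j == 0:
            return linear_slope * m
        if j == 1:
            return threshold_level if m <= threshold_cutoff else 0.0
        if j == 2:
            return constant_level
        return 0.0

    return SimulationTruth(beta=beta, noise_sd=noise_sd, seed=seed)


def simulate_varying_network(
    n: int = 300,
    p: int = 10,
    q: int = 5,
    truth: SimulationTruth | None = None,
    modulator: ArrayLike | None = None,
    x_correlation: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionPanel, ModulatorTable, SimulationTruth]:
    """Generate expression data from the varying-coefficient model.

    Regulator expression is iid standard normal (optionally with an
    exchangeable correlation ``x_correlation``); targets follow
    ``y_al = sum_j beta_jl(m_a) x_aj + eps`` with eps ~ N(0, sigma^2).
    """
    truth = truth or default_truth(p, q, seed=seed)
    rng = np.random.default_rng(seed)
    if modulator is None:
        m = simulate_modulator(n, seed=seed)
    else:
        m = np.asarray(modulator, dtype=float)
        if len(m) != n:
            raise InvalidParameterError("modulator length must equal n")
    if not 0 <= x_correlation < 1:
        raise InvalidParameterError("x_correlation must lie in [0, 1)")
    X = rng.standard_normal((n, p))
    if x_correlation > 0:
        shared = rng.standard_normal((n, 1))
        X = (
            np.sqrt(x_correlation) * shared
            + np.sqrt(1 - x_correlation) * X
        )
    B = truth.coefficient_tensor(m, p, q)  # (n, p, q)
    signal = np.einsum("aj,ajl->al", X, B)
    Y = signal + truth.noise_sd * rng.standard_normal((n, q))
    panel = ExpressionPanel(
        X, Y,
        [f"R{j}" for j in range(p)],
        [f"T{l}" for l in range(q)],
        [f"S{i}" for i in range(n)],
    )
    table = ModulatorTable(m[:, None], panel.sample_ids, ["modulator"])
    return panel, table, truth


def _sparse_orthonormal_loadings(
    p: int, K: int, support_size: int, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Random orthonormal (p, K) loadings supported on `support_size` genes."""
    support = rng.choice(p, size=support_size, replace=False)
    V = np.zeros((p, K))
    block = rng.standard_normal((support_size, K))
    qmat, _ = np.linalg.qr(block)
    V[np.sort(support)] = qmat[:, :K]
    return V


def simulate_common_structure(
    q: int = 5,
    n: int = 200,
    p: int = 50,
    K: int = 1,
    support_size: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[RegulatoryEffectSet, NDArray[np.float64], list[set]]:
    """q effect matrices sharing a sparse low-rank structure R_l = S_l V^T + E.

    V is a sparse orthonormal (p, K) loading matrix shared by all matrices,
    the scores S_l are iid standard normal, and E has sd ``noise_sd``.
    Returns the effect set, the true loadings, and neighbour sets derived
    from the true support (genes on the support are mutually adjacent),
    usable as the similarity input of the common-component analysis.
    """
    if support_size > p:
        raise InvalidParameterError("support_size must not exceed p")
    if K > support_size:
        raise InvalidParameterError("K must not exceed support_size")
    rng = np.random.default_rng(seed)
    V = _sparse_orthonormal_loadings(p, K, support_size, rng)
    regulator_ids = [f"R{j}" for j in range(p)]
    sample_ids = [f"S{i}" for i in range(n)]
    mats = []
    for _ in range(q):
        S = rng.standard_normal((n, K))
        mats.append(S @ V.T + noise_sd * rng.standard_normal((n, p)))
    effects = RegulatoryEffectSet(
        mats, [f"T{l}" for l in range(q)], regulator_ids, sample_ids
    )
    support = set(np.nonzero(np.any(V != 0, axis=1))[0])
    neighbor_sets = [
        {regulator_ids[s] for s in support if s != j} if j in support else set()
        for j in range(p)
    ]
    return effects, V, neighbor_sets


def simulate_drug_response(
    effects: RegulatoryEffectSet,
    causal_edges: Sequence[tuple[str, str]],
    coefficients: Sequence[float],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> NDArray[np.float64]:
    """Sensitivity = linear combination of causal-edge effect columns + noise.

    Percentile labeling of the result yields sensitive/resistant classes
    separable through the designated causal edges.
    """
    if len(causal_edges) != len(coefficients):
        raise InvalidParameterError("one coefficient per causal edge required")
    features, edge_index = effects.feature_matrix()
    pos = []
    for edge in causal_edges:
        edge = (str(edge[0]), str(edge[1]))
        if edge not in edge_index:
            raise InvalidParameterError(f"causal edge {edge!r} not in effects")
        pos.append(edge_index.index(edge))
    rng = np.random.default_rng(seed)
    signal = features[:, pos] @ np.asarray(coefficients, dtype=float)
    return signal + noise_sd * rng.standard_normal(features.shape[0])


def recovery_metrics(
    true_support: ArrayLike | None = None,
    est_support: ArrayLike | None = None,
    true_coef: ArrayLike | None = None,
    est_coef: ArrayLike | None = None,
    true_loading: ArrayLike | None = None,
    est_loading: ArrayLike | None = None,
) -> dict:
    """Support precision/recall/F1, coefficient RMSE and |cosine| of loadings.

    All comparisons require aligned shapes; loading cosine is reported in
    absolute value since loadings are sign-indeterminate.
    """
    out: dict = {}
    if true_support is not None:
        ts = np.asarray(true_support, dtype=bool)
        es = np.asarray(est_support, dtype=bool)
        if ts.shape != es.shape:
            raise InvalidParameterError("support shapes disagree")
        tp = np.count_nonzero(ts & es)
        fp = np.count_nonzero(~ts & es)
        fn = np.count_nonzero(ts & ~es)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        out.update(precision=precision, recall=recall, f1=f1)
    if true_coef is not None:
        tc = np.asarray(true_coef, dtype=float)
        ec = np.asarray(est_coef, dtype=float)
        if tc.shape != ec.shape:
            raise InvalidParameterError("coefficient shapes disagree")
        out["rmse"] = float(np.sqrt(np.mean((tc - ec) ** 2)))
    if true_loading is not None:
        tl = np.asarray(true_loading, dtype=float).ravel()
        el = np.asarray(est_loading, dtype=float).ravel()
        if tl.shape != el.shape:
            raise InvalidParameterError("loading shapes disagree")
        denom = np.linalg.norm(tl) * np.linalg.norm(el)
        out["abs_cosine"] = float(abs(tl @ el) / denom) if denom else 0.0
    return out
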