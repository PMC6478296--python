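"""Evaluation: adjusted mutual information, the AUMIC summary and the
benchmark driver reproducing the planted-partition comparisons.

Partition similarity uses AMI with max-normalization and the permutation
(hypergeometric) null model.  A benchmark run sweeps a mixing grid, samples
networks, runs best-of-restarts inference per model, and records one tidy
row per (parameter, network, model).  The AUMIC of a model is the
trapezoidal integral of its mean-AMI curve over the mixing interval,
normalized by the interval length.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score

from .generators import GNConfig, LFRConfig, gn_network, lfr_network
from .graph import Partition
from .inference import InferenceConfig, InferenceResult, best_of_restarts
from .model_selection import SelectionCriterion, select_k
from .objectives import Objective, get_objective
from .state import BlockState

__all__ = ["ami", "AMICurve", "aumic", "k_ratio", "run_benchmark",
           "ami_curve", "aumic_by_model"]


def _labels(p) -> np.ndarray:
    return p.labels if isinstance(p, Partition) else np.asarray(p)


def ami(labels_a, labels_b) -> float:
    """Adjusted mutual information, max-normalized (AMI_max).

    1 for identical partitions; 0 in expectation under the permutation
    model, and defined as 0 when the normalizer degenerates (e.g. against
    the one-block or all-singleton partition).  Small negative values are
    legal and not clamped.
    """
    a, b = _labels(labels_a), _labels(labels_b)
    if a.size != b.size:
        raise ValueError("partitions must label the same nodes")
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


@dataclass
class AMICurve:
    """Mean AMI per mixing-parameter value."""

    x: np.ndarray
    y: np.ndarray
    n: np.ndarray  # replicates per point

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


def aumic(curve: AMICurve, x_lo: float, x_hi: float) -> float:
    """Area under the AMI curve over ``[x_lo, x_hi]``, trapezoidal rule,
    normalized by the interval length."""
    if x_hi <= x_lo:
        raise ValueError("need x_hi > x_lo")
    x, y = curve.x, curve.y
    if x.min() > x_lo or x.max() < x_hi:
        raise ValueError("curve does not cover the integration interval")
    inside = (x >= x_lo) & (x <= x_hi)
    xs = x[inside]
    ys = y[inside]
    if xs.size < 2:
        raise ValueError("need at least two curve points inside the interval")
    if xs[0] > x_lo:
        xs = np.insert(xs, 0, x_lo)
        ys = np.insert(ys, 0, np.interp(x_lo, x, y))
    if xs[-1] < x_hi:
        xs = np.append(xs, x_hi)
        ys = np.append(ys, np.interp(x_hi, x, y))
    return float(np.trapezoid(ys, xs) / (x_hi - x_lo))


def k_ratio(selected_k: Sequence[int], true_k: Sequence[int]) -> float:
    """Mean selected K over mean true K."""
    selected_k = np.asarray(selected_k, dtype=float)
    true_k = np.asarray(true_k, dtype=float)
    if selected_k.size == 0 or true_k.size == 0:
        raise ValueError("empty input")
    return float(selected_k.mean() / true_k.mean())


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

_DEFAULT_GRID = {
    "gn": np.arange(0.0, 8.5, 0.5),
    "lfr": np.arange(0.0, 0.6, 0.1),
}


def _child_rng(base: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([base, *key])


def run_benchmark(benchmark: str, models: Sequence[str | Objective],
                  config: InferenceConfig, rng: np.random.Generator, *,
                  grid: Sequence[float] | None = None, n_networks: int = 10,
                  k_policy: str = "true_K",
                  criterion: SelectionCriterion | None = None,
                  k_range: tuple[int, int] | None = None,
                  gn_config: GNConfig | None = None,
                  lfr_config: LFRConfig | None = None) -> pd.DataFrame:
    """Run a planted-partition benchmark and return a tidy results table.

    For each grid value, ``n_networks`` networks are sampled; for each
    network and model the configured algorithm runs best-of-restarts and the
    selected partition is scored against the planted one.  ``k_policy`` is
    either ``"true_K"`` (the planted block count is given to the algorithm)
    or ``"sweep"`` (every K in ``k_range`` is fitted and ``criterion`` —
    ``SelectionCriterion("none", ...)`` for the objectives that include K —
    picks the winner).

    Seeds for every (parameter, network, model) cell are derived
    deterministically from ``rng``, so aggregates do not depend on the
    order in which models are listed.
    """
    benchmark = benchmark.lower()
    if benchmark not in _DEFAULT_GRID:
        raise ValueError("benchmark must be 'gn' or 'lfr'")
    if k_policy not in ("true_K", "sweep"):
        raise ValueError("k_policy must be 'true_K' or 'sweep'")
    if k_policy == "sweep":
        if k_range is None:
            raise ValueError("sweep policy needs k_range")
        if criterion is None:
            criterion = SelectionCriterion("none")
    grid = _DEFAULT_GRID[benchmark] if grid is None else np.asarray(grid, float)
    models = [get_objective(m) if isinstance(m, str) else m for m in models]
    base = int(rng.integers(2**31 - 1))
    rows = []
    for ip, param in enumerate(grid):
        for net in range(n_networks):
            g_rng = _child_rng(base, 0, ip, net)
            if benchmark == "gn":
                cfg = gn_config or GNConfig()
                graph, planted = gn_network(
                    GNConfig(k_out=float(param), groups=cfg.groups,
                             group_size=cfg.group_size,
                             mean_degree=cfg.mean_degree), g_rng)
            else:
                cfg = lfr_config or LFRConfig()
                graph, planted = lfr_network(
                    LFRConfig(n=cfg.n, mean_degree=cfg.mean_degree,
                              max_degree=cfg.max_degree,
                              degree_exponent=cfg.degree_exponent,
                              community_exponent=cfg.community_exponent,
                              community_size_range=cfg.community_size_range,
                              mu=float(param)), g_rng)
            for spec in models:
                mkey = zlib.crc32(spec.name.encode())
                r_rng = _child_rng(base, 1, ip, net, mkey)
                if k_policy == "true_K":
                    res = best_of_restarts(graph, spec, planted.K, config, r_rng)
                    k_sel = res.state.K
                else:
                    sweep: dict[int, tuple[float, BlockState]] = {}
                    deltas = moves = 0
                    for K in range(k_range[0], k_range[1] + 1):
                        with warnings.catch_warnings():
                            if K == 1:  # a K=1 "run" is trivially its start
                                warnings.simplefilter("ignore")
                            r = best_of_restarts(graph, spec, K, config, r_rng)
                        sweep[K] = (r.objective, r.state)
                        deltas += r.n_deltas
                        moves += r.n_moves
                    crit = criterion
                    if crit.name != "none" and crit.dc_variant != spec.degree_corrected:
                        crit = SelectionCriterion(crit.name, spec.degree_corrected)
                    k_sel, st = select_k(sweep, crit)
                    res = InferenceResult(st, sweep[k_sel][0], sweep[k_sel][0],
                                          st.labels.copy(), deltas, moves)
                rows.append({
                    "benchmark": benchmark, "param": float(param),
                    "network_id": net, "model": spec.name,
                    "K": int(k_sel if k_policy == "sweep" else res.state.K),
                    "true_K": int(planted.K),
                    "objective": float(res.objective),
                    "ami": ami(res.state.labels, planted),
                    "deltas": int(res.n_deltas), "moves": int(res.n_moves),
                    "seed": base,
                })
    return pd.DataFrame(rows)


def ami_curve(table: pd.DataFrame, model: str) -> AMICurve:
    """Mean-AMI curve of one model from a benchmark table."""
    sub = table[table["model"] == model]
    agg = sub.groupby("param")["ami"].agg(["mean", "count"]).reset_index()
    return AMICurve(agg["param"].to_numpy(), agg["mean"].to_numpy(),
                    agg["count"].to_numpy())


def aumic_by_model(table: pd.DataFrame, x_lo: float, x_hi: float) -> dict[str, float]:
    """Normalized AUMIC per model over ``[x_lo, x_hi]``."""
    return {m: aumic(ami_curve(table, m), x_lo, x_hi)
            for m in table["model"].unique()}
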