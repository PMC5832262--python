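"""Permutation null models and the cross-deployment collar check.

Two randomization procedures assess whether observed network structure
and repeatability could arise from random combinations of connections:

1. matrix permutation — dyad weights (zeros included) are shuffled
   uniformly among the dyad slots of the association matrix, the network
   metrics recomputed at each of (by default) 1,000 iterations, and the
   observed mean metric compared with the 2.5/97.5% quantile band of the
   permuted means;
2. repeatability null — individual labels on metric values are permuted
   (by default within each treatment x replicate stratum, preserving the
   treatment structure while destroying individual identity), the mixed
   model refit, and repeatability recomputed per iteration.

A note on statistic choice: mean graph strength over individuals equals
2 x total weight / n and is exactly conserved by dyad shuffling, so its
null distribution is degenerate at the observed value; mean eigenvector
centrality and mean degree are informative.

The cross-deployment check correlates per-collar metric values from two
independent deployments of the same physical collars: a strong positive
correlation would indicate collar hardware, not animal identity, drives
the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationMatrix
from .brn import (McmcSettings, ModelSpec, PriorSpec, fit_mixed_model,
                  repeatability)
from .netmetrics import _METRIC_FUNCS, build_network

__all__ = [
    "NullDistribution",
    "permute_matrix",
    "metric_null",
    "repeatability_null",
    "cross_deployment_correlation",
]


@dataclass
class NullDistribution:
    """Observed statistic vs its permutation distribution.

    ``nonrandom`` is True when the observed value falls outside the
    2.5-97.5% empirical quantile band of the permuted values.
    """

    statistic_name: str
    observed: float
    permuted: np.ndarray
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    nonrandom: bool = field(init=False)

    def __post_init__(self) -> None:
        self.permuted = np.asarray(self.permuted, dtype=float)
        self.ci_low = float(np.quantile(self.permuted, 0.025))
        self.ci_high = float(np.quantile(self.permuted, 0.975))
        self.nonrandom = bool(self.observed < self.ci_low
                              or self.observed > self.ci_high)

    @property
    def n_perm(self) -> int:
        return self.permuted.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": np.arange(1, self.n_perm + 1),
                             "value": self.permuted})

    def summary(self) -> dict:
        return {"statistic": self.statistic_name, "observed": self.observed,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_perm": int(self.n_perm), "nonrandom": self.nonrandom}


def permute_matrix(
    m: AssociationMatrix,
    seed: int | np.random.Generator,
    mode: str = "weights",
) -> AssociationMatrix:
    """One uniform shuffle of the dyad weights of a symmetric matrix.

    ``mode="weights"`` (default) shuffles the upper-triangle weights —
    zeros included — among the dyad slots and mirrors; the multiset of
    dyad weights is preserved exactly and the diagonal stays zero.
    ``mode="nodes"`` relabels nodes by a random permutation instead
    (leaves every mean metric identical; provided for completeness).
    """
    if not m.symmetric:
        raise ValueError("permute_matrix expects a symmetric matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = m.n
    out = m.copy()
    if mode == "weights":
        iu, ju = np.triu_indices(n, k=1)
        vals = m.weights[iu, ju]
        shuffled = vals[rng.permutation(vals.size)]
        W = np.zeros((n, n))
        W[iu, ju] = shuffled
        W[ju, iu] = shuffled
        out.weights = W
    elif mode == "nodes":
        perm = rng.permutation(n)
        out.weights = m.weights[np.ix_(perm, perm)]
    else:
        raise ValueError("mode must be 'weights' or 'nodes'")
    return out


def _mean_metric_dense(W: np.ndarray, metric: str) -> float:
    """Mean per-individual metric straight from a symmetric weight matrix;
    numerically identical to building the graph and averaging (node set is
    the full roster, so isolates count)."""
    if metric == "strength":
        return float(W.sum(axis=1).mean())
    if metric == "degree":
        return float((W > 0).sum(axis=1).mean())
    if metric == "eigenvector":
        if not W.any():
            return 0.0
        _, evecs = np.linalg.eigh(W)
        v = evecs[:, -1]
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        return float((v / v.max()).mean())
    raise KeyError(metric)


def metric_null(
    m: AssociationMatrix,
    metric: str,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "weights",
) -> NullDistribution:
    """Null distribution of the mean per-individual metric under matrix
    permutation.  One of these per replicate x density x sex x metric
    reproduces the full randomization grid (36 runs for a two-sex,
    three-density, two-replicate design).

    The permutation loop evaluates the metric directly on the shuffled
    weight matrix (same draws, same values as
    ``build_network(permute_matrix(...))``, without graph construction).
    """
    if not m.symmetric:
        raise ValueError("metric_null expects a symmetric matrix")
    func: Callable = _METRIC_FUNCS[metric]
    observed = float(np.mean(list(func(build_network(m)).values())))
    rng = np.random.default_rng(seed)
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    vals = m.weights[iu, ju]
    permuted = np.empty(n_perm)
    W = np.zeros((n, n))
    for b in range(n_perm):
        if mode == "weights":
            shuffled = vals[rng.permutation(vals.size)]
            W[iu, ju] = shuffled
            W[ju, iu] = shuffled
        elif mode == "nodes":
            perm = rng.permutation(n)
            W = m.weights[np.ix_(perm, perm)]
        else:
            raise ValueError("mode must be 'weights' or 'nodes'")
        permuted[b] = _mean_metric_dense(W, metric)
    return NullDistribution(f"mean_{metric}", observed, permuted)


def _permute_within_strata(obs: pd.DataFrame, rng: np.random.Generator,
                           stratified: bool) -> pd.DataFrame:
    """Reassign metric values to individuals by permuting labels, within
    each treatment x replicate stratum (or globally)."""
    out = obs.copy()
    if stratified:
        for _, idx in out.groupby(["density", "replicate"]).groups.items():
            idx = np.asarray(idx)
            out.loc[idx, "value"] = out.loc[idx[rng.permutation(idx.size)],
                                            "value"].to_numpy()
    else:
        out["value"] = out["value"].to_numpy()[rng.permutation(len(out))]
    return out


def repeatability_null(
    obs: pd.DataFrame,
    model_spec: ModelSpec,
    n_perm: int = 1000,
    seed: int = 0,
    mcmc: McmcSettings | None = None,
    prior: PriorSpec = PriorSpec(),
    stratified: bool = True,
    max_retries: int = 5,
) -> NullDistribution:
    """Null distribution of repeatability under individual-label swaps.

    At each iteration metric values are reassigned among individuals
    (within treatment x replicate strata by default), the model refit
    from a derived seed, and the posterior-mean r recorded.  A failed fit
    at an iteration is resampled (up to *max_retries*) and counted once.
    """
    mcmc = mcmc or McmcSettings.quick()
    rng = np.random.default_rng(seed)
    fit = fit_mixed_model(obs, model_spec, prior,
                          McmcSettings(mcmc.n_iter, mcmc.thin, mcmc.burn_in,
                                       seed=int(rng.integers(2**31))))
    observed_est = repeatability(fit)
    if not observed_est.defined:
        raise ValueError("repeatability is undefined for a model without random effects")
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        for attempt in range(max_retries):
            shuffled = _permute_within_strata(obs, rng, stratified)
            sub_seed = int(rng.integers(2**31))
            try:
                pfit = fit_mixed_model(
                    shuffled, model_spec, prior,
                    McmcSettings(mcmc.n_iter, mcmc.thin, mcmc.burn_in, seed=sub_seed))
                permuted[b] = repeatability(pfit).r
                break
            except (np.linalg.LinAlgError, ValueError):  # resample and retry
                if attempt == max_retries - 1:
                    raise
    return NullDistribution("repeatability", float(observed_est.r), permuted)


def cross_deployment_correlation(
    metrics_a: Sequence[float] | pd.Series,
    metrics_b: Sequence[float] | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) of per-collar metric values
    across two deployments of the same collars on different animals.

    Inputs must be aligned by collar id (pass Series indexed by collar to
    have the alignment checked)."""
    if isinstance(metrics_a, pd.Series) and isinstance(metrics_b, pd.Series):
        if not metrics_a.index.equals(metrics_b.index):
            metrics_b = metrics_b.reindex(metrics_a.index)
            if metrics_b.isna().any():
                raise ValueError("collar ids do not match across deployments")
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 matched collars")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
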