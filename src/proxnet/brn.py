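"""Bayesian reaction-norm mixed models, DIC selection, and repeatability.

The response is a per-individual network metric measured once per
density-treatment x replicate (six repeated measures per animal).  Six
nested Gaussian mixed models are fit by a hand-rolled Gibbs sampler over
the conditionally conjugate blocks:

    y = X b + Z u + e,   u_i ~ MVN(0, G),   e ~ N(0, s2_R I)

with fixed effects drawn from a diffuse normal (variance 1e10), the
random-effect covariance G from an inverse-Wishart, and the residual
variance from its one-dimensional inverse-Wishart (inverse-gamma).
Model complexity grows from an intercept-only null (M1) through random
intercepts (M2), a linear density fixed effect (M3), quadratic density
(M4), and individual random slopes (M5) and curvatures (M6); covariance
among all specified random terms is estimated.  Models are compared by
DIC (conditional likelihood, individual effects in focus) with the
within-2-most-complex selection rule, and repeatability

    r = s2_among / (s2_among + s2_within)

is computed per posterior draw, marginalizing s2_among over the observed
standardized densities for random-slope models.

Priors follow the weakly-informative convention of coding the prior
variance as the phenotypic variance of the response divided by 2 (with 4
and 6 as sensitivity settings) and degree of belief nu = 1; the
inverse-Wishart for a q-dimensional G uses scale matrix V*I and
degrees of freedom nu + q - 1 so that nu = 1 keeps the marginal priors
comparably diffuse across model dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec", "PriorSpec", "McmcSettings", "FitResult", "RepeatabilityEstimate",
    "MODELS", "MODEL_ORDER",
    "standardize_density", "fit_mixed_model", "compute_dic", "select_model",
    "repeatability", "prior_sensitivity", "predict_reaction_norms",
    "check_convergence", "normality_report",
]

_TERMS = ("intercept", "density", "density2")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of one candidate model.

    ``fixed`` and ``random`` are ordered subsets of
    ('intercept', 'density', 'density2'); the density terms refer to the
    standardized covariate x and x**2.
    """

    label: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.fixed + self.random:
            if t not in _TERMS:
                raise ValueError(f"unknown model term {t!r}")
        if self.random and self.random[0] != "intercept":
            raise ValueError("random slopes require a random intercept")

    @property
    def q(self) -> int:
        return len(self.random)


#: The six-candidate set, ordered by complexity.
MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", ("intercept",)),
    "M2": ModelSpec("M2", ("intercept",), ("intercept",)),
    "M3": ModelSpec("M3", ("intercept", "density"), ("intercept",)),
    "M4": ModelSpec("M4", ("intercept", "density", "density2"), ("intercept",)),
    "M5": ModelSpec("M5", ("intercept", "density", "density2"),
                    ("intercept", "density")),
    "M6": ModelSpec("M6", ("intercept", "density", "density2"),
                    ("intercept", "density", "density2")),
}
MODEL_ORDER = tuple(MODELS)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors: variance_divisor in {2, 4, 6} sets the
    inverse-Wishart scale to var(response)/divisor; nu is the degree of
    belief; fixed effects get independent N(0, fixed_effect_variance)."""

    variance_divisor: float = 2.0
    nu: float = 1.0
    fixed_effect_variance: float = 1e10


@dataclass(frozen=True)
class McmcSettings:
    """Chain length control; (n_iter - burn_in) / thin draws are stored."""

    n_iter: int = 1_300_000
    thin: int = 1_000
    burn_in: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_iter - self.burn_in) % self.thin:
            raise ValueError("(n_iter - burn_in) must be divisible by thin")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def full(cls, seed: int = 0) -> "McmcSettings":
        """The long, conservative chain: 1.3M iterations, thin 1,000,
        burn-in 300,000 (1,000 stored draws)."""
        return cls(seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcSettings":
        """1,000 stored draws at desk scale: 13,000 / 10 / 3,000."""
        return cls(n_iter=13_000, thin=10, burn_in=3_000, seed=seed)

    @classmethod
    def quick(cls, seed: int = 0) -> "McmcSettings":
        """200 stored draws for permutation-heavy work: 1,200 / 5 / 200."""
        return cls(n_iter=1_200, thin=5, burn_in=200, seed=seed)


@dataclass
class FitResult:
    """Stored posterior draws plus everything needed for DIC, repeatability
    and prediction.  ``beta`` is (draws, p); ``u`` is (draws, m, q); ``G``
    is (draws, q, q); ``sigma2`` is (draws,)."""

    spec: ModelSpec
    prior: PriorSpec
    mcmc: McmcSettings
    individuals: list[str]
    x_values: np.ndarray            # standardized density per observation row
    density_mean: float
    density_sd: float
    y: np.ndarray
    X: np.ndarray
    Z_cols: np.ndarray              # (n_obs, q) random design
    id_index: np.ndarray            # individual index per observation row
    beta: np.ndarray
    u: np.ndarray
    G: np.ndarray
    sigma2: np.ndarray
    degenerate: bool = False

    @property
    def n_obs(self) -> int:
        return self.y.size

    def blups(self) -> pd.DataFrame:
        """Posterior means of the per-individual random effects."""
        if self.spec.q == 0 or self.degenerate:
            return pd.DataFrame(index=self.individuals)
        return pd.DataFrame(self.u.mean(axis=0), index=self.individuals,
                            columns=list(self.spec.random))

    def parameter_chains(self) -> dict[str, np.ndarray]:
        chains = {f"beta[{t}]": self.beta[:, k]
                  for k, t in enumerate(self.spec.fixed)}
        for a in range(self.spec.q):
            for b in range(a + 1):
                chains[f"G[{self.spec.random[a]},{self.spec.random[b]}]"] = \
                    self.G[:, a, b]
        chains["sigma2_resid"] = self.sigma2
        return chains


@dataclass
class RepeatabilityEstimate:
    """Posterior summary of r with its variance partition.

    ``r`` is None for models without random effects (r undefined) and for
    degenerate zero-variance responses.  ``partition`` maps each random
    term to its (design-averaged) diagonal contribution to s2_among;
    ``covariance_contribution`` is the remainder from G's off-diagonals.
    """

    r: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    draws: np.ndarray | None = None
    partition: dict[str, float] = field(default_factory=dict)
    covariance_contribution: float = 0.0
    s2_among: float | None = None
    s2_within: float | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None


def standardize_density(obs: pd.DataFrame) -> pd.DataFrame:
    """Add z-standardized density ``x`` and its square ``x2``.

    Standardization is over the table's rows (for the balanced design this
    equals standardizing the six treatment values).  A single-density
    table has zero SD and is rejected.
    """
    out = obs.copy()
    d = out["density"].to_numpy(dtype=float)
    sd = d.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize density: single density value in table")
    out["x"] = (d - d.mean()) / sd
    out["x2"] = out["x"] ** 2
    return out


def _term_columns(x: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    cols = {"intercept": np.ones_like(x), "density": x, "density2": x * x}
    return np.column_stack([cols[t] for t in terms]) if terms else \
        np.empty((x.size, 0))


def _sample_invwishart(rng: np.random.Generator, dof: float, S: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition (q <= 3)."""
    q = S.shape[0]
    if q == 1:
        return S / rng.chisquare(dof)
    L = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((q, q))
    for i in range(q):
        A[i, i] = np.sqrt(rng.chisquare(dof - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    F = L @ A                      # Wishart(dof, S^-1) draw is F F'
    Finv = np.linalg.inv(F)
    return Finv.T @ Finv


def fit_mixed_model(
    obs: pd.DataFrame,
    spec: ModelSpec,
    prior: PriorSpec = PriorSpec(),
    mcmc: McmcSettings = McmcSettings.desk(),
    fix_sigma2: float | None = None,
) -> FitResult:
    """Gibbs-sample one candidate model on a long-format metric table.

    *obs* needs columns ``individual``, ``density``, ``value`` (rows for a
    single sex x metric).  Blocks are updated in the order beta | rest,
    u | rest, G | rest, sigma2 | rest; all conditionals are conjugate.
    Deterministic given ``mcmc.seed``.

    ``fix_sigma2`` pins the residual variance (no sigma2 block), used to
    validate the sampler against the closed-form conjugate posterior.
    """
    df = obs.dropna(subset=["value"]).copy()
    y = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if y.size == 0:
        raise ValueError("empty observation table")

    individuals = sorted(df["individual"].astype(str).unique())
    id_index = df["individual"].astype(str).map({c: k for k, c in
                                                 enumerate(individuals)}).to_numpy()
    counts = np.bincount(id_index, minlength=len(individuals))
    if spec.q >= 2 and counts.min() < 2:
        raise ValueError("random-slope models need >= 2 observations per individual")

    if "x" not in df.columns:
        df = standardize_density(df)
    x = df["x"].to_numpy(dtype=float)
    dens = df["density"].to_numpy(dtype=float)
    X = _term_columns(x, spec.fixed)
    W = _term_columns(x, spec.random)
    p, q, m, n = X.shape[1], spec.q, len(individuals), y.size

    vy = y.var(ddof=1) if n > 1 else 0.0
    if vy == 0.0:
        warnings.warn("zero-variance response: returning degenerate fit")
        D = mcmc.n_stored
        return FitResult(spec, prior, mcmc, individuals, x, float(dens.mean()),
                         float(dens.std(ddof=0)), y, X, W, id_index,
                         beta=np.full((D, p), y[0]), u=np.zeros((D, m, q)),
                         G=np.zeros((D, q, q)), sigma2=np.zeros(D), degenerate=True)

    V = vy / prior.variance_divisor
    rng = np.random.default_rng(mcmc.seed)

    # Balanced fast path: every individual shares the same covariate rows.
    order = np.lexsort((dens, df.get("replicate", pd.Series(np.zeros(n))).to_numpy(),
                        id_index))
    y_s, x_s, idx_s = y[order], x[order], id_index[order]
    balanced = counts.min() == counts.max()
    if balanced:
        xm = x_s.reshape(m, -1)
        balanced = bool(np.allclose(xm, xm[0]))
    if not balanced:
        raise NotImplementedError(
            "unbalanced designs are not supported: each individual must be "
            "measured at the same covariate values")
    k = counts[0]
    y_mat = y_s.reshape(m, k)
    X_row = _term_columns(x_s[:k], spec.fixed)
    W_row = _term_columns(x_s[:k], spec.random)
    XtX = m * (X_row.T @ X_row)
    WtW = W_row.T @ W_row

    beta = np.zeros(p)
    beta[0] = y.mean()
    u = np.zeros((m, q))
    Gmat = np.eye(q) * V if q else np.zeros((0, 0))
    sigma2 = fix_sigma2 if fix_sigma2 is not None else vy
    dof_G = prior.nu + q - 1 + 1e-12  # chi-square dof must stay positive at q=1
    S0 = np.eye(q) * V * prior.nu

    D = mcmc.n_stored
    beta_d = np.empty((D, p))
    u_d = np.empty((D, m, q))
    G_d = np.empty((D, q, q))
    s2_d = np.empty(D)
    stored = 0
    prior_prec_b = 1.0 / prior.fixed_effect_variance

    for it in range(1, mcmc.n_iter + 1):
        zu = u @ W_row.T if q else 0.0          # (m, k)
        # --- beta | rest ---
        r_mat = y_mat - zu
        prec = XtX / sigma2 + np.eye(p) * prior_prec_b
        rhs = X_row.T @ r_mat.sum(axis=0) / sigma2
        Lb = np.linalg.cholesky(prec)
        mean_b = np.linalg.solve(prec, rhs)
        beta = mean_b + np.linalg.solve(Lb.T, rng.standard_normal(p))
        xb = X_row @ beta                        # (k,)
        # --- u | rest ---
        if q:
            Ginv = np.linalg.inv(Gmat)
            A = WtW / sigma2 + Ginv
            La = np.linalg.cholesky(A)
            B = (y_mat - xb) @ W_row / sigma2    # (m, q)
            mean_u = np.linalg.solve(A, B.T).T
            z = rng.standard_normal((m, q))
            u = mean_u + np.linalg.solve(La.T, z.T).T
            # --- G | rest ---
            SG = S0 + u.T @ u
            Gmat = _sample_invwishart(rng, dof_G + m, SG)
        # --- sigma2 | rest ---
        resid = y_mat - xb - (u @ W_row.T if q else 0.0)
        if fix_sigma2 is None:
            rss = float(np.einsum("ij,ij->", resid, resid))
            sigma2 = (prior.nu * V + rss) / rng.chisquare(prior.nu + n)
        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            beta_d[stored] = beta
            u_d[stored] = u
            if q:
                G_d[stored] = Gmat
            s2_d[stored] = sigma2
            stored += 1

    return FitResult(spec, prior, mcmc, individuals, x_s, float(dens.mean()),
                     float(dens.std(ddof=0)), y_s, np.tile(X_row, (m, 1)),
                     np.tile(W_row, (m, 1)), idx_s,
                     beta=beta_d, u=u_d, G=G_d, sigma2=s2_d)


def _deviance(y, mu, sigma2) -> float:
    n = y.size
    return float(n * np.log(2 * np.pi * sigma2) + np.sum((y - mu) ** 2) / sigma2)


def compute_dic(fit: FitResult, obs: pd.DataFrame | None = None) -> float:
    """Conditional-likelihood DIC: D_bar + p_D with the individual effects
    in focus; p_D = D_bar - D(theta_bar) at the posterior means."""
    if fit.degenerate:
        return float("nan")
    y, X, W, idx = fit.y, fit.X, fit.Z_cols, fit.id_index
    q = fit.spec.q
    mus = fit.beta @ X.T
    if q:
        mus = mus + np.einsum("dnq,nq->dn", fit.u[:, idx, :], W)
    devs = (y.size * np.log(2 * np.pi * fit.sigma2)
            + np.sum((y[None, :] - mus) ** 2, axis=1) / fit.sigma2)
    d_bar = float(devs.mean())
    mu_bar = X @ fit.beta.mean(axis=0)
    if q:
        mu_bar = mu_bar + np.einsum("nq,nq->n", fit.u.mean(axis=0)[idx], W)
    d_hat = _deviance(y, mu_bar, float(fit.sigma2.mean()))
    return d_bar + (d_bar - d_hat)


def select_model(dics: Mapping[str, float]) -> str:
    """Within-2-of-minimum, most-complex-wins selection.

    Among models whose DIC lies within 2 of the smallest, return the one
    highest in the complexity ordering M1 < M2 < ... < M6.
    """
    finite = {lab: d for lab, d in dics.items() if np.isfinite(d)}
    if not finite:
        raise ValueError("no finite DIC values to select among")
    best = min(finite.values())
    candidates = [lab for lab, d in finite.items() if d - best < 2.0]
    return max(candidates, key=MODEL_ORDER.index)


def dic_table(dics: Mapping[str, float]) -> pd.DataFrame:
    """Delta-DIC table relative to the minimum, in complexity order."""
    finite = [d for d in dics.values() if np.isfinite(d)]
    base = min(finite) if finite else np.nan
    rows = [{"model": lab, "DIC": d, "dDIC": d - base}
            for lab, d in sorted(dics.items(), key=lambda kv: MODEL_ORDER.index(kv[0]))]
    return pd.DataFrame(rows)


def repeatability(
    fit: FitResult,
    covariate_values: Sequence[float] | None = None,
) -> RepeatabilityEstimate:
    """Posterior distribution of r = s2_among / (s2_among + s2_within).

    For models with random slopes/curvatures, s2_among is the
    among-individual variance marginalized over the design's standardized
    covariate values x (including G's covariance terms):

        s2_among(x) = G00 + x^2 G11 + x^4 G22
                      + 2x G01 + 2x^2 G02 + 2x^3 G12

    averaged over x.  The partition reports the design-averaged diagonal
    contributions; off-diagonal mass is in ``covariance_contribution``.
    """
    if fit.degenerate or fit.spec.q == 0:
        return RepeatabilityEstimate(r=None)
    xs = np.asarray(covariate_values if covariate_values is not None
                    else np.unique(fit.x_values), dtype=float)
    Wx = _term_columns(xs, fit.spec.random)      # (len(xs), q)
    per_x = np.einsum("kq,dqr,kr->dk", Wx, fit.G, Wx)
    s2_among = per_x.mean(axis=1)                # (draws,)
    r_draws = s2_among / (s2_among + fit.sigma2)
    diag = {t: float(np.mean(Wx[:, a] ** 2) * fit.G[:, a, a].mean())
            for a, t in enumerate(fit.spec.random)}
    s2_among_mean = float(s2_among.mean())
    cov_contrib = s2_among_mean - sum(diag.values())
    return RepeatabilityEstimate(
        r=float(r_draws.mean()),
        ci_low=float(np.quantile(r_draws, 0.025)),
        ci_high=float(np.quantile(r_draws, 0.975)),
        draws=r_draws, partition=diag,
        covariance_contribution=float(cov_contrib),
        s2_among=s2_among_mean, s2_within=float(fit.sigma2.mean()))


def prior_sensitivity(
    obs: pd.DataFrame,
    spec: ModelSpec,
    divisors: Sequence[float] = (2, 4, 6),
    mcmc: McmcSettings = McmcSettings.desk(),
) -> pd.DataFrame:
    """Refit under each prior variance divisor and tabulate r.

    The returned frame carries ``max_pairwise_diff`` in ``attrs``: the
    largest |r_a - r_b| across divisor pairs, the headline robustness
    number."""
    rows = []
    for div in divisors:
        fit = fit_mixed_model(obs, spec, PriorSpec(variance_divisor=div), mcmc)
        est = repeatability(fit)
        rows.append({"divisor": div, "r": est.r, "ci_low": est.ci_low,
                     "ci_high": est.ci_high})
    out = pd.DataFrame(rows)
    rs = out["r"].to_numpy(dtype=float)
    out.attrs["max_pairwise_diff"] = float(np.max(np.abs(rs[:, None] - rs[None, :]))) \
        if len(rs) > 1 else 0.0
    return out


def predict_reaction_norms(
    fit: FitResult,
    density_grid: Sequence[float],
) -> pd.DataFrame:
    """Population and per-individual predicted curves over a density grid.

    The population curve uses the posterior-mean fixed effects; each
    individual adds its posterior-mean random intercept / slope /
    curvature.  Rows: (individual, density, predicted), with the
    population curve under individual == 'population'.
    """
    grid = np.asarray(density_grid, dtype=float)
    xg = (grid - fit.density_mean) / fit.density_sd
    Xg = _term_columns(xg, fit.spec.fixed)
    beta_bar = fit.beta.mean(axis=0)
    pop = Xg @ beta_bar
    rows = [{"individual": "population", "density": float(d), "predicted": float(v)}
            for d, v in zip(grid, pop)]
    if fit.spec.q and not fit.degenerate:
        Wg = _term_columns(xg, fit.spec.random)
        u_bar = fit.u.mean(axis=0)
        for i, ind in enumerate(fit.individuals):
            vals = pop + Wg @ u_bar[i]
            rows += [{"individual": ind, "density": float(d), "predicted": float(v)}
                     for d, v in zip(grid, vals)]
    else:
        for ind in fit.individuals:
            rows += [{"individual": ind, "density": float(d), "predicted": float(v)}
                     for d, v in zip(grid, pop)]
    return pd.DataFrame(rows)


def _lag1_autocorr(z: np.ndarray) -> float:
    if z.std() == 0:
        return float("nan")
    return float(np.corrcoef(z[:-1], z[1:])[0, 1])


def _ess(z: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    n = z.size
    if z.std() == 0:
        return float("nan")
    zc = z - z.mean()
    acf = np.correlate(zc, zc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * zc.var())
    tau = 1.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


def check_convergence(fit: FitResult, threshold: float = 0.1) -> pd.DataFrame:
    """Lag-1 autocorrelation and ESS per stored chain; chains at or above
    the threshold (or undefined, e.g. constant) are flagged."""
    rows = []
    for name, chain in fit.parameter_chains().items():
        ac = _lag1_autocorr(chain)
        rows.append({"parameter": name, "lag1_autocorr": ac, "ess": _ess(chain),
                     "flagged": bool(np.isnan(ac) or abs(ac) >= threshold)})
    return pd.DataFrame(rows)


def normality_report(obs: pd.DataFrame) -> pd.DataFrame:
    """Advisory Shapiro-Wilk check of each metric's response distribution."""
    rows = []
    for metric, grp in obs.groupby("metric"):
        v = grp["value"].to_numpy(dtype=float)
        if v.size >= 3 and np.ptp(v) > 0:
            stat, p = stats.shapiro(v)
        else:
            stat, p = np.nan, np.nan
        rows.append({"metric": metric, "shapiro_w": stat, "p_value": p, "n": v.size})
    return pd.DataFrame(rows)
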