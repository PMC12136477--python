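"""Backfitting MCMC for the partial linear mixture model.

Model:  Y_i = h(Z_i) + X_i' beta + eps_i,  eps_i ~ N(0, sigma2),
with h a sum of soft trees.  Priors: flat on beta, inverse-gamma on sigma2,
depth-penalized tree topologies with Categorical(s) split variables and
uniform cutpoints, Dirichlet(a/M,...,a/M) on s with a/(a+M) ~ Beta(0.5, 1),
per-tree exponential bandwidths, and iid N(0, sigma_mu^2) leaf values.

Each Gibbs sweep updates, for every tree: the structure by a
grow/prune/change Metropolis-Hastings move with the leaf values integrated
out, the bandwidth tau by a log-scale random walk, and the leaf values from
their exact Gaussian conditional; then the split simplex s (conjugate
Dirichlet), the Dirichlet mass a (MH), beta (conjugate normal) and sigma2
(conjugate inverse-gamma).

Internally the response is mapped to [-0.5, 0.5] and every exposure column
min-max scaled to [0, 1]; all returned draws are back on the original scale.
The public update_* functions mirror the compiled sweep step by step on plain
tree objects, which keeps every conditional individually testable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as K
from .soft_forest import (ForestState, SoftTree, SoftTreeNode, arrays_to_tree,
                          basis_matrix, tree_to_arrays)

logger = logging.getLogger("softmix")

_MOVE_NAMES = {K.GROW: "grow", K.PRUNE: "prune", K.CHANGE: "change"}


# ---------------------------------------------------------------------------
# data containers

@dataclass
class MixtureDataset:
    """Outcome Y, exposure matrix Z (n x M) and confounders X (n x d)."""

    Y: np.ndarray
    Z: np.ndarray
    X: np.ndarray | None = None
    exposure_names: list[str] | None = None
    confounder_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = self.Y.size
        if n < 10:
            raise ValueError(f"need at least 10 observations, got {n}")
        if self.Z.shape[0] != n:
            raise ValueError("Y and Z row counts differ")
        if self.X is None or np.size(self.X) == 0:
            self.X = np.empty((n, 0))
        else:
            self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if self.X.shape[0] != n:
                raise ValueError("Y and X row counts differ")
        for name, arr in (("Y", self.Y), ("Z", self.Z), ("X", self.X)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing/non-finite values")
        if self.exposure_names is None:
            self.exposure_names = [f"z{m + 1}" for m in range(self.Z.shape[1])]
        if self.confounder_names is None:
            self.confounder_names = [f"x{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.Y.size

    @property
    def n_exposures(self) -> int:
        return self.Z.shape[1]

    @property
    def n_confounders(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str,
                       exposures: Sequence[str],
                       confounders: Sequence[str] = ()) -> "MixtureDataset":
        return cls(Y=df[outcome].to_numpy(),
                   Z=df[list(exposures)].to_numpy(),
                   X=df[list(confounders)].to_numpy() if confounders else None,
                   exposure_names=list(exposures),
                   confounder_names=list(confounders))


@dataclass
class SamplerConfig:
    """Tuning knobs of the sampler; defaults follow the reference protocol."""

    n_trees: int = 30
    total_draws: int = 20000
    burn_in: int | None = None            # default: half of total_draws
    thin: int = 1
    depth_gamma: float | None = None      # default: 0.3 if n<=500 else 0.1
    depth_beta: float = 2.0
    ig_shape: float = 3.0
    ig_scale: float | None = None         # default: calibrated to the data
    tau_prior_mean: float = 0.1           # exponential bandwidth prior mean
    move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    sigma_mu: float | None = None         # default: 0.5 / (2 sqrt(n_trees))
    tau_prop_sd: float = 0.5
    mass_prop_sd: float = 0.6
    sample_sigma_mu: bool = True
    sigma_mu_prop_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.total_draws // 2
        if not 0 <= self.burn_in < self.total_draws:
            raise ValueError("burn_in must lie in [0, total_draws)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not math.isclose(sum(self.move_probs), 1.0):
            raise ValueError("move_probs must sum to 1")
        if self.depth_gamma is not None and not (0 < self.depth_gamma < 1):
            raise ValueError("depth_gamma must lie in (0, 1)")

    def resolved_gamma(self, n: int) -> float:
        if self.depth_gamma is not None:
            return self.depth_gamma
        return 0.3 if n <= 500 else 0.1

    def resolved_sigma_mu(self) -> float:
        if self.sigma_mu is not None:
            return self.sigma_mu
        return 0.5 / (2.0 * math.sqrt(self.n_trees))

    def resolved_ig_scale(self, y_internal: np.ndarray,
                          design: np.ndarray | None = None) -> float:
        """Scale b of IG(a, b) placing the prior 90th percentile at a rough
        data-based estimate of the error variance.

        The estimate is the residual variance of an OLS fit of the internal
        response on an intercept, the confounders and the (linear) exposures
        — the classic BART-style calibration; anchoring instead on the raw
        response variance grossly overstates sigma2 whenever the signal is
        strong, which drags the posterior upward and starves the forest of
        splits.
        """
        if self.ig_scale is not None:
            return self.ig_scale
        if design is None or design.shape[1] >= y_internal.size:
            target = float(np.var(y_internal))
        else:
            coef, *_ = np.linalg.lstsq(design, y_internal, rcond=None)
            target = float(np.var(y_internal - design @ coef))
        return target / float(stats.invgamma(self.ig_shape).ppf(0.9))


@dataclass
class ModelState:
    """One MCMC state: forest, confounder coefficients, error variance."""

    forest: ForestState
    beta: np.ndarray
    sigma2: float
    fit: np.ndarray   # cached h(Z_i), kept current by the update operations

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.fit = np.asarray(self.fit, dtype=float).ravel()
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


class PosteriorDraws:
    """Retained post-burn-in states plus compact forest snapshots.

    All stored chains are on the original data scale.  The per-draw forest
    snapshots (flat arrays on the internal scale) let any partial-dependence
    summary be evaluated after the run without re-fitting.
    """

    def __init__(self, beta, sigma2, split_probs, dirichlet_mass, usage,
                 h_train, snapshots, Zs, z_min, z_range, y_scale, y_offset,
                 exposure_names, confounder_names, diagnostics=None):
        self.beta = np.asarray(beta, dtype=float)
        self.sigma2 = np.asarray(sigma2, dtype=float)
        self.split_probs = np.asarray(split_probs, dtype=float)
        self.dirichlet_mass = np.asarray(dirichlet_mass, dtype=float)
        self.usage = np.asarray(usage, dtype=bool)
        self.h_train = np.asarray(h_train, dtype=float)
        self.snapshots = snapshots
        self.Zs = np.asarray(Zs, dtype=float)
        self.z_min = np.asarray(z_min, dtype=float)
        self.z_range = np.asarray(z_range, dtype=float)
        self.y_scale = float(y_scale)
        self.y_offset = float(y_offset)
        self.exposure_names = list(exposure_names)
        self.confounder_names = list(confounder_names)
        self.diagnostics = diagnostics or {}

    @property
    def n_draws(self) -> int:
        return self.sigma2.size

    @property
    def n_exposures(self) -> int:
        return self.Zs.shape[1]

    def exposure_index(self, name_or_index) -> int:
        if isinstance(name_or_index, str):
            return self.exposure_names.index(name_or_index)
        m = int(name_or_index)
        if not 0 <= m < self.n_exposures:
            raise IndexError(f"exposure index {m} out of range")
        return m

    def scale_grid(self, m: int, grid: np.ndarray) -> np.ndarray:
        """Map an original-scale exposure grid to the internal [0, 1] scale."""
        return (np.asarray(grid, dtype=float) - self.z_min[m]) / self.z_range[m]

    def observed_exposures(self, m: int) -> np.ndarray:
        """Training values of exposure m on the original scale."""
        return self.Zs[:, m] * self.z_range[m] + self.z_min[m]

    def forest(self, i: int) -> ForestState:
        """Reconstruct the i-th retained forest as SoftTree objects.

        Cutpoints/bandwidths are on the internal [0, 1] exposure scale and
        leaf values on the internal response scale.
        """
        off, var, cut, left, right, mu, taus = self.snapshots[i]
        trees = [arrays_to_tree(var[off[t]:off[t + 1]], cut[off[t]:off[t + 1]],
                                left[off[t]:off[t + 1]],
                                right[off[t]:off[t + 1]],
                                mu[off[t]:off[t + 1]],
                                int(off[t + 1] - off[t]), float(taus[t]))
                 for t in range(off.size - 1)]
        return ForestState(trees=trees, split_probs=self.split_probs[i],
                           dirichlet_mass=float(self.dirichlet_mass[i]),
                           sigma_mu=float(self.diagnostics.get("sigma_mu", 0.05)),
                           depth_gamma=float(self.diagnostics.get("depth_gamma", 0.3)),
                           depth_beta=float(self.diagnostics.get("depth_beta", 2.0)))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        snaps = [[a.tolist() for a in snap] for snap in self.snapshots]
        return json.dumps({
            "beta": self.beta.tolist(), "sigma2": self.sigma2.tolist(),
            "split_probs": self.split_probs.tolist(),
            "dirichlet_mass": self.dirichlet_mass.tolist(),
            "usage": self.usage.astype(int).tolist(),
            "h_train": self.h_train.tolist(),
            "snapshots": snaps, "Zs": self.Zs.tolist(),
            "z_min": self.z_min.tolist(), "z_range": self.z_range.tolist(),
            "y_scale": self.y_scale, "y_offset": self.y_offset,
            "exposure_names": self.exposure_names,
            "confounder_names": self.confounder_names,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str))},
        })

    @classmethod
    def from_json(cls, text: str) -> "PosteriorDraws":
        d = json.loads(text)
        snaps = []
        for off, var, cut, left, right, mu, taus in d["snapshots"]:
            snaps.append((np.asarray(off, np.int64), np.asarray(var, np.int64),
                          np.asarray(cut, float), np.asarray(left, np.int64),
                          np.asarray(right, np.int64), np.asarray(mu, float),
                          np.asarray(taus, float)))
        return cls(beta=d["beta"], sigma2=d["sigma2"],
                   split_probs=d["split_probs"],
                   dirichlet_mass=d["dirichlet_mass"],
                   usage=np.asarray(d["usage"], dtype=bool),
                   h_train=d["h_train"], snapshots=snaps, Zs=d["Zs"],
                   z_min=d["z_min"], z_range=d["z_range"],
                   y_scale=d["y_scale"], y_offset=d["y_offset"],
                   exposure_names=d["exposure_names"],
                   confounder_names=d["confounder_names"],
                   diagnostics=d.get("diagnostics", {}))


# ---------------------------------------------------------------------------
# individual update operations (reference surface; the fused sweep in
# run_mcmc performs exactly these steps through the same compiled kernels)

def log_tree_prior(tree: SoftTree, forest: ForestState) -> float:
    """Log prior of a tree topology and its split rules.

    Depth-d branches contribute log(gamma (1+d)^-beta) plus the split-rule
    density log s_j - log|interval|; depth-d leaves log(1 - gamma (1+d)^-beta).
    """
    gamma = forest.depth_gamma
    if not 0 < gamma < 1:
        raise ValueError(f"depth_gamma must lie in (0, 1), got {gamma}")
    a = tree_to_arrays(tree)
    return float(K._log_tree_prior(a["var"], a["cut"], a["left"], a["parent"],
                                   a["depth"], a["nnode"], forest.split_probs,
                                   gamma, forest.depth_beta))


def integrated_log_likelihood(tree: SoftTree, Z: np.ndarray,
                              partial_residuals: np.ndarray, sigma2: float,
                              sigma_mu: float) -> float:
    """Marginal log likelihood of residuals with leaf values integrated out.

    r ~ N(0, sigma2 I + sigma_mu^2 Phi Phi'), evaluated through the L x L
    (Woodbury) form since the leaf count L is far below n.
    """
    if not (sigma2 > 0 and sigma_mu >= 0):
        raise ValueError("variances must be positive")
    r = np.asarray(partial_residuals, dtype=float).ravel()
    if sigma_mu == 0.0:
        return float(np.sum(stats.norm.logpdf(r, scale=math.sqrt(sigma2))))
    Phi = basis_matrix(Z, tree)
    return float(K._marginal_loglik(Phi, r, sigma2, sigma_mu ** 2))


class ProposeResult(NamedTuple):
    tree: SoftTree | None      # None when the proposal is auto-rejected
    log_ratio: float           # log q(reverse) - log q(forward)
    move: str


def propose_move(tree: SoftTree, split_probs: np.ndarray,
                 rng: np.random.Generator,
                 move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2),
                 ) -> ProposeResult:
    """One grow / prune / change proposal with its MH proposal-density ratio.

    Grow draws the split variable from Categorical(split_probs) and the
    cutpoint uniformly over the interval admissible given the ancestors; a
    stump resamples the move type to grow.
    """
    a = tree_to_arrays(tree)
    s = np.asarray(split_probs, dtype=float)
    scratch = [np.empty(K.NMAX, np.int64) for _ in range(4)]
    pcut = np.empty(K.NMAX)
    pmu = np.empty(K.NMAX)
    pdepth = np.empty(K.NMAX, np.int64)
    move, valid, lqr, pn = K._propose(
        a["var"], a["cut"], a["left"], a["right"], a["parent"], a["depth"],
        a["mu"], a["nnode"], s, move_probs[0], move_probs[1], move_probs[2],
        scratch[0], pcut, scratch[1], scratch[2], scratch[3], pdepth, pmu, rng)
    if not valid:
        return ProposeResult(None, -np.inf, _MOVE_NAMES[move])
    new = arrays_to_tree(scratch[0], pcut, scratch[1], scratch[2], pmu,
                         int(pn), tree.tau)
    return ProposeResult(new, float(lqr), _MOVE_NAMES[move])


def draw_leaf_values(tree: SoftTree, Z: np.ndarray,
                     partial_residuals: np.ndarray, sigma2: float,
                     sigma_mu: float, rng: np.random.Generator) -> SoftTree:
    """Redraw all leaf values jointly from their Gaussian conditional.

    mu | . ~ N((Phi'Phi/sigma2 + I/sigma_mu^2)^-1 Phi'r / sigma2,
               (Phi'Phi/sigma2 + I/sigma_mu^2)^-1).
    """
    if not (sigma2 > 0 and sigma_mu > 0):
        raise ValueError("variances must be positive")
    r = np.asarray(partial_residuals, dtype=float).ravel()
    Phi = basis_matrix(Z, tree)
    z = rng.standard_normal(Phi.shape[1])
    mu_new = K._draw_leaves(Phi, r, sigma2, sigma_mu ** 2, z)
    a = tree_to_arrays(tree)
    l = 0
    for k in range(a["nnode"]):
        if a["var"][k] < 0:
            a["mu"][k] = mu_new[l]
            l += 1
    return arrays_to_tree(a["var"], a["cut"], a["left"], a["right"], a["mu"],
                          a["nnode"], tree.tau)


def update_tau(tree: SoftTree, Z: np.ndarray, partial_residuals: np.ndarray,
               sigma2: float, sigma_mu: float, rng: np.random.Generator,
               prior_rate: float = 10.0, prop_sd: float = 0.5) -> SoftTree:
    """Random-walk MH on log tau under the exponential bandwidth prior.

    The marginal (leaf-integrated) likelihood is the target, so on a
    single-leaf tree the chain simply samples the prior.
    """
    r = np.asarray(partial_residuals, dtype=float).ravel()
    tau_new = tree.tau * math.exp(prop_sd * rng.standard_normal())
    ll_cur = integrated_log_likelihood(tree, Z, r, sigma2, sigma_mu)
    cand = SoftTree(root=tree.root, tau=tau_new)
    ll_new = integrated_log_likelihood(cand, Z, r, sigma2, sigma_mu)
    la = (ll_new - prior_rate * tau_new + math.log(tau_new)) \
        - (ll_cur - prior_rate * tree.tau + math.log(tree.tau))
    if math.log(rng.random()) < la:
        return cand
    return tree


def update_split_probs(forest: ForestState,
                       rng: np.random.Generator) -> np.ndarray:
    """Conjugate Dirichlet update: s ~ Dir(a/M + c_1, ..., a/M + c_M)."""
    M = forest.n_variables
    counts = np.zeros(M)
    for tree in forest.trees:
        for b in tree.branches():
            counts[b.split_index] += 1
    s = rng.dirichlet(forest.dirichlet_mass / M + counts)
    # tiny floor: exact zeros (possible for very small concentrations) would
    # put -inf prior mass on existing splits and break MH ratios
    s = np.clip(s, 1e-12, None)
    s /= s.sum()
    forest.split_probs = s
    return s


def _log_mass_target(a: float, s: np.ndarray, M: int) -> float:
    # Dirichlet(a/M,...) likelihood of s plus the Beta(0.5, 1) prior on
    # u = a/(a+M), with the u -> a change of variables.
    u = a / (a + M)
    logs = np.log(np.clip(s, 1e-300, None))
    return (math.lgamma(a) - M * math.lgamma(a / M)
            + (a / M - 1.0) * float(np.sum(logs))
            + math.log(0.5) - 0.5 * math.log(u)
            + math.log(M) - 2.0 * math.log(a + M))


def update_dirichlet_mass(forest: ForestState, rng: np.random.Generator,
                          prop_sd: float = 0.6,
                          likelihood: bool = True) -> float:
    """MH update of the Dirichlet mass a with a/(a+M) ~ Beta(0.5, 1)."""
    M = forest.n_variables
    a = forest.dirichlet_mass
    a_new = a * math.exp(prop_sd * rng.standard_normal())

    def target(x: float) -> float:
        if likelihood:
            return _log_mass_target(x, forest.split_probs, M)
        u = x / (x + M)
        return (math.log(0.5) - 0.5 * math.log(u)
                + math.log(M) - 2.0 * math.log(x + M))

    la = target(a_new) + math.log(a_new) - target(a) - math.log(a)
    if math.log(rng.random()) < la:
        forest.dirichlet_mass = a_new
    return forest.dirichlet_mass


def update_sigma_mu(sigma_mu: float, leaf_values: np.ndarray, scale: float,
                    rng: np.random.Generator, prop_sd: float = 0.3) -> float:
    """MH update of the leaf scale under a half-Cauchy(scale) prior.

    The conditional likelihood treats every leaf value in the forest as iid
    N(0, sigma_mu^2); sampling the scale lets the ensemble adapt its total
    signal variance to the data instead of committing to a fixed shrinkage.
    """
    mus = np.asarray(leaf_values, dtype=float).ravel()

    def log_target(sm: float) -> float:
        return (-mus.size * math.log(sm)
                - 0.5 * float(mus @ mus) / sm ** 2
                - math.log1p((sm / scale) ** 2))

    cand = sigma_mu * math.exp(prop_sd * rng.standard_normal())
    la = log_target(cand) + math.log(cand) \
        - log_target(sigma_mu) - math.log(sigma_mu)
    return cand if math.log(rng.random()) < la else sigma_mu


def update_beta(state: ModelState, data: MixtureDataset,
                rng: np.random.Generator) -> np.ndarray:
    """Flat-prior conjugate draw: beta ~ N((X'X)^-1 X'(Y-h), sigma2 (X'X)^-1)."""
    X = data.X
    d = X.shape[1]
    if d == 0:
        return state.beta
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < d:
        norms = np.linalg.norm(X, axis=0)
        bad = [data.confounder_names[j] for j in np.where(norms == 0)[0]]
        raise ValueError(
            "confounder matrix is rank deficient"
            + (f" (zero columns: {bad})" if bad else "")
            + "; drop collinear columns")
    mean = np.linalg.solve(XtX, X.T @ (data.Y - state.fit))
    L = np.linalg.cholesky(XtX)
    z = rng.standard_normal(d)
    beta = mean + math.sqrt(state.sigma2) * np.linalg.solve(L.T, z)
    state.beta = beta
    return beta


def update_sigma2(state: ModelState, data: MixtureDataset,
                  rng: np.random.Generator, ig_shape: float = 3.0,
                  ig_scale: float = 1.0) -> float:
    """Conjugate draw sigma2 ~ IG(a + n/2, b + sum r_i^2 / 2)."""
    r = data.Y - state.fit - data.X @ state.beta
    shape = ig_shape + data.n / 2.0
    scale = ig_scale + float(r @ r) / 2.0
    state.sigma2 = scale / rng.gamma(shape)
    return state.sigma2


def update_tree(state: ModelState, data: MixtureDataset, tree_index: int,
                rng: np.random.Generator,
                move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2),
                ) -> bool:
    """Structure MH step for one tree on its backfitting partial residuals.

    On acceptance (and also on rejection, matching the full sweep) the leaf
    values are redrawn conjugately and the cached fit refreshed.
    """
    forest = state.forest
    tree = forest.trees[tree_index]
    Z = data.Z
    fit_t = basis_matrix(Z, tree) @ np.array([lf.mu for lf in tree.leaves()])
    r = data.Y - data.X @ state.beta - (state.fit - fit_t)
    sigma_mu = forest.sigma_mu

    prop = propose_move(tree, forest.split_probs, rng, move_probs)
    accepted = False
    if prop.tree is not None:
        lp_prop = log_tree_prior(prop.tree, forest)
        if np.isfinite(lp_prop):
            ll_prop = integrated_log_likelihood(prop.tree, Z, r, state.sigma2,
                                                sigma_mu)
            ll_cur = integrated_log_likelihood(tree, Z, r, state.sigma2,
                                               sigma_mu)
            lp_cur = log_tree_prior(tree, forest)
            if math.log(rng.random()) < (ll_prop + lp_prop - ll_cur - lp_cur
                                         + prop.log_ratio):
                tree = prop.tree
                accepted = True
    tree = draw_leaf_values(tree, Z, r, state.sigma2, sigma_mu, rng)
    forest.trees[tree_index] = tree
    new_fit_t = basis_matrix(Z, tree) @ np.array(
        [lf.mu for lf in tree.leaves()])
    state.fit = state.fit - fit_t + new_fit_t
    return accepted


# ---------------------------------------------------------------------------
# full chain

def run_mcmc(data: MixtureDataset, config: SamplerConfig | None = None,
             ) -> PosteriorDraws:
    """Run the full backfitting chain and return retained, thinned draws.

    Deterministic given ``config.rng_seed``: two runs with the same seed and
    configuration produce bitwise-identical output.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.rng_seed)
    n, M = data.Z.shape
    d = data.X.shape[1]
    T = config.n_trees

    # internal scales: exposures to [0, 1], response to [-0.5, 0.5]
    z_min = data.Z.min(axis=0)
    z_max = data.Z.max(axis=0)
    z_range = np.where(z_max > z_min, z_max - z_min, 1.0)
    Zs = (data.Z - z_min) / z_range
    y_min = data.Y.min()
    y_rng = data.Y.max() - y_min
    if y_rng == 0:
        y_rng = 1.0
    y = (data.Y - y_min) / y_rng - 0.5
    y_offset = y_min + 0.5 * y_rng

    gamma = config.resolved_gamma(n)
    sigma_mu = config.resolved_sigma_mu()   # fixed value, or HC prior scale
    sigma_mu_scale = sigma_mu
    sigma_mu2 = sigma_mu ** 2
    ig_scale = config.resolved_ig_scale(
        y, np.column_stack([np.ones(n), data.X, Zs]))
    tau_rate = 1.0 / config.tau_prior_mean
    p_grow, p_prune, p_change = config.move_probs

    X = data.X
    if d > 0:
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < d:
            raise ValueError("confounder matrix is rank deficient")
        XtX_chol = np.linalg.cholesky(XtX)

    # forest state: all stumps
    var2 = np.full((T, K.NMAX), -1, dtype=np.int64)
    cut2 = np.zeros((T, K.NMAX))
    left2 = np.full((T, K.NMAX), -1, dtype=np.int64)
    right2 = np.full((T, K.NMAX), -1, dtype=np.int64)
    parent2 = np.full((T, K.NMAX), -1, dtype=np.int64)
    depth2 = np.zeros((T, K.NMAX), dtype=np.int64)
    mu2 = np.zeros((T, K.NMAX))
    nnode1 = np.ones(T, dtype=np.int64)
    tau1 = np.full(T, config.tau_prior_mean)
    fits = np.zeros((T, n))
    s = np.full(M, 1.0 / M)
    mass = float(M)
    beta = np.zeros(d)
    sigma2 = float(np.var(y))
    resid = y - X @ beta if d > 0 else y.copy()

    forest_stub = ForestState(trees=[SoftTree(SoftTreeNode())],
                              split_probs=np.full(M, 1.0 / M),
                              dirichlet_mass=mass, sigma_mu=sigma_mu,
                              depth_gamma=gamma, depth_beta=config.depth_beta)

    keep = (config.total_draws - config.burn_in + config.thin - 1) // config.thin
    out_beta = np.empty((keep, d))
    out_sigma2 = np.empty(keep)
    out_s = np.empty((keep, M))
    out_mass = np.empty(keep)
    out_usage = np.empty((keep, M), dtype=bool)
    out_sigma_mu = np.empty(keep)
    out_h = np.empty((keep, n))
    snapshots: list[tuple] = []
    n_accept = 0
    n_moves = 0
    ptr = 0

    for it in range(config.total_draws):
        for t in range(T):
            n_accept += K._update_tree(
                t, var2, cut2, left2, right2, parent2, depth2, mu2,
                nnode1, tau1, Zs, resid, fits, s, sigma2, sigma_mu2,
                gamma, config.depth_beta, p_grow, p_prune, p_change,
                tau_rate, config.tau_prop_sd, rng)
            n_moves += 1

        if config.sample_sigma_mu:
            leaf_vals = np.concatenate(
                [mu2[t, :nnode1[t]][var2[t, :nnode1[t]] < 0]
                 for t in range(T)])
            sigma_mu = update_sigma_mu(sigma_mu, leaf_vals, sigma_mu_scale,
                                       rng, config.sigma_mu_prop_sd)
            sigma_mu2 = sigma_mu ** 2

        counts = K._split_counts(var2, nnode1, M)
        s = rng.dirichlet(mass / M + counts)
        s = np.clip(s, 1e-12, None)
        s /= s.sum()

        forest_stub.split_probs = s
        forest_stub.dirichlet_mass = mass
        mass = update_dirichlet_mass(forest_stub, rng,
                                     prop_sd=config.mass_prop_sd)

        if d > 0:
            v = X @ beta + resid        # = y - sum of tree fits
            mean = np.linalg.solve(XtX, X.T @ v)
            beta_new = mean + math.sqrt(sigma2) * np.linalg.solve(
                XtX_chol.T, rng.standard_normal(d))
            resid += X @ (beta - beta_new)
            beta = beta_new

        ssr = float(resid @ resid)
        sigma2 = (ig_scale + ssr / 2.0) / rng.gamma(config.ig_shape + n / 2.0)

        if not (np.isfinite(sigma2) and np.isfinite(ssr)):
            raise RuntimeError(f"sampler diverged (NaN) at draw {it}")

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out_beta[ptr] = beta * y_rng
            out_sigma2[ptr] = sigma2 * y_rng ** 2
            out_s[ptr] = s
            out_mass[ptr] = mass
            out_usage[ptr] = counts > 0
            out_sigma_mu[ptr] = sigma_mu
            h_int = y - resid - (X @ beta if d > 0 else 0.0)
            out_h[ptr] = h_int * y_rng + y_offset
            off = np.zeros(T + 1, dtype=np.int64)
            off[1:] = np.cumsum(nnode1)
            snapshots.append((
                off,
                np.concatenate([var2[t, :nnode1[t]] for t in range(T)]),
                np.concatenate([cut2[t, :nnode1[t]] for t in range(T)]),
                np.concatenate([left2[t, :nnode1[t]] for t in range(T)]),
                np.concatenate([right2[t, :nnode1[t]] for t in range(T)]),
                np.concatenate([mu2[t, :nnode1[t]] for t in range(T)]),
                tau1.copy()))
            ptr += 1

    diag = {"accept_rate": n_accept / max(n_moves, 1),
            "sigma_mu": float(out_sigma_mu[:ptr].mean()) if ptr else sigma_mu,
            "depth_gamma": gamma,
            "depth_beta": config.depth_beta,
            "sigma2_posterior_mean": float(out_sigma2.mean())}
    logger.info("chain finished: %d retained draws, structure acceptance %.3f, "
                "posterior mean sigma2 %.4f", ptr, diag["accept_rate"],
                diag["sigma2_posterior_mean"])
    return PosteriorDraws(
        beta=out_beta[:ptr], sigma2=out_sigma2[:ptr], split_probs=out_s[:ptr],
        dirichlet_mass=out_mass[:ptr], usage=out_usage[:ptr],
        h_train=out_h[:ptr], snapshots=snapshots, Zs=Zs, z_min=z_min,
        z_range=z_range, y_scale=y_rng, y_offset=y_offset,
        exposure_names=data.exposure_names,
        confounder_names=data.confounder_names, diagnostics=diag)
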