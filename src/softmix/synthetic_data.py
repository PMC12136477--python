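"""Synthetic data for the simulation study and an NHS-like exposure table.

Four exposure-response surfaces of increasing difficulty are supported:

1. ``h1(z) = 2 sin(pi z1 / 2) + 2 cos(pi z2 / 2) + z1 + z2^2`` with three
   correlated exposures of which only the first two are active;
2. ``h2 = h1 + 4 plogis(z3; 0, 0.3)`` — all three exposures active;
3. ``h3 = 10 z1 (1 - z1) sin(2 pi / z1) + 4 plogis(z2; 0, 0.3) + z1 + z2^2``
   with z1 supported on (0.2, 1], whose first term has varying smoothness;
4. ``h4`` — the case-1 surface embedded in 13 correlated exposures, the
   other eleven inert.

Cases 1-3 use corr(z1,z2)=0.1, corr(z2,z3)=0.3, corr(z1,z3)=0.7.  Exposures
are standard normal marginally (only correlations are prescribed); the case-3
first coordinate is mapped to (0.2, 1] by the rank-preserving probit-uniform
transform 0.2 + 0.8 Phi(z).  Confounders are X1 ~ N(0,1) and
X2 = cos(Z1) + N(0, 0.2) (0.2 a variance), entering with coefficients (2, 2),
and the residual variance is 0.5.

The NHS-like generator emulates the *structure* of a PM2.5 constituent
cohort — 12 log-normal constituent concentrations, demographic confounders
and a continuous cognitive-composite outcome — with an entirely synthetic
correlation matrix and effect; no cohort data are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .sampler import MixtureDataset

CONSTITUENTS = ["Br", "Ca", "Cu", "Fe", "Mn", "Ni", "S", "Se", "Si", "Ti",
                "V", "Zn"]

#: correlations shared by the three-exposure cases
CASE_CORR_3 = np.array([[1.0, 0.1, 0.7],
                        [0.1, 1.0, 0.3],
                        [0.7, 0.3, 1.0]])

_ACTIVE = {1: [True, True, False], 2: [True, True, True],
           3: [True, True, False],
           4: [True, True] + [False] * 11}


def default_corr_13() -> np.ndarray:
    """A fixed synthetic 13 x 13 PD correlation matrix.

    Built once from a low-rank factor draw with a fixed seed, giving a mix of
    weak and strong pairwise correlations comparable to co-measured ambient
    constituents.  Users may substitute any monitor-derived matrix.
    """
    rng = np.random.default_rng(1913)
    A = rng.normal(size=(13, 4)) + 0.6 * rng.normal(size=(13, 1))
    S = A @ A.T + np.diag(rng.uniform(0.5, 1.5, size=13))
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


@dataclass
class SimCaseSpec:
    """Configuration of one simulation case."""

    case_id: int
    n: int = 100
    corr: np.ndarray | None = None
    sigma2_true: float = 0.5
    beta_true: tuple[float, float] = (2.0, 2.0)
    x2_noise_var: float = 0.2
    square_sum: bool = False   # read the quadratic term as (z1+z2)^2 instead
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.case_id not in (1, 2, 3, 4):
            raise ValueError("case_id must be 1, 2, 3 or 4")
        if self.corr is None:
            self.corr = default_corr_13() if self.case_id == 4 else CASE_CORR_3
        self.corr = np.asarray(self.corr, dtype=float)
        M = 13 if self.case_id == 4 else 3
        if self.corr.shape != (M, M):
            raise ValueError(f"case {self.case_id} needs a {M}x{M} corr matrix")
        if not np.allclose(self.corr, self.corr.T) or not np.allclose(
                np.diag(self.corr), 1.0):
            raise ValueError("corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() <= 0:
            raise ValueError("corr must be positive definite")

    @property
    def M(self) -> int:
        return self.corr.shape[0]

    @property
    def active_mask(self) -> np.ndarray:
        return np.asarray(_ACTIVE[self.case_id])


@dataclass
class TruthBundle:
    """Generated dataset plus everything needed to score an estimator."""

    dataset: MixtureDataset
    h_values: np.ndarray                      # true h at the data rows
    active_mask: np.ndarray
    h_fn: Callable[[np.ndarray], np.ndarray]  # vectorized true surface
    spec: SimCaseSpec


def plogis_shifted(x, a: float, b: float):
    """Shifted/scaled logistic CDF: (1 + tanh((x - a) / (2b))) / 2."""
    if not b > 0:
        raise ValueError(f"scale b must be positive, got {b}")
    return (1.0 + np.tanh((np.asarray(x, dtype=float) - a) / (2.0 * b))) / 2.0


def h_case(case_id: int, z: np.ndarray, square_sum: bool = False) -> np.ndarray:
    """True exposure-response surface for one case, vectorized over rows."""
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    z1, z2 = Z[:, 0], Z[:, 1]
    quad = (z1 + z2) ** 2 if square_sum else z1 + z2 ** 2
    if case_id in (1, 4):
        out = 2.0 * np.sin(np.pi * z1 / 2.0) + 2.0 * np.cos(np.pi * z2 / 2.0) \
            + quad
    elif case_id == 2:
        out = (2.0 * np.sin(np.pi * z1 / 2.0) + 2.0 * np.cos(np.pi * z2 / 2.0)
               + quad + 4.0 * plogis_shifted(Z[:, 2], 0.0, 0.3))
    elif case_id == 3:
        if np.any(z1 <= 0.2):
            raise ValueError("case 3 requires z1 in (0.2, 1]")
        out = (10.0 * z1 * (1.0 - z1) * np.sin(2.0 * np.pi / z1)
               + 4.0 * plogis_shifted(z2, 0.0, 0.3) + quad)
    else:
        raise ValueError("case_id must be 1, 2, 3 or 4")
    return out if np.asarray(z).ndim > 1 else float(out[0])


def gen_exposures(spec: SimCaseSpec, rng: np.random.Generator) -> np.ndarray:
    """n x M correlated exposures; case-3 z1 mapped into (0.2, 1]."""
    L = np.linalg.cholesky(spec.corr)
    Z = rng.standard_normal((spec.n, spec.M)) @ L.T
    if spec.case_id == 3:
        Z[:, 0] = 0.2 + 0.8 * stats.norm.cdf(Z[:, 0])
    return Z


def gen_dataset(spec: SimCaseSpec,
                rng: np.random.Generator | None = None) -> TruthBundle:
    """Generate one replicate dataset with its attached ground truth."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    Z = gen_exposures(spec, rng)
    n = spec.n
    X1 = rng.standard_normal(n)
    X2 = np.cos(Z[:, 0]) + rng.normal(0.0, np.sqrt(spec.x2_noise_var), size=n)
    X = np.column_stack([X1, X2])
    h = h_case(spec.case_id, Z, spec.square_sum)
    b1, b2 = spec.beta_true
    Y = h + b1 * X1 + b2 * X2 + rng.normal(0.0, np.sqrt(spec.sigma2_true),
                                           size=n)
    data = MixtureDataset(Y=Y, Z=Z, X=X,
                          exposure_names=[f"z{m + 1}" for m in range(spec.M)],
                          confounder_names=["x1", "x2"])
    return TruthBundle(dataset=data, h_values=h, active_mask=spec.active_mask,
                       h_fn=lambda rows: h_case(spec.case_id, rows,
                                                spec.square_sum),
                       spec=spec)


def true_main_pd(bundle: TruthBundle, m: int, grid: np.ndarray) -> np.ndarray:
    """Partial dependence of the true surface: mean_i h(z_m = g, Z_i,-m)."""
    Z = bundle.dataset.Z
    grid = np.asarray(grid, dtype=float)
    out = np.empty(grid.size)
    for g, val in enumerate(grid):
        Zg = Z.copy()
        Zg[:, m] = val
        out[g] = bundle.h_fn(Zg).mean()
    return out


def true_pair_pd(bundle: TruthBundle, m1: int, m2: int, grid1: np.ndarray,
                 grid2: np.ndarray) -> np.ndarray:
    """Bivariate partial dependence surface of the true h (grid1 x grid2)."""
    Z = bundle.dataset.Z
    out = np.empty((len(grid1), len(grid2)))
    for i, v1 in enumerate(np.asarray(grid1, dtype=float)):
        for j, v2 in enumerate(np.asarray(grid2, dtype=float)):
            Zg = Z.copy()
            Zg[:, m1] = v1
            Zg[:, m2] = v2
            out[i, j] = bundle.h_fn(Zg).mean()
    return out


# ---------------------------------------------------------------------------
# NHS-like synthetic cohort

# synthetic log-scale concentration means (roughly ug/m3 magnitudes)
_LOG_MEANS = {"Br": -5.8, "Ca": -3.2, "Cu": -5.5, "Fe": -2.3, "Mn": -6.2,
              "Ni": -6.3, "S": -0.2, "Se": -7.1, "Si": -2.5, "Ti": -5.5,
              "V": -6.0, "Zn": -4.6}


def default_constituent_corr() -> np.ndarray:
    """Fixed synthetic 12 x 12 PD correlation for the constituent columns."""
    rng = np.random.default_rng(711)
    A = rng.normal(size=(12, 3)) + 0.8 * rng.normal(size=(12, 1))
    S = A @ A.T + np.diag(rng.uniform(0.8, 2.0, size=12))
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def gen_nhs_like(n: int, rng: np.random.Generator | int = 0,
                 corr: np.ndarray | None = None,
                 effect: Callable[[np.ndarray, np.ndarray], np.ndarray]
                 | None = None,
                 noise_sd: float = 0.45) -> MixtureDataset:
    """Synthetic stand-in for a PM2.5-constituent cognitive cohort.

    Twelve log-normal constituent concentrations (columns named Br..Zn,
    log-transformed in the returned exposure matrix), confounders (age, BMI,
    smoking and education indicators) and a continuous composite-score
    outcome.  The default true effect involves only Br and Ti — detrimental
    where Br is low and Ti is high — so selection procedures should rank
    those two first.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if corr is None:
        corr = default_constituent_corr()
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (12, 12):
        raise ValueError("corr must be 12 x 12")
    L = np.linalg.cholesky(corr)
    logc = rng.standard_normal((n, 12)) @ L.T * 0.5
    logc += np.array([_LOG_MEANS[c] for c in CONSTITUENTS])
    conc = np.exp(logc)               # strictly positive concentrations
    Z = np.log(conc)

    age = rng.normal(74.0, 2.3, size=n)
    bmi = rng.normal(26.0, 4.5, size=n)
    smoker = (rng.random(n) < 0.45).astype(float)
    edu = (rng.random(n) < 0.35).astype(float)
    X = np.column_stack([age, bmi, smoker, edu])

    br = (Z[:, CONSTITUENTS.index("Br")] - _LOG_MEANS["Br"]) / 0.5
    ti = (Z[:, CONSTITUENTS.index("Ti")] - _LOG_MEANS["Ti"]) / 0.5
    if effect is None:
        h = -0.8 * plogis_shifted(-br, 0.0, 0.6) * plogis_shifted(ti, 0.0, 0.6)
    else:
        h = np.asarray(effect(Z[:, CONSTITUENTS.index("Br")],
                              Z[:, CONSTITUENTS.index("Ti")]), dtype=float)
    Y = (h - 0.02 * (age - 74.0) - 0.01 * (bmi - 26.0) - 0.1 * smoker
         + 0.15 * edu + rng.normal(0.0, noise_sd, size=n))
    return MixtureDataset(Y=Y, Z=Z, X=X, exposure_names=list(CONSTITUENTS),
                          confounder_names=["age", "bmi", "smoking",
                                            "education"])
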