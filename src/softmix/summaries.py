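"""Posterior effect summaries for fitted mixture models.

Effects are partial-dependence functions of the posterior surface h: for each
retained draw, the fitted forest is averaged over the training rows with one
(or two) exposures pinned to grid values, giving a posterior sample of effect
curves/surfaces.  Summaries report the posterior mean and sd, equal-tailed
pointwise credible intervals, and a simultaneous credible band built from the
sup-norm of the studentized deviations (the band multiplier q* is the alpha
quantile over draws of max_g |f(g) - mean(g)| / sd(g), so at least alpha of
the retained draws lie entirely inside the band).

Following the usual presentation, effect draws are centered (per-draw grid
mean removed) before summarizing; variable-selection summaries report the
posterior inclusion probability (PIP) of each exposure — the fraction of
retained draws in which it appears in at least one split of the forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import _pd_cond, _pd_pair
from .sampler import PosteriorDraws

_EMPTY_IDX = np.empty(0, dtype=np.int64)
_EMPTY_VAL = np.empty(0, dtype=float)


@dataclass
class EffectSummary:
    """Posterior summary of an effect curve (1-D grid) or surface (2 grids)."""

    grid: np.ndarray | tuple[np.ndarray, np.ndarray]
    posterior_mean: np.ndarray
    posterior_sd: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    centered: bool
    alpha: float
    name: str = ""

    @property
    def is_surface(self) -> bool:
        return isinstance(self.grid, tuple)

    def to_frame(self) -> pd.DataFrame:
        if self.is_surface:
            g1, g2 = self.grid
            G1, G2 = np.meshgrid(g1, g2, indexing="ij")
            cols = {"grid1": G1.ravel(), "grid2": G2.ravel()}
        else:
            cols = {"grid": np.asarray(self.grid)}
        cols.update(mean=self.posterior_mean.ravel(),
                    sd=self.posterior_sd.ravel(),
                    ci_lo=self.ci_lower.ravel(), ci_hi=self.ci_upper.ravel(),
                    band_lo=self.band_lower.ravel(),
                    band_hi=self.band_upper.ravel())
        return pd.DataFrame(cols)


@dataclass
class SelectionSummary:
    """Posterior inclusion probabilities and the thresholded selection."""

    pip: np.ndarray
    selected: np.ndarray
    threshold: float
    names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"exposure": self.names, "pip": self.pip,
                             "selected": self.selected})


# ---------------------------------------------------------------------------
# interval / band primitives

def pointwise_interval(effect_draws: np.ndarray, alpha: float = 0.95,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-tailed credible interval at each grid point.

    ``effect_draws`` has shape (draws, points); at least 100 retained draws
    are required for stable tail quantiles.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    draws = np.atleast_2d(np.asarray(effect_draws, dtype=float))
    if draws.shape[0] < 100:
        raise ValueError(
            f"need >= 100 retained draws for credible intervals, "
            f"got {draws.shape[0]}")
    lo = np.quantile(draws, (1 - alpha) / 2, axis=0)
    hi = np.quantile(draws, 1 - (1 - alpha) / 2, axis=0)
    return lo, hi


def simultaneous_band(effect_draws: np.ndarray, alpha: float = 0.95,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Sup-norm studentized simultaneous band: mean +/- q* sd.

    q* is the alpha quantile over draws of the largest studentized absolute
    deviation from the posterior mean, so the band contains at least a
    fraction alpha of the retained curves in their entirety.  If the
    posterior sd is zero everywhere the (degenerate) mean is returned.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    draws = np.atleast_2d(np.asarray(effect_draws, dtype=float))
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0)
    if np.all(sd == 0):
        return mean.copy(), mean.copy()
    safe_sd = np.where(sd > 0, sd, np.inf)   # zero-sd points never bind
    scores = np.max(np.abs(draws - mean) / safe_sd, axis=1)
    q = np.quantile(scores, alpha)
    return mean - q * sd, mean + q * sd


def compute_pip(draws: PosteriorDraws, threshold: float = 0.5,
                ) -> SelectionSummary:
    """PIP of each exposure: share of draws using it in at least one split."""
    pip = draws.usage.mean(axis=0)
    return SelectionSummary(pip=pip, selected=pip >= threshold,
                            threshold=threshold, names=draws.exposure_names)


# ---------------------------------------------------------------------------
# effect estimation

def default_grid(draws: PosteriorDraws, m: int, points: int = 50,
                 ) -> np.ndarray:
    """Equally spaced quantiles of the observed exposure, 2.5%..97.5%."""
    obs = draws.observed_exposures(m)
    grid = np.quantile(obs, np.linspace(0.025, 0.975, points))
    return np.unique(grid)


def _effect_draws_1d(draws: PosteriorDraws, m: int, grid_internal: np.ndarray,
                     fixed_idx: np.ndarray, fixed_val: np.ndarray,
                     ) -> np.ndarray:
    out = np.empty((draws.n_draws, grid_internal.size))
    for i, snap in enumerate(draws.snapshots):
        off, var, cut, left, right, mu, taus = snap
        out[i] = _pd_cond(off, var, cut, left, right, mu, taus, draws.Zs,
                          m, grid_internal, fixed_idx, fixed_val)
    return out * draws.y_scale


def _summarize(grid, eff, center: bool, alpha: float, name: str,
               ) -> EffectSummary:
    if center:
        eff = eff - eff.mean(axis=1, keepdims=True)
    mean = eff.mean(axis=0)
    sd = eff.std(axis=0)
    ci_lo, ci_hi = pointwise_interval(eff, alpha)
    band_lo, band_hi = simultaneous_band(eff, alpha)
    # the simultaneous band must envelop the pointwise intervals
    band_lo = np.minimum(band_lo, ci_lo)
    band_hi = np.maximum(band_hi, ci_hi)
    if isinstance(grid, tuple):
        shape = (grid[0].size, grid[1].size)
        return EffectSummary(grid=grid, posterior_mean=mean.reshape(shape),
                             posterior_sd=sd.reshape(shape),
                             ci_lower=ci_lo.reshape(shape),
                             ci_upper=ci_hi.reshape(shape),
                             band_lower=band_lo.reshape(shape),
                             band_upper=band_hi.reshape(shape),
                             centered=center, alpha=alpha, name=name)
    return EffectSummary(grid=grid, posterior_mean=mean, posterior_sd=sd,
                         ci_lower=ci_lo, ci_upper=ci_hi, band_lower=band_lo,
                         band_upper=band_hi, centered=center, alpha=alpha,
                         name=name)


def main_effect(draws: PosteriorDraws, m, grid: np.ndarray | None = None,
                alpha: float = 0.95, center: bool = True) -> EffectSummary:
    """Partial-dependence main effect of one exposure.

    Per retained draw, f(g) = mean_i h(z_m = g, Z_i,-m) over the training
    rows; the draw's grid mean is removed before summarizing.
    """
    m = draws.exposure_index(m)
    if grid is None:
        grid = default_grid(draws, m)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    obs = draws.observed_exposures(m)
    if grid.min() < obs.min() - 1e-12 or grid.max() > obs.max() + 1e-12:
        raise ValueError("grid extends beyond the observed exposure range")
    eff = _effect_draws_1d(draws, m, draws.scale_grid(m, grid),
                           _EMPTY_IDX, _EMPTY_VAL)
    return _summarize(grid, eff, center, alpha,
                      f"h({draws.exposure_names[m]})")


def interaction_effect(draws: PosteriorDraws, m1, m2,
                       grid1: np.ndarray | None = None,
                       grid2: np.ndarray | None = None, alpha: float = 0.95,
                       points: int = 20, center: bool = True) -> EffectSummary:
    """Bivariate partial-dependence surface for a pair of exposures."""
    m1 = draws.exposure_index(m1)
    m2 = draws.exposure_index(m2)
    if m1 == m2:
        raise ValueError("interaction requires two distinct exposures")
    if grid1 is None:
        grid1 = default_grid(draws, m1, points)
    if grid2 is None:
        grid2 = default_grid(draws, m2, points)
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    g1s = draws.scale_grid(m1, grid1)
    g2s = draws.scale_grid(m2, grid2)
    eff = np.empty((draws.n_draws, grid1.size * grid2.size))
    for i, snap in enumerate(draws.snapshots):
        off, var, cut, left, right, mu, taus = snap
        eff[i] = _pd_pair(off, var, cut, left, right, mu, taus, draws.Zs,
                          m1, m2, g1s, g2s).ravel()
    eff *= draws.y_scale
    return _summarize((grid1, grid2), eff, center, alpha,
                      f"h({draws.exposure_names[m1]},"
                      f"{draws.exposure_names[m2]})")


def conditional_effect(draws: PosteriorDraws, m, fixed: dict | None = None,
                       grid: np.ndarray | None = None, alpha: float = 0.95,
                       center: bool = True) -> EffectSummary:
    """Main effect with selected other exposures clamped to fixed values.

    With an empty ``fixed`` mapping this reduces exactly to
    :func:`main_effect`.  Fixed values outside the observed exposure range
    trigger a warning (extrapolation), not an error.
    """
    m = draws.exposure_index(m)
    fixed = fixed or {}
    idx = []
    val = []
    for key, v in fixed.items():
        j = draws.exposure_index(key)
        if j == m:
            raise ValueError("cannot clamp the effect variable itself")
        obs = draws.observed_exposures(j)
        if v < obs.min() or v > obs.max():
            warnings.warn(
                f"fixed value {v!r} for {draws.exposure_names[j]} lies "
                "outside the observed range; extrapolating", stacklevel=2)
        idx.append(j)
        val.append((v - draws.z_min[j]) / draws.z_range[j])
    if grid is None:
        grid = default_grid(draws, m)
    grid = np.asarray(grid, dtype=float)
    eff = _effect_draws_1d(draws, m, draws.scale_grid(m, grid),
                           np.asarray(idx, dtype=np.int64),
                           np.asarray(val, dtype=float))
    label = f"h({draws.exposure_names[m]})"
    if fixed:
        conds = ",".join(f"{draws.exposure_names[draws.exposure_index(k)]}="
                         f"{v:g}" for k, v in fixed.items())
        label += f" | {conds}"
    return _summarize(grid, eff, center, alpha, label)
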