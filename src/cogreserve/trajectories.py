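"""Lifespan trajectory simulator for brain properties and composed cognition.

Each individual carries, for each brain property, an intercept (value at the
reference age, the youngest age of the grid) and a slope (change per year);
trajectories are linear in age, with an optional fixed quadratic term.  Two
classic scenarios fall out as special cases:

* **reserve** — ``slope_sd = 0``: everyone declines at the same rate and
  between-person differences are constant across the lifespan;
* **maintenance** — ``intercept_sd = 0``: everyone starts at the same level
  and differences emerge with age through differing rates of decline.

Cognition is composed as a convex combination of the brain properties
(default: the simple average of two properties), and *cognitive reserve* in
the clinical, residual sense is the part of cognition not explained by an
ordinary least-squares regression on a single measured property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrajectoryParams",
    "TrajectorySet",
    "CognitionWeights",
    "simulate_trajectories",
    "compose_cognition",
    "slope_between",
    "reserve_residual",
    "dementia_crossing_ages",
]

DEFAULT_AGE_GRID = tuple(range(18, 89))


def _as_per_property(value, n_properties: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_properties, arr.item())
    if arr.shape != (n_properties,):
        raise ValueError(
            f"{name} must be a scalar or length-{n_properties} sequence, "
            f"got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class TrajectoryParams:
    """Population parameters of the linear trajectory model.

    Units are arbitrary; slopes are per year.  ``slope_correlation`` is the
    correlation matrix of the per-property slopes (default off-diagonal 0.5
    for two properties); ``intercept_slope_correlation`` correlates each
    property's intercept with its own slope.
    """

    n_individuals: int = 1000
    age_grid: tuple = DEFAULT_AGE_GRID
    n_properties: int = 2
    intercept_mean: float | tuple = 100.0
    intercept_sd: float | tuple = 5.0
    slope_mean: float | tuple = -0.5
    slope_sd: float | tuple = 0.15
    slope_correlation: np.ndarray | None = None
    intercept_slope_correlation: float = 0.0
    quadratic_mean: float | tuple = 0.0
    seed: int = 0

    def __post_init__(self):
        ages = np.asarray(self.age_grid, dtype=float)
        if ages.size == 0:
            raise ValueError("age_grid must not be empty")
        if ages.size > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError("age_grid must be strictly increasing")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_properties < 1:
            raise ValueError("n_properties must be >= 1")
        object.__setattr__(self, "age_grid", tuple(ages))
        p = self.n_properties
        object.__setattr__(
            self, "intercept_mean", _as_per_property(self.intercept_mean, p, "intercept_mean")
        )
        object.__setattr__(
            self, "intercept_sd", _as_per_property(self.intercept_sd, p, "intercept_sd")
        )
        object.__setattr__(
            self, "slope_mean", _as_per_property(self.slope_mean, p, "slope_mean")
        )
        object.__setattr__(
            self, "slope_sd", _as_per_property(self.slope_sd, p, "slope_sd")
        )
        object.__setattr__(
            self, "quadratic_mean", _as_per_property(self.quadratic_mean, p, "quadratic_mean")
        )
        if np.any(self.intercept_sd < 0) or np.any(self.slope_sd < 0):
            raise ValueError("standard deviations must be >= 0")
        if self.slope_correlation is None:
            corr = np.full((p, p), 0.5)
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.asarray(self.slope_correlation, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"slope_correlation must be {p}x{p}, got {corr.shape}")
        if not np.allclose(corr, corr.T):
            raise ValueError("slope_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("slope_correlation must have unit diagonal")
        if np.any(np.abs(corr) > 1 + 1e-12):
            raise ValueError("slope_correlation entries must lie in [-1, 1]")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                "slope_correlation is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        if not -1.0 <= self.intercept_slope_correlation <= 1.0:
            raise ValueError("intercept_slope_correlation must lie in [-1, 1]")
        object.__setattr__(self, "slope_correlation", corr)

    @property
    def reference_age(self) -> float:
        """Intercepts are defined at the youngest age of the grid."""
        return float(self.age_grid[0])


@dataclass(frozen=True)
class TrajectorySet:
    """Simulated trajectories: ``values[i, p, a]`` over individuals,
    properties and the age grid, together with the generating intercepts
    and slopes."""

    values: np.ndarray
    intercepts: np.ndarray
    slopes: np.ndarray
    params: TrajectoryParams

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.params.age_grid, dtype=float)


@dataclass(frozen=True)
class CognitionWeights:
    """Nonnegative per-property weights summing to one (default: equal)."""

    weights: tuple = (0.5, 0.5)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", tuple(w))

    @classmethod
    def equal(cls, n_properties: int) -> "CognitionWeights":
        return cls(tuple(np.full(n_properties, 1.0 / n_properties)))


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD correlation matrix.

    Eigen-based so that singular matrices (e.g. off-diagonal exactly 1, the
    degenerate identical-slopes case) are handled; tiny negative eigenvalues
    from round-off are clipped to zero.
    """
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_trajectories(params: TrajectoryParams) -> TrajectorySet:
    """Draw per-individual intercepts and slopes and evaluate trajectories.

    Intercepts and slopes follow a multivariate normal.  Slopes are
    correlated across properties by ``slope_correlation``; intercepts are
    independent across properties; each property's intercept and slope
    correlate at ``intercept_slope_correlation``.  The same seed yields a
    bit-identical :class:`TrajectorySet`.
    """
    p = params.n_properties
    # joint correlation of (intercept_1..p, slope_1..p)
    corr = np.eye(2 * p)
    corr[p:, p:] = params.slope_correlation
    for j in range(p):
        corr[j, p + j] = corr[p + j, j] = params.intercept_slope_correlation
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "joint intercept/slope correlation matrix is not positive "
            f"semi-definite (min eigenvalue {eigvals.min():.3g}); "
            "reduce intercept_slope_correlation or the slope correlations"
        )
    factor = _psd_factor(corr)
    sds = np.concatenate([params.intercept_sd, params.slope_sd])
    means = np.concatenate([params.intercept_mean, params.slope_mean])

    rng = np.random.default_rng(params.seed)
    z = rng.standard_normal((params.n_individuals, 2 * p))
    draws = means + (z @ factor.T) * sds
    intercepts = draws[:, :p]
    slopes = draws[:, p:]

    dt = np.asarray(params.age_grid, dtype=float) - params.reference_age
    values = (
        intercepts[:, :, None]
        + slopes[:, :, None] * dt[None, None, :]
        + np.asarray(params.quadratic_mean)[None, :, None] * dt[None, None, :] ** 2
    )
    return TrajectorySet(values=values, intercepts=intercepts, slopes=slopes, params=params)


def compose_cognition(traj: TrajectorySet, w: CognitionWeights | None = None) -> np.ndarray:
    """Cognition as a weighted average of the brain properties.

    Returns an (individual, age) array; with the default equal weights and
    two properties this is the simple average of the two property values.
    """
    if w is None:
        w = CognitionWeights.equal(traj.params.n_properties)
    weights = np.asarray(w.weights, dtype=float)
    if weights.shape != (traj.params.n_properties,):
        raise ValueError(
            f"expected {traj.params.n_properties} weights, got {weights.size}"
        )
    return np.einsum("ipa,p->ia", traj.values, weights)


def slope_between(series: np.ndarray, age_grid, age_lo: float, age_hi: float) -> np.ndarray:
    """Linear slope of a series between two measurement ages.

    ``series`` may be one trajectory (length of the age grid) or a stack of
    them with age as the last axis.  Both ages must lie on the grid.
    """
    ages = np.asarray(age_grid, dtype=float)
    series = np.asarray(series, dtype=float)
    if not age_lo < age_hi:
        raise ValueError("age_lo must be strictly less than age_hi")
    idx = []
    for a in (age_lo, age_hi):
        match = np.flatnonzero(np.isclose(ages, a))
        if match.size == 0:
            raise ValueError(f"age {a} is not on the age grid")
        idx.append(match[0])
    lo, hi = idx
    return (series[..., hi] - series[..., lo]) / (ages[hi] - ages[lo])


def reserve_residual(cognition: np.ndarray, measured_property: np.ndarray) -> np.ndarray:
    """Residual of cognition after OLS regression on one measured property.

    The residual operationalises clinical cognitive reserve: the part of
    cognition that the measured (e.g. grey-matter) property cannot explain.
    Residuals have mean zero by construction.
    """
    y = np.asarray(cognition, dtype=float).ravel()
    x = np.asarray(measured_property, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: cognition {y.size}, property {x.size}")
    if y.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(x) == 0:
        raise ValueError("measured_property is constant; regression is undefined")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def dementia_crossing_ages(
    traj: TrajectorySet, cutoff: float | None = None, property_index: int = 0
) -> np.ndarray:
    """First grid age at which each individual's property falls below a
    cut-off (NaN if never).

    Default cut-off: one population SD below the population mean at the
    youngest age — an arbitrary, reporting-only threshold in the spirit of a
    screening-test criterion.
    """
    vals = traj.values[:, property_index, :]
    if cutoff is None:
        cutoff = float(vals[:, 0].mean() - vals[:, 0].std())
    below = vals < cutoff
    ages = traj.ages
    out = np.full(vals.shape[0], np.nan)
    hit = below.any(axis=1)
    out[hit] = ages[below[hit].argmax(axis=1)]
    return out
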