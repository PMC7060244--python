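"""Ice-aware saturated B-spline smoothing of LSWT series.

Each lake's fortnightly series is smoothed with a cubic B-spline basis that
places an interior knot at every observation time ("saturated").  Ice cover
creates discontinuities in the temperature record, so observations under
ice are set to 0 degC and the basis functions centred on ice-flagged knots
are removed from the fit by fixing their coefficients to exactly zero.
Because the knot set depends only on the observation grid, every lake on
the same grid shares an identical basis — coefficient vectors are then
directly comparable across lakes, which the clustering stage requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.sparse import csr_matrix

from .synthetic import OBS_PER_YEAR, LakeSeries

DEFAULT_ORDER = 4        # cubic
DEFAULT_LAMBDA = 1e-4    # second-difference penalty on free coefficients
DEFAULT_GRID = 96        # seasonal-profile points per year


@dataclass(frozen=True)
class SplineBasis:
    """Saturated B-spline basis shared by all series on one observation grid."""

    order: int
    knots: np.ndarray     # full knot vector incl. boundary multiplicities
    n_basis: int

    @classmethod
    def for_times(cls, times: np.ndarray, order: int = DEFAULT_ORDER) -> "SplineBasis":
        times = np.asarray(times, dtype=float)
        if times.size < OBS_PER_YEAR:
            raise ValueError("need at least one year (24 observations) of data")
        if np.any(np.diff(times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        knots = np.concatenate([
            np.full(order, times[0]), times[1:-1], np.full(order, times[-1]),
        ])
        return cls(order=order, knots=knots, n_basis=times.size - 2 + order)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, SplineBasis) and self.order == other.order
                and self.n_basis == other.n_basis
                and np.array_equal(self.knots, other.knots))

    def greville(self) -> np.ndarray:
        """Greville abscissae: the time each basis function is centred on."""
        k = self.order - 1
        return np.array([self.knots[j + 1: j + 1 + k].mean()
                         for j in range(self.n_basis)])

    def design_matrix(self, t: np.ndarray) -> csr_matrix:
        t = np.clip(np.asarray(t, dtype=float), self.knots[0], self.knots[-1])
        return BSpline.design_matrix(t, self.knots, self.order - 1)


@dataclass
class SmoothFit:
    """Fitted coefficients for one lake, with the ice-knot mask.

    Coefficients are exactly 0 where ``ice_mask`` is true; those basis
    functions were dropped from the least-squares problem.
    """

    basis: SplineBasis
    coefficients: np.ndarray
    ice_mask: np.ndarray
    rss: float
    n_years: int

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), self.basis.knots[0], self.basis.knots[-1])
        spl = BSpline(self.basis.knots, self.coefficients, self.basis.order - 1)
        return np.maximum(spl(t), 0.0) if self.ice_mask.any() else spl(t)


@dataclass(frozen=True)
class SeasonalCurve:
    """Average seasonal temperature profile on a within-year grid.

    ``grid`` holds day-of-year fractions in [0, 1), strictly increasing.
    """

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0) or self.grid[0] < 0 or self.grid[-1] >= 1:
            raise ValueError("grid must be strictly increasing in [0, 1)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite profile values")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def range(self) -> float:
        return float(np.max(self.values) - np.min(self.values))

    @property
    def peak_fraction(self) -> float:
        """Day-of-year fraction at which the profile peaks."""
        return float(self.grid[int(np.argmax(self.values))])


def apply_ice_rule(series: LakeSeries) -> LakeSeries:
    """Set ice-covered observations to 0 degC.

    Observations already flagged as ice keep the flag and get value 0;
    sub-freezing unflagged observations are treated as ice detections
    (flag set, value 0).  Everything else is unchanged.
    """
    ice = series.ice_flags | (series.values < 0.0)
    values = np.where(ice, 0.0, series.values)
    return LakeSeries(series.lake_id, values, ice, series.n_years)


def _ice_coefficient_mask(basis: SplineBasis, times: np.ndarray,
                          ice_flags: np.ndarray) -> np.ndarray:
    """Mask basis functions centred on ice-flagged observation times.

    Each basis function is mapped to the observation time nearest its
    Greville abscissa (boundary functions collapse onto the first/last
    observation); it is masked if that observation is under ice.
    """
    centres = basis.greville()
    nearest = np.clip(np.searchsorted(times, centres), 0, times.size - 1)
    left = np.clip(nearest - 1, 0, times.size - 1)
    use_left = np.abs(times[left] - centres) <= np.abs(times[nearest] - centres)
    obs_idx = np.where(use_left, left, nearest)
    return ice_flags[obs_idx]


def fit_saturated_bspline(
    series: LakeSeries,
    basis: SplineBasis | None = None,
    lam: float = DEFAULT_LAMBDA,
    order: int = DEFAULT_ORDER,
    _design: np.ndarray | None = None,
) -> SmoothFit:
    """Fit the ice-aware saturated B-spline to one lake's series.

    The saturated basis has two more functions than observations, so a
    small second-difference penalty ``lam`` on the free coefficients
    stabilizes the near-interpolating fit.  Ice-masked coefficients are
    fixed at exactly 0.  An all-ice series returns the all-zero fit.
    """
    series = apply_ice_rule(series)
    t = series.decimal_years
    if basis is None:
        basis = SplineBasis.for_times(t, order=order)
    mask = _ice_coefficient_mask(basis, t, series.ice_flags)

    coef = np.zeros(basis.n_basis)
    free = ~mask
    if free.any() and not series.ice_flags.all():
        full = _design if _design is not None else basis.design_matrix(t).toarray()
        b = full[:, free]
        nf = free.sum()
        if nf >= 3:
            d = np.diff(np.eye(nf), n=2, axis=0)
        else:
            d = np.zeros((0, nf))
        ata = b.T @ b + lam * d.T @ d
        coef[free] = solve(ata, b.T @ series.values, assume_a="pos")
    fit = SmoothFit(basis, coef, mask, rss=0.0, n_years=series.n_years)
    resid = series.values - fit(t)
    fit.rss = float(resid @ resid)
    return fit


def fit_population(series_list: list[LakeSeries], lam: float = DEFAULT_LAMBDA,
                   order: int = DEFAULT_ORDER) -> list[SmoothFit]:
    """Fit every series on a common shared basis (grid lengths must match)."""
    if not series_list:
        return []
    n = series_list[0].values.size
    if any(s.values.size != n for s in series_list):
        raise ValueError("all series must share one observation grid")
    basis = SplineBasis.for_times(series_list[0].decimal_years, order=order)
    design = basis.design_matrix(series_list[0].decimal_years).toarray()
    return [fit_saturated_bspline(s, basis=basis, lam=lam, _design=design)
            for s in series_list]


def coefficient_matrix(fits: list[SmoothFit]) -> np.ndarray:
    """Stack coefficient vectors (lakes x n_basis) for clustering."""
    if not fits:
        raise ValueError("no fits given")
    b0 = fits[0].basis
    if any(f.basis != b0 for f in fits[1:]):
        raise ValueError("fits do not share a common basis")
    return np.vstack([f.coefficients for f in fits])


def seasonal_profile(fit: SmoothFit, grid_points_per_year: int = DEFAULT_GRID) -> SeasonalCurve:
    """Average the fitted curve across years on a common within-year grid.

    Evaluates the smooth curve at ``(g + 0.5)/grid_points_per_year`` within
    each observed year and takes the pointwise mean over years (365-day
    synthetic calendar, no leap days).
    """
    if grid_points_per_year < OBS_PER_YEAR:
        raise ValueError(f"grid_points_per_year must be >= {OBS_PER_YEAR}")
    grid = (np.arange(grid_points_per_year) + 0.5) / grid_points_per_year
    years = np.arange(fit.n_years)
    vals = fit((years[:, None] + grid[None, :]).ravel())
    return SeasonalCurve(grid, vals.reshape(fit.n_years, -1).mean(axis=0))
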