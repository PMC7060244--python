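"""Synthetic lake surface water temperature (LSWT) populations.

Generates fortnightly LSWT series with the statistical structure the
thermal-region analysis assumes: nine seasonal archetypes (Northern Frigid
through Tropical Hot) calibrated to reference region-level statistics
(annual mean, annual range, fraction of the year ice-covered), per-lake
random effects, observation noise, and 0 °C clamping under ice.

Also provides a deliberately simple relaxation-type lake temperature
emulator (`simulate_lswt`) that turns location and depth into a seasonal
LSWT cycle.  It is a documented heuristic stand-in for a physical lake
model, not a physics code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

OBS_PER_YEAR = 24  # twice-monthly sampling

#: Region-level reference statistics for the nine global lake thermal
#: regions: percent of lakes, annual mean LSWT (degC), annual range (degC),
#: percent of time ice-covered, percent of lakes with any ice cover.
REGION_TABLE: dict[str, tuple[float, float, float, float, float]] = {
    "NF": (37.8, 3.3, 14.4, 61.0, 100.0),   # Northern Frigid
    "NC": (40.4, 6.1, 20.7, 50.0, 99.6),    # Northern Cool
    "NT": (11.2, 9.8, 23.6, 29.0, 91.9),    # Northern Temperate
    "NW": (1.7, 16.3, 21.8, 1.0, 9.0),      # Northern Warm
    "NH": (1.8, 22.1, 17.4, 0.0, 0.0),      # Northern Hot
    "TH": (3.2, 29.0, 3.9, 0.0, 0.0),       # Tropical Hot
    "SH": (1.8, 24.2, 6.1, 0.0, 0.0),       # Southern Hot
    "SW": (1.7, 15.7, 11.4, 0.0, 0.0),      # Southern Warm
    "ST": (0.5, 7.9, 8.7, 5.0, 21.1),       # Southern Temperate
}

REGION_CODES = tuple(REGION_TABLE)

REGION_NAMES: dict[str, str] = {
    "NF": "Northern Frigid", "NC": "Northern Cool", "NT": "Northern Temperate",
    "NW": "Northern Warm", "NH": "Northern Hot", "TH": "Tropical Hot",
    "SH": "Southern Hot", "SW": "Southern Warm", "ST": "Southern Temperate",
}

#: Day-of-year of the latent seasonal maximum.  Northern-hemisphere regions
#: peak in late July; southern regions in late January.  Tropical Hot is
#: assigned the hemisphere phase of its nominal (northern-tropical) latitude.
PEAK_DOY: dict[str, int] = {
    "NF": 205, "NC": 205, "NT": 205, "NW": 205, "NH": 205, "TH": 205,
    "SH": 25, "SW": 25, "ST": 25,
}

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class SeasonalArchetype:
    """Latent clamped-sinusoid seasonal temperature curve for one region.

    The latent curve is ``m + A cos(2 pi (t - p))`` with ``t`` in decimal
    years and ``p = peak_doy / 365``; the realized curve is its clamp at
    0 degC (ice).  ``realized_mean`` / ``realized_range`` are the annual
    mean and max-min of the realized curve, which the calibration matches
    to the reference table.
    """

    region_code: str
    latent_mean: float
    latent_amplitude: float
    peak_doy: int
    realized_mean: float
    realized_range: float
    ice_fraction: float

    def __post_init__(self) -> None:
        if self.latent_amplitude < 0:
            raise ValueError("latent_amplitude must be >= 0")
        if not 1 <= self.peak_doy <= 365:
            raise ValueError("peak_doy must be in [1, 365]")

    def latent(self, t: np.ndarray | float) -> np.ndarray:
        """Latent (unclamped) curve at decimal-year times ``t``."""
        phase = 2.0 * np.pi * (np.asarray(t, dtype=float) - self.peak_doy / DAYS_PER_YEAR)
        return self.latent_mean + self.latent_amplitude * np.cos(phase)

    def realized(self, t: np.ndarray | float) -> np.ndarray:
        """Realized curve: latent clamped at 0 degC."""
        return np.maximum(self.latent(t), 0.0)


@dataclass(frozen=True)
class LakeMeta:
    """Static lake metadata used by the emulator."""

    lake_id: str
    latitude: float
    longitude: float
    elevation: float = 0.0
    area_km2: float = 1.0
    mean_depth_m: float = 10.0

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        if not -180 <= self.longitude < 180:
            raise ValueError(f"longitude {self.longitude} out of [-180, 180)")
        if self.area_km2 <= 0:
            raise ValueError("area_km2 must be > 0")
        if self.mean_depth_m <= 0:
            raise ValueError("mean_depth_m must be > 0")


@dataclass
class LakeSeries:
    """One lake's fortnightly LSWT observations with ice flags.

    Sampling is uniform at 24 observations per year; observation ``i``
    maps to decimal year ``(i + 0.5) / 24``.  Values are 0 degC exactly
    where the ice flag is set, and never negative.
    """

    lake_id: str
    values: np.ndarray
    ice_flags: np.ndarray
    n_years: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ice_flags = np.asarray(self.ice_flags, dtype=bool)
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        n = OBS_PER_YEAR * self.n_years
        if self.values.shape != (n,) or self.ice_flags.shape != (n,):
            raise ValueError(
                f"series length must be 24 * n_years = {n}, "
                f"got {self.values.shape[0]} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite temperatures in lake {self.lake_id}")

    @property
    def times(self) -> np.ndarray:
        """Fortnight indices 0 .. 24*n_years - 1."""
        return np.arange(self.values.size)

    @property
    def decimal_years(self) -> np.ndarray:
        return (self.times + 0.5) / OBS_PER_YEAR


# ---------------------------------------------------------------------------
# Archetype calibration

def _clamped_mean(m: float, a: float) -> float:
    """Annual mean of max(m + a*cos(2 pi t), 0) in closed form."""
    if a <= 0:
        return max(m, 0.0)
    c = m / a
    if c >= 1:
        return m
    if c <= -1:
        return 0.0
    beta = np.arccos(-c)  # half-width (radians) of the above-zero arc
    return (m * beta + a * np.sin(beta)) / np.pi


def clamped_ice_fraction(m: float, a: float) -> float:
    """Fraction of the year the latent sinusoid m + a*cos is below 0 degC."""
    if a <= 0:
        return 0.0 if m > 0 else 1.0
    c = m / a
    if c >= 1:
        return 0.0
    if c <= -1:
        return 1.0
    return float(np.arccos(c) / np.pi)


def make_archetype(region_code: str) -> SeasonalArchetype:
    """Build the calibrated seasonal archetype for a region code.

    For regions whose latent sinusoid stays above 0 degC, the latent mean
    and amplitude are simply the table mean and half-range.  For freezing
    regions the clamp distorts both statistics, so the latent parameters
    are solved so that the realized (clamped) curve reproduces the table's
    mean and range: the range pins ``latent_mean + amplitude`` and the
    mean is matched by a 1-D root solve.
    """
    if region_code not in REGION_TABLE:
        raise ValueError(
            f"unknown region code {region_code!r}; valid codes: "
            + ", ".join(REGION_CODES)
        )
    _, mean_c, range_c, _, _ = REGION_TABLE[region_code]
    peak = PEAK_DOY[region_code]

    m0, a0 = mean_c, range_c / 2.0
    if m0 - a0 > 0:  # never freezes: clamp inactive
        return SeasonalArchetype(region_code, m0, a0, peak, mean_c, range_c,
                                 ice_fraction=0.0)

    # Freezing: realized range = (m + A) - 0, so A = range - m; match mean.
    def resid(m: float) -> float:
        return _clamped_mean(m, range_c - m) - mean_c

    lo, hi = -10.0 * range_c, range_c / 2.0 - 1e-9
    m = brentq(resid, lo, hi, xtol=1e-6)
    a = range_c - m
    return SeasonalArchetype(
        region_code, m, a, peak,
        realized_mean=_clamped_mean(m, a),
        realized_range=m + a,
        ice_fraction=clamped_ice_fraction(m, a),
    )


def default_region_counts(n_lakes: int = 732, min_per_region: int = 20) -> dict[str, int]:
    """Apportion lakes to regions proportionally to the reference percentages.

    Largest-remainder apportionment, then any region below ``min_per_region``
    is raised to the minimum with the excess removed one lake at a time from
    the currently largest region.  Deterministic.
    """
    pct = {c: REGION_TABLE[c][0] for c in REGION_CODES}
    total_pct = sum(pct.values())
    raw = {c: n_lakes * p / total_pct for c, p in pct.items()}
    counts = {c: int(np.floor(r)) for c, r in raw.items()}
    short = n_lakes - sum(counts.values())
    for c in sorted(REGION_CODES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    for c in REGION_CODES:
        while counts[c] < min_per_region:
            counts[c] += 1
            donor = max(REGION_CODES, key=lambda d: counts[d])
            counts[donor] -= 1
    return counts


def generate_population(
    counts_per_region: dict[str, int] | None = None,
    sd_mean: float = 0.8,
    sd_range: float = 1.5,
    obs_noise: float = 0.5,
    n_years: int = 16,
    seed: int = 42,
) -> tuple[list[LakeSeries], list[str]]:
    """Generate a synthetic lake population with known region membership.

    Each lake draws a Gaussian offset on its latent mean (sd ``sd_mean``
    degC) and latent range (sd ``sd_range`` degC), then iid observation
    noise (sd ``obs_noise`` degC) on non-ice samples.  Sub-zero samples are
    clamped to 0 degC with the ice flag set.  Draws are taken in lake order
    from a single seeded generator, so output is reproducible bit-for-bit.

    Returns the series list and the true region code per lake.
    """
    if counts_per_region is None:
        counts_per_region = default_region_counts()
    for code in counts_per_region:
        if code not in REGION_TABLE:
            raise ValueError(f"unknown region code {code!r}")
    if any(n < 0 for n in counts_per_region.values()):
        raise ValueError("counts must be non-negative")
    if sum(counts_per_region.values()) == 0:
        raise ValueError("at least one region must have a positive count")
    if min(sd_mean, sd_range, obs_noise) < 0:
        raise ValueError("noise standard deviations must be non-negative")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")

    rng = np.random.default_rng(seed)
    t = (np.arange(OBS_PER_YEAR * n_years) + 0.5) / OBS_PER_YEAR
    series: list[LakeSeries] = []
    labels: list[str] = []
    i = 0
    for code in REGION_CODES:
        n = counts_per_region.get(code, 0)
        arch = make_archetype(code)
        for _ in range(n):
            dm = rng.normal(0.0, sd_mean) if sd_mean > 0 else 0.0
            dr = rng.normal(0.0, sd_range) if sd_range > 0 else 0.0
            m = arch.latent_mean + dm
            a = max(arch.latent_amplitude + dr / 2.0, 0.0)
            phase = 2.0 * np.pi * (t - arch.peak_doy / DAYS_PER_YEAR)
            latent = m + a * np.cos(phase)
            ice = latent <= 0.0
            vals = np.where(ice, 0.0, latent)
            if obs_noise > 0:
                noise = rng.normal(0.0, obs_noise, size=t.size)
                vals = np.where(ice, 0.0, vals + noise)
            frozen = ice | (vals <= 0.0)
            vals = np.where(frozen, 0.0, vals)
            series.append(LakeSeries(f"lake{i:04d}", vals, frozen, n_years))
            labels.append(code)
            i += 1
    return series, labels


# ---------------------------------------------------------------------------
# Relaxation emulator

@dataclass(frozen=True)
class EmulatorParams:
    """Parameters of the relaxation LSWT emulator.

    The surface temperature relaxes towards a location-dependent equilibrium
    curve E(t) with an e-folding time tau = tau0 * (1 + depth/depth_scale)
    (deeper lakes respond more slowly).  E(t) is a closed-form sinusoid:
    annual mean ``27 - 0.55*|lat| - 6.5*(elev/1000)`` degC and amplitude
    ``0.03*lat^2`` capped at ``amp_cap`` degC, peaking at the hemisphere's
    summer.  An explicit heuristic, not a physical lake model.
    """

    tau0: float = 5.0            # days; response time at zero depth
    depth_scale: float = 10.0    # m
    mean_intercept: float = 27.0  # degC at equator, sea level
    lat_lapse: float = 0.55      # degC per degree |latitude|
    elev_lapse: float = 6.5      # degC per km elevation
    amp_per_lat2: float = 0.03   # degC per degree^2 latitude
    amp_cap: float = 20.0        # degC
    mean_warming: float = 0.0    # degC added to E mean (climate scenarios)
    timestep: float = 1.0        # days

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.depth_scale <= 0 or self.timestep <= 0:
            raise ValueError("tau0, depth_scale and timestep must be > 0")

    def equilibrium(self, meta: LakeMeta, t_days: np.ndarray) -> np.ndarray:
        """Equilibrium temperature curve E(t) at the lake's location."""
        e_mean = (self.mean_intercept - self.lat_lapse * abs(meta.latitude)
                  - self.elev_lapse * meta.elevation / 1000.0 + self.mean_warming)
        e_amp = min(self.amp_per_lat2 * meta.latitude ** 2, self.amp_cap)
        peak = PEAK_DOY["NF"] if meta.latitude >= 0 else PEAK_DOY["SH"]
        return e_mean + e_amp * np.cos(2 * np.pi * (t_days - peak) / DAYS_PER_YEAR)


def simulate_lswt(
    meta: LakeMeta,
    params: EmulatorParams | None = None,
    n_years: int = 16,
    seed: int | None = None,
    obs_noise: float = 0.0,
    forcing: np.ndarray | None = None,
) -> LakeSeries:
    """Simulate a fortnightly LSWT series for one lake with the emulator.

    Daily explicit Euler relaxation towards the equilibrium curve, then
    fortnightly subsampling (days 1 and 15 of twelve 30.4-day synthetic
    months).  The latent state is unclamped; output is clamped at 0 degC
    with the ice flag set.  ``forcing`` overrides the built-in equilibrium
    curve (daily values, one per step).
    """
    params = params or EmulatorParams()
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    n_steps = int(np.ceil(n_years * DAYS_PER_YEAR / params.timestep))
    t_days = np.arange(n_steps) * params.timestep
    e = np.asarray(forcing, dtype=float) if forcing is not None \
        else params.equilibrium(meta, t_days)
    if e.shape != (n_steps,):
        raise ValueError(f"forcing must have {n_steps} daily values")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite forcing")

    tau = params.tau0 * (1.0 + meta.mean_depth_m / params.depth_scale)
    a = params.timestep / tau
    temp = np.empty(n_steps)
    temp[0] = e[0]
    for i in range(n_steps - 1):
        temp[i + 1] = temp[i] + a * (e[i] - temp[i])

    # fortnightly sample days: day 1 and 15 of each 30.4-day month
    idx = []
    for year in range(n_years):
        for month in range(12):
            d0 = int(np.floor((year * DAYS_PER_YEAR + month * 30.4) / params.timestep))
            idx.extend([d0, min(d0 + int(round(14 / params.timestep)), n_steps - 1)])
    sampled = temp[np.array(idx)]
    if obs_noise > 0:
        rng = np.random.default_rng(seed)
        sampled = sampled + rng.normal(0.0, obs_noise, size=sampled.size)
    ice = sampled <= 0.0
    vals = np.where(ice, 0.0, sampled)
    return LakeSeries(meta.lake_id, vals, ice, n_years)
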