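"""Synthetic EHR-like daily visit counts, covariates, and geographies.

Everything downstream of this module (exposure classification, the
counterfactual learner, excess-visit estimation) is exercised against data
produced here, so the generator records exact ground truth alongside every
stochastic draw: the deterministic mean of each cell-day and the
multiplicative lift applied to it, from which expected excess counts are
recomputable in closed form.

The generative model for a daily count in one stratum × modality × cause
cell is

    count ~ NegBin(mu, k),
    mu = baseline * weekday[dow] * exp(a * cos(2*pi*(doy - peak)/365.25))
         * exp(sum_j c_j * (x_jd - center_j)) * lift(d),

with ``k`` the negative-binomial dispersion (variance mu + mu^2/k; the
k -> inf limit is Poisson) and ``lift(d)`` a per-cell multiplicative effect
profile that is identically 1 before the event date.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

__all__ = [
    "MODALITIES",
    "CAUSES",
    "MET_COVARIATES",
    "WASTEWATER_COVARIATES",
    "SimulationConfig",
    "GroundTruth",
    "ArealUnit",
    "FirePerimeter",
    "ConfigurationError",
    "GenerationError",
    "generate_calendar",
    "generate_covariates",
    "generate_visits",
    "generate_geography",
    "expected_window_excess",
]

MODALITIES: tuple[str, ...] = ("outpatient", "virtual")
CAUSES: tuple[str, ...] = (
    "all_cause",
    "cardiovascular",
    "injury",
    "neuropsychiatric",
    "respiratory",
)

MET_COVARIATES: tuple[str, ...] = ("tmax", "tmin", "rhmax", "rhmin", "wind", "srad")
WASTEWATER_COVARIATES: tuple[str, ...] = ("ww_flu", "ww_rsv", "ww_sarscov2")


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


class GenerationError(RuntimeError):
    """Raised when a requested simulation would be degenerate (mu <= 0 or overflow)."""


@dataclass(frozen=True)
class MetSpec:
    """Annual-harmonic + AR(1) noise model for one daily meteorological series."""

    mean: float
    amplitude: float
    peak_doy: float
    noise_sd: float


@dataclass(frozen=True)
class WastewaterSpec:
    """Weekly log-normal viral-level model: level = exp(harmonic + noise), constant per ISO week."""

    log_amplitude: float
    peak_doy: float
    log_noise_sd: float


# Winters are cool, humid, low-radiation, with occasional strong offshore wind;
# respiratory viral levels peak in early January. Magnitudes are plausible for
# coastal Southern California but are synthetic defaults, not observed data.
DEFAULT_MET_SPECS: Mapping[str, MetSpec] = {
    "tmax": MetSpec(mean=22.0, amplitude=5.0, peak_doy=215.0, noise_sd=2.0),
    "tmin": MetSpec(mean=11.0, amplitude=4.0, peak_doy=215.0, noise_sd=1.5),
    "rhmax": MetSpec(mean=80.0, amplitude=8.0, peak_doy=30.0, noise_sd=5.0),
    "rhmin": MetSpec(mean=35.0, amplitude=10.0, peak_doy=215.0, noise_sd=5.0),
    "wind": MetSpec(mean=3.5, amplitude=1.0, peak_doy=350.0, noise_sd=0.8),
    "srad": MetSpec(mean=200.0, amplitude=80.0, peak_doy=172.0, noise_sd=15.0),
}

DEFAULT_WW_SPECS: Mapping[str, WastewaterSpec] = {
    "ww_flu": WastewaterSpec(log_amplitude=1.0, peak_doy=5.0, log_noise_sd=0.2),
    "ww_rsv": WastewaterSpec(log_amplitude=0.8, peak_doy=355.0, log_noise_sd=0.2),
    "ww_sarscov2": WastewaterSpec(log_amplitude=0.5, peak_doy=10.0, log_noise_sd=0.2),
}

# Mon..Sun; weekday-heavy outpatient pattern. Sums to exactly 7.
DEFAULT_WEEKDAY_MULTIPLIERS: tuple[float, ...] = (1.15, 1.10, 1.05, 1.05, 1.00, 0.85, 0.80)

DEFAULT_WINDOWS: tuple[tuple[date, date], ...] = (
    (date(2022, 11, 1), date(2023, 1, 31)),
    (date(2023, 11, 1), date(2024, 1, 31)),
    (date(2024, 11, 1), date(2025, 1, 31)),
)

# Small log-linear dependencies: visits rise when it is cold, windy, and
# viral levels are high. Coefficients are per unit of the (centred) covariate.
DEFAULT_COVARIATE_COEFFICIENTS: Mapping[str, float] = {
    "tmax": -0.01,
    "wind": 0.02,
    "ww_flu": 0.10,
    "ww_rsv": 0.06,
    "ww_sarscov2": 0.06,
}


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study.

    Defaults emulate three November-January seasonal windows ending
    January 2025 with an event (ignition) on 2025-01-07, weekday-structured
    counts with a winter seasonal peak, covariate dependence, and
    negative-binomial overdispersion.
    """

    seasonal_windows: tuple[tuple[date, date], ...] = DEFAULT_WINDOWS
    event_date: date = date(2025, 1, 7)
    strata: tuple[str, ...] = ("high", "moderate", "minimal")
    modalities: tuple[str, ...] = MODALITIES
    causes: tuple[str, ...] = CAUSES
    #: visits/day per cell; a float applies to every cell, a mapping may be
    #: keyed by cause or by (stratum, modality, cause).
    baseline_rate: float | Mapping = field(
        default_factory=lambda: {
            "all_cause": 400.0,
            "cardiovascular": 60.0,
            "injury": 50.0,
            "neuropsychiatric": 55.0,
            "respiratory": 90.0,
        }
    )
    weekday_multipliers: tuple[float, ...] = DEFAULT_WEEKDAY_MULTIPLIERS
    annual_amplitude: float = 0.2
    annual_peak_doy: float = 10.0
    #: per-stratum override of annual_amplitude (used e.g. for confounded
    #: difference-in-differences demonstrations).
    annual_amplitude_by_stratum: Mapping[str, float] = field(default_factory=dict)
    covariate_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_COEFFICIENTS)
    )
    #: multiplicative lift by day offset from event_date, keyed by
    #: (stratum, modality, cause); cells absent from the mapping have lift 1.
    effect_profile: Mapping[tuple[str, str, str], Sequence[float]] = field(default_factory=dict)
    #: negative-binomial dispersion k (variance mu + mu^2/k); np.inf -> Poisson.
    dispersion: float = 10.0
    met_specs: Mapping[str, MetSpec] = field(default_factory=lambda: dict(DEFAULT_MET_SPECS))
    ww_specs: Mapping[str, WastewaterSpec] = field(default_factory=lambda: dict(DEFAULT_WW_SPECS))
    ar1_phi: float = 0.7
    #: scales every covariate noise SD; 0 gives the deterministic harmonics.
    covariate_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weekday_multipliers) != 7:
            raise ConfigurationError("weekday_multipliers must have 7 entries (Mon..Sun)")
        if any(m <= 0 for m in self.weekday_multipliers):
            raise ConfigurationError("weekday_multipliers must be positive")
        if abs(float(np.mean(self.weekday_multipliers)) - 1.0) > 1e-9:
            raise ConfigurationError("weekday_multipliers must average to 1 within 1e-9")
        if not self.dispersion > 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.covariate_noise_scale < 0:
            raise ConfigurationError("covariate_noise_scale must be >= 0")
        for cell, profile in self.effect_profile.items():
            if any(v < 0 for v in profile):
                raise ConfigurationError(f"effect profile for {cell} has a negative lift")
        for cell in (self.strata, self.modalities, self.causes):
            if len(set(cell)) != len(cell):
                raise ConfigurationError("strata/modalities/causes must be unique labels")
        # baseline rates positive wherever specified
        if isinstance(self.baseline_rate, Mapping):
            if any(v <= 0 for v in self.baseline_rate.values()):
                raise ConfigurationError("baseline rates must be > 0")
        elif not self.baseline_rate > 0:
            raise ConfigurationError("baseline rate must be > 0")

    # -- helpers -----------------------------------------------------------

    def cells(self) -> list[tuple[str, str, str]]:
        return [
            (s, m, c) for s in self.strata for m in self.modalities for c in self.causes
        ]

    def rate_for(self, stratum: str, modality: str, cause: str) -> float:
        if isinstance(self.baseline_rate, Mapping):
            key = (stratum, modality, cause)
            if key in self.baseline_rate:
                return float(self.baseline_rate[key])
            if cause in self.baseline_rate:
                return float(self.baseline_rate[cause])
            raise ConfigurationError(f"no baseline rate for cell {key}")
        return float(self.baseline_rate)

    def amplitude_for(self, stratum: str) -> float:
        return float(self.annual_amplitude_by_stratum.get(stratum, self.annual_amplitude))

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class GroundTruth:
    """Exact generator-side truth recorded next to each simulated dataset.

    ``daily`` holds, per cell-date, the counterfactual mean ``mu0`` (the mean
    with lift forced to 1) and the applied lift. ``window_excess`` and
    ``window_pct`` are the expected excess counts and percent change over
    post-event windows of the given day lengths, recomputable as
    sum(mu0 * (lift - 1)) and 100 * sum(mu0*(lift-1)) / sum(mu0).
    """

    daily: pd.DataFrame
    window_excess: dict[tuple[str, str, str, int], float]
    window_pct: dict[tuple[str, str, str, int], float]


# ---------------------------------------------------------------------------
# calendar
# ---------------------------------------------------------------------------


def generate_calendar(config: SimulationConfig) -> pd.DatetimeIndex:
    """Union of all seasonal-window dates, ascending.

    Windows must be chronologically ordered and non-overlapping, and the
    event date must fall inside the final window.
    """
    windows = list(config.seasonal_windows)
    if not windows:
        raise ConfigurationError("at least one seasonal window is required")
    for start, end in windows:
        if start > end:
            raise ConfigurationError(f"window {start}..{end} has start > end")
    for (s0, e0), (s1, _e1) in zip(windows, windows[1:]):
        if s1 <= e0:
            raise ConfigurationError(
                f"seasonal windows overlap or are out of order: {s0}..{e0} then {s1}.."
            )
    final_start, final_end = windows[-1]
    if not (final_start <= config.event_date <= final_end):
        raise ConfigurationError(
            f"event_date {config.event_date} is outside the final window {final_start}..{final_end}"
        )
    parts = [pd.date_range(start, end, freq="D") for start, end in windows]
    return pd.DatetimeIndex(np.concatenate([p.values for p in parts]))


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def _annual_harmonic(doy: np.ndarray, amplitude: float, peak_doy: float) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi * phi, 1e-12))
    eps = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def generate_covariates(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Daily meteorology plus weekly wastewater levels on the study calendar.

    Meteorological series are a smooth annual harmonic plus AR(1) noise.
    Wastewater levels are positive, follow their own winter-peaked seasonal
    trajectory, and are constant within each ISO week. The same seed gives
    bit-identical output.
    """
    if seed is None:
        seed = config.seed
    calendar = generate_calendar(config)
    rng = np.random.default_rng(seed)
    doy = calendar.dayofyear.to_numpy(dtype=float)
    n = len(calendar)

    data: dict[str, np.ndarray] = {}
    for name in MET_COVARIATES:
        spec = config.met_specs[name]
        base = spec.mean + _annual_harmonic(doy, spec.amplitude, spec.peak_doy)
        noise = _ar1(rng, n, config.ar1_phi, spec.noise_sd * config.covariate_noise_scale)
        data[name] = base + noise

    iso = calendar.isocalendar()
    week_key = (iso["year"].astype(int) * 100 + iso["week"].astype(int)).to_numpy()
    uniq_weeks, inverse = np.unique(week_key, return_inverse=True)
    # day-of-year of each ISO week's first calendar day, for the weekly harmonic
    first_idx = np.array([int(np.argmax(inverse == k)) for k in range(len(uniq_weeks))])
    week_doy = doy[first_idx]
    for name in WASTEWATER_COVARIATES:
        spec = config.ww_specs[name]
        log_level = _annual_harmonic(week_doy, spec.log_amplitude, spec.peak_doy)
        log_level = log_level + rng.normal(
            0.0, spec.log_noise_sd * config.covariate_noise_scale, size=len(uniq_weeks)
        )
        data[name] = np.exp(log_level)[inverse]

    return pd.DataFrame(data, index=calendar)


# ---------------------------------------------------------------------------
# visit counts
# ---------------------------------------------------------------------------

def _covariate_centers(config: SimulationConfig) -> dict[str, float]:
    """Centring constants: the annual mean of each covariate's deterministic part.

    Wastewater levels centre at exp(0) = 1-ish seasonal mean I0(a); we use the
    plain annual mean of the harmonic exponent's exp, computed on a dense grid.
    """
    centers: dict[str, float] = {}
    grid = np.arange(1.0, 366.0)
    for name in MET_COVARIATES:
        spec = config.met_specs[name]
        centers[name] = spec.mean
    for name in WASTEWATER_COVARIATES:
        spec = config.ww_specs[name]
        centers[name] = float(np.mean(np.exp(_annual_harmonic(grid, spec.log_amplitude, spec.peak_doy))))
    return centers


def _lift_series(
    config: SimulationConfig, calendar: pd.DatetimeIndex, cell: tuple[str, str, str]
) -> np.ndarray:
    profile = config.effect_profile.get(cell)
    lift = np.ones(len(calendar))
    if profile is None:
        return lift
    offsets = (calendar - pd.Timestamp(config.event_date)).days
    mask = (offsets >= 0) & (offsets < len(profile))
    lift[mask] = np.asarray(profile, dtype=float)[offsets[mask]]
    return lift


def _cell_mu0(
    config: SimulationConfig,
    calendar: pd.DatetimeIndex,
    covariates: pd.DataFrame,
    cell: tuple[str, str, str],
) -> np.ndarray:
    """Counterfactual (lift-free) mean for one cell on every calendar date."""
    stratum, modality, cause = cell
    base = config.rate_for(stratum, modality, cause)
    wk = np.asarray(config.weekday_multipliers, dtype=float)[calendar.dayofweek]
    doy = calendar.dayofyear.to_numpy(dtype=float)
    annual = np.exp(_annual_harmonic(doy, config.amplitude_for(stratum), config.annual_peak_doy))
    centers = _covariate_centers(config)
    log_cov = np.zeros(len(calendar))
    for name, coef in config.covariate_coefficients.items():
        if name not in covariates.columns:
            raise ConfigurationError(f"covariate coefficient refers to unknown series {name!r}")
        log_cov += coef * (covariates[name].to_numpy() - centers[name])
    return base * wk * annual * np.exp(log_cov)


def generate_visits(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    seed: int | None = None,
    windows: Sequence[int] = (7, 14),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the daily visit cube and record its exact ground truth.

    Returns a tidy frame with columns (date, stratum, modality, cause, count)
    covering every calendar date of every cell, and a :class:`GroundTruth`
    whose expected window excesses are seed-free closed forms of the config
    and covariates.
    """
    if seed is None:
        seed = config.seed
    calendar = generate_calendar(config)
    if not calendar.isin(covariates.index).all():
        raise GenerationError("covariates do not cover the full study calendar")
    covariates = covariates.loc[calendar]
    rng = np.random.default_rng(seed)

    frames = []
    truth_rows = []
    window_excess: dict[tuple[str, str, str, int], float] = {}
    window_pct: dict[tuple[str, str, str, int], float] = {}
    offsets = (calendar - pd.Timestamp(config.event_date)).days

    for cell in config.cells():
        stratum, modality, cause = cell
        mu0 = _cell_mu0(config, calendar, covariates, cell)
        lift = _lift_series(config, calendar, cell)
        mu = mu0 * lift
        if not np.all(np.isfinite(mu)) or np.any(mu > 1e12):
            raise GenerationError(f"cell {cell}: mean overflows")
        if np.any(mu0 <= 0):
            raise GenerationError(f"cell {cell}: nonpositive mean")
        counts = _sample_counts(rng, mu, config.dispersion)
        frames.append(
            pd.DataFrame(
                {
                    "date": calendar,
                    "stratum": stratum,
                    "modality": modality,
                    "cause": cause,
                    "count": counts,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "date": calendar,
                    "stratum": stratum,
                    "modality": modality,
                    "cause": cause,
                    "mu0": mu0,
                    "lift": lift,
                }
            )
        )
        for w in windows:
            mask = (offsets >= 0) & (offsets < w)
            excess = float(np.sum(mu0[mask] * (lift[mask] - 1.0)))
            expected = float(np.sum(mu0[mask]))
            window_excess[(stratum, modality, cause, int(w))] = excess
            window_pct[(stratum, modality, cause, int(w))] = 100.0 * excess / expected

    visits = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        daily=pd.concat(truth_rows, ignore_index=True),
        window_excess=window_excess,
        window_pct=window_pct,
    )
    return visits, truth


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def expected_window_excess(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    windows: Sequence[int] = (7, 14),
) -> dict[tuple[str, str, str, int], float]:
    """Seed-free recomputation of GroundTruth.window_excess from the config."""
    calendar = generate_calendar(config)
    covariates = covariates.loc[calendar]
    offsets = (calendar - pd.Timestamp(config.event_date)).days
    out: dict[tuple[str, str, str, int], float] = {}
    for cell in config.cells():
        mu0 = _cell_mu0(config, calendar, covariates, cell)
        lift = _lift_series(config, calendar, cell)
        for w in windows:
            mask = (offsets >= 0) & (offsets < w)
            out[cell + (int(w),)] = float(np.sum(mu0[mask] * (lift[mask] - 1.0)))
    return out


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArealUnit:
    unit_id: str
    geometry: Polygon
    county: str


@dataclass(frozen=True)
class FirePerimeter:
    fire_id: str
    geometry: Polygon


#: width of the band of fire boxes, and the tract square side, in metres
_FIRE_HALF_HEIGHT = 1000.0
_TRACT_SIDE = 1000.0
_FIRE_SPACING = 4000.0


def generate_geography(
    n_tracts: int = 25,
    n_fires: int = 7,
    seed: int = 0,
    class_mix: tuple[int, int, int] | None = None,
    threshold_km: float = 20.0,
    focal_county: str = "Los Angeles",
    outside_county: str = "Ventura",
) -> tuple[list[ArealUnit], list[FirePerimeter]]:
    """Planar tract and fire-perimeter polygons with constructed distances.

    Fires are 2 km-tall boxes sharing the band y in [-1, 1] km; tracts are
    1 km squares placed due north with their x-extent inside the fire band's
    x-extent, so each tract's minimum boundary-to-boundary distance to the
    nearest perimeter is exactly its vertical offset. ``class_mix`` =
    (n_high, n_moderate, n_minimal) pins the expected exposure classes by
    construction: high tracts sit strictly under ``threshold_km``, the others
    strictly above, with minimal tracts labelled with a non-focal county.
    Coordinates are metres in an arbitrary planar projection.
    """
    if n_fires < 1:
        raise ValueError("n_fires must be >= 1")
    if class_mix is not None:
        n_tracts = sum(class_mix)
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")

    rng = np.random.default_rng(seed)
    fires = [
        FirePerimeter(
            fire_id=f"fire_{i}",
            geometry=box(
                i * _FIRE_SPACING - 1000.0,
                -_FIRE_HALF_HEIGHT,
                i * _FIRE_SPACING + 1000.0,
                _FIRE_HALF_HEIGHT,
            ),
        )
        for i in range(n_fires)
    ]
    if class_mix is None:
        classes = rng.choice(3, size=n_tracts, p=(0.4, 0.4, 0.2))
    else:
        classes = np.repeat([0, 1, 2], class_mix)

    units: list[ArealUnit] = []
    for i, cls in enumerate(classes):
        if cls == 0:
            d_km = rng.uniform(0.2, max(threshold_km - 0.5, 0.3))
            county = focal_county
        else:
            d_km = rng.uniform(threshold_km + 0.5, threshold_km * 3.0)
            county = focal_county if cls == 1 else outside_county
        # keep the tract's x-extent inside one fire box's x-extent so the
        # nearest perimeter point is directly below and distance is exact
        j = int(rng.integers(0, n_fires))
        x0 = rng.uniform(j * _FIRE_SPACING - 1000.0, j * _FIRE_SPACING + 1000.0 - _TRACT_SIDE)
        y0 = _FIRE_HALF_HEIGHT + d_km * 1000.0
        units.append(
            ArealUnit(
                unit_id=f"tract_{i:04d}",
                geometry=box(x0, y0, x0 + _TRACT_SIDE, y0 + _TRACT_SIDE),
                county=county,
            )
        )
    return units, fires
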