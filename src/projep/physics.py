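"""Closed-form design physics of projection electrophoresis.

Projection electrophoresis runs hundreds of single-cell PAGE separations in
parallel along the z-axis of a microwell-stippled polyacrylamide gel block.
The microwell pitch (lane spacing), electric field, and separation time are
set by a small group of diffusion-dominated design relations:

* band broadening          sigma(t)^2 = sigma0^2 + 2 D t
* lane crosstalk           Gaussian mass beyond half the well pitch
* separation resolution    R_s = dmu * E * t / (2 (sigma1 + sigma2))
* Peclet trade-off         Pe = t_overlap / t_{R_s = 1}

plus transport-coefficient estimators (Stokes-Einstein free-solution
diffusivity, Ogston size-exclusion partitioning, in-gel hindered diffusion)
and the least-squares fits used to extract mobilities and diffusivities
from measured migration and band-width data.

Units: lengths in um, time in s, diffusivity in um^2/s, electric field in
V/cm, electrophoretic mobility in cm^2/(V s). A mobility mu in an electric
field E gives a migration velocity mu*E*1e4 um/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .errors import ConfigurationError, ExtrapolationWarning, NoSolutionError

BOLTZMANN_J_PER_K = 1.380649e-23
#: velocity in um/s per (cm^2/(V s) * V/cm)
_MOBILITY_TO_UM_PER_S = 1.0e4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinSpecies:
    """Physical descriptors of one protein analyte / fluorescence channel.

    ``d_gel`` and ``partition_k`` map gel density (%T, w/v acrylamide) to the
    in-gel diffusivity (um^2/s) and equilibrium partition coefficient
    k = C_gel / C_solution.
    """

    name: str
    mass_kda: float
    r_h_nm: float | None = None
    d_free: float | None = None
    d_gel: Mapping[float, float] = field(default_factory=dict)
    partition_k: Mapping[float, float] = field(default_factory=dict)
    mobility: float | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        if not self.mass_kda > 0:
            raise ValueError(f"mass must be positive, got {self.mass_kda}")
        if self.r_h_nm is not None and not self.r_h_nm > 0:
            raise ValueError("hydrodynamic radius must be positive")
        if self.d_free is not None and not self.d_free > 0:
            raise ValueError("free-solution diffusivity must be positive")
        for pt, d in self.d_gel.items():
            if not d > 0:
                raise ValueError(f"D_gel at {pt}%T must be positive")
            if self.d_free is not None and d > self.d_free:
                raise ValueError(
                    f"D_gel at {pt}%T exceeds free-solution diffusivity"
                )
        for pt, k in self.partition_k.items():
            if not 0 < k <= 1:
                raise ValueError(f"partition coefficient at {pt}%T not in (0, 1]")

    def d_in_gel(self, percent_t: float) -> float:
        try:
            return self.d_gel[percent_t]
        except KeyError:
            raise ConfigurationError(
                f"{self.name}: no in-gel diffusivity for {percent_t}%T"
            ) from None

    def k_in_gel(self, percent_t: float) -> float:
        try:
            return self.partition_k[percent_t]
        except KeyError:
            raise ConfigurationError(
                f"{self.name}: no partition coefficient for {percent_t}%T"
            ) from None


@dataclass(frozen=True)
class GelSpec:
    """Geometry and polymer structure of a microwell-stippled gel block."""

    percent_t: float
    thickness_um: float = 1000.0
    well_diameter_um: float = 32.0
    well_depth_um: float = 40.0
    pitch_um: float = 200.0
    temperature_k: float = 277.15
    fiber_radius_nm: float | None = None
    volume_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.pitch_um < self.well_diameter_um:
            raise ValueError("pitch must be at least the microwell diameter")
        if self.thickness_um < self.well_depth_um:
            raise ValueError("gel thickness must exceed the microwell depth")
        if self.volume_fraction is not None and not 0 < self.volume_fraction < 1:
            raise ValueError("polymer volume fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SeparationConditions:
    """Field strength and timing of one electrophoresis run.

    ``t_diff_s`` is the total elapsed in-gel diffusion time (lysis +
    electrophoresis + any hold before photocapture); it can exceed but never
    undershoot the electrophoresis time.
    """

    field_v_per_cm: float
    ep_time_s: float
    lysis_time_s: float = 0.0
    t_diff_s: float | None = None
    sigma0_um: float = 16.0

    def __post_init__(self) -> None:
        if self.field_v_per_cm < 0:
            raise ValueError("field strength must be non-negative")
        if self.ep_time_s < 0 or self.lysis_time_s < 0:
            raise ValueError("times must be non-negative")
        if self.t_diff_s is None:
            object.__setattr__(self, "t_diff_s", self.ep_time_s + self.lysis_time_s)
        if self.t_diff_s < self.ep_time_s:
            raise ValueError("total diffusion time cannot undershoot EP time")

    def replace_time(self, ep_time_s: float) -> "SeparationConditions":
        return SeparationConditions(
            field_v_per_cm=self.field_v_per_cm,
            ep_time_s=ep_time_s,
            lysis_time_s=self.lysis_time_s,
            t_diff_s=None,
            sigma0_um=self.sigma0_um,
        )


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with its goodness of fit."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a line needs at least two points")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class BandBroadeningFit:
    """Result of fitting sigma^2 vs t to the diffusional broadening law."""

    fit: LinearFit
    d_um2_per_s: float
    sigma0_um: float | None
    intercept_nonphysical: bool


@dataclass(frozen=True)
class OverlapTime:
    """Time for a band to broaden to the lane-crosstalk limit."""

    time_s: float
    feasible: bool


@dataclass(frozen=True)
class ThroughputReport:
    """Serial first-to-last sampling delay vs parallel separation rate."""

    serial_delay_min: int | None = None
    serial_delay_exact_min: float | None = None
    parallel_rate_per_s: int | None = None
    parallel_rate_exact_per_s: float | None = None


# ---------------------------------------------------------------------------
# band broadening and lane-layout rules
# ---------------------------------------------------------------------------


def band_sigma(sigma0_um, d_um2_per_s, t_s):
    """Gaussian band width after diffusing for ``t_s`` seconds.

    sigma(t) = sqrt(sigma0^2 + 2 D t); accepts scalars or arrays.
    """
    sigma0 = np.asarray(sigma0_um, dtype=float)
    d = np.asarray(d_um2_per_s, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if np.any(sigma0 < 0) or np.any(d < 0) or np.any(t < 0):
        raise ValueError("sigma0, D and t must all be non-negative")
    out = np.sqrt(sigma0**2 + 2.0 * d * t)
    return float(out) if out.ndim == 0 else out


def overlap_fraction(
    pitch_um: float, sigma_um: float, sidedness: Literal["one", "two"] = "two"
) -> float:
    """Fraction of a Gaussian band lying beyond half the well pitch.

    This is the mass a lane bleeds into one neighbor (``one``) or shares
    with both neighbors (``two``, the default design convention).
    """
    if pitch_um <= 0 or sigma_um <= 0:
        raise ValueError("pitch and sigma must be positive")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    tail = 1.0 - ndtr(pitch_um / 2.0 / sigma_um)
    return tail if sidedness == "one" else 2.0 * tail


def lane_density(pitch_um: float) -> float:
    """Separation lanes per mm^2 for a square microwell grid."""
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    return (1000.0 / pitch_um) ** 2


def wells_in_gel(gel_side_mm: float, pitch_um: float) -> int:
    """Number of microwells fitting on a square gel of the given side."""
    if gel_side_mm <= 0 or pitch_um <= 0:
        raise ValueError("gel side and pitch must be positive")
    per_side = int(math.floor(gel_side_mm * 1000.0 / pitch_um))
    return per_side**2


def overlap_time(
    d_um2_per_s: float,
    pitch_um: float,
    sigma0_um: float,
    rule: Literal["4sigma", "6sigma"] = "6sigma",
) -> OverlapTime:
    """Invert the broadening law at the pitch-over-rule-factor band width.

    Returns the time at which sigma_xy reaches pitch/4 or pitch/6, i.e. the
    maximum assay time before neighboring lanes overlap beyond the design
    rule. Infeasible geometries (injected band already too wide) report
    zero time with ``feasible=False``.
    """
    factor = {"4sigma": 4.0, "6sigma": 6.0}.get(rule)
    if factor is None:
        raise ValueError("rule must be '4sigma' or '6sigma'")
    if d_um2_per_s <= 0 or pitch_um <= 0 or sigma0_um < 0:
        raise ValueError("D and pitch must be positive, sigma0 non-negative")
    sigma_limit = pitch_um / factor
    if sigma_limit <= sigma0_um:
        return OverlapTime(0.0, feasible=sigma_limit == sigma0_um)
    t = (sigma_limit**2 - sigma0_um**2) / (2.0 * d_um2_per_s)
    return OverlapTime(t, feasible=True)


# ---------------------------------------------------------------------------
# separation resolution and the Peclet trade-off
# ---------------------------------------------------------------------------


def _require(species: ProteinSpecies, percent_t: float) -> tuple[float, float]:
    if species.mobility is None:
        raise ConfigurationError(f"{species.name}: electrophoretic mobility not set")
    return species.mobility, species.d_in_gel(percent_t)


def separation_resolution(
    sp1: ProteinSpecies,
    sp2: ProteinSpecies,
    cond: SeparationConditions,
    percent_t: float = 7.0,
    t_s: float | None = None,
) -> float:
    """Separation resolution R_s of a species pair after ``t_s`` seconds.

    R_s = dmu * E * t / (2 (sigma1 + sigma2)) with each sigma following the
    diffusional broadening law from the shared injected width sigma0. By the
    4-sigma peak-width convention, R_s >= 1 means baseline-resolved bands.
    """
    mu1, d1 = _require(sp1, percent_t)
    mu2, d2 = _require(sp2, percent_t)
    t = cond.ep_time_s if t_s is None else t_s
    if t < 0:
        raise ValueError("time must be non-negative")
    dz = abs(mu1 - mu2) * cond.field_v_per_cm * t * _MOBILITY_TO_UM_PER_S
    s1 = band_sigma(cond.sigma0_um, d1, t)
    s2 = band_sigma(cond.sigma0_um, d2, t)
    return dz / (2.0 * (s1 + s2))


def time_to_resolution(
    sp1: ProteinSpecies,
    sp2: ProteinSpecies,
    cond: SeparationConditions,
    target_rs: float = 1.0,
    percent_t: float = 7.0,
    t_max_s: float = 1.0e4,
    xtol_s: float = 1.0e-3,
) -> float:
    """Electrophoresis time at which the pair reaches ``target_rs``.

    R_s(t) is monotone increasing for dmu*E > 0, so a bracketed root on
    (0, t_max_s] is safe; an unreachable target raises ``NoSolutionError``.
    """

    def f(t: float) -> float:
        return separation_resolution(sp1, sp2, cond, percent_t, t_s=t) - target_rs

    if f(t_max_s) < 0:
        raise NoSolutionError(
            f"R_s = {target_rs} not reachable within {t_max_s} s at "
            f"E = {cond.field_v_per_cm} V/cm"
        )
    return float(optimize.brentq(f, 0.0, t_max_s, xtol=xtol_s))


def peclet(
    sp1: ProteinSpecies,
    sp2: ProteinSpecies,
    pitch_um: float,
    cond: SeparationConditions,
    percent_t: float = 7.0,
) -> float:
    """Peclet number: lane-overlap time over time-to-unit-resolution.

    The overlap clock uses the faster-diffusing species of the pair under
    the conservative 6-sigma pitch rule. Pe > 1 means the separation
    resolves before bands bleed into neighboring lanes.
    """
    d_fast = max(sp1.d_in_gel(percent_t), sp2.d_in_gel(percent_t))
    t_over = overlap_time(d_fast, pitch_um, cond.sigma0_um, "6sigma")
    if not t_over.feasible or t_over.time_s == 0.0:
        return 0.0
    t_rs1 = time_to_resolution(
        sp1, sp2, cond, 1.0, percent_t, t_max_s=10.0 * t_over.time_s
    )
    return t_over.time_s / t_rs1


# ---------------------------------------------------------------------------
# transport-coefficient estimators
# ---------------------------------------------------------------------------


def stokes_einstein_d(
    r_h_nm: float, temperature_k: float = 298.15, viscosity_mpas: float = 0.89
) -> float:
    """Free-solution diffusivity D = k_B T / (6 pi eta r_H), in um^2/s."""
    if r_h_nm <= 0 or temperature_k <= 0 or viscosity_mpas <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    d_m2 = BOLTZMANN_J_PER_K * temperature_k / (
        6.0 * math.pi * viscosity_mpas * 1e-3 * r_h_nm * 1e-9
    )
    return d_m2 * 1e12


def ogston_partition(r_h_nm: float, gel: GelSpec) -> float:
    """Size-exclusion partition coefficient k = exp(-phi (1 + r_H/a)^2).

    ``a`` is the gel fiber radius and ``phi`` the polymer volume fraction;
    both must be set on the GelSpec (see :func:`calibrated_gel`).
    """
    if r_h_nm < 0:
        raise ValueError("hydrodynamic radius must be non-negative")
    if gel.fiber_radius_nm is None or gel.volume_fraction is None:
        raise ConfigurationError(
            "gel fiber radius and polymer volume fraction are required "
            "for Ogston partitioning"
        )
    k = math.exp(-gel.volume_fraction * (1.0 + r_h_nm / gel.fiber_radius_nm) ** 2)
    return min(k, 1.0)


# Transport coefficients for the three simulated proteins at 4 C:
# hydrodynamic radius (nm), free-solution D and in-gel D (um^2/s), and
# partition coefficients for the 7%T separation and 20%T lysis gels.
TRANSPORT_TABLE = pd.DataFrame(
    [
        ("TurboGFP", 26.0, 2.30, 66.1, 13.6, 0.949, 0.501, 0.0415),
        ("BSA", 66.5, 3.01, 50.5, 7.90, 0.349, 0.344, 0.00744),
        ("HER2", 185.0, 3.76, 40.4, 4.88, 0.139, 0.213, 8.16e-4),
    ],
    columns=["name", "mass_kda", "r_h_nm", "d_sol", "d_7t", "d_20t", "k_7t", "k_20t"],
)


def transport_species(name: str) -> ProteinSpecies:
    """One of the three tabulated simulation proteins, fully parameterized."""
    row = TRANSPORT_TABLE.loc[TRANSPORT_TABLE["name"] == name]
    if row.empty:
        raise KeyError(f"unknown tabulated species {name!r}")
    r = row.iloc[0]
    return ProteinSpecies(
        name=r["name"],
        mass_kda=r["mass_kda"],
        r_h_nm=r["r_h_nm"],
        d_free=r["d_sol"],
        d_gel={7.0: r["d_7t"], 20.0: r["d_20t"]},
        partition_k={7.0: r["k_7t"], 20.0: r["k_20t"]},
    )


@dataclass(frozen=True)
class GelCalibration:
    """Structural gel parameters fitted to the built-in transport table.

    One fiber radius is shared across gel densities; the polymer volume
    fraction and the hindrance prefactor are per-%T. The hindrance factor
    is the stretched exponential D_gel/D_free = exp(-c(%T) * r_H^p).
    """

    fiber_radius_nm: float
    volume_fraction: Mapping[float, float]
    hindrance_exponent: float
    hindrance_coeff: Mapping[float, float]

    def phi(self, percent_t: float) -> float:
        return _interp_through_origin(percent_t, self.volume_fraction)

    def coeff(self, percent_t: float) -> float:
        return _interp_through_origin(percent_t, self.hindrance_coeff)

    @property
    def support_percent_t(self) -> tuple[float, float]:
        keys = sorted(self.hindrance_coeff)
        return 0.0, keys[-1]


def _interp_through_origin(percent_t: float, table: Mapping[float, float]) -> float:
    """Piecewise-linear value through (0, 0) and the calibrated points."""
    if percent_t < 0:
        raise ValueError("%T must be non-negative")
    pts = [(0.0, 0.0)] + sorted(table.items())
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if percent_t <= xs[-1]:
        return float(np.interp(percent_t, xs, ys))
    # linear extrapolation from the last segment
    slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    return float(ys[-1] + slope * (percent_t - xs[-1]))


@lru_cache(maxsize=1)
def table_calibration() -> GelCalibration:
    """Fit (a, phi_7, phi_20) and (p, c_7, c_20) to the transport table.

    Partition coefficients are fitted in log space with the Ogston model;
    diffusivity ratios with the stretched-exponential hindrance factor.
    Both fits reproduce all six tabulated entries to better than 5%
    relative error (see the test suite).
    """
    tbl = TRANSPORT_TABLE
    r = tbl["r_h_nm"].to_numpy()
    ln_k7 = np.log(tbl["k_7t"].to_numpy())
    ln_k20 = np.log(tbl["k_20t"].to_numpy())

    def k_resid(params):
        a, phi7, phi20 = params
        model7 = -phi7 * (1.0 + r / a) ** 2
        model20 = -phi20 * (1.0 + r / a) ** 2
        return np.concatenate([model7 - ln_k7, model20 - ln_k20])

    k_fit = optimize.least_squares(k_resid, x0=[0.63, 0.032, 0.146])
    a, phi7, phi20 = k_fit.x

    ln_h7 = np.log(tbl["d_7t"].to_numpy() / tbl["d_sol"].to_numpy())
    ln_h20 = np.log(tbl["d_20t"].to_numpy() / tbl["d_sol"].to_numpy())

    def h_resid(params):
        p, c7, c20 = params
        return np.concatenate(
            [-c7 * r**p - ln_h7, -c20 * r**p - ln_h20]
        )

    h_fit = optimize.least_squares(h_resid, x0=[0.6, 0.97, 2.6])
    p, c7, c20 = h_fit.x
    return GelCalibration(
        fiber_radius_nm=float(a),
        volume_fraction={7.0: float(phi7), 20.0: float(phi20)},
        hindrance_exponent=float(p),
        hindrance_coeff={7.0: float(c7), 20.0: float(c20)},
    )


def calibrated_gel(percent_t: float, **kwargs) -> GelSpec:
    """GelSpec with fiber radius and volume fraction from the calibration."""
    cal = table_calibration()
    kwargs.setdefault("fiber_radius_nm", cal.fiber_radius_nm)
    kwargs.setdefault("volume_fraction", cal.phi(percent_t))
    return GelSpec(percent_t=percent_t, **kwargs)


def gel_hindered_d(
    species: ProteinSpecies, gel: GelSpec, calibration: GelCalibration | None = None
) -> float:
    """In-gel diffusivity from the calibrated sieving hindrance factor.

    D_gel = D_free * exp(-c(%T) * r_H^p); the factor lies in (0, 1], tends
    to 1 as %T -> 0, and decreases with both r_H and gel density. Gel
    densities above the calibration support trigger an
    :class:`ExtrapolationWarning`.
    """
    if species.d_free is None or species.r_h_nm is None:
        raise ConfigurationError(
            f"{species.name}: free-solution D and hydrodynamic radius required"
        )
    cal = calibration or table_calibration()
    lo, hi = cal.support_percent_t
    if gel.percent_t > hi:
        warnings.warn(
            f"{gel.percent_t}%T is outside the hindrance calibration support "
            f"({lo}-{hi}%T); extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    factor = math.exp(
        -cal.coeff(gel.percent_t) * species.r_h_nm**cal.hindrance_exponent
    )
    return species.d_free * factor


# ---------------------------------------------------------------------------
# least-squares fits to measured data
# ---------------------------------------------------------------------------


def _linfit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("at least two distinct x values are required")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(np.clip(res.rvalue**2, 0.0, 1.0)),
        n_points=int(x.size),
    )


def fit_band_broadening(
    sigma_xy_um: Sequence[float], t_diff_s: Sequence[float]
) -> BandBroadeningFit:
    """Fit sigma_xy^2 vs t_diff to extract (sigma0, D).

    D = slope / 2. A negative intercept (as in noisy short-time data) is
    flagged non-physical and reported with ``sigma0_um=None`` rather than
    failing the fit.
    """
    sigma = np.asarray(sigma_xy_um, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("band widths must be non-negative")
    fit = _linfit(t_diff_s, sigma**2)
    nonphysical = fit.intercept < 0
    sigma0 = None if nonphysical else math.sqrt(fit.intercept)
    return BandBroadeningFit(
        fit=fit,
        d_um2_per_s=fit.slope / 2.0,
        sigma0_um=sigma0,
        intercept_nonphysical=nonphysical,
    )


@dataclass(frozen=True)
class MigrationFit:
    fit: LinearFit
    velocity_um_per_s: float
    mobility_cm2_per_vs: float


def fit_migration(
    z_um: Sequence[float], t_s: Sequence[float], e_v_per_cm: float
) -> MigrationFit:
    """Fit migration distance vs time; mobility = velocity / E."""
    if e_v_per_cm <= 0:
        raise ValueError("field strength must be positive")
    fit = _linfit(t_s, z_um)
    velocity = fit.slope
    return MigrationFit(
        fit=fit,
        velocity_um_per_s=velocity,
        mobility_cm2_per_vs=velocity / (e_v_per_cm * _MOBILITY_TO_UM_PER_S),
    )


def fit_log_mass_mobility(species: Sequence[ProteinSpecies]) -> LinearFit:
    """Fit log10(mass) vs electrophoretic mobility across a protein panel."""
    mu = []
    logm = []
    for sp in species:
        if sp.mobility is None:
            raise ConfigurationError(f"{sp.name}: mobility not set")
        if sp.mass_kda <= 0:
            raise ValueError(f"{sp.name}: mass must be positive")
        mu.append(sp.mobility)
        logm.append(math.log10(sp.mass_kda))
    return _linfit(mu, logm)


def mass_from_mobility(fit: LinearFit, mobility_cm2_per_vs: float) -> float:
    """Invert a log-mass-vs-mobility fit to predict a molecular mass."""
    return float(10.0 ** fit.predict(mobility_cm2_per_vs))


def throughput_metrics(
    n_cells: int | None = None,
    serial_rate_per_min: float | None = None,
    n_lanes: int | None = None,
    active_time_s: float | None = None,
) -> ThroughputReport:
    """Serial first-to-last interrogation delay and parallel assay rate.

    Serial systems sample one cell at a time: the last cell waits
    n_cells / rate minutes. A projection device runs every lane at once:
    its rate is n_lanes / active_time separations per second. Both
    headline numbers are floored to whole units.
    """
    serial_exact = serial_int = None
    parallel_exact = parallel_int = None
    if n_cells is not None or serial_rate_per_min is not None:
        if n_cells is None or serial_rate_per_min is None:
            raise ValueError("serial delay needs both n_cells and serial rate")
        if serial_rate_per_min <= 0:
            raise ValueError("serial rate must be positive")
        if n_cells <= 0:
            raise ValueError("cell count must be positive")
        serial_exact = n_cells / serial_rate_per_min
        serial_int = int(math.floor(serial_exact))
    if n_lanes is not None or active_time_s is not None:
        if n_lanes is None or active_time_s is None:
            raise ValueError("parallel rate needs both n_lanes and active time")
        if active_time_s <= 0 or n_lanes <= 0:
            raise ValueError("lane count and active time must be positive")
        parallel_exact = n_lanes / active_time_s
        parallel_int = int(math.floor(parallel_exact))
    return ThroughputReport(
        serial_delay_min=serial_int,
        serial_delay_exact_min=serial_exact,
        parallel_rate_per_s=parallel_int,
        parallel_rate_exact_per_s=parallel_exact,
    )


def design_table(
    sp1: ProteinSpecies,
    sp2: ProteinSpecies,
    cond: SeparationConditions,
    pitches_um: Sequence[float],
    times_s: Sequence[float] | None = None,
    percent_t: float = 7.0,
    rule: Literal["4sigma", "6sigma"] = "6sigma",
) -> pd.DataFrame:
    """Design-rule sweep over pitch (and optionally EP time).

    Columns: pitch_um, E_V_per_cm, t_s, Rs, Pe, overlap_fraction,
    lane_density_per_mm2.
    """
    d_fast = max(sp1.d_in_gel(percent_t), sp2.d_in_gel(percent_t))
    times = [cond.ep_time_s] if times_s is None else list(times_s)
    rows = []
    for pitch in pitches_um:
        for t in times:
            sigma = band_sigma(cond.sigma0_um, d_fast, t)
            try:
                pe = peclet(sp1, sp2, pitch, cond, percent_t)
            except NoSolutionError:
                pe = float("nan")  # R_s = 1 unreachable before lane overlap
            rows.append(
                {
                    "pitch_um": pitch,
                    "E_V_per_cm": cond.field_v_per_cm,
                    "t_s": t,
                    "Rs": separation_resolution(sp1, sp2, cond, percent_t, t_s=t),
                    "Pe": pe,
                    "overlap_fraction": overlap_fraction(pitch, sigma),
                    "lane_density_per_mm2": lane_density(pitch),
                }
            )
    return pd.DataFrame(rows)
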