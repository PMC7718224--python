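"""Axisymmetric finite-volume diffusion solver for lysate dilution.

Models the reaction-free diffusion of solubilized protein out of a
microwell during in-well lysis and (as an instantaneous-injection
simplification) during electrophoresis. The domain is an (r, z) half-plane
around the microwell axis: a dense lysis-gel lid on top, a thin fluid film
between the two gels, the microwell recess holding the cell, and the
separation-gel slab below.

Size-exclusion partitioning at gel/solution interfaces imposes a
concentration jump c_gel = k * c_solution with continuous flux. The solver
works in the chemical-potential variable w = c / k, which is continuous
across interfaces, with harmonic-mean D*k face conductances:

    k(r,z) dw/dt = (1/r) d/dr ( r D k dw/dr ) + d/dz ( D k dw/dz )

Time stepping is backward Euler; each schedule stage assembles one sparse
operator and reuses a single sparse LU factorization for all of its steps.
Open edges are modeled as Dirichlet c = 0 ghost cells, no-flux edges as
zero face conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .errors import ConfigurationError, StabilityError
from .physics import GelSpec, ProteinSpecies

# region codes
SOLUTION = 0
GEL_SEP = 1  # separation gel (7%T)
GEL_LID = 2  # lysis/lid gel (20%T)
CELL = 3

REGION_NAMES = {SOLUTION: "solution", GEL_SEP: "gel_7%T", GEL_LID: "gel_20%T", CELL: "cell"}


@dataclass(frozen=True)
class DomainGrid:
    """Uniform axisymmetric (r, z) grid with a per-node region map.

    ``region`` has shape (nz, nr); z increases downward into the separation
    gel, r = 0 is the symmetry axis. ``bc`` maps edges ('r_max', 'z_min',
    'z_max') to 'open' (Dirichlet c = 0) or 'noflux'; the axis edge is
    always a symmetry (no-flux) boundary.
    """

    r_um: np.ndarray
    z_um: np.ndarray
    region: np.ndarray
    bc: Mapping[str, str] = field(
        default_factory=lambda: {"r_max": "open", "z_min": "open", "z_max": "open"}
    )

    def __post_init__(self) -> None:
        if self.region.shape != (self.z_um.size, self.r_um.size):
            raise ValueError("region map must have shape (nz, nr)")
        for edge, kind in self.bc.items():
            if kind not in ("open", "noflux"):
                raise ValueError(f"unknown boundary condition {kind!r} on {edge}")

    @property
    def dr(self) -> float:
        return float(self.r_um[1] - self.r_um[0])

    @property
    def dz(self) -> float:
        return float(self.z_um[1] - self.z_um[0])

    def node_volumes(self) -> np.ndarray:
        """Cylindrical cell volumes (per radian) as a (nz, nr) array."""
        dr, dz = self.dr, self.dz
        r_weight = self.r_um.astype(float).copy()
        # axis cell spans [0, dr/2]: integral of r dr = dr^2/8
        r_weight[0] = dr / 8.0
        return np.broadcast_to(r_weight * dr * dz, self.region.shape).copy()


@dataclass(frozen=True)
class Stage:
    """One interval of the piecewise-constant transport schedule."""

    duration_s: float
    d_map: Mapping[int, float]
    k_map: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("stage duration must be positive")
        for k in self.k_map.values():
            if not 0 < k <= 1:
                raise ValueError("partition coefficients must lie in (0, 1]")
        for d in self.d_map.values():
            if d <= 0:
                raise ValueError("diffusivities must be positive")


@dataclass(frozen=True)
class DiffusionSchedule:
    stages: Sequence[Stage]
    output_times_s: Sequence[float]

    def __post_init__(self) -> None:
        total = sum(s.duration_s for s in self.stages)
        for t in self.output_times_s:
            if t < 0 or t > total + 1e-9:
                raise ValueError("output times must lie within the schedule")


@dataclass
class ConcentrationField:
    """Concentration snapshots c(r, z) at the requested output times."""

    grid: DomainGrid
    times_s: np.ndarray
    c_um: np.ndarray  # shape (nt, nz, nr), concentration in uM

    def total_moles(self) -> np.ndarray:
        """Moles (per radian, arbitrary scale) at each output time."""
        vol = self.grid.node_volumes()
        return np.einsum("tij,ij->t", self.c_um, vol)


def build_projection_geometry(
    gel: GelSpec,
    cell_radius_um: float | None = None,
    cell_height_um: float | None = None,
    fluid_layer_um: float = 5.0,
    lid_gel_um: float = 0.0,
    r_max_um: float = 500.0,
    gel_depth_um: float = 500.0,
    spacing_um: float = 2.0,
) -> DomainGrid:
    """Microwell-in-gel-slab geometry with a lysis-gel lid.

    The cell defaults to a cylinder filling the microwell. z = 0 is the top
    of the lid gel; the separation-gel face sits at lid + fluid, the well
    recess extends ``gel.well_depth_um`` below the face, and the separation
    gel continues to ``gel_depth_um`` below the face (clipped to the gel
    thickness).
    """
    well_r = gel.well_diameter_um / 2.0
    if cell_radius_um is None:
        cell_radius_um = well_r
    if cell_height_um is None:
        cell_height_um = gel.well_depth_um
    if cell_radius_um > well_r or cell_height_um > gel.well_depth_um:
        raise ConfigurationError("cell cylinder does not fit inside the microwell")

    depth = min(gel_depth_um, gel.thickness_um)
    z_max = lid_gel_um + fluid_layer_um + depth
    nr = int(round(r_max_um / spacing_um)) + 1
    nz = int(round(z_max / spacing_um)) + 1
    r = np.linspace(0.0, r_max_um, nr)
    z = np.linspace(0.0, z_max, nz)

    region = np.full((nz, nr), GEL_SEP, dtype=np.int8)
    zz = z[:, None]
    rr = r[None, :]
    face = lid_gel_um + fluid_layer_um
    region[zz[:, 0] < lid_gel_um, :] = GEL_LID
    if fluid_layer_um > 0:
        region[(zz[:, 0] >= lid_gel_um) & (zz[:, 0] < face), :] = SOLUTION
    # microwell recess (open solution), then cell cylinder at the bottom
    in_well = (zz >= face) & (zz < face + gel.well_depth_um) & (rr <= well_r)
    region[in_well] = SOLUTION
    cell_top = face + gel.well_depth_um - cell_height_um
    in_cell = (
        (zz >= cell_top)
        & (zz < face + gel.well_depth_um)
        & (rr <= cell_radius_um)
    )
    region[in_cell] = CELL
    return DomainGrid(r_um=r, z_um=z, region=region)


def lysis_schedule(
    species: ProteinSpecies,
    lysis_time_s: float,
    ep_time_s: float = 0.0,
    output_times_s: Sequence[float] | None = None,
    sep_percent_t: float = 7.0,
    lid_percent_t: float = 20.0,
) -> DiffusionSchedule:
    """Two-stage transport schedule for in-well lysis then electrophoresis.

    During lysis the tabulated per-region diffusivities and partition
    coefficients apply. Afterwards all partition coefficients drop to 1 and
    every region takes the separation-gel diffusivity (instantaneous
    injection of the lysate profile into the separation gel).
    """
    if species.d_free is None:
        raise ConfigurationError(f"{species.name}: free-solution D required")
    d_sep = species.d_in_gel(sep_percent_t)
    stages = [
        Stage(
            duration_s=lysis_time_s,
            d_map={
                SOLUTION: species.d_free,
                CELL: species.d_free,
                GEL_SEP: d_sep,
                GEL_LID: species.d_in_gel(lid_percent_t),
            },
            k_map={
                SOLUTION: 1.0,
                CELL: 1.0,
                GEL_SEP: species.k_in_gel(sep_percent_t),
                GEL_LID: species.k_in_gel(lid_percent_t),
            },
        )
    ]
    if ep_time_s > 0:
        stages.append(
            Stage(
                duration_s=ep_time_s,
                d_map={c: d_sep for c in (SOLUTION, CELL, GEL_SEP, GEL_LID)},
                k_map={c: 1.0 for c in (SOLUTION, CELL, GEL_SEP, GEL_LID)},
            )
        )
    if output_times_s is None:
        output_times_s = [0.0, lysis_time_s + ep_time_s]
    return DiffusionSchedule(stages=stages, output_times_s=output_times_s)


def initial_cell_concentration(grid: DomainGrid, c0_um: float = 2.0) -> np.ndarray:
    """Uniform initial concentration inside the cell region, zero elsewhere."""
    c = np.zeros_like(grid.region, dtype=float)
    c[grid.region == CELL] = c0_um
    return c


def _face_conductances(grid: DomainGrid, stage: Stage):
    """Harmonic-mean D*k conductances on radial and axial faces."""
    dk = np.zeros_like(grid.region, dtype=float)
    for code, d in stage.d_map.items():
        k = stage.k_map[code]
        dk[grid.region == code] = d * k
    if np.any(dk[np.isin(grid.region, list(stage.d_map))] <= 0):
        raise ConfigurationError("stage transport maps do not cover all regions")

    def harmonic(a, b):
        return 2.0 * a * b / (a + b)

    h_r = harmonic(dk[:, :-1], dk[:, 1:])  # faces between r columns
    h_z = harmonic(dk[:-1, :], dk[1:, :])  # faces between z rows
    return dk, h_r, h_z


def _assemble(grid: DomainGrid, stage: Stage, dt: float):
    """Backward-Euler operator (I*kV/dt + L) and the per-node k*V diagonal."""
    nz, nr = grid.region.shape
    dr, dz = grid.dr, grid.dz
    n = nz * nr
    dk, h_r, h_z = _face_conductances(grid, stage)

    k_node = np.zeros_like(dk)
    for code, kv in stage.k_map.items():
        k_node[grid.region == code] = kv
    vol = grid.node_volumes()
    kv_diag = (k_node * vol).ravel()

    r_weight = grid.r_um.astype(float).copy()
    r_weight[0] = dr / 8.0  # axis cell volume weight (unused for faces)
    r_face = grid.r_um[:-1] + dr / 2.0  # radius of face i+1/2
    # face "areas" per radian: radial faces r_face*dz, axial faces r_weight*dr
    area_r = r_face * dz
    area_z = r_weight * dr

    idx = np.arange(n).reshape(nz, nr)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add_flux(i_a, i_b, g):
        # conductance g couples nodes a and b: L contribution
        rows.append(i_a)
        cols.append(i_b)
        vals.append(-g)
        rows.append(i_b)
        cols.append(i_a)
        vals.append(-g)
        np.add.at(diag, i_a, g)
        np.add.at(diag, i_b, g)

    # radial internal faces
    for i in range(nr - 1):
        g = h_r[:, i] * area_r[i] / dr
        add_flux(idx[:, i], idx[:, i + 1], g)
    # axial internal faces
    for j in range(nz - 1):
        g = h_z[j, :] * area_z / dz
        add_flux(idx[j, :], idx[j + 1, :], g)

    # open (Dirichlet c=0 ghost) edges: one-sided conductance to zero
    if grid.bc.get("r_max", "open") == "open":
        g = dk[:, -1] * (grid.r_um[-1] + dr / 2.0) * dz / dr
        np.add.at(diag, idx[:, -1], g)
    if grid.bc.get("z_min", "open") == "open":
        g = dk[0, :] * area_z / dz
        np.add.at(diag, idx[0, :], g)
    if grid.bc.get("z_max", "open") == "open":
        g = dk[-1, :] * area_z / dz
        np.add.at(diag, idx[-1, :], g)

    rows = np.concatenate([np.concatenate(rows), np.arange(n)])
    cols = np.concatenate([np.concatenate(cols), np.arange(n)])
    vals = np.concatenate([np.concatenate(vals), diag + kv_diag / dt])
    a = csc_matrix((vals, (rows, cols)), shape=(n, n))
    return a, kv_diag, k_node


def solve(
    grid: DomainGrid,
    schedule: DiffusionSchedule,
    c0_um: np.ndarray | None = None,
    dt_s: float = 0.025,
    negative_tol: float = 1e-9,
) -> ConcentrationField:
    """Integrate the schedule and return concentration snapshots.

    ``c0_um`` defaults to 2 uM inside the cell region. Concentrations more
    negative than ``negative_tol`` (relative to the initial maximum) abort
    with :class:`StabilityError`; backward Euler keeps them at roundoff.
    """
    if c0_um is None:
        c0_um = initial_cell_concentration(grid)
    if c0_um.shape != grid.region.shape:
        raise ValueError("initial field shape does not match the grid")
    if np.any(c0_um < 0):
        raise ValueError("initial concentrations must be non-negative")

    out_times = np.asarray(sorted(schedule.output_times_s), dtype=float)
    snaps = np.empty((out_times.size, *grid.region.shape))
    c_scale = max(float(c0_um.max()), 1.0)

    c = c0_um.astype(float).copy()
    t = 0.0
    out_i = 0
    while out_i < out_times.size and out_times[out_i] <= 1e-12:
        snaps[out_i] = c
        out_i += 1

    stage_start = 0.0
    for stage in schedule.stages:
        a, kv_diag, k_node = _assemble(grid, stage, dt_s)
        # chemical-potential variable is continuous; concentration jumps
        w = c / k_node
        lu = splu(a)
        stage_end = stage_start + stage.duration_s
        while t < stage_end - 1e-12:
            step = min(dt_s, stage_end - t)
            if abs(step - dt_s) > 1e-12:
                a_last, kv_last, _ = _assemble(grid, stage, step)
                w = splu(a_last).solve(kv_last / step * w.ravel()).reshape(w.shape)
            else:
                w = lu.solve(kv_diag / dt_s * w.ravel()).reshape(w.shape)
            t += step
            c = k_node * w
            if c.min() < -negative_tol * c_scale:
                raise StabilityError(
                    f"negative concentration {c.min():.3e} at t = {t:.3f} s"
                )
            while out_i < out_times.size and out_times[out_i] <= t + 1e-9:
                snaps[out_i] = np.clip(c, 0.0, None)
                out_i += 1
        stage_start = stage_end
    # any remaining requested times equal the final time within tolerance
    while out_i < out_times.size:
        snaps[out_i] = np.clip(c, 0.0, None)
        out_i += 1
    return ConcentrationField(grid=grid, times_s=out_times, c_um=snaps)


def dilution_metrics(
    field: ConcentrationField, well_radius_um: float
) -> pd.DataFrame:
    """Per-time dilution summary mimicking wide-field detection.

    The z-integrated intensity map collapses c(r, z) along z (wide-field
    fluorescence sees the whole depth); the in-well fraction is the share
    of that intensity within the well footprint, relative to t = 0.

    Columns: t_s, max_conc_um, frac_in_well.
    """
    grid = field.grid
    dz = grid.dz
    dr = grid.dr
    r_weight = grid.r_um.astype(float).copy()
    r_weight[0] = dr / 8.0
    in_foot = grid.r_um <= well_radius_um + 1e-9

    rows = []
    ref = None
    for t, c in zip(field.times_s, field.c_um):
        z_int = c.sum(axis=0) * dz  # intensity per radial position
        in_well = float((z_int[in_foot] * r_weight[in_foot]).sum() * dr)
        if ref is None:
            ref = in_well if in_well > 0 else 1.0
        rows.append(
            {
                "t_s": float(t),
                "max_conc_um": float(c.max()),
                "frac_in_well": in_well / ref,
            }
        )
    return pd.DataFrame(rows)
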