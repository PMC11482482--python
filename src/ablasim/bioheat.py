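"""Transient Pennes bioheat integration on the axisymmetric grid.

Solves

    rho_T C_T dT/dt = k_T lap(T) + rho_b C_b omega_b (T_b - T) + Qm + Qext

with a conservative finite-volume discretization in (r, z) and implicit
backward-Euler time stepping (unconditionally stable on the graded grid).
The applicator interior is excluded from the solve: circulating coolant is
represented by a convective (Robin) flux h*(T_cool - T) on every needle-wall
face, the standard simplification for water-cooled shafts.  Outer domain
boundaries are held at the initial temperature by default (they sit tens of
millimeters from the heated zone); an insulated variant exists for the
energy-balance oracle.  Vaporization latent heat and temperature-dependent
properties are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .em import SARField
from .geometry import DomainGrid
from .materials import BloodProperties, MaterialTable

__all__ = [
    "ThermalConfig",
    "TemperatureHistory",
    "ProbeSet",
    "run_transient",
    "sample_probes",
    "default_phantom_probes",
]

ZERO_C = 273.15


@dataclass(frozen=True)
class ThermalConfig:
    """Settings of the transient thermal solve (SI units, temperatures in K
    except the coolant which is specified in degC as on the device)."""

    duration: float = 600.0
    time_step: float = 0.5
    snapshot_interval: float = 1.0
    initial_temperature: float = 290.15  # K
    blood: BloodProperties = field(default_factory=BloodProperties)
    coolant_temperature: float = 7.0  # degC
    coolant_heat_transfer_coefficient: float = 500.0  # W/(m^2 K)
    include_perfusion: bool = False
    include_metabolic: bool = False
    boundary: str = "dirichlet"  # or "insulated" (oracle hook)

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.time_step <= 0 or self.snapshot_interval <= 0:
            raise ValueError("time step and snapshot interval must be > 0")
        if self.boundary not in ("dirichlet", "insulated"):
            raise ValueError("boundary must be 'dirichlet' or 'insulated'")


@dataclass
class TemperatureHistory:
    """Snapshot stack of the temperature field plus the running maximum."""

    grid: DomainGrid
    times: np.ndarray  # (nt,) s, strictly increasing from 0
    fields: np.ndarray  # (nt, nr, nz) K
    max_field: np.ndarray  # (nr, nz) K, running maximum over the whole run

    def __post_init__(self) -> None:
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must strictly increase from 0")
        if not np.isfinite(self.fields).all():
            raise ValueError("temperature history contains non-finite values")

    @property
    def final(self) -> np.ndarray:
        return self.fields[-1]

    def peak_temperature(self, celsius: bool = True) -> float:
        """Largest temperature ever reached outside the applicator."""
        m = np.where(self.grid.needle_mask, -np.inf, self.max_field)
        t = float(np.max(m))
        return t - ZERO_C if celsius else t


@dataclass(frozen=True)
class ProbeSet:
    """Labelled (r, z) sampling locations in meters."""

    labels: tuple[str, ...]
    r: tuple[float, ...]
    z: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.r) == len(self.z)):
            raise ValueError("labels, r and z must have equal length")


def default_phantom_probes() -> ProbeSet:
    """Sensor positions of the phantom experiment: 10 mm and 20 mm from the
    axis at 18 mm above the tip, plus the 5 mm / 20 mm evaluation point."""
    return ProbeSet(
        labels=("r10mm_z18mm", "r20mm_z18mm", "r5mm_z20mm"),
        r=(10e-3, 20e-3, 5e-3),
        z=(18e-3, 18e-3, 20e-3),
    )


def _cell_properties(grid: DomainGrid, materials: MaterialTable):
    nr, nz = grid.nr, grid.nz
    rho_cp = np.empty((nr, nz))
    k = np.empty((nr, nz))
    omega_b = np.empty((nr, nz))
    qm = np.empty((nr, nz))
    for i, name in enumerate(grid.material_names):
        m = materials[name]
        sel = grid.material_ids == i
        rho_cp[sel] = m.density * m.specific_heat
        k[sel] = m.thermal_conductivity
        omega_b[sel] = m.perfusion_rate
        qm[sel] = m.metabolic_heat
    return rho_cp, k, omega_b, qm


def run_transient(
    grid: DomainGrid,
    materials: MaterialTable,
    source: SARField,
    config: ThermalConfig,
) -> TemperatureHistory:
    """Integrate the bioheat equation and return the snapshot history.

    The source is expected power-normalized; perfusion and metabolic terms
    are gated by the config flags (off for the phantom case).
    """
    if source.q_ext.shape != (grid.nr, grid.nz):
        raise ValueError("source and grid shapes do not match")
    nr, nz = grid.nr, grid.nz
    rho_cp, kcond, omega_b, qm = _cell_properties(grid, materials)
    if config.include_perfusion and config.blood is None:
        raise ValueError("perfusion enabled but no blood properties given")
    vol = grid.cell_volumes
    needle = grid.needle_mask
    solve = ~needle
    n_unk = int(solve.sum())
    index = -np.ones((nr, nz), dtype=np.int64)
    index[solve] = np.arange(n_unk)

    t_cool = config.coolant_temperature + ZERO_C
    h = config.coolant_heat_transfer_coefficient
    t_bc = config.initial_temperature

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_unk)
    const = np.zeros(n_unk)  # temperature-independent RHS contributions (W)

    def harmonic(ka, kb):
        s = ka + kb
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0, 2 * ka * kb / np.where(s > 0, s, 1.0), 0.0)
        return out

    # ---- radial faces -----------------------------------------------------
    area_r = 2 * np.pi * grid.r_edges[:, None] * grid.dz[None, :]  # (nr+1, nz)
    dist_r = np.diff(grid.r_centers)  # (nr-1,)
    kf = harmonic(kcond[:-1, :], kcond[1:, :])
    g_int = kf * area_r[1:nr, :] / dist_r[:, None]  # conductance (W/K)
    both = solve[:-1, :] & solve[1:, :]
    ia, ib = index[:-1, :][both], index[1:, :][both]
    g = g_int[both]
    rows += [ia, ib, ia, ib]
    cols += [ib, ia, ia, ib]
    vals += [-g, -g, g, g]
    # needle-wall Robin faces (solve cell next to applicator cell)
    for sl_solve, sl_needle, face in (
        ((slice(1, None), slice(None)), (slice(None, -1), slice(None)), area_r[1:nr, :]),
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None)), area_r[1:nr, :]),
    ):
        m = solve[sl_solve] & needle[sl_needle]
        iu = index[sl_solve][m]
        ga = h * face[m]
        np.add.at(diag, iu, ga)
        np.add.at(const, iu, ga * t_cool)
    # outer radial boundary
    if config.boundary == "dirichlet":
        m = solve[-1, :]
        iu = index[-1, :][m]
        g = (kcond[-1, :] * area_r[-1, :] / (grid.r_edges[-1] - grid.r_centers[-1]))[m]
        np.add.at(diag, iu, g)
        np.add.at(const, iu, g * t_bc)
    # axis face: symmetry, zero flux

    # ---- axial faces ------------------------------------------------------
    ring = np.pi * (grid.r_edges[1:] ** 2 - grid.r_edges[:-1] ** 2)  # (nr,)
    dist_z = np.diff(grid.z_centers)
    kf = harmonic(kcond[:, :-1], kcond[:, 1:])
    g_int = kf * ring[:, None] / dist_z[None, :]
    both = solve[:, :-1] & solve[:, 1:]
    ia, ib = index[:, :-1][both], index[:, 1:][both]
    g = g_int[both]
    rows += [ia, ib, ia, ib]
    cols += [ib, ia, ia, ib]
    vals += [-g, -g, g, g]
    for sl_solve, sl_needle in (
        ((slice(None), slice(1, None)), (slice(None), slice(None, -1))),
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
    ):
        m = solve[sl_solve] & needle[sl_needle]
        iu = index[sl_solve][m]
        ga = h * ring[np.nonzero(m)[0]]
        np.add.at(diag, iu, ga)
        np.add.at(const, iu, ga * t_cool)
    if config.boundary == "dirichlet":
        for j, dzz in ((0, grid.z_centers[0] - grid.z_edges[0]), (nz - 1, grid.z_edges[-1] - grid.z_centers[-1])):
            m = solve[:, j]
            iu = index[:, j][m]
            g = (kcond[:, j] * ring / dzz)[m]
            np.add.at(diag, iu, g)
            np.add.at(const, iu, g * t_bc)

    # ---- volumetric terms -------------------------------------------------
    perf = np.zeros((nr, nz))
    if config.include_perfusion:
        blood = config.blood
        perf = blood.density * blood.specific_heat * omega_b * vol
        diag += perf[solve]
        const += (perf * blood.temperature)[solve]
    q = source.q_ext * vol
    if config.include_metabolic:
        q = q + qm * vol
    const += q[solve]

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unk, n_unk),
    ).tocsr() + sp.diags(diag)

    dt = config.time_step
    cap = (rho_cp * vol)[solve] / dt
    A = (K + sp.diags(cap)).tocsc()
    lu = spla.splu(A)

    n_steps = int(round(config.duration / dt))
    every = max(1, int(round(config.snapshot_interval / dt)))

    T = np.full((nr, nz), float(config.initial_temperature))
    T[needle] = t_cool
    x = T[solve].copy()
    snapshots = [T.copy()]
    times = [0.0]
    max_field = T.copy()

    for step in range(1, n_steps + 1):
        x = lu.solve(cap * x + const)
        if not np.isfinite(x).all():
            raise RuntimeError(f"thermal solve diverged at step {step} (t = {step * dt:g} s)")
        # fancy-index max does not write back in place; do it explicitly
        mf = max_field[solve]
        np.maximum(mf, x, out=mf)
        max_field[solve] = mf
        if step % every == 0 or step == n_steps:
            T = np.full((nr, nz), t_cool)
            T[solve] = x
            snapshots.append(T.copy())
            times.append(step * dt)

    return TemperatureHistory(
        grid=grid,
        times=np.asarray(times),
        fields=np.asarray(snapshots),
        max_field=max_field,
    )


def _bilinear_weights(coords: np.ndarray, x: float):
    """Index pair and weights for linear interpolation with edge clamping."""
    i = int(np.searchsorted(coords, x)) - 1
    i = min(max(i, 0), len(coords) - 2)
    c0, c1 = coords[i], coords[i + 1]
    w = (x - c0) / (c1 - c0)
    w = min(max(w, 0.0), 1.0)
    return i, w


def sample_probes(history: TemperatureHistory, probes: ProbeSet) -> pd.DataFrame:
    """Bilinear probe sampling of every snapshot; output in degC.

    Probes must lie inside the domain and outside the applicator; within the
    half-cell margin next to a boundary the nearest in-cell value is used.
    """
    grid = history.grid
    rc, zc = grid.r_centers, grid.z_centers
    data: dict[str, np.ndarray] = {"time_s": history.times}
    for label, r, z in zip(probes.labels, probes.r, probes.z, strict=True):
        if not (grid.r_edges[0] <= r <= grid.r_edges[-1] and grid.z_edges[0] <= z <= grid.z_edges[-1]):
            raise ValueError(f"probe {label!r} at (r={r:g}, z={z:g}) lies outside the grid")
        ci = min(int(np.searchsorted(grid.r_edges, r, side="right")) - 1, grid.nr - 1)
        cj = min(int(np.searchsorted(grid.z_edges, z, side="right")) - 1, grid.nz - 1)
        if grid.needle_mask[ci, cj]:
            raise ValueError(f"probe {label!r} lies inside the applicator")
        i, wr = _bilinear_weights(rc, r)
        j, wz = _bilinear_weights(zc, z)
        block = history.fields[:, i : i + 2, j : j + 2]
        vals = (
            block[:, 0, 0] * (1 - wr) * (1 - wz)
            + block[:, 1, 0] * wr * (1 - wz)
            + block[:, 0, 1] * (1 - wr) * wz
            + block[:, 1, 1] * wr * wz
        )
        data[label] = vals - ZERO_C
    return pd.DataFrame(data)
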