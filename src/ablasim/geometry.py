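"""Applicator and domain geometry, and rasterization onto an axisymmetric grid.

Coordinate convention: axisymmetric (r, z) half-plane with the applicator on
the axis; z = 0 at the needle tip, z increasing toward the hub (offsets
"above the tip" are +z), r >= 0 from the axis.  The computational rectangle
is [0, domain_radius] x [z_min, z_max] with z_max = insertion depth below the
top surface of the medium.

The applicator is a monopole coaxial antenna: copper inner conductor, PTFE
dielectric, copper outer conductor interrupted by a radiating slot ~25 mm
above the tip, an outer catheter sheath, and a ceramic tip.  Nominal layer
radii follow a 50-ohm PTFE coax inside the published 1.45 mm outer diameter;
they are configurable because the true internals are proprietary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .materials import NEEDLE_MATERIALS

__all__ = [
    "NeedleSpec",
    "DomainSpec",
    "GridPolicy",
    "Region",
    "Geometry",
    "DomainGrid",
    "build_geometry",
    "rasterize",
    "uniform_grid",
]


@dataclass(frozen=True)
class NeedleSpec:
    """Monopole coaxial applicator geometry (meters unless noted)."""

    outer_diameter: float = 1.45e-3
    shaft_length: float = 0.150
    inner_conductor_radius: float = 0.145e-3
    dielectric_outer_radius: float = 0.50e-3
    outer_conductor_outer_radius: float = 0.60e-3
    catheter_outer_radius: float = 0.725e-3
    slot_center_offset_from_tip: float = 25e-3
    slot_width: float = 1.0e-3
    tip_length: float = 5.0e-3
    tip_material: str = "tip"
    coolant_temperature: float = 7.0  # degC
    coolant_heat_transfer_coefficient: float = 500.0  # W/(m^2 K)
    shielded: bool = False  # test hook: close the slot and cap the tip in copper

    def __post_init__(self) -> None:
        radii = (
            self.inner_conductor_radius,
            self.dielectric_outer_radius,
            self.outer_conductor_outer_radius,
            self.catheter_outer_radius,
        )
        if not all(b > a > 0 for a, b in zip(radii, radii[1:], strict=False)):
            raise ValueError("needle layer radii must be strictly increasing")
        if abs(self.catheter_outer_radius - self.outer_diameter / 2) > 1e-9:
            raise ValueError("catheter outer radius must equal outer_diameter / 2")
        if self.slot_center_offset_from_tip >= self.shaft_length:
            raise ValueError("slot must lie on the shaft")
        if self.slot_bottom < self.tip_length:
            raise ValueError("slot overlaps the tip region")

    @property
    def slot_bottom(self) -> float:
        return self.slot_center_offset_from_tip - self.slot_width / 2

    @property
    def slot_top(self) -> float:
        return self.slot_center_offset_from_tip + self.slot_width / 2

    @property
    def radius(self) -> float:
        return self.outer_diameter / 2


@dataclass(frozen=True)
class DomainSpec:
    """Cylindrical simulation domain (phantom column or liver block)."""

    case_kind: str = "phantom"
    domain_radius: float = 51.45e-3  # 102.9 mm inner diameter column
    domain_height: float = 125e-3
    insertion_depth: float = 80e-3  # needle tip depth below the top surface
    tumor_half_length: float = 5.5e-3  # half-axis along z (clinical only)
    tumor_half_width: float = 4.35e-3  # half-axis along r
    tumor_center_z: float = 25e-3  # relative to the needle tip
    initial_temperature: float = 290.15  # K

    def __post_init__(self) -> None:
        if self.case_kind not in ("phantom", "clinical"):
            raise ValueError("case_kind must be 'phantom' or 'clinical'")
        if not 0 < self.insertion_depth < self.domain_height:
            raise ValueError("domain must enclose the needle insertion depth")
        if self.case_kind == "clinical":
            if self.tumor_center_z + self.tumor_half_length > self.z_max:
                raise ValueError("tumor ellipse must lie inside the domain")
            if self.tumor_half_width > self.domain_radius:
                raise ValueError("tumor ellipse must lie inside the domain")

    @property
    def z_min(self) -> float:
        return -(self.domain_height - self.insertion_depth)

    @property
    def z_max(self) -> float:
        return self.insertion_depth


@dataclass(frozen=True)
class Region:
    """A closed axisymmetric region with a material label.

    ``contains(r, z)`` is vectorized; regions are queried in order and the
    first match wins, so they are listed innermost (applicator) first.
    """

    name: str
    material: str
    contains: Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class Geometry:
    regions: tuple[Region, ...]
    needle: NeedleSpec
    domain: DomainSpec

    def material_at(self, r: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Material label of each (r, z) point (first-match over regions)."""
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        out = np.full(r.shape, "", dtype=object)
        undecided = np.ones(r.shape, dtype=bool)
        for region in self.regions:
            hit = undecided & region.contains(r, z)
            out[hit] = region.material
            undecided &= ~hit
        if undecided.any():
            i = np.argwhere(undecided)[0]
            raise ValueError(f"geometry does not cover point index {tuple(i)}")
        return out


def _box(r0, r1, z0, z1):
    def contains(r, z):
        return (r >= r0) & (r < r1) & (z >= z0) & (z < z1)

    return contains


def build_geometry(needle: NeedleSpec, domain: DomainSpec) -> Geometry:
    """Assemble the closed region list partitioning the (r, z) rectangle.

    The slot region (gap in the outer conductor) carries the coax dielectric
    material; the tip region carries the tip material; the tissue (and, for a
    clinical case, the tumor ellipse) fills the remainder.
    """
    n, d = needle, domain
    top = d.z_max + 1e-12  # half-open boxes: include the top boundary row
    rin, rdi, rout, rcat = (
        n.inner_conductor_radius,
        n.dielectric_outer_radius,
        n.outer_conductor_outer_radius,
        n.catheter_outer_radius,
    )
    regions: list[Region] = []

    if n.shielded:
        # test hook: continuous outer conductor, copper plug instead of a tip
        regions += [
            Region("tip_plug", "outer_conductor", _box(0, rout, 0, n.tip_length)),
            Region("inner_conductor", "inner_conductor", _box(0, rin, n.tip_length, top)),
            Region("coax_dielectric", "dielectric", _box(rin, rdi, n.tip_length, top)),
            Region("outer_conductor", "outer_conductor", _box(rdi, rout, n.tip_length, top)),
            Region("catheter", "catheter", _box(rout, rcat, 0, top)),
        ]
    else:
        regions += [
            Region("tip", n.tip_material, _box(0, rcat, 0, n.tip_length)),
            Region("inner_conductor", "inner_conductor", _box(0, rin, n.tip_length, top)),
            Region("coax_dielectric", "dielectric", _box(rin, rdi, n.tip_length, top)),
            # outer conductor above and below the radiating slot
            Region("outer_conductor_upper", "outer_conductor", _box(rdi, rout, n.slot_top, top)),
            Region("slot", "dielectric", _box(rdi, rout, n.slot_bottom, n.slot_top)),
            Region(
                "outer_conductor_lower", "outer_conductor", _box(rdi, rout, n.tip_length, n.slot_bottom)
            ),
            Region("catheter", "catheter", _box(rout, rcat, n.tip_length, top)),
        ]

    if d.case_kind == "clinical":
        a, b, zc = d.tumor_half_width, d.tumor_half_length, d.tumor_center_z

        def in_tumor(r, z, a=a, b=b, zc=zc):
            return (r / a) ** 2 + ((z - zc) / b) ** 2 <= 1.0

        regions.append(Region("tumor", "tumor", in_tumor))

    tissue = "phantom" if d.case_kind == "phantom" else "liver"

    def everywhere(r, z):
        return np.ones(np.shape(r), dtype=bool)

    regions.append(Region("tissue", tissue, everywhere))
    return Geometry(regions=tuple(regions), needle=n, domain=d)


@dataclass(frozen=True)
class GridPolicy:
    """Graded-resolution policy for rasterization.

    Cell edges snap exactly to the needle layer radii and to the tip/slot z
    positions, so every applicator layer is resolved at any setting.  Cells
    are finest near the needle wall and the slot and coarsen outward.
    """

    fine_cell: float = 0.1e-3  # near needle wall / slot
    max_cell: float = 1.0e-3  # far-field cap
    cells_per_layer: tuple[int, int, int, int] = (2, 4, 2, 2)
    mid_cell: float = 0.5e-3

    @classmethod
    def coarse(cls) -> "GridPolicy":
        """Reduced resolution for quick runs and tests."""
        return cls(fine_cell=0.25e-3, max_cell=1.5e-3, cells_per_layer=(1, 2, 1, 1), mid_cell=1.0e-3)


@dataclass
class DomainGrid:
    """Cell-centered axisymmetric tensor grid with per-cell material labels."""

    r_edges: np.ndarray  # (nr+1,), r_edges[0] == 0
    z_edges: np.ndarray  # (nz+1,)
    material_names: list[str]  # index -> label
    material_ids: np.ndarray  # (nr, nz) int

    def __post_init__(self) -> None:
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        if self.r_edges[0] != 0.0:
            raise ValueError("grid must start on the axis (r_edges[0] == 0)")
        if np.any(np.diff(self.r_edges) <= 0) or np.any(np.diff(self.z_edges) <= 0):
            raise ValueError("grid edges must be strictly increasing")
        if self.material_ids.shape != (self.nr, self.nz):
            raise ValueError("material_ids shape mismatch")

    @property
    def nr(self) -> int:
        return len(self.r_edges) - 1

    @property
    def nz(self) -> int:
        return len(self.z_edges) - 1

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def dr(self) -> np.ndarray:
        return np.diff(self.r_edges)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def cell_volumes(self) -> np.ndarray:
        """(nr, nz) volumes of the solids of revolution pi*(r1^2-r0^2)*dz."""
        ring = np.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        return ring[:, None] * self.dz[None, :]

    def material_mask(self, *names: str) -> np.ndarray:
        ids = [self.material_names.index(n) for n in names if n in self.material_names]
        if not ids:
            return np.zeros((self.nr, self.nz), dtype=bool)
        return np.isin(self.material_ids, ids)

    @property
    def needle_mask(self) -> np.ndarray:
        return self.material_mask(*NEEDLE_MATERIALS)

    def label_array(self) -> np.ndarray:
        return np.asarray(self.material_names, dtype=object)[self.material_ids]


def _segment_edges(z0: float, z1: float, size: float) -> np.ndarray:
    """Uniform edges covering [z0, z1] with cells no larger than ``size``."""
    n = max(1, int(np.ceil((z1 - z0) / size - 1e-9)))
    return np.linspace(z0, z1, n + 1)


def _piecewise_edges(breaks: list[tuple[float, float]], stop: float) -> np.ndarray:
    """Concatenate uniform segments; ``breaks`` = [(start, cell size), ...]."""
    edges = [np.array([breaks[0][0]])]
    for (a, size), (b, _next) in zip(breaks, breaks[1:] + [(stop, 0.0)], strict=False):
        if b <= a + 1e-12:
            continue
        edges.append(_segment_edges(a, b, size)[1:])
    return np.concatenate(edges)


def rasterize(geometry: Geometry, policy: GridPolicy | None = None) -> DomainGrid:
    """Rasterize a geometry onto a graded axisymmetric grid.

    The material of each cell is the material of the region containing its
    center.  Edges snap to all needle layer radii and to the tip and slot z
    coordinates, so the thinnest layer is always resolved.
    """
    policy = policy or GridPolicy()
    n, d = geometry.needle, geometry.domain
    if policy.fine_cell > n.slot_width / 2:
        raise ValueError(
            f"fine cell {policy.fine_cell:g} m too coarse for slot width {n.slot_width:g} m"
        )

    # --- radial edges: snap to layer radii, then grade outward -------------
    layer_r = [0.0, n.inner_conductor_radius, n.dielectric_outer_radius,
               n.outer_conductor_outer_radius, n.catheter_outer_radius]
    r_edges = [np.array([0.0])]
    for (a, b), m in zip(zip(layer_r, layer_r[1:], strict=False), policy.cells_per_layer, strict=True):
        r_edges.append(np.linspace(a, b, m + 1)[1:])
    # graded growth from the needle wall out to the domain radius
    r = n.catheter_outer_radius
    size = policy.fine_cell
    grown = []
    while r < d.domain_radius - 1e-12:
        step = min(size, d.domain_radius - r)
        r += step
        grown.append(r)
        size = min(size * 1.2, policy.max_cell)
    r_edges.append(np.array(grown))
    r_edges = np.concatenate(r_edges)
    r_edges[-1] = d.domain_radius

    # --- axial edges: fine near slot and tip, graded elsewhere -------------
    st, sb, tl = n.slot_top, n.slot_bottom, n.tip_length
    breaks = [
        (d.z_min, policy.max_cell),
        (-10e-3, policy.mid_cell),
        (0.0, policy.mid_cell),
        (tl, policy.mid_cell),
        (sb - 3e-3, 2 * policy.fine_cell),
        (sb, policy.fine_cell),
        (st, 2 * policy.fine_cell),
        (st + 3e-3, policy.mid_cell),
        (st + 10e-3, policy.max_cell),
    ]
    breaks = [(max(b, d.z_min), s) for b, s in breaks]
    # drop out-of-order entries that collapse for unusual specs
    cleaned = [breaks[0]]
    for b, s in breaks[1:]:
        if b > cleaned[-1][0] + 1e-12:
            cleaned.append((b, s))
    z_edges = _piecewise_edges(cleaned, d.z_max)
    z_edges[-1] = d.z_max

    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    R, Z = np.meshgrid(rc, zc, indexing="ij")
    labels = geometry.material_at(R, Z)
    names = sorted(set(labels.ravel().tolist()))
    index = {name: i for i, name in enumerate(names)}
    ids = np.vectorize(index.__getitem__, otypes=[np.int32])(labels)

    grid = DomainGrid(r_edges=r_edges, z_edges=z_edges, material_names=names, material_ids=ids)
    _check_layers_resolved(grid, geometry)
    return grid


def _check_layers_resolved(grid: DomainGrid, geometry: Geometry) -> None:
    needed = {"inner_conductor", "dielectric", "outer_conductor", "catheter"}
    if geometry.needle.shielded:
        needed = {"inner_conductor", "dielectric", "outer_conductor", "catheter"}
    present = set(grid.material_names)
    missing = needed - present
    if missing:
        raise ValueError(f"grid too coarse to resolve needle layer(s): {sorted(missing)}")


def uniform_grid(
    radius: float,
    z_min: float,
    z_max: float,
    cell: float,
    material: str = "liver",
) -> DomainGrid:
    """Homogeneous single-material cylinder on a uniform grid (oracle helper)."""
    r_edges = _segment_edges(0.0, radius, cell)
    z_edges = _segment_edges(z_min, z_max, cell)
    ids = np.zeros((len(r_edges) - 1, len(z_edges) - 1), dtype=np.int32)
    return DomainGrid(r_edges=r_edges, z_edges=z_edges, material_names=[material], material_ids=ids)
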