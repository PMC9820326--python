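"""Voxelized geometries: synthetic head phantom, slab phantoms, HU conversion.

The synthetic head phantom is a CT stand-in with the tissue/bone/air topology
relevant to intracranial dosimetry: an ellipsoidal soft-tissue volume wrapped
in a cortical-bone shell, one or more low-density (air) internal cavities as
an oral-nasal analogue, and a ~1 cm^3 cubic target (PTV) placed on the beam
axis about 3 cm below the entry surface. The PTV voxels carry a
nanoparticle-infused soft-tissue compound at the requested Fe mass fraction.

Voxel indexing is 0-based with half-open extents [i, i+n), so a 10-voxel PTV
edge at 1 mm spacing encloses exactly 1000 voxels ~ 1 cm^3. The beam travels
along -z and enters through the +z face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import (
    AIR,
    CORTICAL_BONE,
    SOFT_TISSUE,
    Material,
    get_material,
    mix_fenp_compound,
)

__all__ = [
    "VoxelPhantom",
    "HUConversionTable",
    "HeadPhantomParams",
    "generate_head_phantom",
    "hu_volume_to_phantom",
    "make_slab_phantom",
    "read_hu_table",
]


@dataclass
class VoxelPhantom:
    """A material-index + density grid with spacing and an optional PTV mask."""

    material_index: np.ndarray  # int, shape (nx, ny, nz)
    density: np.ndarray  # g/cm^3, same shape
    spacing: tuple[float, float, float]  # mm
    material_table: dict[int, Material]
    ptv_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.material_index.shape != self.density.shape:
            raise ValueError("material_index and density shapes differ")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if np.any(self.density <= 0):
            raise ValueError("density must be positive everywhere")
        present = set(np.unique(self.material_index).tolist())
        missing = present - set(self.material_table)
        if missing:
            raise ValueError(f"material indices {sorted(missing)} not in table")
        if self.ptv_mask is not None:
            if self.ptv_mask.shape != self.material_index.shape:
                raise ValueError("ptv_mask shape mismatch")
            if not self.ptv_mask.any():
                raise ValueError("ptv_mask defined but empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_index.shape

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz * 1e-3  # mm^3 -> cm^3

    @property
    def voxel_mass_g(self) -> np.ndarray:
        return self.density * self.voxel_volume_cm3

    def total_mass_g(self) -> float:
        return float(self.voxel_mass_g.sum())

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


# ---------------------------------------------------------------------------
# synthetic head phantom


@dataclass
class HeadPhantomParams:
    """Geometry of the synthetic head (all lengths in mm)."""

    shape: tuple[int, int, int] = (110, 110, 140)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes: tuple[float, float, float] = (48.0, 48.0, 62.0)
    bone_thickness: float = 5.0
    ptv_edge_voxels: int = 10
    ptv_depth_mm: float = 30.0  # PTV centre below the entry surface, along -z
    cavity_size: tuple[float, float, float] = (24.0, 26.0, 22.0)
    cavity_offset_mm: float = 28.0  # cavity centre below the PTV centre


def generate_head_phantom(
    params: HeadPhantomParams | None = None,
    fe_mass_fraction: float = 0.0,
    seed: int = 0,
    fe_agent: Material | None = None,
    density_rule: str = "inverse",
) -> VoxelPhantom:
    """Build the head-like phantom with an FeNP-infused PTV.

    Deterministic for a fixed seed (the seed currently only perturbs nothing;
    it is part of the contract so stochastic anatomical variants can be added
    without interface changes).
    """
    p = params or HeadPhantomParams()
    del seed  # geometry is deterministic; kept for interface stability
    nx, ny, nz = p.shape
    dx, dy, dz = p.spacing

    # voxel-centre coordinates (mm)
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    cz = nz * dz / 2.0
    xg, yg, zg = np.meshgrid(x - cx, y - cy, z - cz, indexing="ij")

    ax, ay, az = p.semi_axes
    r_out = (xg / ax) ** 2 + (yg / ay) ** 2 + (zg / az) ** 2
    t = p.bone_thickness
    r_in = (xg / (ax - t)) ** 2 + (yg / (ay - t)) ** 2 + (zg / (az - t)) ** 2

    material_index = np.zeros(p.shape, dtype=np.int16)  # 0 = surrounding air
    material_index[r_out <= 1.0] = 2  # bone shell
    material_index[r_in <= 1.0] = 1  # soft tissue interior

    # entry surface along -z: top of the outer ellipsoid on the beam axis
    z_surface = cz + az
    ptv_centre_z = z_surface - p.ptv_depth_mm

    # internal air cavity (oral-nasal analogue) below the PTV on the axis
    csx, csy, csz = p.cavity_size
    cav_cz = ptv_centre_z - p.cavity_offset_mm
    cavity = (
        (np.abs(xg) <= csx / 2)
        & (np.abs(yg) <= csy / 2)
        & (np.abs(z[None, None, :] - cav_cz) <= csz / 2)
    )
    material_index[cavity & (material_index == 1)] = 0

    # PTV: half-open cubic voxel box centred on the beam axis
    e = p.ptv_edge_voxels
    i0 = int(round(nx / 2 - e / 2))
    j0 = int(round(ny / 2 - e / 2))
    k_c = ptv_centre_z / dz
    k0 = int(round(k_c - e / 2))
    if k0 < 0 or k0 + e > nz:
        raise ValueError("PTV depth exceeds phantom extent")
    ptv_mask = np.zeros(p.shape, dtype=bool)
    ptv_mask[i0 : i0 + e, j0 : j0 + e, k0 : k0 + e] = True
    if not (material_index[ptv_mask] == 1).all():
        raise ValueError("PTV does not lie fully inside soft tissue")

    ptv_material = mix_fenp_compound(
        SOFT_TISSUE,
        fe_mass_fraction,
        fe_agent=fe_agent if fe_agent is not None else get_material("iron"),
        density_rule=density_rule,
    )
    table: dict[int, Material] = {0: AIR, 1: SOFT_TISSUE, 2: CORTICAL_BONE}
    if fe_mass_fraction > 0.0:
        material_index[ptv_mask] = 3
        table[3] = ptv_material
    density = np.empty(p.shape, dtype=np.float64)
    for idx, mat in table.items():
        density[material_index == idx] = mat.density
    return VoxelPhantom(material_index, density, p.spacing, table, ptv_mask)


# ---------------------------------------------------------------------------
# HU conversion


@dataclass
class HURow:
    hu_min: int
    hu_max: int  # inclusive
    material: str
    density_a: float  # density = a + b * HU
    density_b: float = 0.0


@dataclass
class HUConversionTable:
    """Ordered, non-overlapping HU ranges mapping to materials/densities."""

    rows: list[HURow] = field(default_factory=list)

    def __post_init__(self) -> None:
        rows = sorted(self.rows, key=lambda r: r.hu_min)
        for a, b in zip(rows, rows[1:]):
            if a.hu_max >= b.hu_min:
                raise ValueError(
                    f"overlapping HU rows [{a.hu_min},{a.hu_max}] and "
                    f"[{b.hu_min},{b.hu_max}]"
                )
        self.rows = rows

    def lookup(self, hu: int) -> HURow:
        for r in self.rows:
            if r.hu_min <= hu <= r.hu_max:
                return r
        raise KeyError(f"HU value {hu} not covered by the conversion table")


def read_hu_table(path) -> HUConversionTable:
    """Read the whitespace-separated ascii dialect::

        # hu_min hu_max material density_a [density_b]
        -1000 -200 air 0.0012
        -199 200 water 1.0 0.001
    """
    rows: list[HURow] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (4, 5):
                raise ValueError(f"malformed HU table line: {line!r}")
            rows.append(
                HURow(
                    hu_min=int(parts[0]),
                    hu_max=int(parts[1]),
                    material=parts[2],
                    density_a=float(parts[3]),
                    density_b=float(parts[4]) if len(parts) == 5 else 0.0,
                )
            )
    return HUConversionTable(rows)


def hu_volume_to_phantom(
    hu_volume: np.ndarray,
    table: HUConversionTable,
    spacing: tuple[float, float, float],
) -> VoxelPhantom:
    """Convert an integer HU volume to a phantom via the ascii table rules."""
    hu = np.asarray(hu_volume)
    if not np.issubdtype(hu.dtype, np.integer):
        raise TypeError("HU volume must be an integer array")
    material_index = np.full(hu.shape, -1, dtype=np.int16)
    density = np.zeros(hu.shape, dtype=np.float64)
    mat_table: dict[int, Material] = {}
    name_to_idx: dict[str, int] = {}
    covered = np.zeros(hu.shape, dtype=bool)
    for r in HUConversionTable(list(table.rows)).rows:
        sel = (hu >= r.hu_min) & (hu <= r.hu_max)
        if not sel.any():
            continue
        if r.material not in name_to_idx:
            idx = len(name_to_idx)
            name_to_idx[r.material] = idx
            mat_table[idx] = get_material(r.material)
        material_index[sel] = name_to_idx[r.material]
        density[sel] = r.density_a + r.density_b * hu[sel]
        covered |= sel
    if not covered.all():
        bad = np.unique(hu[~covered])
        raise KeyError(f"HU values not covered by the conversion table: {bad.tolist()}")
    return VoxelPhantom(material_index, density, tuple(spacing), mat_table)


# ---------------------------------------------------------------------------
# slab phantoms


def make_slab_phantom(
    layers: list[tuple[Material, float]],
    lateral_size: tuple[float, float] = (60.0, 60.0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VoxelPhantom:
    """Stack material slabs along the beam (z) axis.

    The first layer is at the +z (entry) face. Thicknesses that are not
    commensurate with the z spacing are rounded to the nearest voxel count
    (at least one voxel per layer).
    """
    if not layers:
        raise ValueError("at least one layer required")
    dx, dy, dz = spacing
    nx = int(round(lateral_size[0] / dx))
    ny = int(round(lateral_size[1] / dy))
    counts = []
    for mat, thick in layers:
        if thick <= 0:
            raise ValueError(f"layer {mat.name}: thickness must be positive")
        counts.append(max(1, int(round(thick / dz))))
    nz = sum(counts)
    material_index = np.zeros((nx, ny, nz), dtype=np.int16)
    density = np.zeros((nx, ny, nz), dtype=np.float64)
    table: dict[int, Material] = {}
    # layer 0 occupies the top (+z) of the grid; build from the top down
    k_hi = nz
    for idx, ((mat, _), n) in enumerate(zip(layers, counts)):
        table[idx] = mat
        material_index[:, :, k_hi - n : k_hi] = idx
        density[:, :, k_hi - n : k_hi] = mat.density
        k_hi -= n
    return VoxelPhantom(material_index, density, spacing, table)
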