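"""Voxel Monte Carlo photon/electron transport in a uniform magnetic field.

Photons undergo analog transport with Woodcock (majorant) free-path sampling
against the voxel grid: photoelectric absorption (with Fe K-shell
relaxation), Compton scattering with exact Klein-Nishina kinematics, and
pair production. Secondary electrons and positrons are tracked with a
condensed-history scheme: continuous energy loss along the step (collision
plus locally deposited radiative losses), Highland/Gaussian multiple
scattering, and the exact helical rotation of the direction vector about the
magnetic field axis. The Lorentz force rotates the direction only - it never
changes the kinetic energy. Positrons annihilate at rest into two back-to-
back 0.511 MeV photons.

Histories are processed in large numpy batches; a run consists of
independent cycles with sub-seeds spawned from (seed, cycle index) so that
cycles are reproducible and statistically independent. Per-history energy is
conserved exactly up to float accumulation: every cycle asserts
energy_in == deposits + escapes to 1e-6 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamSpec, sample_primaries
from .materials import (
    ELECTRON_REST_MEV,
    ELEMENTS,
    ENERGY_MAX_MEV,
    ENERGY_MIN_MEV,
    FE_K_ALPHA_MEV,
    FE_K_EDGE_MEV,
    FE_K_FLUORESCENCE_YIELD,
    Material,
    build_stopping_power_model,
    mu_compton,
    mu_pair,
    mu_photoelectric,
    _element_pe_mass_coeff,
)
from .phantom import VoxelPhantom

__all__ = [
    "ParticleState",
    "FieldSpec",
    "TransportConfig",
    "ScoringGrids",
    "sample_primary",
    "charged_step",
    "run_simulation",
    "gyroradius_mm",
]

_ANNIHILATION_MEV = 2.0 * ELECTRON_REST_MEV


@dataclass
class ParticleState:
    """A single particle, mainly used by the stepping API and tests."""

    kind: str  # "photon" | "electron" | "positron"
    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    kinetic_energy: float  # MeV
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction norm {norm} != 1")
        if self.kinetic_energy < 0 or self.weight <= 0:
            raise ValueError("invalid particle state")

    @property
    def charge_sign(self) -> int:
        return {"photon": 0, "electron": -1, "positron": +1}[self.kind]


@dataclass
class FieldSpec:
    """Uniform static magnetic field; the electric field is fixed to zero."""

    B: tuple[float, float, float] = (0.0, 0.0, 0.0)  # tesla

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.B))

    @property
    def unit(self) -> np.ndarray:
        b = np.asarray(self.B, dtype=float)
        m = np.linalg.norm(b)
        return b / m if m > 0 else np.array([0.0, 0.0, 1.0])


@dataclass
class TransportConfig:
    n_primaries: int = 200_000
    n_cycles: int = 5
    photon_cutoff_mev: float = 0.001
    electron_cutoff_mev: float = 0.001
    seed: int = 0
    max_step_mm: float = 1.0
    gyro_step_fraction: float = 0.1
    #: cap on the fractional energy loss per condensed step, kept small so
    #: single-step deposits stay well below typical voxel doses
    max_energy_loss_fraction: float = 0.05
    #: residual CSDA range below which an electron deposits locally; a
    #: voxel-scale range-rejection that leaves millimetre dose unchanged
    range_rejection_mm: float = 0.3
    score_fluence: bool = True
    batch_size: int = 50_000
    max_electron_iterations: int = 40_000

    def __post_init__(self) -> None:
        if self.photon_cutoff_mev < 0.001 or self.electron_cutoff_mev < 0.001:
            raise ValueError("cut-offs below the 0.001 MeV transport floor")
        if self.n_cycles < 2:
            raise ValueError("need >= 2 cycles for batch variance estimation")


@dataclass
class ScoringGrids:
    """Per-cycle scored grids plus run metadata.

    ``energy_deposit`` is GeV per cycle per voxel; the fluence grids are
    track length estimators in cm per cm^3 per primary. ``fluence_primary``
    counts photon path segments before the first real interaction only.
    """

    energy_deposit: np.ndarray  # (n_cycles, nx, ny, nz), GeV
    fluence_primary: np.ndarray
    fluence_charged: np.ndarray
    n_primaries: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return self.energy_deposit.shape[0]


def gyroradius_mm(kinetic_energy_mev: float, b_tesla: float) -> float:
    """Full-momentum helix radius r = pc / (0.29979 B) in mm."""
    pc = math.sqrt(kinetic_energy_mev**2 + 2.0 * kinetic_energy_mev * ELECTRON_REST_MEV)
    return pc / (0.29979 * b_tesla)


def sample_primary(beam: BeamSpec, rng: np.random.Generator, phantom: VoxelPhantom, n: int = 1):
    """Draw primary photon states from the beam model (see beam module)."""
    pos, dirs, e = sample_primaries(beam, n, rng, phantom.extent_mm())
    return pos, dirs, e


# ---------------------------------------------------------------------------
# geometry helpers


def _rotate_about_axis(u: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of row vectors u about a fixed unit axis."""
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    ax = axis[None, :]
    cross = np.cross(np.broadcast_to(ax, u.shape), u)
    dot = (u @ axis)[:, None]
    return u * c + cross * s + ax * dot * (1.0 - c)


def _deflect(u: np.ndarray, theta_x: np.ndarray, theta_y: np.ndarray) -> np.ndarray:
    """Small-angle deflection of unit vectors u by independent Gaussian
    projected angles in two orthogonal transverse directions."""
    # build an orthonormal frame (e1, e2, u)
    helper = np.where(np.abs(u[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(helper, u)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    v = u + theta_x[:, None] * e1 + theta_y[:, None] * e2
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _scatter_direction(u: np.ndarray, cos_t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors u by polar angle acos(cos_t) with uniform azimuth."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = 2.0 * math.pi * rng.random(len(u))
    helper = np.where(np.abs(u[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(helper, u)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    v = (
        u * cos_t[:, None]
        + (np.cos(phi) * sin_t)[:, None] * e1
        + (np.sin(phi) * sin_t)[:, None] * e2
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    cos_t = 2.0 * rng.random(n) - 1.0
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * math.pi * rng.random(n)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


# ---------------------------------------------------------------------------
# tabulated material data for the inner loop


class _EngineTables:
    """Per-material log-energy lookup tables congruent with the phantom."""

    N_GRID = 512

    def __init__(self, phantom: VoxelPhantom):
        keys = sorted(phantom.material_table)
        self.materials: list[Material] = [phantom.material_table[k] for k in keys]
        remap = np.full(max(keys) + 1, -1, dtype=np.int16)
        for row, k in enumerate(keys):
            remap[k] = row
        self.compact_index = remap[phantom.material_index]  # (nx,ny,nz) rows
        if np.any(self.compact_index < 0):
            raise ValueError("phantom material index not covered by table")

        self.grid = np.geomspace(ENERGY_MIN_MEV, ENERGY_MAX_MEV, self.N_GRID)
        self.log_e0 = math.log(self.grid[0])
        self.dlog = math.log(self.grid[1]) - self.log_e0

        m = len(self.materials)
        n = self.N_GRID
        self.mu_pe = np.zeros((m, n))
        self.mu_co = np.zeros((m, n))
        self.mu_pp = np.zeros((m, n))
        self.fe_pe_frac = np.zeros((m, n))
        self.s_tot = np.zeros((m, n))  # total mass stopping power MeV cm^2/g
        self.csda = np.zeros((m, n))  # g/cm^2
        self.x0_mass = np.zeros(m)  # radiation length g/cm^2
        for i, mat in enumerate(self.materials):
            self.mu_pe[i] = mu_photoelectric(mat, self.grid)
            self.mu_co[i] = mu_compton(mat, self.grid)
            self.mu_pp[i] = mu_pair(mat, self.grid)
            w_fe = mat.mass_fractions.get("Fe", 0.0)
            if w_fe > 0:
                fe_pe = w_fe * _element_pe_mass_coeff(ELEMENTS["Fe"], self.grid)
                self.fe_pe_frac[i] = np.where(self.mu_pe[i] > 0, fe_pe / self.mu_pe[i], 0.0)
            spm = build_stopping_power_model(mat, self.grid)
            self.s_tot[i] = spm.collision_stopping_power / (1.0 - spm.radiative_fraction)
            self.csda[i] = spm.csda_range
            self.x0_mass[i] = _radiation_length(mat)
        self.mu_tot = self.mu_pe + self.mu_co + self.mu_pp

        rho_max = np.zeros(m)
        for i in range(m):
            sel = self.compact_index == i
            rho_max[i] = phantom.density[sel].max() if sel.any() else 0.0
        # 1% pad absorbs log-linear interpolation error in the majorant
        self.mu_majorant = 1.01 * (self.mu_tot * rho_max[:, None]).max(axis=0)

    def _locate(self, e: np.ndarray):
        k = (np.log(np.clip(e, self.grid[0], self.grid[-1])) - self.log_e0) / self.dlog
        i = np.clip(k.astype(np.int64), 0, self.N_GRID - 2)
        return i, k - i

    def interp_row(self, table: np.ndarray, m: np.ndarray, e: np.ndarray) -> np.ndarray:
        i, f = self._locate(e)
        return table[m, i] * (1.0 - f) + table[m, i + 1] * f

    def interp_flat(self, table: np.ndarray, e: np.ndarray) -> np.ndarray:
        i, f = self._locate(e)
        return table[i] * (1.0 - f) + table[i + 1] * f


def _radiation_length(mat: Material) -> float:
    inv = 0.0
    for sym, w in mat.mass_fractions.items():
        el = ELEMENTS[sym]
        x0 = 716.4 * el.A / (el.Z * (el.Z + 1) * math.log(287.0 / math.sqrt(el.Z)))
        inv += w / x0
    return 1.0 / inv


# ---------------------------------------------------------------------------
# public single-particle stepping (exact helix + CSDA loss)


def charged_step(
    state: ParticleState,
    field_spec: FieldSpec,
    material: Material,
    step_mm: float,
    rng: np.random.Generator | None = None,
) -> tuple[ParticleState, float]:
    """Advance one charged particle by ``step_mm`` of path length.

    The direction is rotated by the exact helix angle about the field axis
    (midpoint rule: half rotation, straight move, half rotation), the energy
    is reduced by the collision stopping power integrated over the path, and
    the deposit is returned. Magnetic rotation itself changes no energy.
    Multiple scattering is applied only when an ``rng`` is supplied.
    """
    if state.kind == "photon":
        raise ValueError("charged_step applies to electrons/positrons only")
    if state.kinetic_energy < ENERGY_MIN_MEV:
        raise ValueError("particle below transport cut-off")
    u = state.direction.copy()
    if not np.all(np.isfinite(u)) or np.linalg.norm(u) == 0:
        raise FloatingPointError("invalid direction")
    b_mag = field_spec.magnitude
    pos = state.position.copy()
    if b_mag > 0:
        r_mm = gyroradius_mm(state.kinetic_energy, b_mag)
        angle = -state.charge_sign * step_mm / r_mm
        axis = field_spec.unit
        u = _rotate_about_axis(u[None, :], axis, np.array([angle / 2.0]))[0]
        pos = pos + u * step_mm
        u = _rotate_about_axis(u[None, :], axis, np.array([angle / 2.0]))[0]
    else:
        pos = pos + u * step_mm

    spm = build_stopping_power_model(material)
    s_col = np.interp(
        math.log(state.kinetic_energy), np.log(spm.energy_grid), spm.collision_stopping_power
    )
    deposit = min(state.kinetic_energy, float(s_col) * material.density * step_mm / 10.0)
    t_new = state.kinetic_energy - deposit

    if rng is not None and t_new > ENERGY_MIN_MEV:
        x_over_x0 = (step_mm / 10.0) * material.density / _radiation_length(material)
        if x_over_x0 > 0:
            theta0 = _highland_theta0(np.array([state.kinetic_energy]), np.array([x_over_x0]))[0]
            u = _deflect(u[None, :], rng.normal(0, theta0, 1), rng.normal(0, theta0, 1))[0]

    new_state = ParticleState(
        kind=state.kind,
        position=pos,
        direction=u / np.linalg.norm(u),
        kinetic_energy=max(t_new, 0.0),
        weight=state.weight,
    )
    return new_state, deposit


def _highland_theta0(t_mev: np.ndarray, x_over_x0: np.ndarray) -> np.ndarray:
    tau = t_mev / ELECTRON_REST_MEV
    pc = np.sqrt(t_mev**2 + 2.0 * t_mev * ELECTRON_REST_MEV)
    beta = np.sqrt(tau * (tau + 2.0)) / (tau + 1.0)
    log_corr = np.clip(1.0 + 0.038 * np.log(np.maximum(x_over_x0, 1e-12)), 0.25, None)
    return 13.6 / (beta * pc) * np.sqrt(x_over_x0) * log_corr


# ---------------------------------------------------------------------------
# the batched engine


class _CycleScorer:
    def __init__(self, shape, score_fluence: bool):
        self.edep = np.zeros(shape, dtype=np.float64)  # MeV
        self.score_fluence = score_fluence
        self.fl_primary = np.zeros(shape, dtype=np.float64)  # mm of track
        self.fl_charged = np.zeros(shape, dtype=np.float64)
        self.energy_in = 0.0
        self.escaped = 0.0
        self.track_len_electron = 0.0
        self.track_len_positron = 0.0


def _voxel_flat_index(pos_mm, spacing, shape):
    """Flat voxel index and in-grid mask for row positions."""
    i = np.floor(pos_mm[:, 0] / spacing[0]).astype(np.int64)
    j = np.floor(pos_mm[:, 1] / spacing[1]).astype(np.int64)
    k = np.floor(pos_mm[:, 2] / spacing[2]).astype(np.int64)
    inside = (
        (i >= 0) & (i < shape[0]) & (j >= 0) & (j < shape[1]) & (k >= 0) & (k < shape[2])
    )
    flat = (i * shape[1] + j) * shape[2] + k
    return np.where(inside, flat, 0), inside


def _score_track_lengths(scorer_grid, pos, dirs, lengths_mm, spacing, shape, sub_mm):
    """March substeps along straight segments, adding in-grid substep lengths
    to the voxel containing each substep midpoint."""
    n_sub = np.maximum(1, np.ceil(lengths_mm / sub_mm).astype(np.int64))
    max_sub = int(n_sub.max()) if len(n_sub) else 0
    flat_grid = scorer_grid.reshape(-1)
    ds = lengths_mm / n_sub
    for j in range(max_sub):
        act = n_sub > j
        if not act.any():
            break
        mid = pos[act] + dirs[act] * ((j + 0.5) * ds[act])[:, None]
        flat, inside = _voxel_flat_index(mid, spacing, shape)
        np.add.at(flat_grid, flat[inside], ds[act][inside])


def _sample_compton(e0: np.ndarray, rng: np.random.Generator):
    """Klein-Nishina energy-fraction sampling (standard two-branch
    rejection). Returns (eps, cos_theta)."""
    k = e0 / ELECTRON_REST_MEV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    alpha1 = -np.log(eps_min)
    alpha2 = 0.5 * (1.0 - eps_min**2)
    eps = np.empty_like(e0)
    cos_t = np.empty_like(e0)
    todo = np.arange(len(e0))
    while len(todo):
        km = k[todo]
        em = eps_min[todo]
        a1 = alpha1[todo]
        a2 = alpha2[todo]
        u1, u2, u3 = rng.random((3, len(todo)))
        branch1 = u1 < a1 / (a1 + a2)
        e_try = np.where(branch1, em * np.exp(a1 * u2), np.sqrt(em**2 + (1.0 - em**2) * u2))
        ct = 1.0 - (1.0 - e_try) / (km * e_try)
        sin2 = np.clip(1.0 - ct**2, 0.0, None)
        g = 1.0 - e_try * sin2 / (1.0 + e_try**2)
        ok = u3 <= g
        idx = todo[ok]
        eps[idx] = e_try[ok]
        cos_t[idx] = ct[ok]
        todo = todo[~ok]
    return eps, cos_t


class _Bank:
    """Structure-of-arrays particle bank."""

    def __init__(self, pos=None, dirs=None, energy=None, charge=None, primary=None):
        z3 = np.zeros((0, 3))
        z = np.zeros(0)
        self.pos = z3 if pos is None else pos
        self.dirs = z3 if dirs is None else dirs
        self.energy = z if energy is None else energy
        self.charge = np.zeros(0, dtype=np.int8) if charge is None else charge
        self.primary = np.zeros(0, dtype=bool) if primary is None else primary

    def __len__(self) -> int:
        return len(self.energy)

    @staticmethod
    def concat(banks):
        banks = [b for b in banks if len(b)]
        if not banks:
            return _Bank()
        return _Bank(
            pos=np.concatenate([b.pos for b in banks]),
            dirs=np.concatenate([b.dirs for b in banks]),
            energy=np.concatenate([b.energy for b in banks]),
            charge=np.concatenate([b.charge for b in banks]),
            primary=np.concatenate([b.primary for b in banks]),
        )


def _transport_photons(
    bank: _Bank,
    tables: _EngineTables,
    phantom: VoxelPhantom,
    config: TransportConfig,
    scorer: _CycleScorer,
    rng: np.random.Generator,
) -> _Bank:
    """Track a photon bank to extinction; returns the charged-particle bank."""
    spacing = phantom.spacing
    shape = phantom.shape
    sub_mm = min(spacing)
    density_flat = phantom.density.reshape(-1)
    mat_flat = tables.compact_index.reshape(-1)
    edep_flat = scorer.edep.reshape(-1)

    out_pos, out_dir, out_e, out_q = [], [], [], []

    pos, dirs, e, primary = bank.pos, bank.dirs, bank.energy, bank.primary
    while len(e):
        mu_maj = tables.interp_flat(tables.mu_majorant, e)  # 1/cm
        s_mm = -np.log(rng.random(len(e))) / mu_maj * 10.0
        if scorer.score_fluence and primary.any():
            # primary fluence counts pre-first-interaction segments; clip
            # the in-grid portion implicitly via midpoint rejection
            _score_track_lengths(
                scorer.fl_primary, pos[primary], dirs[primary], s_mm[primary], spacing, shape, sub_mm
            )
        pos = pos + dirs * s_mm[:, None]
        flat, inside = _voxel_flat_index(pos, spacing, shape)
        scorer.escaped += float(e[~inside].sum())
        if not inside.all():
            pos, dirs, e, primary, flat = (
                pos[inside],
                dirs[inside],
                e[inside],
                primary[inside],
                flat[inside],
            )
        if not len(e):
            break
        m = mat_flat[flat]
        rho = density_flat[flat]
        mu_tot = tables.interp_row(tables.mu_tot, m, e) * rho
        mu_maj = tables.interp_flat(tables.mu_majorant, e)
        real = rng.random(len(e)) < np.minimum(mu_tot / mu_maj, 1.0)
        if not real.any():
            continue

        # split interacting subset
        r_pos, r_dir, r_e = pos[real], dirs[real], e[real]
        r_flat, r_m = flat[real], m[real]
        pos, dirs, e, primary = pos[~real], dirs[~real], e[~real], primary[~real]

        mu_pe = tables.interp_row(tables.mu_pe, r_m, r_e)
        mu_co = tables.interp_row(tables.mu_co, r_m, r_e)
        mu_pp = tables.interp_row(tables.mu_pp, r_m, r_e)
        xi = rng.random(len(r_e)) * (mu_pe + mu_co + mu_pp)
        is_pe = xi < mu_pe
        is_co = (~is_pe) & (xi < mu_pe + mu_co)
        is_pp = ~(is_pe | is_co)

        new_photons = []

        # --- photoelectric (with Fe K relaxation)
        if is_pe.any():
            p_e = r_e[is_pe]
            p_flat = r_flat[is_pe]
            fe_frac = tables.interp_row(tables.fe_pe_frac, r_m[is_pe], p_e)
            on_fe = (rng.random(len(p_e)) < fe_frac) & (p_e > FE_K_EDGE_MEV)
            t_electron = np.where(on_fe, p_e - FE_K_EDGE_MEV, p_e)
            binding_local = np.where(on_fe, FE_K_EDGE_MEV, 0.0)
            fluor = on_fe & (rng.random(len(p_e)) < FE_K_FLUORESCENCE_YIELD)
            binding_local = binding_local - np.where(fluor, FE_K_ALPHA_MEV, 0.0)
            np.add.at(edep_flat, p_flat, binding_local)
            out_pos.append(r_pos[is_pe])
            out_dir.append(r_dir[is_pe])
            out_e.append(t_electron)
            out_q.append(np.full(is_pe.sum(), -1, dtype=np.int8))
            if fluor.any():
                nf = int(fluor.sum())
                new_photons.append(
                    _Bank(
                        pos=r_pos[is_pe][fluor],
                        dirs=_isotropic_directions(nf, rng),
                        energy=np.full(nf, FE_K_ALPHA_MEV),
                        charge=np.zeros(nf, dtype=np.int8),
                        primary=np.zeros(nf, dtype=bool),
                    )
                )

        # --- Compton (exact kinematic closure E0 = E' + T_e)
        if is_co.any():
            c_e = r_e[is_co]
            c_dir = r_dir[is_co]
            eps, cos_t = _sample_compton(c_e, rng)
            e_sc = eps * c_e
            t_e = c_e - e_sc
            new_dir = _scatter_direction(c_dir, cos_t, rng)
            # electron direction from momentum conservation
            pe_vec = c_e[:, None] * c_dir - e_sc[:, None] * new_dir
            pe_norm = np.linalg.norm(pe_vec, axis=1, keepdims=True)
            pe_vec = np.where(pe_norm > 1e-12, pe_vec / np.maximum(pe_norm, 1e-12), c_dir)
            out_pos.append(r_pos[is_co])
            out_dir.append(pe_vec)
            out_e.append(t_e)
            out_q.append(np.full(is_co.sum(), -1, dtype=np.int8))
            # scattered photon continues (no longer primary)
            above = e_sc >= config.photon_cutoff_mev
            np.add.at(edep_flat, r_flat[is_co][~above], e_sc[~above])
            new_photons.append(
                _Bank(
                    pos=r_pos[is_co][above],
                    dirs=new_dir[above],
                    energy=e_sc[above],
                    charge=np.zeros(int(above.sum()), dtype=np.int8),
                    primary=np.zeros(int(above.sum()), dtype=bool),
                )
            )

        # --- pair production (e+/e- share E - 1.022 MeV)
        if is_pp.any():
            pp_e = r_e[is_pp]
            share = rng.random(len(pp_e))
            t_pair = pp_e - _ANNIHILATION_MEV
            out_pos.append(r_pos[is_pp])
            out_dir.append(r_dir[is_pp])
            out_e.append(share * t_pair)
            out_q.append(np.full(is_pp.sum(), -1, dtype=np.int8))
            out_pos.append(r_pos[is_pp])
            out_dir.append(r_dir[is_pp])
            out_e.append((1.0 - share) * t_pair)
            out_q.append(np.full(is_pp.sum(), +1, dtype=np.int8))

        if new_photons:
            nb = _Bank.concat(new_photons)
            pos = np.concatenate([pos, nb.pos])
            dirs = np.concatenate([dirs, nb.dirs])
            e = np.concatenate([e, nb.energy])
            primary = np.concatenate([primary, nb.primary])

    if out_e:
        return _Bank(
            pos=np.concatenate(out_pos),
            dirs=np.concatenate(out_dir),
            energy=np.concatenate(out_e),
            charge=np.concatenate(out_q),
            primary=np.zeros(sum(len(x) for x in out_e), dtype=bool),
        )
    return _Bank()


def _transport_charged(
    bank: _Bank,
    tables: _EngineTables,
    phantom: VoxelPhantom,
    field_spec: FieldSpec,
    config: TransportConfig,
    scorer: _CycleScorer,
    rng: np.random.Generator,
) -> _Bank:
    """Condensed-history transport of a charged bank; returns the photon
    bank of annihilation quanta."""
    spacing = phantom.spacing
    shape = phantom.shape
    density_flat = phantom.density.reshape(-1)
    mat_flat = tables.compact_index.reshape(-1)
    edep_flat = scorer.edep.reshape(-1)
    fl_flat = scorer.fl_charged.reshape(-1)

    b_mag = field_spec.magnitude
    b_axis = field_spec.unit
    cutoff = config.electron_cutoff_mev

    ann_pos = []

    pos, dirs, t, q = bank.pos, bank.dirs, bank.energy, bank.charge
    # drop sub-cut-off entries immediately (local deposit)
    flat0, inside0 = _voxel_flat_index(pos, spacing, shape)
    low = t < cutoff
    if low.any():
        np.add.at(edep_flat, flat0[low & inside0], t[low & inside0])
        scorer.escaped += float(t[low & ~inside0].sum())
        if (low & (q > 0)).any():
            ann_pos.append(pos[low & (q > 0) & inside0])
            scorer.escaped += _ANNIHILATION_MEV * float((low & (q > 0) & ~inside0).sum())
        keep = ~low
        pos, dirs, t, q = pos[keep], dirs[keep], t[keep], q[keep]

    for _ in range(config.max_electron_iterations):
        if not len(t):
            break
        flat, inside = _voxel_flat_index(pos, spacing, shape)
        if not inside.all():
            esc = ~inside
            scorer.escaped += float(t[esc].sum())
            scorer.escaped += _ANNIHILATION_MEV * float((q[esc] > 0).sum())
            pos, dirs, t, q, flat = pos[inside], dirs[inside], t[inside], q[inside], flat[inside]
            if not len(t):
                break
        m = mat_flat[flat]
        rho = density_flat[flat]
        s_mass = tables.interp_row(tables.s_tot, m, t)  # MeV cm^2/g
        csda = tables.interp_row(tables.csda, m, t)  # g/cm^2

        # voxel-scale range rejection (local density!) - never fires in air
        stop_here = (csda / rho) * 10.0 < config.range_rejection_mm
        if stop_here.any():
            np.add.at(edep_flat, flat[stop_here], t[stop_here])
            if (stop_here & (q > 0)).any():
                ann_pos.append(pos[stop_here & (q > 0)])
            keep = ~stop_here
            pos, dirs, t, q, flat, m, rho, s_mass = (
                pos[keep], dirs[keep], t[keep], q[keep], flat[keep], m[keep], rho[keep], s_mass[keep],
            )
            if not len(t):
                break

        dedx_mm = s_mass * rho / 10.0  # MeV per mm
        step = np.minimum(config.max_step_mm, config.max_energy_loss_fraction * t / dedx_mm)
        if b_mag > 0:
            pc = np.sqrt(t**2 + 2.0 * t * ELECTRON_REST_MEV)
            r_mm = pc / (0.29979 * b_mag)
            step = np.minimum(step, config.gyro_step_fraction * r_mm)

        # exact helical rotation (midpoint rule), then straight move
        if b_mag > 0:
            angle = -q.astype(float) * step / r_mm
            u_half = _rotate_about_axis(dirs, b_axis, 0.5 * angle)
            new_pos = pos + u_half * step[:, None]
            new_dirs = _rotate_about_axis(u_half, b_axis, 0.5 * angle)
        else:
            new_pos = pos + dirs * step[:, None]
            new_dirs = dirs

        # deposit continuously along the step: half at the first-quarter
        # point, half at the three-quarter point of the segment
        dep = np.minimum(t, dedx_mm * step)
        q1 = pos + (new_pos - pos) * 0.25
        q3 = pos + (new_pos - pos) * 0.75
        f1, in1 = _voxel_flat_index(q1, spacing, shape)
        f3, in3 = _voxel_flat_index(q3, spacing, shape)
        f1 = np.where(in1, f1, flat)
        f3 = np.where(in3, f3, flat)
        np.add.at(edep_flat, f1, 0.5 * dep)
        np.add.at(edep_flat, f3, 0.5 * dep)
        if scorer.score_fluence:
            np.add.at(fl_flat, f1, 0.5 * step)
            np.add.at(fl_flat, f3, 0.5 * step)
        is_pos = q > 0
        scorer.track_len_electron += float(step[~is_pos].sum())
        scorer.track_len_positron += float(step[is_pos].sum())
        t = t - dep
        pos = new_pos

        # Highland multiple scattering over the step
        x_over_x0 = (step / 10.0) * rho / tables.x0_mass[m]
        alive = t >= cutoff
        if alive.any():
            theta0 = _highland_theta0(np.maximum(t, cutoff), x_over_x0)
            theta0 = np.where(alive, theta0, 0.0)
            new_dirs = _deflect(new_dirs, rng.normal(0.0, 1.0, len(t)) * theta0,
                                rng.normal(0.0, 1.0, len(t)) * theta0)
        dirs = new_dirs

        if not alive.all():
            dead = ~alive
            # residual kinetic energy deposits at the stopping voxel
            flat_d, inside_d = _voxel_flat_index(pos[dead], spacing, shape)
            np.add.at(edep_flat, flat_d[inside_d], t[dead][inside_d])
            scorer.escaped += float(t[dead][~inside_d].sum())
            dead_pos_mask = dead & (q > 0)
            if dead_pos_mask.any():
                flat_p, inside_p = _voxel_flat_index(pos[dead_pos_mask], spacing, shape)
                ann_pos.append(pos[dead_pos_mask][inside_p])
                scorer.escaped += _ANNIHILATION_MEV * float((~inside_p).sum())
            pos, dirs, t, q = pos[alive], dirs[alive], t[alive], q[alive]
    else:
        if len(t):
            # safety valve: deposit stragglers locally and record the event
            flat, inside = _voxel_flat_index(pos, spacing, shape)
            np.add.at(edep_flat, flat[inside], t[inside])
            scorer.escaped += float(t[~inside].sum())
            if (q > 0).any():
                ann_pos.append(pos[(q > 0) & inside])
                scorer.escaped += _ANNIHILATION_MEV * float(((q > 0) & ~inside).sum())

    if ann_pos:
        centres = np.concatenate(ann_pos)
        n = len(centres)
        if n:
            d1 = _isotropic_directions(n, rng)
            return _Bank(
                pos=np.concatenate([centres, centres]),
                dirs=np.concatenate([d1, -d1]),
                energy=np.full(2 * n, ELECTRON_REST_MEV),
                charge=np.zeros(2 * n, dtype=np.int8),
                primary=np.zeros(2 * n, dtype=bool),
            )
    return _Bank()


def _run_cycle(
    phantom: VoxelPhantom,
    beam: BeamSpec,
    field_spec: FieldSpec,
    config: TransportConfig,
    tables: _EngineTables,
    cycle: int,
) -> _CycleScorer:
    ss = np.random.SeedSequence(entropy=(config.seed, cycle))
    rng_source, rng_photon, rng_electron = [np.random.default_rng(c) for c in ss.spawn(3)]
    scorer = _CycleScorer(phantom.shape, config.score_fluence)
    extent = phantom.extent_mm()

    remaining = config.n_primaries
    while remaining > 0:
        n = min(config.batch_size, remaining)
        remaining -= n
        pos, dirs, e = sample_primaries(beam, n, rng_source, extent)
        scorer.energy_in += float(e.sum())
        bank = _Bank(
            pos=pos,
            dirs=dirs,
            energy=e,
            charge=np.zeros(n, dtype=np.int8),
            primary=np.ones(n, dtype=bool),
        )
        # annihilation photons feed back into photon transport until empty
        while len(bank):
            charged = _transport_photons(bank, tables, phantom, config, scorer, rng_photon)
            bank = _transport_charged(
                charged, tables, phantom, field_spec, config, scorer, rng_electron
            )
    return scorer


def run_simulation(
    phantom: VoxelPhantom,
    beam: BeamSpec,
    field_spec: FieldSpec,
    config: TransportConfig,
) -> ScoringGrids:
    """Run ``n_cycles`` independent cycles and return per-cycle grids.

    Raises if per-cycle energy bookkeeping (in = deposited + escaped) is
    violated beyond 1e-6 relative.
    """
    tables = _EngineTables(phantom)
    n_cycles = config.n_cycles
    shape = (n_cycles,) + phantom.shape
    edep = np.zeros(shape)
    fl_p = np.zeros(shape)
    fl_c = np.zeros(shape)
    ledger = []
    for c in range(n_cycles):
        scorer = _run_cycle(phantom, beam, field_spec, config, tables, c)
        deposited = float(scorer.edep.sum())
        balance = abs(scorer.energy_in - deposited - scorer.escaped)
        if balance > 1e-6 * scorer.energy_in:
            raise RuntimeError(
                f"cycle {c}: energy bookkeeping violated by {balance:.3e} MeV "
                f"(in={scorer.energy_in:.6e}, dep={deposited:.6e}, esc={scorer.escaped:.6e})"
            )
        edep[c] = scorer.edep * 1e-3  # MeV -> GeV
        vol = phantom.voxel_volume_cm3
        norm = 1.0 / (10.0 * vol * config.n_primaries)  # mm -> cm, per volume+primary
        fl_p[c] = scorer.fl_primary * norm
        fl_c[c] = scorer.fl_charged * norm
        ledger.append(
            {
                "cycle": c,
                "energy_in_mev": scorer.energy_in,
                "deposited_mev": deposited,
                "escaped_mev": scorer.escaped,
                "track_len_electron_mm": scorer.track_len_electron,
                "track_len_positron_mm": scorer.track_len_positron,
            }
        )
    return ScoringGrids(
        energy_deposit=edep,
        fluence_primary=fl_p,
        fluence_charged=fl_c,
        n_primaries=config.n_primaries,
        metadata={
            "seed": config.seed,
            "n_cycles": n_cycles,
            "B_tesla": tuple(field_spec.B),
            "cycles": ledger,
        },
    )
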