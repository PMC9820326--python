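"""Materials, photon interaction coefficients and electron stopping powers.

The transport engine works on *macroscopic* mass coefficients (cm^2/g) built
from a small per-element data set:

* Compton scattering on free electrons via the analytic Klein-Nishina total
  cross section (no incoherent-scattering-function correction),
* photoelectric absorption as a per-element power-law fit in energy anchored
  to standard tabulations at 10 and 100 keV,
* pair production as a Z^2/A parameterization with a (E - 2 m_e c^2)^3 / E^2
  threshold shape anchored to the standard water value at 6 MeV,
* Moller (Bethe-type) collision stopping power for electrons with
  Bragg-additivity mean excitation energies, plus an approximate radiative
  fraction; CSDA ranges by numerical integration of 1/S.

Rayleigh scattering is deliberately omitted: it redistributes photons by a
few degrees without energy transfer and has negligible impact on megavoltage
dose. Iron K-shell relaxation after photoelectric absorption is modelled as a
6.4 keV fluorescence photon with yield 0.34, otherwise local (Auger) deposit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ElementSpec",
    "Material",
    "CrossSectionSet",
    "StoppingPowerModel",
    "ELEMENTS",
    "ELECTRON_REST_MEV",
    "ENERGY_MIN_MEV",
    "ENERGY_MAX_MEV",
    "FE_K_EDGE_MEV",
    "FE_K_ALPHA_MEV",
    "FE_K_FLUORESCENCE_YIELD",
    "get_material",
    "mix_fenp_compound",
    "photon_coefficients",
    "klein_nishina_total_cm2",
    "electron_stopping_power",
    "build_cross_section_set",
    "build_stopping_power_model",
    "load_material_library",
    "save_material_library",
]

ELECTRON_REST_MEV = 0.5109989
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403e-13
AVOGADRO = 6.02214076e23
BARN_CM2 = 1.0e-24

#: transport/grid energy window (MeV): low cut-off to spectrum maximum
ENERGY_MIN_MEV = 0.001
ENERGY_MAX_MEV = 7.0

PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_REST_MEV  # 1.022 MeV

FE_K_EDGE_MEV = 0.007112
FE_K_ALPHA_MEV = 0.0064
FE_K_FLUORESCENCE_YIELD = 0.34


@dataclass(frozen=True)
class ElementSpec:
    """A chemical element with the attributes transport needs."""

    symbol: str
    Z: int
    A: float  # g/mol
    density_ref: float  # g/cm^3, reference bulk density
    I_eV: float  # mean excitation energy
    # photoelectric mass attenuation anchors (cm^2/g) at 10 keV and 100 keV;
    # approximate fits to standard tabulations, interpolated as a power law.
    pe_10keV: float = 0.0
    pe_100keV: float = 0.0

    def __post_init__(self) -> None:
        if self.Z < 1 or self.A <= 0 or self.density_ref <= 0:
            raise ValueError(f"invalid element spec {self.symbol}")


ELEMENTS: dict[str, ElementSpec] = {
    e.symbol: e
    for e in [
        ElementSpec("H", 1, 1.008, 8.375e-5, 19.2, 0.004, 2.5e-6),
        ElementSpec("C", 6, 12.011, 2.0, 78.0, 2.1, 1.6e-3),
        ElementSpec("N", 7, 14.007, 1.165e-3, 82.0, 3.3, 2.2e-3),
        ElementSpec("O", 8, 15.999, 1.332e-3, 95.0, 5.4, 3.1e-3),
        ElementSpec("Na", 11, 22.990, 0.971, 149.0, 15.0, 1.0e-2),
        ElementSpec("Mg", 12, 24.305, 1.74, 156.0, 21.0, 1.5e-2),
        ElementSpec("P", 15, 30.974, 2.2, 173.0, 42.0, 3.2e-2),
        ElementSpec("S", 16, 32.06, 2.0, 180.0, 52.0, 4.0e-2),
        ElementSpec("Cl", 17, 35.45, 2.995e-3, 174.0, 62.0, 5.0e-2),
        ElementSpec("Ar", 18, 39.948, 1.662e-3, 188.0, 65.0, 5.5e-2),
        ElementSpec("K", 19, 39.098, 0.862, 190.0, 82.0, 7.0e-2),
        ElementSpec("Ca", 20, 40.078, 1.55, 191.0, 95.0, 8.5e-2),
        ElementSpec("Fe", 26, 55.845, 7.874, 286.0, 165.0, 0.21),
    ]
}


@dataclass(frozen=True)
class Material:
    """A homogeneous material defined by element mass fractions.

    ``fe_mass_fraction`` records the admixed nanoparticle-agent fraction for
    infused virtual compounds (0 for plain materials); it is metadata for
    reporting, the physics only sees the resulting element fractions.
    """

    name: str
    mass_fractions: dict[str, float]
    density: float  # g/cm^3
    mean_excitation_energy: float  # eV
    fe_mass_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError(f"{self.name}: mean excitation energy must be positive")
        unknown = set(self.mass_fractions) - set(ELEMENTS)
        if unknown:
            raise KeyError(f"{self.name}: unknown elements {sorted(unknown)}")
        if not 0.0 <= self.fe_mass_fraction <= 1.0:
            raise ValueError(f"{self.name}: fe_mass_fraction must lie in [0, 1]")

    @property
    def electrons_per_gram(self) -> float:
        """N_A * sum(w_i Z_i / A_i), electrons per gram."""
        za = sum(w * ELEMENTS[s].Z / ELEMENTS[s].A for s, w in self.mass_fractions.items())
        return AVOGADRO * za

    @property
    def z_over_a(self) -> float:
        return sum(w * ELEMENTS[s].Z / ELEMENTS[s].A for s, w in self.mass_fractions.items())

    @property
    def z2_over_a(self) -> float:
        return sum(w * ELEMENTS[s].Z ** 2 / ELEMENTS[s].A for s, w in self.mass_fractions.items())


# ---------------------------------------------------------------------------
# reference material library (ICRU-44-like compositions)

_LIBRARY: dict[str, Material] = {}


def _register(m: Material) -> Material:
    _LIBRARY[m.name] = m
    return m


WATER = _register(Material("water", {"H": 0.1119, "O": 0.8881}, 1.0, 75.0))
AIR = _register(
    Material(
        "air",
        {"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827},
        1.2048e-3,
        85.7,
    )
)
SOFT_TISSUE = _register(
    Material(
        "soft_tissue",
        {
            "H": 0.102,
            "C": 0.143,
            "N": 0.034,
            "O": 0.708,
            "Na": 0.002,
            "P": 0.003,
            "S": 0.003,
            "Cl": 0.002,
            "K": 0.003,
        },
        1.06,
        74.7,
    )
)
CORTICAL_BONE = _register(
    Material(
        "cortical_bone",
        {
            "H": 0.034,
            "C": 0.155,
            "N": 0.042,
            "O": 0.435,
            "Na": 0.001,
            "Mg": 0.002,
            "P": 0.103,
            "S": 0.003,
            "Ca": 0.225,
        },
        1.92,
        106.4,
    )
)
IRON = _register(Material("iron", {"Fe": 1.0}, 7.874, 286.0))
# magnetite Fe3O4: 3*55.845 / (3*55.845 + 4*15.999) = 0.7236 Fe by mass
MAGNETITE = _register(
    Material(
        "magnetite",
        {"Fe": 0.72360, "O": 0.27640},
        5.17,
        248.6,  # Bragg additivity over Fe/O
    )
)


def get_material(name: str) -> Material:
    try:
        return _LIBRARY[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; known: {sorted(_LIBRARY)}") from None


def register_material(m: Material) -> Material:
    """Add a material to the runtime library (overwrites same name)."""
    return _register(m)


# ---------------------------------------------------------------------------
# mixing


def _bragg_mean_excitation(materials: list[Material], weights: list[float]) -> float:
    """Mean excitation energy of a mixture by Bragg additivity (ln-weighted
    by electron fraction)."""
    num = 0.0
    den = 0.0
    for m, w in zip(materials, weights):
        za = m.z_over_a
        num += w * za * math.log(m.mean_excitation_energy)
        den += w * za
    return math.exp(num / den)


def mix_fenp_compound(
    base: Material,
    fe_mass_fraction: float,
    fe_agent: Material = IRON,
    density_rule: str = "inverse",
    allow_out_of_range: bool = False,
) -> Material:
    """Build a nanoparticle-infused virtual compound.

    The agent (elemental Fe by default; magnetite is the documented
    alternative) is admixed at mass fraction ``fe_mass_fraction``; element
    fractions combine mass-weighted and the density follows the inverse
    (volume-additive) mixture rule ``1/rho = sum(w_i / rho_i)`` unless
    ``density_rule='linear'`` is requested.
    """
    w = float(fe_mass_fraction)
    if not (0.0 <= w <= 0.10) and not allow_out_of_range:
        raise ValueError(
            f"fe_mass_fraction {w} outside the studied [0, 0.10] range; "
            "pass allow_out_of_range=True to override"
        )
    if w == 0.0:
        return base
    fractions: dict[str, float] = {}
    for sym, f in base.mass_fractions.items():
        fractions[sym] = fractions.get(sym, 0.0) + (1.0 - w) * f
    for sym, f in fe_agent.mass_fractions.items():
        fractions[sym] = fractions.get(sym, 0.0) + w * f
    if density_rule == "inverse":
        density = 1.0 / ((1.0 - w) / base.density + w / fe_agent.density)
    elif density_rule == "linear":
        density = (1.0 - w) * base.density + w * fe_agent.density
    else:
        raise ValueError(f"unknown density rule {density_rule!r}")
    i_mean = _bragg_mean_excitation([base, fe_agent], [1.0 - w, w])
    return Material(
        name=f"{base.name}+{fe_agent.name}_{100 * w:g}pct",
        mass_fractions=fractions,
        density=density,
        mean_excitation_energy=i_mean,
        fe_mass_fraction=w if fe_agent.name != "magnetite" else w,
    )


# ---------------------------------------------------------------------------
# photon interaction coefficients


def klein_nishina_total_cm2(energy_mev):
    """Total Klein-Nishina cross section per free electron, in cm^2.

    Analytic closed form; tends to the Thomson value 0.6652 barn as E -> 0.
    """
    e = np.asarray(energy_mev, dtype=float)
    k = e / ELECTRON_REST_MEV
    k = np.where(k < 1e-8, 1e-8, k)
    log_term = np.log1p(2.0 * k)
    term1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - log_term / k)
    term2 = log_term / (2.0 * k)
    term3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    sigma = 2.0 * math.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * (term1 + term2 - term3)
    return sigma if sigma.shape else float(sigma)


def _element_pe_mass_coeff(spec: ElementSpec, energy_mev):
    """Photoelectric mass attenuation (cm^2/g) of one element: power law
    through the 10/100 keV anchors, with a crude Fe K-edge jump below
    7.112 keV."""
    e = np.asarray(energy_mev, dtype=float)
    if spec.pe_10keV <= 0:
        return np.zeros_like(e)
    slope = math.log10(spec.pe_100keV / spec.pe_10keV)
    mu = spec.pe_10keV * (e / 0.01) ** slope
    if spec.symbol == "Fe":
        mu = np.where(e < FE_K_EDGE_MEV, mu / 8.2, mu)
    return mu


def mu_photoelectric(material: Material, energy_mev):
    e = np.asarray(energy_mev, dtype=float)
    mu = np.zeros_like(e)
    for sym, w in material.mass_fractions.items():
        mu = mu + w * _element_pe_mass_coeff(ELEMENTS[sym], e)
    return mu


def mu_compton(material: Material, energy_mev):
    return klein_nishina_total_cm2(energy_mev) * material.electrons_per_gram


# pair-production amplitude anchored so water reaches the standard
# ~3.7e-3 cm^2/g at 6 MeV (nuclear + electron field lumped together)
_PAIR_AMPLITUDE = 2.91e-4


def mu_pair(material: Material, energy_mev):
    e = np.asarray(energy_mev, dtype=float)
    shape = np.where(
        e > PAIR_THRESHOLD_MEV,
        ((e - PAIR_THRESHOLD_MEV) / np.maximum(e, 1e-12)) ** 3 * e,
        0.0,
    )
    return _PAIR_AMPLITUDE * material.z2_over_a * shape


def photon_coefficients(material: Material, energy_mev, check_range: bool = True):
    """Per-process photon mass attenuation coefficients (cm^2/g).

    Returns a dict with keys ``photoelectric``, ``compton``, ``pair`` and
    ``total``. Energies must lie in the transport window
    [``ENERGY_MIN_MEV``, ``ENERGY_MAX_MEV``].
    """
    e = np.asarray(energy_mev, dtype=float)
    if check_range and (np.any(e < ENERGY_MIN_MEV) or np.any(e > ENERGY_MAX_MEV)):
        raise ValueError(
            f"energy outside transport range [{ENERGY_MIN_MEV}, {ENERGY_MAX_MEV}] MeV"
        )
    pe = mu_photoelectric(material, e)
    co = mu_compton(material, e)
    pp = mu_pair(material, e)
    return {
        "photoelectric": pe,
        "compton": co,
        "pair": pp,
        "total": pe + co + pp,
    }


# ---------------------------------------------------------------------------
# electron stopping power


def _collision_stopping_power(z_over_a: float, i_ev: float, energy_mev):
    """Moller collision mass stopping power (MeV cm^2/g) for electrons.

    Standard Bethe-type formula without the density-effect correction, which
    keeps the 0.1-7 MeV values within a few percent of reference tabulations.
    """
    t = np.asarray(energy_mev, dtype=float)
    tau = t / ELECTRON_REST_MEV
    beta2 = tau * (tau + 2.0) / (tau + 1.0) ** 2
    i_ratio2 = (i_ev * 1e-6 / ELECTRON_REST_MEV) ** 2
    f_minus = (
        1.0
        - beta2
        + (tau**2 / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (tau + 1.0) ** 2
    )
    bracket = np.log(tau**2 * (tau + 2.0) / (2.0 * i_ratio2)) + f_minus
    return 0.1535336 * z_over_a / beta2 * bracket


def radiative_fraction(material: Material, energy_mev):
    """Approximate fraction of the total stopping power that is radiative,
    using the rule-of-thumb S_rad/S_col ~ Z_eff * T / 800 (T in MeV)."""
    t = np.asarray(energy_mev, dtype=float)
    z_eff = material.z2_over_a / material.z_over_a
    ratio = z_eff * t / 800.0
    return ratio / (1.0 + ratio)


def electron_stopping_power(material: Material, energy_mev):
    """Collision mass stopping power (MeV cm^2/g) and CSDA range (g/cm^2).

    The CSDA range is the numerical integral of 1/S_total from the 1 keV
    transport cut-off up to the requested energy.
    """
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e < ENERGY_MIN_MEV) or np.any(e > ENERGY_MAX_MEV):
        raise ValueError(
            f"energy outside transport range [{ENERGY_MIN_MEV}, {ENERGY_MAX_MEV}] MeV"
        )
    s_col = _collision_stopping_power(material.z_over_a, material.mean_excitation_energy, e)
    model = build_stopping_power_model(material)
    csda = np.interp(np.log(e), np.log(model.energy_grid), model.csda_range)
    if np.ndim(energy_mev) == 0:
        return float(s_col), float(csda)
    return s_col, csda


# ---------------------------------------------------------------------------
# tabulated sets for the transport engine


@dataclass(frozen=True)
class CrossSectionSet:
    """Photon mass attenuation coefficients tabulated on an energy grid."""

    energy_grid: np.ndarray  # MeV, strictly increasing
    mu_photoelectric: np.ndarray
    mu_compton: np.ndarray
    mu_pair: np.ndarray
    mu_total: np.ndarray
    fluorescence_yield_K: dict[str, float] = field(
        default_factory=lambda: {"Fe": FE_K_FLUORESCENCE_YIELD}
    )

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        for arr in (self.mu_photoelectric, self.mu_compton, self.mu_pair):
            if np.any(np.asarray(arr) < 0):
                raise ValueError("negative attenuation coefficient")
        resid = np.abs(
            self.mu_total - (self.mu_photoelectric + self.mu_compton + self.mu_pair)
        )
        if np.any(resid > 1e-12 * np.maximum(self.mu_total, 1e-30)):
            raise ValueError("mu_total must equal the sum of process coefficients")


@dataclass(frozen=True)
class StoppingPowerModel:
    """Electron stopping data on an energy grid for one material."""

    energy_grid: np.ndarray  # MeV
    collision_stopping_power: np.ndarray  # MeV cm^2/g
    radiative_fraction: np.ndarray
    csda_range: np.ndarray  # g/cm^2

    def __post_init__(self) -> None:
        if np.any(self.collision_stopping_power <= 0):
            raise ValueError("stopping power must be positive on the grid")
        if np.any(np.diff(self.csda_range) < 0):
            raise ValueError("CSDA range must be monotone increasing")


def default_energy_grid(n: int = 256) -> np.ndarray:
    return np.geomspace(ENERGY_MIN_MEV, ENERGY_MAX_MEV, n)


def build_cross_section_set(material: Material, energy_grid=None) -> CrossSectionSet:
    grid = default_energy_grid() if energy_grid is None else np.asarray(energy_grid, float)
    c = photon_coefficients(material, grid)
    return CrossSectionSet(
        energy_grid=grid,
        mu_photoelectric=c["photoelectric"],
        mu_compton=c["compton"],
        mu_pair=c["pair"],
        mu_total=c["total"],
    )


_SPM_CACHE: dict[tuple, StoppingPowerModel] = {}


def build_stopping_power_model(material: Material, energy_grid=None) -> StoppingPowerModel:
    if energy_grid is None:
        key = (material.name, material.density, material.mean_excitation_energy)
        cached = _SPM_CACHE.get(key)
        if cached is not None:
            return cached
        model = _SPM_CACHE[key] = _build_spm(material, default_energy_grid())
        return model
    return _build_spm(material, np.asarray(energy_grid, float))


def _build_spm(material: Material, grid: np.ndarray) -> StoppingPowerModel:
    s_col = _collision_stopping_power(
        material.z_over_a, material.mean_excitation_energy, grid
    )
    rad = radiative_fraction(material, grid)
    s_tot = s_col / (1.0 - rad)
    # cumulative trapezoid of 1/S_tot from the cut-off
    inv = 1.0 / s_tot
    csda = np.concatenate(
        [[0.0], np.cumsum(0.5 * (inv[1:] + inv[:-1]) * np.diff(grid))]
    )
    return StoppingPowerModel(
        energy_grid=grid,
        collision_stopping_power=s_col,
        radiative_fraction=rad,
        csda_range=csda,
    )


# ---------------------------------------------------------------------------
# material library file I/O (YAML)


def save_material_library(path, materials: list[Material]) -> None:
    payload = [
        {
            "name": m.name,
            "mass_fractions": dict(m.mass_fractions),
            "density": m.density,
            "mean_excitation_energy": m.mean_excitation_energy,
            "fe_mass_fraction": m.fe_mass_fraction,
        }
        for m in materials
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_material_library(path) -> list[Material]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    mats = [
        Material(
            name=item["name"],
            mass_fractions=item["mass_fractions"],
            density=float(item["density"]),
            mean_excitation_energy=float(item["mean_excitation_energy"]),
            fe_mass_fraction=float(item.get("fe_mass_fraction", 0.0)),
        )
        for item in payload
    ]
    for m in mats:
        _register(m)
    return mats
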