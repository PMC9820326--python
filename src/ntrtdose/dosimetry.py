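"""Dose maps, batch uncertainties, percent difference maps, profiles, DER.

The batch (cycle) estimator: dose is the mean over independent cycles of the
per-voxel energy deposit divided by voxel mass and by primaries per cycle;
the relative uncertainty is the standard error of that mean,
s.d.(cycles) / (sqrt(n_cycles) * mean).

The relative dose difference map is
    dD(r) = 100 * (D(r) - D_ref(r)) / D_ref(r)   [%]
and the dose-enhancement ratio DER is the mean target (PTV) dose with the
nanoparticle admixture divided by the mean target dose in reference
conditions, with the two mean-dose uncertainties combined in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import VoxelPhantom
from .transport import ScoringGrids

__all__ = [
    "DoseMap",
    "DERResult",
    "grids_to_dosemap",
    "dose_difference_map",
    "compute_der",
    "mean_dose_in_mask",
    "extract_profiles",
    "tissue_air_interface_mask",
    "max_interface_difference",
]


@dataclass
class DoseMap:
    """Per-voxel dose (GeV/g per primary) with 1 s.d. relative uncertainty
    of the cycle-mean; undefined voxels (zero mass or zero dose) are masked."""

    dose: np.ndarray
    rel_uncertainty: np.ndarray
    n_cycles: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")


@dataclass
class DERResult:
    fe_mass_fraction: float
    setup_label: str
    mean_ptv_dose: float
    mean_ptv_dose_ref: float
    der: float
    der_uncertainty: float  # 1 s.d.


def grids_to_dosemap(cycles: ScoringGrids, phantom: VoxelPhantom) -> DoseMap:
    """Combine per-cycle energy-deposit grids into dose mean and batch
    standard error."""
    if cycles.n_cycles < 2:
        raise ValueError("need >= 2 cycles")
    if cycles.energy_deposit.shape[1:] != phantom.shape:
        raise ValueError("grids not congruent with phantom")
    mass = phantom.voxel_mass_g
    per_cycle = cycles.energy_deposit / mass[None, ...] / cycles.n_primaries
    mean = per_cycle.mean(axis=0)
    sd = per_cycle.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, sd / (np.sqrt(cycles.n_cycles) * mean), 0.0)
    return DoseMap(
        dose=mean,
        rel_uncertainty=rel,
        n_cycles=cycles.n_cycles,
        provenance=dict(cycles.metadata),
    )


def dose_difference_map(
    test: DoseMap, reference: DoseMap, mask: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Voxelwise percent difference dD = 100 (D - D_ref)/D_ref.

    Returns (dD map with NaN where the reference is zero, count of undefined
    voxels inside the mask)."""
    if test.dose.shape != reference.dose.shape:
        raise ValueError("dose maps not congruent")
    if mask is None:
        mask = np.ones(test.dose.shape, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (test.dose - reference.dose) / reference.dose
    undefined = (reference.dose == 0) & mask
    delta = np.where(reference.dose > 0, delta, np.nan)
    return delta, int(undefined.sum())


def mean_dose_in_mask(dose_map: DoseMap, mask: np.ndarray) -> tuple[float, float]:
    """Unweighted mean dose over mask voxels and its relative 1 s.d.
    uncertainty (voxel uncertainties propagated assuming independence)."""
    if not mask.any():
        raise ValueError("empty mask")
    d = dose_map.dose[mask]
    mean = float(d.mean())
    abs_sigma = dose_map.rel_uncertainty[mask] * d
    sigma_mean = float(np.sqrt(np.sum(abs_sigma**2)) / mask.sum())
    return mean, (sigma_mean / mean if mean > 0 else 0.0)


def compute_der(
    test: DoseMap,
    reference: DoseMap,
    ptv_mask: np.ndarray,
    fe_mass_fraction: float = float("nan"),
    setup_label: str = "",
) -> DERResult:
    """Mean PTV dose ratio with quadrature-propagated uncertainty."""
    if test.dose.shape != reference.dose.shape or test.dose.shape != ptv_mask.shape:
        raise ValueError("masks/maps not congruent")
    m_test, rel_test = mean_dose_in_mask(test, ptv_mask)
    m_ref, rel_ref = mean_dose_in_mask(reference, ptv_mask)
    if m_ref <= 0:
        raise ValueError("reference mean PTV dose must be positive")
    der = m_test / m_ref
    rel = float(np.hypot(rel_test, rel_ref))
    return DERResult(
        fe_mass_fraction=fe_mass_fraction,
        setup_label=setup_label,
        mean_ptv_dose=m_test,
        mean_ptv_dose_ref=m_ref,
        der=der,
        der_uncertainty=der * rel,
    )


def cycle_profile(
    cycles: ScoringGrids,
    phantom: VoxelPhantom,
    along: int,
    centre: tuple[int, int, int],
    width_voxels: int = 11,
    roi_half_width: int | None = None,
):
    """1D dose profile with *batch* (cycle-to-cycle) uncertainties.

    The profile is the dose averaged over a ``width_voxels``-wide square
    column around ``centre`` transverse to the ``along`` axis, computed per
    cycle; the uncertainty is the standard error over cycles. Unlike
    propagating per-voxel uncertainties through the window average, this
    respects the spatial correlation of voxel doses from shared electron
    tracks.

    Returns (indices, mean profile, 1 s.d. of the mean).
    """
    if cycles.n_cycles < 2:
        raise ValueError("need >= 2 cycles")
    mass = phantom.voxel_mass_g
    per_cycle = cycles.energy_deposit / mass[None, ...] / cycles.n_primaries
    hw = width_voxels // 2
    sel: list = [slice(None)] * 3
    for ax in range(3):
        if ax != along:
            sel[ax] = slice(max(0, centre[ax] - hw), centre[ax] + hw + 1)
    window = per_cycle[(slice(None), *sel)]
    axes = tuple(1 + ax for ax in range(3) if ax != along)
    prof_c = window.mean(axis=axes)  # (n_cycles, n_along)
    mean = prof_c.mean(axis=0)
    sig = prof_c.std(axis=0, ddof=1) / np.sqrt(cycles.n_cycles)
    idx = np.arange(phantom.shape[along])
    if roi_half_width is not None:
        c = centre[along]
        lo, hi = max(0, c - roi_half_width), min(phantom.shape[along], c + roi_half_width + 1)
        return idx[lo:hi], mean[lo:hi], sig[lo:hi]
    return idx, mean, sig


def tissue_air_interface_mask(
    phantom: VoxelPhantom,
    distance_mm: float = 5.0,
    air_density: float = 0.1,
    tissue_density: float = 0.5,
) -> np.ndarray:
    """Voxels within ``distance_mm`` of a tissue-air (dense/low-density)
    interface, on either side of it.

    The interface is the set of low-density voxels that touch a dense voxel
    (and vice versa); the band is grown with a Euclidean distance transform
    honouring the voxel spacing. Exterior air that never touches tissue is
    naturally included only near the phantom surface; callers normally
    combine this with a dose threshold to restrict to the irradiated region.
    """
    low = phantom.density < air_density
    dense = phantom.density > tissue_density
    if not low.any() or not dense.any():
        return np.zeros(phantom.shape, dtype=bool)
    grown_low = ndimage.binary_dilation(low)
    grown_dense = ndimage.binary_dilation(dense)
    surface = (low & grown_dense) | (dense & grown_low)
    if not surface.any():
        return np.zeros(phantom.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~surface, sampling=phantom.spacing)
    return dist <= distance_mm


def max_interface_difference(
    test: DoseMap,
    reference: DoseMap,
    phantom: VoxelPhantom,
    distance_mm: float = 5.0,
    dose_threshold: float = 0.10,
) -> float:
    """Maximum |percent difference| at voxels near tissue-air interfaces.

    Voxels with reference dose below ``dose_threshold`` of the maximum
    reference dose in dense (tissue-like) voxels are excluded: the usual
    low-dose exclusion when reporting relative differences, which otherwise
    diverge where the denominator is statistically empty. The threshold is
    anchored to dense voxels because a single electron track in a
    near-massless air voxel can set an arbitrarily high dose maximum."""
    band = tissue_air_interface_mask(phantom, distance_mm)
    dd, _ = dose_difference_map(test, reference)
    dense_max = reference.dose[phantom.density > 0.5].max()
    sel = band & (reference.dose >= dose_threshold * dense_max)
    if not sel.any():
        raise ValueError("no evaluable interface voxels above the dose threshold")
    return float(np.nanmax(np.abs(dd[sel])))


def extract_profiles(
    dose_map: DoseMap,
    plane: str = "transversal",
    centre: tuple[int, int, int] | None = None,
    roi_half_width: int | None = None,
    width_voxels: int = 1,
):
    """1D dose profiles with uncertainties through a point.

    ``plane='transversal'`` (fixed z): vertical profile along x, horizontal
    along y. ``plane='sagittal'`` (fixed x): vertical along z, horizontal
    along y. Profiles are ``width_voxels`` wide (default single voxel, the
    dashed-line convention of planar dose figures).

    Returns a dict with 'vertical' and 'horizontal' entries of
    (positions, dose, abs_sigma).
    """
    shape = dose_map.dose.shape
    if centre is None:
        centre = tuple(s // 2 for s in shape)
    ci, cj, ck = centre
    if not (0 <= ci < shape[0] and 0 <= cj < shape[1] and 0 <= ck < shape[2]):
        raise ValueError("profile centre outside grid")

    def _line(fixed: dict[int, int], along: int):
        sel: list = [slice(None)] * 3
        hw = width_voxels // 2
        for ax, idx in fixed.items():
            sel[ax] = slice(max(0, idx - hw), idx + hw + 1)
        d = dose_map.dose[tuple(sel)]
        var = (dose_map.rel_uncertainty[tuple(sel)] * d) ** 2
        axes = tuple(i for i in range(3) if i in fixed)
        n = int(np.prod([d.shape[i] for i in axes]))
        prof = d.mean(axis=axes)
        sig = np.sqrt(var.sum(axis=axes)) / n
        idx = np.arange(shape[along])
        if roi_half_width is not None:
            c = centre[along]
            lo = max(0, c - roi_half_width)
            hi = min(shape[along], c + roi_half_width + 1)
            return idx[lo:hi], prof[lo:hi], sig[lo:hi]
        return idx, prof, sig

    if plane == "transversal":
        vertical = _line({1: cj, 2: ck}, 0)  # along x
        horizontal = _line({0: ci, 2: ck}, 1)  # along y
    elif plane == "sagittal":
        vertical = _line({0: ci, 1: cj}, 2)  # along z (depth)
        horizontal = _line({0: ci, 2: ck}, 1)  # along y
    else:
        raise ValueError("plane must be 'transversal' or 'sagittal'")
    return {"vertical": vertical, "horizontal": horizontal}
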