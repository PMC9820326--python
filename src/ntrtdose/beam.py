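"""Primary beam model: 6 MV photon spectrum histogram and parallel-beam source.

The spectral shape is a parameterized stand-in for a clinical 6 MV linac
phase-space spectrum: a gamma-like fluence density phi(E) ~ E^0.6 exp(-E/1.2)
truncated to (0.025, 6.5] MeV, which reproduces the characteristic low-energy
rise, broad maximum near 0.5-1 MeV, mean energy ~1.8 MeV and 6.5 MeV
endpoint. Any user histogram (CSV) can be substituted. The beam is modelled
as parallel along -z with uniform fluence over a rectangular field; phase-
space angular correlations are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BeamSpec", "default_6mv_spectrum", "load_spectrum_csv", "save_spectrum_csv", "sample_primaries"]


@dataclass
class BeamSpec:
    """Energy histogram + rectangular parallel field geometry."""

    bin_edges: np.ndarray  # MeV, length n+1, strictly increasing
    probabilities: np.ndarray  # length n, sums to 1
    field_size: tuple[float, float] = (30.0, 30.0)  # mm, (x, y) at entry plane
    source_z: float | None = None  # mm; defaults to the phantom +z face

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("need one probability per bin")
        if np.any(self.probabilities < 0) or self.probabilities.sum() <= 0:
            raise ValueError("probabilities must be non-negative with positive sum")
        if self.bin_edges[0] <= 0 or self.bin_edges[-1] > 7.0:
            raise ValueError("spectrum support must lie within (0, 7] MeV")
        self.probabilities = self.probabilities / self.probabilities.sum()

    @property
    def mean_energy(self) -> float:
        centres = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(np.sum(centres * self.probabilities))


def default_6mv_spectrum(n_bins: int = 130) -> BeamSpec:
    """The packaged parameterized 6 MV spectrum histogram."""
    edges = np.linspace(0.025, 6.5, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    density = centres**0.6 * np.exp(-centres / 1.2)
    prob = density * np.diff(edges)
    return BeamSpec(bin_edges=edges, probabilities=prob / prob.sum())


def save_spectrum_csv(path, beam: BeamSpec) -> None:
    pd.DataFrame(
        {
            "bin_low_MeV": beam.bin_edges[:-1],
            "bin_high_MeV": beam.bin_edges[1:],
            "probability": beam.probabilities,
        }
    ).to_csv(path, index=False)


def load_spectrum_csv(path, **kwargs) -> BeamSpec:
    df = pd.read_csv(path)
    required = {"bin_low_MeV", "bin_high_MeV", "probability"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectrum CSV needs columns {sorted(required)}")
    lows = df["bin_low_MeV"].to_numpy(float)
    highs = df["bin_high_MeV"].to_numpy(float)
    if not np.allclose(lows[1:], highs[:-1]):
        raise ValueError("spectrum bins must be contiguous")
    edges = np.concatenate([lows, highs[-1:]])
    return BeamSpec(bin_edges=edges, probabilities=df["probability"].to_numpy(float), **kwargs)


def sample_primaries(
    beam: BeamSpec,
    n: int,
    rng: np.random.Generator,
    phantom_extent_mm: tuple[float, float, float],
):
    """Draw n primary photons: energies from the histogram (uniform within a
    bin), positions uniform over the field rectangle centred on the beam
    axis at the source plane, direction -z.

    Returns (positions (n,3) mm, directions (n,3), energies (n,) MeV).
    """
    if len(beam.probabilities) == 0:
        raise ValueError("empty spectrum")
    idx = rng.choice(len(beam.probabilities), size=n, p=beam.probabilities)
    lo = beam.bin_edges[idx]
    hi = beam.bin_edges[idx + 1]
    energies = lo + (hi - lo) * rng.random(n)
    ex, ey, ez = phantom_extent_mm
    fx, fy = beam.field_size
    z0 = beam.source_z if beam.source_z is not None else ez - 1e-6
    pos = np.empty((n, 3), dtype=np.float64)
    pos[:, 0] = ex / 2.0 + fx * (rng.random(n) - 0.5)
    pos[:, 1] = ey / 2.0 + fy * (rng.random(n) - 0.5)
    pos[:, 2] = z0
    dirs = np.zeros((n, 3), dtype=np.float64)
    dirs[:, 2] = -1.0
    return pos, dirs, energies
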