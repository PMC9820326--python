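"""Synthetic inputs with known ground truth for every analysis stage.

Survival/TER datasets emulate hyperthermia cell-viability series (three
glioblastoma-related cell types at fixed 60-minute application by default)
generated from a known TER model with multiplicative log-normal noise; noisy
cycle grids emulate batch Monte Carlo outputs for the dose statistics. Every
generator is a pure function of (spec, seed), and the ground truth is
returned next to the data so recovery tests are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermal import SurvivalDataset, TERModel, ter_evaluate
from .transport import ScoringGrids

__all__ = [
    "GeneratorSpec",
    "DEFAULT_CELL_LABELS",
    "generate_survival_dataset",
    "generate_cycle_grids",
]

DEFAULT_CELL_LABELS = ("SVZ-NSC", "GBM-CSC", "GBM-Astrocyte")


@dataclass
class GeneratorSpec:
    """Ground-truth TER model and sampling design for survival data."""

    true_model: TERModel = field(
        default_factory=lambda: TERModel(ter0=1.0, c1=0.02, c2=0.3, t_c=45.0)
    )
    temperatures: tuple[float, ...] = (37.0, 39.0, 41.0, 43.0, 45.0)
    times: tuple[float, ...] = (60.0,)
    noise_sigma: float = 0.02  # log-normal sigma on multiplicative noise
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if len(self.temperatures) == 0:
            raise ValueError("empty temperature grid")


def generate_survival_dataset(
    spec: GeneratorSpec,
    cell_labels: tuple[str, ...] = DEFAULT_CELL_LABELS,
    cell_models: dict[str, TERModel] | None = None,
) -> tuple[SurvivalDataset, dict[str, TERModel]]:
    """TER series per cell label with multiplicative log-normal noise.

    ``cell_models`` overrides the per-cell ground truth (default: the spec's
    single true model for every label). Returns (dataset, ground truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 0x5D)))
    truth = {
        label: (cell_models or {}).get(label, spec.true_model) for label in cell_labels
    }
    rows = []
    for label in cell_labels:
        model = truth[label]
        for temp in spec.temperatures:
            for t in spec.times:
                clean = float(ter_evaluate(model, temp, t))
                for _ in range(spec.replicates):
                    noise = (
                        float(np.exp(rng.normal(0.0, spec.noise_sigma)))
                        if spec.noise_sigma > 0
                        else 1.0
                    )
                    rows.append(
                        {
                            "cell_type": label,
                            "T_C": temp,
                            "t_min": t,
                            "value": clean * noise,
                            "sigma": clean * spec.noise_sigma
                            if spec.noise_sigma > 0
                            else float("nan"),
                        }
                    )
    data = SurvivalDataset(table=pd.DataFrame(rows), value_kind="ter")
    return data, truth


def generate_cycle_grids(
    shape: tuple[int, int, int],
    mean_map: np.ndarray | float,
    rel_sigma: float,
    n_cycles: int,
    seed: int = 0,
    n_primaries: int = 1,
) -> ScoringGrids:
    """Independent per-cycle deposit grids ~ Normal(mean, (rel_sigma mean)^2)
    truncated at zero, emulating batch Monte Carlo outputs."""
    if rel_sigma < 0:
        raise ValueError("rel_sigma must be non-negative")
    if n_cycles < 2:
        raise ValueError("need >= 2 cycles")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xC)))
    mean = np.broadcast_to(np.asarray(mean_map, dtype=float), shape)
    grids = np.empty((n_cycles,) + tuple(shape))
    for c in range(n_cycles):
        if rel_sigma == 0:
            grids[c] = mean
        else:
            grids[c] = np.clip(rng.normal(mean, rel_sigma * mean), 0.0, None)
    zeros = np.zeros_like(grids)
    return ScoringGrids(
        energy_deposit=grids,
        fluence_primary=zeros,
        fluence_charged=zeros.copy(),
        n_primaries=n_primaries,
        metadata={"synthetic": True, "seed": seed, "rel_sigma": rel_sigma},
    )
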