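"""Synthetic datasets and experiment templates.

The raw laboratory measurements behind the model (2D dose-response tables
and longitudinal spheroid areas) are not distributed, so every test and
example runs on synthetic stand-ins generated here: Hill-shaped
dose-response curves with optional Gaussian noise, and parametric growth
trajectories (exponential, arrested, regressing, relapsing) with
multiplicative lognormal replicate noise.  Generators are pure functions of
their parameters and seed.

``default_experiment()`` bundles the study template the simulator was
designed around: treatment on day 4 post-seeding, observation every two
days out to day 21, TMZ doses {100, 200, 300, 500, 1000} uM and DOX doses
{0.1, 0.3, 0.5, 0.9} uM with combinations of 500 uM TMZ against each DOX
dose, ten replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis_metrics import GrowthRecord
from .drug_transport import DosingSchedule, DrugParams
from .engine import DrugSpec
from .pharmacodynamics import FateModel, build_fate_model

__all__ = [
    "generate_dose_response",
    "generate_reference_growth",
    "default_experiment",
    "ExperimentTemplate",
    "GROWTH_SCENARIOS",
]

GROWTH_SCENARIOS = ("untreated_exponential", "arrested", "regressing", "relapse")

#: 72 h exposure in the 2D assay over a 22 h mean cycle
DEFAULT_EXPOSURE_CYCLES = 72.0 / 22.0

# transport parameters for the two reference drugs
TMZ_DIFFUSION_CM2_S = 8.68e-7
TMZ_UPTAKE_M_PER_CELL_S = 1.4e-10
DOX_DIFFUSION_CM2_S = 8.68e-8
DOX_UPTAKE_M_PER_CELL_S = 1.4e-13

# synthetic 2D dose-response shape parameters (emulating the monolayer assay:
# half-inhibition for TMZ only above 500 uM; DOX effective at ~0.05 uM)
TMZ_IC50_UM = 550.0
TMZ_HILL_SLOPE = 1.5
DOX_IC50_UM = 0.05
DOX_HILL_SLOPE = 1.0

TMZ_DOSES_UM = (100.0, 200.0, 300.0, 500.0, 1000.0)
DOX_DOSES_UM = (0.1, 0.3, 0.5, 0.9)


def generate_dose_response(
    ic50_uM: float,
    hill_slope: float,
    doses_uM: Sequence[float],
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Hill-shaped % inhibition table: 100 * c^s / (ic50^s + c^s) + noise.

    Noisy values may leave [0, 100]; downstream calibration clamps them.
    """
    if ic50_uM <= 0:
        raise ValueError("ic50 must be positive")
    doses = np.asarray(doses_uM, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    cs = doses**hill_slope
    inhibition = 100.0 * cs / (ic50_uM**hill_slope + cs)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("pass an rng when noise_sd > 0")
        inhibition = inhibition + rng.normal(0.0, noise_sd, size=len(doses))
    inhibition = np.minimum(inhibition, 100.0)
    return pd.DataFrame(
        {"concentration_uM": doses, "inhibition_percent": inhibition}
    )


def generate_reference_growth(
    scenario: str,
    rng: Optional[np.random.Generator] = None,
    days: Optional[np.ndarray] = None,
    n_replicates: int = 6,
    initial_area_um2: float = 2.0e5,
    area_doubling_days: float = 4.0,
    regression_rate_per_day: float = 0.15,
    relapse_nadir_day: float = 8.0,
    relapse_regrowth_rate_per_day: float = 0.35,
    noise_cv: float = 0.0,
) -> GrowthRecord:
    """Parametric stand-in for a longitudinal spheroid-area experiment.

    Scenarios: ``untreated_exponential`` (areas double every
    ``area_doubling_days``), ``arrested`` (plateau), ``regressing``
    (exponential decay) and ``relapse`` (decay to a nadir, then regrowth).
    Sampling cadence defaults to every 2 days out to day 21, with
    multiplicative lognormal replicate noise of coefficient ``noise_cv``.
    """
    if scenario not in GROWTH_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {GROWTH_SCENARIOS}")
    if days is None:
        days = np.arange(0.0, 21.0 + 1e-9, 2.0)
    days = np.asarray(days, dtype=float)
    if scenario == "untreated_exponential":
        mean = initial_area_um2 * 2.0 ** (days / area_doubling_days)
    elif scenario == "arrested":
        mean = np.full_like(days, initial_area_um2)
    elif scenario == "regressing":
        mean = initial_area_um2 * np.exp(-regression_rate_per_day * days)
    else:  # relapse
        nadir = initial_area_um2 * np.exp(-regression_rate_per_day * relapse_nadir_day)
        mean = np.where(
            days <= relapse_nadir_day,
            initial_area_um2 * np.exp(-regression_rate_per_day * days),
            nadir * np.exp(relapse_regrowth_rate_per_day * (days - relapse_nadir_day)),
        )
    if noise_cv > 0:
        if rng is None:
            raise ValueError("pass an rng when noise_cv > 0")
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_replicates, len(days)))
        areas = mean[None, :] * noise
    else:
        areas = np.tile(mean, (n_replicates, 1))
    return GrowthRecord(condition=scenario, days=days, areas=areas)


@dataclass
class ExperimentTemplate:
    """The default two-drug study layout used by the CLI and examples."""

    tmz_doses_uM: tuple = TMZ_DOSES_UM
    dox_doses_uM: tuple = DOX_DOSES_UM
    combination_tmz_uM: float = 500.0
    schedule: DosingSchedule = field(default_factory=DosingSchedule)
    exposure_cycles: float = DEFAULT_EXPOSURE_CYCLES

    def tmz_fate_model(self) -> FateModel:
        """Cytostatic calibration (lambda = 1) from the synthetic 2D curve."""
        table = generate_dose_response(
            TMZ_IC50_UM, TMZ_HILL_SLOPE, np.geomspace(5.0, 2000.0, 9)
        )
        return build_fate_model(
            table, lam=1.0, exposure_cycles=self.exposure_cycles, name="TMZ",
            sustained_death=False,
        )

    def dox_fate_model(self) -> FateModel:
        """Cytotoxic calibration (lambda = 0) with a sustained death hazard."""
        table = generate_dose_response(
            DOX_IC50_UM, DOX_HILL_SLOPE, np.geomspace(0.0015, 5.0, 9)
        )
        return build_fate_model(
            table, lam=0.0, exposure_cycles=self.exposure_cycles, name="DOX",
            sustained_death=True,
        )

    def tmz_spec(self, dose_uM: float, transport_mode: str = "reaction_diffusion") -> DrugSpec:
        return DrugSpec(
            params=DrugParams(
                name="TMZ",
                diffusion_cm2_s=TMZ_DIFFUSION_CM2_S,
                uptake_M_per_cell_s=TMZ_UPTAKE_M_PER_CELL_S,
                boundary_dose_M=dose_uM * 1e-6,
                transport_mode=transport_mode,
            ),
            schedule=self.schedule,
            fate_model=self.tmz_fate_model(),
        )

    def dox_spec(self, dose_uM: float, transport_mode: str = "reaction_diffusion") -> DrugSpec:
        return DrugSpec(
            params=DrugParams(
                name="DOX",
                diffusion_cm2_s=DOX_DIFFUSION_CM2_S,
                uptake_M_per_cell_s=DOX_UPTAKE_M_PER_CELL_S,
                boundary_dose_M=dose_uM * 1e-6,
                transport_mode=transport_mode,
            ),
            schedule=self.schedule,
            fate_model=self.dox_fate_model(),
        )


def default_experiment() -> ExperimentTemplate:
    return ExperimentTemplate()
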