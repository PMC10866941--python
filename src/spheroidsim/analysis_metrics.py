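"""Evaluation metrics: growth inhibition, IC50, RMSE, replicate assembly.

"Area" for a simulated spheroid slice is the count of viable-state sites
times the site spacing squared (debris excluded), matching how segmented 2D
spheroid areas are read off micrographs of the central plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthRecord",
    "growth_inhibition",
    "ic50",
    "rmse_inhibition",
    "assemble_inhibition_series",
]


@dataclass
class GrowthRecord:
    """Replicated viable-area time series for one experimental condition.

    ``areas`` has shape (n_replicates, n_timepoints); ``days`` are days
    post-treatment, strictly increasing.
    """

    condition: str
    days: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.areas = np.atleast_2d(np.asarray(self.areas, dtype=float))
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.areas.shape[1] != len(self.days):
            raise ValueError("areas must have one column per timepoint")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.areas.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV form: condition, replicate, day, area."""
        rows = []
        for rep in range(self.n_replicates):
            for j, day in enumerate(self.days):
                rows.append(
                    {
                        "condition": self.condition,
                        "replicate": rep,
                        "day": day,
                        "area": self.areas[rep, j],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, condition: str | None = None) -> "GrowthRecord":
        required = {"condition", "replicate", "day", "area"}
        if not required.issubset(frame.columns):
            raise ValueError(f"growth table needs columns {sorted(required)}")
        if condition is not None:
            frame = frame[frame["condition"] == condition]
        else:
            conditions = frame["condition"].unique()
            if len(conditions) != 1:
                raise ValueError(
                    "table holds several conditions; pass the one to extract"
                )
            condition = conditions[0]
        pivot = frame.pivot_table(index="replicate", columns="day", values="area")
        return cls(
            condition=str(condition),
            days=pivot.columns.to_numpy(dtype=float),
            areas=pivot.to_numpy(dtype=float),
        )


def growth_inhibition(positive_control: float, test_value: float) -> float:
    """Percent growth inhibition: ((control - test) * 100) / control.

    Negative values (apparent growth stimulation) are passed through;
    clamping is the caller's choice.
    """
    if positive_control <= 0:
        raise ValueError("positive control must be positive")
    return (positive_control - test_value) * 100.0 / positive_control


def ic50(dose_response: pd.DataFrame) -> float:
    """Concentration (uM) inhibiting half of the population.

    Linear interpolation on (log10 concentration, inhibition) at the first
    upward crossing of 50%; an exactly-50% point returns its concentration.
    Raises if the table never brackets 50%.
    """
    required = {"concentration_uM", "inhibition_percent"}
    if not required.issubset(dose_response.columns):
        raise ValueError(f"dose-response table must have columns {sorted(required)}")
    conc = dose_response["concentration_uM"].to_numpy(dtype=float)
    inhib = dose_response["inhibition_percent"].to_numpy(dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive for log interpolation")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    for i in range(len(conc)):
        if inhib[i] == 50.0:
            return float(conc[i])
        if i > 0 and inhib[i - 1] < 50.0 < inhib[i]:
            x0, x1 = np.log10(conc[i - 1]), np.log10(conc[i])
            y0, y1 = inhib[i - 1], inhib[i]
            x = x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0)
            return float(10.0**x)
    raise ValueError("IC50 not bracketed: inhibition never crosses 50%")


def rmse_inhibition(
    reference_days: Sequence[float],
    reference_ratio: Sequence[float],
    simulated_days: Sequence[float],
    simulated_ratio: Sequence[float],
) -> float:
    """RMSE between two treated/untreated area-ratio time series.

    The series are matched on their common timepoints (intersection, which
    must be non-empty):  sqrt( sum_t (ratio_v(t) - ratio_s(t))^2 / N_t ).
    """
    ref_d = np.asarray(reference_days, dtype=float)
    sim_d = np.asarray(simulated_days, dtype=float)
    ref_r = np.asarray(reference_ratio, dtype=float)
    sim_r = np.asarray(simulated_ratio, dtype=float)
    common, ref_idx, sim_idx = np.intersect1d(ref_d, sim_d, return_indices=True)
    if len(common) == 0:
        raise ValueError("no common timepoints between the two series")
    diff = ref_r[ref_idx] - sim_r[sim_idx]
    return float(np.sqrt(np.sum(diff**2) / len(common)))


def assemble_inhibition_series(
    treated: GrowthRecord, control: GrowthRecord
) -> pd.DataFrame:
    """Treated/untreated area-ratio trajectory with propagated spread.

    Per common timepoint: ratio = mean(treated) / mean(control); the SD is
    first-order propagation of the replicate SDs,
    ratio * sqrt((sd_T/mean_T)^2 + (sd_C/mean_C)^2).  Returns a frame with
    columns day, ratio_mean, ratio_sd, n_treated, n_control.
    """
    if treated.n_replicates < 1 or control.n_replicates < 1:
        raise ValueError("need at least one replicate on each arm")
    common, ti, ci = np.intersect1d(treated.days, control.days, return_indices=True)
    if len(common) == 0:
        raise ValueError("no common timepoints between treated and control")
    t_areas = treated.areas[:, ti]
    c_areas = control.areas[:, ci]
    mean_t = t_areas.mean(axis=0)
    mean_c = c_areas.mean(axis=0)
    if np.any(mean_c <= 0):
        raise ValueError("control mean area is zero at some timepoint")
    sd_t = t_areas.std(axis=0, ddof=1) if treated.n_replicates > 1 else np.zeros_like(mean_t)
    sd_c = c_areas.std(axis=0, ddof=1) if control.n_replicates > 1 else np.zeros_like(mean_c)
    ratio = mean_t / mean_c
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_t = np.where(mean_t > 0, sd_t / np.where(mean_t > 0, mean_t, 1.0), 0.0)
        rel_c = sd_c / mean_c
    ratio_sd = ratio * np.sqrt(rel_t**2 + rel_c**2)
    return pd.DataFrame(
        {
            "day": common,
            "ratio_mean": ratio,
            "ratio_sd": ratio_sd,
            "n_treated": treated.n_replicates,
            "n_control": control.n_replicates,
        }
    )
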