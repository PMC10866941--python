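"""Dose-response to single-cell fate calibration.

The framework reduces a drug's action to two per-cycle probabilities at
mitosis: ``p``, the chance a cycling cell is unaffected and divides, and
``lambda``, the fraction of affected cells that enter irreversible G0
arrest rather than die.  Arrest probability is lambda*(1-p), death
probability (1-lambda)*(1-p).  Viable cells are the cycling ones plus the
arrested ones, which accumulate over cycles.

Tracking expectations of this branching process for ``k`` cycles gives the
treated-to-untreated viable ratio in closed form:

    P_k = (2p)^k                       cycling cells per founder
    G_k = lam*(1-p) * ((2p)^k - 1) / (2p - 1)      arrested (G0) cells
    ratio(p, lam, k) = (P_k + G_k) / 2^k

with the 2p = 1 limit G_k = k*lam*(1-p).  Equating this ratio to measured
dose-response inhibition (72 h assay, k = 72/22 ~ 3.27 cycles; real powers
extend the form to fractional k) and inverting for ``p`` converts a
conventional dose-response curve into dose-dependent single-cell fate
probabilities.  Because arrested cells stay in the viable pool, cytostatic
(lam = 1) and cytotoxic (lam = 0) drugs reaching the same end-of-assay
inhibition require different per-cycle survival p.

Fate lookups key on each cell's maximum experienced concentration, so a
hazard persists at later mitoses even after the extracellular field has
decayed -- the mechanism behind the long-term death probability of a
cytotoxic drug retained in tissue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lattice_core import Cell

__all__ = [
    "DoseResponsePoint",
    "FateModel",
    "viable_ratio",
    "calibrate_p",
    "build_fate_model",
    "decide_fate",
    "pava_non_increasing",
]

logger = logging.getLogger(__name__)

#: floor applied to target viable ratios so calibration stays well posed at
#: (numerically) 100% inhibition
RATIO_FLOOR = 1e-6


@dataclass(frozen=True)
class DoseResponsePoint:
    """One measured point: concentration (uM) vs % growth inhibition."""

    concentration_uM: float
    inhibition_percent: float

    def __post_init__(self) -> None:
        if self.concentration_uM < 0:
            raise ValueError("concentration must be non-negative")
        if self.inhibition_percent > 100.0:
            raise ValueError("inhibition cannot exceed 100%")


def _check_probs(p: float, lam: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")


def viable_ratio(
    p: float, lam: float, k: float, spontaneous_death: float = 0.0
) -> float:
    """Treated/untreated viable-population ratio after ``k`` cycles.

    ``spontaneous_death`` optionally folds a per-cycle intrinsic death
    probability into both numerator and denominator; it cancels to first
    order and defaults to zero in calibration.
    """
    _check_probs(p, lam)
    if k < 0:
        raise ValueError("k must be non-negative")
    if not 0.0 <= spontaneous_death < 1.0:
        raise ValueError("spontaneous_death must lie in [0, 1)")
    s = 1.0 - spontaneous_death
    a = 2.0 * s * p  # cycling-population growth factor per cycle
    if abs(a - 1.0) < 1e-12:
        g = k * s * lam * (1.0 - p)
    else:
        g = s * lam * (1.0 - p) * (a**k - 1.0) / (a - 1.0)
    return (a**k + g) / (2.0 * s) ** k


def calibrate_p(
    target_ratio: float, lam: float, k: float, spontaneous_death: float = 0.0
) -> float:
    """Invert ``viable_ratio`` for ``p`` at a measured viability ratio.

    The ratio is strictly increasing in p, so the root is unique; bisection
    (Brent) refines it until the ratio mismatch is below 1e-9.  Targets
    outside the attainable range [ratio(0), 1] raise with the range in the
    message -- a fully cytostatic drug, for instance, cannot push the viable
    ratio below lam / 2^k because arrested cells stay countable.
    """
    _check_probs(0.5, lam)
    if k < 0:
        raise ValueError("k must be non-negative")
    if not 0.0 < target_ratio <= 1.0:
        raise ValueError(f"target_ratio must lie in (0, 1], got {target_ratio}")
    floor = viable_ratio(0.0, lam, k, spontaneous_death)
    if target_ratio >= 1.0:
        return 1.0
    if target_ratio < floor:
        raise ValueError(
            f"target ratio {target_ratio:.6g} below the attainable range "
            f"[{floor:.6g}, 1] for lambda={lam}, k={k}"
        )
    if target_ratio == floor:
        return 0.0

    def f(p: float) -> float:
        return viable_ratio(p, lam, k, spontaneous_death) - target_ratio

    p = brentq(f, 0.0, 1.0, xtol=1e-13, rtol=8.9e-16)
    assert abs(f(p)) < 1e-9
    return float(p)


def pava_non_increasing(y: Sequence[float], w: Optional[Sequence[float]] = None) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences (L2)."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    blocks = [[y[i], w[i]] for i in range(len(y))]
    # enforce non-increasing by negating and enforcing non-decreasing
    vals = [[-v, wt] for v, wt in blocks]
    out: list[list[float]] = []
    counts: list[int] = []
    for v, wt in vals:
        out.append([v, wt])
        counts.append(1)
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            v1, w1 = out.pop()
            c1 = counts.pop()
            v0, w0 = out.pop()
            c0 = counts.pop()
            wt_new = w0 + w1
            out.append([(v0 * w0 + v1 * w1) / wt_new, wt_new])
            counts.append(c0 + c1)
    result = []
    for (v, _), c in zip(out, counts):
        result.extend([-v] * c)
    return np.array(result)


@dataclass
class FateModel:
    """Calibrated per-drug fate probabilities as a function of dose.

    ``concentrations_uM``/``p_values`` tabulate the unaffected probability;
    lookups interpolate linearly in log10 concentration with constant
    extrapolation outside the measured range, and a zero concentration is
    always unaffected (p = 1).  ``sustained_death`` records that the drug's
    death hazard is meant to persist after the field decays; persistence is
    realized automatically because lookups key on the exposure peak.
    """

    name: str
    lam: float
    exposure_cycles: float
    concentrations_uM: np.ndarray
    p_values: np.ndarray
    sustained_death: bool = False

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if np.any(self.concentrations_uM <= 0):
            raise ValueError("calibration concentrations must be positive")
        if np.any(np.diff(self.concentrations_uM) <= 0):
            raise ValueError("calibration concentrations must be strictly increasing")
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p values must lie in [0, 1]")
        if np.any(np.diff(self.p_values) > 1e-12):
            raise ValueError("p values must be non-increasing in dose")

    @classmethod
    def from_constant(
        cls, name: str, p: float, lam: float, exposure_cycles: float = 3.0, **kw
    ) -> "FateModel":
        """Dose-independent model (handy for validation runs)."""
        return cls(
            name=name,
            lam=lam,
            exposure_cycles=exposure_cycles,
            concentrations_uM=np.array([1e-6, 1e6]),
            p_values=np.array([p, p]),
            **kw,
        )

    def p_of(self, concentration_uM: float) -> float:
        """Unaffected probability at a concentration (uM)."""
        if concentration_uM <= 0.0:
            return 1.0
        logc = math.log10(concentration_uM)
        return float(
            np.interp(logc, np.log10(self.concentrations_uM), self.p_values)
        )

    def to_frame(self) -> pd.DataFrame:
        """Audit table of the calibrated probabilities."""
        return pd.DataFrame(
            {
                "concentration_uM": self.concentrations_uM,
                "p": self.p_values,
                "lambda": self.lam,
                "k": self.exposure_cycles,
                "sustained_death": self.sustained_death,
            }
        )


def build_fate_model(
    dose_response: pd.DataFrame,
    lam: float,
    exposure_cycles: float,
    name: str = "drug",
    sustained_death: bool = False,
) -> FateModel:
    """Calibrate a ``FateModel`` from a dose-response table.

    Expects columns ``concentration_uM`` and ``inhibition_percent`` with at
    least two positive, strictly increasing concentrations.  Each inhibition
    is converted to a target viable ratio (clamped into (1e-6, 1]; negative
    inhibition, i.e. apparent growth stimulation, clamps to ratio 1 with a
    logged warning), inverted for p, and the resulting sequence is projected
    onto non-increasing monotone form (pool-adjacent-violators) when
    measurement noise makes the raw p's locally non-monotone.  Targets below
    the lambda-dependent attainable floor calibrate to p = 0.
    """
    required = {"concentration_uM", "inhibition_percent"}
    if not required.issubset(dose_response.columns):
        raise ValueError(f"dose-response table must have columns {sorted(required)}")
    if len(dose_response) < 2:
        raise ValueError("need at least two dose points to calibrate")
    conc = dose_response["concentration_uM"].to_numpy(dtype=float)
    inhib = dose_response["inhibition_percent"].to_numpy(dtype=float)
    if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(inhib)):
        raise ValueError("dose-response values must be finite")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")

    floor = viable_ratio(0.0, lam, exposure_cycles)
    raw_p = np.empty(len(conc))
    for i, ih in enumerate(inhib):
        ratio = 1.0 - ih / 100.0
        if ratio > 1.0:
            logger.warning(
                "%s: inhibition %.3g%% < 0 at %.4g uM clamped to ratio 1 (p = 1)",
                name,
                ih,
                conc[i],
            )
            ratio = 1.0
        ratio = max(ratio, RATIO_FLOOR)
        if ratio < floor:
            logger.warning(
                "%s: target ratio %.3g at %.4g uM is below the attainable "
                "floor %.3g for lambda=%.3g; calibrating p = 0",
                name,
                ratio,
                conc[i],
                floor,
                lam,
            )
            raw_p[i] = 0.0
        else:
            raw_p[i] = calibrate_p(ratio, lam, exposure_cycles)

    p_mono = pava_non_increasing(raw_p)
    if np.max(np.abs(p_mono - raw_p)) > 1e-12:
        logger.info(
            "%s: non-monotone raw p sequence adjusted by isotonic projection "
            "(max change %.3g)",
            name,
            float(np.max(np.abs(p_mono - raw_p))),
        )
    return FateModel(
        name=name,
        lam=lam,
        exposure_cycles=exposure_cycles,
        concentrations_uM=conc,
        p_values=np.clip(p_mono, 0.0, 1.0),
        sustained_death=sustained_death,
    )


def decide_fate(
    cell: Cell,
    fate_models: dict[str, FateModel],
    rng: np.random.Generator,
) -> str:
    """Monotherapy fate draw at mitosis: proliferate, arrest, or die.

    The unaffected probability is looked up at the cell's maximum
    experienced concentration of the (single) drug.  Combination runs go
    through :func:`spheroidsim.combination_model.decide_fate_combination`,
    of which this is the one-drug special case.
    """
    from .combination_model import decide_fate_combination

    return decide_fate_combination(cell, fate_models, "toxic_dominates", rng)
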