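"""Combination-therapy fate algebra under probabilistic independence.

The null model assumes the probability of a cell being affected by one drug
is unchanged by the presence of the other: with per-drug affected
probabilities P_A = 1 - p_A and P_B = 1 - p_B, the chance of being affected
by either is P_A + P_B - P_A * P_B.  A cell affected by only one drug takes
that drug's fate split; a cell affected by both where the realized fates
disagree (one drug arrests, the other kills) has no prescribed outcome, so
the resolution is a policy: ``toxic_dominates`` (death wins, the default --
death is absorbing), ``static_dominates``, or ``coin_flip``.

``bliss_expected_inhibition`` is the population-level analogue used to score
supra-additivity of observed combination effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lattice_core import Cell
from .pharmacodynamics import FateModel
from . import streams

__all__ = [
    "INTERSECTION_POLICIES",
    "combined_affected_probability",
    "realized_drug_fates",
    "resolve_fates",
    "decide_fate_combination",
    "bliss_expected_inhibition",
    "bliss_excess",
    "classify_relapse",
    "run_combination_experiment",
]

INTERSECTION_POLICIES = ("toxic_dominates", "static_dominates", "coin_flip")


def combined_affected_probability(p_affected_a: float, p_affected_b: float):
    """Independence union of two affected-probabilities.

    Returns ``(P_AB, decomposition)`` where the decomposition maps
    ``only_a``/``only_b``/``both``/``neither`` to their probabilities (two
    independent Bernoulli draws; sums to one).
    """
    for v in (p_affected_a, p_affected_b):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"affected probability outside [0, 1]: {v}")
    pa, pb = p_affected_a, p_affected_b
    decomposition = {
        "only_a": pa * (1.0 - pb),
        "only_b": pb * (1.0 - pa),
        "both": pa * pb,
        "neither": (1.0 - pa) * (1.0 - pb),
    }
    return pa + pb - pa * pb, decomposition


def resolve_fates(realized: Sequence[str], policy: str, u_policy: float = 0.5) -> str:
    """Combine per-drug realized fates ("none", "G0", "die") into one outcome."""
    if policy not in INTERSECTION_POLICIES:
        raise ValueError(f"unknown intersection policy {policy!r}")
    active = [f for f in realized if f != "none"]
    if not active:
        return "proliferate"
    if all(f == "G0" for f in active):
        return "G0"
    if all(f == "die" for f in active):
        return "die"
    # mixed cytostatic/cytotoxic intersection
    if policy == "toxic_dominates":
        return "die"
    if policy == "static_dominates":
        return "G0"
    return "die" if u_policy < 0.5 else "G0"


def realized_drug_fates(
    cell: Cell,
    fate_models: dict[str, FateModel],
    uniforms: dict[str, tuple[float, float]],
) -> list[str]:
    """Per-drug realized fate from pre-drawn uniforms (u_affected, u_arrest)."""
    fates = []
    for name, model in fate_models.items():
        # exposure records are molar (field units); calibration tables are uM
        conc_uM = cell.max_conc.get(name, 0.0) * 1e6
        p = model.p_of(conc_uM)
        u1, u2 = uniforms[name]
        if u1 < p:
            fates.append("none")
        elif u2 < model.lam:
            fates.append("G0")
        else:
            fates.append("die")
    return fates


def decide_fate_combination(
    cell: Cell,
    fate_models: dict[str, FateModel],
    intersection_policy: str,
    rng: np.random.Generator,
    *,
    seed_root: Optional[int] = None,
) -> str:
    """Fate draw at mitosis under any number of drugs.

    With ``seed_root`` given, uniforms come from counter-based streams keyed
    by (cell id, cycle index, drug), so each drug's draws are reproducible
    and unperturbed by other drugs; otherwise ``rng`` supplies them.
    """
    if intersection_policy not in INTERSECTION_POLICIES:
        raise ValueError(f"unknown intersection policy {intersection_policy!r}")
    uniforms: dict[str, tuple[float, float]] = {}
    for name in fate_models:
        if seed_root is not None:
            g = streams.keyed_generator(
                seed_root, cell.cell_id, cell.cycle_index, streams.drug_channel(name)
            )
            u = g.random(2)
        else:
            u = rng.random(2)
        uniforms[name] = (float(u[0]), float(u[1]))
    fates = realized_drug_fates(cell, fate_models, uniforms)
    needs_policy_draw = {"G0", "die"} <= set(fates) and intersection_policy == "coin_flip"
    if needs_policy_draw:
        if seed_root is not None:
            g = streams.keyed_generator(
                seed_root, cell.cell_id, cell.cycle_index, streams.POLICY_CHANNEL
            )
            u3 = float(g.random())
        else:
            u3 = float(rng.random())
    else:
        u3 = 0.5
    return resolve_fates(fates, intersection_policy, u3)


# ---------------------------------------------------------------------------
# population-level scores
# ---------------------------------------------------------------------------


def bliss_expected_inhibition(effect_a: float, effect_b: float) -> float:
    """Expected combined fractional effect under Bliss independence."""
    for v in (effect_a, effect_b):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"fractional effect outside [0, 1]: {v}")
    return effect_a + effect_b - effect_a * effect_b


def bliss_excess(observed: float, effect_a: float, effect_b: float) -> float:
    """Observed minus Bliss-expected effect; positive = supra-additive."""
    return observed - bliss_expected_inhibition(effect_a, effect_b)


def classify_relapse(
    ratio_series: np.ndarray,
    days: np.ndarray,
    regrowth_factor: float = 1.10,
    sustain_days: float = 2.0,
) -> bool:
    """Flag regrowth of a treated/untreated ratio trajectory after its nadir.

    Relapse = the ratio exceeds ``regrowth_factor`` times its minimum and
    stays above it for at least ``sustain_days`` of consecutive observation.
    """
    ratio_series = np.asarray(ratio_series, dtype=float)
    days = np.asarray(days, dtype=float)
    if ratio_series.shape != days.shape:
        raise ValueError("ratio series and days must have the same shape")
    if len(ratio_series) < 2:
        return False
    i_nadir = int(np.argmin(ratio_series))
    threshold = regrowth_factor * ratio_series[i_nadir]
    above = ratio_series[i_nadir:] > threshold
    t = days[i_nadir:]
    run_start = None
    for i, flag in enumerate(above):
        if flag and run_start is None:
            run_start = t[i]
        elif flag and t[i] - run_start >= sustain_days:
            return True
        elif not flag:
            run_start = None
    return False


@dataclass
class CombinationSummary:
    """Per-dose-pair outcome of a combination grid run."""

    dose_a_uM: float
    dose_b_uM: float
    days: np.ndarray
    inhibition_ratio_mean: np.ndarray
    inhibition_ratio_sd: np.ndarray
    relapse: bool
    n_replicates: int


def run_combination_experiment(
    config,
    drug_a_builder,
    drug_b_builder,
    doses_a_uM: Sequence[float],
    doses_b_uM: Sequence[float],
    hypothesis: str = "null_independence",
    intersection_policy: str = "toxic_dominates",
    n_replicates: Optional[int] = None,
    base_seed: Optional[int] = None,
):
    """Run a dose grid of combination spheroid simulations.

    ``drug_a_builder(dose_uM)`` / ``drug_b_builder(dose_uM)`` return
    :class:`spheroidsim.engine.DrugSpec` objects at the requested dose.
    ``hypothesis`` is ``null_independence`` (both drugs keep their
    monotherapy transport) or ``alternative_fit`` (drug B switches to the
    no-diffusion, step-dilution transport while the fate algebra stays the
    null one).  Returns ``(summary_frame, summaries)`` with per-pair mean
    and SD inhibition-ratio trajectories and a relapse flag.
    """
    from .engine import run_replicates
    from .analysis_metrics import assemble_inhibition_series

    if hypothesis not in ("null_independence", "alternative_fit"):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    doses_a = list(doses_a_uM)
    doses_b = list(doses_b_uM)
    if not doses_a or not doses_b:
        raise ValueError("dose lists must be non-empty")
    reps = config.n_replicates if n_replicates is None else n_replicates
    seed = config.rng_seed if base_seed is None else base_seed

    control = run_replicates(config, [], seed, n_replicates=reps)
    rows = []
    summaries = []
    for da in doses_a:
        for db in doses_b:
            drugs = []
            if da > 0:
                drugs.append(drug_a_builder(da))
            if db > 0:
                spec_b = drug_b_builder(db)
                if hypothesis == "alternative_fit":
                    spec_b = spec_b.with_transport_mode("no_diffusion_alternative_fit")
                drugs.append(spec_b)
            treated = run_replicates(
                config, drugs, seed, n_replicates=reps, policy=intersection_policy
            )
            series = assemble_inhibition_series(treated, control)
            relapse = classify_relapse(series["ratio_mean"].to_numpy(), series["day"].to_numpy())
            summaries.append(
                CombinationSummary(
                    dose_a_uM=da,
                    dose_b_uM=db,
                    days=series["day"].to_numpy(),
                    inhibition_ratio_mean=series["ratio_mean"].to_numpy(),
                    inhibition_ratio_sd=series["ratio_sd"].to_numpy(),
                    relapse=relapse,
                    n_replicates=reps,
                )
            )
            rows.append(
                {
                    "dose_a_uM": da,
                    "dose_b_uM": db,
                    "final_inhibition_ratio": series["ratio_mean"].iloc[-1],
                    "min_inhibition_ratio": float(series["ratio_mean"].min()),
                    "relapse": relapse,
                    "n_replicates": reps,
                }
            )
    return pd.DataFrame(rows), summaries
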