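"""Dose-response calibration: closed form, inversion, fate model, fate draws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spheroidsim import (
    Cell,
    FateModel,
    build_fate_model,
    calibrate_p,
    decide_fate,
    viable_ratio,
)
from spheroidsim.pharmacodynamics import pava_non_increasing


def branching_oracle(p, lam, k, n_founders, rng):
    """Monte Carlo branching process, independent of the closed form.

    Per cycle each cycling cell divides unaffected (prob p, two cycling
    daughters), arrests permanently (prob lam*(1-p)) or dies.  Returns the
    mean viable count per founder divided by 2^k, and its standard error.
    """
    cycling = np.ones(n_founders, dtype=np.int64)
    arrested = np.zeros(n_founders, dtype=np.int64)
    for _ in range(int(k)):
        unaffected = rng.binomial(cycling, p)
        affected = cycling - unaffected
        newly_arrested = rng.binomial(affected, lam)
        arrested += newly_arrested
        cycling = 2 * unaffected
    viable = (cycling + arrested) / 2.0 ** int(k)
    return viable.mean(), viable.std(ddof=1) / np.sqrt(n_founders)


class TestViableRatio:
    def test_unaffected_drug_gives_ratio_one(self):
        for lam in (0.0, 0.5, 1.0):
            for k in (1, 3, 3.27):
                assert viable_ratio(1.0, lam, k) == pytest.approx(1.0)

    def test_pure_cytotoxic_closed_form_is_p_to_the_k(self):
        # lam=0: ratio = (2p)^k / 2^k = p^k, so ratio 0.5 at k=3 gives
        # p = 0.5^(1/3) ~ 0.7937
        p = 0.5 ** (1.0 / 3.0)
        assert viable_ratio(p, 0.0, 3) == pytest.approx(0.5, abs=1e-12)
        assert p == pytest.approx(0.7937, abs=5e-5)

    def test_pure_cytostatic_half_inhibition(self):
        """lam=1, k=3, target 0.5 inverts to p ~ 0.695 (bisection value)."""
        p = calibrate_p(0.5, 1.0, 3)
        assert p == pytest.approx(0.695, abs=1e-3)
        assert viable_ratio(p, 1.0, 3) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("k", [1, 3])
    def test_matches_branching_oracle(self, p, lam, k):
        rng = np.random.default_rng(hash((p, lam, k)) % 2**31)
        mean, se = branching_oracle(p, lam, k, 100_000, rng)
        assert abs(viable_ratio(p, lam, k) - mean) < 3 * se + 1e-9

    def test_half_growth_factor_limit(self):
        # 2p = 1 limit uses the l'Hopital form G_k = k lam (1-p)
        assert viable_ratio(0.5, 1.0, 3) == pytest.approx((1 + 3 * 0.5) / 8)

    def test_strictly_increasing_in_p(self):
        for lam in (0.0, 0.5, 1.0):
            for k in (1.0, 3.0, 3.27):
                ratios = [viable_ratio(p, lam, k) for p in np.linspace(0, 1, 21)]
                assert np.all(np.diff(ratios) > 0)

    def test_non_decreasing_in_lambda(self):
        for p in (0.1, 0.5, 0.9):
            for k in (1.0, 3.27):
                ratios = [viable_ratio(p, lam, k) for lam in np.linspace(0, 1, 11)]
                assert np.all(np.diff(ratios) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            viable_ratio(1.2, 0.5, 3)
        with pytest.raises(ValueError):
            viable_ratio(0.5, -0.1, 3)


class TestCalibrateP:
    def test_target_one_gives_p_one(self):
        assert calibrate_p(1.0, 0.7, 3.27) == 1.0

    def test_worked_cytotoxic_example(self):
        assert calibrate_p(0.5, 0.0, 3) == pytest.approx(0.7937005, abs=1e-6)

    @given(
        p=st.floats(0.01, 0.99),
        lam=st.floats(0.0, 1.0),
        k=st.floats(0.5, 5.0),
    )
    def test_round_trip_inverts_viable_ratio(self, p, lam, k):
        ratio = viable_ratio(p, lam, k)
        if ratio <= viable_ratio(0.0, lam, k):  # at/below attainable floor
            return
        assert calibrate_p(ratio, lam, k) == pytest.approx(p, abs=1e-6)

    def test_below_floor_reports_attainable_range(self):
        # fully cytostatic: floor = 1 / 2^k
        with pytest.raises(ValueError, match="attainable range"):
            calibrate_p(0.05, 1.0, 3)

    def test_mechanism_changes_calibrated_p_at_equal_inhibition(self):
        """Equal end-of-assay inhibition calibrates differently by mechanism,
        because arrested cells accumulate in the viable pool."""
        for r in (0.3, 0.5, 0.7):
            assert calibrate_p(r, 1.0, 3) != pytest.approx(
                calibrate_p(r, 0.0, 3), abs=1e-6
            )


class TestBuildFateModel:
    def test_interpolation_linear_in_log_dose(self):
        table = pd.DataFrame(
            {"concentration_uM": [1.0, 10.0], "inhibition_percent": [0.0, 50.0]}
        )
        model = build_fate_model(table, lam=0.0, exposure_cycles=3, name="A")
        assert model.p_of(1.0) == pytest.approx(1.0)
        assert model.p_of(10.0) == pytest.approx(0.7937005, abs=1e-6)
        # log-midpoint sits halfway between the endpoint p's
        mid = model.p_of(np.sqrt(10.0))
        assert mid == pytest.approx((1.0 + 0.7937005) / 2.0, abs=1e-6)

    def test_constant_extrapolation_and_zero_dose(self):
        table = pd.DataFrame(
            {"concentration_uM": [1.0, 10.0], "inhibition_percent": [20.0, 60.0]}
        )
        model = build_fate_model(table, lam=0.5, exposure_cycles=3, name="A")
        assert model.p_of(100.0) == model.p_of(10.0)
        assert model.p_of(0.5) == model.p_of(1.0)
        assert model.p_of(0.0) == 1.0

    def test_growth_stimulation_clamps_to_unaffected(self, caplog):
        table = pd.DataFrame(
            {"concentration_uM": [1.0, 10.0], "inhibition_percent": [-5.0, 50.0]}
        )
        with caplog.at_level("WARNING"):
            model = build_fate_model(table, lam=0.0, exposure_cycles=3)
        assert model.p_of(1.0) == 1.0
        assert "clamped" in caplog.text

    def test_noisy_p_sequence_projected_monotone(self):
        table = pd.DataFrame(
            {
                "concentration_uM": [1.0, 2.0, 4.0, 8.0],
                "inhibition_percent": [10.0, 30.0, 20.0, 60.0],
            }
        )
        model = build_fate_model(table, lam=0.0, exposure_cycles=3)
        assert np.all(np.diff(model.p_values) <= 1e-12)
        # matches a direct pool-adjacent-violators projection of the raw p's
        raw = np.array(
            [calibrate_p(1 - i / 100, 0.0, 3) for i in [10.0, 30.0, 20.0, 60.0]]
        )
        np.testing.assert_allclose(model.p_values, pava_non_increasing(raw), atol=1e-12)

    def test_pava_oracle_simple_average(self):
        # one violation pools two neighbors to their mean
        np.testing.assert_allclose(
            pava_non_increasing([0.9, 0.5, 0.7, 0.3]), [0.9, 0.6, 0.6, 0.3]
        )

    def test_pava_matches_sklearn_isotonic_projection(self, rng):
        from sklearn.isotonic import IsotonicRegression

        for _ in range(20):
            y = rng.uniform(0, 1, size=rng.integers(2, 12))
            ours = pava_non_increasing(y)
            ref = IsotonicRegression(increasing=False).fit_transform(
                np.arange(len(y)), y
            )
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_unordered_concentrations_rejected(self):
        table = pd.DataFrame(
            {"concentration_uM": [10.0, 1.0], "inhibition_percent": [50.0, 0.0]}
        )
        with pytest.raises(ValueError, match="increasing"):
            build_fate_model(table, lam=0.0, exposure_cycles=3)

    def test_single_point_rejected(self):
        table = pd.DataFrame(
            {"concentration_uM": [10.0], "inhibition_percent": [50.0]}
        )
        with pytest.raises(ValueError, match="two dose points"):
            build_fate_model(table, lam=0.0, exposure_cycles=3)


class TestDecideFate:
    def _cell_with_exposure(self, conc_M):
        cell = Cell(cell_id=0)
        cell.record_exposure("A", conc_M)
        return cell

    def test_unaffected_drug_always_proliferates(self, rng):
        model = FateModel.from_constant("A", p=1.0, lam=0.5)
        cell = self._cell_with_exposure(1e-6)
        assert all(
            decide_fate(cell, {"A": model}, rng) == "proliferate" for _ in range(200)
        )

    def test_certain_cytostatic_always_arrests(self, rng):
        model = FateModel.from_constant("A", p=0.0, lam=1.0)
        cell = self._cell_with_exposure(1e-6)
        assert all(decide_fate(cell, {"A": model}, rng) == "G0" for _ in range(200))

    def test_outcome_proportions_match_multinomial(self, rng):
        """p=0.6, lam=0.5 over 1e5 draws: (0.6, 0.2, 0.2) within 3 sigma."""
        model = FateModel.from_constant("A", p=0.6, lam=0.5)
        cell = self._cell_with_exposure(1e-6)
        n = 100_000
        counts = {"proliferate": 0, "G0": 0, "die": 0}
        for _ in range(n):
            counts[decide_fate(cell, {"A": model}, rng)] += 1
        for outcome, expected in (("proliferate", 0.6), ("G0", 0.2), ("die", 0.2)):
            sigma = np.sqrt(n * expected * (1 - expected))
            assert abs(counts[outcome] - n * expected) < 3 * sigma

    def test_zero_exposure_never_affected(self, rng):
        model = FateModel.from_constant("A", p=0.1, lam=0.0)
        cell = Cell(cell_id=0)  # no exposure recorded
        assert all(
            decide_fate(cell, {"A": model}, rng) == "proliferate" for _ in range(200)
        )
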