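"""Reaction-diffusion drug fields, dosing schedules, and exposure records."""

import numpy as np
import pytest

from spheroidsim import (
    Cell,
    DosingSchedule,
    DrugField,
    DrugParams,
    Lattice,
    SimulationConfig,
    alternative_fit_step,
    apply_medium_exchange,
    init_spheroid_slice,
    record_max_concentration,
    step_field,
)
from spheroidsim.drug_transport import explicit_stability_limit_s

D_FAST = 8.68e-7  # cm^2/s


def make_field(
    n=31, D=D_FAST, gamma=0.0, dose=1.0, mode="reaction_diffusion", init=None
):
    params = DrugParams("X", D, gamma, dose, transport_mode=mode)
    return DrugField(params, DosingSchedule(), n, n, initial_concentration_M=init)


def analytic_dirichlet_relaxation(n, D, dose, t, spacing_um=15.0, n_terms=400):
    """Series solution for a square with zero interior and bath-clamped edges.

    The deficit from the bath separates into a product of 1D slab series:
    C = dose * (1 - f(x, t) f(y, t)) with
    f(x, t) = sum_m 4/(m pi) sin(m pi x / L) exp(-D (m pi / L)^2 t), m odd.
    """
    h = spacing_um * 1e-4
    L = (n - 1) * h
    x = np.arange(n) * h
    f = np.zeros(n)
    for j in range(n_terms):
        m = 2 * j + 1
        f += 4 / (m * np.pi) * np.sin(m * np.pi * x / L) * np.exp(
            -D * (m * np.pi / L) ** 2 * t
        )
    return dose - dose * np.outer(f, f)


class TestStepField:
    def test_uniform_field_at_bath_is_steady_state(self):
        field = make_field(gamma=0.0, init=1.0)
        lat = Lattice(31, 31)
        before = field.grid.copy()
        for _ in range(10):
            step_field(field, lat, 60.0)
        np.testing.assert_allclose(field.grid, before, atol=1e-12)

    def test_relaxation_matches_analytic_series(self):
        """Implicit solution vs the separable slab series, < 1% of the dose."""
        field = make_field(n=61, init=0.0)
        lat = Lattice(61, 61)
        t = 0.0
        for _ in range(60):
            step_field(field, lat, 60.0)
            t += 60.0
        ref = analytic_dirichlet_relaxation(61, D_FAST, 1.0, t)
        assert np.max(np.abs(field.grid - ref)) < 0.01

    def test_interior_rises_monotonically_toward_bath(self):
        field = make_field(n=31, init=0.0)
        lat = Lattice(31, 31)
        prev_deficit = np.inf
        for _ in range(30):
            step_field(field, lat, 60.0)
            deficit = np.max(np.abs(field.grid - 1.0))
            assert deficit <= prev_deficit + 1e-12
            prev_deficit = deficit
        assert prev_deficit < 1e-3

    def test_uptake_depresses_center_below_rim(self, rng):
        cfg = SimulationConfig(n_rows=41, n_cols=41)
        lat = init_spheroid_slice(cfg, 10, rng)
        field = make_field(n=41, gamma=2e-10, dose=1e-4, init=0.0)
        for _ in range(120):
            step_field(field, lat, 60.0)
        c = field.grid
        assert c[20, 20] < c[20, 2]

    def test_maximum_principle_bounds(self, rng):
        cfg = SimulationConfig(n_rows=41, n_cols=41)
        lat = init_spheroid_slice(cfg, 10, rng)
        field = make_field(n=41, gamma=1e-9, dose=1e-5, init=0.0)
        for _ in range(200):
            step_field(field, lat, 60.0)
            assert field.grid.min() >= 0.0
            assert field.grid.max() <= 1e-5 + 1e-18

    def test_explicit_and_implicit_solvers_agree(self, rng):
        """Cross-validation on a 2 h horizon with an uptake sink, < 0.5%."""
        cfg = SimulationConfig(n_rows=41, n_cols=41)
        lat = init_spheroid_slice(cfg, 10, rng)
        dose = 1e-4
        fi = make_field(n=41, gamma=2e-10, dose=dose, init=0.0)
        fe = make_field(n=41, gamma=2e-10, dose=dose, init=0.0)
        for _ in range(120):
            step_field(fi, lat, 60.0)
        dt_e = 0.25
        for _ in range(int(7200 / dt_e)):
            step_field(fe, lat, dt_e, method="explicit")
        assert np.max(np.abs(fi.grid - fe.grid)) / dose < 0.005

    def test_explicit_rejects_unstable_step(self):
        field = make_field()
        lat = Lattice(31, 31)
        limit = explicit_stability_limit_s(D_FAST, 15.0)
        with pytest.raises(ValueError, match="stability"):
            step_field(field, lat, 2 * limit, method="explicit")

    def test_homogeneous_mode_tracks_bath_exactly(self):
        field = make_field(mode="homogeneous", dose=0.5)
        lat = Lattice(31, 31)
        step_field(field, lat, 60.0)
        assert np.all(field.grid == 0.5)
        apply_medium_exchange(field, 0.5)
        step_field(field, lat, 60.0)
        assert np.all(field.grid == 0.25)


class TestMediumExchange:
    def test_zero_fraction_no_change(self):
        field = make_field(dose=1.0, init=1.0)
        apply_medium_exchange(field, 0.0)
        assert field.bath_dose_M == 1.0

    def test_full_exchange_zeroes_bath(self):
        field = make_field(dose=1.0, init=1.0)
        apply_medium_exchange(field, 1.0)
        assert field.bath_dose_M == 0.0

    def test_two_half_exchanges_quarter_dose(self):
        field = make_field(dose=500e-6, init=500e-6)
        apply_medium_exchange(field, 0.5)
        apply_medium_exchange(field, 0.5)
        assert field.bath_dose_M == pytest.approx(125e-6)

    def test_interior_untouched_by_exchange(self):
        field = make_field(dose=1.0, init=0.7)
        interior_before = field.grid[5:-5, 5:-5].copy()
        apply_medium_exchange(field, 0.5)
        np.testing.assert_array_equal(field.grid[5:-5, 5:-5], interior_before)

    def test_fraction_out_of_range_rejected(self):
        field = make_field()
        with pytest.raises(ValueError):
            apply_medium_exchange(field, 1.5)


class TestAlternativeFit:
    def make_alt_field(self, dose, retained=1.0 / 3.0):
        params = DrugParams("B", 0.0, 0.0, dose, transport_mode="no_diffusion_alternative_fit")
        sched = DosingSchedule(alternative_fit_retained_fraction=retained)
        return DrugField(params, sched, 11, 11)

    def test_constant_before_72h(self):
        field = self.make_alt_field(0.9e-6)
        alternative_fit_step(field, 0.0, 71.0)
        assert np.all(field.grid == 0.9e-6)

    def test_two_dilutions_with_one_third_retained(self):
        field = self.make_alt_field(0.9e-6)
        alternative_fit_step(field, 0.0, 121.0)  # crosses 72 h and 120 h
        assert field.n_dilutions == 2
        assert field.grid[0, 0] == pytest.approx(0.9e-6 / 9.0)

    def test_dilutions_only_at_scheduled_marks(self):
        field = self.make_alt_field(1.0)
        t = 0.0
        event_times = []
        for _ in range(180):
            before = field.bath_dose_M
            alternative_fit_step(field, t, 1.0)
            t += 1.0
            if field.bath_dose_M != before:
                event_times.append(t)
        assert event_times == [72.0, 120.0, 168.0]

    def test_requires_alternative_mode(self):
        field = make_field()
        with pytest.raises(ValueError, match="mode"):
            alternative_fit_step(field, 0.0, 1.0)


class TestExposureRecording:
    def test_constant_field_sets_peak_everywhere(self):
        lat = Lattice(11, 11)
        for i in range(5):
            lat.place((5, i), Cell())
        field = make_field(n=11, mode="homogeneous", dose=2.0)
        step_field(field, lat, 60.0)
        record_max_concentration(field, lat)
        assert all(c.max_conc["X"] == 2.0 for c in lat.cells.values())

    def test_peak_survives_field_decay(self):
        lat = Lattice(11, 11)
        cell = Cell()
        lat.place((5, 5), cell)
        field = make_field(n=11, mode="homogeneous", dose=2.0)
        step_field(field, lat, 60.0)
        record_max_concentration(field, lat)
        apply_medium_exchange(field, 0.9)
        step_field(field, lat, 60.0)
        record_max_concentration(field, lat)
        assert cell.max_conc["X"] == 2.0
        assert cell.current_conc["X"] == pytest.approx(0.2)

    def test_newborn_starts_from_local_value_not_inherited(self):
        lat = Lattice(11, 11)
        mother = Cell()
        lat.place((5, 5), mother)
        field = make_field(n=11, mode="homogeneous", dose=2.0)
        step_field(field, lat, 60.0)
        record_max_concentration(field, lat)
        apply_medium_exchange(field, 0.75)
        step_field(field, lat, 60.0)
        daughter = Cell()
        lat.place((5, 6), daughter)
        record_max_concentration(field, lat)
        assert mother.max_conc["X"] == 2.0
        assert daughter.max_conc["X"] == pytest.approx(0.5)


class TestDrugParams:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            DrugParams("X", -1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            DrugParams("X", 1e-7, 0.0, -1.0)

    def test_unknown_transport_mode_rejected(self):
        with pytest.raises(ValueError, match="transport_mode"):
            DrugParams("X", 1e-7, 0.0, 1.0, transport_mode="teleport")

    def test_schedule_exchange_times(self):
        sched = DosingSchedule()
        times = sched.medium_exchange_times_h(24.0 * 10)
        assert list(times) == [72.0, 120.0, 168.0, 216.0]
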