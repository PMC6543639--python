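"""Selection dynamics through fractionated courses and repopulation models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lqhet import (
    FractionationSchedule,
    GridConfig,
    InputDomainError,
    LQParams,
    RadiosensitivityGrid,
    RepopulationModel,
    TumorState,
    apply_fraction,
    apply_repopulation,
    build_grid,
    repopulation_rates,
    resistance_shift,
    simulate_course,
    summarize,
    survival_fraction,
)

from conftest import OE33


@pytest.fixture(scope="module")
def oe33_state():
    return TumorState(build_grid(OE33, GridConfig()), 1e10)


class TestApplyFraction:
    def test_homogeneous_state_scales_without_composition_change(self):
        g = RadiosensitivityGrid.from_points([(0.3, 0.02)])
        st0 = TumorState(g, 1e10)
        st1 = apply_fraction(st0, 2.0)
        assert st1.total_cells == pytest.approx(
            1e10 * survival_fraction(LQParams(0.3, 0.02), 2.0, 1), rel=1e-12
        )
        np.testing.assert_allclose(st1.grid.density, st0.grid.density)

    def test_two_subset_hand_computed_weights(self):
        # exp(-0.48) = 0.6188, exp(-0.88) = 0.4148; renormalized by hand.
        g = RadiosensitivityGrid.from_points([(0.2, 0.02), (0.4, 0.02)], [0.5, 0.5])
        st1 = apply_fraction(TumorState(g, 1e10), 2.0)
        w = st1.grid.to_frame().sort_values("alpha")["density"].to_numpy()
        s_sens, s_res = math.exp(-0.88), math.exp(-0.48)
        assert w[0] == pytest.approx(s_res / (s_res + s_sens), abs=1e-4)
        assert w[0] == pytest.approx(0.5987, abs=2e-4)
        assert w[1] == pytest.approx(0.4013, abs=2e-4)

    def test_oe33_after_25x2_matches_published_row(self, oe33_state):
        state = oe33_state
        for _ in range(25):
            state = apply_fraction(state, 2.0)
        s = summarize(state.grid)
        assert s.mean_alpha_beta_ratio == pytest.approx(13.7, abs=0.1)
        assert s.mean_sf2 == pytest.approx(0.56, abs=0.005)

    def test_zero_dose_rejected(self, oe33_state):
        with pytest.raises(InputDomainError):
            apply_fraction(oe33_state, 0.0)


class TestRepopulationRates:
    def test_theta_zero_gives_flat_mu(self, oe33_state):
        rates = repopulation_rates(oe33_state.grid, RepopulationModel.resistant_faster(0.3, 0.0))
        sup = oe33_state.grid.support
        np.testing.assert_allclose(rates[sup], 0.3)

    def test_max_sf2_cell_gets_exactly_mu(self, oe33_state):
        model = RepopulationModel.resistant_faster(0.3, 5.5)
        rates = repopulation_rates(oe33_state.grid, model)
        assert rates.max() == pytest.approx(0.3, rel=1e-12)
        sup = oe33_state.grid.support
        imax = np.argmax(np.where(sup, oe33_state.grid.sf2, -1))
        assert rates.flat[imax] == pytest.approx(0.3, rel=1e-12)

    def test_hand_computed_coupled_rate(self):
        # two subsets with SF2 0.4 and 0.6: slower cell gets mu*exp(theta*(0.4-0.6))
        a_for = lambda s2: -0.5 * math.log(s2) - 2 * 0.02  # invert SF2 at beta=0.02
        g = RadiosensitivityGrid.from_points(
            [(a_for(0.4), 0.02), (a_for(0.6), 0.02)], [0.5, 0.5]
        )
        rates = repopulation_rates(g, RepopulationModel.resistant_faster(0.3, 5.5))
        assert rates.max() == pytest.approx(0.3)
        slow = rates[rates > 0].min()
        assert slow == pytest.approx(0.3 * math.exp(-1.1), abs=1e-4)  # 0.0999

    def test_sensitive_faster_inverts_ordering(self, oe33_state):
        res = repopulation_rates(oe33_state.grid, RepopulationModel.resistant_faster())
        sen = repopulation_rates(oe33_state.grid, RepopulationModel.sensitive_faster())
        sup = oe33_state.grid.support
        s2 = oe33_state.grid.sf2[sup]
        hi, lo = s2 > np.quantile(s2, 0.9), s2 < np.quantile(s2, 0.1)
        assert res[sup][hi].mean() > res[sup][lo].mean()
        assert sen[sup][hi].mean() < sen[sup][lo].mean()


class TestApplyRepopulation:
    def test_uniform_growth_is_pure_scaling(self, oe33_state):
        st1 = apply_repopulation(oe33_state, RepopulationModel.uniform(0.15))
        assert st1.total_cells == pytest.approx(1.15e10, rel=1e-12)
        np.testing.assert_array_equal(st1.grid.density, oe33_state.grid.density)

    def test_zero_rate_is_identity(self, oe33_state):
        st1 = apply_repopulation(oe33_state, RepopulationModel.none())
        assert st1.total_cells == oe33_state.total_cells

    def test_resistant_faster_raises_mean_sf2_in_one_day(self, oe33_state):
        st1 = apply_repopulation(oe33_state, RepopulationModel.resistant_faster())
        assert summarize(st1.grid).mean_sf2 > summarize(oe33_state.grid).mean_sf2


class TestSimulateCourse:
    def test_pure_growth_with_empty_dose_days(self, oe33_state):
        # one token fraction on day 10 -> 9 leading growth-only days
        sched = FractionationSchedule(((10, 2.0),))
        traj = simulate_course(oe33_state, sched, RepopulationModel.uniform(0.10))
        day9 = traj.records[9]
        assert day9.total_cells == pytest.approx(1e10 * 1.10**9, rel=1e-9)
        np.testing.assert_allclose(
            traj.records[9].summary.mean_sf2, traj.initial.summary.mean_sf2, rtol=1e-12
        )

    def test_standard_course_selects_resistant_majority(self, oe33_state):
        traj = simulate_course(
            oe33_state,
            FractionationSchedule.weekday(35, 2.0),
            RepopulationModel.uniform(0.15),
        )
        final_bins = traj.final.summary.bin_fractions
        assert final_bins[(0.55, 1.0)] > 0.80
        assert traj.final.day == 47
        assert len(traj.records) == 48  # day 0 + days 1..47

    def test_uniform_rate_only_scales_absolute_counts(self, oe33_state):
        sched = FractionationSchedule.weekday(15, 2.0)
        t_a = simulate_course(oe33_state, sched, RepopulationModel.uniform(0.05))
        t_b = simulate_course(oe33_state, sched, RepopulationModel.uniform(0.25))
        for ra, rb in zip(t_a.records, t_b.records):
            assert ra.summary.mean_sf2 == pytest.approx(rb.summary.mean_sf2, abs=1e-12)
            assert ra.summary.mean_alpha_beta_ratio == pytest.approx(
                rb.summary.mean_alpha_beta_ratio, abs=1e-10
            )
        ratio = t_b.final.total_cells / t_a.final.total_cells
        assert ratio == pytest.approx((1.25 / 1.05) ** sched.last_day, rel=1e-9)

    def test_homogeneous_limit_reproduces_closed_form(self):
        g = RadiosensitivityGrid.from_points([(0.35, 0.025)])
        sched = FractionationSchedule.weekday(10, 3.0)
        traj = simulate_course(TumorState(g, 1e10), sched, RepopulationModel.uniform(0.15))
        expected = (
            1e10
            * survival_fraction(LQParams(0.35, 0.025), 3.0, 10)
            * 1.15**sched.last_day
        )
        assert traj.final.total_cells == pytest.approx(expected, rel=1e-9)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(perm=st.permutations(list(range(5))))
    def test_fraction_order_invariance_without_repopulation(self, perm):
        doses = [1.0, 2.0, 3.0, 4.5, 7.0]
        grid = build_grid(OE33, GridConfig(resolution=101))
        base = TumorState(grid, 1e10)
        ref = base
        for d in doses:
            ref = apply_fraction(ref, d)
        other = base
        for i in perm:
            other = apply_fraction(other, doses[i])
        np.testing.assert_allclose(other.grid.density, ref.grid.density, atol=1e-10)
        assert other.total_cells == pytest.approx(ref.total_cells, rel=1e-10)

    def test_trajectory_csv_roundtrip(self, oe33_state, tmp_path):
        traj = simulate_course(
            oe33_state, FractionationSchedule.weekday(5, 2.0), RepopulationModel.uniform()
        )
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df["day"]) == list(range(0, 6))
        assert df["total_cells"].iloc[-1] == pytest.approx(traj.final.total_cells)


class TestResistanceShift:
    def test_day_zero_shifts_are_zero(self, oe33_state):
        traj = simulate_course(
            oe33_state, FractionationSchedule.weekday(5, 2.0), RepopulationModel.uniform()
        )
        shifts = resistance_shift(traj)
        assert shifts["sf2_shift"].iloc[0] == 0.0
        assert shifts["alpha_beta_shift"].iloc[0] == 0.0

    def test_selection_directions_across_course(self, oe33_state):
        traj = simulate_course(
            oe33_state, FractionationSchedule.weekday(35, 2.0), RepopulationModel.uniform()
        )
        shifts = resistance_shift(traj)
        fraction_days = [r.day for r in traj.records if r.fraction_index is not None]
        ab = shifts.set_index("day")["alpha_beta_shift"].loc[fraction_days]
        s2 = shifts.set_index("day")["sf2_shift"].loc[fraction_days]
        assert (ab.diff().dropna() < 0).all()  # ratio falls on every fraction day
        assert (s2.diff().dropna() > 0).all()  # SF2 rises on every fraction day
        assert shifts["sf2_shift"].iloc[-1] > 0
        assert shifts["alpha_beta_shift"].iloc[-1] < 0

    def test_homogeneous_tumor_never_shifts(self):
        g = RadiosensitivityGrid.from_points([(0.3, 0.03)])
        traj = simulate_course(
            TumorState(g, 1e10),
            FractionationSchedule.weekday(10, 2.0),
            RepopulationModel.uniform(),
        )
        shifts = resistance_shift(traj)
        assert (shifts["sf2_shift"].abs() < 1e-12).all()
        assert (shifts["alpha_beta_shift"].abs() < 1e-10).all()


class TestScheduleFamilies:
    """Orderings across BED-equivalent arms and repopulation couplings."""

    ARMS = [(25, 2.0), (20, 2.4), (15, 3.0), (10, 4.2), (5, 7.0)]

    @pytest.fixture()
    def d4_state(self, tumors):
        return tumors["D4"]

    def test_bed_equivalence_breaking_across_arms(self, d4_state):
        survivals, shifts = [], []
        for n, d in self.ARMS:
            traj = simulate_course(
                d4_state, FractionationSchedule.weekday(n, d), RepopulationModel.uniform(0.15)
            )
            survivals.append(traj.final.total_cells / d4_state.total_cells)
            shifts.append(resistance_shift(traj)["sf2_shift"].iloc[-1])
        # larger dose per fraction: lower end survival, smaller induced shift
        assert all(a > b for a, b in zip(survivals, survivals[1:]))
        assert all(a > b for a, b in zip(shifts, shifts[1:]))

    def test_arm_beds_are_close_to_60(self):
        # rounded fraction counts: exact BEDs are 60 / 59.52 / 58.5 / 59.64 / 59.5
        for (n, d), expected in zip(self.ARMS, (60.0, 59.52, 58.5, 59.64, 59.5)):
            sched = FractionationSchedule.weekday(n, d)
            assert sched.bed(10.0) == pytest.approx(expected, abs=1e-9)

    def test_repopulation_coupling_orders_survival_curves(self, d4_state):
        sched = FractionationSchedule.weekday(25, 2.0)
        curves = {
            mode: simulate_course(d4_state, sched, model)
            for mode, model in [
                ("uniform", RepopulationModel.uniform(0.15)),
                ("resistant", RepopulationModel.resistant_faster(0.3, 5.5)),
                ("sensitive", RepopulationModel.sensitive_faster(0.3, 5.5)),
            ]
        }
        uni = np.array([r.total_cells for r in curves["uniform"].records[1:]])
        res = np.array([r.total_cells for r in curves["resistant"].records[1:]])
        sen = np.array([r.total_cells for r in curves["sensitive"].records[1:]])
        # by end of course the coupled modes bracket the uniform curve
        assert res[-1] > uni[-1] > sen[-1]
        assert (res[10:] >= uni[10:]).all()
        assert (sen[10:] <= uni[10:]).all()
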