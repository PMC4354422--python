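import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.integrate import quad

from chondrosim import kinetics
from chondrosim.grid_operators import make_age_grid
from chondrosim.kinetics import (
    CellStateLocal,
    ChemState,
    age_boundary_inflows,
    age_integral,
    cell_rates,
    chem_reaction_rates,
    ecm_rate,
    gamma_kernel,
    heaviside,
    hill,
)
from chondrosim.parameters import default_params


def _local_cells(n_a, **kwargs):
    base = dict(C_U=0.0, C_E=0.0, S_A=0.0, D_N=0.0,
                C_T_of_a=np.zeros(n_a), S_T_of_a=np.zeros(n_a))
    base.update(kwargs)
    return CellStateLocal(**base)


def _zero_chem(**kwargs):
    base = dict(R=0.0, M=0.0, F=0.0, P=0.0, U=0.0)
    base.update(kwargs)
    return ChemState(**base)


class TestHeavisideAndHill:
    @pytest.mark.parametrize("theta, expected", [(0.5, 1.0), (-0.5, 0.0),
                                                 (0.0, 0.0)])
    def test_heaviside_branches(self, theta, expected):
        assert heaviside(theta) == expected

    @pytest.mark.parametrize("x, lam, expected", [
        (0.0, 5.0, 0.0),
        (5.0, 5.0, 0.5),
        # initial ROS burst level against its half-saturation constant
        (240.0, 5.0, 240.0 / 245.0),
    ])
    def test_hill_values(self, x, lam, expected):
        assert hill(x, lam) == pytest.approx(expected, rel=1e-12)

    def test_hill_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            hill(-1.0, 5.0)

    @given(x=st.floats(0, 1e6), y=st.floats(0, 1e6),
           lam=st.floats(0.01, 100))
    def test_hill_monotone_and_bounded(self, x, y, lam):
        lo, hi = sorted([x, y])
        assert 0.0 <= hill(lo, lam) <= hill(hi, lam) < 1.0


class TestGammaKernel:
    def test_midpoint_value(self):
        # tanh(0) = 0 so the kernel is gamma_0/sigma at the transition age
        assert gamma_kernel(1.0, 1.0, 2.0, 0.05) == pytest.approx(2.0 / 0.05)

    def test_vanishes_well_before_transition_age(self):
        val = gamma_kernel(1.0 - 10 * 0.05, 1.0, 1.0, 0.05)
        assert val < 1e-8 * (1.0 / 0.05)

    def test_plateau_doubles_when_spread_halves(self):
        a = 10.0  # far beyond the transition age
        v1 = gamma_kernel(a, 1.0, 1.0, 0.05)
        v2 = gamma_kernel(a, 1.0, 1.0, 0.025)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    @given(hnp.arrays(np.float64, 10,
                      elements=st.floats(0, 3, allow_nan=False)))
    def test_nonnegative_and_nondecreasing(self, ages):
        ages = np.sort(ages)
        vals = gamma_kernel(ages, 1.0, 1.0, 0.05)
        assert np.all(vals >= 0)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_rejects_nonpositive_spread(self):
        with pytest.raises(ValueError):
            gamma_kernel(1.0, 1.0, 1.0, 0.0)


class TestAgeIntegral:
    def test_constant_density_exact(self):
        ag = make_age_grid(129, 3.0)
        assert age_integral(np.ones(129), ag.centers) == pytest.approx(3.0)

    def test_linear_density_exact(self):
        ag = make_age_grid(64, 3.0)
        density = 2.0 + 3.0 * ag.centers
        exact = 2.0 * 3.0 + 1.5 * 3.0**2
        assert age_integral(density, ag.centers) == pytest.approx(
            exact, rel=1e-12
        )

    def test_second_order_against_quadrature(self):
        # smooth sharp integrand: transition kernel with a 0.1-day spread
        exact, _ = quad(lambda a: gamma_kernel(a, 1.0, 1.0, 0.1), 0, 3,
                        limit=200)
        errs = []
        for n_a in (64, 1024):
            ag = make_age_grid(n_a, 3.0)
            approx = age_integral(gamma_kernel(ag.centers, 1.0, 1.0, 0.1),
                                  ag.centers)
            errs.append(abs(approx - exact))
        # 16x refinement should shrink the error by roughly 16^2
        assert errs[0] < 1e-3
        assert errs[0] / max(errs[1], 1e-15) > 50

    def test_length_mismatch_rejected(self):
        ag = make_age_grid(16, 3.0)
        with pytest.raises(ValueError):
            age_integral(np.ones(15), ag.centers)


class TestChemAndEcmRates:
    def setup_method(self):
        self.p = default_params()
        self.ag = make_age_grid(129, 3.0)

    def test_all_zero_state_is_inert(self):
        rates = chem_reaction_rates(_zero_chem(), _local_cells(129),
                                    self.p, self.ag.centers)
        assert rates == (0.0, 0.0, 0.0, 0.0)

    def test_ros_pure_decay(self):
        rates = chem_reaction_rates(_zero_chem(R=240.0), _local_cells(129),
                                    self.p, self.ag.centers)
        assert rates[0] == pytest.approx(-60.0 * 240.0)

    def test_damp_production_by_necrotic_cells(self):
        cells = _local_cells(129, D_N=100_000.0)
        rates = chem_reaction_rates(_zero_chem(), cells, self.p,
                                    self.ag.centers)
        assert rates[1] == pytest.approx(5.17e-7 * 1e5)

    def test_ecm_inert_without_cytokine(self):
        assert ecm_rate(_zero_chem(U=30.0), self.p) == 0.0

    def test_ecm_gated_off_above_epo_threshold(self):
        chem = _zero_chem(U=30.0, F=5.0, P=self.p.P_c + 0.5)
        assert ecm_rate(chem, self.p) == 0.0

    def test_ecm_degradation_value(self):
        chem = _zero_chem(U=30.0, F=0.5, P=0.0)
        assert ecm_rate(chem, self.p) == pytest.approx(
            -0.0193 * 30.0 * 0.5
        )


class TestBoundaryInflows:
    def setup_method(self):
        self.p = default_params()
        self.ag = make_age_grid(129, 3.0)

    def test_no_ros_no_ct_inflow(self):
        cells = _local_cells(129, C_U=1e5)
        inflow_ct, _ = age_boundary_inflows(_zero_chem(), cells, self.p,
                                            self.ag.centers)
        assert inflow_ct == 0.0

    def test_empty_ct_no_st_inflow(self):
        chem = _zero_chem(M=1.0, F=1.0)
        _, inflow_st = age_boundary_inflows(chem, _local_cells(129),
                                            self.p, self.ag.centers)
        assert inflow_st == 0.0

    def test_ct_inflow_value(self):
        cells = _local_cells(129, C_U=1e5)
        chem = _zero_chem(R=240.0)
        inflow_ct, _ = age_boundary_inflows(chem, cells, self.p,
                                            self.ag.centers)
        assert inflow_ct == pytest.approx(10.0 * 1e5 * 240.0 / 245.0)

    def test_st_inflow_gated_by_epo(self):
        ct = np.full(129, 100.0)
        cells = _local_cells(129, C_T_of_a=ct)
        chem = _zero_chem(M=1.0, F=1.0, P=self.p.P_c + 1.0)
        _, inflow_st = age_boundary_inflows(chem, cells, self.p,
                                            self.ag.centers)
        assert inflow_st == 0.0


nonneg = st.floats(0, 1e5, allow_nan=False, allow_infinity=False)


class TestCellRatesBookkeeping:
    @given(
        c=st.tuples(nonneg, nonneg, nonneg, nonneg),
        chemv=st.tuples(nonneg, nonneg, nonneg,
                        st.floats(0, 0.99), nonneg),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_sink_mass_equals_destination_fluxes(self, c, chemv, seed):
        """Every age-local sink removed from C_T (S_T) must reappear as
        the paired transition flux: mass is only moved, never lost."""
        p = default_params()
        ag = make_age_grid(32, 3.0)
        rng = np.random.default_rng(seed)
        cells = CellStateLocal(
            C_U=c[0], C_E=c[1], S_A=c[2], D_N=c[3],
            C_T_of_a=rng.uniform(0, 1e5, 32),
            S_T_of_a=rng.uniform(0, 1e5, 32),
        )
        chem = ChemState(*chemv)
        cr = cell_rates(chem, cells, p, ag.centers)
        removed_ct = age_integral(cr.sink_CT * cells.C_T_of_a, ag.centers)
        removed_st = age_integral(cr.sink_ST * cells.S_T_of_a, ag.centers)
        assert removed_ct == pytest.approx(
            cr.flux_ct_to_st + cr.flux_ct_to_ce, rel=1e-9, abs=1e-9
        )
        assert removed_st == pytest.approx(
            cr.flux_st_to_da + cr.flux_st_to_sa, rel=1e-9, abs=1e-9
        )
        # unstructured compartments: rates decompose into paired fluxes
        assert cr.dC_U == pytest.approx(
            cr.flux_sa_to_cu + cr.flux_ce_to_cu - cr.flux_cu_to_ct,
            rel=1e-12, abs=1e-12,
        )
        assert cr.dS_A == pytest.approx(
            cr.flux_st_to_sa - cr.flux_sa_to_cu - cr.flux_sa_to_da,
            rel=1e-12, abs=1e-12,
        )

    def test_boundary_inflow_matches_ct_to_st_flux(self):
        """The S_T age-zero inflow equals the DAMPs/IL-6 sink integrated
        over the C_T age distribution (cell-number conservation across
        the transition)."""
        p = default_params()
        ag = make_age_grid(32, 3.0)
        rng = np.random.default_rng(7)
        cells = _local_cells(32, C_U=5e4, C_T_of_a=rng.uniform(0, 1e5, 32))
        chem = ChemState(R=2.0, M=0.1, F=0.05, P=0.01, U=30.0)
        cr = cell_rates(chem, cells, p, ag.centers)
        _, inflow_st = age_boundary_inflows(chem, cells, p, ag.centers)
        assert inflow_st == pytest.approx(cr.flux_ct_to_st, rel=1e-12)

    def test_no_epo_no_recovery(self):
        p = default_params()
        ag = make_age_grid(16, 3.0)
        cells = _local_cells(16, S_A=1e4)
        cr = cell_rates(_zero_chem(), cells, p, ag.centers)
        assert cr.flux_sa_to_cu == 0.0

    def test_epo_gate_shuts_signaling_sinks(self):
        """Above the EPO threshold only the delayed kernel transition
        keeps draining C_T; the DAMPs/IL-6 routes close."""
        p = default_params()
        ag = make_age_grid(32, 3.0)
        cells = _local_cells(32, C_T_of_a=np.full(32, 10.0))
        chem = ChemState(R=2.0, M=1.0, F=1.0, P=p.P_c + 1.0, U=30.0)
        cr = cell_rates(chem, cells, p, ag.centers)
        assert cr.flux_ct_to_st == 0.0
        assert cr.flux_ct_to_ce > 0.0

    def test_sinks_vanish_with_their_compartment(self):
        """Each sink is proportional to its own compartment, so emptying
        a compartment zeroes every outgoing rate (nonnegativity)."""
        p = default_params()
        ag = make_age_grid(16, 3.0)
        chem = ChemState(R=3.0, M=0.4, F=0.3, P=0.2, U=29.0)
        cells = _local_cells(16)  # everything empty
        cr = cell_rates(chem, cells, p, ag.centers)
        for name in ("flux_cu_to_ct", "flux_ct_to_st", "flux_ct_to_ce",
                     "flux_st_to_sa", "flux_st_to_da", "flux_sa_to_da",
                     "flux_sa_to_cu", "flux_ce_to_cu", "flux_dn_cleared"):
            assert getattr(cr, name) == 0.0, name
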