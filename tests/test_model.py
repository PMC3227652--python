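"""Unit tests of the ODE core: reaction fluxes, conservation, two-phase runs."""

import dataclasses

import numpy as np
import pytest

import smadscreen as ss
from smadscreen._kinetics import IDX_HN, N_STATE
from smadscreen.model import (
    PM_PER_NM,
    PARAMETER_NAMES,
    equilibrate,
    initial_state,
    rhs,
)

TINY = 1e-300  # effectively-off rate that still satisfies positivity


def params_with(**kwargs) -> ss.ParameterSet:
    base = {name: TINY for name in PARAMETER_NAMES}
    base["h"] = 1.0
    base.update(kwargs)
    return ss.ParameterSet(**base)


def random_params(rng) -> ss.ParameterSet:
    vals = 10.0 ** rng.uniform(-4, -1, 19)
    return ss.ParameterSet(**dict(zip(PARAMETER_NAMES[:19], vals)), h=2.0)


class TestRhs:
    def test_empty_state_has_no_flux(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = random_params(rng)
            dy = rhs(np.zeros(N_STATE), 0.0, p, ligand_pM=200.0)
            assert np.all(dy == 0.0)

    def test_single_binding_reaction(self):
        # only ligand-receptor binding active: R + L -> LR at k2*L*R
        p = params_with(k2=1.0)
        y = np.zeros(N_STATE)
        y[0] = 1.0  # R = 1 nM
        dy = rhs(y, 0.0, p, ligand_pM=200.0)  # L = 0.2 nM
        expected = np.zeros(N_STATE)
        expected[0] = -0.2
        expected[1] = +0.2
        np.testing.assert_allclose(dy, expected, atol=1e-12)

    def test_structural_conservation_of_derivatives(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            p = random_params(rng)
            y = rng.uniform(0, 50, N_STATE)
            dy = rhs(y, 0.0, p, ligand_pM=500.0)
            scale = np.abs(dy).max() + 1e-30
            d_receptor = dy[0] + dy[1] + dy[2] + dy[3]
            d_rsmad = (dy[4] + dy[5] + dy[11] + dy[12]
                       + 2 * (dy[7] + dy[14]) + dy[8] + dy[15])
            d_cosmad = dy[6] + dy[13] + dy[8] + dy[15]
            assert abs(d_receptor) < 1e-12 * scale + 1e-20
            assert abs(d_rsmad) < 1e-12 * scale + 1e-20
            assert abs(d_cosmad) < 1e-12 * scale + 1e-20

    def test_negative_ligand_rejected(self):
        p = params_with(k2=1.0)
        with pytest.raises(ValueError):
            rhs(np.zeros(N_STATE), 0.0, p, ligand_pM=-1.0)

    def test_transcription_saturates_at_k14(self, sustained_ps):
        # holding H_n >= 100 * k15 drives the transcription flux to within 1% of k14
        y = np.zeros(N_STATE)
        y[IDX_HN] = 100.0 * sustained_ps.k15
        dy = rhs(y, 0.0, sustained_ps, ligand_pM=0.0)
        txn_flux = dy[16]  # dm_n/dt with m_n = 0
        assert txn_flux == pytest.approx(sustained_ps.k14, rel=0.01)


class TestParameterSet:
    @pytest.mark.parametrize("bad", [{"k1": 0.0}, {"k5": -1.0}, {"k9": float("nan")},
                                     {"k14": float("inf")}, {"h": 0.5}])
    def test_invalid_values_rejected(self, bad):
        good = {name: 1.0 for name in PARAMETER_NAMES}
        with pytest.raises(ValueError):
            ss.ParameterSet(**{**good, **bad})

    def test_array_round_trip(self, sustained_ps):
        again = ss.ParameterSet.from_array(sustained_ps.as_array())
        assert again == sustained_ps

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            ss.ParameterSet.from_dict({"k0": 1.0})


class TestProtocol:
    def test_constant_preset_level(self):
        p = ss.LigandProtocol.constant()
        assert p.value_pM(0.0) == 200.0 == p.value_pM(36000.0)

    def test_triangle_shape(self):
        p = ss.LigandProtocol.triangle()
        assert p.value_pM(0.0) == 0.0
        assert p.value_pM(9000.0) == pytest.approx(360.0)
        assert p.value_pM(18000.0) == pytest.approx(720.0)
        assert p.value_pM(27000.0) == pytest.approx(360.0)
        assert p.value_pM(40000.0) == 0.0

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            ss.LigandProtocol.constant(-5.0)


class TestSimulate:
    def test_blocked_phosphorylation_gives_flat_zero_output(self, sustained_ps):
        ps = dataclasses.replace(sustained_ps, k7=1e-30)
        trace = ss.simulate(ps)
        assert trace.success
        assert trace.value.max() < 1e-6  # pM

    def test_near_zero_ligand_stays_below_threshold(self, sustained_ps):
        trace = ss.simulate(sustained_ps, protocol=ss.LigandProtocol.constant(1e-6))
        assert trace.success
        assert trace.value.max() < 10.0  # pM

    def test_trace_grid_is_dense_and_increasing(self, sustained_ps):
        trace = ss.simulate(sustained_ps)
        assert np.all(np.diff(trace.t) > 0)
        assert np.max(np.diff(trace.t)) <= 60.0
        assert trace.t[-1] == 36000.0
        assert np.all(trace.value >= -1e-9)

    def test_matches_stored_oracle_reference_trace(self, sustained_ps):
        # reference generated once with the independent fixed-step RK4 integrator
        from importlib import resources

        from smadscreen.io import read_trace_tsv

        ref = read_trace_tsv(resources.files("smadscreen") / "fixtures"
                             / "reference_trace_sustained.tsv")
        trace = ss.simulate(sustained_ps)
        assert trace.success
        sim = np.interp(ref.t, trace.t, trace.value)
        assert np.max(np.abs(sim - ref.value)) <= 0.01 * ref.value.max()

    def test_nonfinite_parameter_rejected_before_integration(self):
        good = {name: 1.0 for name in PARAMETER_NAMES}
        with pytest.raises(ValueError):
            ss.ParameterSet(**{**good, "k3": float("nan")})


class TestConservation:
    def test_totals_constant_and_equal_to_inputs(self, sustained_ps):
        totals = ss.TotalConcentrations()
        trace, t, states = ss.simulate(sustained_ps, totals, return_states=True)
        assert trace.success
        cons = ss.conserved_totals(states)
        for name, expected in (("receptor", 1.0), ("r_smad", 60.0), ("co_smad", 100.0)):
            series = cons[name]
            assert series[0] == pytest.approx(expected, rel=1e-6)
            assert np.max(np.abs(series - expected)) <= 1e-6 * expected

    def test_doubling_rsmad_total_doubles_its_conservation_trace(self, sustained_ps):
        t1 = ss.TotalConcentrations()
        t2 = ss.TotalConcentrations(S_tot=120.0)
        _, _, s1 = ss.simulate(sustained_ps, t1, return_states=True)
        _, _, s2 = ss.simulate(sustained_ps, t2, return_states=True)
        c1 = ss.conserved_totals(s1)["r_smad"]
        c2 = ss.conserved_totals(s2)["r_smad"]
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-6)


def test_long_low_ligand_hold_reaches_steady_state(sustained_ps):
    """100 h under near-zero ligand drives |dH_n/dt| below 1e-12 nM/s."""
    y = equilibrate(sustained_ps, ss.TotalConcentrations(), duration_s=360000.0)
    dy = rhs(y, 0.0, sustained_ps, ligand_pM=1e-6)
    assert abs(dy[IDX_HN]) < 1e-12


def test_stiff_solver_agrees_with_fixed_step_oracle():
    """H_n from LSODA matches independent RK4 within 0.5% of peak on random sets."""
    ranges = ss.default_ranges()
    rng_seed = 2
    candidates = ss.sample_parameters(ranges, 200, rng_seed)
    totals = ss.TotalConcentrations()
    checked = 0
    for ps in candidates:
        try:
            t_o, states = ss.simulate_oracle(ps, totals, 200.0, 3600.0)
        except ValueError:  # too stiff for the explicit oracle
            continue
        trace = ss.simulate(ps, totals, ss.LigandProtocol.constant(200.0, 3600.0),
                            ss.SolverOptions())
        assert trace.success
        hn_o = states[:, IDX_HN] * PM_PER_NM
        hn_s = np.interp(t_o, trace.t, trace.value)
        denom = max(hn_o.max(), 1e-6)
        assert np.max(np.abs(hn_s - hn_o)) <= 0.005 * denom
        checked += 1
        if checked == 10:
            break
    assert checked == 10
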