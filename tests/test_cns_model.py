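import numpy as np
import pytest

from cnspk.cns_model import (
    BARRIERS,
    COMPARTMENTS,
    BarrierDisposition,
    CalibrationError,
    CnsModelError,
    CnsOptions,
    build_system,
    hindrance_factor,
    kpuu_steady_state,
    paracellular_clearance,
    pk_descriptors,
    scale_af_interspecies,
    simulate_cns,
    simulate_coupled,
    simulation_to_frame,
    solve_asymmetry_factors,
    steady_state_concentrations,
)
from cnspk.plasma_pk import DoseEvent
from conftest import make_drug


class TestHindrance:
    def test_free_diffusion_limit(self):
        assert hindrance_factor(0.0) == 1.0

    @pytest.mark.parametrize("lam", [1.0, 1.5, 10.0])
    def test_steric_exclusion(self, lam):
        assert hindrance_factor(lam) == 0.0

    def test_monotone_decreasing(self):
        grid = np.linspace(0.0, 0.999, 500)
        values = [hindrance_factor(x) for x in grid]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(v >= 0 for v in values)


class TestParacellular:
    def test_halving_pore_radius_decreases_clearance(self, rat_physiology):
        from cnspk.physiology import Perturbation, apply_perturbations

        drug = make_drug(mw=300.0)
        narrow = apply_perturbations(rat_physiology, [Perturbation("pore_radius_nm", 0.5)])
        assert paracellular_clearance(narrow, drug, "BBB") < paracellular_clearance(
            rat_physiology, drug, "BBB"
        )

    def test_huge_molecule_excluded(self, rat_physiology):
        drug = make_drug(mw=80000.0)
        assert paracellular_clearance(rat_physiology, drug, "BBB") == 0.0

    def test_scales_with_surface(self, rat_physiology):
        drug = make_drug(mw=250.0)
        bbb = paracellular_clearance(rat_physiology, drug, "BBB")
        lv = paracellular_clearance(rat_physiology, drug, "BCSFB_LV")
        assert bbb / lv == pytest.approx(rat_physiology.sa_bbb / rat_physiology.sa_bcsfb_lv)

    def test_unknown_barrier(self, rat_physiology):
        with pytest.raises(CnsModelError):
            paracellular_clearance(rat_physiology, make_drug(), "AQUEDUCT")


class TestBuildSystem:
    def test_neutral_drug_has_unit_phf(self, rat_physiology):
        system = build_system(rat_physiology, make_drug(), af_mode="passive")
        assert all(v == 1.0 for v in system.phf.values())
        bbb = system.barriers["BBB"]
        assert bbb.cl_in == pytest.approx(bbb.cl_out, rel=1e-12)

    def test_kpuu_one_gives_unit_af(self, rat_physiology):
        drug = make_drug(kpuu={"ecf": 1.0, "lv": 1.0, "cm": 1.0})
        system = build_system(rat_physiology, drug, af_mode="solve")
        for barrier in BARRIERS:
            assert system.barriers[barrier].af_in == 1.0
            assert system.barriers[barrier].af_ef == 1.0

    def test_charged_drug_transcellular_gated_paracellular_not(self, rat_physiology):
        # strong base: tiny neutral fraction -> transcellular term suppressed,
        # paracellular term identical to the neutral analogue's
        base = make_drug(charge_class="base", pkb=12.0)
        neutral = make_drug()
        s_base = build_system(rat_physiology, base, af_mode="passive")
        s_neutral = build_system(rat_physiology, neutral, af_mode="passive")
        assert s_base.barriers["BBB"].cl_para == s_neutral.barriers["BBB"].cl_para
        gated = s_base.barriers["BBB"].cl_trans * s_base.phf["MV"]
        ungated = s_neutral.barriers["BBB"].cl_trans * s_neutral.phf["MV"]
        assert gated < 1e-3 * ungated

    def test_use_provided_requires_overrides(self, rat_physiology):
        with pytest.raises(CnsModelError):
            build_system(rat_physiology, make_drug(), af_mode="use-provided")

    def test_unknown_mode(self, rat_physiology):
        with pytest.raises(CnsModelError):
            build_system(rat_physiology, make_drug(), af_mode="nope")

    def test_solve_requires_targets(self, rat_physiology):
        drug = make_drug(kpuu={"ecf": 0.5})  # lv, cm missing
        with pytest.raises(CnsModelError, match="BCSFB"):
            build_system(rat_physiology, drug, af_mode="solve")

    def test_barrier_disposition_invariant(self):
        with pytest.raises(CnsModelError):
            BarrierDisposition(
                barrier="BBB", cl_para=1.0, cl_trans=1.0, phf_donor=1.0,
                phf_tissue=1.0, af_in=2.0, af_ef=2.0,
            )
        with pytest.raises(CnsModelError):
            BarrierDisposition(
                barrier="BBB", cl_para=1.0, cl_trans=1.0, phf_donor=1.0,
                phf_tissue=1.0, af_in=0.5,
            )


class TestAsymmetryFactors:
    def test_reduced_symmetric_single_barrier(self, rat_physiology):
        """Single symmetric passive barrier, everything else off:
        Kp_uu = 0.5 must give AF_ef = 2 (closed-form steady-state balance)."""
        drug = make_drug(kpuu={"ecf": 0.5, "lv": 1.0, "cm": 1.0})
        options = CnsOptions(
            icf_exchange=False, lysosome=False, membrane_binding=False, ecf_bulk_flow=False
        )
        system = build_system(rat_physiology, drug, af_mode="passive", options=options)
        for barrier in ("BCSFB_LV", "BCSFB_TFV"):
            system.barriers[barrier].cl_para = 0.0
            system.barriers[barrier].cl_trans = 0.0
        system.barriers["BBB"].cl_para = 1.0
        system.barriers["BBB"].cl_trans = 0.0
        solve_asymmetry_factors(system)
        assert system.barriers["BBB"].af_in == 1.0
        assert system.barriers["BBB"].af_ef == pytest.approx(2.0, rel=1e-9)

    def test_quinidine_round_trip(self, rat_physiology, drugs):
        system = build_system(rat_physiology, drugs["quinidine"], af_mode="solve")
        ratios = kpuu_steady_state(system)
        assert ratios["ecf"] == pytest.approx(1.5, rel=1e-6)
        assert system.barriers["BBB"].af_in > 1.0
        assert system.barriers["BBB"].af_ef == 1.0

    def test_efflux_scenario_branch(self, rat_physiology, drugs):
        system = build_system(rat_physiology, drugs["methotrexate"], af_mode="solve")
        for barrier in BARRIERS:
            assert system.barriers[barrier].af_in == 1.0
            assert system.barriers[barrier].af_ef > 1.0

    def test_unreachable_target_diagnostic(self, rat_physiology):
        # Kp_uu > 1 at LV while BBB demands near-total efflux is fine, but a
        # target above what infinite influx could sustain is not constructible;
        # instead check the documented failure: efflux target above the
        # passive ceiling. A Kp_uu just below 1 with a sub-passive ceiling is
        # exercised via an artificial barrier with no efflux to scale.
        drug = make_drug(kpuu={"ecf": 0.9999999, "lv": 1.0, "cm": 1.0})
        options = CnsOptions(
            icf_exchange=False, lysosome=False, membrane_binding=False, ecf_bulk_flow=True
        )
        system = build_system(rat_physiology, drug, af_mode="passive", options=options)
        # make passive clearance tiny so bulk-flow drag keeps ECF far below target
        system.barriers["BBB"].cl_para = 1e-8
        system.barriers["BBB"].cl_trans = 0.0
        with pytest.raises(CalibrationError, match="Kp_uu"):
            solve_asymmetry_factors(system)

    def test_scale_af_boundary(self):
        assert scale_af_interspecies(8.0, 8.0) == 1.0

    def test_scale_af_hand_example(self):
        assert scale_af_interspecies(16.0, 8.0) == 2.0

    def test_scale_af_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert scale_af_interspecies(4.0, 8.0) == 1.0


class TestSteadyState:
    def test_membrane_binding_equilibrium(self, rat_physiology):
        # ICF exchange disabled: BCM only sees ECF, so the steady-state
        # membrane-to-water ratio is exactly P_oct-water
        drug = make_drug(logp=2.0, kpuu={"ecf": 1.0, "lv": 1.0, "cm": 1.0})
        options = CnsOptions(icf_exchange=False)
        system = build_system(rat_physiology, drug, af_mode="solve", options=options)
        conc = steady_state_concentrations(system)
        idx = {c: i for i, c in enumerate(COMPARTMENTS)}
        assert conc[idx["BCM"]] / conc[idx["ECF"]] == pytest.approx(100.0, rel=1e-9)

    def test_lysosomal_trapping_of_base(self, rat_physiology):
        base = make_drug(charge_class="base", pkb=9.0, kpuu={"ecf": 1.0, "lv": 1.0, "cm": 1.0})
        neutral = make_drug(kpuu={"ecf": 1.0, "lv": 1.0, "cm": 1.0})
        idx = {c: i for i, c in enumerate(COMPARTMENTS)}
        conc_b = steady_state_concentrations(build_system(rat_physiology, base, af_mode="solve"))
        conc_n = steady_state_concentrations(build_system(rat_physiology, neutral, af_mode="solve"))
        assert conc_b[idx["LYS"]] / conc_b[idx["ICF"]] > 1.0
        assert conc_n[idx["LYS"]] / conc_n[idx["ICF"]] == pytest.approx(1.0, rel=1e-9)

    def test_lysosome_ratio_matches_phf_balance(self, rat_physiology):
        base = make_drug(charge_class="base", pkb=9.0, kpuu={"ecf": 1.0, "lv": 1.0, "cm": 1.0})
        system = build_system(rat_physiology, base, af_mode="solve")
        conc = steady_state_concentrations(system)
        idx = {c: i for i, c in enumerate(COMPARTMENTS)}
        expected = system.phf["ICF"] / system.phf["LYS"]
        assert conc[idx["LYS"]] / conc[idx["ICF"]] == pytest.approx(expected, rel=1e-9)


class TestSimulate:
    def test_null_input(self, rat_physiology, neutral_drug, time_grid):
        system = build_system(rat_physiology, neutral_drug, af_mode="solve")
        sim = simulate_cns(system, 0.0, time_grid)
        np.testing.assert_array_equal(sim.conc, 0.0)

    def test_constant_input_converges_to_kpuu(self, rat_physiology, drugs):
        system = build_system(rat_physiology, drugs["phenytoin"], af_mode="solve")
        times = np.concatenate([[0.0], 2.0 ** np.arange(0, 25)])
        sim = simulate_cns(system, 1.0, times)
        assert sim["ECF"][-1] == pytest.approx(0.26, rel=1e-6)

    def test_linearity_in_forcing(self, rat_physiology, neutral_drug, time_grid):
        system = build_system(rat_physiology, neutral_drug, af_mode="solve")
        forcing = np.exp(-time_grid / 120.0)
        one = simulate_cns(system, forcing, time_grid)
        two = simulate_cns(system, 2.0 * forcing, time_grid)
        np.testing.assert_allclose(two.conc, 2.0 * one.conc, rtol=1e-9)

    def test_nonnegative_states(self, rat_physiology, drugs, plasma_models, time_grid):
        system = build_system(rat_physiology, drugs["morphine"], af_mode="solve")
        sim = simulate_coupled(
            system, plasma_models["rat"]["morphine"], [DoseEvent(amount=1e6)], time_grid
        )
        assert sim.conc.min() >= -1e-12

    def test_expm_vs_lsoda(self, rat_physiology, drugs):
        system = build_system(rat_physiology, drugs["acetaminophen"], af_mode="solve")
        times = np.linspace(0.0, 240.0, 121)
        forcing = 100.0 * np.exp(-times / 60.0)
        exact = simulate_cns(system, forcing, times, method="expm")
        lsoda = simulate_cns(system, forcing, times, method="lsoda")
        scale = exact.conc.max()
        np.testing.assert_allclose(lsoda.conc, exact.conc, rtol=2e-4, atol=1e-6 * scale)

    def test_coupled_matches_profile_driven(self, human_physiology, drugs, plasma_models):
        # slow plasma kinetics so the piecewise-linear forcing interpolation
        # of the profile-driven route is well resolved on the grid
        from cnspk.drug_params import select_kpuu_variant
        from cnspk.plasma_pk import simulate_plasma

        drug = select_kpuu_variant(drugs["acetaminophen"], "human")
        system = build_system(human_physiology, drug, af_mode="solve")
        spec = plasma_models["human"]["acetaminophen"]
        doses = [DoseEvent(amount=1e9)]
        times = np.arange(0.0, 480.5, 0.5)
        coupled = simulate_coupled(system, spec, doses, times)
        profile = simulate_plasma(spec, doses, times)
        driven = simulate_cns(system, profile, times)
        scale = coupled.conc.max()
        np.testing.assert_allclose(driven.conc, coupled.conc, atol=2e-4 * scale)

    def test_mass_conservation(self, rat_physiology, neutral_drug):
        # compare the total-amount change over a window after the fast
        # microvessel transient to the trapezoidal boundary-flux integral
        system = build_system(rat_physiology, neutral_drug, af_mode="solve")
        p = rat_physiology
        times = np.arange(0.0, 60.001, 0.002)  # fine grid: quadrature limits accuracy
        sim = simulate_cns(system, 1.0, times)
        amounts = sim.conc.T * system.volumes  # BCM conc is amount/volume too
        total = amounts.sum(axis=1)
        idx = {c: i for i, c in enumerate(COMPARTMENTS)}
        net_rate = (
            p.q_cbf * (sim.plasma_unbound - sim.conc[idx["MV"]])
            - (p.q_csf + p.q_ecf) * sim.conc[idx["SAS"]]
        )
        net = np.trapezoid(net_rate, times)
        assert total[-1] - total[0] == pytest.approx(net, rel=1e-3)

    def test_plasma_profile_must_cover_grid(self, rat_physiology, neutral_drug):
        from cnspk.plasma_pk import PlasmaProfile

        system = build_system(rat_physiology, neutral_drug, af_mode="solve")
        profile = PlasmaProfile(
            times=np.array([0.0, 10.0]),
            conc_total=np.array([1.0, 1.0]),
            conc_unbound=np.array([1.0, 1.0]),
        )
        with pytest.raises(CnsModelError, match="cover"):
            simulate_cns(system, profile, np.array([0.0, 20.0]))


class TestDescriptors:
    def test_constant_profile(self):
        times = np.array([0.0, 5.0, 10.0])
        cmax, tmax, auc = pk_descriptors(times, [3.0, 3.0, 3.0])
        assert (cmax, tmax, auc) == (3.0, 0.0, 30.0)

    def test_triangle(self):
        times = np.array([0.0, 1.0, 2.0])
        cmax, tmax, auc = pk_descriptors(times, [0.0, 4.0, 0.0])
        assert cmax == 4.0 and tmax == 1.0
        assert auc == pytest.approx(0.5 * 2.0 * 4.0)

    def test_monotone_decreasing(self):
        cmax, tmax, _ = pk_descriptors([0.0, 1.0, 2.0], [5.0, 3.0, 1.0])
        assert tmax == 0.0 and cmax == 5.0

    def test_first_maximum_tie_break(self):
        _, tmax, _ = pk_descriptors([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 1.0])
        assert tmax == 1.0

    def test_needs_two_points(self):
        with pytest.raises(CnsModelError):
            pk_descriptors([0.0], [1.0])


class TestOutput:
    def test_tidy_frame(self, rat_physiology, neutral_drug, time_grid):
        system = build_system(rat_physiology, neutral_drug, af_mode="solve")
        sim = simulate_cns(system, 1.0, time_grid)
        frame = simulation_to_frame(sim, "probe", replicate=3)
        assert set(frame.columns) == {
            "drug", "compartment", "time_min", "conc_ng_per_ml", "replicate"
        }
        assert sorted(frame["compartment"].unique()) == sorted(COMPARTMENTS)
        assert len(frame) == len(COMPARTMENTS) * len(time_grid)
        assert (frame["replicate"] == 3).all()
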