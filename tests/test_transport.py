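"""Transport kernels, the coupled stepper, and its conservation/limit oracles."""

import dataclasses
import math

import numpy as np
import pytest

from liposim import (Simulator, binding_source, build_grid, cell_exchange,
                     default_config, peclet_factor, simulate, spatial_mean,
                     transcapillary_flux)
from liposim.config import (BindingUptakeParams, HeatingSchedule,
                            NumericsParams, NORMAL, TUMOUR)
from liposim.transport import TissueState

from conftest import with_numerics


def small_numerics(**kw):
    base = dict(n_tumour=12, n_normal=6, dt=10.0, t_end=3600.0,
                output_every=60.0)
    base.update(kw)
    return NumericsParams(**base)


class TestPecletFactor:
    def test_zero_limit(self):
        assert peclet_factor(0.0) == 1.0

    def test_small_pe_series_agreement(self):
        """Pe/(e^Pe - 1) vs its Taylor series across the small-Pe range."""
        for pe in np.logspace(-12, -4, 9):
            series = 1.0 - pe / 2.0 + pe * pe / 12.0
            assert abs(peclet_factor(pe) - series) < 1e-10
            assert abs(peclet_factor(-pe) - (1.0 + pe / 2.0 + pe * pe / 12.0)) \
                < 1e-10

    def test_continuity_at_branch_switch(self):
        lo, hi = peclet_factor(0.999e-8), peclet_factor(1.001e-8)
        assert abs(lo - hi) < 1e-10

    def test_large_pe_limits(self):
        assert peclet_factor(50.0) == pytest.approx(50.0 / math.expm1(50.0))
        assert peclet_factor(-50.0) == pytest.approx(50.0, rel=1e-12)

    def test_vectorised(self):
        pe = np.array([0.0, 1e-10, 1.0, -1.0])
        out = peclet_factor(pe)
        assert out.shape == pe.shape


class TestTranscapillaryFlux:
    def test_diffusive_limit(self):
        assert transcapillary_flux(1.0, 0.0, 0.0, 1e-8, 1e4, 0.15) == \
            pytest.approx(1e-4, rel=1e-12)

    def test_no_gradient_no_filtration(self):
        assert transcapillary_flux(0.7, 0.7, 0.0, 1e-8, 1e4, 0.15) == 0.0

    def test_heated_tumour_example(self):
        """Hand-evaluated pore-model flux at the heated free-drug parameters."""
        fv, sigma, p, sv = 6.0e-4, 0.15, 3.0e-6 * 2.56, 20000.0
        fvs = fv * (1.0 - sigma)
        psv = p * sv
        pe = fvs / psv
        expected = fvs + psv * pe / math.expm1(pe)
        got = transcapillary_flux(1.0, 0.0, fv, p, sv, sigma)
        assert got == pytest.approx(expected, rel=1e-12)
        assert pe == pytest.approx(3.32e-3, rel=1e-2)
        assert got == pytest.approx(0.1539, rel=1e-3)

    def test_zero_permeability_pure_convection(self):
        assert transcapillary_flux(1.0, 0.5, 6.0e-4, 0.0, 2e4, 0.15) == \
            pytest.approx(6.0e-4 * 0.85)

    def test_scales_linearly_in_cp_at_ce_zero(self):
        a = transcapillary_flux(1.0, 0.0, 1e-4, 1e-8, 1e4, 0.2)
        b = transcapillary_flux(2.0, 0.0, 1e-4, 1e-8, 1e4, 0.2)
        assert b == pytest.approx(2.0 * a, rel=1e-12)


class TestBindingSource:
    def test_zero(self):
        assert binding_source(0.0, 0.0, 0.833, 0.278) == 0.0

    def test_equilibrium_ratio(self):
        # C_be/C_fe = ka/kd = 2.996 makes the net source vanish
        assert binding_source(1.0, 0.833 / 0.278, 0.833, 0.278) == \
            pytest.approx(0.0, abs=1e-12)
        assert 0.833 / 0.278 == pytest.approx(2.996, rel=1e-3)

    def test_pure_association(self):
        assert binding_source(1.0, 0.0, 0.833, 0.278) == pytest.approx(-0.833)


class TestCellExchange:
    bind = BindingUptakeParams()

    def test_no_uptake_without_free_drug(self):
        zeta, eps = cell_exchange(0.0, 0.0, self.bind, 0.4)
        assert zeta == 0.0 and eps == 0.0

    def test_uptake_half_saturation(self):
        c_half = self.bind.ke * 0.4
        assert c_half == pytest.approx(8.76e-5, rel=1e-12)
        zeta, _ = cell_exchange(c_half, 0.0, self.bind, 0.4)
        assert zeta == pytest.approx(self.bind.vmax / 2.0, rel=1e-12)

    def test_efflux_saturates_at_vmax(self):
        _, eps = cell_exchange(0.0, 1e-6, self.bind, 0.4)
        assert eps == pytest.approx(4.67e-15, rel=1e-5)

    def test_vectorised(self):
        zeta, eps = cell_exchange(np.array([0.0, 1e-4]), np.zeros(2),
                                  self.bind, 0.4)
        assert zeta.shape == (2,)


class TestStepperInvariants:
    def test_zero_dose_stays_zero(self):
        cfg = default_config("infusion")
        cfg = dataclasses.replace(cfg, pk=dataclasses.replace(cfg.pk, dose=0.0),
                                  numerics=small_numerics())
        res = simulate(cfg)
        for region in (TUMOUR, NORMAL):
            for field in ("C_le", "C_fe", "C_be", "C_i"):
                assert np.all(res.means[region][field] == 0.0)
            np.testing.assert_allclose(res.survival[region], 1.0, rtol=1e-12)

    def test_infusion_keeps_liposome_field_zero(self, infusion_coarse):
        for region in (TUMOUR, NORMAL):
            assert np.all(infusion_coarse.means[region]["C_le"] == 0.0)

    def test_positivity(self, liposome_coarse, infusion_coarse):
        for res in (liposome_coarse, infusion_coarse):
            for region in (TUMOUR, NORMAL):
                for field in ("C_le", "C_fe", "C_be", "C_i", "D_c"):
                    assert np.min(res.means[region][field]) >= 0.0
            for arr in (res.final_state.c_le, res.final_state.c_fe,
                        res.final_state.c_be, res.final_state.c_i):
                assert np.min(arr) >= 0.0

    def test_infusion_plasma_peaks_at_end_of_infusion(self, infusion_coarse):
        t = infusion_coarse.times
        c_fp = infusion_coarse.plasma["C_fp"]
        assert t[int(np.argmax(c_fp))] == pytest.approx(7200.0, abs=60.0)

    def test_liposome_free_drug_zero_before_heating(self, liposome_coarse):
        t = liposome_coarse.times
        pre = t < 86400.0
        for region in (TUMOUR, NORMAL):
            assert np.all(liposome_coarse.means[region]["C_fe"][pre] == 0.0)
            assert np.all(liposome_coarse.means[region]["C_i"][pre] == 0.0)
        # but encapsulated drug has been extravasating all along
        assert liposome_coarse.means[TUMOUR]["C_le"][pre][-1] > 0.0

    def test_no_release_means_no_free_drug_ever(self):
        cfg = default_config("liposome")
        cfg = dataclasses.replace(
            cfg, heating=HeatingSchedule(krel_42=0.0),
            numerics=small_numerics(t_end=90000.0, output_every=600.0))
        res = simulate(cfg)
        for region in (TUMOUR, NORMAL):
            for field in ("C_fe", "C_be", "C_i"):
                assert np.all(res.means[region][field] == 0.0)
        assert res.final_state.c_le.max() > 0.0

    def test_liposome_confined_to_tumour_without_flow_and_diffusion(
            self, zero_flow):
        """With convection and diffusion disabled, liposomes never appear in
        normal tissue: their only route there is from the tumour side."""
        cfg = default_config("liposome")
        cfg = dataclasses.replace(
            cfg,
            liposome=dataclasses.replace(cfg.liposome, d_tumour=0.0,
                                         d_normal=0.0),
            numerics=small_numerics(t_end=90000.0, output_every=600.0))
        grid = build_grid(cfg.numerics.n_tumour, cfg.numerics.n_normal)
        res = Simulator(cfg, grid=grid, flow=zero_flow(grid)).run()
        assert np.all(res.means[NORMAL]["C_le"] == 0.0)
        assert np.all(res.final_state.c_le[grid.mask(NORMAL)] == 0.0)
        assert res.final_state.c_le[grid.mask(TUMOUR)].max() > 0.0

    def test_budget_identity(self, liposome_coarse):
        """Cumulative transcapillary input = tissue inventory change +
        lymphatic loss + net cellular exchange."""
        b = liposome_coarse.budget
        lhs = b["transcapillary_in"]
        rhs = (b["inventory_end"] - b["inventory_0"]
               + b["lymph_out"] + b["cellular_net"])
        assert abs(lhs - rhs) / max(abs(lhs), 1e-300) < 1e-6


class TestConservationAndConvergence:
    def test_closed_system_mass_conservation(self, zero_flow):
        """1000 implicit steps of a closed system (no vascular exchange, no
        lymph, no flow) with binding, release and cellular uptake active:
        total drug mass drifts by < 1e-8 relative."""
        cfg = default_config("liposome")
        z = lambda sp: dataclasses.replace(sp, p_tumour=0.0, p_normal=0.0)
        cfg = dataclasses.replace(
            cfg, free=z(cfg.free), bound=z(cfg.bound), liposome=z(cfg.liposome),
            heating=HeatingSchedule(t_on=2000.0, t_dur=3000.0, krel_42=0.0078),
            numerics=small_numerics(t_end=10000.0, output_every=1000.0))
        grid = build_grid(cfg.numerics.n_tumour, cfg.numerics.n_normal)
        sim = Simulator(cfg, grid=grid, flow=zero_flow(grid))

        state = TissueState.zeros(grid, sim.dc0)
        state.c_le[:] = 1.0e-3
        state.c_fe[:] = 1.0e-4 * np.exp(-(grid.r_centers / 0.01) ** 2)
        res = sim.run(initial_state=state)

        def total_mass(s):
            extra = np.sum((s.c_le + s.c_fe + s.c_be) * grid.areas)
            intra = np.sum(sim.dc0 * s.c_i * grid.areas)
            return extra + intra

        m0, m1 = total_mass(state), total_mass(res.final_state)
        assert abs(m1 - m0) / m0 < 1e-8

    def test_diffusion_matches_heat_kernel(self, zero_flow):
        """Pure radial diffusion of a Gaussian pulse vs the closed-form 2D
        heat kernel: L2 error < 1% at the default resolution."""
        cfg = default_config("infusion")
        d_free, sigma0, t_end = 3.4e-10, 3.0e-3, 12000.0
        z = lambda sp: dataclasses.replace(sp, p_tumour=0.0, p_normal=0.0)
        cfg = dataclasses.replace(
            cfg,
            free=dataclasses.replace(z(cfg.free), d_tumour=d_free,
                                     d_normal=d_free),
            bound=z(cfg.bound),
            binding=BindingUptakeParams(ka=0.0, kd=0.0, vmax=0.0, s_bound=0.0),
            pk=dataclasses.replace(cfg.pk, dose=0.0),
            numerics=NumericsParams(n_tumour=250, n_normal=100, dt=10.0,
                                    t_end=t_end, output_every=t_end))
        grid = build_grid(250, 100)
        sim = Simulator(cfg, grid=grid, flow=zero_flow(grid))
        state = TissueState.zeros(grid, sim.dc0)
        r = grid.r_centers
        state.c_fe[:] = np.exp(-r**2 / (2.0 * sigma0**2))
        res = sim.run(initial_state=state)

        var = sigma0**2 + 2.0 * d_free * t_end
        exact = (sigma0**2 / var) * np.exp(-r**2 / (2.0 * var))
        num = res.final_state.c_fe
        w = grid.areas
        l2 = np.sqrt(np.sum(w * (num - exact) ** 2) / np.sum(w * exact**2))
        assert l2 < 0.01

    def test_time_step_self_convergence(self, liposome_coarse):
        """Halving dt from 10 s to 5 s changes the 48-h tumour-mean
        intracellular concentration by < 0.5%."""
        cfg5 = with_numerics(default_config("liposome"), dt=5.0)
        res5 = simulate(cfg5)
        c10 = liposome_coarse.means[TUMOUR]["C_i"][-1]
        c5 = res5.means[TUMOUR]["C_i"][-1]
        assert abs(c10 - c5) / abs(c5) < 0.005


class TestResultPlumbing:
    def test_record_cadence_and_save(self, tmp_path):
        cfg = default_config("infusion")
        cfg = dataclasses.replace(cfg, numerics=small_numerics(t_end=600.0))
        res = simulate(cfg, record_profiles=True)
        assert res.times[0] == 0.0 and res.times[-1] == 600.0
        assert res.times.size == 11
        assert res.profiles["C_fe"].shape == (11, res.grid.n_cells)
        res.save(tmp_path)
        for name in ("results.csv", "plasma.csv", "survival.csv", "flow.csv"):
            assert (tmp_path / name).exists()

    def test_mismatched_flow_grid_rejected(self, zero_flow):
        cfg = default_config("infusion")
        cfg = dataclasses.replace(cfg, numerics=small_numerics())
        with pytest.raises(ValueError):
            Simulator(cfg, grid=build_grid(12, 6), flow=zero_flow(build_grid(4, 2)))
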