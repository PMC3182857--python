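"""Stochastic cycle durations, area growth law, and cell division."""

import math

import numpy as np
import pytest

import notchfence as nf
from notchfence.cycle import (
    CellClock,
    CycleParams,
    cleavage_direction,
    divide_cell,
    division_ready,
    new_clock,
    sample_cycle_duration,
    update_preferred_area,
)
from notchfence.mesh import InitialConditionSpec, build_hex_patch, polygon_area, validate

from conftest import random_tissue, rectangle_cell_mesh


class TestDurationSampling:
    def test_degenerate_limit(self, rng):
        t = sample_cycle_duration(10.0, 1e9, rng)
        assert t == pytest.approx(10.0, abs=1e-6)

    def test_moments_match_exponential_law(self, rng):
        t_det, lam, n = 10.0, 0.4, 100_000
        samples = np.array([sample_cycle_duration(t_det, lam, rng) for _ in range(n)])
        mean_se = (1 / lam) / math.sqrt(n)
        assert abs(samples.mean() - (t_det + 1 / lam)) < 3 * mean_se
        # std of the sample std is ~ sigma/sqrt(2n) for the exponential-ish tail
        assert abs(samples.std() - 1 / lam) < 4 * mean_se

    def test_invalid_params(self, rng):
        with pytest.raises(ValueError):
            sample_cycle_duration(-1.0, 1.0, rng)

    def test_steady_state_age_density_newborns_double_dividers(self, rng):
        """Clock-only branching process: in exponential growth the cell-age
        density decays so that newborn cells are twice as frequent as cells
        at the end of their cycle."""
        params = CycleParams()
        t_det, lam = params.t_det_bulk, params.rate("C")
        # event-driven: each cell divides exactly at its sampled duration
        durations = [sample_cycle_duration(t_det, lam, rng) for _ in range(400)]
        births = [-rng.uniform(0.0, d) for d in durations]  # random initial phase
        horizon = 3.0 * params.mean_cycle("C")
        cells = list(zip(births, durations))
        done = []
        while cells:
            b, d = cells.pop()
            if b + d < horizon:
                for _ in range(2):
                    cells.append(
                        (b + d, sample_cycle_duration(t_det, lam, rng))
                    )
            else:
                done.append((b, d))
        phases = np.array([(horizon - b) / d for b, d in done])
        hist, _ = np.histogram(phases, bins=10, range=(0.0, 1.0))
        ratio = hist[0] / hist[-1]
        assert 1.5 < ratio < 2.6  # ideal value 2 with Monte-Carlo slack


class TestPreferredAreaGrowth:
    def test_latent_phase_exact(self):
        p = CycleParams()
        ck = CellClock(birth_time=0.0, duration=100.0, preferred_area=1.0)
        # elapsed 0.3 t' with latent fraction 0.5: still latent
        for t in np.arange(0.0, 30.0, 1.7):
            update_preferred_area(ck, t, 1.7, p)
        assert ck.preferred_area == 1.0

    def test_growth_linear_to_machine_precision(self):
        p = CycleParams()
        ck = CellClock(birth_time=0.0, duration=100.0, preferred_area=1.0)
        dt = 0.03
        t = 0.0
        while t < 80.0 - 1e-12:
            update_preferred_area(ck, t, dt, p)
            t += dt
        grow_time = t - 50.0  # growth began at latent_fraction * duration
        assert ck.preferred_area == pytest.approx(1.0 + p.v_a * grow_time, abs=1e-12)

    def test_common_speed_for_all_cell_types(self):
        p = CycleParams()
        cko = CellClock(birth_time=0.0, duration=200.0, preferred_area=1.0)
        ckc = CellClock(birth_time=0.0, duration=100.0, preferred_area=1.0)
        # give both the same growing time
        update_preferred_area(cko, 110.0, 10.0, p)
        update_preferred_area(ckc, 60.0, 10.0, p)
        assert cko.preferred_area == pytest.approx(ckc.preferred_area, rel=1e-12)

    def test_random_phase_initial_clock_consistency(self, rng):
        p = CycleParams()
        for _ in range(200):
            ck = new_clock(p, "C", 0.0, rng, random_phase=True)
            age = -ck.birth_time
            assert 0.0 <= age <= ck.duration
            grow = max(0.0, age - p.latent_fraction * ck.duration)
            assert ck.preferred_area == pytest.approx(
                p.a_ref + ck.growth_speed * grow
            )
            # per-cell mode: the cell doubles A0 over its own growth phase
            assert ck.growth_speed == pytest.approx(
                p.a_ref / ((1 - p.latent_fraction) * ck.duration)
            )

    def test_common_mode_shares_one_speed(self, rng):
        p = CycleParams(growth_mode="common")
        speeds = {new_clock(p, t, 0.0, rng).growth_speed for t in ("C", "O", "clone")}
        assert speeds == {p.v_a}


class TestDivisionReady:
    def test_threshold_is_sharp(self):
        p = CycleParams()
        ck = CellClock(birth_time=0.0, duration=100.0, preferred_area=1.8)
        t = 80.0  # growing phase
        assert not division_ready(p.a_div - 1e-9, ck, t, p)
        assert division_ready(p.a_div, ck, t, p)

    def test_latent_cell_never_divides(self):
        p = CycleParams()
        ck = CellClock(birth_time=0.0, duration=100.0, preferred_area=1.0)
        assert not division_ready(5.0, ck, 10.0, p)


class TestCrowding:
    def test_compressed_cell_outlives_its_intended_duration(self):
        """A cell squeezed below the division threshold keeps cycling: its
        realized duration exceeds the sampled t'."""
        from notchfence.dynamics import SimState, TopologyThresholds, evolve
        from notchfence.dynamics import EventLog
        from notchfence.identity import CellIdentity
        from notchfence.mechanics import MechanicsParams
        from notchfence.cycle import new_clock

        mesh, idents = build_hex_patch(InitialConditionSpec(nrows=1, ncols=1))
        # crushing exterior tension keeps the actual area far below a_div
        mech = MechanicsParams(lambda_exterior=3.0)
        params = CycleParams()
        rng = np.random.default_rng(1)
        clock = new_clock(params, "C", 0.0, rng)
        state = SimState(
            mesh=mesh,
            identities=idents,
            clocks={0: clock},
            mechanics=mech,
            cycle=params,
            thresholds=TopologyThresholds(),
            rng=rng,
            events=EventLog(),
        )
        evolve(state, 1.3 * clock.duration)
        assert mesh.n_cells() == 1  # no division despite the clock running out
        assert mesh.time > clock.duration
        assert polygon_area(mesh, next(iter(mesh.cells))) < params.a_div


class TestDivideCell:
    def test_rectangle_splits_into_equal_squares(self, rng):
        p = CycleParams(sigma_theta=1e-9, theta_max=1e-6)
        m = rectangle_cell_mesh(2.0, 1.0)
        m.time = 5.0
        ck = CellClock(birth_time=0.0, duration=4.0, preferred_area=2.0)
        d1, d2, rec = divide_cell(m, 0, rng, p, clock=ck, cell_type="C")
        a1, a2 = polygon_area(m, d1), polygon_area(m, d2)
        assert a1 == pytest.approx(1.0, rel=1e-6)
        assert a2 == pytest.approx(1.0, rel=1e-6)
        # cleavage orthogonal to the long (x) side: edge is vertical
        assert abs(abs(rec.angle_deg) - 90.0) < 1e-3
        assert rec.realized_duration == pytest.approx(5.0)
        validate(m)

    @pytest.mark.parametrize("seed", range(8))
    def test_daughters_conserve_mother_area(self, seed):
        mesh, idents = random_tissue(seed, nrows=3, ncols=3)
        r = np.random.default_rng(seed)
        p = CycleParams()
        cid = list(mesh.cells)[int(r.integers(mesh.n_cells()))]
        before = polygon_area(mesh, cid)
        total_before = mesh.total_area()
        d1, d2, _ = divide_cell(mesh, cid, r, p)
        assert polygon_area(mesh, d1) + polygon_area(mesh, d2) == pytest.approx(
            before, abs=1e-9
        )
        assert mesh.total_area() == pytest.approx(total_before, abs=1e-9)
        assert mesh.n_cells() == 10  # one more than the 9-cell patch
        validate(mesh)

    def test_truncated_gaussian_noise_stats(self, rng):
        from scipy.stats import truncnorm

        p = CycleParams(sigma_theta=15.0, theta_max=30.0)
        m = rectangle_cell_mesh(3.0, 1.0)
        devs = []
        for _ in range(10_000):
            d = cleavage_direction(m, 0, rng, p)
            ang = math.degrees(math.atan2(d[1], d[0]))
            # unperturbed cleavage is vertical (90 deg)
            dev = ang - 90.0
            if dev > 90:
                dev -= 180.0
            if dev < -90:
                dev += 180.0
            devs.append(dev)
        devs = np.asarray(devs)
        assert np.all(np.abs(devs) <= p.theta_max + 1e-9)
        a, b = -p.theta_max / p.sigma_theta, p.theta_max / p.sigma_theta
        expected_std = truncnorm.std(a, b, loc=0.0, scale=p.sigma_theta)
        assert abs(devs.std() - expected_std) / expected_std < 0.05

    def test_random_cleavage_mode_is_isotropic(self, rng):
        p = CycleParams(random_cleavage=True)
        m = rectangle_cell_mesh(4.0, 1.0)  # strongly anisotropic cell
        angs = []
        for _ in range(2000):
            d = cleavage_direction(m, 0, rng, p)
            angs.append(math.atan2(d[1], d[0]) % math.pi)
        hist, _ = np.histogram(angs, bins=6, range=(0, math.pi))
        assert hist.max() / hist.min() < 1.5  # no Hertwig bias


class TestParamsValidation:
    def test_defaults_satisfy_constraints(self):
        p = CycleParams()
        assert p.t_det_organizer == pytest.approx(2 * p.t_det_bulk)
        assert p.mean_cycle("O") == pytest.approx(2 * p.mean_cycle("C"))
        # clone cells cycle faster than bulk
        assert p.t_det("clone") < p.t_det("C")

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            CycleParams(a_div=0.5)
        with pytest.raises(ValueError):
            CycleParams(latent_fraction=1.5)
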