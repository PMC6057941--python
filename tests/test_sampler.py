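import numpy as np
import pytest

from contactsieve.geometry import (
    build_torsion_chain,
    pair_distance,
    segments_from_ss,
    to_coordinates,
)
from contactsieve.restraints import (
    ContactRecord,
    RestraintSet,
    clash_energy,
    total_restraint_energy,
)
from contactsieve.sampler import (
    make_schedule,
    run_annealing,
    torsion_move,
    update_lambdas,
)


class TestMakeSchedule:
    def test_endpoints_exact(self):
        s = make_schedule(50)
        assert s.D_values[0] == 150.0 and s.D_values[-1] == 3.0
        assert s.T_values[0] == 10.0 and s.T_values[-1] == 0.1

    def test_two_steps_only_endpoints(self):
        s = make_schedule(2)
        np.testing.assert_allclose(s.D_values, [150.0, 3.0])

    def test_geometric_ratios(self):
        s = make_schedule(20)
        ratios = s.D_values[1:] / s.D_values[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert (np.diff(s.D_values) < 0).all()
        assert (np.diff(s.T_values) < 0).all()

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(10, D_start=3.0, D_end=150.0)
        with pytest.raises(ValueError):
            make_schedule(1)


class TestUpdateLambdas:
    def test_zero_noise_zero_gradient_unchanged(self):
        rng = np.random.default_rng(0)
        lam = np.array([0.3, 0.8])
        out = update_lambdas(lam, [5.0, 6.9], D=3.0, T=0.0, rng=rng)
        np.testing.assert_array_equal(out, lam)

    def test_strong_violation_drives_lambda_down(self):
        rng = np.random.default_rng(0)
        out = update_lambdas([0.1], [17.0], D=3.0, T=0.0, rng=rng)
        assert out[0] < 0.1

    def test_clamped_to_unit_interval(self):
        class _PosNoise:
            def standard_normal(self, shape):
                return np.full(shape, 10.0)

        out = update_lambdas([1.0], [5.0], D=3.0, T=5.0, rng=_PosNoise())
        assert out[0] == 1.0

    def test_input_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            update_lambdas([1.2], [5.0], D=3.0, T=1.0)

    def test_t_zero_dynamics_bistable(self):
        """The switching energy is concave in lambda, so the drift fixed
        point lam* = (d-d0)^2 / (2 D^2) is unstable: noiseless updates
        run to 0 from below it and to 1 from above it."""
        d, D = 10.0, 5.0
        lam_star = (d - 7.0) ** 2 / (2 * D**2)  # 0.18
        rng = np.random.default_rng(0)
        lo = np.array([lam_star - 0.05])
        hi = np.array([lam_star + 0.05])
        for _ in range(4000):
            lo = update_lambdas(lo, [d], D=D, T=0.0, rng=rng)
            hi = update_lambdas(hi, [d], D=D, T=0.0, rng=rng)
        assert lo[0] == pytest.approx(0.0, abs=1e-6)
        assert hi[0] == pytest.approx(1.0, abs=1e-6)

    def test_lambda_mass_moves_to_zero_as_cost_anneals(self):
        """For a fixed violated distance, the stationary lambda
        distribution shifts toward 0 as D decreases through the
        annealing range."""
        d, T = 12.0, 0.3
        means = []
        for D in (150.0, 30.0, 3.0):
            rng = np.random.default_rng(42)
            lam = np.full(200, 0.5)
            trace = []
            for step in range(1500):
                lam = update_lambdas(lam, np.full(200, d), D=D, T=T, rng=rng)
                if step >= 750:
                    trace.append(lam.mean())
            means.append(np.mean(trace))
        assert means[0] >= means[1] - 0.05
        assert means[1] >= means[2] - 0.05
        assert means[0] - means[2] > 0.3


class TestTorsionMove:
    def _rset(self):
        return RestraintSet([ContactRecord(3, 12, 1.0)], D=10.0)

    def test_all_fixed_is_noop(self):
        ch = build_torsion_chain("A" * 6, segments_from_ss("EEEEEE"))
        co = to_coordinates(ch)
        rng = np.random.default_rng(0)
        ch2, co2, accepted = torsion_move(ch, self._rset(), co, 1.0, rng)
        assert not accepted
        assert ch2 is ch and co2 is co

    def test_fixed_residues_never_perturbed(self, hairpin_chain):
        co = to_coordinates(hairpin_chain)
        rng = np.random.default_rng(1)
        ch = hairpin_chain
        phi0 = ch.phi[ch.fixed].copy()
        psi0 = ch.psi[ch.fixed].copy()
        for _ in range(50):
            ch, co, _ = torsion_move(ch, self._rset(), co, 5.0, rng)
        np.testing.assert_array_equal(ch.phi[ch.fixed], phi0)
        np.testing.assert_array_equal(ch.psi[ch.fixed], psi0)

    def test_downhill_always_accepted(self, hairpin_chain):
        # with T=0 any accepted move must not increase the energy
        co = to_coordinates(hairpin_chain)
        rset = self._rset()
        rng = np.random.default_rng(3)

        def energy(c):
            return clash_energy(c) + total_restraint_energy(rset, c)

        e = energy(co)
        ch = hairpin_chain
        for _ in range(40):
            ch, co, accepted = torsion_move(ch, rset, co, 0.0, rng)
            e_new = energy(co)
            if accepted:
                assert e_new <= e + 1e-9
            e = e_new


class TestRunAnnealing:
    def _setup(self):
        ss = "CCEEEECCEEEECC"
        ch = build_torsion_chain("A" * len(ss), segments_from_ss(ss))
        rset = RestraintSet([ContactRecord(3, 12, 1.0)], D=150.0)
        return ch, rset

    def test_same_seed_bit_identical(self):
        ch, rset = self._setup()
        sch = make_schedule(20)
        a = run_annealing(ch, rset, sch, 30, seed=7)
        b = run_annealing(ch, rset, sch, 30, seed=7)
        assert np.array_equal(a.chain.phi, b.chain.phi)
        assert np.array_equal(a.chain.psi, b.chain.psi)
        assert np.array_equal(a.lambdas, b.lambdas)
        assert np.array_equal(a.coords.ca, b.coords.ca)

    def test_zero_contacts_pure_clash_annealing(self):
        ch, _ = self._setup()
        res = run_annealing(ch, RestraintSet([]), make_schedule(10), 20, seed=1)
        assert res.lambdas.size == 0
        assert np.isfinite(res.energy_trace).all()

    def test_template_not_mutated(self):
        ch, rset = self._setup()
        phi0 = ch.phi.copy()
        run_annealing(ch, rset, make_schedule(10), 20, seed=2)
        np.testing.assert_array_equal(ch.phi, phi0)

    def test_restraint_pulls_pair_together(self):
        ch, rset = self._setup()
        res = run_annealing(ch, rset, make_schedule(80), 80, seed=5)
        d0 = pair_distance(to_coordinates(ch), 3, 12)
        d1 = pair_distance(res.coords, 3, 12)
        assert d1 < d0
        assert d1 < 10.0

    def test_enormous_cost_pins_violated_lambdas_on(self):
        """With D huge, switching off a violated restraint is never
        favorable, so its lambda is driven back to 1 whatever the noise
        does.  (Satisfied restraints see a flat landscape in lambda and
        are untouched by D.)"""
        # rigid all-strand chain: the long-range pair stays violated
        ss = "E" * 14
        chain = build_torsion_chain("A" * 14, segments_from_ss(ss))
        rset = RestraintSet([ContactRecord(1, 14, 1.0)], D=1e6)
        sch = make_schedule(40, D_start=1e6, D_end=1e6 - 1.0)
        ok = 0
        for seed in range(10):
            res = run_annealing(chain, rset, sch, 0, seed=seed)
            ok += (res.lambdas > 0.5).all()
        assert ok >= 9

    def test_incremental_rotation_matches_rebuilt_energy(self):
        """The kernel's suffix rotations and the sequential rebuild must
        describe the same structure: the final trace energy equals the
        energy recomputed from the rebuilt coordinates."""
        ch, rset = self._setup()
        sch = make_schedule(15)
        res = run_annealing(ch, rset, sch, 40, seed=9)
        check = RestraintSet(
            [
                ContactRecord(c.i, c.j, c.score, lam=float(l))
                for c, l in zip(rset.contacts, res.lambdas)
            ],
            D=sch.D_values[-1],
        )
        e = clash_energy(res.coords) + total_restraint_energy(check, res.coords)
        assert e == pytest.approx(res.energy_trace[-1], rel=1e-9, abs=1e-9)
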