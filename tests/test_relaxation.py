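import numpy as np
import pytest

from glycostd.errors import ValidationError
from glycostd.relaxation import (
    RelaxationParameters, TheoreticalEpitope,
    build_spin_system, r_noe, r_noe_series, relaxation_matrix,
    simulate_std, two_spin_sigma_rho,
)
from glycostd.structures import Atom, Ensemble, Frame

from conftest import make_atom


def oracle_sigma_rho(r_angstrom, freq_mhz, tau_c_ns):
    """Independent closed-form dipolar rates (coded separately from the package)."""
    mu0 = 1.25663706212e-06
    hbar = 1.054571817e-34
    gamma = 2.6752218744e8
    tau = tau_c_ns * 1e-9
    w0 = 2 * np.pi * freq_mhz * 1e6
    J = lambda w: 2 * tau / (5 * (1 + (w * tau) ** 2))  # noqa: E731
    k = (mu0 / (4 * np.pi)) ** 2 * gamma ** 4 * hbar ** 2 / 10 / (r_angstrom * 1e-10) ** 6
    sigma = k * (6 * J(2 * w0) - J(0))
    rho = k * (J(0) + 3 * J(w0) + 6 * J(2 * w0))
    return sigma, rho


def proton(name, chain, resid, pos):
    return Atom(name, "H", "LIG" if chain == "L" else "PRO", resid, chain,
                np.array(pos, dtype=float))


def pair_ensemble(r):
    return Ensemble([Frame([
        proton("H1", "L", 1, (0, 0, 0)),
        proton("HA", "P", 2, (r, 0, 0)),
    ])])


class TestRates:
    def test_two_spin_matches_independent_oracle(self):
        params = RelaxationParameters()
        for r in (2.0, 2.5, 3.7, 6.0):
            sigma, rho = two_spin_sigma_rho(r, params)
            osigma, orho = oracle_sigma_rho(r, 600.0, 34.956)
            assert sigma == pytest.approx(osigma, rel=1e-10)
            assert rho == pytest.approx(orho, rel=1e-10)

    def test_r6_scaling_over_random_distances(self):
        rng = np.random.default_rng(31)
        params = RelaxationParameters()
        for _ in range(20):
            r = rng.uniform(1.5, 8.0)
            s1, _ = two_spin_sigma_rho(r, params)
            s2, _ = two_spin_sigma_rho(2 * r, params)
            assert s1 / s2 == pytest.approx(64.0, rel=1e-10)

    def test_slow_tumbling_sigma_negative(self):
        sigma, _ = two_spin_sigma_rho(3.0, RelaxationParameters())
        assert sigma < 0

    def test_matrix_symmetric_and_matches_two_spin(self):
        params = RelaxationParameters()
        frame = Frame([
            proton("H1", "L", 1, (0, 0, 0)),
            proton("H2", "L", 1, (3.1, 0, 0)),
            proton("HA", "P", 2, (0, 4.2, 0)),
        ])
        spins = build_spin_system(frame, "chain L", params)
        R = relaxation_matrix(spins, params).R
        np.testing.assert_allclose(R, R.T, rtol=0, atol=0)
        s12, _ = two_spin_sigma_rho(3.1, params)
        assert R[0, 1] == pytest.approx(s12, rel=1e-12)

    def test_coincident_protons_rejected(self):
        params = RelaxationParameters()
        frame = Frame([
            proton("H1", "L", 1, (0, 0, 0)),
            proton("H2", "L", 1, (0.1, 0, 0)),
        ])
        spins = build_spin_system(frame, "chain L", params)
        with pytest.raises(ValidationError, match="coincide"):
            relaxation_matrix(spins, params)


class TestSpinSystem:
    def test_cutoff_inclusion_exclusion(self):
        params = RelaxationParameters(cutoff=10.0)
        frame = Frame([
            proton("H1", "L", 1, (0, 0, 0)),
            proton("HA", "P", 2, (9.9, 0, 0)),
            proton("HB", "P", 3, (10.1, 0, 0)),
        ])
        spins = build_spin_system(frame, "chain L", params)
        assert spins.ids == ["L:1:H1", "P:2:HA"]

    def test_matches_brute_force_pair_filter(self):
        rng = np.random.default_rng(41)
        params = RelaxationParameters(cutoff=6.0)
        atoms = [proton(f"H{i}", "L", 1, rng.uniform(-3, 3, 3)) for i in range(2)]
        atoms += [proton(f"HP{i}", "P", 2, rng.uniform(-9, 9, 3)) for i in range(3)]
        frame = Frame(atoms)
        spins = build_spin_system(frame, "chain L", params)
        lig_pos = [a.position for a in atoms[:2]]
        expected = {f"P:2:{a.name}" for a in atoms[2:]
                    if min(np.linalg.norm(a.position - lp) for lp in lig_pos) <= 6.0}
        assert set(spins.ids) - {"L:1:H0", "L:1:H1"} == expected

    def test_requires_hydrogens(self):
        frame = Frame([make_atom("C1", "C", "LIG", 1, "L", (0, 0, 0))])
        with pytest.raises(ValidationError, match="hydrogen"):
            build_spin_system(frame, "chain L", RelaxationParameters())


class TestSimulateStd:
    def test_no_saturation_source_gives_zero(self):
        params = RelaxationParameters()
        ens = Ensemble([Frame([
            proton("H1", "L", 1, (0, 0, 0)),
            proton("H2", "L", 1, (2.5, 0, 0)),
        ])])
        calc = simulate_std(ens, "chain L", "chain P", params)
        assert all(v == 0.0 for v in calc.std_calc.values())

    def test_two_spin_analytic_solution(self):
        params = RelaxationParameters()
        r = 2.8
        sigma, rho = two_spin_sigma_rho(r, params)
        expected = params.bound_fraction * (-sigma / rho) * (
            1 - np.exp(-rho * params.t_sat)
        )
        calc = simulate_std(pair_ensemble(r), "chain L", "chain P", params)
        assert calc.std_calc["L:1:H1"] == pytest.approx(expected, abs=1e-6)

    def test_proximity_monotonicity(self):
        params = RelaxationParameters()
        ens = Ensemble([Frame([
            proton("HA", "L", 1, (2.5, 0, 0)),
            proton("HB", "L", 1, (6.0, 0, 0)),
            proton("HP", "P", 2, (0, 0, 0)),
        ])])
        calc = simulate_std(ens, "chain L", "chain P", params)
        assert calc.std_calc["L:1:HA"] > calc.std_calc["L:1:HB"]

    def test_buildup_monotone_nondecreasing(self):
        params = RelaxationParameters()
        times = np.linspace(0.0, params.t_sat, 12)
        calc = simulate_std(pair_ensemble(2.6), "chain L", "chain P", params,
                            times=times)
        t, curve = calc.buildup
        assert np.all(np.diff(curve[:, 0]) >= -1e-15)
        assert curve[0, 0] == pytest.approx(0.0, abs=1e-12)


class TestRNoe:
    def test_perfect_agreement_zero(self):
        calc = TheoreticalEpitope(std_calc={"A": 0.6, "B": 0.8})
        assert r_noe({"A": 0.6, "B": 0.8}, calc).r_noe == 0.0

    def test_zero_prediction_gives_one(self):
        calc = TheoreticalEpitope(std_calc={"A": 0.0, "B": 0.0})
        assert r_noe({"A": 0.6, "B": 0.8}, calc).r_noe == pytest.approx(1.0)

    def test_hand_worked_value(self):
        calc = TheoreticalEpitope(std_calc={"A": 0.5, "B": 0.7})
        res = r_noe({"A": 0.6, "B": 0.8}, calc)
        assert res.r_noe == pytest.approx(np.sqrt(0.02 / 1.00), abs=1e-9)

    def test_all_zero_experimental_undefined(self):
        calc = TheoreticalEpitope(std_calc={"A": 0.1})
        with pytest.raises(ValidationError, match="zero"):
            r_noe({"A": 0.0}, calc)

    def test_relative_normalization_identical_for_both(self):
        calc = TheoreticalEpitope(std_calc={"A": 0.05, "B": 0.025})
        res = r_noe({"A": 0.6, "B": 0.3}, calc, normalize="relative")
        assert res.r_noe == pytest.approx(0.0, abs=1e-12)

    def test_closed_loop_perturbation_monotone(self):
        # "experimental" epitope generated by the model itself; growing coordinate
        # noise must monotonically degrade the R-factor
        params = RelaxationParameters()
        rng = np.random.default_rng(55)
        base = [
            proton("H1", "L", 1, (0.0, 0.0, 0.0)),
            proton("H2", "L", 1, (2.9, 0.5, 0.0)),
            proton("H3", "L", 1, (5.3, 0.0, 1.0)),
            proton("HA", "P", 2, (-2.4, 0.8, 0.2)),
            proton("HB", "P", 2, (1.5, -2.6, 0.7)),
        ]
        ref = Ensemble([Frame(base)])
        exp = simulate_std(ref, "chain L", "chain P", params).std_calc
        noise = rng.standard_normal((len(base), 3))
        noise /= np.linalg.norm(noise, axis=1, keepdims=True)
        rs = []
        for level in (0.0, 0.125, 0.25, 0.375, 0.5):
            atoms = [
                Atom(a.name, a.element, a.residue_name, a.residue_id, a.chain_id,
                     a.position + level * noise[i])
                for i, a in enumerate(base)
            ]
            calc = simulate_std(Ensemble([Frame(atoms)]), "chain L", "chain P", params)
            rs.append(r_noe(exp, calc).r_noe)
        assert rs[0] == pytest.approx(0.0, abs=1e-12)
        assert all(b > a for a, b in zip(rs, rs[1:]))

    def test_series_statistics(self):
        params = RelaxationParameters()
        frames = [
            Frame([proton("H1", "L", 1, (0, 0, 0)), proton("HA", "P", 2, (r, 0, 0))])
            for r in (2.5, 2.8, 3.1)
        ]
        ens = Ensemble(frames)
        calc = simulate_std(ens, "chain L", "chain P", params)
        res = r_noe_series(calc.std_calc, calc)
        assert res.series.shape == (3,)
        assert res.series_mean == pytest.approx(np.mean(res.series))
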