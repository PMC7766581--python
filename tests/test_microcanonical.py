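"""Microcanonical analysis tests: entropy construction, Bézier smoothing
and differentiation against analytic oracles, and transition detection /
classification on synthetic densities of states with known structure."""

import numpy as np
import pytest

from semiflex.fixtures import (
    SyntheticDosSpec,
    double_tangent_beta,
    generate_synthetic_dos,
)
from semiflex.microcanonical import (
    EntropyCurve,
    bezier_smooth,
    derivative_curves,
    entropy_from_dos,
    find_transitions,
    transition_table,
)
from semiflex.wham import DensityOfStatesEstimate


def _dos(energies, ln_g):
    return DensityOfStatesEstimate(
        energies=np.asarray(energies, dtype=float),
        ln_g=np.asarray(ln_g, dtype=float),
        support=np.isfinite(ln_g),
    )


TWO_GAUSS_SPEC = SyntheticDosSpec(
    family="two-gaussian", e_min=-20, e_max=80, n_bins=200,
    centers=(0.0, 50.0), widths=(6.0, 10.0), weights=(1.0, 2.4154952753575298e7),
)


class TestEntropy:
    def test_two_state_toy(self):
        ent = entropy_from_dos(_dos([0.0, 1.0, 2.0, 3.0], np.log([1, 2, 4, 8])))
        assert ent.s[0] == pytest.approx(0.0)
        assert ent.s[1] == pytest.approx(np.log(2))

    def test_gauge_shift_moves_s_but_not_derivatives(self):
        dos = generate_synthetic_dos(TWO_GAUSS_SPEC)
        shifted = _dos(dos.energies, dos.ln_g + 12.5)
        c1 = derivative_curves(entropy_from_dos(dos), n_grid=300)
        c2 = derivative_curves(entropy_from_dos(shifted), n_grid=300)
        assert np.allclose(c2.s - c1.s, 12.5, atol=1e-6)
        for name in ("beta", "gamma", "delta"):
            assert np.allclose(getattr(c1, name), getattr(c2, name), atol=1e-8)

    def test_constant_ln_g_gives_flat_beta(self):
        ent = entropy_from_dos(_dos(np.linspace(0, 10, 30), np.zeros(30)))
        curves = derivative_curves(ent, n_grid=100)
        assert np.allclose(curves.beta, 0.0, atol=1e-10)


class TestBezier:
    def test_affine_data_reproduced_exactly(self):
        x = np.linspace(0, 10, 50)
        curve = bezier_smooth(x, 3.0 * x - 2.0)
        y, d1, d2, _ = curve.evaluate(np.linspace(0, 10, 97))
        assert np.allclose(y, 3.0 * np.linspace(0, 10, 97) - 2.0, atol=1e-9)
        assert np.allclose(d1, 3.0, atol=1e-8)
        assert np.allclose(d2, 0.0, atol=1e-8)

    def test_endpoint_interpolation(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 5, 25))
        x[0], x[-1] = 0.0, 5.0
        y = rng.normal(size=25)
        curve = bezier_smooth(x, y)
        out, *_ = curve.evaluate(np.array([0.0, 5.0]))
        assert out[0] == pytest.approx(y[0], abs=1e-10)
        assert out[1] == pytest.approx(y[-1], abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_convexity_preserved(self, seed):
        """Bézier curves inherit convexity from their control polygon."""
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 1, 40)
        slopes = np.cumsum(rng.random(39))  # increasing slopes -> convex
        y = np.concatenate([[0.0], np.cumsum(slopes * np.diff(x))])
        curve = bezier_smooth(x, y)
        _, _, d2, _ = curve.evaluate(np.linspace(0, 1, 300))
        assert np.all(d2 >= -1e-8)

    def test_nonmonotone_x_rejected(self):
        with pytest.raises(ValueError):
            bezier_smooth(np.array([0.0, 2.0, 1.0, 3.0]), np.zeros(4))


class TestDerivatives:
    def test_log_entropy_analytic_oracle(self):
        """S = a + c ln(E - E_off) has beta = c/(E - E_off) and
        gamma = -c/(E - E_off)^2 exactly."""
        e = np.linspace(2.0, 12.0, 400)
        c, off = 3.0, 1.0
        ent = EntropyCurve(energies=e, s=5.0 + c * np.log(e - off))
        curves = derivative_curves(ent, n_grid=500)
        inner = slice(50, 450)  # away from endpoints
        eg = curves.energies[inner]
        assert np.allclose(curves.beta[inner], c / (eg - off), rtol=0.01)
        assert np.allclose(curves.gamma[inner], -c / (eg - off) ** 2, rtol=0.02)

    def test_beta_matches_finite_difference_of_smoothed_s(self):
        dos = generate_synthetic_dos(TWO_GAUSS_SPEC)
        curves = derivative_curves(entropy_from_dos(dos), n_grid=800)
        fd = np.gradient(curves.s, curves.energies)
        assert np.allclose(curves.beta[5:-5], fd[5:-5], rtol=5e-3, atol=5e-4)

    def test_affine_entropy_has_zero_curvature(self):
        e = np.linspace(0, 10, 50)
        curves = derivative_curves(EntropyCurve(energies=e, s=2.0 - 0.7 * e), n_grid=200)
        assert np.allclose(curves.beta, -0.7, atol=1e-8)
        assert np.allclose(curves.gamma, 0.0, atol=1e-8)
        assert np.allclose(curves.delta, 0.0, atol=1e-7)


class TestTransitionDetection:
    def test_strictly_concave_entropy_yields_no_transitions(self):
        e = np.linspace(2.0, 12.0, 300)
        ent = EntropyCurve(energies=e, s=3.0 * np.log(e - 1.0))
        records = find_transitions(derivative_curves(ent, n_grid=400), ent)
        assert records == []

    def test_two_gaussian_first_order_matches_double_tangent(self):
        """A bimodal g(E) produces a convex intruder whose inflection
        (positive minimum of beta) must sit at the Maxwell slope."""
        dos = generate_synthetic_dos(TWO_GAUSS_SPEC)
        ent = entropy_from_dos(dos, e_min=float(dos.energies[0]))
        curves = derivative_curves(ent, n_grid=1000)
        records = find_transitions(curves, ent)
        first = [r for r in records if r.order == 1]
        assert len(first) == 1
        beta_ref = double_tangent_beta(ent.energies, ent.s)
        assert first[0].beta_tr == pytest.approx(beta_ref, rel=0.05)
        # designed transition only: nothing else at this noise-free level
        assert all(r.order != 1 or r is first[0] for r in records)

    def test_two_gaussian_stability_under_bin_halving(self):
        def beta_tr(n_bins):
            spec = SyntheticDosSpec(
                family="two-gaussian", e_min=-20, e_max=80, n_bins=n_bins,
                centers=(0.0, 50.0), widths=(6.0, 10.0), weights=(1.0, 2.4154952753575298e7),
            )
            ent = entropy_from_dos(generate_synthetic_dos(spec))
            recs = find_transitions(derivative_curves(ent, n_grid=800), ent)
            return [r for r in recs if r.order == 1][0].beta_tr

        assert beta_tr(400) == pytest.approx(beta_tr(200), rel=0.02)

    def test_cubic_flat_point_in_beta_is_second_order(self):
        """beta with a flat inflection at E* (gamma peaking negatively
        there) must classify as one independent second-order transition
        and nothing else."""
        e = np.linspace(0.0, 20.0, 400)
        e_star, a, c3 = 8.0, 0.02, 0.004
        beta = 2.0 - a * (e - e_star) - c3 * (e - e_star) ** 3
        s = np.concatenate([[0.0], np.cumsum(0.5 * (beta[1:] + beta[:-1]) * np.diff(e))])
        ent = EntropyCurve(energies=e, s=s)
        records = find_transitions(derivative_curves(ent, n_grid=800), ent)
        assert len(records) == 1
        rec = records[0]
        assert rec.order == 2 and rec.dependence == "independent"
        assert rec.e_tr == pytest.approx(e_star, abs=3 * (e[1] - e[0]))
        assert rec.signal_strength < 0

    def test_energy_shift_covariance(self):
        dos = generate_synthetic_dos(TWO_GAUSS_SPEC)
        shift = 17.0
        moved = DensityOfStatesEstimate(
            energies=dos.energies + shift, ln_g=dos.ln_g, support=dos.support,
        )
        r0 = find_transitions(derivative_curves(entropy_from_dos(dos), n_grid=600))
        r1 = find_transitions(derivative_curves(entropy_from_dos(moved), n_grid=600))
        assert len(r0) == len(r1)
        for a, b in zip(r0, r1):
            assert b.e_tr == pytest.approx(a.e_tr + shift, abs=1e-6)
            assert b.beta_tr == pytest.approx(a.beta_tr, abs=1e-8)
            assert b.order == a.order

    def test_dependent_records_need_lower_energy_partner(self):
        """A positive-valued minimum of gamma with no order-1 transition
        below it must not be reported."""
        # gamma = 0.05 + 0.01 (E - 10)^2: positive minimum at E = 10,
        # beta increasing -> no order-1 anywhere
        e = np.linspace(0.0, 20.0, 400)
        gamma = 0.05 + 0.01 * (e - 10.0) ** 2
        beta = np.concatenate([[1.0], 1.0 + np.cumsum(0.5 * (gamma[1:] + gamma[:-1]) * np.diff(e))])
        s = np.concatenate([[0.0], np.cumsum(0.5 * (beta[1:] + beta[:-1]) * np.diff(e))])
        records = find_transitions(derivative_curves(EntropyCurve(energies=e, s=s), n_grid=600))
        assert all(r.dependence != "dependent" for r in records)


class TestTransitionTable:
    def test_empty_records_give_header_only(self):
        table = transition_table([])
        assert len(table) == 0
        assert list(table.columns) == [
            "kappa", "E_tr", "Delta_E", "beta_tr", "order", "dependence", "significance",
        ]

    def test_reduced_energy_column(self):
        from semiflex.microcanonical import TransitionRecord

        rec = TransitionRecord(
            e_tr=-225.2, delta_e=np.nan, beta_tr=2.95, order=1,
            dependence="independent", signal_strength=2.95, significance=np.inf,
        )
        table = transition_table([rec], kappa=0.0, e_min=-261.7)
        assert table.loc[0, "Delta_E"] == pytest.approx(36.5)

    def test_delta_e_identity(self):
        dos = generate_synthetic_dos(TWO_GAUSS_SPEC)
        ent = entropy_from_dos(dos, e_min=-20.0)
        records = find_transitions(derivative_curves(ent, n_grid=500), ent)
        for r in records:
            assert r.delta_e == pytest.approx(r.e_tr - (-20.0), abs=1e-9)
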