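"""Fisher information tests.

The central oracle of the whole package: analytic sensitivities must agree
with central finite differences of the simulator, for every parameter, under
both model variants, across random schemes.  Everything downstream (FIM,
CRLB, design criterion) is checked against independent linear-algebra paths.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import inv as scipy_inv

from vfadesign import (
    FlipAngleScheme,
    KineticParameters,
    WITH_B1S,
    WITHOUT_B1S,
    WeightSpec,
    crlb,
    fim,
    l_optimality,
    nondimensionalize,
    sensitivities,
    simulate,
    transition_matrix,
    transition_matrix_grad,
)
from vfadesign.exceptions import SingularInformationError
from vfadesign.fisher import CONDITION_THRESHOLD, ParameterScales, fim_from_sensitivities
from vfadesign.kinetics import param_names

ALL_NAMES = ("k", "R1S", "R1P", "S0", "P0", "B1S")


def _fd_dy(params, scheme, name, variant, rel_step=1e-6):
    """Central finite differences of the simulated signal."""
    theta = np.array([getattr(params, n) for n in ALL_NAMES])
    j = ALL_NAMES.index(name)
    h = rel_step * max(abs(theta[j]), 1e-3)
    tp, tm = theta.copy(), theta.copy()
    tp[j] += h
    tm[j] -= h
    yp = simulate(KineticParameters(*tp), scheme).y
    ym = simulate(KineticParameters(*tm), scheme).y
    return (yp - ym) / (2 * h)


class TestTransitionMatrixGrad:
    def test_initial_state_gradients_are_zero(self, nominal):
        grads = transition_matrix_grad(nominal, 2.0)
        for name in ("S0", "P0", "B1S"):
            assert np.all(grads[name] == 0.0)

    @pytest.mark.parametrize(
        "params",
        [
            KineticParameters(k=0.0135, R1S=1 / 35, R1P=1 / 54, S0=5.0, P0=0.1),
            KineticParameters(k=0.0, R1S=1 / 35, R1P=1 / 54, S0=5.0, P0=0.1),
            # exactly degenerate and nearly degenerate rate combinations
            KineticParameters(k=0.01, R1S=0.02, R1P=0.03, S0=1.0, P0=0.0),
            KineticParameters(k=0.01, R1S=0.02, R1P=0.03 + 1e-7, S0=1.0, P0=0.0),
        ],
    )
    def test_against_finite_differences(self, params):
        grads = transition_matrix_grad(params, 2.0)
        for name in ("k", "R1S", "R1P"):
            val = getattr(params, name)
            h = 1e-6 * max(val, 1e-4)
            gp = transition_matrix(params.replace(**{name: val + h}), 2.0)
            gm = transition_matrix(params.replace(**{name: max(val - h, 0.0)}), 2.0)
            denom = val + h - max(val - h, 0.0)
            fd = (gp - gm) / denom
            assert np.abs(grads[name] - fd).max() < 1e-5 * max(np.abs(fd).max(), 1.0)

    def test_k_zero_off_diagonal_closed_form(self, nominal):
        # at k = 0: dG21/dk = (exp(-R1S TR) - exp(-R1P TR)) / (R1P - R1S)
        p = nominal.replace(k=0.0)
        tr = 2.0
        expected = (np.exp(-p.R1S * tr) - np.exp(-p.R1P * tr)) / (p.R1P - p.R1S)
        assert np.isclose(transition_matrix_grad(p, tr)["k"][1, 0], expected, rtol=1e-10)


class TestSensitivities:
    def test_zero_angles_give_zero_information(self, nominal):
        scheme = FlipAngleScheme(np.zeros(8), 2.0)
        sens = sensitivities(nominal, scheme, WITH_B1S)
        assert np.all(sens.dy == 0.0)

    @pytest.mark.parametrize("variant", [WITHOUT_B1S, WITH_B1S])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_match_finite_differences(self, variant, seed):
        """Primary oracle: analytic dy/dtheta == central FD to 1e-5 relative."""
        rng = np.random.default_rng(seed)
        params = KineticParameters(
            k=rng.uniform(0.005, 0.05),
            R1S=rng.uniform(0.01, 0.1),
            R1P=rng.uniform(0.01, 0.1),
            S0=rng.uniform(1, 10),
            P0=rng.uniform(0, 0.5),
            B1S=rng.uniform(0.7, 1.3),
        )
        scheme = FlipAngleScheme(rng.uniform(0.0, 90.0, size=15), rng.uniform(0.5, 4))
        sens = sensitivities(params, scheme, variant)
        for i, name in enumerate(sens.order):
            fd = _fd_dy(params, scheme, name, variant)
            scale = max(np.abs(fd).max(), 1e-12)
            assert np.abs(sens.dy[i] - fd).max() / scale < 1e-5, name

    def test_normalized_sensitivities_scale(self, nominal, sparse_vfa_scheme):
        raw = sensitivities(nominal, sparse_vfa_scheme)
        nrm = sensitivities(nominal, sparse_vfa_scheme, normalization="s0-sin-alpha0")
        c = nominal.S0 * np.sin(np.deg2rad(sparse_vfa_scheme.angles_deg[0]))
        assert np.allclose(nrm.dy * c, raw.dy)

    def test_differentiated_normalization_matches_fd(self, nominal, sparse_vfa_scheme):
        # when the S0 derivative goes through the factor, it must match FD of
        # the normalized simulation
        sens = sensitivities(
            nominal, sparse_vfa_scheme,
            normalization="s0-sin-alpha0", differentiate_normalization=True,
        )
        i = sens.order.index("S0")
        h = 1e-6 * nominal.S0

        def normed_y(p):
            y = simulate(p, sparse_vfa_scheme).y
            return y / (p.S0 * np.sin(np.deg2rad(sparse_vfa_scheme.angles_deg[0])))

        fd = (
            normed_y(nominal.replace(S0=nominal.S0 + h))
            - normed_y(nominal.replace(S0=nominal.S0 - h))
        ) / (2 * h)
        assert np.abs(sens.dy[i] - fd).max() < 1e-5 * max(np.abs(fd).max(), 1e-12)

    def test_p0_derivative_at_first_point(self, nominal, sparse_vfa_scheme):
        p = nominal.replace(P0=0.0)
        sens = sensitivities(p, sparse_vfa_scheme, WITH_B1S)
        i = sens.order.index("P0")
        a0 = np.deg2rad(sparse_vfa_scheme.angles_deg[0])
        assert np.isclose(sens.dy[i][1, 0], np.sin(p.B1S * a0))
        assert sens.dy[i][0, 0] == 0.0


class TestFIM:
    def test_no_measurements_no_information(self, nominal):
        scheme = FlipAngleScheme(np.zeros(8), 2.0)
        res = fim(nominal, scheme, 5e-3)
        assert np.all(res.matrix == 0.0)
        assert not res.invertible

    def test_sigma_scaling(self, nominal, sparse_vfa_scheme):
        f1 = fim(nominal, sparse_vfa_scheme, 5e-3)
        f2 = fim(nominal, sparse_vfa_scheme, 5e-2)
        assert np.allclose(f2.matrix * 100.0, f1.matrix)

    @given(seed=st.integers(0, 500))
    def test_symmetric_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        params = KineticParameters(
            k=rng.uniform(0.001, 0.1), R1S=rng.uniform(0.005, 0.2),
            R1P=rng.uniform(0.005, 0.2), S0=rng.uniform(0.5, 10),
            P0=rng.uniform(0, 1), B1S=rng.uniform(0.5, 1.5),
        )
        scheme = FlipAngleScheme(rng.uniform(0, 90, size=10), 2.0)
        res = fim(params, scheme, 5e-3, WITH_B1S)
        assert np.abs(res.matrix - res.matrix.T).max() < 1e-10
        eigs = np.linalg.eigvalsh(res.matrix)
        assert eigs.min() >= -1e-10 * np.trace(res.matrix)

    def test_extra_terminal_excitation_adds_information(self, nominal):
        # an excitation where no later pulses follow can only add terms to
        # the information sum (mid-sequence pulses instead consume
        # magnetization and can reduce later sensitivities)
        rng = np.random.default_rng(3)
        angles = rng.uniform(0, 40, size=12)
        angles[8:] = 0.0
        base = fim(nominal, FlipAngleScheme(angles, 2.0), 5e-3)
        bumped = angles.copy()
        bumped[10] = 25.0
        more = fim(nominal, FlipAngleScheme(bumped, 2.0), 5e-3)
        assert np.all(np.diag(more.matrix) >= np.diag(base.matrix) - 1e-12)
        assert np.trace(more.matrix) > np.trace(base.matrix)

    def test_cfa_with_b1s_is_rank_deficient(self, nominal):
        """Constant angles make B1S completely correlated with the others."""
        cfa = FlipAngleScheme.constant(13.5, 76, 2.0)
        res = fim(nominal, cfa, 5e-3, WITH_B1S)
        assert not res.invertible
        assert res.condition > CONDITION_THRESHOLD
        # while a VFA scheme keeps all six parameters identifiable
        vfa = FlipAngleScheme(np.linspace(5, 60, 76), 2.0)
        assert fim(nominal, vfa, 5e-3, WITH_B1S).invertible

    def test_normalization_cancels_in_fim(self, nominal, sparse_vfa_scheme):
        c = nominal.S0 * np.sin(np.deg2rad(sparse_vfa_scheme.angles_deg[0]))
        raw = fim(nominal, sparse_vfa_scheme, 5e-3)
        nrm = fim_from_sensitivities(
            sensitivities(nominal, sparse_vfa_scheme, normalization="s0-sin-alpha0"),
            5e-3 / c,
        )
        assert np.allclose(raw.matrix, nrm.matrix)


class TestCRLB:
    def test_diagonal_fim(self):
        res = type(fim(KineticParameters(0.01, 0.1, 0.1, 1, 0), FlipAngleScheme(np.array([30.0]), 1.0), 1.0))
        from vfadesign.fisher import FIMResult

        f = FIMResult(np.diag([4.0, 9.0]), ("a", "b"), 2.25, True, 1.0)
        assert np.allclose(crlb(f), np.diag([0.25, 1 / 9.0]))

    def test_product_with_fim_is_identity(self, nominal, sparse_vfa_scheme):
        f = fim(nominal, sparse_vfa_scheme, 5e-3)
        assert np.abs(f.matrix @ crlb(f) - np.eye(5)).max() < 1e-8

    def test_singular_raises(self, nominal):
        f = fim(nominal, FlipAngleScheme(np.zeros(5), 2.0), 5e-3)
        with pytest.raises(SingularInformationError):
            crlb(f)


class TestLOptimality:
    def test_zero_weights(self, nominal, sparse_vfa_scheme):
        f = fim(nominal, sparse_vfa_scheme, 5e-3)
        assert l_optimality(f, WeightSpec({"k": 0.0})) == 0.0

    def test_identity_weights_are_a_optimality(self, nominal, sparse_vfa_scheme):
        f = fim(nominal, sparse_vfa_scheme, 5e-3)
        w = WeightSpec({n: 1.0 for n in param_names(WITHOUT_B1S)})
        assert np.isclose(l_optimality(f, w), np.trace(crlb(f)), rtol=1e-12)

    def test_against_brute_force_trace(self, nominal, sparse_vfa_scheme):
        f = fim(nominal, sparse_vfa_scheme, 5e-3)
        w = WeightSpec.relative(nominal, "k", "R1P")
        wmat = np.diag(w.vector(f.order))
        brute = np.trace(wmat @ scipy_inv(f.matrix))
        assert abs(l_optimality(f, w) - brute) <= 1e-10 * abs(brute)


class TestNondimensionalize:
    def test_rate_scaling(self, nominal):
        scaled, _ = nondimensionalize(nominal, 2.0)
        assert np.isclose(scaled[0], 0.027)

    def test_round_trip(self, nominal):
        scaled, scales = nondimensionalize(nominal, 2.0, WITH_B1S)
        back = scales.to_physical(scaled)
        assert np.allclose(back, nominal.as_array(WITH_B1S), rtol=1e-14)

    def test_l_optimality_invariant_under_scaling(self, nominal, sparse_vfa_scheme):
        """tr(W I^-1) is unchanged when theta, I and W transform consistently."""
        f = fim(nominal, sparse_vfa_scheme, 5e-3)
        w = WeightSpec.relative(nominal, "k", "R1S", "R1P")
        base = l_optimality(f, w)
        _, scales = nondimensionalize(nominal, 2.0)
        d = np.diag(1.0 / scales.factors)
        fim_scaled = d @ f.matrix @ d  # I in the scaled parameterization
        # Var(theta_i * s_i) = s_i^2 Var(theta_i), so weights carry 1/s_i^2
        wvec = w.vector(f.order) / scales.factors**2
        scaled_val = np.trace(np.diag(wvec) @ np.linalg.inv(fim_scaled))
        assert np.isclose(base, scaled_val, rtol=1e-10)
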