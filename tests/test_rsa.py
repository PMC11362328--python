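import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slopesem import aux_params, congruence_test, delta_se, vertex_x
from slopesem.rsa import AUX_NAMES, RSAParams, aux_gradients, rsa_from_fit


def _finite_floats(lo, hi):
    return st.floats(lo, hi, allow_nan=False, allow_infinity=False)


class TestAuxParams:
    def test_congruence_identities(self):
        """A congruence-shaped surface has a1=a2=a3=0, a4=4*b3, p11=1 and
        ridge p10 at its limit 0."""
        c = -2.5
        pts = aux_params(np.array([0, 0, 0, c, -2 * c, c], dtype=float))
        assert pts["a1"] == 0 and pts["a2"] == pytest.approx(0) and pts["a3"] == 0
        assert pts["a4"] == pytest.approx(4 * c)
        assert pts["p11"] == pytest.approx(1.0)
        assert pts["ridge"] is True
        assert pts["p10"] == pytest.approx(0.0)

    def test_against_hessian_eigendecomposition(self):
        """p11 matches the first principal axis from an independent
        eigen-decomposition of the surface Hessian."""
        b = np.array([0.0, 0.1, 0.2, -0.3, 0.05, -0.2])
        pts = aux_params(b)
        H = np.array([[2 * b[3], b[4]], [b[4], 2 * b[5]]])
        w, V = np.linalg.eigh(H)
        # first principal axis: eigenvector of the larger eigenvalue
        v = V[:, np.argmax(w)]
        slope = v[1] / v[0]
        assert pts["p11"] == pytest.approx(slope, abs=1e-10)
        # stationary point solves grad = 0; p10 = y0 - p11*x0
        x0, y0 = np.linalg.solve(H, -b[1:3])
        assert pts["p10"] == pytest.approx(y0 - slope * x0, abs=1e-10)

    def test_degenerate_quadratic_part(self):
        pts = aux_params(np.array([0.0, 1, 1, 0, 0, 0]))
        assert pts["undefined"] is not None
        assert np.isnan(pts["p10"]) and np.isnan(pts["p11"])

    def test_vertex_worked_example(self):
        assert round(vertex_x(5.64, -10.81), 2) == 0.26


class TestDeltaSE:
    def test_linear_combination(self):
        cov = np.zeros((6, 6))
        cov[1, 1], cov[2, 2] = 0.04, 0.09
        ses = delta_se(np.array([0, 0.5, 0.2, -1.0, 0.3, -0.8]), cov)
        assert ses["a1"] == pytest.approx(np.sqrt(0.13))
        assert ses["a3"] == pytest.approx(np.sqrt(0.13))

    def test_zero_covariance_gives_zero_se(self):
        ses = delta_se(np.array([0, 0.5, 0.2, -1.0, 0.3, -0.8]), np.zeros((6, 6)))
        assert all(ses[n] == 0 for n in AUX_NAMES)

    @settings(derandomize=True, max_examples=25)
    @given(
        b1=_finite_floats(-2, 2), b2=_finite_floats(-2, 2),
        b3=_finite_floats(-3, -0.2), b4=_finite_floats(0.3, 3),
        b5=_finite_floats(-3, -0.2),
    )
    def test_gradients_match_finite_differences(self, b1, b2, b3, b4, b5):
        b = np.array([0.0, b1, b2, b3, b4, b5])
        pts = aux_params(b)
        if pts["undefined"] or pts["ridge"]:
            return
        grads = aux_gradients(b)
        eps = 1e-7
        for name in AUX_NAMES:
            fd = np.zeros(6)
            for j in range(1, 6):
                bp, bm = b.copy(), b.copy()
                bp[j] += eps
                bm[j] -= eps
                pp, pm = aux_params(bp), aux_params(bm)
                if pp["ridge"] or pm["ridge"]:
                    return
                fd[j] = (pp[name] - pm[name]) / (2 * eps)
            scale = max(1.0, np.abs(grads[name]).max())
            assert np.allclose(grads[name], fd, atol=1e-5 * scale)

    @settings(derandomize=True, max_examples=25)
    @given(
        b0=_finite_floats(-1, 1), b1=_finite_floats(-2, 2), b2=_finite_floats(-2, 2),
        b3=_finite_floats(-3, -0.2), b4=_finite_floats(0.3, 3),
        b5=_finite_floats(-3, -0.2), w=_finite_floats(-2, 2),
    )
    def test_surface_reconstruction_along_congruence_line(
        self, b0, b1, b2, b3, b4, b5, w
    ):
        """Predicted z along X = Y = w equals b0 + a1*w + a2*w^2."""
        b = np.array([b0, b1, b2, b3, b4, b5])
        pts = aux_params(b)
        direct = b0 + b1 * w + b2 * w + b3 * w**2 + b4 * w**2 + b5 * w**2
        via_aux = b0 + pts["a1"] * w + pts["a2"] * w**2
        assert direct == pytest.approx(via_aux, abs=1e-8 * max(1, abs(direct)))


class TestCongruenceTest:
    @staticmethod
    def _params(ci):
        return RSAParams(
            points={n: np.mean(ci[n]) for n in AUX_NAMES},
            se={n: 1.0 for n in AUX_NAMES},
            conf_int=ci,
            source="delta",
        )

    def test_accepted_when_all_conditions_met(self):
        ci = {n: (-0.5, 0.5) for n in ("a1", "a2", "a3", "p10")}
        ci["p11"] = (0.7, 1.3)
        ci["a4"] = (-3.0, -1.0)
        verdict = congruence_test(self._params(ci))
        assert verdict.accepted
        assert all(verdict.conditions.values())

    @pytest.mark.parametrize(
        "name, interval",
        [("a4", (-0.5, 0.1)), ("p11", (1.2, 1.6)), ("a1", (0.2, 0.9))],
    )
    def test_rejected_on_single_violation(self, name, interval):
        ci = {n: (-0.5, 0.5) for n in ("a1", "a2", "a3", "p10")}
        ci["p11"] = (0.7, 1.3)
        ci["a4"] = (-3.0, -1.0)
        ci[name] = interval
        assert not congruence_test(self._params(ci)).accepted

    def test_undefined_axes_reject(self):
        fit = rsa_from_fit(np.array([0.0, 1, 1, 0, 0, 0]), np.eye(6) * 0.01)
        verdict = fit.congruence_test()
        assert not verdict.accepted
        assert verdict.reason is not None
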