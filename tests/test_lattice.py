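"""D3Q19 moment basis, equilibrium moments, MRT/BGK equivalence."""

import numpy as np
import pytest

from gastroflow import lattice as L


def test_moment_basis_orthogonal():
    G = L.M @ L.M.T
    assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-10)
    assert np.allclose(L.M_INV @ L.M, np.eye(19), atol=1e-12)


def test_stencil_structure():
    assert L.W.sum() == pytest.approx(1.0)
    assert np.all(L.C[L.OPP] == -L.C)
    # lattice isotropy: sum w c_a c_b = cs^2 delta_ab
    for a in range(3):
        for b in range(3):
            s = np.sum(L.W * L.C[:, a] * L.C[:, b])
            assert s == pytest.approx(L.CS2 if a == b else 0.0, abs=1e-12)


def test_equilibrium_moments():
    rho = 1.07
    u = np.array([0.02, -0.01, 0.03])
    fe = L.feq(rho, u)
    assert fe.sum() == pytest.approx(rho, rel=1e-12)
    np.testing.assert_allclose(fe @ L.C, rho * u, rtol=1e-12)


def test_mrt_with_equal_rates_is_bgk():
    # independent BGK oracle: f' = f - (f - feq)/tau, elementwise
    rng = np.random.default_rng(0)
    tau = 0.8
    rho = 1.0 + 0.05 * rng.standard_normal()
    u = 0.05 * rng.standard_normal(3)
    f = L.feq(rho, u) + 0.01 * rng.standard_normal(19)
    rho_a = f.sum()
    u_a = (f @ L.C) / rho_a
    fe = L.feq(rho_a, u_a)
    bgk = f - (f - fe) / tau
    A = L.collision_matrix(L.relaxation_rates(tau, bgk=True))
    mrt = f - A @ (f - fe)
    np.testing.assert_allclose(mrt, bgk, atol=1e-13)


def test_mrt_conserves_mass_and_momentum():
    rng = np.random.default_rng(1)
    f = np.abs(rng.standard_normal(19)) * 0.05
    rho = f.sum()
    u = (f @ L.C) / rho
    fe = L.feq(rho, u)
    A = L.collision_matrix(L.relaxation_rates(0.6))
    fp = f - A @ (f - fe)
    assert fp.sum() == pytest.approx(rho, rel=1e-12)
    np.testing.assert_allclose(fp @ L.C, rho * u, atol=1e-14)


def test_magic_relation():
    tau = 1.3
    s_odd = L.magic_odd_rate(tau)
    lam = (tau - 0.5) * (1.0 / s_odd - 0.5)
    assert lam == pytest.approx(3.0 / 16.0, rel=1e-12)
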