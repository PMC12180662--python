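"""Conditional flow: invertibility, change of variables, conditioning."""

import numpy as np
import pytest

from sliceflow import cnf
from sliceflow.autodiff import Adam, Tensor


def perturbed_flow(dim, cond_dim, n_coupling=3, hidden=16, seed=0, scale=0.3):
    flow = cnf.FlowModel(dim, condition_dim=cond_dim, n_coupling=n_coupling,
                         hidden=hidden, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for p in flow.params:
        p.data = p.data + rng.normal(0.0, scale, p.data.shape)
    return flow


def test_identity_initialization_is_identity(rng):
    flow = cnf.FlowModel(6, condition_dim=4, n_coupling=8, hidden=32)
    x = rng.normal(size=(10, 6))
    cond = rng.normal(size=(10, 4))
    z, logdet = flow.forward(x, cond)
    assert np.allclose(z, x)
    assert np.allclose(logdet, 0.0)
    assert np.allclose(flow.inverse(x, cond), x)


def test_roundtrip_inversion(rng):
    flow = perturbed_flow(8, 4)
    x = rng.normal(size=(50, 8))
    cond = rng.normal(size=(50, 4))
    z, _ = flow.forward(x, cond)
    assert np.abs(flow.inverse(z, cond) - x).max() < 1e-5
    x2 = flow.inverse(x, cond)
    z2, _ = flow.forward(x2, cond)
    assert np.abs(z2 - x).max() < 1e-5


def test_logdet_matches_numerical_jacobian(rng):
    flow = perturbed_flow(4, 2)
    x = rng.normal(size=(1, 4))
    cond = rng.normal(size=(1, 2))
    _, logdet = flow.forward(x, cond)
    eps = 1e-6
    jac = np.zeros((4, 4))
    for i in range(4):
        xp, xm = x.copy(), x.copy()
        xp[0, i] += eps
        xm[0, i] -= eps
        jac[:, i] = (flow.forward(xp, cond)[0] - flow.forward(xm, cond)[0])[0] / (2 * eps)
    assert abs(logdet[0] - np.log(abs(np.linalg.det(jac)))) < 1e-3


def test_forward_inverse_logdet_antisymmetry(rng):
    """log|det J| of the inverse equals the negated forward value."""
    flow = perturbed_flow(4, 2)
    x = rng.normal(size=(1, 4))
    cond = rng.normal(size=(1, 2))
    z, logdet_fwd = flow.forward(x, cond)
    eps = 1e-6
    jac = np.zeros((4, 4))
    for i in range(4):
        zp, zm = z.copy(), z.copy()
        zp[0, i] += eps
        zm[0, i] -= eps
        jac[:, i] = (flow.inverse(zp, cond) - flow.inverse(zm, cond))[0] / (2 * eps)
    assert abs(np.log(abs(np.linalg.det(jac))) + logdet_fwd[0]) < 1e-3


def test_single_coupling_closed_form():
    """d=2 single layer: the inverse divides by exp(s) after shift removal."""
    flow = cnf.FlowModel(2, condition_dim=2, n_coupling=1, hidden=4, seed=0)
    rng = np.random.default_rng(5)
    for p in flow.params:
        p.data = p.data + rng.normal(0.0, 0.4, p.data.shape)
    x = rng.normal(size=(6, 2))
    cond = rng.normal(size=(6, 2))
    z, logdet = flow.forward(x, cond)
    # reconstruct s, t by hand from the single subnet
    perm, inv = flow.perms[0], flow.inv_perms[0]
    xa = x[:, perm][:, :1]
    w1, b1, w2, b2 = flow._layers[0]
    hidden = np.maximum(np.concatenate([xa, cond], 1) @ w1.data + b1.data, 0)
    st = hidden @ w2.data + b2.data
    s = flow.clamp * np.tanh(st[:, :1] / flow.clamp)
    t = st[:, 1:]
    zb = z[:, perm][:, 1:]
    xb_rec = (zb - t) / np.exp(s)
    assert np.allclose(xb_rec, x[:, perm][:, 1:], atol=1e-10)
    assert np.allclose(logdet, s.ravel())


def test_identity_flow_gaussian_log_likelihood():
    flow2 = cnf.FlowModel(2, condition_dim=2, n_coupling=2, hidden=8)
    lp = cnf.log_likelihood(np.zeros((1, 2)), np.zeros((1, 2)), flow2)
    assert abs(lp[0] - (-np.log(2 * np.pi))) < 1e-9
    flow1 = cnf.FlowModel(2, condition_dim=2, n_coupling=1, hidden=4)
    # d=2 at x=(1,0): -log 2pi - 1/2
    lp1 = cnf.log_likelihood(np.array([[1.0, 0.0]]), np.zeros((1, 2)), flow1)
    assert abs(lp1[0] - (-np.log(2 * np.pi) - 0.5)) < 1e-9


def test_change_of_variables_identity(rng):
    flow = perturbed_flow(5, 4)
    x = rng.normal(size=(20, 5))
    cond = rng.normal(size=(20, 4))
    z, logdet = flow.forward(x, cond)
    base = -0.5 * 5 * np.log(2 * np.pi) - 0.5 * (z**2).sum(axis=1)
    assert np.allclose(cnf.log_likelihood(x, cond, flow), base + logdet)


def test_density_normalizes_by_quadrature(rng):
    flow = perturbed_flow(2, 2, n_coupling=2, hidden=8, scale=0.4)
    grid = np.linspace(-6, 6, 201)
    xx, yy = np.meshgrid(grid, grid)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    cond = np.zeros((len(pts), 2))
    lp = cnf.log_likelihood(pts, cond, flow)
    integral = np.exp(lp).sum() * (grid[1] - grid[0]) ** 2
    assert abs(integral - 1.0) < 0.05


def test_nll_objective_identities(rng):
    flow = cnf.FlowModel(2, condition_dim=2, n_coupling=2, hidden=8)
    zeros = np.zeros((5, 2))
    assert abs(cnf.nll_objective(zeros, zeros, flow) - np.log(2 * np.pi)) < 1e-9
    flow_p = perturbed_flow(3, 2)
    x = rng.normal(size=(11, 3))
    cond = rng.normal(size=(11, 2))
    assert np.isclose(
        cnf.nll_objective(x, cond, flow_p),
        -cnf.log_likelihood(x, cond, flow_p).mean(),
    )
    with pytest.raises(ValueError, match="empty"):
        cnf.nll_objective(np.zeros((0, 3)), np.zeros((0, 2)), flow_p)


def test_training_reaches_source_entropy(rng):
    """NLL of a fitted 2D Gaussian approaches its differential entropy."""
    cov = np.array([[1.0, 0.6], [0.6, 0.5]])
    chol = np.linalg.cholesky(cov)
    x = rng.normal(size=(2000, 2)) @ chol.T
    cond = np.zeros((2000, 2))
    flow = cnf.FlowModel(2, condition_dim=2, n_coupling=4, hidden=32, seed=0)
    opt = Adam(flow.params, lr=1e-2)
    for step in range(200):
        xt, ct = Tensor(x), Tensor(cond)
        lp = cnf.log_likelihood_tensor(xt, ct, flow)
        loss = lp.mean() * (-1.0)
        opt.zero_grad()
        loss.backward()
        opt.step()
    entropy = 0.5 * np.log(np.linalg.det(2 * np.pi * np.e * cov))
    assert abs(cnf.nll_objective(x, cond, flow) - entropy) < 0.1


def test_positional_condition_contract():
    pc = cnf.positional_condition(8, 8, 32)
    assert pc.shape == (64, 32)
    assert pc.min() >= -1.0 and pc.max() <= 1.0
    assert len(np.unique(np.round(pc, 12), axis=0)) == 64  # pairwise distinct
    assert np.array_equal(pc, cnf.positional_condition(8, 8, 32))  # input-free
    with pytest.raises(ValueError, match="even"):
        cnf.positional_condition(8, 8, 33)


def test_dimension_mismatch_rejected(rng):
    flow = cnf.FlowModel(4, condition_dim=2, n_coupling=1, hidden=4)
    with pytest.raises(ValueError, match="shape"):
        flow.forward(rng.normal(size=(3, 5)), rng.normal(size=(3, 2)))
    with pytest.raises(ValueError, match="condition"):
        flow.forward(rng.normal(size=(3, 4)), rng.normal(size=(3, 3)))


def test_state_dict_roundtrip(rng, tmp_path):
    flow = perturbed_flow(6, 4)
    x = rng.normal(size=(7, 6))
    cond = rng.normal(size=(7, 4))
    ref = cnf.log_likelihood(x, cond, flow)
    path = tmp_path / "flow.npz"
    np.savez(path, **flow.state_dict())
    restored = cnf.FlowModel.from_state_dict(dict(np.load(path)))
    assert np.allclose(cnf.log_likelihood(x, cond, restored), ref)
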