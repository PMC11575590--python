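"""The network core: scalar oracles, exact derivatives, weight gradients,
hard constraints, and checkpoint round trips."""

import numpy as np
import pytest

from gammanet._net import MLP, silu, silu_d1, silu_d2
from gammanet.embeddings import HashEmbeddingBackend, embed_component
from gammanet.model import GAS_CONSTANT, GibbsExcessNet, MixtureQuery, cosine_distance
from gammanet.errors import ZeroVector


def test_single_neuron_matches_scalar_formula():
    """A 1-1-1 net with hand-set weights equals w2*silu(w1*z+b1)+b2."""
    net = MLP([np.array([[2.0]]), np.array([[3.0]])], [np.array([0.5]), np.array([-1.0])])
    z = 0.7
    u = 2.0 * z + 0.5
    expected = 3.0 * (u / (1.0 + np.exp(-u))) - 1.0
    assert np.isclose(net.forward([[z]])[0, 0], expected, rtol=1e-12)


def test_zero_weights_give_zero_output():
    net = MLP([np.zeros((3, 2)), np.zeros((2, 3))], [np.zeros(3), np.zeros(2)])
    np.testing.assert_array_equal(net.forward(np.ones((4, 2))), 0.0)


def test_silu_derivatives_match_finite_differences(rng):
    z = rng.normal(scale=2.0, size=200)
    h = 1e-6
    np.testing.assert_allclose(silu_d1(z), (silu(z + h) - silu(z - h)) / (2 * h), atol=1e-8)
    h2 = 1e-4  # second difference: larger step to stay above roundoff
    np.testing.assert_allclose(
        silu_d2(z), (silu(z + h2) - 2 * silu(z) + silu(z - h2)) / h2**2, atol=1e-6
    )


def test_forward2_derivatives_match_finite_differences(rng):
    net = MLP.create([3, 5, 1], rng)
    base = rng.normal(size=3)
    direction = np.array([0.3, -1.0, 2.0])

    def f(t):
        return net.forward((base + t * direction)[None, :])[0, 0]

    y, dy, d2y = net.forward2(base[None, :], direction, 0.0)
    h = 1e-6
    assert np.isclose(y[0, 0], f(0.0))
    assert np.isclose(dy[0, 0], (f(h) - f(-h)) / (2 * h), rtol=1e-5)
    h2 = 1e-4  # second difference needs a larger step to beat roundoff
    assert np.isclose(d2y[0, 0], (f(h2) - 2 * f(0) + f(-h2)) / h2**2, rtol=1e-3, atol=1e-8)


def test_backward_tape_gradients_match_finite_differences(rng):
    """Reverse-mode gradients of both the value and its input-derivative
    channel agree with central differences for every parameter."""
    net = MLP.create([4, 6, 3], rng)
    x = rng.normal(size=(5, 4))
    dx = rng.normal(size=(5, 4))
    wv = rng.normal(size=(5, 3))
    wd = rng.normal(size=(5, 3))

    def loss():
        y, dy, _ = net.forward_tape(x, dx)
        return float((wv * y).sum() + (wd * dy).sum())

    y, dy, tape = net.forward_tape(x, dx)
    grads, _, _ = net.backward_tape(tape, wv, wd)
    params = net.parameters()
    eps = 1e-6
    for p, g in zip(params, grads):
        flat_idx = [tuple(rng.integers(0, s) for s in p.shape) for _ in range(4)]
        for idx in flat_idx:
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert np.isclose(g[idx], fd, rtol=1e-5, atol=1e-7)


# ----------------------------------------------------------- cosine distance


@pytest.mark.parametrize(
    "u, v, expected",
    [
        ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0),
        ((1.0, 0.0), (0.0, 1.0), 1.0),
        ((1.0, 0.0), (-1.0, 0.0), 2.0),
    ],
)
def test_cosine_distance_reference_values(u, v, expected):
    assert cosine_distance(np.array(u), np.array(v)) == pytest.approx(expected, abs=1e-15)


def test_cosine_distance_identical_is_exactly_zero(rng):
    u = rng.normal(size=7)
    assert cosine_distance(u, u.copy()) == 0.0


def test_cosine_distance_zero_vector_raises():
    with pytest.raises(ZeroVector):
        cosine_distance(np.zeros(3), np.ones(3))


# -------------------------------------------------------------- architecture


def test_mixture_embedding_symmetric_and_zero_map(make_model, rng):
    m = make_model(seed=5)
    c1 = rng.normal(size=(1, m.hidden + 2))
    c2 = rng.normal(size=(1, m.hidden + 2))
    np.testing.assert_array_equal(m.mixture_embedding(c1, c2), m.mixture_embedding(c2, c1))
    # the sum equals the two forward passes added elementwise
    np.testing.assert_allclose(
        m.mixture_embedding(c1, c2), m.alpha.forward(c1) + m.alpha.forward(c2), rtol=1e-14
    )


def test_hard_constraint_product_arithmetic():
    """g^E = x1(1-x1) * d_cos * R * T * g_NN with all factors forced to
    known values: 0.25 * 1 * R * 300 * 1 = 623.58 J/mol."""
    assert 0.25 * 1.0 * GAS_CONSTANT * 300.0 * 1.0 == pytest.approx(623.58, abs=0.01)


def test_g_excess_hand_assembled_from_factors(make_model, comp_pair):
    """g^E equals the product of its reported factors for a real model."""
    m = make_model(seed=9)
    c1, c2 = comp_pair
    q = MixtureQuery(c1, c2, 300.0, 0.5)
    h = m.theta_embed(np.vstack([c1.embedding, c2.embedding]))
    d = cosine_distance(h[0], h[1])
    g_nn = m.g_excess_nn(q)
    assert m.g_excess(q) == pytest.approx(0.25 * d * GAS_CONSTANT * 300.0 * g_nn, rel=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_permutation_invariance_of_g_excess(seed, make_model, backend, rng):
    m = make_model(seed=seed)
    c1 = embed_component(f"P{seed}a", backend)
    c2 = embed_component(f"P{seed}b", backend)
    x1 = float(rng.uniform(0.05, 0.95))
    T = float(rng.uniform(250, 400))
    g_fwd = m.g_excess(MixtureQuery(c1, c2, T, x1))
    g_swp = m.g_excess(MixtureQuery(c2, c1, T, 1.0 - x1))
    assert g_fwd == g_swp  # exact: two-term sum commutes in floating point


@pytest.mark.parametrize("seed", range(5))
def test_hard_zeros_for_any_weights(seed, make_model, comp_pair):
    """Pure-component and identical-component zeros hold before any
    training, for arbitrary random weights."""
    m = make_model(seed=seed)
    c1, c2 = comp_pair
    assert m.g_excess(MixtureQuery(c1, c2, 310.0, 0.0)) == 0.0
    assert m.g_excess(MixtureQuery(c1, c2, 310.0, 1.0)) == 0.0
    for x1 in (0.0, 0.21, 0.5, 0.93, 1.0):
        assert m.g_excess(MixtureQuery(c1, c1, 310.0, x1)) == 0.0


def test_smoothness_exact_vs_finite_difference(make_model, comp_pair):
    m = make_model(seed=2)
    ge = m.ge_function(*comp_pair)
    h = 1e-6
    for x1 in (0.1, 0.35, 0.5, 0.77, 0.9):
        _, d1, _ = ge.derivatives(x1, 320.0)
        fd = (ge(x1 + h, 320.0) - ge(x1 - h, 320.0)) / (2 * h)
        assert np.isclose(d1, fd, rtol=1e-5)


def test_checkpoint_roundtrip_bitwise(make_model, comp_pair, tmp_path):
    m = make_model(seed=4)
    path = tmp_path / "model.json"
    m.save(path)
    m2 = GibbsExcessNet.load(path)
    c1, c2 = comp_pair
    for x1 in (0.2, 0.6):
        q = MixtureQuery(c1, c2, 333.0, x1)
        assert m.g_excess(q) == m2.g_excess(q)  # bit-for-bit reproduction


def test_full_model_weight_gradients_match_finite_differences(rng):
    """End-to-end gradient check through the hard-constraint wrapper,
    cosine distance and all three networks, including an
    identical-component row."""
    be = HashEmbeddingBackend(dim=6, seed=1)
    m = GibbsExcessNet.create(embedding_dim=6, hidden=5, seed=7)
    n = 4
    E1 = np.stack([be.embed(f"A{i}") for i in range(n)])
    E2 = np.stack([be.embed(f"B{i}") for i in range(n)])
    E2[3] = E1[3]
    T = rng.uniform(290, 350, n)
    x1 = rng.uniform(0.05, 0.95, n)
    w1 = rng.standard_normal(n)
    w2 = rng.standard_normal(n)

    def loss():
        ln1, ln2 = m.ln_gamma(E1, E2, T, x1)
        return float(w1 @ ln1 + w2 @ ln2)

    fw = m.forward_training(E1, E2, T, x1)
    grads = m.backward_training(fw, w1, w2)
    eps = 1e-6
    for p, g in zip(m.parameters(), grads):
        for idx in [tuple(rng.integers(0, s) for s in p.shape) for _ in range(4)]:
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert np.isclose(g[idx], fd, rtol=2e-4, atol=1e-9)
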