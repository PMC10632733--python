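import numpy as np
import pytest

from mranet.data import ResponseDataset
from mranet.model import MRAModel, SimulationError, relaxation_response
from mranet.structure import NetworkStructure, PerturbationMap

from conftest import two_node_model


def test_control_condition_maps_to_zero(chain):
    model, _ = two_node_model()
    np.testing.assert_array_equal(model.simulate_response(np.array([0.7, -1.0]), ()), 0.0)


def test_two_node_chain_hand_computation():
    """A->B with r=0.5 and inhibitor strength -2 on A: B drops by 1 log2 unit.

    The inhibitor acts on A's outgoing signal only, so A's own readout
    stays at 0 while B sees r * u = -1.
    """
    model, params = two_node_model(0.5, -2.0)
    np.testing.assert_allclose(model.simulate_response(params, ("iA",)), [0.0, -1.0])


def test_negative_feedback_raises_inhibited_node():
    """MEK->ERK->RAF->MEK loop with net-negative feedback: pMEK rises under MEKi."""
    s = NetworkStructure(("RAF", "MEK", "ERK"),
                         (("MEK", "ERK"), ("ERK", "RAF"), ("RAF", "MEK")),
                         {n: "enzyme" for n in ("RAF", "MEK", "ERK")})
    p = PerturbationMap({"MEKi": ("MEK", "inhibition")})
    ds = ResponseDataset([(), ("MEKi",)], ["RAF", "MEK", "ERK"], np.ones((2, 3, 1)))
    model = MRAModel(s, p, ds)
    params = np.array([1.0, -1.38, 1.0, -1.0])
    x = model.simulate_response(params, ("MEKi",))
    # independent dense solve of (I - r) x = r u_inh
    r = np.zeros((3, 3))
    r[2, 1], r[0, 2], r[1, 0] = 1.0, -1.38, 1.0
    u = np.array([0.0, -1.0, 0.0])
    expected = np.linalg.solve(np.eye(3) - r, r @ u)
    np.testing.assert_allclose(x, expected, atol=1e-12)
    assert x[1] > 0  # pMEK increases


def test_linearity_in_perturbation_strength():
    model, params = two_node_model(0.8, -1.0)
    x1 = model.simulate_response(params, ("iA",))
    params3 = params.copy()
    params3[1] *= 3
    np.testing.assert_allclose(model.simulate_response(params3, ("iA",)), 3 * x1)


def test_additivity_on_disconnected_subnetworks():
    """Two agents on unconnected chains: combination row = sum of singles."""
    s = NetworkStructure(("A", "B", "C", "D"), (("A", "B"), ("C", "D")),
                         {n: "enzyme" for n in "ABCD"})
    p = PerturbationMap({"iA": ("A", "inhibition"), "sC": ("C", "stimulation")})
    conds = [(), ("iA",), ("sC",), ("iA", "sC")]
    ds = ResponseDataset(conds, ["B", "D"], np.ones((4, 2, 1)))
    model = MRAModel(s, p, ds)
    params = np.array([0.6, -0.9, -1.1, 0.8])
    m = model.simulate(params, conds)
    np.testing.assert_allclose(m[3], m[1] + m[2], atol=1e-12)


def test_zero_parameter_model_gives_zero_matrix():
    model, _ = two_node_model()
    m = model.simulate(np.zeros(2), [(), ("iA",)])
    np.testing.assert_array_equal(m, 0.0)


def test_singular_system_raises_and_penalizes():
    model, _ = two_node_model()
    s = NetworkStructure(("A", "B"), (("A", "B"), ("B", "A")),
                         {"A": "enzyme", "B": "enzyme"})
    p = PerturbationMap({"iA": ("A", "inhibition")})
    ds = ResponseDataset([(), ("iA",)], ["A", "B"], np.ones((2, 2, 1)))
    cyclic = MRAModel(s, p, ds)
    singular = np.array([1.0, 1.0, -1.0])  # loop product 1 => I - r singular
    with pytest.raises(SimulationError, match="singular"):
        cyclic.simulate(singular, [("iA",)])
    res = cyclic.residuals(singular)
    assert res.shape == (cyclic.n_data,) and (res > 100).all()


def _random_stable_model(rng, n_nodes=5, radius=0.8):
    nodes = tuple(f"n{i}" for i in range(n_nodes))
    links = tuple((a, b) for a in nodes for b in nodes if a != b)
    s = NetworkStructure(nodes, links, {n: "enzyme" for n in nodes})
    p = PerturbationMap({"inh": (nodes[0], "inhibition"),
                         "stim": (nodes[1], "stimulation")})
    conds = [(), ("inh",), ("stim",), ("inh", "stim")]
    ds = ResponseDataset(conds, list(nodes), np.ones((4, n_nodes, 1)))
    model = MRAModel(s, p, ds)
    r_vals = rng.normal(0, 0.5, size=len(links))
    r = np.zeros((n_nodes, n_nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    for v, (a, b) in zip(r_vals, links):
        r[idx[b], idx[a]] = v
    rho = np.abs(np.linalg.eigvals(r)).max()
    if rho > radius:
        r_vals *= radius / rho
    params = np.concatenate([r_vals, rng.normal(0, 1, 2)])
    return model, params, conds


@pytest.mark.parametrize("seed", [0, 1])
def test_relaxation_oracle_agrees_with_linear_solve(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        model, params, conds = _random_stable_model(rng)
        for cond in conds:
            direct = model.simulate_response(params, cond, full=True)
            fixed_point = relaxation_response(model, params, cond)
            np.testing.assert_allclose(direct, fixed_point, atol=1e-8)


def test_relaxation_diverges_above_unit_spectral_radius():
    s = NetworkStructure(("A", "B"), (("A", "B"), ("B", "A")),
                         {"A": "enzyme", "B": "enzyme"})
    p = PerturbationMap({"sA": ("A", "stimulation")})
    ds = ResponseDataset([(), ("sA",)], ["A", "B"], np.ones((2, 2, 1)))
    model = MRAModel(s, p, ds)
    params = np.array([1.5, 1.5, 1.0])  # spectral radius 1.5
    with pytest.raises(SimulationError, match="diverged"):
        relaxation_response(model, params, ("sA",))


def test_relaxation_zero_perturbation_fixed_point():
    model, params = two_node_model()
    np.testing.assert_allclose(relaxation_response(model, params, ()), 0.0, atol=1e-12)


def test_analytic_jacobian_matches_finite_differences(chain):
    ds = chain.datasets(seed=3, attach_true_sigma=True)["XX"]
    model = MRAModel(chain.structure, chain.perturbation_map, ds)
    theta = chain.truth_vector("XX") + 0.1
    jac = model.jacobian(theta)
    eps = 1e-6
    for j in range(model.n_params):
        dp = np.zeros_like(theta)
        dp[j] = eps
        num = (model.residuals(theta + dp) - model.residuals(theta - dp)) / (2 * eps)
        np.testing.assert_allclose(jac[:, j], num, rtol=1e-5, atol=1e-7)
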