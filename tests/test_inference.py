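import numpy as np
import pytest
from scipy.stats import chi2

from mranet.data import ResponseDataset
from mranet.model import MRAModel
from mranet.pathways import (
    InferenceError,
    PathDefinition,
    compare_models,
    enumerate_paths,
    pathway_coefficient,
    pathway_table,
    propagate_ci,
)
from mranet.profile import profile_parameter, profile_parameters
from mranet.structure import NetworkStructure, PerturbationMap


def test_profile_threshold_uses_configured_df(chain_fit):
    prof8 = profile_parameter(chain_fit, "r:A->B", df=8)
    assert prof8.threshold == pytest.approx(15.507, abs=1e-3)
    prof1 = profile_parameter(chain_fit, "r:A->B", df=1)
    assert prof1.threshold == pytest.approx(3.841, abs=1e-3)


def test_profile_default_df_counts_fixed_inhibitors(chain_fit):
    # two inhibitors held fixed -> df = 1 + 2
    prof = profile_parameter(chain_fit, "r:A->B")
    assert prof.df == 3


def test_profile_minimum_matches_global_optimum(chain_fit):
    prof = profile_parameter(chain_fit, "r:B->C")
    assert np.nanmin(prof.ssr_profile) >= chain_fit.ssr - 1e-6
    i = np.argmin(np.abs(prof.grid - prof.mle))
    assert prof.ssr_profile[i] == pytest.approx(chain_fit.ssr, abs=1e-6)
    assert prof.ci_low <= prof.mle <= prof.ci_high


def test_ci_width_non_decreasing_in_df(chain_fit):
    widths = []
    for df in (1, 3, 8):
        prof = profile_parameter(chain_fit, "r:C->A", df=df)
        widths.append(prof.ci_high - prof.ci_low)
    assert widths[0] <= widths[1] <= widths[2]


@pytest.fixture(scope="module")
def nonidentifiable_pair():
    """Two-link chain with only the end node measured: r1*r2 identifiable,
    neither factor alone."""
    s = NetworkStructure(("A", "B", "C"), (("A", "B"), ("B", "C")),
                         {n: "enzyme" for n in "ABC"})
    p = PerturbationMap({"sA": ("A", "stimulation")})
    rng = np.random.default_rng(42)
    conds = [(), ("sA",)]
    values = np.ones((2, 1, 3))
    values[1, 0] = 2.0 ** (0.72 + rng.normal(0, 0.05, 3))  # r1*r2*sA = 0.72
    ds = ResponseDataset(conds, ["C"], values, sigma=np.full((2, 1), 0.05 / np.sqrt(3)))
    model = MRAModel(s, p, ds)
    res = model.fit(n_starts=30, seed=1)
    return res


def test_structurally_nonidentifiable_parameter_is_unbounded(nonidentifiable_pair):
    res = nonidentifiable_pair
    prof = profile_parameter(res, "r:A->B", fixed_params=[])
    assert not np.isfinite(prof.ci_low) or not np.isfinite(prof.ci_high)


def test_constant_product_collapses_propagated_ci(nonidentifiable_pair):
    """Anti-correlated factors: the propagated CI of their product with the
    stimulation strength held fixed collapses despite wide member CIs."""
    res = nonidentifiable_pair
    profs = {n: profile_parameter(res, n, fixed_params=["k:sA"])
             for n in ("r:A->B", "r:B->C")}
    path = PathDefinition("prod", "crosstalk", (("A", "B"), ("B", "C")))
    lo, hi = propagate_ci(profs, path, res)
    assert np.isfinite(lo) and np.isfinite(hi)
    assert hi - lo < 1e-6


def test_enumerate_paths_fixture_reports_mapk_loop():
    from mranet.scenarios import (FIXTURE_READOUTS, LITERATURE_LINKS,
                                  completed_network, fixture_perturbation_map)

    defs = enumerate_paths(completed_network(), fixture_perturbation_map(),
                           FIXTURE_READOUTS, base_links=LITERATURE_LINKS)
    names = {d.name for d in defs}
    assert "loop:ERK->RAF->MEK->ERK" in names
    kinds = {d.kind for d in defs}
    assert kinds == {"canonical", "feedback_loop", "crosstalk"}
    canon = [d for d in defs if d.kind == "canonical"]
    assert {d.agent for d in canon} == {"FGF4", "ActA", "NoLIF"}


def test_enumerate_paths_acyclic_structure_has_no_loops():
    s = NetworkStructure(("A", "B"), (("A", "B"),), {"A": "enzyme", "B": "enzyme"})
    p = PerturbationMap({"sA": ("A", "stimulation")})
    defs = enumerate_paths(s, p, ["B"])
    assert [d.kind for d in defs] == ["canonical"]


def test_path_counts_match_dfs_oracle():
    """Crosstalk enumeration equals brute-force DFS on a random DAG + 1 cycle."""
    import networkx as nx

    rng = np.random.default_rng(11)
    nodes = tuple(f"n{i}" for i in range(7))
    links = [(nodes[i], nodes[j]) for i in range(7) for j in range(i + 1, 7)
             if rng.random() < 0.4]
    links.append((nodes[5], nodes[1]))  # close one cycle
    links = list(dict.fromkeys(links))
    s = NetworkStructure(nodes, tuple(links), {n: "enzyme" for n in nodes})
    p = PerturbationMap({"s0": (nodes[0], "stimulation")})
    measured = [nodes[4], nodes[6]]
    base = tuple(links[:-1])
    defs = enumerate_paths(s, p, measured, base_links=base)
    loops = [d for d in defs if d.kind == "feedback_loop"]
    g = nx.DiGraph(links)
    assert len(loops) == len(list(nx.simple_cycles(g)))
    # every enumerated path is a genuine simple path of the graph
    for d in defs:
        if d.kind != "feedback_loop":
            for a, b in d.links:
                assert g.has_edge(a, b)


def test_loop_coefficient_invariant_to_rotation(chain_fit):
    links = (("A", "B"), ("B", "C"), ("C", "A"))
    products = []
    for k in range(3):
        rotated = links[k:] + links[:k]
        path = PathDefinition(f"loop{k}", "feedback_loop", rotated)
        products.append(pathway_coefficient(chain_fit, path).value)
    np.testing.assert_allclose(products, products[0])


def test_pathway_coefficient_is_product_of_members(chain_fit):
    path = PathDefinition("p", "canonical", (("A", "B"), ("B", "C")), agent="sA")
    coef = pathway_coefficient(chain_fit, path)
    expected = (chain_fit.get("k:sA") * chain_fit.get("r:A->B")
                * chain_fit.get("r:B->C"))
    assert coef.value == pytest.approx(expected, rel=1e-12)
    assert coef.negative == (expected < 0)


def test_single_link_path_ci_equals_profile_ci(chain_fit):
    prof = profile_parameter(chain_fit, "r:A->B")
    path = PathDefinition("one", "crosstalk", (("A", "B"),))
    # agreement up to the bound-refinement (bisection) resolution
    lo, hi = propagate_ci({"r:A->B": prof}, path, chain_fit)
    assert lo == pytest.approx(prof.ci_low, abs=1e-3)
    assert hi == pytest.approx(prof.ci_high, abs=1e-3)


def test_propagate_requires_all_member_profiles(chain_fit):
    path = PathDefinition("p", "crosstalk", (("A", "B"), ("B", "C")))
    with pytest.raises(InferenceError, match="no profile"):
        propagate_ci({"r:A->B": profile_parameter(chain_fit, "r:A->B")},
                     path, chain_fit)


def test_compare_identical_fits_finds_no_differences(chain_fit):
    defs = [PathDefinition("loop", "feedback_loop",
                           (("A", "B"), ("B", "C"), ("C", "A")))]
    profs = profile_parameters(chain_fit)
    table = compare_models(chain_fit, chain_fit, defs, profs, profs)
    assert not table["significant"].any()


def test_touching_intervals_count_as_overlap():
    """Sharing exactly one endpoint is overlap (not significant)."""
    from mranet.pathways import intervals_disjoint

    assert not intervals_disjoint((0.0, 1.0), (1.0, 2.0))
    assert not intervals_disjoint((0.0, 1.5), (1.0, 2.0))
    assert intervals_disjoint((0.0, 1.0), (1.1, 2.0))
    assert intervals_disjoint((1.1, 2.0), (0.0, 1.0))
    assert not intervals_disjoint((-np.inf, 1.0), (0.5, np.inf))


def test_pathway_table_shape(chain_fit):
    defs = [PathDefinition("loop", "feedback_loop",
                           (("A", "B"), ("B", "C"), ("C", "A")))]
    table = pathway_table(chain_fit, defs, profile_parameters(chain_fit))
    assert list(table.columns) == ["name", "kind", "flagged", "value", "ci_low", "ci_high"]
    assert np.isfinite(table.loc[0, "ci_low"])
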