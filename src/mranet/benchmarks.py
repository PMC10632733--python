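"""Study-scale benchmark evaluations of the full pipeline.

Each function runs one self-contained evaluation on synthetic data drawn
from the ground-truth scenarios in :mod:`mranet.scenarios` — design
enumeration, simulation-oracle agreement, parameter recovery and
confidence-interval coverage, missing-link recovery and false-positive
control of the network extension, residual calibration, and the two-line
differential comparison.  All randomness is derived from the single seed
each function receives.

Problem sizes are chosen to keep a full benchmark run on one CPU in the
ten-minute range: recovery and coverage use the small identifiable chain
network, extension benchmarks run single rounds of the full 16-node study
design, and the differential comparison profiles only the members of the
two pathways of interest.
"""

from __future__ import annotations

import numpy as np

from .extension import extend_joint
from .model import MRAModel, relaxation_response
from .pathways import compare_models, enumerate_paths
from .profile import profile_parameter
from .scenarios import (
    EXCLUDED_PAIRS,
    FIXTURE_AGENTS,
    FIXTURE_READOUTS,
    LITERATURE_LINKS,
    build_design,
    chain_scenario,
    differential_scenario,
    generate_dataset,
    null_scenario,
    withheld_link_scenario,
)

LOOP_NAME = "loop:ERK->RAF->MEK->ERK"
ACTA_NAME = "canonical:ActA:ACTR->SMAD2"


def design_counts() -> tuple[int, int]:
    """(treatments, condition-readout data points per cell line)."""
    design = build_design(list(FIXTURE_AGENTS), EXCLUDED_PAIRS)
    n_treatments = len([c for c in design if c])
    return n_treatments, n_treatments * len(FIXTURE_READOUTS)


def oracle_agreement(n_models: int = 100, seed: int = 0) -> float:
    """Max |matrix solve - relaxation fixed point| over random stable models."""
    from .data import ResponseDataset
    from .structure import NetworkStructure, PerturbationMap

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_models):
        n = int(rng.integers(3, 7))
        nodes = tuple(f"n{i}" for i in range(n))
        links = tuple((a, b) for a in nodes for b in nodes if a != b)
        s = NetworkStructure(nodes, links, {x: "enzyme" for x in nodes})
        p = PerturbationMap({"inh": (nodes[0], "inhibition"),
                             "stim": (nodes[-1], "stimulation")})
        conds = [(), ("inh",), ("stim",), ("inh", "stim")]
        ds = ResponseDataset(conds, list(nodes), np.ones((4, n, 1)))
        model = MRAModel(s, p, ds)
        r_vals = rng.normal(0, 0.5, size=len(links))
        r = model.r_matrix(np.concatenate([r_vals, np.zeros(2)]))
        rho = np.abs(np.linalg.eigvals(r)).max()
        if rho > 0.8:
            r_vals *= 0.8 / rho
        params = np.concatenate([r_vals, rng.normal(0, 1, 2)])
        cond = conds[int(rng.integers(1, 4))]
        direct = model.simulate_response(params, cond, full=True)
        fixed_point = relaxation_response(model, params, cond)
        worst = max(worst, float(np.abs(direct - fixed_point).max()))
    return worst


def noiseless_recovery(n_starts: int = 500, seed: int = 0) -> float:
    """Max |estimate - truth| after a cold multi-start fit on noiseless data."""
    sc = chain_scenario()
    ds = generate_dataset(sc.structure, sc.perturbation_map, sc.true_params["XX"],
                          design=sc.design, readouts=sc.readouts,
                          noise_sd=0.0, seed=seed)
    model = MRAModel(sc.structure, sc.perturbation_map, ds)
    res = model.fit(n_starts=n_starts, seed=seed)
    return float(np.abs(res.params - sc.truth_vector("XX")).max())


def ci_coverage(n_runs: int = 100, seed: int = 0, noise_sd: float = 0.1,
                n_starts: int = 10) -> float:
    """Fraction of noisy chain runs with every true link coefficient inside
    its propagated 95% profile-likelihood CI."""
    sc = chain_scenario(noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    truth = sc.true_params["XX"]
    hits = 0
    for _ in range(n_runs):
        ds = generate_dataset(sc.structure, sc.perturbation_map, truth,
                              design=sc.design, readouts=sc.readouts,
                              noise_sd=noise_sd, seed=rng,
                              attach_true_sigma=True)
        model = MRAModel(sc.structure, sc.perturbation_map, ds)
        res = model.fit(n_starts=n_starts, seed=int(rng.integers(2**31)))
        ok = True
        for s, t in sc.structure.links:
            name = f"r:{s}->{t}"
            prof = profile_parameter(res, name)
            if not (prof.ci_low <= truth[name] <= prof.ci_high):
                ok = False
                break
        hits += ok
    return hits / n_runs


def _closes_mapk_loop(structure, link) -> bool:
    import networkx as nx

    g = structure.to_graph()
    g.add_edge(*link)
    return any({"MEK", "ERK"} & set(c) for c in nx.simple_cycles(g))


def link_recovery(n_runs: int = 20, seed: int = 0, alpha: float = 0.005,
                  initial_n_starts: int = 12) -> float:
    """Fraction of runs in which extension first accepts a link closing the
    withheld MAPK feedback loop (or an equivalent loop closure)."""
    sc = withheld_link_scenario()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        datasets = sc.datasets(seed=int(rng.integers(2**31)), attach_true_sigma=True)
        trace = extend_joint(sc.start_structure, sc.perturbation_map, datasets,
                             alpha=alpha, n_starts=1,
                             initial_n_starts=initial_n_starts,
                             seed=int(rng.integers(2**31)), max_links=1)
        if trace.accepted and _closes_mapk_loop(sc.start_structure,
                                                trace.accepted[0].link):
            hits += 1
    return hits / n_runs


def null_rejection(n_runs: int = 20, seed: int = 0, alpha: float = 0.005,
                   initial_n_starts: int = 12) -> float:
    """Fraction of null-scenario runs in which extension accepts no link."""
    sc = null_scenario()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        datasets = sc.datasets(seed=int(rng.integers(2**31)), attach_true_sigma=True)
        trace = extend_joint(sc.start_structure, sc.perturbation_map, datasets,
                             alpha=alpha, n_starts=1,
                             initial_n_starts=initial_n_starts,
                             seed=int(rng.integers(2**31)), max_links=1)
        hits += not trace.accepted
    return hits / n_runs


def residual_calibration(n_sims: int = 200, seed: int = 0,
                         noise_sd: float = 0.1) -> float:
    """mean(ssr at the true parameters) / n_data over noisy simulations.

    With correctly specified Gaussian noise the residual at the truth is
    chi-square with n_data degrees of freedom, so the ratio should be 1.
    """
    sc = differential_scenario(noise_sd=noise_sd)
    truth = sc.true_params["XX"]
    theta = sc.truth_vector("XX")
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_sims):
        ds = generate_dataset(sc.structure, sc.perturbation_map, truth,
                              design=sc.design, readouts=sc.readouts,
                              noise_sd=noise_sd, seed=rng,
                              attach_true_sigma=True)
        model = MRAModel(sc.structure, sc.perturbation_map, ds)
        ratios.append(model.ssr(theta) / model.n_data)
    return float(np.mean(ratios))


def differential_comparison(seed: int = 0, noise_sd: float = 0.1,
                            n_starts: int = 60) -> dict:
    """Fit both cell lines of the differential scenario and compare the
    MAPK-feedback loop and Activin canonical pathway coefficients."""
    sc = differential_scenario(noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    datasets = sc.datasets(seed=int(rng.integers(2**31)), attach_true_sigma=True)
    fits, profs = {}, {}
    defs = enumerate_paths(sc.structure, sc.perturbation_map, FIXTURE_READOUTS,
                           base_links=LITERATURE_LINKS)
    key = [d for d in defs if d.name in (LOOP_NAME, ACTA_NAME)]
    members = sorted({m for d in key for m in d.members})
    for line in ("XX", "XO"):
        model = MRAModel(sc.structure, sc.perturbation_map, datasets[line])
        fits[line] = model.fit(n_starts=n_starts, seed=int(rng.integers(2**31)))
        profs[line] = {m: profile_parameter(fits[line], m) for m in members}
    table = compare_models(fits["XX"], fits["XO"], key, profs["XX"], profs["XO"])
    table = table.set_index("name")
    return {
        "mapk_loop_xx": float(table.loc[LOOP_NAME, "value_XX"]),
        "mapk_loop_xo": float(table.loc[LOOP_NAME, "value_XO"]),
        "acta_pathway_xx": float(table.loc[ACTA_NAME, "value_XX"]),
        "acta_pathway_xo": float(table.loc[ACTA_NAME, "value_XO"]),
        "mapk_loop_significant": bool(table.loc[LOOP_NAME, "significant"]),
        "acta_significant": bool(table.loc[ACTA_NAME, "significant"]),
        "ssr_xx": fits["XX"].ssr,
        "ssr_xo": fits["XO"].ssr,
        "n_data": fits["XX"].n_data,
    }
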