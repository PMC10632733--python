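"""Synthetic ground-truth networks and perturbation-response datasets.

Emulates the study design used throughout the package's tests: a 16-node
pluripotency signaling network probed with 10 perturbation agents (7
kinase/receptor inhibitors, 2 ligand stimulations, 1 ligand withdrawal)
in all single and pairwise treatments except two same-pathway pairs — 53
treatments — read out on 7 phosphoproteins in 3 biological replicates,
with multiplicative (log-normal) noise on the fold changes.  Two "cell
lines" share one network structure and differ only in parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import ResponseDataset
from .model import MRAModel
from .structure import NetworkStructure, PerturbationMap, condition

# --------------------------------------------------------------------- #
# study-like fixture: nodes, literature links, added links, agents

FIXTURE_NODE_CLASSES: dict[str, str] = {
    "LIFR": "receptor", "JAK": "enzyme", "STAT3": "transcription_factor",
    "IGFR": "receptor", "PI3K": "enzyme", "AKT": "enzyme",
    "GSK3": "enzyme", "mTOR": "enzyme",
    "FGFR": "receptor", "RAS": "enzyme", "RAF": "enzyme",
    "MEK": "enzyme", "ERK": "enzyme",
    "ACTR": "receptor", "SMAD2": "transcription_factor",
    "BMPR": "receptor",
}

FIXTURE_NODES = tuple(FIXTURE_NODE_CLASSES)

#: Literature-derived starting links: the five canonical pathway chains
#: (LIF->JAK/STAT3, IGF->PI3K/AKT->GSK3/mTOR, FGF->RAS/RAF/MEK/ERK,
#: ActA->SMAD2, BMP receptor) with no crosstalk or feedback.
LITERATURE_LINKS: tuple[tuple[str, str], ...] = (
    ("LIFR", "JAK"), ("JAK", "STAT3"),
    ("IGFR", "PI3K"), ("PI3K", "AKT"), ("AKT", "GSK3"), ("AKT", "mTOR"),
    ("FGFR", "RAS"), ("RAS", "RAF"), ("RAF", "MEK"), ("MEK", "ERK"),
    ("ACTR", "SMAD2"),
    ("BMPR", "SMAD2"),
)

#: Crosstalk/feedback links the completed fixture carries on top of the
#: literature network (receptor-level crosstalks and the MAPK feedback).
ADDED_LINKS: tuple[tuple[str, str], ...] = (
    ("JAK", "FGFR"),
    ("GSK3", "IGFR"),
    ("ERK", "RAF"),
    ("ACTR", "RAS"),
    ("LIFR", "AKT"),
)

FIXTURE_READOUTS = ("AKT", "GSK3", "mTOR", "MEK", "ERK", "STAT3", "SMAD2")

FIXTURE_AGENTS: dict[str, tuple[str, str]] = {
    "IGFRi": ("IGFR", "inhibition"),
    "PI3Ki": ("PI3K", "inhibition"),
    "FGFRi": ("FGFR", "inhibition"),
    "MEKi": ("MEK", "inhibition"),
    "JAKi": ("JAK", "inhibition"),
    "GSK3i": ("GSK3", "inhibition"),
    "BMPRi": ("BMPR", "inhibition"),
    "FGF4": ("FGFR", "stimulation"),
    "ActA": ("ACTR", "stimulation"),
    "NoLIF": ("LIFR", "stimulation"),   # withdrawal: unconstrained, negative strength
}

#: Same-pathway combinations excluded from the treatment design.
EXCLUDED_PAIRS: tuple[frozenset[str], ...] = (
    frozenset({"IGFRi", "PI3Ki"}),
    frozenset({"MEKi", "FGFRi"}),
)

_SHARED_TRUTH: dict[str, float] = {
    "r:LIFR->JAK": 0.9, "r:JAK->STAT3": 1.0,
    "r:IGFR->PI3K": 1.0, "r:PI3K->AKT": 0.9,
    "r:AKT->GSK3": 0.8, "r:AKT->mTOR": 0.7,
    "r:FGFR->RAS": 1.0, "r:RAS->RAF": 0.9,
    "r:RAF->MEK": 1.0, "r:MEK->ERK": 1.0,
    "r:ACTR->SMAD2": 1.0, "r:BMPR->SMAD2": -0.3,
    "r:JAK->FGFR": 0.5, "r:GSK3->IGFR": 0.5,
    "r:ACTR->RAS": -0.3, "r:LIFR->AKT": 0.4,
    "k:IGFRi": -1.5, "k:PI3Ki": -1.2, "k:FGFRi": -1.5, "k:MEKi": -1.2,
    "k:JAKi": -1.5, "k:GSK3i": -1.0, "k:BMPRi": -1.0,
    "k:FGF4": 1.0, "k:NoLIF": -1.0,
}

#: Line-specific truths: the MAPK feedback (MEK->ERK->RAF->MEK loop product)
#: is -0.09 in the XX-like line vs -1.38 in the XO-like line, and the ActA
#: canonical coefficient (stimulation strength x ACTR->SMAD2) is 0.43 vs 0.95.
TRUTH_XX = {**_SHARED_TRUTH, "r:ERK->RAF": -0.09, "k:ActA": 0.43}
TRUTH_XO = {**_SHARED_TRUTH, "r:ERK->RAF": -1.38, "k:ActA": 0.95}

DEFAULT_NOISE_SD = 0.15   # log2 units, per replicate
DEFAULT_N_REPLICATES = 3


def literature_network() -> NetworkStructure:
    """The crosstalk/feedback-free starting network."""
    return NetworkStructure(FIXTURE_NODES, LITERATURE_LINKS, dict(FIXTURE_NODE_CLASSES))


def completed_network() -> NetworkStructure:
    """Literature network plus the named crosstalk and feedback links."""
    return NetworkStructure(FIXTURE_NODES, LITERATURE_LINKS + ADDED_LINKS,
                            dict(FIXTURE_NODE_CLASSES))


def fixture_perturbation_map() -> PerturbationMap:
    return PerturbationMap(dict(FIXTURE_AGENTS))


def default_network() -> tuple[NetworkStructure, PerturbationMap, dict[str, float], dict[str, float]]:
    """Completed two-cell-line fixture: structure, agent map, XX/XO truths."""
    return completed_network(), fixture_perturbation_map(), dict(TRUTH_XX), dict(TRUTH_XO)


# --------------------------------------------------------------------- #
# perturbation design

def build_design(agents: Sequence[str],
                 excluded_pairs: Iterable[frozenset[str] | tuple[str, str]] = (),
                 ) -> list[tuple[str, ...]]:
    """Vehicle control + all singles + all unordered pairs minus exclusions.

    Deterministic order: control first, singles in agent order, then pairs
    in combination order.
    """
    if len(set(agents)) != len(agents):
        raise ValueError("agents must be distinct")
    excluded = {frozenset(p) for p in excluded_pairs}
    design: list[tuple[str, ...]] = [condition()]
    design.extend(condition([a]) for a in agents)
    for a, b in combinations(agents, 2):
        if frozenset({a, b}) not in excluded:
            design.append(condition([a, b]))
    return design


def study_design() -> list[tuple[str, ...]]:
    """The 53-treatment design (plus control) of the fixture study."""
    return build_design(list(FIXTURE_AGENTS), EXCLUDED_PAIRS)


# --------------------------------------------------------------------- #
# dataset generation

def params_vector(structure: NetworkStructure, pmap: PerturbationMap,
                  values: Mapping[str, float]) -> np.ndarray:
    """Order a name->value map into the model's parameter vector."""
    names = ([f"r:{s}->{t}" for s, t in structure.links]
             + [f"k:{a}" for a in pmap.agents])
    missing = [n for n in names if n not in values]
    if missing:
        raise KeyError(f"missing parameter values: {missing}")
    return np.array([values[n] for n in names], dtype=float)


def _simulation_model(structure: NetworkStructure, pmap: PerturbationMap,
                      design: Sequence[tuple[str, ...]],
                      readouts: Sequence[str]) -> MRAModel:
    placeholder = ResponseDataset(list(design), list(readouts),
                                  np.ones((len(design), len(readouts), 1)))
    return MRAModel(structure, pmap, placeholder)


def simulate_design(structure: NetworkStructure, pmap: PerturbationMap,
                    values: Mapping[str, float] | np.ndarray,
                    design: Sequence[tuple[str, ...]],
                    readouts: Sequence[str] = FIXTURE_READOUTS) -> np.ndarray:
    """Noise-free log2 responses, shape (conditions, readouts)."""
    model = _simulation_model(structure, pmap, design, readouts)
    theta = (values if isinstance(values, np.ndarray)
             else params_vector(structure, pmap, values))
    return model.simulate(theta, list(design))


def generate_dataset(structure: NetworkStructure, pmap: PerturbationMap,
                     values: Mapping[str, float],
                     design: Sequence[tuple[str, ...]] | None = None,
                     readouts: Sequence[str] = FIXTURE_READOUTS,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     n_replicates: int = DEFAULT_N_REPLICATES,
                     seed: int | np.random.Generator | None = None,
                     cell_line: str = "",
                     attach_true_sigma: bool = False) -> ResponseDataset:
    """Simulate a noisy perturbation-response dataset from a ground truth.

    Each replicate observation is ``2**(log2 response + N(0, noise_sd))``;
    the vehicle-control row is exactly 1 (responses are defined relative to
    it).  With ``attach_true_sigma`` the dataset carries the exact error of
    the replicate mean, ``noise_sd / sqrt(n_replicates)``, instead of
    estimating it from the replicate spread.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if design is None:
        design = build_design(list(pmap.agents), EXCLUDED_PAIRS)
    log2_sim = simulate_design(structure, pmap, values, design, readouts)
    n_c, n_r = log2_sim.shape
    noise = rng.normal(0.0, noise_sd, size=(n_c, n_r, n_replicates)) if noise_sd > 0 \
        else np.zeros((n_c, n_r, n_replicates))
    ctrl = list(design).index(())
    noise[ctrl] = 0.0
    values_arr = 2.0 ** (log2_sim[:, :, None] + noise)
    sigma = None
    if attach_true_sigma:
        sigma = np.full((n_c, n_r), max(noise_sd, 1e-12) / np.sqrt(n_replicates))
    return ResponseDataset(list(design), list(readouts), values_arr,
                           cell_line=cell_line, sigma=sigma,
                           meta={"seed": getattr(seed, "bit_generator", seed) if not isinstance(seed, np.random.Generator) else "generator",
                                 "noise_sd": noise_sd, "n_replicates": n_replicates})


# --------------------------------------------------------------------- #
# benchmark scenarios

@dataclass
class Scenario:
    """A ground-truth scenario: structure, truths per line, and design."""

    name: str
    structure: NetworkStructure          # data-generating structure
    start_structure: NetworkStructure    # structure handed to reconstruction
    perturbation_map: PerturbationMap
    readouts: tuple[str, ...]
    design: list[tuple[str, ...]]
    true_params: dict[str, dict[str, float]]   # cell line -> name -> value
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = DEFAULT_N_REPLICATES
    meta: dict = field(default_factory=dict)

    def datasets(self, seed: int | None = None,
                 attach_true_sigma: bool = False) -> dict[str, ResponseDataset]:
        rng = np.random.default_rng(seed)
        out = {}
        for line, values in self.true_params.items():
            out[line] = generate_dataset(
                self.structure, self.perturbation_map, values,
                design=self.design, readouts=self.readouts,
                noise_sd=self.noise_sd, n_replicates=self.n_replicates,
                seed=rng, cell_line=line, attach_true_sigma=attach_true_sigma)
        return out

    def truth_vector(self, line: str) -> np.ndarray:
        return params_vector(self.structure, self.perturbation_map,
                             self.true_params[line])


def chain_scenario(noise_sd: float = 0.1) -> Scenario:
    """Small fully identifiable network (3-node chain closed by a feedback).

    Every parameter is structurally identifiable from the single/pairwise
    design: node ratios fix the link coefficients and levels fix the
    perturbation strengths.  Used for exact-recovery and CI-coverage tests.
    """
    structure = NetworkStructure(
        ("A", "B", "C"),
        (("A", "B"), ("B", "C"), ("C", "A")),
        {"A": "enzyme", "B": "enzyme", "C": "enzyme"},
    )
    pmap = PerturbationMap({
        "iA": ("A", "inhibition"),
        "iB": ("B", "inhibition"),
        "sA": ("A", "stimulation"),
    })
    truth = {"r:A->B": 0.8, "r:B->C": 1.0, "r:C->A": -0.5,
             "k:iA": -1.2, "k:iB": -1.0, "k:sA": 1.0}
    design = build_design(list(pmap.agents))
    return Scenario("chain", structure, structure, pmap, ("A", "B", "C"),
                    design, {"XX": dict(truth), "XO": dict(truth)},
                    noise_sd=noise_sd)


def withheld_link_scenario(noise_sd: float = 0.1) -> Scenario:
    """Fixture pair whose truth adds only the MAPK feedback (ERK->RAF).

    Network reconstruction starts from the feedback-free literature
    structure and should close the MEK->ERK->RAF->MEK loop first.
    """
    base = literature_network()
    truth_structure = base.with_link("ERK", "RAF")
    names = set(f"r:{s}->{t}" for s, t in truth_structure.links) | {
        f"k:{a}" for a in FIXTURE_AGENTS}
    tx = {k: v for k, v in TRUTH_XX.items() if k in names}
    to = {k: v for k, v in TRUTH_XO.items() if k in names}
    return Scenario("withheld_link", truth_structure, base,
                    fixture_perturbation_map(), FIXTURE_READOUTS,
                    study_design(), {"XX": tx, "XO": to}, noise_sd=noise_sd)


def differential_scenario(noise_sd: float = 0.1) -> Scenario:
    """Completed fixture with line-specific MAPK feedback and ActA strength."""
    structure = completed_network()
    return Scenario("differential", structure, structure,
                    fixture_perturbation_map(), FIXTURE_READOUTS,
                    study_design(), {"XX": dict(TRUTH_XX), "XO": dict(TRUTH_XO)},
                    noise_sd=noise_sd)


def null_scenario(noise_sd: float = 0.1) -> Scenario:
    """No missing links, no between-line differences (false-positive control)."""
    base = literature_network()
    names = set(f"r:{s}->{t}" for s, t in base.links) | {f"k:{a}" for a in FIXTURE_AGENTS}
    truth = {k: v for k, v in TRUTH_XX.items() if k in names}
    return Scenario("null", base, base, fixture_perturbation_map(),
                    FIXTURE_READOUTS, study_design(),
                    {"XX": dict(truth), "XO": dict(truth)}, noise_sd=noise_sd)


def make_benchmark_suite(seed: int | None = None) -> dict[str, Scenario]:
    """The standard test scenarios, keyed by name.

    The seed is recorded in each scenario's metadata; datasets are drawn
    deterministically from it via :meth:`Scenario.datasets`.
    """
    suite = {
        "chain": chain_scenario(),
        "withheld_link": withheld_link_scenario(),
        "differential": differential_scenario(),
        "null": null_scenario(),
    }
    for s in suite.values():
        s.meta["seed"] = seed
    return suite
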