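"""Greedy joint network completion across two cell lines.

Starting from the literature structure, every admissible candidate link
(source a receptor or enzyme — nodes acting through post-translational
modification — target anything but a ligand) is added individually to
each cell line's model and the data refitted.  A link's improvement is
gated by a likelihood-ratio test (chi-square on the residual decrease,
one degree of freedom per added parameter) with Benjamini-Hochberg
adjustment per cell line across the round's candidates; a link is
eligible only if significant in both lines, since one common structure is
kept throughout.  Among eligible links the one with the highest relative
residual reduction averaged over the two lines is accepted; after each
acceptance every link is tested for removability.  Rounds repeat until no
eligible link remains or a safety cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .data import DEFAULT_SIGMA_MIN, ResponseDataset
from .model import MRAModel
from .structure import NetworkStructure, PerturbationMap

Link = tuple[str, str]

CANDIDATE_SOURCE_CLASSES = frozenset({"receptor", "enzyme"})


@dataclass
class LinkTestResult:
    """Outcome of testing one candidate link in both cell lines."""

    link: Link
    ssr_before: dict[str, float]
    ssr_after: dict[str, float]
    delta_ssr: dict[str, float] = field(default_factory=dict)
    p_raw: dict[str, float] = field(default_factory=dict)
    p_adj: dict[str, float] = field(default_factory=dict)
    params_after: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.delta_ssr:
            self.delta_ssr = {k: max(self.ssr_before[k] - self.ssr_after[k], 0.0)
                              for k in self.ssr_before}

    def relative_reduction(self, line: str) -> float:
        before = self.ssr_before[line]
        return self.delta_ssr[line] / before if before > 0 else 0.0

    @property
    def mean_relative_reduction(self) -> float:
        return float(np.mean([self.relative_reduction(l) for l in self.ssr_before]))


@dataclass
class ExtensionTrace:
    """Accepted links in order, with per-line residual trajectories."""

    initial_ssr: dict[str, float]
    accepted: list[LinkTestResult] = field(default_factory=list)
    removable_per_round: list[list[Link]] = field(default_factory=list)
    stopping_reason: str = ""
    final_structure: NetworkStructure | None = None
    final_results: dict[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.accepted, start=1):
            row = {"round": i, "source": t.link[0], "target": t.link[1],
                   "mean_relative_reduction": t.mean_relative_reduction}
            for line in t.ssr_before:
                row[f"ssr_before_{line}"] = t.ssr_before[line]
                row[f"ssr_after_{line}"] = t.ssr_after[line]
                row[f"delta_ssr_{line}"] = t.delta_ssr[line]
                row[f"p_adj_{line}"] = t.p_adj.get(line, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def candidate_links(structure: NetworkStructure) -> list[Link]:
    """Admissible new links, ordered lexicographically.

    Sources are nodes acting via post-translational modification
    (receptors and enzymes); targets may be anything except a ligand.
    Self-links and existing links are excluded.
    """
    classes = structure.node_classes
    missing = [n for n in structure.nodes if n not in classes]
    if missing:
        raise ValueError(f"node classes missing for {missing}")
    existing = set(structure.links)
    out = []
    for src in structure.nodes:
        if classes[src] not in CANDIDATE_SOURCE_CLASSES:
            continue
        for tgt in structure.nodes:
            if tgt == src or classes[tgt] == "ligand" or (src, tgt) in existing:
                continue
            out.append((src, tgt))
    return sorted(out)


def lrt_pvalue(delta_ssr: float, df: int = 1) -> float:
    """Upper-tail chi-square probability of a residual decrease.

    Negative decreases (optimizer noise) are clipped to zero (p = 1).
    """
    return float(chi2.sf(max(delta_ssr, 0.0), df))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _fit_with_link(structure: NetworkStructure, pmap: PerturbationMap,
                   dataset: ResponseDataset, link: Link,
                   warm_params: np.ndarray, n_starts: int, seed: int,
                   sigma_min: float, xtol: float):
    """Refit one line with one extra link, warm-started from the parent fit."""
    new_structure = structure.with_link(*link)
    model = MRAModel(new_structure, pmap, dataset, sigma_min)
    n_old_links = len(structure.links)
    warm = np.insert(np.asarray(warm_params, float), n_old_links, 0.0)
    res = model.fit(n_starts=n_starts, seed=seed, x0=warm, xtol=xtol)
    return res


def extend_joint(structure: NetworkStructure, pmap: PerturbationMap,
                 datasets: Mapping[str, ResponseDataset],
                 alpha: float = 0.005,
                 n_starts: int = 4,
                 initial_n_starts: int = 50,
                 seed: int | None = None,
                 max_links: int = 15,
                 require: str = "both",
                 prune: bool = False,
                 sigma_min: float = DEFAULT_SIGMA_MIN,
                 xtol: float = 1e-10,
                 bh_scope: str = "per_line") -> ExtensionTrace:
    """Jointly extend one shared structure against two cell lines' data.

    Parameters
    ----------
    datasets
        Map cell-line label -> dataset (two entries in the study design).
    alpha
        Significance threshold on BH-adjusted likelihood-ratio p-values.
    n_starts
        Starts per candidate refit: one warm start from the parent optimum
        plus ``n_starts - 1`` Latin-hypercube starts.
    initial_n_starts
        Starts for the initial (and post-acceptance) full fits.
    require
        ``"both"`` (default): a link must be significant in every cell
        line; ``"any"``: in at least one.
    bh_scope
        ``"per_line"`` (default): adjust within each line across the
        round's candidates; ``"pooled"``: adjust over all lines at once.
    prune
        Remove links flagged removable after each acceptance.
    """
    if require not in ("both", "any"):
        raise ValueError("require must be 'both' or 'any'")
    if bh_scope not in ("per_line", "pooled"):
        raise ValueError("bh_scope must be 'per_line' or 'pooled'")
    rng = np.random.default_rng(seed)
    lines = list(datasets)

    def _fit_all(struct: NetworkStructure, warm: Mapping[str, np.ndarray] | None = None):
        fits = {}
        for line in lines:
            model = MRAModel(struct, pmap, datasets[line], sigma_min)
            x0 = None if warm is None else warm[line]
            fits[line] = model.fit(n_starts=initial_n_starts,
                                   seed=int(rng.integers(2**31)), x0=x0, xtol=xtol)
        return fits

    fits = _fit_all(structure)
    trace = ExtensionTrace(initial_ssr={l: fits[l].ssr for l in lines})

    while True:
        if len(trace.accepted) >= max_links:
            trace.stopping_reason = "max_links"
            break
        candidates = candidate_links(structure)
        if not candidates:
            trace.stopping_reason = "no_candidates"
            break
        tests: list[LinkTestResult] = []
        for link in candidates:
            ssr_before, ssr_after, params_after = {}, {}, {}
            failed = False
            for line in lines:
                try:
                    res = _fit_with_link(structure, pmap, datasets[line], link,
                                         fits[line].params, n_starts,
                                         int(rng.integers(2**31)), sigma_min, xtol)
                except Exception:
                    failed = True
                    break
                ssr_before[line] = fits[line].ssr
                ssr_after[line] = res.ssr
                params_after[line] = res.params
            if failed:
                import warnings
                warnings.warn(f"candidate {link} skipped: fit failure")
                continue
            t = LinkTestResult(link, ssr_before, ssr_after, params_after=params_after)
            t.p_raw = {l: lrt_pvalue(t.delta_ssr[l], df=1) for l in lines}
            tests.append(t)
        if not tests:
            trace.stopping_reason = "no_candidates"
            break
        if bh_scope == "per_line":
            for line in lines:
                adj = bh_adjust([t.p_raw[line] for t in tests])
                for t, a in zip(tests, adj):
                    t.p_adj[line] = float(a)
        else:
            flat = [t.p_raw[line] for t in tests for line in lines]
            adj = bh_adjust(flat)
            k = 0
            for t in tests:
                for line in lines:
                    t.p_adj[line] = float(adj[k])
                    k += 1
        if require == "both":
            eligible = [t for t in tests if all(t.p_adj[l] < alpha for l in lines)]
        else:
            eligible = [t for t in tests if any(t.p_adj[l] < alpha for l in lines)]
        if not eligible:
            trace.stopping_reason = "no_eligible"
            break
        # highest averaged relative reduction; ties broken lexicographically
        best_red = max(t.mean_relative_reduction for t in eligible)
        best = min((t for t in eligible if t.mean_relative_reduction == best_red),
                   key=lambda t: t.link)

        structure = structure.with_link(*best.link)
        fits = _fit_all(structure, warm={l: best.params_after[l] for l in lines})
        for line in lines:
            best.ssr_after[line] = min(best.ssr_after[line], fits[line].ssr)
        trace.accepted.append(best)

        removable = check_removal(structure, pmap, datasets, fits, alpha=alpha,
                                  sigma_min=sigma_min, xtol=xtol)
        trace.removable_per_round.append(removable)
        if prune and removable:
            for link in removable:
                structure = structure.without_link(*link)
            fits = _fit_all(structure)

    trace.final_structure = structure
    trace.final_results = fits
    return trace


def check_removal(structure: NetworkStructure, pmap: PerturbationMap,
                  datasets: Mapping[str, ResponseDataset],
                  fits: Mapping[str, object], alpha: float = 0.005,
                  sigma_min: float = DEFAULT_SIGMA_MIN,
                  xtol: float = 1e-10) -> list[Link]:
    """Links whose removal does not significantly worsen either line's fit.

    For each link the model is refitted without it; the link is removable
    if the residual increase stays below the chi-square ``1 - alpha``
    quantile (df = parameters removed, here 1) in every cell line.
    """
    threshold = chi2.ppf(1 - alpha, df=1)
    removable = []
    for i, link in enumerate(structure.links):
        ok = True
        for line, res in fits.items():
            reduced = structure.without_link(*link)
            model = MRAModel(reduced, pmap, datasets[line], sigma_min)
            warm = np.delete(res.params, i)
            _theta, ssr, _conv = model._local_fit(warm, xtol=xtol)
            if ssr - res.ssr >= threshold:
                ok = False
                break
        if ok:
            removable.append(link)
    return removable
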