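"""Steady-state MRA model of a perturbed signaling network.

The network response is modeled on the log2 scale as a linear steady
state.  Collect the local response coefficients ``r`` of all links into a
matrix (``r[target, source]``).  A treatment applies inhibitor strengths
``u_inh`` (acting multiplicatively on the targeted node's *outgoing*
signal, i.e. additively in log space on what downstream nodes see) and
stimulation strengths ``u_stim`` (additive inputs, including ligand
withdrawal as an unconstrained, typically negative, strength).  The
steady-state log2 fold changes ``x`` solve

    x = r (x + u_inh) + u_stim        =>        x = (I - r)^{-1} (r u_inh + u_stim)

Because an inhibitor acts on its target's output only, the target's own
readout is not directly reduced — it responds only through the network,
which is what lets a negative feedback raise pMEK under MEK inhibition.

:class:`MRAModel` binds a :class:`~mranet.structure.NetworkStructure`,
a :class:`~mranet.structure.PerturbationMap` and a
:class:`~mranet.data.ResponseDataset` and exposes simulation, the
error-standardized residual, its analytic Jacobian, and multi-start
maximum-likelihood fitting (Latin-hypercube starts + Levenberg-Marquardt).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .data import DEFAULT_SIGMA_MIN, ResponseDataset
from .structure import (
    MODE_INHIBITION,
    MODE_STIMULATION,
    NetworkStructure,
    PerturbationMap,
)

SINGULARITY_TOL = 1e-12   # |det(I - r)| below this is treated as singular
PENALTY_RESIDUAL = 1e3    # per-point residual assigned to singular parameter vectors


class SimulationError(RuntimeError):
    """Raised when the steady-state system is singular or divergent."""


class FitError(RuntimeError):
    """Raised when no optimization start converges."""


def _build_r_matrix(n_nodes: int, tgt_idx: np.ndarray, src_idx: np.ndarray,
                    link_values: np.ndarray) -> np.ndarray:
    r = np.zeros((n_nodes, n_nodes))
    r[tgt_idx, src_idx] = link_values
    return r


class MRAModel:
    """Maximum-likelihood MRA model for one cell line.

    Parameters
    ----------
    structure
        Directed network; one free local response coefficient per link.
    perturbation_map
        Agent -> (target node, mode); one free strength per agent.
    dataset
        Fold-change responses; fitting uses replicate-mean log2 values of
        the non-control conditions, standardized by the per-cell error.
    sigma_min
        Floor on estimated measurement errors (log2 units).

    The free parameter vector is the concatenation of link coefficients
    (named ``r:SRC->TGT``) and agent strengths (named ``k:AGENT``).
    """

    def __init__(self, structure: NetworkStructure, perturbation_map: PerturbationMap,
                 dataset: ResponseDataset, sigma_min: float = DEFAULT_SIGMA_MIN):
        perturbation_map.validate_against(structure)
        for readout in dataset.readouts:
            if readout not in structure.nodes:
                raise ValueError(f"readout {readout!r} is not a network node")
        self.structure = structure
        self.perturbation_map = perturbation_map
        self.dataset = dataset
        self.sigma_min = sigma_min

        self.nodes = structure.nodes
        self._node_index = structure.node_index
        self._n_nodes = len(self.nodes)
        self._src_idx = np.array([self._node_index[s] for s, _ in structure.links], dtype=int)
        self._tgt_idx = np.array([self._node_index[t] for _, t in structure.links], dtype=int)

        self.param_names: list[str] = (
            [f"r:{s}->{t}" for s, t in structure.links]
            + [f"k:{a}" for a in perturbation_map.agents]
        )
        self.n_links = len(structure.links)
        self.n_params = len(self.param_names)

        self._agents = perturbation_map.agents
        self._agent_target = np.array([self._node_index[perturbation_map.target(a)]
                                       for a in self._agents], dtype=int)
        self._agent_is_inh = np.array([perturbation_map.mode(a) == MODE_INHIBITION
                                       for a in self._agents], dtype=bool)

        # Fitted conditions: every non-control condition in the dataset.
        self._cond_idx = dataset.treatment_indices
        self.fit_conditions = [dataset.conditions[i] for i in self._cond_idx]
        self._active = self._activity_matrix(self.fit_conditions)  # agents x conds

        self._measured_rows = np.array([self._node_index[r] for r in dataset.readouts], dtype=int)
        y = dataset.log2_mean()[self._cond_idx]                    # conds x readouts
        sigma = dataset.errors(sigma_min)[self._cond_idx]
        self._mask = np.isfinite(y) & np.isfinite(sigma)
        self._y = y
        self._sigma = sigma
        self.n_data = int(self._mask.sum())

    # ------------------------------------------------------------------ #
    # forward simulation

    def _activity_matrix(self, conditions: Sequence[tuple[str, ...]]) -> np.ndarray:
        agent_pos = {a: i for i, a in enumerate(self._agents)}
        act = np.zeros((len(self._agents), len(conditions)), dtype=bool)
        for c, cond in enumerate(conditions):
            for agent in cond:
                if agent not in agent_pos:
                    raise ValueError(f"condition {cond!r} uses unknown agent {agent!r}")
                act[agent_pos[agent], c] = True
        return act

    def _inputs(self, params: np.ndarray, active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-node inhibitor and stimulation inputs, shape (nodes, conds)."""
        strengths = params[self.n_links:]
        n_cond = active.shape[1]
        u_inh = np.zeros((self._n_nodes, n_cond))
        u_stim = np.zeros((self._n_nodes, n_cond))
        for i, k in enumerate(self._agent_target):
            contrib = strengths[i] * active[i]
            if self._agent_is_inh[i]:
                u_inh[k] += contrib
            else:
                u_stim[k] += contrib
        return u_inh, u_stim

    def r_matrix(self, params: np.ndarray) -> np.ndarray:
        return _build_r_matrix(self._n_nodes, self._tgt_idx, self._src_idx,
                               np.asarray(params, float)[: self.n_links])

    def simulate(self, params: np.ndarray, conditions: Sequence[tuple[str, ...]],
                 full: bool = False) -> np.ndarray:
        """Predicted log2 fold changes, shape (conditions, readouts).

        With ``full=True`` all network nodes are returned instead of the
        measured readouts.  Raises :class:`SimulationError` if ``I - r``
        is singular at these parameters.
        """
        params = np.asarray(params, float)
        r = self.r_matrix(params)
        m = np.eye(self._n_nodes) - r
        sign, logdet = np.linalg.slogdet(m)
        if sign == 0 or logdet < np.log(SINGULARITY_TOL):
            raise SimulationError(
                f"singular steady-state system (|det(I-r)| < {SINGULARITY_TOL:g}) "
                f"at parameters {np.array2string(params, precision=3)}")
        active = self._activity_matrix(conditions)
        u_inh, u_stim = self._inputs(params, active)
        x = np.linalg.solve(m, r @ u_inh + u_stim)                 # nodes x conds
        if full:
            return x.T
        return x[self._measured_rows].T

    def simulate_response(self, params: np.ndarray, condition: tuple[str, ...],
                          full: bool = False) -> np.ndarray:
        """Predicted log2 fold change of one condition (1-D array)."""
        return self.simulate(params, [condition], full=full)[0]

    # ------------------------------------------------------------------ #
    # residuals and Jacobian

    def _simulate_fit(self, params: np.ndarray):
        r = self.r_matrix(params)
        m = np.eye(self._n_nodes) - r
        sign, logdet = np.linalg.slogdet(m)
        if sign == 0 or logdet < np.log(SINGULARITY_TOL):
            return None
        u_inh, u_stim = self._inputs(params, self._active)
        x = np.linalg.solve(m, r @ u_inh + u_stim)
        return r, m, u_inh, x

    def residuals(self, params: np.ndarray) -> np.ndarray:
        """Error-standardized residual vector over non-missing data points."""
        sim = self._simulate_fit(np.asarray(params, float))
        if sim is None:
            return np.full(self.n_data, PENALTY_RESIDUAL)
        _, _, _, x = sim
        pred = x[self._measured_rows].T                            # conds x readouts
        res = (pred - self._y) / self._sigma
        return res[self._mask]

    def ssr(self, params: np.ndarray) -> float:
        """Error-standardized sum of squared residuals (the model residual)."""
        r = self.residuals(params)
        return float(r @ r)

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`residuals` w.r.t. the parameters."""
        params = np.asarray(params, float)
        sim = self._simulate_fit(params)
        if sim is None:
            return np.zeros((self.n_data, self.n_params))
        r, m, u_inh, x = sim
        a = np.linalg.inv(m)
        n_cond = x.shape[1]
        jac = np.empty((self.n_data, self.n_params))
        meas = self._measured_rows
        mask = self._mask
        sigma = self._sigma
        # link coefficients: dx = (x_s + u_inh_s) * A[:, t]
        for p in range(self.n_links):
            s, t = self._src_idx[p], self._tgt_idx[p]
            dx = np.outer(a[meas, t], x[s] + u_inh[s])             # readouts x conds
            jac[:, p] = (dx.T / sigma)[mask]
        # agent strengths
        ar = a @ r
        for i in range(len(self._agents)):
            k = self._agent_target[i]
            col = ar[meas, k] if self._agent_is_inh[i] else a[meas, k]
            dx = np.outer(col, self._active[i].astype(float))
            jac[:, self.n_links + i] = (dx.T / sigma)[mask]
        return jac

    # ------------------------------------------------------------------ #
    # fitting

    def _local_fit(self, x0: np.ndarray, free: np.ndarray | None = None,
                   xtol: float = 1e-10, max_nfev: int = 2000):
        """One damped least-squares run; optionally only a subset is free."""
        x0 = np.asarray(x0, float)
        if free is None:
            fun, jac, start = self.residuals, self.jacobian, x0
            unpack = lambda th: th
        else:
            free = np.asarray(free, bool)
            base = x0.copy()

            def unpack(th):
                full = base.copy()
                full[free] = th
                return full

            fun = lambda th: self.residuals(unpack(th))
            jac = lambda th: self.jacobian(unpack(th))[:, free]
            start = x0[free]
        # MINPACK's LM needs at least as many residuals as free parameters;
        # fall back to the trust-region solver for under-determined problems
        method = "lm" if self.n_data >= len(start) else "trf"
        sol = least_squares(fun, start, jac=jac, method=method,
                            xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=max_nfev)
        return unpack(sol.x), float(sol.cost * 2), bool(sol.status > 0)

    def fit(self, n_starts: int = 1000, seed: int | None = None,
            bounds: tuple[float, float] = (-5.0, 5.0),
            x0: np.ndarray | Sequence[np.ndarray] | None = None,
            xtol: float = 1e-10, max_nfev: int = 2000):
        """Multi-start maximum-likelihood fit.

        Draws ``n_starts`` initial vectors by Latin-hypercube sampling over
        the ``bounds`` box (warm starts passed via ``x0`` are tried first
        and count toward ``n_starts``), minimizes the error-standardized
        residual from each with the Levenberg-Marquardt algorithm, and
        returns the best solution as an :class:`~mranet.results.MRAResults`.
        """
        from .results import MRAResults

        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.n_data <= self.n_params:
            import warnings
            warnings.warn("fewer data points than free parameters; inference is unreliable")

        warm: list[np.ndarray] = []
        if x0 is not None:
            arr = np.asarray(x0, float)
            warm = [arr] if arr.ndim == 1 else [np.asarray(v, float) for v in arr]
        else:
            # the no-interaction model is a cheap, reliable deterministic start
            warm = [np.zeros(self.n_params)]
        n_lhs = max(n_starts - len(warm), 0)
        starts = list(warm)
        if n_lhs > 0:
            sampler = qmc.LatinHypercube(d=self.n_params, seed=seed)
            lo, hi = bounds
            starts.extend(qmc.scale(sampler.random(n_lhs), lo, hi))

        # apply sign hints to LHS starts so hinted links begin on their side
        hints = self.structure.sign_hints
        if hints:
            hint_idx = [(i, hints[l]) for i, l in enumerate(self.structure.links) if l in hints]
            for v in starts[len(warm):]:
                for i, sgn in hint_idx:
                    v[i] = sgn * abs(v[i])

        best = None
        n_converged = 0
        for start in starts[:n_starts] if len(starts) > n_starts else starts:
            try:
                theta, ssr, ok = self._local_fit(start, xtol=xtol, max_nfev=max_nfev)
            except Exception:
                continue
            if ok and ssr < PENALTY_RESIDUAL**2 * self.n_data * 0.5:
                n_converged += 1
            if best is None:
                best = (theta, ssr)
                continue
            # structurally non-identifiable directions produce exactly flat
            # valleys; among (numerically) tied optima keep the minimum-norm
            # representative so downstream profiling starts at a sane scale
            tol = 1e-6 * (1.0 + best[1])
            if ssr < best[1] - tol:
                best = (theta, ssr)
            elif ssr < best[1] + tol and np.linalg.norm(theta) < np.linalg.norm(best[0]):
                best = (theta, ssr)
        if best is None or n_converged == 0:
            raise FitError(f"all {len(starts)} optimization starts failed")
        theta, ssr = best
        return MRAResults(self, theta, ssr, start_seed=seed, n_starts=len(starts),
                          converged_fraction=n_converged / len(starts))


# ---------------------------------------------------------------------- #
# independent fixed-point oracle (used for verification)

def relaxation_response(model: MRAModel, params: np.ndarray, condition: tuple[str, ...],
                        tol: float = 1e-10, max_iter: int = 200000,
                        damping: float = 1.0) -> np.ndarray:
    """Steady state by damped relaxation of ``x <- r (x + u_inh) + u_stim``.

    An independent route to the same fixed point that :meth:`MRAModel.simulate`
    obtains by a direct linear solve; converges iff the spectral radius of
    the (damped) iteration matrix is below one, and raises
    :class:`SimulationError` otherwise.  Returns all-node log2 responses.
    """
    params = np.asarray(params, float)
    r = model.r_matrix(params)
    active = model._activity_matrix([condition])
    u_inh, u_stim = model._inputs(params, active)
    u_inh, u_stim = u_inh[:, 0], u_stim[:, 0]
    x = np.zeros(model._n_nodes)
    for _ in range(max_iter):
        x_new = (1 - damping) * x + damping * (r @ (x + u_inh) + u_stim)
        if not np.all(np.isfinite(x_new)) or np.abs(x_new).max() > 1e12:
            raise SimulationError("relaxation diverged: spectral radius of r >= 1")
        if np.abs(x_new - x).max() < tol:
            return x_new
        x = x_new
    raise SimulationError("relaxation did not converge within max_iter")
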