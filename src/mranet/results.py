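"""Fit results: parameter estimates, residual diagnostics, summaries."""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np


class MRAResults:
    """Maximum-likelihood fit of an :class:`~mranet.model.MRAModel`.

    Attributes
    ----------
    params : ndarray
        Best parameter vector (link coefficients then agent strengths).
    ssr : float
        Error-standardized sum of squared residuals at the optimum.
    n_data, n_params : int
        Non-missing data points and free parameters; ``n_data - n_params``
        is the expected residual under a correctly specified model.
    start_seed, n_starts, converged_fraction
        Multi-start provenance.
    """

    def __init__(self, model, params: np.ndarray, ssr: float,
                 start_seed: int | None = None, n_starts: int = 1,
                 converged_fraction: float = 1.0):
        self.model = model
        self.params = np.asarray(params, float)
        self.ssr = float(ssr)
        self.n_data = model.n_data
        self.n_params = model.n_params
        self.start_seed = start_seed
        self.n_starts = n_starts
        self.converged_fraction = converged_fraction

    # ------------------------------------------------------------------ #

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.params)))

    def get(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    @property
    def dof(self) -> int:
        return self.n_data - self.n_params

    def predicted(self) -> np.ndarray:
        """Model log2 responses for the fitted conditions x readouts."""
        return self.model.simulate(self.params, self.model.fit_conditions)

    def rsquared_per_readout(self) -> dict[str, float]:
        """Coefficient of determination between data and simulation per readout."""
        pred = self.predicted()
        y = self.model._y
        out = {}
        for j, readout in enumerate(self.model.dataset.readouts):
            ok = self.model._mask[:, j]
            yy, pp = y[ok, j], pred[ok, j]
            ss_res = float(np.sum((yy - pp) ** 2))
            ss_tot = float(np.sum((yy - yy.mean()) ** 2))
            out[readout] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return out

    def refit(self, fixed: Mapping[str, float] | None = None,
              x0: np.ndarray | None = None, xtol: float = 1e-10):
        """Re-optimize with some parameters held fixed (by name).

        Returns ``(params, ssr)`` of the constrained optimum, warm-started
        from ``x0`` (default: the current estimate).
        """
        theta0 = self.params.copy() if x0 is None else np.asarray(x0, float).copy()
        free = np.ones(self.n_params, dtype=bool)
        if fixed:
            for name, value in fixed.items():
                i = self.param_names.index(name)
                theta0[i] = value
                free[i] = False
        theta, ssr, _ok = self.model._local_fit(theta0, free=free, xtol=xtol)
        return theta, ssr

    def profile(self, name: str, **kwargs):
        """Profile likelihood of one parameter; see
        :func:`mranet.profile.profile_parameter`."""
        from .profile import profile_parameter

        return profile_parameter(self, name, **kwargs)

    # ------------------------------------------------------------------ #

    def summary(self) -> str:
        lines = [
            "MRA network model fit",
            "=" * 54,
            f"cell line:            {self.model.dataset.cell_line or '-'}",
            f"nodes / links:        {len(self.model.nodes)} / {self.model.n_links}",
            f"data points (n):      {self.n_data}",
            f"free parameters (p):  {self.n_params}",
            f"residual (ssr):       {self.ssr:.4g}   [E(ssr) ~ n - p = {self.dof}]",
            f"starts / converged:   {self.n_starts} / {self.converged_fraction:.0%}"
            + (f"   seed={self.start_seed}" if self.start_seed is not None else ""),
            "-" * 54,
            f"{'parameter':<28}{'estimate':>12}",
            "-" * 54,
        ]
        for name, value in self.params_dict().items():
            lines.append(f"{name:<28}{value:>12.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cell_line": self.model.dataset.cell_line,
            "nodes": list(self.model.nodes),
            "links": [list(l) for l in self.model.structure.links],
            "node_classes": dict(self.model.structure.node_classes),
            "perturbation_map": {a: list(self.model.perturbation_map.entries[a])
                                 for a in self.model.perturbation_map.agents},
            "params": self.params_dict(),
            "ssr": self.ssr,
            "n_data": self.n_data,
            "n_params": self.n_params,
            "start_seed": self.start_seed,
            "n_starts": self.n_starts,
            "converged_fraction": self.converged_fraction,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MRAResults {self.model.dataset.cell_line or 'fit'}: "
                f"ssr={self.ssr:.4g}, n={self.n_data}, p={self.n_params}>")
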