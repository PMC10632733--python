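"""Profile-likelihood confidence intervals for model parameters.

The likelihood profile of a parameter is obtained by holding it fixed at a
grid of values walking outward from its maximum-likelihood estimate while
re-optimizing every other free parameter — except the inhibitor strengths,
which are held at their MLEs following the study's procedure, so that the
chi-square threshold uses ``df = 1 + (number of fixed inhibitors)`` degrees
of freedom (8 for the seven-inhibitor study design).  The 95% confidence
bounds are the parameter values where the residual increase over the
global minimum crosses the chi-square quantile; a bound that is not
crossed within the walk limit is reported as infinite (the parameter is
practically non-identifiable on that side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

WALK_LIMIT = 50.0        # |theta| beyond which a bound counts as unbounded
STEP_REL = 0.2           # multiplicative step: 20% of current magnitude
STEP_MIN = 0.05          # additive floor near zero


@dataclass
class ProfileResult:
    """Likelihood profile and confidence interval of one parameter."""

    name: str
    mle: float
    mle_ssr: float
    df: int
    threshold: float                       # chi-square quantile (ssr increase)
    grid: np.ndarray                       # ascending profiled values (incl. MLE)
    ssr_profile: np.ndarray
    co_params: np.ndarray                  # (n_grid, n_params) full vectors
    ci_low: float
    ci_high: float
    alpha: float = 0.95
    invalid: list[int] = field(default_factory=list)

    @property
    def bounded(self) -> tuple[bool, bool]:
        return np.isfinite(self.ci_low), np.isfinite(self.ci_high)

    def within_ci(self) -> np.ndarray:
        """Boolean mask of grid points inside the confidence region."""
        ref = min(self.mle_ssr, float(np.nanmin(self.ssr_profile)))
        return self.ssr_profile - ref <= self.threshold + 1e-9


def default_fixed_params(model) -> list[str]:
    """Inhibitor strength parameters, fixed during profiling by default."""
    return [f"k:{a}" for a in model.perturbation_map.inhibitors]


def _next_value(theta: float, direction: int) -> float:
    step = max(STEP_REL * abs(theta), STEP_MIN)
    return theta + direction * step


def _refine_bound(results, name, fixed_at_mle, th_in, th_out, warm, target,
                  xtol, points, max_bisect=25):
    """Bisect between an inside and an outside grid point until the profile
    crosses the chi-square threshold; returns the crossing value."""
    ssr_in = None
    for _ in range(max_bisect):
        mid = 0.5 * (th_in + th_out)
        try:
            params, ssr = results.refit(fixed={name: mid, **fixed_at_mle},
                                        x0=warm, xtol=xtol)
        except Exception:
            break
        points.append((mid, ssr, params))
        warm = params
        if ssr - results.ssr > target:
            th_out = mid
        else:
            th_in, ssr_in = mid, ssr
        if abs(th_out - th_in) < 1e-4 * max(1.0, abs(th_in)):
            break
    return 0.5 * (th_in + th_out)


def profile_parameter(results, name: str, df: int | None = None,
                      alpha: float = 0.95,
                      fixed_params: list[str] | None = None,
                      walk_limit: float = WALK_LIMIT,
                      xtol: float = 1e-8) -> ProfileResult:
    """Profile one parameter of a fitted model.

    Parameters
    ----------
    results : MRAResults
        A converged fit.
    name
        Parameter to profile, e.g. ``"r:ERK->RAF"`` or ``"k:ActA"``.
    df
        Degrees of freedom of the chi-square threshold; defaults to
        ``1 + len(fixed_params)`` (the study's convention gives 8).
    fixed_params
        Parameters held at their MLEs while profiling; defaults to all
        inhibitor strengths.  The profiled parameter must not be listed.
    """
    model = results.model
    if name not in results.param_names:
        raise KeyError(f"unknown parameter {name!r}")
    if fixed_params is None:
        fixed_params = default_fixed_params(model)
    fixed_params = [p for p in fixed_params if p != name]
    if df is None:
        df = 1 + len(fixed_params)
    threshold = float(chi2.ppf(alpha, df))

    mle = results.get(name)
    mle_ssr = results.ssr
    fixed_at_mle = {p: results.get(p) for p in fixed_params}

    points: list[tuple[float, float, np.ndarray]] = [(mle, mle_ssr, results.params.copy())]
    bounds = {}
    for direction in (-1, +1):
        theta = mle
        warm = results.params.copy()
        prev = (mle, mle_ssr)
        bound = direction * np.inf
        while True:
            theta = _next_value(theta, direction)
            if abs(theta) > walk_limit:
                break
            try:
                params, ssr = results.refit(
                    fixed={name: theta, **fixed_at_mle}, x0=warm, xtol=xtol)
            except Exception:
                points.append((theta, np.nan, np.full_like(results.params, np.nan)))
                continue
            points.append((theta, ssr, params))
            warm = params
            if ssr - mle_ssr > threshold:
                bound = _refine_bound(results, name, fixed_at_mle,
                                      th_in=prev[0], th_out=theta, warm=warm,
                                      target=threshold, xtol=xtol, points=points)
                break
            prev = (theta, ssr)
        bounds[direction] = bound

    points.sort(key=lambda t: t[0])
    grid = np.array([p[0] for p in points])
    ssr_profile = np.array([p[1] for p in points])
    co_params = np.vstack([p[2] for p in points])
    invalid = [i for i in range(len(points)) if not np.isfinite(ssr_profile[i])]

    ci_low = min(bounds[-1], mle)
    ci_high = max(bounds[+1], mle)
    return ProfileResult(name=name, mle=mle, mle_ssr=mle_ssr, df=df,
                         threshold=threshold, grid=grid, ssr_profile=ssr_profile,
                         co_params=co_params, ci_low=float(ci_low),
                         ci_high=float(ci_high), alpha=alpha, invalid=invalid)


def profile_parameters(results, names: list[str] | None = None,
                       **kwargs) -> dict[str, ProfileResult]:
    """Profile several (default: all link) parameters; returns name -> profile."""
    if names is None:
        names = results.param_names[: results.model.n_links]
    return {n: profile_parameter(results, n, **kwargs) for n in names}
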