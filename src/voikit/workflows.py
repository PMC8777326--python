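"""Budget-driven estimation workflows shared by the CLI and scripts.

Given a target RMSE ``epsilon``, every workflow applies the same error
split — bias bounded by eps/2, variance by 3*eps^2/4.  The inner-sample
count needed to meet the bias bound is calibrated by the multilevel bias
extrapolation (plain MC and QMC cannot estimate their own bias); outer
counts come from pilot variance estimates (MC) or from doubling the point
set until the replicate variance meets the bound (QMC).
"""

from __future__ import annotations

import math

import numpy as np

from .mlmc import choose_inner_samples, mlmc_evppi
from .models import DecisionProblem
from .nested_mc import VoiEstimate, evpi_mc, evppi_nested_mc, evppi_from_outer
from .qmc import DEFAULT_K, rqmc_evpi, rqmc_evppi

__all__ = ["estimate_evpi", "estimate_evppi"]

_PILOT_OUTER = 1000
_QMC_START_N = 256
_MAX_EVALS = 200_000_000  # hard cap on nb evaluations for one adaptive run


def estimate_evpi(
    problem: DecisionProblem,
    method: str = "mc",
    epsilon: float | None = None,
    n: int | None = None,
    k_reps: int = DEFAULT_K,
    seed: int | np.random.Generator | None = None,
) -> VoiEstimate:
    """EVPI with either an explicit sample count or an RMSE target.

    The plain estimator's own bias is O(1/N) downward and is not separately
    budgeted: the variance bound drives N.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if (epsilon is None) == (n is None):
        raise ValueError("supply exactly one of epsilon or n")
    if method == "mc":
        if n is None:
            pilot = evpi_mc(problem, _PILOT_OUTER, rng)
            var = (pilot.std_error * math.sqrt(_PILOT_OUTER)) ** 2
            n = max(2, math.ceil(var / (0.75 * epsilon**2)))
        est = evpi_mc(problem, n, rng)
        if epsilon is not None:
            est.total_nb_evaluations += _PILOT_OUTER
            est.diagnostics["epsilon"] = epsilon
        return est
    if method == "qmc":
        if n is not None:
            return rqmc_evpi(problem, n, k_reps, rng)
        variance_bound = 0.75 * epsilon**2
        n_try = _QMC_START_N
        cost = 0
        while True:
            est = rqmc_evpi(problem, n_try, k_reps, rng)
            cost += est.total_nb_evaluations
            if est.std_error**2 <= variance_bound or n_try * 2 * k_reps > _MAX_EVALS:
                est.total_nb_evaluations = cost
                est.diagnostics["epsilon"] = epsilon
                return est
            n_try *= 2
    raise ValueError(f"unknown EVPI method {method!r} (use 'mc' or 'qmc')")


def estimate_evppi(
    problem: DecisionProblem,
    subset: str,
    method: str = "qmc",
    epsilon: float | None = None,
    n_outer: int | None = None,
    n_inner: int | None = None,
    k_reps: int = DEFAULT_K,
    seed: int | np.random.Generator | None = None,
    max_level: int = 12,
    max_evals: int = _MAX_EVALS,
) -> VoiEstimate:
    """EVPPI by nested MC, MLMC, or randomized QMC.

    With an RMSE target, MC and QMC first run the multilevel bias pilot to
    pick M = 2^L meeting the bias bound, then size the outer sampling to meet
    the variance bound.  Explicit (n_outer, n_inner) budgets bypass planning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    explicit = n_outer is not None
    if (epsilon is not None) == explicit:
        raise ValueError("supply exactly one of epsilon or explicit (n_outer, n_inner)")
    if method == "mlmc":
        if explicit:
            raise ValueError("MLMC is epsilon-driven; explicit budgets are not supported")
        est, _ = mlmc_evppi(problem, subset, epsilon, rng, max_level=max_level)
        return est

    bias = None
    pilot_cost = 0
    if not explicit:
        n_inner, remaining, stats = choose_inner_samples(
            problem, subset, epsilon, rng, max_level=max_level
        )
        bias = -remaining
        pilot_cost = sum(s.n * s.cost_per_sample for s in stats)
    elif n_inner is None:
        n_inner = 1

    if method == "mc":
        if not explicit:
            sampler = problem.conditional_sampler(subset)
            x = sampler.marginal_x().sample(_PILOT_OUTER, rng)
            _, se = evppi_from_outer(problem, subset, x, n_inner, rng)
            var = (se * math.sqrt(_PILOT_OUTER)) ** 2
            n_outer = max(2, math.ceil(var / (0.75 * epsilon**2)))
            pilot_cost += _PILOT_OUTER * n_inner
            if n_outer * n_inner > max_evals:
                n_outer = max(2, max_evals // n_inner)
        est = evppi_nested_mc(problem, subset, n_outer, n_inner, rng)
        est.bias_estimate = bias
        est.ci95 = None
        est.__post_init__()
        est.total_nb_evaluations += pilot_cost
        if epsilon is not None:
            est.diagnostics["epsilon"] = epsilon
        return est

    if method == "qmc":
        if explicit:
            return rqmc_evppi(problem, subset, n_outer, n_inner, k_reps, rng)
        variance_bound = 0.75 * epsilon**2
        n_try = _QMC_START_N
        cost = pilot_cost
        while True:
            est = rqmc_evppi(
                problem, subset, n_try, n_inner, k_reps, rng, bias_estimate=bias
            )
            cost += est.total_nb_evaluations
            if (
                est.std_error**2 <= variance_bound
                or 2 * n_try * n_inner * k_reps > max_evals
            ):
                est.total_nb_evaluations = cost
                est.diagnostics["epsilon"] = epsilon
                return est
            n_try *= 2

    raise ValueError(f"unknown EVPPI method {method!r} (use 'mc', 'mlmc' or 'qmc')")
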