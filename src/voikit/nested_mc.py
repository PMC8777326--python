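"""Standard (pseudo-random) nested Monte Carlo estimators of EVPI and EVPPI.

EVPI is estimated from N joint draws Z^(n) as

    (1/N) sum_n max_d f_d(Z^(n))  -  max_d (1/N) sum_n f_d(Z^(n)),

which is biased downward (the second term is biased upward by Jensen's
inequality).  EVPPI for a subset X uses N outer draws X^(n) with M inner
conditional draws Y^(n,m); the first term averages max_d of inner means and
the second term is max_d of the grand mean over all N*M draws, reusing the
same draws (which correlates the two terms — accounted for by the
delta-method standard error below).

For a target root-mean-square error eps, the bias is bounded by eps/2 and the
variance by 3*eps^2/4; the inner count scales like 1/eps and the outer count
like 1/eps^2, so total nested-MC cost scales like eps^-3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from .models import DecisionProblem

__all__ = ["BudgetPlan", "VoiEstimate", "evpi_mc", "evppi_nested_mc", "plan_budget"]

#: default cap on elements of the (chunk, M) inner workspace; keeps peak
#: memory around tens of MB regardless of the requested budget
_CHUNK_ELEMENTS = 1 << 20


@dataclass(frozen=True)
class BudgetPlan:
    """Split of a target MSE eps^2 into bias and variance bounds.

    bias_bound = eps/2 and variance_bound = 3*eps^2/4, so that
    bias_bound^2 + variance_bound = eps^2.
    """

    epsilon: float
    n_outer: int
    n_inner: int

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("sample counts must be >= 1")

    @property
    def bias_bound(self) -> float:
        return self.epsilon / 2.0

    @property
    def variance_bound(self) -> float:
        return 0.75 * self.epsilon**2


@dataclass
class VoiEstimate:
    """A value-of-information estimate with its uncertainty accounting.

    ``bias_estimate`` is the estimated expectation error E[estimator] - truth
    (available when a multilevel bias extrapolation was run); ``ci95`` is the
    normal-theory interval estimate +/- 1.96*SE, widened to cover the
    bias-corrected point when a bias estimate is available.
    ``total_nb_evaluations`` counts parameter draws at which the net-benefit
    vector was evaluated, the cost unit used for cross-method comparison.
    """

    estimate: float
    std_error: float
    n_outer: int
    n_inner: int
    total_nb_evaluations: int
    method: str
    bias_estimate: float | None = None
    k_reps: int | None = None
    ci95: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci95 is None:
            self.ci95 = _credible_interval(self.estimate, self.std_error, self.bias_estimate)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(self.ci95)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def summary(self) -> str:
        lo, hi = self.ci95
        bias = "n/a" if self.bias_estimate is None else f"{self.bias_estimate:.4g}"
        return (
            f"{self.method}: estimate {self.estimate:.2f} "
            f"(SE {self.std_error:.3g}, bias {bias}), "
            f"95% CrI [{lo:.2f}, {hi:.2f}], "
            f"cost {self.total_nb_evaluations} nb draws"
        )


def _credible_interval(
    estimate: float, std_error: float, bias_estimate: float | None
) -> tuple[float, float]:
    """Normal-theory 95% interval, widened by the signed bias when known.

    With bias b = E[est] - truth, the bias-corrected point is est - b; the
    interval is the hull of (est +/- 1.96 SE) and (est - b +/- 1.96 SE).
    """
    half = 1.96 * std_error
    lo, hi = estimate - half, estimate + half
    if bias_estimate is not None:
        corrected = estimate - bias_estimate
        lo = min(lo, corrected - half)
        hi = max(hi, corrected + half)
    return (lo, hi)


def _outer_chunks(n_outer: int, n_inner: int) -> Iterator[tuple[int, int]]:
    step = max(1, _CHUNK_ELEMENTS // max(1, n_inner))
    for lo in range(0, n_outer, step):
        yield lo, min(lo + step, n_outer)


def evpi_mc(
    problem: DecisionProblem,
    n: int,
    stream: np.random.Generator | int | None = None,
) -> VoiEstimate:
    """EVPI by plain Monte Carlo on ``n`` joint parameter draws.

    The standard error treats the second term by the delta method: with d*
    the empirical best decision, the per-draw values
    g_n = max_d f_d(Z^(n)) - f_{d*}(Z^(n)) have mean equal to the estimate
    and their spread yields SE = sd(g)/sqrt(n), accounting for the
    correlation between the two terms (they share the same draws).
    """
    if n < 2:
        raise ValueError("need at least 2 draws for an EVPI estimate")
    rng = stream if isinstance(stream, np.random.Generator) else np.random.default_rng(stream)
    ndec = problem.n_decisions
    sum_d = np.zeros(ndec)
    row_max: list[np.ndarray] = []
    nb_rows: list[np.ndarray] = []
    for lo, hi in _outer_chunks(n, 1):
        z = problem.params.sample(hi - lo, rng)
        nb = problem.net_benefits(z)
        sum_d += nb.sum(axis=0)
        row_max.append(nb.max(axis=1))
        nb_rows.append(nb)
    d_star = int(np.argmax(sum_d))  # ties: lowest index via argmax
    g = np.concatenate([rm - nb[:, d_star] for rm, nb in zip(row_max, nb_rows)])
    estimate = float(g.mean())
    se = float(g.std(ddof=1) / math.sqrt(n))
    return VoiEstimate(
        estimate=estimate,
        std_error=se,
        n_outer=n,
        n_inner=1,
        total_nb_evaluations=n,
        method="evpi_mc",
    )


def evppi_from_outer(
    problem: DecisionProblem,
    subset: str,
    x: np.ndarray,
    n_inner: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Nested estimator value and SE for given outer draws of the subset.

    Shared engine for the pseudo-random and QMC-outer estimators: ``x`` holds
    the outer draws (canonical subset order), inner conditional draws are
    pseudo-random.  Returns (estimate, std_error).
    """
    sampler = problem.conditional_sampler(subset)
    n_outer = x.shape[0]
    ndec = problem.n_decisions
    grand = np.zeros(ndec)
    maxima = np.empty(n_outer)
    inner_means: list[np.ndarray] = []
    for lo, hi in _outer_chunks(n_outer, n_inner):
        z = sampler.sample_full(x[lo:hi], n_inner, rng)
        nb = problem.net_benefits(z)          # (chunk, M, D)
        im = nb.mean(axis=1)                  # (chunk, D)
        inner_means.append(im)
        maxima[lo:hi] = im.max(axis=1)
        grand += im.sum(axis=0)
    d_star = int(np.argmax(grand))
    h = np.concatenate([maxima[lo:hi] - im[:, d_star]
                        for (lo, hi), im in zip(_outer_chunks(n_outer, n_inner), inner_means)])
    estimate = float(h.mean())
    se = float(h.std(ddof=1) / math.sqrt(n_outer)) if n_outer > 1 else float("nan")
    return estimate, se


def evppi_nested_mc(
    problem: DecisionProblem,
    subset: str,
    n_outer: int,
    n_inner: int,
    stream: np.random.Generator | int | None = None,
) -> VoiEstimate:
    """EVPPI for a named subset by nested Monte Carlo (N outer, M inner)."""
    if n_outer < 2:
        raise ValueError("need at least 2 outer draws")
    if n_inner < 1:
        raise ValueError("need at least 1 inner draw")
    rng = stream if isinstance(stream, np.random.Generator) else np.random.default_rng(stream)
    sampler = problem.conditional_sampler(subset)  # validates subset
    x = sampler.marginal_x().sample(n_outer, rng)
    estimate, se = evppi_from_outer(problem, subset, x, n_inner, rng)
    return VoiEstimate(
        estimate=estimate,
        std_error=se,
        n_outer=n_outer,
        n_inner=n_inner,
        total_nb_evaluations=n_outer * n_inner,
        method="evppi_nested_mc",
        diagnostics={"subset": subset},
    )


def plan_budget(
    epsilon: float,
    bias_per_inner: float | None = None,
    pilot_variance: float | None = None,
) -> BudgetPlan:
    """Sample counts achieving MSE eps^2 under the eps/2–3eps^2/4 split.

    ``bias_per_inner`` is the estimated bias constant c in bias ~ c/M (e.g.
    from a multilevel bias extrapolation at M=1); ``pilot_variance`` the
    estimated per-outer-draw variance of the estimator's summand.  Either may
    be omitted, in which case the corresponding count defaults to 1 (inner)
    or the variance-only rule is skipped.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    bias_bound = epsilon / 2.0
    variance_bound = 0.75 * epsilon**2
    n_inner = 1 if bias_per_inner is None else max(1, math.ceil(abs(bias_per_inner) / bias_bound))
    n_outer = 2 if pilot_variance is None else max(2, math.ceil(pilot_variance / variance_bound))
    return BudgetPlan(epsilon=epsilon, n_outer=n_outer, n_inner=n_inner)
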