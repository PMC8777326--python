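"""Multilevel Monte Carlo estimation of EVPPI.

Level ``l`` of the hierarchy is the nested estimator with ``M = 2**l`` inner
samples.  Writing e_l for the per-outer-draw summand of the first (nested)
term, the telescoping identity

    E[e_L] = E[e_0] + sum_{l=1..L} E[d_l],        d_l = e_l - e_{l-1},

lets the deeply-nested estimator be assembled from cheap, low-variance level
differences: d_l couples the fine and coarse summands on *shared* inner
draws, with the coarse value taken as the antithetic average of e_{l-1}
evaluated on the two halves of the fine level's 2**l inner draws.  Because
the expected level differences decay geometrically (|E[d_l]| ~ c 2^{-alpha l}),
the remaining bias beyond the finest simulated level can be extrapolated —
this bias estimate also calibrates the inner-sample count for the plain
nested-MC and QMC estimators.

The non-nested second term of the EVPPI estimator (max_d of the grand mean)
is handled outside the telescoping sum — which applies to the nested first
term only, avoiding spurious level-to-level correlation in the second term.
A standalone plain-MC run identifies the best current-information decision
d*, and f_{d*} is then subtracted per draw inside the level-0 stream: the
expectation is unchanged but the common net-benefit shift shared by all
decisions cancels, keeping the level-0 variance on the scale of the
information value itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import DecisionProblem
from .nested_mc import VoiEstimate, _outer_chunks

__all__ = [
    "MlmcLevelStats",
    "level_difference_samples",
    "extrapolate_bias",
    "fit_level_decay",
    "optimal_allocation",
    "mlmc_evppi",
    "choose_inner_samples",
    "best_decision",
]

MAX_LEVEL_DEFAULT = 12
PILOT_DRAWS = 100  # initial outer draws per new level


@dataclass
class MlmcLevelStats:
    """Running summary of one level's difference samples.

    ``mean_diff``/``var_diff`` summarise d_l draws (e_0 draws at level 0);
    ``cost_per_sample`` is the number of parameter draws per d_l draw, 2**l.
    """

    level: int
    n: int
    mean_diff: float
    var_diff: float

    @property
    def cost_per_sample(self) -> int:
        return 2**self.level


class _Accumulator:
    """Streaming sum/sum-of-squares for one level."""

    def __init__(self, level: int):
        self.level = level
        self.n = 0
        self.total = 0.0
        self.total_sq = 0.0

    def add(self, draws: np.ndarray) -> None:
        self.n += draws.size
        self.total += float(draws.sum())
        self.total_sq += float(np.square(draws).sum())

    @property
    def mean(self) -> float:
        return self.total / self.n if self.n else math.nan

    @property
    def var(self) -> float:
        if self.n < 2:
            return math.nan
        return max(0.0, (self.total_sq - self.n * self.mean**2) / (self.n - 1))

    def stats(self) -> MlmcLevelStats:
        return MlmcLevelStats(self.level, self.n, self.mean, self.var)


def level_difference_samples(
    problem: DecisionProblem,
    subset: str,
    level: int,
    n: int,
    stream: np.random.Generator | int | None = None,
    d_star: int | None = None,
) -> np.ndarray:
    """Draw ``n`` coupled level-difference samples d_l (e_0 samples at l=0).

    Each draw uses one outer sample of the subset and 2**l shared inner
    conditional draws: the fine summand averages all of them, the coarse
    summand is the antithetic mean of the coarser estimator on the first and
    second halves.

    At level 0, when the index ``d_star`` of the overall best decision is
    supplied, the draw is max_d f_d - f_{d_star} — the per-draw coupling of
    the estimator's non-nested second term, whose expectation is the level-0
    value estimate and whose variance is orders of magnitude below that of
    the raw maximum (the common net-benefit shift cancels).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    rng = stream if isinstance(stream, np.random.Generator) else np.random.default_rng(stream)
    sampler = problem.conditional_sampler(subset)
    m = 2**level
    out = np.empty(n)
    for lo, hi in _outer_chunks(n, m):
        x = sampler.marginal_x().sample(hi - lo, rng)
        z = sampler.sample_full(x, m, rng)
        nb = problem.net_benefits(z)  # (chunk, m, D)
        if level == 0:
            vals = nb[:, 0, :].max(axis=1)
            if d_star is not None:
                vals = vals - nb[:, 0, d_star]
            out[lo:hi] = vals
            continue
        fine = nb.mean(axis=1).max(axis=1)
        half = m // 2
        coarse_a = nb[:, :half, :].mean(axis=1).max(axis=1)
        coarse_b = nb[:, half:, :].mean(axis=1).max(axis=1)
        out[lo:hi] = fine - 0.5 * (coarse_a + coarse_b)
    return out


def fit_level_decay(
    stats: list[MlmcLevelStats], quantity: str = "mean"
) -> tuple[float, float, float]:
    """Weighted log2-linear fit of |mean_diff| (or var_diff) vs level.

    Fits log2 q_l = log2 c - rate*l over the difference levels (l >= 1) by
    least squares, weighting by the inverse squared relative standard error
    of each level mean.  Returns (rate, log2_c, trend_sign).
    """
    diffs = sorted((s for s in stats if s.level >= 1), key=lambda s: s.level)
    if len(diffs) < 2:
        raise ValueError("need at least 2 difference levels (3 levels total) to fit decay")
    levels = np.array([s.level for s in diffs], dtype=float)
    if quantity == "mean":
        values = np.array([s.mean_diff for s in diffs])
    elif quantity == "variance":
        values = np.array([s.var_diff for s in diffs])
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    mags = np.abs(values)
    if np.all(mags == 0):
        return math.inf, -math.inf, 0.0
    floor = mags[mags > 0].min() * 1e-9
    mags = np.maximum(mags, floor)
    if quantity == "mean":
        se = np.array([math.sqrt(max(s.var_diff, 0.0) / max(s.n, 1)) for s in diffs])
        w = 1.0 / np.maximum((se / mags) ** 2, 1e-12)
    else:
        w = np.ones_like(mags)
    y = np.log2(mags)
    wsum = w.sum()
    lbar = (w * levels).sum() / wsum
    ybar = (w * y).sum() / wsum
    denom = (w * (levels - lbar) ** 2).sum()
    if denom == 0:
        raise ValueError("need at least 2 distinct levels")
    slope = (w * (levels - lbar) * (y - ybar)).sum() / denom
    rate = -slope
    log2_c = ybar + rate * lbar
    trend = float(np.sign(values[-1])) or float(np.sign(values.sum()))
    return rate, log2_c, trend


def _bias_beyond(rate: float, log2_c: float, trend: float, level: int) -> float:
    """Remaining telescoping tail sum_{l>level} E[d_l] from the fitted decay."""
    if rate == math.inf:
        return 0.0
    tail = 2.0 ** (log2_c - rate * (level + 1)) / (1.0 - 2.0**-rate)
    return trend * tail


def extrapolate_bias(stats: list[MlmcLevelStats]) -> float:
    """Estimated remaining bias-correction tail beyond the finest level.

    Fits |E[d_l]| ~ c 2^(-alpha l); the tail beyond level L then equals
    |E[d_L]| / (2^alpha - 1) under a perfect fit, signed like the level
    means.  This is the amount the finest-level estimator still *under-*
    corrects by, i.e. estimator bias = minus the returned value.
    """
    alpha, log2_c, trend = fit_level_decay(stats, "mean")
    if trend == 0.0:
        return 0.0
    if alpha <= 0:
        raise ValueError(
            f"level means do not decay (fitted alpha={alpha:.3f}); "
            "increase pilot samples or check the coupling"
        )
    finest = max(s.level for s in stats if s.level >= 1)
    return _bias_beyond(alpha, log2_c, trend, finest)


def optimal_allocation(
    stats: list[MlmcLevelStats], variance_budget: float
) -> dict[int, int]:
    """Per-level outer counts N_l with sum_l V_l/N_l <= variance_budget.

    Standard multilevel allocation: N_l proportional to sqrt(V_l / C_l),
    scaled by sum_j sqrt(V_j C_j) / budget, then ceilinged.
    """
    if variance_budget <= 0:
        raise ValueError("variance budget must be positive")
    scale = sum(math.sqrt(max(s.var_diff, 0.0) * s.cost_per_sample) for s in stats)
    out: dict[int, int] = {}
    for s in stats:
        v = max(s.var_diff, 0.0)
        if v == 0.0 or scale == 0.0:
            out[s.level] = 1
        else:
            out[s.level] = max(1, math.ceil(scale * math.sqrt(v / s.cost_per_sample) / variance_budget))
    return out


def best_decision(
    problem: DecisionProblem, n: int, rng: np.random.Generator
) -> int:
    """Index of the empirically best decision under current information.

    Standalone plain-MC estimate of argmax_d E[f_d(Z)], the anchor of the
    estimator's non-nested second term.  Ties resolve to the lowest index.
    """
    z = problem.params.sample(n, rng)
    return int(np.argmax(problem.net_benefits(z).mean(axis=0)))


def _grow_level(
    acc: _Accumulator,
    problem: DecisionProblem,
    subset: str,
    target_n: int,
    rng: np.random.Generator,
    d_star: int | None = None,
) -> int:
    extra = target_n - acc.n
    if extra <= 0:
        return 0
    draws = level_difference_samples(problem, subset, acc.level, extra, rng, d_star)
    acc.add(draws)
    return extra * 2**acc.level


#: cap on nb evaluations spent refining any single pilot level
_PILOT_LEVEL_BUDGET = 8_000_000


def _remaining_bias(
    accs: dict[int, "_Accumulator"], level: int, tail_beyond_top: float
) -> float:
    """Telescoping tail beyond ``level``: simulated level means plus the
    fitted extrapolation beyond the finest simulated level."""
    top = max(accs)
    partial = sum(accs[l].mean for l in range(level + 1, top + 1))
    return partial + tail_beyond_top


def mlmc_pilot(
    problem: DecisionProblem,
    subset: str,
    epsilon: float,
    rng: np.random.Generator,
    max_level: int = MAX_LEVEL_DEFAULT,
    pilot_n: int = PILOT_DRAWS,
    d_star: int | None = None,
) -> tuple[dict[int, _Accumulator], int, tuple[float, float, float], int, float]:
    """Find the coarsest level L whose remaining bias is within eps/2.

    Levels are added until the *extrapolated* tail beyond the finest
    simulated level is a small fraction of the bias bound, and each level's
    mean is refined until its standard error resolves either the bound or
    the mean itself.  The remaining bias beyond a candidate level is then the
    sum of the directly simulated level means above it plus the fitted tail,
    which is far more robust than extrapolating from the first few levels.

    Returns (accumulators, target level, decay fit, nb-evaluation cost,
    remaining bias at the target level).
    """
    bias_bound = epsilon / 2.0
    accs: dict[int, _Accumulator] = {}
    cost = 0
    for lev in (0, 1, 2):
        accs[lev] = _Accumulator(lev)
        cost += _grow_level(accs[lev], problem, subset, pilot_n, rng, d_star)
    for _ in range(12 * (max_level + 4)):
        # refine noisy level means: se must resolve the bound or the mean
        grew = False
        for lev in sorted(accs):
            if lev == 0:
                continue
            acc = accs[lev]
            if acc.n < 2:
                continue
            cap = max(pilot_n, _PILOT_LEVEL_BUDGET // 2**lev)
            # d_l draws are spiky (decision flips are rare events), so small
            # pilots can badly underestimate both mean and variance: insist
            # on a floor before trusting the standard-error rule
            floor_n = min(cap, max(pilot_n, 1000))
            if acc.n < floor_n:
                cost += _grow_level(acc, problem, subset, floor_n, rng, d_star)
                grew = True
            se = math.sqrt(acc.var / acc.n)
            tol = max(bias_bound / 3.0, abs(acc.mean) / 4.0)
            if se > tol and acc.n < cap:
                want = min(cap, 10 * acc.n, math.ceil(acc.var / tol**2) + 1)
                if want > acc.n:
                    cost += _grow_level(acc, problem, subset, want, rng, d_star)
                    grew = True
        stats = [a.stats() for a in accs.values()]
        try:
            fit = fit_level_decay(stats, "mean")
        except ValueError:
            fit = None
        top = max(accs)
        if fit is None or fit[0] <= 0:
            if grew:
                continue
            if top < max_level:
                accs[top + 1] = _Accumulator(top + 1)
                cost += _grow_level(accs[top + 1], problem, subset, pilot_n, rng, d_star)
                continue
            raise ValueError(
                "pilot level means do not decay; cannot bound the bias "
                f"for subset {subset!r} (try a larger epsilon)"
            )
        alpha, log2_c, trend = fit
        tail = _bias_beyond(alpha, log2_c, trend, top)
        if abs(tail) > 0.5 * bias_bound:
            if top < max_level:
                accs[top + 1] = _Accumulator(top + 1)
                cost += _grow_level(accs[top + 1], problem, subset, pilot_n, rng, d_star)
                continue
            if abs(tail) > bias_bound:
                raise ValueError(
                    f"bias bound {bias_bound:.3g} unreachable within max level "
                    f"{max_level}; use a larger epsilon"
                )
        if grew:
            continue
        for lev in range(0, top + 1):
            remaining = _remaining_bias(accs, lev, tail)
            if abs(remaining) <= bias_bound:
                return accs, lev, (alpha, log2_c, trend), cost, remaining
    raise ValueError("multilevel pilot failed to settle on a level count")


def choose_inner_samples(
    problem: DecisionProblem,
    subset: str,
    epsilon: float,
    stream: np.random.Generator | int | None = None,
    max_level: int = MAX_LEVEL_DEFAULT,
    pilot_n: int = PILOT_DRAWS,
) -> tuple[int, float, list[MlmcLevelStats]]:
    """Inner-sample count M = 2**L bounding the nested bias by eps/2.

    Runs the multilevel bias pilot and returns (M, signed remaining bias at
    that M, level stats).  This is the calibration step shared by the plain
    nested-MC and QMC workflows, which cannot estimate their own bias.
    """
    rng = stream if isinstance(stream, np.random.Generator) else np.random.default_rng(stream)
    accs, target, _fit, _cost, remaining = mlmc_pilot(
        problem, subset, epsilon, rng, max_level, pilot_n
    )
    return 2**target, remaining, [a.stats() for a in sorted(accs.values(), key=lambda a: a.level)]


def mlmc_evppi(
    problem: DecisionProblem,
    subset: str,
    epsilon: float,
    stream: np.random.Generator | int | None = None,
    max_level: int = MAX_LEVEL_DEFAULT,
    pilot_n: int = PILOT_DRAWS,
    max_refinements: int = 8,
) -> tuple[VoiEstimate, list[MlmcLevelStats]]:
    """Adaptive multilevel EVPPI estimate with RMSE target ``epsilon``.

    A standalone plain-MC run first identifies the best decision under
    current information, d* = argmax_d E[f_d(Z)]; the non-nested second term
    is then coupled into the level-0 stream per draw as max_d f_d - f_{d*},
    which removes the common net-benefit shift and keeps the level-0
    variance on the scale of the information value itself.  The level count
    L is grown until the remaining bias (simulated level means above L plus
    the extrapolated tail) is below eps/2; outer counts N_l come from the
    optimal allocation so the total variance is below 3 eps^2/4.  With a
    fixed master seed the whole adaptive run is deterministic.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = stream if isinstance(stream, np.random.Generator) else np.random.default_rng(stream)
    variance_budget = 0.75 * epsilon**2

    n_anchor = 4000
    d_star = best_decision(problem, n_anchor, rng)
    cost0 = n_anchor

    accs, target, fit, cost, _remaining0 = mlmc_pilot(
        problem, subset, epsilon, rng, max_level, pilot_n, d_star
    )
    cost += cost0

    for _ in range(max_refinements):
        level_stats = [accs[lev].stats() for lev in sorted(accs) if lev <= target]
        need_more = False
        for lev, n_req in optimal_allocation(level_stats, variance_budget).items():
            grown = _grow_level(accs[lev], problem, subset, n_req, rng, d_star)
            if grown:
                cost += grown
                need_more = True
        if not need_more:
            break

    # the pilot's remaining-bias estimate was formed under controlled level
    # standard errors; keep it (post-refinement re-fits over-weight the now
    # ultra-precise low levels and extrapolate the tail poorly)
    remaining = _remaining0
    final_stats = [a.stats() for a in sorted(accs.values(), key=lambda a: a.level)]
    alpha = fit[0]
    try:
        beta_rate, _, _ = fit_level_decay(final_stats, "variance")
    except ValueError:
        beta_rate = math.nan

    used = [accs[lev] for lev in sorted(accs) if lev <= target]
    estimate = float(sum(a.mean for a in used))
    var_est = sum(a.var / a.n for a in used if a.n > 0)
    se = math.sqrt(var_est)
    bias_estimate = None if math.isnan(remaining) else -remaining

    est = VoiEstimate(
        estimate=estimate,
        std_error=se,
        n_outer=sum(a.n for a in used),
        n_inner=2**target,
        total_nb_evaluations=cost,
        method="mlmc_evppi",
        bias_estimate=bias_estimate,
        diagnostics={
            "subset": subset,
            "epsilon": epsilon,
            "L": target,
            "alpha": alpha,
            "beta": beta_rate,
            "d_star": problem.decisions[d_star],
            "d_star_n": n_anchor,
            "levels": [
                {"level": s.level, "n": s.n, "mean_diff": s.mean_diff,
                 "var_diff": s.var_diff, "cost_per_sample": s.cost_per_sample}
                for s in final_stats
            ],
        },
    )
    return est, final_stats


def level_table(stats: list[MlmcLevelStats]):
    """Per-level convergence diagnostics as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "level": s.level,
                "n": s.n,
                "mean_diff": s.mean_diff,
                "var_diff": s.var_diff,
                "cost_per_sample": s.cost_per_sample,
            }
            for s in sorted(stats, key=lambda s: s.level)
        ]
    )


def plot_level_decay(stats: list[MlmcLevelStats], ax=None):
    """log2 |mean| and log2 variance of the level differences vs level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    diffs = [s for s in sorted(stats, key=lambda s: s.level) if s.level >= 1]
    levels = [s.level for s in diffs]
    ax.plot(levels, [math.log2(max(abs(s.mean_diff), 1e-300)) for s in diffs],
            "o-", label="log2 |mean d_l|")
    ax.plot(levels, [math.log2(max(s.var_diff, 1e-300)) for s in diffs],
            "s--", label="log2 var d_l")
    ax.set_xlabel("level l (inner samples M = 2^l)")
    ax.legend()
    return ax
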