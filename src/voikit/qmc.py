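"""Low-discrepancy point sets and randomized QMC estimators of EVPI/EVPPI.

Two generators are provided: Sobol sequences (Joe–Kuo direction numbers, via
scipy) and rank-1 lattice rules.  For dimensions s < 40 the Sobol sequence
has the dyadic balance property: the subsequence 2^m <= n < 2^(m+1) places
exactly 2^(m-s) points in each of the 2^s cubes formed by bisecting the unit
hypercube in every dimension (for m >= s).

Randomized QMC draws K independently scrambled replicates of the point set,
transforms each into outer parameter draws through the inverse-CDF/Cholesky
map, and averages the K per-replicate estimates; the replicate spread gives
the standard error.  Scrambling defaults to a digital shift — a bitwise
exclusive-or of every point with one random dyadic vector per replicate,
which preserves the balance property — with nested (Owen) scrambling
available as an option.  QMC is applied to the *outer* samples only; inner
conditional draws stay pseudo-random.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc as _scipy_qmc

from .models import DecisionProblem
from .nested_mc import VoiEstimate, evppi_from_outer

__all__ = [
    "QmcPointSet",
    "lattice_points",
    "sobol_points",
    "digital_shift",
    "rqmc_evpi",
    "rqmc_evppi",
    "population_scale",
]

_SOBOL_BITS = 30
_SOBOL_SCALE = 1 << _SOBOL_BITS
DEFAULT_K = 16  # replicate count; 8–32 is the empirically sufficient range


def lattice_points(n: int, z: np.ndarray) -> np.ndarray:
    """Rank-1 lattice rule: row i is frac(i * z / n), i = 0..n-1.

    Every component of the generating vector ``z`` must be coprime with
    ``n``, which makes each coordinate a permutation of {0, 1/n, ..., (n-1)/n}
    (in one dimension: equally spaced quantiles).
    """
    z = np.atleast_1d(np.asarray(z, dtype=np.int64))
    for zi in z:
        if math.gcd(int(zi), n) != 1:
            raise ValueError(f"generating-vector component {zi} shares a factor with n={n}")
    i = np.arange(n, dtype=np.int64)[:, None]
    return (i * z[None, :] % n) / float(n)


def sobol_points(
    n: int,
    s: int,
    scramble_seed: int | np.random.Generator | None = None,
    kind: str = "digital_shift",
    skip_origin: bool | None = None,
) -> np.ndarray:
    """First ``n`` points of the s-dimensional Sobol sequence.

    Unscrambled points follow the standard Joe–Kuo direction numbers.  With a
    ``scramble_seed``, points are randomized per ``kind``: ``digital_shift``
    (bitwise XOR with one random dyadic shift, balance-preserving) or ``owen``
    (nested uniform scrambling).  By default the all-zeros first point is
    skipped when no scrambling is applied, because a boundary point breaks
    inverse-CDF transforms; pass ``skip_origin=False`` to index the raw
    sequence from 0 (needed when checking balance over dyadic subsequences).
    """
    if s >= 40:
        warnings.warn(
            f"dimension {s} >= 40: the dyadic balance property is no longer guaranteed",
            UserWarning,
            stacklevel=2,
        )
    if kind not in ("digital_shift", "owen"):
        raise ValueError(f"unknown scrambling kind {kind!r}")
    if scramble_seed is None:
        skip = True if skip_origin is None else skip_origin
        eng = _scipy_qmc.Sobol(d=s, scramble=False, bits=_SOBOL_BITS)
        if skip:
            eng.fast_forward(1)
        return eng.random(n)
    rng = (
        scramble_seed
        if isinstance(scramble_seed, np.random.Generator)
        else np.random.default_rng(scramble_seed)
    )
    if kind == "owen":
        eng = _scipy_qmc.Sobol(d=s, scramble=True, bits=_SOBOL_BITS, rng=rng)
        return eng.random(n)
    raw = _scipy_qmc.Sobol(d=s, scramble=False, bits=_SOBOL_BITS).random(n)
    return digital_shift(raw, rng)


def digital_shift(points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Digitally shift a dyadic point set: bitwise XOR with one random vector.

    Each coordinate is interpreted as a 30-bit binary fraction and XOR-ed
    with a random 30-bit word drawn once per dimension, which uniformly
    randomizes the points while preserving dyadic balance.
    """
    points = np.asarray(points, dtype=float)
    ints = (points * _SOBOL_SCALE).astype(np.int64)
    shift = rng.integers(0, _SOBOL_SCALE, size=points.shape[-1], dtype=np.int64)
    return (ints ^ shift) / float(_SOBOL_SCALE)


@dataclass(frozen=True)
class QmcPointSet:
    """K replicated low-discrepancy point sets, each N x s in [0, 1)."""

    kind: str
    dim: int
    n: int
    k: int
    points: np.ndarray  # (k, n, dim)

    @classmethod
    def sobol(
        cls,
        n: int,
        dim: int,
        k: int,
        master_seed: int | np.random.Generator | None = None,
        scramble_kind: str = "digital_shift",
    ) -> "QmcPointSet":
        rng = (
            master_seed
            if isinstance(master_seed, np.random.Generator)
            else np.random.default_rng(master_seed)
        )
        pts = np.stack(
            [sobol_points(n, dim, scramble_seed=rng, kind=scramble_kind) for _ in range(k)]
        )
        return cls("sobol", dim, n, k, pts)

    @classmethod
    def lattice(
        cls,
        n: int,
        z: np.ndarray,
        k: int,
        master_seed: int | np.random.Generator | None = None,
    ) -> "QmcPointSet":
        """Lattice replicates randomized by a uniform (Cranley–Patterson) shift."""
        rng = (
            master_seed
            if isinstance(master_seed, np.random.Generator)
            else np.random.default_rng(master_seed)
        )
        base = lattice_points(n, z)
        pts = np.stack([(base + rng.random(base.shape[1])) % 1.0 for _ in range(k)])
        return cls("lattice", base.shape[1], n, k, pts)


def _replicate_points(
    kind: str,
    n: int,
    dim: int,
    k: int,
    rng: np.random.Generator,
    z: np.ndarray | None = None,
    scramble_kind: str = "digital_shift",
) -> QmcPointSet:
    if kind == "sobol":
        return QmcPointSet.sobol(n, dim, k, rng, scramble_kind)
    if kind == "lattice":
        if z is None:
            # simple default generating vector (Korobov form with a fixed
            # multiplier); adequate for the moderate dimensions used here
            a = 1571
            z = np.array([pow(a, j, n) if math.gcd(pow(a, j, n), n) == 1 else 1
                          for j in range(dim)], dtype=np.int64)
            z[z == 0] = 1
        return QmcPointSet.lattice(n, z, k, rng)
    raise ValueError(f"unknown generator kind {kind!r}")


def rqmc_evpi(
    problem: DecisionProblem,
    n: int,
    k_reps: int = DEFAULT_K,
    master_seed: int | np.random.Generator | None = None,
    kind: str = "sobol",
) -> VoiEstimate:
    """EVPI from K randomized QMC replicates of N outer points.

    Each replicate transforms a scrambled point set into joint parameter
    draws and evaluates the plain EVPI estimator; the mean over replicates is
    the estimate and the replicate spread gives SE = sd / sqrt(K).
    """
    if k_reps < 1:
        raise ValueError("need at least one replicate")
    rng = (
        master_seed
        if isinstance(master_seed, np.random.Generator)
        else np.random.default_rng(master_seed)
    )
    pset = _replicate_points(kind, n, problem.params.dim, k_reps, rng)
    reps = np.empty(k_reps)
    for k in range(k_reps):
        theta = problem.params.transform(pset.points[k])
        nb = problem.net_benefits(theta)
        reps[k] = nb.max(axis=1).mean() - nb.mean(axis=0).max()
    estimate = float(reps.mean())
    if k_reps >= 2:
        se = float(reps.std(ddof=1) / math.sqrt(k_reps))
    else:
        se = math.nan
        warnings.warn("K < 2 replicates: no standard error available", UserWarning)
    return VoiEstimate(
        estimate=estimate,
        std_error=se,
        n_outer=n,
        n_inner=1,
        k_reps=k_reps,
        total_nb_evaluations=n * k_reps,
        method=f"evpi_rqmc_{kind}",
        diagnostics={"replicates": reps.tolist()},
    )


def rqmc_evppi(
    problem: DecisionProblem,
    subset: str,
    n_outer: int,
    n_inner: int,
    k_reps: int = DEFAULT_K,
    master_seed: int | np.random.Generator | None = None,
    kind: str = "sobol",
    bias_estimate: float | None = None,
) -> VoiEstimate:
    """EVPPI with QMC outer samples and pseudo-random inner samples.

    The outer subset draws of each of the K replicates come from an
    independently scrambled point set through the inverse-CDF/Cholesky map;
    the M inner conditional draws remain pseudo-random.  ``bias_estimate``
    (E[estimator] - truth, typically minus the multilevel extrapolated tail
    at matched M) widens the credible interval when supplied.
    """
    if k_reps < 1:
        raise ValueError("need at least one replicate")
    rng = (
        master_seed
        if isinstance(master_seed, np.random.Generator)
        else np.random.default_rng(master_seed)
    )
    sampler = problem.conditional_sampler(subset)
    x_spec = sampler.marginal_x()
    pset = _replicate_points(kind, n_outer, x_spec.dim, k_reps, rng)
    reps = np.empty(k_reps)
    for k in range(k_reps):
        x = x_spec.transform(pset.points[k])
        reps[k], _ = evppi_from_outer(problem, subset, x, n_inner, rng)
    estimate = float(reps.mean())
    if k_reps >= 2:
        se = float(reps.std(ddof=1) / math.sqrt(k_reps))
    else:
        se = math.nan
        warnings.warn("K < 2 replicates: no standard error available", UserWarning)
    return VoiEstimate(
        estimate=estimate,
        std_error=se,
        n_outer=n_outer,
        n_inner=n_inner,
        k_reps=k_reps,
        total_nb_evaluations=n_outer * n_inner * k_reps,
        method=f"evppi_rqmc_{kind}",
        bias_estimate=bias_estimate,
        diagnostics={"subset": subset, "replicates": reps.tolist()},
    )


def population_scale(
    per_person: float,
    annual_patients: float,
    discount_factor: float = 1.035,
    horizon_years: int = 10,
) -> float:
    """Scale a per-person value to the discounted population over a horizon.

    Returns per_person * sum_{t=0}^{horizon-1} annual_patients / discount^t:
    the effective number of patients over the technology lifetime, times the
    per-person value of information.
    """
    if discount_factor < 1:
        raise ValueError("discount factor must be >= 1")
    if horizon_years < 1:
        raise ValueError("horizon must be at least one year")
    t = np.arange(horizon_years)
    return float(per_person * annual_patients * np.sum(discount_factor ** -t))
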