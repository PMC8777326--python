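"""Distribution primitives for decision-model parameter vectors.

A parameter vector Z is described by an ordered sequence of independent
*blocks*: univariate Beta or Normal components, or multivariate-Normal (MVN)
blocks whose components are correlated.  The block order fixes a canonical
coordinate system, so a row of uniforms in [0,1)^s maps deterministically to a
parameter draw — this is what lets low-discrepancy point sets drive sampling.

The module provides

* inverse-CDF transforms (uniforms -> parameters), with MVN blocks mapped
  through a componentwise standard-normal quantile followed by a fixed
  lower-triangular Cholesky factor;
* exact Gaussian conditioning of MVN blocks (Schur complement);
* a :class:`ConditionalSampler` that draws the complement Y of a parameter
  subset X given X = x, used by nested estimators of partial-information value;
* moment-matching of an MVN block to a table of MCMC posterior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "BetaBlock",
    "NormalBlock",
    "MvnBlock",
    "DistributionSpec",
    "ConditionalSampler",
    "inverse_cdf_transform",
    "mvn_condition",
    "fit_mvn",
]

# Uniforms are clamped away from {0, 1} before quantile transforms so that
# scrambled QMC points on the boundary cannot produce infinite parameters.
_UNIFORM_EPS = np.finfo(float).eps


def _clamp_uniforms(u: np.ndarray) -> np.ndarray:
    return np.clip(u, _UNIFORM_EPS, 1.0 - _UNIFORM_EPS)


@dataclass(frozen=True)
class BetaBlock:
    """Univariate Beta(a, b) component."""

    name: str
    a: float
    b: float

    @property
    def names(self) -> tuple[str, ...]:
        return (self.name,)

    @property
    def dim(self) -> int:
        return 1

    def transform(self, u: np.ndarray) -> np.ndarray:
        return stats.beta.ppf(_clamp_uniforms(u), self.a, self.b)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.a, self.b, size=(n, 1))


@dataclass(frozen=True)
class NormalBlock:
    """Univariate Normal(mean, sd) component."""

    name: str
    mean: float
    sd: float

    @property
    def names(self) -> tuple[str, ...]:
        return (self.name,)

    @property
    def dim(self) -> int:
        return 1

    def transform(self, u: np.ndarray) -> np.ndarray:
        return self.mean + self.sd * stats.norm.ppf(_clamp_uniforms(u))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self.sd * rng.standard_normal((n, 1))


@dataclass(frozen=True)
class MvnBlock:
    """Correlated multivariate-Normal block.

    The lower-triangular Cholesky factor of ``cov`` fixes how consecutive
    uniform coordinates map to components, so QMC runs are reproducible
    bit-for-bit given seeds.
    """

    block_names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    _chol: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "block_names", tuple(self.block_names))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size) or mean.size != len(self.block_names):
            raise ValueError(
                f"MVN block {self.block_names}: inconsistent mean/cov/name dimensions"
            )
        if not np.allclose(cov, cov.T):
            raise ValueError(f"MVN block {self.block_names}: covariance not symmetric")
        try:
            chol = linalg.cholesky(cov, lower=True)
        except linalg.LinAlgError as exc:
            # PSD-but-singular covariances (e.g. fitted to degenerate MCMC
            # tables) get a negligible diagonal jitter; indefinite ones fail
            eigs = linalg.eigvalsh(cov)
            scale = max(abs(eigs[-1]), 1.0)
            if eigs[0] < -1e-10 * scale:
                raise ValueError(
                    f"MVN block {self.block_names}: covariance not positive semi-definite"
                ) from exc
            jitter = 1e-12 * scale * np.eye(mean.size)
            chol = linalg.cholesky(cov + jitter, lower=True)
        object.__setattr__(self, "_chol", chol)

    @property
    def names(self) -> tuple[str, ...]:
        return self.block_names

    @property
    def dim(self) -> int:
        return len(self.block_names)

    @property
    def cholesky(self) -> np.ndarray:
        return self._chol

    def transform(self, u: np.ndarray) -> np.ndarray:
        z = stats.norm.ppf(_clamp_uniforms(u))
        return self.mean + z @ self._chol.T

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.dim))
        return self.mean + z @ self._chol.T


Block = BetaBlock | NormalBlock | MvnBlock


class DistributionSpec:
    """Ordered collection of independent distribution blocks for Z."""

    def __init__(self, blocks: Iterable[Block]):
        self.blocks: tuple[Block, ...] = tuple(blocks)
        names: list[str] = []
        for block in self.blocks:
            names.extend(block.names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names across blocks")
        self.names: tuple[str, ...] = tuple(names)
        self._index = {name: i for i, name in enumerate(names)}
        # column span of each block in the canonical coordinate order
        self._spans: list[tuple[int, int]] = []
        start = 0
        for block in self.blocks:
            self._spans.append((start, start + block.dim))
            start += block.dim

    @property
    def dim(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def transform(self, uniforms: np.ndarray) -> np.ndarray:
        """Map an (n, s) array of uniforms to parameter draws."""
        u = np.atleast_2d(np.asarray(uniforms, dtype=float))
        if u.shape[1] != self.dim:
            raise ValueError(
                f"uniform array has width {u.shape[1]}, expected {self.dim}"
            )
        out = np.empty_like(u)
        for block, (lo, hi) in zip(self.blocks, self._spans):
            out[:, lo:hi] = block.transform(u[:, lo:hi])
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty((n, self.dim))
        for block, (lo, hi) in zip(self.blocks, self._spans):
            out[:, lo:hi] = block.sample(n, rng)
        return out

    def marginal(self, names: Sequence[str]) -> "DistributionSpec":
        """Marginal law of a subset, in canonical coordinate order.

        Partial MVN blocks marginalise to the sub-mean / sub-covariance MVN.
        """
        wanted = set(names)
        unknown = wanted - set(self.names)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)}")
        blocks: list[Block] = []
        for block in self.blocks:
            keep = [i for i, nm in enumerate(block.names) if nm in wanted]
            if not keep:
                continue
            if len(keep) == block.dim or not isinstance(block, MvnBlock):
                if isinstance(block, MvnBlock) and len(keep) < block.dim:
                    raise AssertionError  # unreachable: non-MVN blocks are scalar
                blocks.append(block)
            else:
                idx = np.array(keep)
                blocks.append(
                    MvnBlock(
                        tuple(block.names[i] for i in keep),
                        block.mean[idx],
                        block.cov[np.ix_(idx, idx)],
                    )
                )
        return DistributionSpec(blocks)

    def mean(self) -> np.ndarray:
        """Componentwise means (Beta mean a/(a+b); Normal/MVN mean)."""
        out = np.empty(self.dim)
        for block, (lo, hi) in zip(self.blocks, self._spans):
            if isinstance(block, BetaBlock):
                out[lo:hi] = block.a / (block.a + block.b)
            else:
                out[lo:hi] = np.atleast_1d(block.mean)
        return out


def inverse_cdf_transform(uniforms: np.ndarray, spec: DistributionSpec) -> np.ndarray:
    """Inverse-CDF map of uniforms in [0,1)^s to parameter draws under ``spec``."""
    return spec.transform(uniforms)


def mvn_condition(
    mean: np.ndarray,
    cov: np.ndarray,
    observed_index_set: Sequence[int],
    observed_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian conditioning of N(mean, cov) on a set of components.

    Returns the conditional mean and covariance of the unobserved components
    given the observed ones.  The conditional covariance (the Schur complement
    of the observed sub-matrix) does not depend on the observed values.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    obs = np.asarray(sorted(observed_index_set), dtype=int)
    k = mean.size
    if obs.size == 0:
        return mean.copy(), cov.copy()
    if obs.size >= k:
        raise ValueError("observed index set must be a proper subset")
    free = np.setdiff1d(np.arange(k), obs)
    s_oo = cov[np.ix_(obs, obs)]
    s_fo = cov[np.ix_(free, obs)]
    s_ff = cov[np.ix_(free, free)]
    try:
        solve = linalg.cho_solve(linalg.cho_factor(s_oo, lower=True), np.eye(obs.size))
    except linalg.LinAlgError as exc:
        raise ValueError("observed block of covariance is singular") from exc
    gain = s_fo @ solve
    x = np.asarray(observed_values, dtype=float)
    cond_mean = mean[free] + (x - mean[obs]) @ gain.T
    cond_cov = s_ff - gain @ s_fo.T
    return cond_mean, cond_cov


def fit_mvn(
    samples: pd.DataFrame | np.ndarray,
    names: Sequence[str] | None = None,
    skew_threshold: float = 1.0,
) -> MvnBlock:
    """Moment-match an MVN block to a table of posterior draws.

    Rows are MCMC iterations, columns are named parameters.  A warning is
    emitted when any marginal's sample skewness exceeds ``skew_threshold`` —
    a crude adequacy check for the multivariate-normal approximation, which is
    typically reasonable for effects on a log-odds or log-hazard scale.
    """
    if isinstance(samples, pd.DataFrame):
        if names is None:
            names = tuple(str(c) for c in samples.columns)
        arr = samples.to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(samples, dtype=float))
        if names is None:
            names = tuple(f"x{i}" for i in range(arr.shape[1]))
    m, k = arr.shape
    if m <= k:
        raise ValueError(f"need more draws ({m}) than parameters ({k}) to fit an MVN")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample table contains non-finite entries")
    mean = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False)
    cov = np.atleast_2d(cov)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = stats.skew(arr, axis=0)
    bad = np.flatnonzero(np.abs(np.nan_to_num(skew)) > skew_threshold)
    if bad.size:
        flagged = ", ".join(f"{names[i]} (skew {skew[i]:.2f})" for i in bad)
        warnings.warn(
            f"marginal skewness exceeds {skew_threshold}: {flagged}; "
            "the multivariate-normal approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    return MvnBlock(tuple(names), mean, cov)


class ConditionalSampler:
    """Sampler for the complement Y of a parameter subset X, given X = x.

    Blocks wholly outside the subset are independent of X and are drawn from
    their marginals.  When the subset splits a correlated MVN block, the
    complement components are drawn from the exact conditional MVN, whose mean
    is affine in the observed components and whose covariance is fixed.

    :meth:`sample_full` assembles complete parameter vectors in the canonical
    coordinate order, broadcasting each outer draw x over ``m`` inner draws.
    """

    def __init__(self, spec: DistributionSpec, subset_names: Sequence[str]):
        subset = set(subset_names)
        unknown = subset - set(spec.names)
        if unknown:
            raise KeyError(f"unknown parameters in subset: {sorted(unknown)}")
        if not subset:
            raise ValueError("subset must be non-empty")
        self.spec = spec
        # canonical (spec-ordered) subset columns; x arrays use this order
        self.subset_names = tuple(n for n in spec.names if n in subset)
        self.subset_indices = spec.indices(self.subset_names)
        self.complement_names = tuple(n for n in spec.names if n not in subset)
        self.complement_indices = spec.indices(self.complement_names)
        x_pos = {name: j for j, name in enumerate(self.subset_names)}

        self._independent: list[tuple[Block, np.ndarray]] = []
        # split MVN blocks: (free cols in Z, obs cols in x, gain, cond mean offset,
        # Cholesky of conditional covariance)
        self._split: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for block in spec.blocks:
            in_x = [nm in subset for nm in block.names]
            if all(in_x):
                continue
            cols = spec.indices(block.names)
            if not any(in_x):
                self._independent.append((block, cols))
                continue
            # only MVN blocks have dim > 1, so a split block is MVN
            assert isinstance(block, MvnBlock)
            obs = np.flatnonzero(in_x)
            free = np.flatnonzero(~np.asarray(in_x))
            cond_mean0, cond_cov = mvn_condition(
                block.mean, block.cov, obs, block.mean[obs]
            )
            gain = np.linalg.solve(
                block.cov[np.ix_(obs, obs)], block.cov[np.ix_(obs, free)]
            ).T  # (free, obs)
            chol = linalg.cholesky(cond_cov, lower=True)
            x_cols = np.array([x_pos[block.names[i]] for i in obs])
            self._split.append(
                (cols[free], x_cols, gain, block.mean, (obs, free, chol))
            )

    @property
    def x_dim(self) -> int:
        return len(self.subset_names)

    @property
    def y_dim(self) -> int:
        return len(self.complement_names)

    def marginal_x(self) -> DistributionSpec:
        """Marginal law of the subset X (used to drive X from QMC points)."""
        return self.spec.marginal(self.subset_names)

    def sample_x(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.marginal_x().sample(n, rng)

    def sample_full(
        self, x: np.ndarray, m: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw full parameter vectors Z = (X, Y) with Y ~ law(Y | X = x).

        Parameters
        ----------
        x : (n, x_dim) outer draws of the subset, canonical order.
        m : inner draws per outer draw.

        Returns
        -------
        (n, m, s) array in the spec's canonical coordinate order.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.x_dim:
            raise ValueError(f"x has width {x.shape[1]}, expected {self.x_dim}")
        n = x.shape[0]
        z = np.empty((n, m, self.spec.dim))
        z[:, :, self.subset_indices] = x[:, None, :]
        for block, cols in self._independent:
            draws = block.sample(n * m, rng).reshape(n, m, block.dim)
            z[:, :, cols] = draws
        for free_cols, x_cols, gain, mean, (obs, free, chol) in self._split:
            xo = x[:, x_cols]
            cond_mean = mean[free] + (xo - mean[obs]) @ gain.T  # (n, |free|)
            eps = rng.standard_normal((n, m, free.size))
            z[:, :, free_cols] = cond_mean[:, None, :] + eps @ chol.T
        return z
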