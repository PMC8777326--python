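"""Decision-model contract and the two built-in models.

A :class:`DecisionProblem` bundles everything a value-of-information estimator
needs: the decision options D, a vectorised net-monetary-benefit function
f_d(Z), the joint law of the parameter vector Z, the willingness-to-pay
threshold λ, and named subsets X of Z for partial-information queries.

Two models ship with the package:

* the depression treatment decision tree — three options (no treatment,
  cognitive behavioural therapy, antidepressants), a 12-dimensional parameter
  vector mixing Beta event probabilities, correlated log-odds-ratio blocks
  from a network meta-analysis posterior, and Normal 30-year costs/QALYs;
* a linear-Gaussian toy model with closed-form EVPI and EVPPI, used as an
  analytic oracle in the test-suite.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats
from scipy.special import expit, logit

from .distributions import (
    BetaBlock,
    ConditionalSampler,
    DistributionSpec,
    MvnBlock,
    NormalBlock,
)

__all__ = [
    "DecisionProblem",
    "DepressionParams",
    "ToyModelSpec",
    "net_benefit",
    "sample_parameters",
    "depression_spec",
    "depression_model",
    "toy_model",
    "toy_closed_form",
    "load_problem",
    "PARAM_ORDER",
]

DEFAULT_WTP = 20_000.0  # GBP per QALY; conventional threshold


@dataclass(frozen=True)
class DecisionProblem:
    """A cost-effectiveness decision problem for value-of-information analysis.

    ``net_benefits`` maps an (..., s) array of parameter vectors (canonical
    coordinate order of ``params``) to an (..., |D|) array of net monetary
    benefits, one column per decision in ``decisions`` order.
    """

    decisions: tuple
    net_benefits: Callable[[np.ndarray], np.ndarray]
    params: DistributionSpec
    wtp: float
    subsets: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        if not self.decisions:
            raise ValueError("decision set must be non-empty")
        for sub, names in self.subsets.items():
            if not names:
                raise ValueError(f"subset {sub!r} is empty")
            unknown = set(names) - set(self.params.names)
            if unknown:
                raise ValueError(f"subset {sub!r} has unknown parameters {unknown}")

    @property
    def n_decisions(self) -> int:
        return len(self.decisions)

    def subset_names(self, subset: str) -> tuple[str, ...]:
        try:
            return tuple(self.subsets[subset])
        except KeyError:
            raise KeyError(
                f"unknown subset {subset!r}; known: {sorted(self.subsets)}"
            ) from None

    def conditional_sampler(self, subset: str | Sequence[str]) -> ConditionalSampler:
        names = self.subset_names(subset) if isinstance(subset, str) else tuple(subset)
        return ConditionalSampler(self.params, names)


# ---------------------------------------------------------------------------
# Depression decision tree
# ---------------------------------------------------------------------------

#: Canonical coordinate order of the 12 stochastic parameters.  Correlated
#: log-odds-ratio blocks occupy adjacent coordinates so QMC points map onto
#: them through a single lower-triangular Cholesky factor.
PARAM_ORDER: tuple[str, ...] = (
    "p_rec_1",
    "p_rel_1",
    "lorrec_2",
    "lorrec_3",
    "lorrel_2",
    "lorrel_3",
    "c_rec",
    "c_rel",
    "c_nrec",
    "q_rec",
    "q_rel",
    "q_nrec",
)

C_TREAT = (0.0, 300.0, 30.0)  # fixed initial treatment cost per option, GBP

_SUBSETS = {
    "probabilities": (
        "p_rec_1", "p_rel_1", "lorrec_2", "lorrec_3", "lorrel_2", "lorrel_3",
    ),
    "costs_qalys": ("c_rec", "c_rel", "c_nrec", "q_rec", "q_rel", "q_nrec"),
    "cbt": ("lorrec_2", "lorrel_2"),
    "antidepressant": ("lorrec_3", "lorrel_3"),
    "all": PARAM_ORDER,
}


@dataclass(frozen=True)
class DepressionParams:
    """One parameter draw for the depression tree (natural units).

    Probabilities refer to the no-treatment arm; log odds ratios shift them
    onto the CBT (option 2) and antidepressant (option 3) arms via
    ``expit(logit(p) + lor)``.  Costs and QALYs are 30-year totals for the
    three terminal states: recovery without relapse, recovery with relapse,
    and no recovery.
    """

    p_rec_1: float
    p_rel_1: float
    lorrec_2: float
    lorrec_3: float
    lorrel_2: float
    lorrel_3: float
    c_rec: float
    c_rel: float
    c_nrec: float
    q_rec: float
    q_rel: float
    q_nrec: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_ORDER])


def depression_spec() -> DistributionSpec:
    """Joint distribution of the 12 depression-model parameters.

    Event probabilities on no treatment are Beta; the log-odds-ratio pairs
    (CBT, antidepressant) for recovery and for relapse are the two bivariate
    Normal posterior approximations from the network meta-analysis; 30-year
    costs and QALYs are independent Normals.
    """
    return DistributionSpec(
        [
            BetaBlock("p_rec_1", 6.0, 200.0),
            BetaBlock("p_rel_1", 2.0, 100.0),
            MvnBlock(
                ("lorrec_2", "lorrec_3"),
                [0.99, 1.33],
                [[0.22, 0.15], [0.15, 0.20]],
            ),
            MvnBlock(
                ("lorrel_2", "lorrel_3"),
                [-1.48, -0.40],
                [[0.14, 0.05], [0.05, 0.11]],
            ),
            NormalBlock("c_rec", 1000.0, 50.0),
            NormalBlock("c_rel", 2000.0, 100.0),
            NormalBlock("c_nrec", 2500.0, 125.0),
            NormalBlock("q_rec", 26.0, 2.0),
            NormalBlock("q_rel", 23.0, 3.0),
            NormalBlock("q_nrec", 20.0, 4.0),
        ]
    )


def _depression_nb_all(theta: np.ndarray, wtp: float, c_treat: Sequence[float]) -> np.ndarray:
    """Net benefit of all three options; theta is (..., 12) in PARAM_ORDER."""
    theta = np.asarray(theta, dtype=float)
    p_rec_1 = theta[..., 0]
    p_rel_1 = theta[..., 1]
    lg_rec = logit(p_rec_1)
    lg_rel = logit(p_rel_1)
    out = np.empty(theta.shape[:-1] + (3,))
    for d in range(3):
        if d == 0:
            p_rec, p_rel = p_rec_1, p_rel_1
        else:
            p_rec = expit(lg_rec + theta[..., 1 + d])   # lorrec_2 / lorrec_3
            p_rel = expit(lg_rel + theta[..., 3 + d])   # lorrel_2 / lorrel_3
        rec_norel = p_rec * (1.0 - p_rel)
        rec_rel = p_rec * p_rel
        nrec = 1.0 - p_rec
        qaly = rec_norel * theta[..., 9] + rec_rel * theta[..., 10] + nrec * theta[..., 11]
        cost = (
            rec_norel * theta[..., 6]
            + rec_rel * theta[..., 7]
            + nrec * theta[..., 8]
            + c_treat[d]
        )
        out[..., d] = wtp * qaly - cost
    return out


def net_benefit(
    params: DepressionParams,
    decision: int,
    wtp: float = DEFAULT_WTP,
    c_treat: Sequence[float] = C_TREAT,
) -> float:
    """Net monetary benefit of one option for one parameter draw (GBP)."""
    if decision not in (1, 2, 3):
        raise ValueError(f"unknown decision {decision!r}; options are 1, 2, 3")
    theta = params.as_array()
    if decision > 1:
        lor_rec = theta[1 + decision - 1]
        lor_rel = theta[3 + decision - 1]
        p_rec = expit(logit(theta[0]) + lor_rec)
        p_rel = expit(logit(theta[1]) + lor_rel)
    else:
        p_rec, p_rel = theta[0], theta[1]
    for label, p in (("recovery", p_rec), ("relapse", p_rel)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"derived {label} probability {p} outside (0, 1)")
    return float(_depression_nb_all(theta, wtp, c_treat)[decision - 1])


def depression_model(
    wtp: float = DEFAULT_WTP, c_treat: Sequence[float] = C_TREAT
) -> DecisionProblem:
    """The built-in depression treatment decision tree."""
    spec = depression_spec()
    c_treat = tuple(float(c) for c in c_treat)

    def nb_all(theta: np.ndarray) -> np.ndarray:
        return _depression_nb_all(theta, wtp, c_treat)

    return DecisionProblem(
        decisions=(1, 2, 3),
        net_benefits=nb_all,
        params=spec,
        wtp=wtp,
        subsets=dict(_SUBSETS),
        name="depression",
    )


def sample_parameters(
    n: int | None = None,
    source: np.random.Generator | np.ndarray | int | None = None,
) -> np.ndarray:
    """Draw depression-model parameter vectors, (n, 12) in PARAM_ORDER.

    ``source`` is either a seeded generator (or seed) for pseudo-random
    sampling, or an (n, 12) array of uniforms in [0, 1) — the latter path lets
    low-discrepancy point sets drive the sampler through the inverse-CDF /
    Cholesky transform.
    """
    spec = depression_spec()
    if isinstance(source, np.ndarray):
        u = np.atleast_2d(source)
        if u.shape[1] != spec.dim:
            raise ValueError(
                f"uniform array has width {u.shape[1]}, expected {spec.dim}"
            )
        return spec.transform(u)
    rng = np.random.default_rng(source)
    if n is None:
        raise ValueError("n is required for pseudo-random sampling")
    return spec.sample(n, rng)


# ---------------------------------------------------------------------------
# Linear-Gaussian toy model (analytic oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyModelSpec:
    """Two decisions: nb(d=1) = 0 and nb(d=2) = X + Y.

    X ~ N(mu_x, sigma_x^2) is the queryable component, Y ~ N(0, sigma_y^2)
    independent noise.  EVPI and EVPPI(X) are available in closed form, which
    makes this the convergence oracle for all estimator families.
    """

    mu_x: float = 0.0
    sigma_x: float = 1.0
    sigma_y: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("standard deviations must be non-negative")


def toy_closed_form(spec: ToyModelSpec) -> tuple[float, float]:
    """Exact (EVPI, EVPPI_X) for the linear-Gaussian toy model.

    With W = X + Y ~ N(mu, s^2), E[max(0, W)] = s·phi(mu/s) + mu·Phi(mu/s),
    so EVPI = E[max(0, W)] − max(0, mu) and EVPPI_X replaces s by sigma_x.
    """
    mu = spec.mu_x
    base = max(mu, 0.0)

    def gain(s: float) -> float:
        if s == 0.0:
            return 0.0
        r = mu / s
        return float(s * stats.norm.pdf(r) + mu * stats.norm.cdf(r)) - base

    evpi = gain(float(np.hypot(spec.sigma_x, spec.sigma_y)))
    evppi_x = gain(spec.sigma_x)
    return evpi, evppi_x


def toy_model(spec: ToyModelSpec = ToyModelSpec()) -> DecisionProblem:
    blocks = [
        NormalBlock("x", spec.mu_x, spec.sigma_x),
        NormalBlock("y", 0.0, spec.sigma_y),
    ]

    def nb_all(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = np.zeros(theta.shape[:-1] + (2,))
        out[..., 1] = theta[..., 0] + theta[..., 1]
        return out

    return DecisionProblem(
        decisions=(1, 2),
        net_benefits=nb_all,
        params=DistributionSpec(blocks),
        wtp=0.0,
        subsets={"x": ("x",), "y": ("y",), "all": ("x", "y")},
        name="toy",
    )


# ---------------------------------------------------------------------------
# YAML/JSON model configuration
# ---------------------------------------------------------------------------

_BUILTINS = {"depression": depression_model, "toy": lambda **kw: toy_model()}


def _spec_from_config(blocks_cfg: Sequence[Mapping]) -> DistributionSpec:
    blocks = []
    for cfg in blocks_cfg:
        kind = cfg["kind"]
        if kind == "beta":
            blocks.append(BetaBlock(cfg["name"], float(cfg["alpha"]), float(cfg["beta"])))
        elif kind == "normal":
            blocks.append(NormalBlock(cfg["name"], float(cfg["mean"]), float(cfg["sd"])))
        elif kind == "mvn":
            blocks.append(MvnBlock(tuple(cfg["names"]), cfg["mean"], cfg["cov"]))
        else:
            raise ValueError(f"unknown block kind {kind!r}")
    return DistributionSpec(blocks)


def load_problem(source: str | Mapping, wtp: float | None = None) -> DecisionProblem:
    """Build a DecisionProblem from a builtin name, YAML path, or config dict.

    The configurable model family is the depression-style decision tree: the
    config supplies the 12 parameter blocks (in canonical order), the fixed
    per-option treatment-cost vector, the willingness-to-pay threshold, and
    the named subsets.
    """
    if isinstance(source, str):
        if source in _BUILTINS:
            kwargs = {} if wtp is None else {"wtp": wtp}
            return _BUILTINS[source](**kwargs)
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if cfg.get("kind", "depression_tree") != "depression_tree":
        raise ValueError(f"unsupported model kind {cfg.get('kind')!r}")
    spec = _spec_from_config(cfg["blocks"])
    if tuple(spec.names) != PARAM_ORDER:
        raise ValueError(
            "depression_tree configs must define exactly the canonical "
            f"parameters in order {PARAM_ORDER}"
        )
    wtp_val = float(wtp if wtp is not None else cfg.get("wtp", DEFAULT_WTP))
    c_treat = tuple(float(c) for c in cfg.get("c_treat", C_TREAT))

    def nb_all(theta: np.ndarray) -> np.ndarray:
        return _depression_nb_all(theta, wtp_val, c_treat)

    subsets = {k: tuple(v) for k, v in cfg.get("subsets", _SUBSETS).items()}
    return DecisionProblem(
        decisions=(1, 2, 3),
        net_benefits=nb_all,
        params=spec,
        wtp=wtp_val,
        subsets=subsets,
        name=str(cfg.get("name", "custom")),
    )


def packaged_config(name: str = "depression") -> dict:
    """Load a model config shipped with the package."""
    text = (
        importlib.resources.files("voikit").joinpath(f"configs/{name}.yaml").read_text()
    )
    return yaml.safe_load(text)
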