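"""Maximum-likelihood fitting, AIC comparison and Δ2 confidence regions.

Likelihood surfaces of hidden-rate models are flat and multimodal, so
rates are optimized on the log10 scale by bounded Nelder-Mead restarted
from log-uniform random draws over the rate bounds; restart seeds derive
from one master seed via a counter so "n random restarts" is exactly
reproducible.  Uncertainty is summarized dentist-style: a random walk in
log-rate space keeps every point whose log-likelihood is within Δ
(default 2) of the maximum, and the per-parameter extremes plus the
accepted-sample covariance (for ridge detection) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import NEG_INF, NodeConstraint, Propagator, RootPrior, _pruning
from .models import RateModel
from .traits import TraitMatrix
from .tree import Phylogeny

__all__ = [
    "FitResult",
    "RestartRecord",
    "ConfidenceRegion",
    "fit_model",
    "fit_with_fixed_node",
    "aic_table",
    "sample_confidence_region",
]


@dataclass
class RestartRecord:
    seed: int
    start_theta: np.ndarray
    end_theta: np.ndarray
    end_lnl: float
    converged: bool
    n_evals: int


@dataclass
class FitResult:
    model: RateModel
    theta: np.ndarray  # rates per Myr at the optimum
    lnl: float
    n_params: int
    restarts: list[RestartRecord]
    seed: int
    root_prior: RootPrior
    constraints: list[NodeConstraint] = field(default_factory=list)
    constrained: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.lnl

    @property
    def aicc(self) -> float:
        # small-sample correction with n = number of tips is debatable for
        # phylogenetic data; reported for reference only
        return self.aic

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "theta": self.theta.tolist(),
            "param_names": self.model.param_names,
            "lnl": self.lnl,
            "n_params": self.n_params,
            "aic": self.aic,
            "seed": self.seed,
            "root_prior": self.root_prior.kind,
            "constrained": self.constrained,
            "restarts": [
                {
                    "seed": r.seed,
                    "end_lnl": r.end_lnl,
                    "converged": r.converged,
                    "n_evals": r.n_evals,
                }
                for r in self.restarts
            ],
        }


class _Objective:
    """Negative log-likelihood over log10 rates, with cached tree tensors."""

    def __init__(self, tree, traits, model, root_prior, constraints):
        self.tree = tree
        self.traits = traits
        self.model = model
        self.root_prior = root_prior
        self.constraints = constraints
        self.n_evals = 0

    def lnl(self, theta: np.ndarray) -> float:
        self.n_evals += 1
        prop = Propagator(self.model.assemble_Q(theta))
        res = _pruning(
            self.tree, self.traits, self.model, prop, self.root_prior, self.constraints
        )
        return res.lnl

    def neg_lnl_log10(self, x: np.ndarray) -> float:
        val = self.lnl(10.0**x)
        if val == NEG_INF or not np.isfinite(val):
            return 1e100
        return -val


def fit_model(
    tree: Phylogeny,
    traits: TraitMatrix,
    model: RateModel,
    n_restarts: int = 10,
    seed: int = 0,
    root_prior: RootPrior = RootPrior("flat"),
    constraints: list[NodeConstraint] | None = None,
    bounds: tuple[float, float] | None = None,
    max_evals: int | None = None,
    start_range: tuple[float, float] | None = None,
) -> FitResult:
    """Fit rates by Nelder-Mead on log10 rates with random restarts.

    Deterministic given (seed, n_restarts); every restart trajectory is
    recorded.  ``start_range`` narrows the log-uniform start
    distribution without narrowing the optimization bounds.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    lo, hi = bounds if bounds is not None else model.bounds
    s_lo, s_hi = start_range if start_range is not None else (lo, hi)
    k = model.n_params
    constraints = list(constraints) if constraints else []
    obj = _Objective(tree, traits, model, root_prior, constraints)
    log_bounds = [(np.log10(lo), np.log10(hi))] * k
    maxfev = max_evals if max_evals is not None else max(400, 250 * k)

    records: list[RestartRecord] = []
    for r in range(n_restarts):
        sub_seed = seed + r
        rng = np.random.default_rng(sub_seed)
        x0 = rng.uniform(np.log10(s_lo), np.log10(s_hi), size=k)
        obj.n_evals = 0
        res = minimize(
            obj.neg_lnl_log10,
            x0,
            method="Nelder-Mead",
            bounds=log_bounds,
            options={"maxfev": maxfev, "fatol": 1e-8, "xatol": 1e-6},
        )
        records.append(
            RestartRecord(
                seed=sub_seed,
                start_theta=10.0**x0,
                end_theta=10.0**res.x,
                end_lnl=-res.fun if res.fun < 1e99 else NEG_INF,
                converged=bool(res.success),
                n_evals=obj.n_evals,
            )
        )
    finite = [r for r in records if np.isfinite(r.end_lnl)]
    if not finite:
        raise RuntimeError(
            "optimizer failed on all restarts; last diagnostics: "
            + "; ".join(f"seed={r.seed} lnl={r.end_lnl}" for r in records)
        )
    best = max(finite, key=lambda r: r.end_lnl)
    return FitResult(
        model=model,
        theta=best.end_theta.copy(),
        lnl=best.end_lnl,
        n_params=k,
        restarts=records,
        seed=seed,
        root_prior=root_prior,
        constraints=constraints,
        constrained=bool(constraints),
    )


def fit_with_fixed_node(
    tree: Phylogeny,
    traits: TraitMatrix,
    model: RateModel,
    constraint: NodeConstraint,
    **kwargs,
) -> FitResult:
    """ML fit with a node fixed to a state set inside every likelihood
    evaluation (e.g. 'the focal ancestor is trait-present, any class')."""
    if not (0 <= constraint.node < tree.n_nodes):
        raise ValueError(f"constraint node {constraint.node} not in tree")
    extra = list(kwargs.pop("constraints", []) or [])
    return fit_model(
        tree, traits, model, constraints=[constraint] + extra, **kwargs
    )


def aic_table(fits: list[FitResult]) -> pd.DataFrame:
    """Model comparison table sorted by AIC (ties: fewer parameters)."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = [
        {"model": f.model.name, "k": f.n_params, "lnl": f.lnl, "aic": f.aic}
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df


@dataclass
class ConfidenceRegion:
    delta: float
    lnl_max: float
    samples: np.ndarray  # (n_accept, k) rates
    lnls: np.ndarray
    lower: np.ndarray  # per-parameter min over accepted
    upper: np.ndarray
    covariance: np.ndarray  # covariance of accepted log10 rates (ridges)

    def contains(self, theta) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))


def sample_confidence_region(
    fit: FitResult,
    tree: Phylogeny,
    traits: TraitMatrix,
    delta: float = 2.0,
    n_samples: int = 1000,
    seed: int = 0,
    step: float = 0.25,
) -> ConfidenceRegion:
    """Random-walk sampling of the Δ-likelihood region around the MLE.

    Proposals are Gaussian steps in log10-rate space; a point is accepted
    iff its log-likelihood is within ``delta`` of the maximum.  The walk
    restarts at the MLE whenever a proposal is rejected, which keeps the
    chain inside the region while still probing its extremes.
    """
    obj = _Objective(tree, traits, fit.model, fit.root_prior, fit.constraints)
    lnl0 = obj.lnl(fit.theta)
    if not np.isfinite(lnl0) or lnl0 < fit.lnl - delta - 1e-6:
        raise ValueError(
            f"fit does not reproduce its own likelihood (got {lnl0}, "
            f"reported {fit.lnl}); refusing to sample around a non-MLE point"
        )
    lnl_max = max(lnl0, fit.lnl)
    k = fit.n_params
    lo, hi = np.log10(fit.model.bounds[0]), np.log10(fit.model.bounds[1])
    rng = np.random.default_rng(seed)
    x_mle = np.log10(fit.theta)
    accepted = [fit.theta.copy()]
    lnls = [lnl0]

    def inside(x):
        val = obj.lnl(10.0**x)
        return (np.isfinite(val) and val >= lnl_max - delta), val

    # seed the walk with per-axis Δ-boundary points found by doubling +
    # bisection (other parameters held at the MLE)
    chain_starts = [x_mle.copy()]
    for i in range(k):
        for sign in (+1.0, -1.0):
            width = step
            x_in = x_mle.copy()
            while width < (hi - lo):
                x_try = x_mle.copy()
                x_try[i] = np.clip(x_mle[i] + sign * width, lo, hi)
                ok, _ = inside(x_try)
                if not ok:
                    break
                x_in = x_try
                if x_try[i] in (lo, hi):
                    break
                width *= 2.0
            else:
                x_try = x_in
            x_out = x_try
            for _ in range(12):  # bisect between inside and outside
                mid = 0.5 * (x_in + x_out)
                ok, val = inside(mid)
                if ok:
                    x_in = mid
                    accepted.append(10.0**mid)
                    lnls.append(val)
                else:
                    x_out = mid
            chain_starts.append(x_in.copy())

    per_chain = max(1, n_samples // len(chain_starts))
    for x0 in chain_starts:
        x = x0.copy()
        for _ in range(per_chain):
            prop = np.clip(x + rng.normal(0.0, step, size=k), lo, hi)
            ok, val = inside(prop)
            if ok:
                x = prop
                accepted.append(10.0**prop)
                lnls.append(val)
            else:
                x = x0.copy()
    samples = np.array(accepted)
    if len(samples) == 0:
        raise ValueError("no accepted samples in the Δ region")
    logs = np.log10(samples)
    cov = np.cov(logs.T) if len(samples) > 1 else np.zeros((k, k))
    return ConfidenceRegion(
        delta=delta,
        lnl_max=lnl_max,
        samples=samples,
        lnls=np.array(lnls),
        lower=samples.min(axis=0),
        upper=samples.max(axis=0),
        covariance=np.atleast_2d(cov),
    )
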