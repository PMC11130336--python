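"""Exact tip-data likelihoods by the pruning algorithm.

The likelihood of the observed tip states under a composite-state
continuous-time Markov chain is computed by Felsenstein's post-order
recursion: each node carries a conditional (partial) likelihood vector
over composite states, children contribute ``P(t) @ partial`` messages,
and the root combines the result with a root prior.  Per-node rescaling
with accumulated log factors keeps 10^4-tip trees away from underflow.

Branch transition probabilities ``P(t) = expm(Q t)`` are computed for
all edges at once from one eigendecomposition of Q per likelihood
evaluation, with a scipy ``expm`` fallback when the eigenvector matrix
is ill-conditioned; zero-length branches get an identity matrix without
an exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .models import RateModel
from .traits import TraitMatrix
from .tree import Phylogeny

__all__ = [
    "RootPrior",
    "NodeConstraint",
    "LikelihoodResult",
    "transition_matrix",
    "tip_partials",
    "tree_loglik",
    "stationary_distribution",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class RootPrior:
    """Weighting of composite states at the root.

    ``flat`` (default): uniform over composite states.  ``stationary``:
    the chain's stationary distribution.  ``fitzjohn``: weights
    proportional to the root's own conditional likelihoods (the
    observed-conditional prior of FitzJohn et al.).  ``user``: an
    explicit probability vector.
    """

    kind: str = "flat"
    vector: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in {"flat", "stationary", "fitzjohn", "user"}:
            raise ValueError(f"unknown root prior kind {self.kind!r}")
        if self.kind == "user":
            if self.vector is None:
                raise ValueError("user prior needs a vector")
            v = np.asarray(self.vector, dtype=float)
            if np.any(v < 0) or not np.isclose(v.sum(), 1.0):
                raise ValueError("user prior must be a probability vector")

    def resolve(self, Q: np.ndarray, root_partial: np.ndarray) -> np.ndarray:
        S = Q.shape[0]
        if self.kind == "flat":
            return np.full(S, 1.0 / S)
        if self.kind == "stationary":
            return stationary_distribution(Q)
        if self.kind == "fitzjohn":
            tot = root_partial.sum()
            if tot <= 0:
                return np.full(S, 1.0 / S)
            return root_partial / tot
        return np.asarray(self.vector, dtype=float)


@dataclass(frozen=True)
class NodeConstraint:
    """Restrict a node to a set of allowed composite states."""

    node: int
    allowed: frozenset[int]

    def __post_init__(self):
        if not self.allowed:
            raise ValueError("allowed state set must be non-empty")

    @classmethod
    def observed(cls, node: int, obs_state: int, space) -> "NodeConstraint":
        """Constrain the observed part only ('present, any class')."""
        allowed = frozenset(
            i for i in range(space.size) if space.obs_part(i) == obs_state
        )
        return cls(node=node, allowed=allowed)

    def mask(self, S: int) -> np.ndarray:
        m = np.zeros(S)
        m[list(self.allowed)] = 1.0
        return m


@dataclass
class LikelihoodResult:
    lnl: float
    partials: np.ndarray  # (n_nodes, S), rescaled
    log_scale: np.ndarray  # (n_nodes,) accumulated per-node log factors
    prior: np.ndarray  # resolved root prior actually used
    prior_kind: str
    impossible: bool = False

    def to_dict(self) -> dict:
        return {
            "lnl": self.lnl,
            "prior_kind": self.prior_kind,
            "prior": self.prior.tolist(),
            "impossible": self.impossible,
        }


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1 by least squares (handles reducible Q)."""
    S = Q.shape[0]
    A = np.vstack([Q.T, np.ones(S)])
    b = np.zeros(S + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, entries clipped to [0, 1]."""
    if t < 0:
        raise ValueError("t must be >= 0")
    Q = np.asarray(Q, dtype=float)
    if t == 0:
        return np.eye(Q.shape[0])
    P = scipy.linalg.expm(Q * t)
    return np.clip(P, 0.0, 1.0)


class Propagator:
    """Batched P(t) for many branch lengths from one decomposition of Q."""

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self._eig = None
        try:
            w, V = np.linalg.eig(self.Q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e10:
                self._eig = (w, V, Vinv)
        except np.linalg.LinAlgError:
            pass

    def batch(self, ts: np.ndarray) -> np.ndarray:
        """(E, S, S) array of transition matrices for branch lengths ts."""
        ts = np.asarray(ts, dtype=float)
        S = self.Q.shape[0]
        if self._eig is not None:
            w, V, Vinv = self._eig
            E = np.exp(np.multiply.outer(ts, w))  # (E, S)
            P = np.einsum("ij,ej,jk->eik", V, E, Vinv)
            P = np.real(P)
        else:
            P = np.empty((len(ts), S, S))
            cache: dict[float, np.ndarray] = {}
            for i, t in enumerate(ts):
                key = float(t)
                if key not in cache:
                    cache[key] = scipy.linalg.expm(self.Q * key)
                P[i] = cache[key]
        P[ts == 0.0] = np.eye(S)
        return np.clip(P, 0.0, 1.0)


def tip_partials(traits: TraitMatrix, space) -> dict[str, np.ndarray]:
    """Per-tip conditional likelihood vectors.

    An observed state puts 1 on every composite state with that observed
    part; an unknown ('?') tip gets an all-ones vector.
    """
    if traits.n_observed != space.n_observed:
        raise ValueError(
            f"trait space has {traits.n_observed} observed states, "
            f"model space has {space.n_observed}"
        )
    out = {}
    for lab, s in traits.states.items():
        if s is None:
            out[lab] = np.ones(space.size)
        else:
            out[lab] = space.observed_mask(s)
    return out


def _partials_matrix(
    tree: Phylogeny, traits: TraitMatrix, space, constraints
) -> np.ndarray:
    S = space.size
    L = np.ones((tree.n_nodes, S))
    per_tip = tip_partials(traits, space)
    for v in tree.tip_ids:
        lab = tree.labels[v]
        if lab not in per_tip:
            raise ValueError(f"tip {lab!r} has no trait entry")
        L[v] = per_tip[lab]
    if constraints:
        for c in constraints:
            if not (0 <= c.node < tree.n_nodes):
                raise ValueError(f"constraint node {c.node} not in tree")
            L[c.node] *= c.mask(S)
    return L


def tree_loglik(
    tree: Phylogeny,
    traits: TraitMatrix,
    model: RateModel,
    theta,
    root_prior: RootPrior = RootPrior("flat"),
    constraints: list[NodeConstraint] | None = None,
) -> LikelihoodResult:
    """Log-likelihood of the tip data by level-batched pruning.

    Constraints zero out disallowed composite states at the constrained
    node before its message is passed rootward.  Data impossible under
    the model/constraints yields ``lnl = -inf`` with ``impossible=True``
    rather than an exception.
    """
    Q = model.assemble_Q(theta)
    prop = Propagator(Q)
    return _pruning(tree, traits, model, prop, root_prior, constraints)


def _pruning(
    tree: Phylogeny,
    traits: TraitMatrix,
    model: RateModel,
    prop: Propagator,
    root_prior: RootPrior,
    constraints=None,
    P_all: np.ndarray | None = None,
) -> LikelihoodResult:
    space = model.space
    S = space.size
    partial = _partials_matrix(tree, traits, space, constraints)
    log_scale = np.zeros(tree.n_nodes)
    if P_all is None:
        P_all = prop.batch(tree.length)  # P_all[v]: edge above node v

    for level in tree.levels():
        # finalize scaling for this level, then push messages to parents
        mx = partial[level].max(axis=1)
        ok = mx > 0
        partial[level[ok]] /= mx[ok, None]
        log_scale[level[ok]] += np.log(mx[ok])
        nonroot = level[level != tree.root]
        if len(nonroot) == 0:
            continue
        msgs = np.einsum("eij,ej->ei", P_all[nonroot], partial[nonroot])
        parents = tree.parent[nonroot]
        np.multiply.at(partial, parents, msgs)
        np.add.at(log_scale, parents, log_scale[nonroot])

    root_partial = partial[tree.root]
    prior = root_prior.resolve(prop.Q, root_partial)
    total = float(prior @ root_partial)
    if root_prior.kind == "fitzjohn" and root_partial.sum() > 0:
        pass  # prior already proportional to root partial
    if total <= 0 or not np.isfinite(total):
        return LikelihoodResult(
            lnl=NEG_INF,
            partials=partial,
            log_scale=log_scale,
            prior=prior,
            prior_kind=root_prior.kind,
            impossible=True,
        )
    lnl = float(np.log(total) + log_scale[tree.root])
    return LikelihoodResult(
        lnl=lnl,
        partials=partial,
        log_scale=log_scale,
        prior=prior,
        prior_kind=root_prior.kind,
    )
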