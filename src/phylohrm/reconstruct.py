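"""Marginal and joint ancestral state reconstruction.

Marginal mode gives, for every node, the posterior probability of each
composite state given all tip data (up-down algorithm: tipward partials
from pruning combined with a rootward "outside" pass).  Joint mode gives
the single assignment of composite states to all nodes that maximizes
their joint probability (Pupko-style max-product dynamic program with
back-pointers, run in log space).  Ties in the joint optimum are broken
deterministically toward the lowest composite-state index and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import (
    NodeConstraint,
    Propagator,
    RootPrior,
    _partials_matrix,
    _pruning,
)
from .models import RateModel
from .traits import TraitMatrix
from .tree import Phylogeny

__all__ = [
    "Reconstruction",
    "marginal_reconstruct",
    "joint_reconstruct",
    "collapse_to_observed",
]

_TIE_TOL = 1e-10


@dataclass
class Reconstruction:
    mode: str  # "marginal" | "joint"
    tree: Phylogeny
    model: RateModel
    theta: np.ndarray
    root_prior: RootPrior
    node_probs: np.ndarray | None = None  # (n_nodes, S), marginal mode
    node_states: np.ndarray | None = None  # (n_nodes,), joint mode
    lnl: float | None = None
    joint_log_prob: float | None = None
    ties: list[dict] = field(default_factory=list)

    @property
    def space(self):
        return self.model.space


def marginal_reconstruct(
    tree: Phylogeny,
    traits: TraitMatrix,
    model: RateModel,
    theta,
    root_prior: RootPrior = RootPrior("flat"),
    constraints: list[NodeConstraint] | None = None,
) -> Reconstruction:
    """Posterior composite-state probabilities at every node.

    Outside vectors are propagated root-to-tip: the root's outside is
    the prior; a child's outside is ``P^T @ (outside(parent) * product
    of sibling messages)``.  Posterior at a node is proportional to
    outside * inside, normalized per node (rescaling cancels).
    """
    theta = np.asarray(theta, dtype=float)
    Q = model.assemble_Q(theta)
    prop = Propagator(Q)
    P_all = prop.batch(tree.length)
    res = _pruning(tree, traits, model, prop, root_prior, constraints, P_all=P_all)
    if res.impossible:
        raise ValueError("data impossible under the model/constraints")
    partial = res.partials  # rescaled inside vectors
    S = model.space.size

    # messages child -> parent from the rescaled partials
    msgs = np.einsum("eij,ej->ei", P_all, partial)  # msgs[v]: message up edge v
    outside = np.zeros((tree.n_nodes, S))
    outside[tree.root] = res.prior
    post = np.zeros((tree.n_nodes, S))
    for v in tree.preorder():
        vec = outside[v] * partial[v]
        tot = vec.sum()
        if tot <= 0:
            raise ValueError(f"zero posterior mass at node {v}")
        post[v] = vec / tot
        kids = tree.children[v]
        if not kids:
            continue
        kid_msgs = msgs[kids]  # (c, S)
        for idx, c in enumerate(kids):
            sib = np.prod(np.delete(kid_msgs, idx, axis=0), axis=0) if len(kids) > 1 else np.ones(S)
            contrib = outside[v] * sib
            out_c = P_all[c].T @ contrib
            tot_c = out_c.sum()
            outside[c] = out_c / tot_c if tot_c > 0 else out_c
    return Reconstruction(
        mode="marginal",
        tree=tree,
        model=model,
        theta=theta,
        root_prior=root_prior,
        node_probs=post,
        lnl=res.lnl,
    )


def joint_reconstruct(
    tree: Phylogeny,
    traits: TraitMatrix,
    model: RateModel,
    theta,
    root_prior: RootPrior = RootPrior("flat"),
    constraints: list[NodeConstraint] | None = None,
) -> Reconstruction:
    """Single likeliest assignment of composite states to all nodes.

    Tips with an observed state are confined to matching composite
    states; unknown tips are reconstructed like internal nodes.  The
    root maximization includes the root prior.
    """
    theta = np.asarray(theta, dtype=float)
    Q = model.assemble_Q(theta)
    prop = Propagator(Q)
    P_all = prop.batch(tree.length)
    S = model.space.size
    with np.errstate(divide="ignore"):
        logP = np.log(P_all)
        log_site = np.log(_partials_matrix(tree, traits, model.space, constraints))

    # C[v, j] = best log contribution of v's subtree+edge given parent state j
    C = np.zeros((tree.n_nodes, S))
    back = np.zeros((tree.n_nodes, S), dtype=int)
    ties: list[dict] = []
    Lbest = log_site.copy()  # best subtree log prob given own state
    for v in tree.postorder:
        for c in tree.children[v]:
            Lbest[v] += C[c]
        if v == tree.root:
            continue
        scores = logP[v] + Lbest[v][None, :]  # (parent S, child S)
        back[v] = np.argmax(scores, axis=1)
        C[v] = scores[np.arange(S), back[v]]
        tie_rows = (np.isclose(scores, C[v][:, None], atol=_TIE_TOL) & np.isfinite(scores)).sum(axis=1) > 1
        if np.any(tie_rows):
            ties.append({"node": int(v), "parent_states": np.where(tie_rows)[0].tolist()})

    with np.errstate(divide="ignore"):
        root_score = np.log(root_prior.resolve(Q, np.exp(Lbest[tree.root] - Lbest[tree.root].max()))) + Lbest[tree.root]
    if not np.any(np.isfinite(root_score)):
        raise ValueError("data impossible under the model/constraints")
    states = np.zeros(tree.n_nodes, dtype=int)
    states[tree.root] = int(np.argmax(root_score))
    if (np.isclose(root_score, root_score.max(), atol=_TIE_TOL) & np.isfinite(root_score)).sum() > 1:
        ties.append({"node": int(tree.root), "parent_states": []})
    for v in tree.preorder():
        for c in tree.children[v]:
            states[c] = back[c, states[v]]
    joint_lp = float(root_score[states[tree.root]])
    return Reconstruction(
        mode="joint",
        tree=tree,
        model=model,
        theta=theta,
        root_prior=root_prior,
        node_states=states,
        joint_log_prob=joint_lp,
        ties=ties,
    )


def collapse_to_observed(recon: Reconstruction):
    """Map composite states to their observed part.

    Joint mode: per-node observed codes, shape (n_nodes,).  Marginal
    mode: per-node observed-state probabilities, shape (n_nodes,
    n_observed), summed over rate classes.
    """
    space = recon.space
    if recon.mode == "joint":
        return np.array([space.obs_part(s) for s in recon.node_states])
    k = space.n_classes
    return recon.node_probs.reshape(recon.node_probs.shape[0], space.n_observed, k).sum(axis=2)
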