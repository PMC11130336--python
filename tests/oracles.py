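"""Independent brute-force oracles for tiny instances.

Everything here enumerates over explicit state assignments or integrates
matrix exponentials directly, sharing no code path with the pruning /
dynamic-programming implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.integrate
import scipy.linalg

from phylohrm.likelihood import RootPrior, _partials_matrix


def _edge_P(tree, Q):
    return {v: scipy.linalg.expm(Q * tree.length[v]) for v in range(tree.n_nodes)}


def _assignment_weight(tree, P, L, prior, amap):
    """Probability mass of one full internal-node assignment, with tips
    summed over their allowed composite states."""
    p = prior[amap[tree.root]]
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        pa = amap[tree.parent[v]]
        if tree.is_tip(v):
            p *= float(P[v][pa] @ L[v])
        else:
            p *= P[v][pa, amap[v]]
    return p


def enum_loglik(tree, traits, model, theta, root_prior=RootPrior("flat"), constraints=None):
    """lnL as an explicit sum over all internal-node composite states."""
    Q = model.assemble_Q(theta)
    P = _edge_P(tree, Q)
    L = _partials_matrix(tree, traits, model.space, constraints)
    S = model.space.size
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    if root_prior.kind == "fitzjohn":
        # resolve against the enumerated conditional root likelihoods
        d = np.zeros(S)
        for assign in itertools.product(range(S), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            d[amap[tree.root]] += _assignment_weight(
                tree, P, L, np.ones(S), amap
            )
        prior = d / d.sum() if d.sum() > 0 else np.full(S, 1.0 / S)
    else:
        prior = root_prior.resolve(Q, None)
    total = 0.0
    for assign in itertools.product(range(S), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        total += _assignment_weight(tree, P, L, prior, amap)
    if total <= 0:
        return float("-inf")
    return float(np.log(total))


def enum_marginal(tree, traits, model, theta, root_prior=RootPrior("flat")):
    """Exact per-node posterior over composite states.

    Enumerates assignments of the internal nodes only; for a fixed
    internal assignment each tip's state distribution factorizes, so tip
    posteriors accumulate analytically.  Tips count as nodes too (their
    allowed states come from the observed trait)."""
    Q = model.assemble_Q(theta)
    P = _edge_P(tree, Q)
    L = _partials_matrix(tree, traits, model.space, None)
    S = model.space.size
    prior = root_prior.resolve(Q, None) if root_prior.kind != "fitzjohn" else None
    if prior is None:
        raise NotImplementedError("fitzjohn prior not supported by this oracle")
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tips = [v for v in range(tree.n_nodes) if tree.is_tip(v)]
    post = np.zeros((tree.n_nodes, S))
    total = 0.0
    for assign in itertools.product(range(S), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        p = prior[amap[tree.root]]
        tip_dists = {}
        for v in internals:
            if v != tree.root:
                p *= P[v][amap[tree.parent[v]], amap[v]]
        for v in tips:
            w = P[v][amap[tree.parent[v]]] * L[v]
            tip_dists[v] = w
            p *= w.sum()
        if p == 0:
            continue
        total += p
        for v in internals:
            post[v, amap[v]] += p
        for v in tips:
            w = tip_dists[v]
            post[v] += p * w / w.sum()
    return post / total


def enum_joint(tree, traits, model, theta, root_prior=RootPrior("flat")):
    """Exact max-probability assignment of composite states to all nodes.

    Enumerates internal assignments; for a fixed internal assignment the
    best tip states maximize independently.  Returns (assignment array,
    log of the maximized joint probability)."""
    Q = model.assemble_Q(theta)
    P = _edge_P(tree, Q)
    L = _partials_matrix(tree, traits, model.space, None)
    S = model.space.size
    prior = root_prior.resolve(Q, None)
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tips = [v for v in range(tree.n_nodes) if tree.is_tip(v)]
    best, best_p = None, -1.0
    for assign in itertools.product(range(S), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        p = prior[amap[tree.root]]
        for v in internals:
            if v != tree.root:
                p *= P[v][amap[tree.parent[v]], amap[v]]
        tip_states = {}
        for v in tips:
            w = P[v][amap[tree.parent[v]]] * L[v]
            s = int(np.argmax(w))
            tip_states[v] = s
            p *= w[s]
        if p > best_p:
            full = np.zeros(tree.n_nodes, dtype=int)
            for v in internals:
                full[v] = amap[v]
            for v, s in tip_states.items():
                full[v] = s
            best_p, best = p, full
    return best, (np.log(best_p) if best_p > 0 else float("-inf"))


def expected_event_count(Q, start, T, n_grid=2001):
    """E[number of jumps in [0, T]] for a CTMC from ``start``:
    integral of occupancy(t) . exit_rates dt, by Simpson quadrature."""
    exit_rates = -np.diag(Q)
    ts = np.linspace(0.0, T, n_grid)
    occ = np.array([scipy.linalg.expm(Q * t)[start] for t in ts])
    integrand = occ @ exit_rates
    return float(scipy.integrate.simpson(integrand, x=ts))


def random_tree_newick(rng, n_tips, max_len=2.0):
    """Random topology with random branch lengths, as newick text."""
    parts = [f"L{i}:{rng.uniform(0.05, max_len):.4f}" for i in range(n_tips)]
    while len(parts) > 1:
        k = 2 if len(parts) == 2 else int(rng.integers(2, min(3, len(parts)) + 1))
        idx = rng.choice(len(parts), size=k, replace=False)
        merged = "(" + ",".join(parts[i] for i in sorted(idx)) + f"):{rng.uniform(0.05, max_len):.4f}"
        parts = [p for i, p in enumerate(parts) if i not in set(idx)] + [merged]
    return parts[0].rsplit(":", 1)[0] + ";"
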