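"""Event counting and downstream analyses of a reconstructed history.

Gains and losses are counted edge-by-edge from a joint reconstruction:
an event is noted whenever the most likely estimates at the parent and
child of an edge differ in the observed state.  Such counts are minima —
a state can change and change back within a single edge without leaving
a trace at the nodes — and every summary carries that caveat flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import FitResult, fit_model
from .likelihood import RootPrior
from .models import build_hidden_rates_model
from .reconstruct import Reconstruction, collapse_to_observed, marginal_reconstruct
from .traits import TraitMatrix
from .tree import Phylogeny, find_mrca

__all__ = [
    "TransitionSummary",
    "RateGrid",
    "count_transitions",
    "tabulate_clade_events",
    "label_rate_classes",
    "rate_grid_scan",
    "ancestor_probability",
]


@dataclass
class TransitionSummary:
    events: pd.DataFrame  # columns: child_node, parent_obs, child_obs
    totals: dict[tuple[int, int], int]
    n_edges: int
    minimum_change_caveat: bool = True

    @property
    def gains(self) -> int:
        """Transitions out of the trait-absent state (observed 0 -> >0)."""
        return sum(n for (a, b), n in self.totals.items() if a == 0 and b != 0)

    @property
    def losses(self) -> int:
        """Transitions into the trait-absent state (observed >0 -> 0)."""
        return sum(n for (a, b), n in self.totals.items() if a != 0 and b == 0)


def count_transitions(tree: Phylogeny, recon: Reconstruction) -> TransitionSummary:
    """Tally observed-state changes between the ends of every edge."""
    if recon.mode != "joint":
        raise ValueError("count_transitions requires a joint-mode reconstruction")
    obs = collapse_to_observed(recon)
    rows = []
    totals: dict[tuple[int, int], int] = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p == -1:
            continue
        a, b = int(obs[p]), int(obs[v])
        if a != b:
            rows.append({"child_node": v, "parent_obs": a, "child_obs": b})
            totals[(a, b)] = totals.get((a, b), 0) + 1
    events = pd.DataFrame(rows, columns=["child_node", "parent_obs", "child_obs"])
    return TransitionSummary(events=events, totals=totals, n_edges=tree.n_nodes - 1)


def tabulate_clade_events(
    tree: Phylogeny,
    summary: TransitionSummary,
    clades: dict[str, list[str]],
    other_label: str = "(other)",
) -> pd.DataFrame:
    """Assign each event to the smallest named clade containing its edge.

    Clades are given as name -> tip set and resolved to MRCAs; an edge
    belongs to a clade when its parent node is inside the clade's
    subtree.  Events outside all named clades land in a catch-all row.
    Totals are conserved: column sums equal the summary's totals.
    """
    clade_nodes = {}
    clade_sizes = {}
    for name, tips in clades.items():
        m = find_mrca(tree, tips)
        nodes = set(tree.subtree_nodes(m).tolist())
        clade_nodes[name] = nodes
        clade_sizes[name] = len(nodes)
    names = sorted(clades, key=lambda n: clade_sizes[n])  # smallest first
    counts = {name: {"gains": 0, "losses": 0} for name in names}
    counts[other_label] = {"gains": 0, "losses": 0}
    for _, ev in summary.events.iterrows():
        parent = int(tree.parent[int(ev.child_node)])
        target = other_label
        for name in names:
            if parent in clade_nodes[name]:
                target = name
                break
        kind = "gains" if ev.parent_obs == 0 else "losses"
        counts[target][kind] += 1
    rows = [
        {"clade": name, "gains": c["gains"], "losses": c["losses"]}
        for name, c in counts.items()
    ]
    return pd.DataFrame(rows)


def label_rate_classes(
    fit: FitResult, negligible: float = 1e-6
) -> dict[str, str]:
    """Name the hidden classes of a fitted 3-class binary model.

    The class whose trait-absent composite state has negligible total
    exit rate (no pathway to gain) is the non-precursor; the class with
    the largest gain rate is the intermediary; the remaining class is
    the precursor.  Raises if the three roles are not uniquely
    assignable, listing the rate signature.
    """
    space = fit.model.space
    if space.n_observed != 2 or space.n_classes != 3:
        raise ValueError("rate-class labelling expects a binary 3-class model")
    Q = fit.model.assemble_Q(fit.theta)
    k = space.n_classes
    exit_from_absent = np.array(
        [-Q[space.index(0, c), space.index(0, c)] for c in range(k)]
    )
    gain = np.array([Q[space.index(0, c), space.index(1, c)] for c in range(k)])
    signature = {
        space.classes[c]: {"exit_from_absent": float(exit_from_absent[c]), "gain": float(gain[c])}
        for c in range(k)
    }
    non_prec = [c for c in range(k) if exit_from_absent[c] < negligible]
    if len(non_prec) != 1:
        raise ValueError(f"non-precursor class not uniquely assignable: {signature}")
    rest = [c for c in range(k) if c != non_prec[0]]
    if np.isclose(gain[rest[0]], gain[rest[1]], rtol=1e-9, atol=0):
        raise ValueError(f"intermediary class not uniquely assignable: {signature}")
    inter = rest[0] if gain[rest[0]] > gain[rest[1]] else rest[1]
    prec = (set(rest) - {inter}).pop()
    return {
        space.classes[non_prec[0]]: "non-precursor",
        space.classes[inter]: "intermediary",
        space.classes[prec]: "precursor",
    }


@dataclass
class RateGrid:
    focal_node: int
    records: pd.DataFrame  # gain, loss, lnl, p_obs0, p_obs1, ...
    anchor_fit: FitResult
    spec: dict = field(default_factory=dict)


def _grid_pairs(gain_mle: float, loss_mle: float, spec: dict) -> np.ndarray:
    """(n, 2) gain/loss pairs including the MLE pair.

    Default: 100 couples spread evenly on the log10 scale over factors
    1e-2..1e2 of the MLE, with the gain factor ascending and the loss
    factor descending so the loss/gain ratio sweeps monotonically; the
    point nearest the MLE is replaced by the MLE pair exactly.  A
    ``mode='factorial'`` option lays an even sqrt(n) x sqrt(n) factor
    grid instead; ``mode='linear'`` spaces factors linearly.
    """
    n = int(spec.get("n", 100))
    if n < 1:
        raise ValueError("grid spec is empty")
    span = float(spec.get("log10_span", 2.0))
    mode = spec.get("mode", "couples")
    if mode == "factorial":
        m = max(2, int(round(np.sqrt(n))))
        f = np.logspace(-span, span, m)
        gains = np.repeat(f * gain_mle, m)
        losses = np.tile(f * loss_mle, m)
        pairs = np.column_stack([gains, losses])
    elif mode in {"couples", "linear"}:
        if mode == "linear":
            f = np.linspace(10.0**-span, 10.0**span, n)
        else:
            f = np.logspace(-span, span, n)
        pairs = np.column_stack([f * gain_mle, f[::-1] * loss_mle])
    else:
        raise ValueError(f"unknown grid mode {mode!r}")
    d = np.abs(np.log10(pairs[:, 0] / gain_mle)) + np.abs(np.log10(pairs[:, 1] / loss_mle))
    pairs[np.argmin(d)] = (gain_mle, loss_mle)
    return pairs


def rate_grid_scan(
    tree: Phylogeny,
    traits: TraitMatrix,
    focal_node: int,
    grid_spec: dict | None = None,
    seed: int = 0,
    root_prior: RootPrior = RootPrior("flat"),
    n_restarts: int = 5,
) -> RateGrid:
    """Scan gain/loss rate pairs around a no-hidden-state anchor fit.

    A 1-class 2-parameter binary model is fitted to anchor the grid at
    its MLE; for every (gain, loss) pair the tree log-likelihood and the
    focal node's marginal observed-state probabilities are recorded,
    ready for plotting likelihood against the ancestor's state call.
    """
    if traits.space != "binary":
        raise ValueError("rate grid scan requires binary traits")
    if not (0 <= focal_node < tree.n_nodes):
        raise ValueError(f"focal node {focal_node} not in tree")
    spec = dict(grid_spec or {})
    model = build_hidden_rates_model(2, 1)
    anchor = fit_model(
        tree, traits, model, n_restarts=n_restarts, seed=seed, root_prior=root_prior
    )
    gain_mle, loss_mle = anchor.theta  # param order: gain (0->1), loss (1->0)
    pairs = _grid_pairs(gain_mle, loss_mle, spec)
    rows = []
    for gain, loss in pairs:
        recon = marginal_reconstruct(tree, traits, model, [gain, loss], root_prior)
        p_obs = collapse_to_observed(recon)[focal_node]
        rows.append(
            {
                "gain": gain,
                "loss": loss,
                "lnl": recon.lnl,
                "p_absent": p_obs[0],
                "p_present": p_obs[1],
            }
        )
    return RateGrid(
        focal_node=focal_node,
        records=pd.DataFrame(rows),
        anchor_fit=anchor,
        spec={"n": len(pairs), **spec},
    )


def ancestor_probability(recon: Reconstruction, node: int) -> np.ndarray:
    """Collapsed observed-state probability vector at one node."""
    if recon.mode != "marginal":
        raise ValueError("ancestor_probability requires a marginal reconstruction")
    if not (0 <= node < recon.tree.n_nodes):
        raise ValueError(f"unknown node {node}")
    return collapse_to_observed(recon)[node]
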