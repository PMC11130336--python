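"""Synthetic trees and trait histories with event-level ground truth.

Trees come from a constant-rate birth-death process conditioned on a
tip count by repeated simulation (an approximate conditioning — see the
methods note).  Trait histories are simulated exactly along each edge
(exponential waiting times from the current composite state's total
exit rate, destination drawn by relative rates), and the full event
chain is kept so reconstruction and transition counting can be checked
against truth.

The flagship fixture emulates the statistical structure of the
nitrogen-fixing clade: a binary trait under a 3-class hidden-rate model
whose classes follow the qualitative ordering inferred for root-nodule
symbiosis — gains from a labile intermediary class are an order of
magnitude faster than entry into that class from the precursor class,
losses are two orders slower still, and a non-precursor class is
absorbing for trait-absent lineages — with the precursor seeded at an
ingroup ancestor and the non-precursor everywhere else.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import RateModel, build_hidden_rates_model
from .traits import TraitMatrix, write_trait_table
from .tree import Phylogeny, write_newick

__all__ = [
    "SimHistory",
    "FixtureBundle",
    "simulate_tree",
    "simulate_trait_history",
    "make_nfc_like_fixture",
    "mask_states",
    "DEFAULT_NFC_RATES",
]

# Default 3-class rate profile (events/Myr on a height-100 tree), chosen
# so the expected number of independent gains on a 1,000-tip ingroup is
# a handful, mirroring the inferred ordering for root-nodule symbiosis:
# gain from the intermediary is 10x the precursor->intermediary rate,
# loss of the trait is 150x slower than that gain, the precursor loses
# lability (-> non-precursor) twice as readily as it gains it
# (-> intermediary), and the intermediary returns to the precursor at
# the same rate as it gains the trait.  The non-precursor class R1 is
# absorbing for trait-absent lineages (exit rates at the lower bound).
GAIN_FROM_INTERMEDIARY = 0.02
DEFAULT_NFC_RATES = {
    "classes": {"R1": "non-precursor", "R2": "precursor", "R3": "intermediary"},
    "gain_intermediary": GAIN_FROM_INTERMEDIARY,
    "precursor_to_intermediary": GAIN_FROM_INTERMEDIARY / 10,
    "precursor_to_nonprecursor": 2 * GAIN_FROM_INTERMEDIARY / 10,
    "intermediary_to_precursor": GAIN_FROM_INTERMEDIARY,
    "loss": GAIN_FROM_INTERMEDIARY / 150,
    "negligible": 1e-9,
}


@dataclass
class SimHistory:
    """Event-level truth of a simulated trait history."""

    node_states: np.ndarray  # true composite state per node
    events: dict[int, list[tuple[float, int, int]]]  # child node -> [(time, from, to)]
    obs_changes: np.ndarray  # per-edge (indexed by child node) observed-change count
    n_classes: int  # to collapse composite event states to observed parts
    seed: int
    params: dict = field(default_factory=dict)

    def true_gains(self) -> int:
        """Observed absent -> present events, counted event-by-event."""
        return self._count(lambda a, b: a == 0 and b != 0)

    def true_losses(self) -> int:
        return self._count(lambda a, b: a != 0 and b == 0)

    def _count(self, pred) -> int:
        k = self.n_classes
        n = 0
        for evs in self.events.values():
            for _, a, b in evs:
                if pred(a // k, b // k):
                    n += 1
        return n


@dataclass
class FixtureBundle:
    tree: Phylogeny
    traits: TraitMatrix  # possibly masked
    full_traits: TraitMatrix  # before masking
    history: SimHistory
    model: RateModel
    theta: np.ndarray
    ingroup_node: int
    clades: dict[str, list[str]]
    seed: int
    regenerations: int = 0

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(self.tree))
        write_trait_table(self.traits, out / "traits.csv")
        self.model.to_json(out / "model.json", theta=self.theta)
        truth = {
            "seed": self.seed,
            "ingroup_node": self.ingroup_node,
            "regenerations": self.regenerations,
            "true_gains": self.history.true_gains(),
            "true_losses": self.history.true_losses(),
            "node_states": self.history.node_states.tolist(),
            "clades": self.clades,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        (out / "README.txt").write_text(
            "Synthetic hidden-rates fixture: tree.nwk (ultrametric birth-death"
            " tree), traits.csv (binary tip states, '?' = masked), model.json"
            " (generating model + rates), truth.json (event-level truth).\n"
        )


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream of a master seed (tree / history / mask / ...)."""
    key = zlib.crc32(name.encode()) % (2**31)
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def simulate_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    scale_height: float | None = None,
    max_attempts: int = 1000,
) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on ``n_tips`` survivors.

    Simulation runs forward from a root split until the extant count
    first reaches ``n_tips`` (then extends tips by one more exponential
    waiting time); lineages that die are pruned and unifurcations
    suppressed.  Trees going extinct are discarded and re-simulated.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth <= 0 or death < 0 or birth <= death:
        raise ValueError("need birth > death >= 0")
    rng = _substream(seed, "tree")
    for _ in range(max_attempts):
        phylo = _simulate_bd_once(n_tips, birth, death, rng)
        if phylo is not None:
            if scale_height is not None:
                depth = phylo.node_depths()[phylo.tip_ids[0]]
                phylo = Phylogeny(
                    parent=phylo.parent,
                    children=phylo.children,
                    length=phylo.length * (scale_height / depth),
                    labels=phylo.labels,
                    root=phylo.root,
                )
            return phylo
    raise RuntimeError(f"no surviving tree in {max_attempts} attempts")


def _simulate_bd_once(n_tips, birth, death, rng):
    # grow a lineage list; each lineage: (birth_time, parent_lineage)
    parent = [-1]
    t_start = [0.0]
    t_end: list[float | None] = [None]
    alive = [0]
    extinct: set[int] = set()
    t = 0.0
    # root split at time 0
    for _ in range(2):
        parent.append(0)
        t_start.append(0.0)
        t_end.append(None)
    t_end[0] = 0.0
    alive = [1, 2]
    while len(alive) < n_tips:
        rate = len(alive) * (birth + death)
        t += rng.exponential(1.0 / rate)
        lin = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death):
            t_end[lin] = t
            for _ in range(2):
                parent.append(lin)
                t_start.append(t)
                t_end.append(None)
            alive.remove(lin)
            alive.extend([len(parent) - 2, len(parent) - 1])
        else:
            t_end[lin] = t
            alive.remove(lin)
            extinct.add(lin)
            if not alive:
                return None
    t += rng.exponential(1.0 / (len(alive) * (birth + death)))
    for lin in alive:
        t_end[lin] = t

    # keep only lineages with surviving descendants; suppress unifurcations
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    survives = [False] * n
    for i in range(n - 1, -1, -1):
        if i in extinct:
            continue
        if not children[i]:
            survives[i] = i in set(alive)
        else:
            survives[i] = any(survives[c] for c in children[i])
    if not survives[0]:
        return None

    new_parent: list[int] = []
    new_children: list[list[int]] = []
    new_length: list[float] = []
    new_labels: list[str | None] = []
    tip_counter = [0]

    def build(lin: int, top_time: float, parent_id: int) -> None:
        kids = [c for c in children[lin] if survives[c]]
        while len(kids) == 1:  # suppress unifurcation through dead side
            lin = kids[0]
            kids = [c for c in children[lin] if survives[c]]
        node_id = len(new_parent)
        new_parent.append(parent_id)
        new_children.append([])
        new_length.append(t_end[lin] - top_time)
        new_labels.append(None)
        if parent_id >= 0:
            new_children[parent_id].append(node_id)
        if not kids:
            tip_counter[0] += 1
            new_labels[node_id] = f"t{tip_counter[0]}"
        else:
            for c in kids:
                build(c, t_end[lin], node_id)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n_tips + 1000))
    try:
        build(0, 0.0, -1)
    finally:
        sys.setrecursionlimit(old)
    if tip_counter[0] != n_tips:
        return None
    return Phylogeny(
        parent=np.array(new_parent, dtype=int),
        children=new_children,
        length=np.array(new_length),
        labels=new_labels,
        root=0,
    )


def simulate_trait_history(
    tree: Phylogeny,
    model: RateModel,
    theta,
    root_state: int,
    seed: int = 0,
    forced_states: dict[int, int] | None = None,
) -> tuple[TraitMatrix, SimHistory]:
    """Exact event-time simulation of the composite chain along every edge.

    ``forced_states`` resets the state at given nodes before their
    descendant edges are simulated (used to seed a clade-localized rate
    class).  Trait space of the output follows the model's observed
    states.
    """
    theta = np.asarray(theta, dtype=float)
    Q = model.assemble_Q(theta)
    space = model.space
    S = space.size
    if not (0 <= root_state < S):
        raise ValueError(f"root state {root_state} outside composite space")
    rng = _substream(seed, "history")
    forced = dict(forced_states or {})
    node_states = np.zeros(tree.n_nodes, dtype=int)
    events: dict[int, list[tuple[float, int, int]]] = {}
    obs_changes = np.zeros(tree.n_nodes, dtype=int)
    node_states[tree.root] = forced.get(tree.root, root_state)
    for v in tree.preorder():
        if v == tree.root:
            continue
        state = int(node_states[tree.parent[v]])
        if v in forced:
            state = forced[v]
        t, T = 0.0, float(tree.length[v])
        evs: list[tuple[float, int, int]] = []
        while True:
            exit_rate = -Q[state, state]
            if exit_rate <= 0:
                break
            t += rng.exponential(1.0 / exit_rate)
            if t >= T:
                break
            probs = Q[state].clip(min=0.0)
            probs[state] = 0.0
            dest = int(rng.choice(S, p=probs / probs.sum()))
            evs.append((t, state, dest))
            if space.obs_part(state) != space.obs_part(dest):
                obs_changes[v] += 1
            state = dest
        if evs:
            events[int(v)] = evs
        node_states[v] = state
    space_tag = "binary" if space.n_observed == 2 else "ternary"
    states = {
        tree.labels[i]: space.obs_part(int(node_states[i])) for i in tree.tip_ids
    }
    traits = TraitMatrix(states, space_tag)
    hist = SimHistory(
        node_states=node_states,
        events=events,
        obs_changes=obs_changes,
        n_classes=space.n_classes,
        seed=seed,
        params={"theta": theta.tolist(), "root_state": root_state, "model": model.name},
    )
    return traits, hist


def mask_states(traits: TraitMatrix, fraction: float, seed: int = 0) -> TraitMatrix:
    """Mask a uniformly random fraction of tips to unknown ('?')."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    labels = sorted(traits.states)
    n_mask = int(round(fraction * len(labels)))
    rng = _substream(seed, "mask")
    chosen = rng.choice(len(labels), size=n_mask, replace=False)
    new = dict(traits.states)
    for i in chosen:
        new[labels[i]] = None
    return TraitMatrix(new, traits.space)


def nfc_like_model_and_theta(
    rates: dict | None = None,
) -> tuple[RateModel, np.ndarray]:
    """3-class binary no-gain-class model with the default rate profile."""
    r = {**DEFAULT_NFC_RATES, **(rates or {})}
    model = build_hidden_rates_model(2, 3, no_gain_class="R1")
    space = model.space
    eps = r["negligible"]
    theta = np.full(model.n_params, eps)

    def set_rate(i, j, value):
        p = model.index_matrix[i, j]
        if p == 0:
            raise ValueError("attempt to set a forbidden transition")
        theta[p - 1] = value

    A, P = 0, 1  # observed absent / present
    NP, PR, IN = 0, 1, 2  # classes R1..R3
    set_rate(space.index(A, PR), space.index(A, IN), r["precursor_to_intermediary"])
    set_rate(space.index(A, PR), space.index(A, NP), r["precursor_to_nonprecursor"])
    set_rate(space.index(A, IN), space.index(A, PR), r["intermediary_to_precursor"])
    set_rate(space.index(A, IN), space.index(P, IN), r["gain_intermediary"])
    for c in (NP, PR, IN):
        set_rate(space.index(P, c), space.index(A, c), r["loss"])
    return model, theta


def make_nfc_like_fixture(
    n_tips: int = 1000,
    rates: dict | None = None,
    unknown_fraction: float = 0.0,
    seed: int = 0,
    tree_height: float = 100.0,
    min_gains: int = 2,
    max_regen: int = 20,
    ingroup_fraction: float = 0.5,
) -> FixtureBundle:
    """Simulate a clade-structured multiple-gain history of a binary trait.

    A height-``tree_height`` ultrametric tree is generated, the internal
    node whose clade is closest to ``ingroup_fraction`` of the tips is
    designated the ingroup ancestor and seeded in the precursor class;
    the rest of the tree evolves from the absorbing non-precursor class,
    so outgroup tips stay trait-absent.  The fixture is regenerated with
    an incremented seed (count logged) until the true history contains
    at least ``min_gains`` distinct observed gains.
    """
    if n_tips < 100:
        raise ValueError("fixture needs n_tips >= 100")
    model, theta = nfc_like_model_and_theta(rates)
    space = model.space
    A = 0
    NP, PR = 0, 1
    for regen in range(max_regen):
        s = seed + regen
        tree = simulate_tree(n_tips, seed=s, scale_height=tree_height)
        sizes = {
            int(v): len(tree.subtree_tip_labels(v))
            for v in range(tree.n_nodes)
            if not tree.is_tip(v) and v != tree.root
        }
        target = ingroup_fraction * n_tips
        ingroup = min(sizes, key=lambda v: abs(sizes[v] - target))
        traits, hist = simulate_trait_history(
            tree,
            model,
            theta,
            root_state=space.index(A, NP),
            seed=s,
            forced_states={ingroup: space.index(A, PR)},
        )
        if hist.true_gains() >= min_gains:
            masked = (
                mask_states(traits, unknown_fraction, seed=s)
                if unknown_fraction > 0
                else traits
            )
            ingroup_tips = tree.subtree_tip_labels(ingroup)
            outgroup_tips = [t for t in tree.tip_labels if t not in set(ingroup_tips)]
            return FixtureBundle(
                tree=tree,
                traits=masked,
                full_traits=traits,
                history=hist,
                model=model,
                theta=theta,
                ingroup_node=ingroup,
                clades={"ingroup": ingroup_tips, "outgroup": outgroup_tips},
                seed=seed,
                regenerations=regen,
            )
    raise RuntimeError(
        f"no history with >= {min_gains} gains in {max_regen} regenerations"
    )
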