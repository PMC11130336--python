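"""Tip trait tables and the clade-uniformity backfill rule.

Observed states are small integer codes; ``None`` marks an unknown
('?') tip.  Two state spaces are supported: binary presence/absence of
root nodule symbiosis (0 = absent, 1 = present) and the ternary symbiont
split (0 = absent, 1 = actinorhizal, 2 = rhizobial).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tree import Phylogeny

__all__ = [
    "TraitMatrix",
    "read_trait_table",
    "write_trait_table",
    "backfill_uniform_clades",
    "STATE_SPACES",
]

STATE_SPACES = {
    "binary": ["absent", "present"],
    "ternary": ["absent", "actinorhizal", "rhizobial"],
}

_UNKNOWN_TOKENS = {"?", "NA", "", "nan", "None"}


@dataclass
class TraitMatrix:
    """Tip label -> observed state code (or None for unknown)."""

    states: dict[str, int | None]
    space: str = "binary"

    def __post_init__(self) -> None:
        if self.space not in STATE_SPACES:
            raise ValueError(f"unknown state space {self.space!r}")
        n = self.n_observed
        for lab, s in self.states.items():
            if s is not None and not (0 <= s < n):
                raise ValueError(
                    f"state {s!r} for {lab!r} outside {self.space} space (0..{n - 1})"
                )

    @property
    def n_observed(self) -> int:
        return len(STATE_SPACES[self.space])

    @property
    def state_labels(self) -> list[str]:
        return STATE_SPACES[self.space]

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, label: str) -> int | None:
        return self.states[label]

    def unknown_labels(self) -> set[str]:
        return {lab for lab, s in self.states.items() if s is None}

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(dict(self.states), self.space)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.states),
                "state": ["?" if s is None else s for s in self.states.values()],
            }
        )


def _parse_state(token, space: str, row: int):
    text = str(token).strip()
    if text in _UNKNOWN_TOKENS:
        return None
    try:
        code = int(text)
    except ValueError:
        raise ValueError(f"row {row}: state {token!r} is not an integer code or '?'")
    if not (0 <= code < len(STATE_SPACES[space])):
        raise ValueError(f"row {row}: state code {code} outside {space} space")
    return code


def read_trait_table(path, space: str = "binary", sep: str | None = None) -> TraitMatrix:
    """Read a 2-column delimited table (label, state) with a header row.

    '?'/'NA'/'' map to unknown.  Duplicate labels and codes outside the
    declared space are errors listing the offending rows.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("trait table needs at least 2 columns (label, state)")
    labels = df.iloc[:, 0].astype(str).str.strip()
    dups = labels[labels.duplicated()].tolist()
    if dups:
        raise ValueError(f"duplicate labels in trait table: {sorted(set(dups))}")
    errors, states = [], {}
    for row, (lab, tok) in enumerate(zip(labels, df.iloc[:, 1]), start=2):
        try:
            states[lab] = _parse_state(tok, space, row)
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid state codes: " + "; ".join(errors))
    return TraitMatrix(states, space)


def write_trait_table(traits: TraitMatrix, path, sep: str = ",") -> None:
    traits.to_frame().to_csv(path, sep=sep, index=False)


def backfill_uniform_clades(
    tree: Phylogeny,
    traits: TraitMatrix,
    min_scored: int = 1,
    policy: str = "smallest",
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Assign unscored tips the state of their closest scored relatives in
    state-uniform regions of the tree.

    For each unscored tip, the smallest enclosing clade holding at least
    ``min_scored`` scored tips decides: if all its scored tips share one
    state the tip receives that state, otherwise it stays unknown.
    Already-scored tips are never changed, and the rule is idempotent.

    Returns the new matrix plus a report of assignments
    (columns: label, state, clade_node, clade_scored).
    """
    if policy != "smallest":
        raise ValueError(f"unknown backfill policy {policy!r}")
    for lab in traits.states:
        tree.tip_id(lab)  # raises on tips absent from the tree

    # per-node: set of scored states below, count of scored tips below
    state_sets: list[set[int]] = [set() for _ in range(tree.n_nodes)]
    counts = [0] * tree.n_nodes
    for v in tree.postorder:
        if tree.is_tip(v):
            s = traits.states.get(tree.labels[v])
            if s is not None:
                state_sets[v].add(s)
                counts[v] = 1
        else:
            for c in tree.children[v]:
                state_sets[v] |= state_sets[c]
                counts[v] += counts[c]

    new_states = dict(traits.states)
    rows = []
    for lab, s in traits.states.items():
        if s is not None:
            continue
        v = tree.tip_id(lab)
        while v != tree.root and counts[v] < min_scored:
            v = int(tree.parent[v])
        if counts[v] >= min_scored and len(state_sets[v]) == 1:
            (state,) = state_sets[v]
            new_states[lab] = state
            rows.append(
                {"label": lab, "state": state, "clade_node": v, "clade_scored": counts[v]}
            )
    report = pd.DataFrame(rows, columns=["label", "state", "clade_node", "clade_scored"])
    return TraitMatrix(new_states, traits.space), report
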