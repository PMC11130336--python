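"""Composite state spaces and parameterized transition-rate matrices.

A hidden-rate-class model pairs each observed trait state with an
unobserved rate class; the composite chain moves either between observed
states within a class (trait gain/loss at that class's tempo) or between
classes within an observed state (a shift in evolutionary lability).
Simultaneous "dual" changes of both parts are forbidden by default, the
standard hidden-rates convention.

The rate matrix is encoded by an integer index matrix ``M``: entry 0
means the transition is forbidden (exactly 0 in Q), entry ``p > 0``
means the transition uses free rate parameter ``p - 1``.  Rates are in
events per Myr.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpace",
    "RateModel",
    "build_hidden_rates_model",
    "build_precursor_model",
    "build_three_state_pathway_model",
    "assemble_Q",
    "count_free_params",
]

DEFAULT_BOUNDS = (1e-9, 100.0)


@dataclass(frozen=True)
class StateSpace:
    """Observed states crossed with hidden rate classes.

    Composite index = ``obs_index * n_classes + class_index`` (all
    classes of observed state 0 first, then of state 1, ...).
    """

    observed: tuple[str, ...]
    classes: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.observed)) != len(self.observed):
            raise ValueError("observed state labels must be unique")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class labels must be unique")

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def size(self) -> int:
        return self.n_observed * self.n_classes

    def index(self, obs: int, cls: int) -> int:
        return obs * self.n_classes + cls

    def obs_part(self, composite: int) -> int:
        return composite // self.n_classes

    def class_part(self, composite: int) -> int:
        return composite % self.n_classes

    def composite_label(self, composite: int) -> str:
        return f"{self.observed[self.obs_part(composite)]}/{self.classes[self.class_part(composite)]}"

    def labels(self) -> list[str]:
        return [self.composite_label(i) for i in range(self.size)]

    def observed_mask(self, obs: int) -> np.ndarray:
        """0/1 vector marking composite states whose observed part is ``obs``."""
        m = np.zeros(self.size)
        m[self.index(obs, 0) : self.index(obs, 0) + self.n_classes] = 1.0
        return m


@dataclass
class RateModel:
    """A parameter-indexed rate matrix over a composite state space."""

    space: StateSpace
    index_matrix: np.ndarray  # (S, S) int; 0 forbidden, p>0 -> theta[p-1]
    name: str
    param_names: list[str] = field(default_factory=list)
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self):
        S = self.space.size
        M = np.asarray(self.index_matrix, dtype=int)
        if M.shape != (S, S):
            raise ValueError(f"index matrix must be {S}x{S}")
        np.fill_diagonal(M, 0)
        self.index_matrix = M
        k = self.n_params
        used = set(np.unique(M)) - {0}
        if used != set(range(1, k + 1)):
            raise ValueError("parameter indices must be contiguous 1..k")
        if not self.param_names:
            self.param_names = [f"q{p}" for p in range(1, k + 1)]

    @property
    def n_params(self) -> int:
        return int(self.index_matrix.max())

    def assemble_Q(self, theta) -> np.ndarray:
        return assemble_Q(self, theta)

    # -- serialization ----------------------------------------------------
    def to_config(self, theta=None) -> dict:
        cfg = {
            "name": self.name,
            "observed": list(self.space.observed),
            "classes": list(self.space.classes),
            "index_matrix": self.index_matrix.tolist(),
            "param_names": list(self.param_names),
            "bounds": list(self.bounds),
        }
        if theta is not None:
            cfg["theta"] = list(map(float, theta))
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "RateModel":
        return cls(
            space=StateSpace(tuple(cfg["observed"]), tuple(cfg["classes"])),
            index_matrix=np.array(cfg["index_matrix"], dtype=int),
            name=cfg["name"],
            param_names=list(cfg.get("param_names", [])),
            bounds=tuple(cfg.get("bounds", DEFAULT_BOUNDS)),
        )

    def to_json(self, path, theta=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_config(theta), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RateModel":
        with open(path) as fh:
            return cls.from_config(json.load(fh))


def assemble_Q(model: RateModel, theta) -> np.ndarray:
    """Fill Q off-diagonals from theta via the index matrix; each row sums
    to 0.  Forbidden entries are exactly 0 for any theta."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.n_params,):
        raise ValueError(f"theta must have length {model.n_params}, got {theta.shape}")
    if np.any(theta < 0):
        raise ValueError("rates must be >= 0")
    M = model.index_matrix
    Q = np.zeros(M.shape)
    nz = M > 0
    Q[nz] = theta[M[nz] - 1]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def count_free_params(model: RateModel) -> int:
    return model.n_params


def _finalize(space, allowed, name, rates_equal=False):
    """Number the allowed directed transitions into an index matrix."""
    S = space.size
    M = np.zeros((S, S), dtype=int)
    names = []
    for p, (i, j, label) in enumerate(allowed, start=1):
        M[i, j] = 1 if rates_equal else p
        names.append(label)
    if rates_equal:
        names = ["rate"]
    return RateModel(space=space, index_matrix=M, name=name, param_names=names)


def _default_obs_labels(n_observed: int) -> tuple[str, ...]:
    if n_observed == 2:
        return ("absent", "present")
    if n_observed == 3:
        return ("absent", "actinorhizal", "rhizobial")
    raise ValueError("n_observed must be 2 or 3")


def build_hidden_rates_model(
    n_observed: int = 2,
    n_classes: int = 1,
    no_gain_class: str | int | None = None,
    rates_equal: bool = False,
    allow_dual: bool = False,
) -> RateModel:
    """Fully unequal-rates hidden-class model (corHMM-style).

    Allowed transitions: every observed-state change within a class and
    every directed class change within an observed state, each with its
    own rate (``rates_equal=True`` collapses them to a single shared
    rate).  ``no_gain_class`` names a class in which gains (transitions
    out of observed state 0 into a trait-present state) are forbidden,
    modelling lineages with no pathway to the trait.  ``allow_dual=True``
    additionally permits simultaneous changes of both parts (off by
    default).
    """
    if not (1 <= n_classes <= 5):
        raise ValueError("n_classes must be in 1..5")
    obs = _default_obs_labels(n_observed)
    classes = tuple(f"R{c + 1}" for c in range(n_classes))
    space = StateSpace(obs, classes)
    if no_gain_class is not None:
        if isinstance(no_gain_class, int):
            if not (0 <= no_gain_class < n_classes):
                raise ValueError(f"no-gain class index {no_gain_class} out of range")
            no_gain = no_gain_class
        else:
            if no_gain_class not in classes:
                raise ValueError(f"no-gain class {no_gain_class!r} not in {classes}")
            no_gain = classes.index(no_gain_class)
    else:
        no_gain = None

    allowed = []
    for a in range(n_observed):
        for b in range(n_observed):
            for ca in range(n_classes):
                for cb in range(n_classes):
                    i, j = space.index(a, ca), space.index(b, cb)
                    if i == j:
                        continue
                    obs_change, cls_change = a != b, ca != cb
                    if obs_change and cls_change and not allow_dual:
                        continue
                    if obs_change and a == 0 and ca == no_gain and (cb == no_gain or allow_dual):
                        continue  # no gains from the no-gain class
                    allowed.append((i, j, f"{space.composite_label(i)}->{space.composite_label(j)}"))
    tag = "" if no_gain is None else f"+nogain({classes[no_gain]})"
    kind = "ER" if rates_equal else "ARD"
    name = f"hidden{n_classes}_{kind}{tag}" if n_observed == 2 else f"hidden{n_classes}o{n_observed}_{kind}{tag}"
    return _finalize(space, allowed, name, rates_equal)


def build_precursor_model() -> RateModel:
    """The classical two-rate precursor model of trait gain.

    Absent lineages are split into a non-precursor and a precursor
    class; the trait can only be gained from the precursor
    (absent/nonprecursor <-> absent/precursor -> present, with loss back
    to the precursor).
    """
    space = StateSpace(("absent", "present"), ("nonprecursor", "precursor"))
    NP, P = 0, 1
    allowed = [
        (space.index(0, NP), space.index(0, P), "absent/NP->absent/P"),
        (space.index(0, P), space.index(0, NP), "absent/P->absent/NP"),
        (space.index(0, P), space.index(1, P), "gain"),
        (space.index(1, P), space.index(0, P), "loss"),
    ]
    return _finalize(space, allowed, "precursor2")


def build_three_state_pathway_model() -> RateModel:
    """Two-rate, three-state stepping-stone model of nodulation gain.

    Observed states are absent, actinorhizal and rhizobial; two hidden
    classes (non-precursor, precursor).  Actinorhizal symbiosis is
    gained only from the precursor class of the absent state, rhizobial
    symbiosis only from the actinorhizal state; losses return to the
    absent state within a class, and class changes occur within the
    absent state.  The direct absent -> rhizobial transition is
    forbidden.
    """
    space = StateSpace(
        ("absent", "actinorhizal", "rhizobial"), ("nonprecursor", "precursor")
    )
    NP, P = 0, 1
    allowed = [
        (space.index(0, NP), space.index(0, P), "absent/NP->absent/P"),
        (space.index(0, P), space.index(0, NP), "absent/P->absent/NP"),
        (space.index(0, P), space.index(1, P), "gain_actinorhizal"),
        (space.index(1, NP), space.index(2, NP), "gain_rhizobial/NP"),
        (space.index(1, P), space.index(2, P), "gain_rhizobial/P"),
        (space.index(1, NP), space.index(0, NP), "loss_actinorhizal/NP"),
        (space.index(1, P), space.index(0, P), "loss_actinorhizal/P"),
        (space.index(2, NP), space.index(0, NP), "loss_rhizobial/NP"),
        (space.index(2, P), space.index(0, P), "loss_rhizobial/P"),
    ]
    return _finalize(space, allowed, "pathway3state")
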