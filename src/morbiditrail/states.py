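"""Nine-state progression state space for a three-disease comorbidity trio.

States (1-indexed):

1. healthy — no chronic disease
2. non-trio disease only
3. first trio disease only      6. first + second
4. second trio disease only     7. first + third
5. third trio disease only      8. second + third
9. all three (absorbing)

Allowed transitions add one disease at a time: 1→{2,3,4,5}, 2→{3,4,5},
each single state to the two duals containing it, each dual to 9.
State 9 has no outgoing edges.  Non-trio diseases never remove a person
from states 3–9: those states are defined by the trio-component subset
present, and state 2 applies only when no trio component is present.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .conditions import DISEASE_GROUPS, DiseaseProfile

N_STATES = 9

#: allowed one-disease-at-a-time progression edges, 1-indexed
DEFAULT_EDGES: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (1, 4), (1, 5),
    (2, 3), (2, 4), (2, 5),
    (3, 6), (3, 7),
    (4, 6), (4, 8),
    (5, 7), (5, 8),
    (6, 9), (7, 9), (8, 9),
)


@dataclass(frozen=True)
class StateSpace:
    """State labels, trio assignment and allowed-transition structure."""

    trio: tuple[str, str, str]
    adjacency: np.ndarray = field(repr=False)  # 9x9 boolean, [i-1, j-1]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (N_STATES, N_STATES):
            raise ValueError("adjacency must be 9x9")
        if adj[N_STATES - 1].any():
            raise ValueError("state 9 must be absorbing (no outgoing edges)")
        if not nx.is_directed_acyclic_graph(nx.DiGraph(adj)):
            raise ValueError("allowed-transition graph must be acyclic")
        object.__setattr__(self, "adjacency", adj)

    @property
    def labels(self) -> tuple[str, ...]:
        a, b, c = self.trio
        return (
            "healthy",
            "non-trio disease",
            a, b, c,
            f"{a}+{b}", f"{a}+{c}", f"{b}+{c}",
            f"{a}+{b}+{c}",
        )

    @property
    def absorbing(self) -> tuple[int, ...]:
        return tuple(
            i + 1 for i in range(N_STATES) if not self.adjacency[i].any()
        )

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        rows, cols = np.nonzero(self.adjacency)
        return tuple((int(i) + 1, int(j) + 1) for i, j in zip(rows, cols))

    def reachability(self) -> np.ndarray:
        """Boolean 9x9 matrix: multi-step path (incl. staying) i→j exists."""
        m = self.adjacency.astype(np.int64) + np.eye(N_STATES, dtype=np.int64)
        return np.linalg.matrix_power(m, N_STATES) > 0


def build_state_space(trio=("CVD", "MTD", "SMD"), edges=DEFAULT_EDGES) -> StateSpace:
    """Construct the 9-state space for a trio of disease-system labels.

    ``trio`` order fixes which disease is "first/second/third" and hence
    which single state (3/4/5) and dual state (6/7/8) each maps to.
    """
    trio = tuple(str(t).upper() for t in trio)
    if len(set(trio)) != 3 or not set(trio) <= set(DISEASE_GROUPS):
        raise ValueError(
            f"trio must be 3 distinct labels from {DISEASE_GROUPS}, got {trio}"
        )
    adj = np.zeros((N_STATES, N_STATES), dtype=bool)
    for i, j in edges:
        adj[i - 1, j - 1] = True
    return StateSpace(trio=trio, adjacency=adj)


#: trio-component subset → state, keyed by (first present, second, third)
_SUBSET_STATE = {
    (): None,  # resolved to 1 or 2 by non-trio flags
    (0,): 3, (1,): 4, (2,): 5,
    (0, 1): 6, (0, 2): 7, (1, 2): 8,
    (0, 1, 2): 9,
}


def assign_state(profile: DiseaseProfile, trio=("CVD", "MTD", "SMD")) -> int:
    """Map a disease profile to a state index in 1..9.

    The trio-component subset alone determines states 3–9; state 2 is
    assigned only when no trio component is present but some other
    disease is.
    """
    trio = tuple(str(t).upper() for t in trio)
    present = profile.present_groups()
    subset = tuple(k for k, d in enumerate(trio) if d in present)
    state = _SUBSET_STATE[subset]
    if state is not None:
        return state
    return 2 if (present - set(trio)) else 1


def state_trio_flags(state: int) -> tuple[int, int, int]:
    """Presence flags of (first, second, third) trio disease in a state."""
    flags = {
        1: (0, 0, 0), 2: (0, 0, 0),
        3: (1, 0, 0), 4: (0, 1, 0), 5: (0, 0, 1),
        6: (1, 1, 0), 7: (1, 0, 1), 8: (0, 1, 1),
        9: (1, 1, 1),
    }
    return flags[state]
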