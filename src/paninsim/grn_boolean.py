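"""Boolean dynamics of the pancreatic gene-regulatory network.

The network couples two exogenous cytokine inputs (``x1`` = TNFa, ``x2`` =
TGFb1) to twelve regulated agents: four stellate-cell genes (``y1``..``y4``),
four cancer-cell genes (``c1``..``c4``) and four phenotype read-outs
(``z1``..``z4``).  Two literals carry explicit time delays and are treated
here as frozen exogenous bits: ``y1_delayed`` (past RAS) and ``c3_delayed``
(past mutated PIP3).

Rules are stored in a small structured form -- a conjunction of OR-groups of
possibly negated literals -- which both the Boolean evaluator and the
continuous translation (:mod:`paninsim.grn_dde`) share.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

__all__ = [
    "AGENTS",
    "INPUT_AGENTS",
    "REGULATED_AGENTS",
    "DELAYED_LITERALS",
    "NetworkVariant",
    "BooleanState",
    "Literal",
    "rule_groups",
    "rule_string",
    "eval_agent",
    "step_sync",
    "enumerate_attractors",
    "network_json",
]

#: Agent name -> biological identity.
AGENTS = {
    "x1": "TNFa",
    "x2": "TGFb1",
    "y1": "RAS",
    "y2": "P53",
    "y3": "PIP3",
    "y4": "ERK",
    "c1": "BCL-XL",
    "c2": "P53c",
    "c3": "PIP3c",
    "c4": "P21",
    "z1": "healthy apoptosis",
    "z2": "healthy proliferation",
    "z3": "cancer apoptosis",
    "z4": "cancer proliferation",
}

INPUT_AGENTS = ("x1", "x2")
REGULATED_AGENTS = ("y1", "y2", "y3", "y4", "c1", "c2", "c3", "c4", "z1", "z2", "z3", "z4")
#: Names of the frozen delayed copies available as literals.
DELAYED_LITERALS = ("y1_delayed", "c3_delayed")


class NetworkVariant(str, Enum):
    """Which wiring of the RAS rule is used.

    In the healthy variant the mutated-PIP3 literal ``c3`` is removed from
    the RAS rule; everything else is identical.
    """

    CANCER = "cancer"
    HEALTHY = "healthy"


@dataclass(frozen=True)
class Literal:
    """A single (possibly negated) occurrence of an agent in a rule."""

    name: str
    negated: bool = False

    def value(self, lookup) -> int:
        v = lookup(self.name)
        return (1 - v) if self.negated else v


def _lit(spec: str) -> Literal:
    if spec.startswith("-"):
        return Literal(spec[1:], negated=True)
    return Literal(spec)


def _groups(*groups: tuple[str, ...]) -> tuple[tuple[Literal, ...], ...]:
    return tuple(tuple(_lit(s) for s in g) for g in groups)


# Each rule is an AND of OR-groups.  A lone literal forms a 1-element group.
# The P53c rule -(c2||c3)&(-c3||c4) is expanded by De Morgan into
# (-c2)&(-c3)&(-c3||c4).
_RULES_CANCER: dict[str, tuple[tuple[Literal, ...], ...]] = {
    "y1": _groups(("x1", "y3", "y4", "c3", "y1_delayed")),
    "y2": _groups(("y1",), ("-y2",), ("-y3",)),
    "y3": _groups(("y4",), ("-y2",)),
    "y4": _groups(("x2", "y1")),
    "c1": _groups(("c3", "y1_delayed"), ("-c2",)),
    "c2": _groups(("-c2",), ("-c3",), ("-c3", "c4")),
    "c3": _groups(("-c2",), ("y1_delayed",)),
    "c4": _groups(("x2", "c2")),
    "z1": _groups(("y2",)),
    "z2": _groups(("y3",)),
    "z3": _groups(("-c3",), ("-c1", "c2"), ("z3",)),
    "z4": _groups(("y1_delayed",), ("c3_delayed",), ("-c4",)),
}

_RULES_HEALTHY = dict(_RULES_CANCER)
_RULES_HEALTHY["y1"] = _groups(("x1", "y3", "y4", "y1_delayed"))

#: Human-readable rule strings (table syntax) keyed by variant then agent.
_RULE_STRINGS = {
    NetworkVariant.CANCER: {
        "y1": "(x1||y3||y4||c3||y^1)",
        "y2": "(y1)&(-y2)&(-y3)",
        "y3": "(y4)&(-y2)",
        "y4": "(x2||y1)",
        "c1": "(c3||y^1)&(-c2)",
        "c2": "-(c2||c3)&(-c3||c4)",
        "c3": "(-c2)&(y^1)",
        "c4": "(x2||c2)",
        "z1": "(y2)",
        "z2": "(y3)",
        "z3": "(-c3)&(-c1||c2)&(z3)",
        "z4": "(y^1)&(c^3)&(-c4)",
    },
}
_RULE_STRINGS[NetworkVariant.HEALTHY] = dict(
    _RULE_STRINGS[NetworkVariant.CANCER], y1="(x1||y3||y4||y^1)"
)


def rule_groups(agent: str, variant: NetworkVariant) -> tuple[tuple[Literal, ...], ...]:
    """Structured rule (AND of OR-groups) for a regulated agent."""
    if agent in INPUT_AGENTS:
        raise ValueError(f"agent {agent!r} is an exogenous input and has no rule")
    rules = _RULES_HEALTHY if variant is NetworkVariant.HEALTHY else _RULES_CANCER
    try:
        return rules[agent]
    except KeyError:
        raise ValueError(f"unknown agent {agent!r}") from None


def rule_string(agent: str, variant: NetworkVariant) -> str:
    return _RULE_STRINGS[NetworkVariant(variant)][agent]


@dataclass(frozen=True)
class BooleanState:
    """Full Boolean state: 12 regulated bits, 2 inputs, 2 frozen delayed bits."""

    values: tuple[int, ...]  # regulated agents, order of REGULATED_AGENTS
    x1: int = 0
    x2: int = 0
    y1_delayed: int = 0
    c3_delayed: int = 0

    def __post_init__(self):
        if len(self.values) != len(REGULATED_AGENTS):
            raise ValueError("need exactly 12 regulated agent values")
        for b in (*self.values, self.x1, self.x2, self.y1_delayed, self.c3_delayed):
            if b not in (0, 1):
                raise ValueError("Boolean state entries must be 0 or 1")

    def __getitem__(self, name: str) -> int:
        if name == "x1":
            return self.x1
        if name == "x2":
            return self.x2
        if name == "y1_delayed":
            return self.y1_delayed
        if name == "c3_delayed":
            return self.c3_delayed
        try:
            return self.values[REGULATED_AGENTS.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def as_dict(self) -> dict[str, int]:
        d = {a: v for a, v in zip(REGULATED_AGENTS, self.values)}
        d.update(x1=self.x1, x2=self.x2, y1_delayed=self.y1_delayed, c3_delayed=self.c3_delayed)
        return d


def eval_agent(agent: str, state: BooleanState, variant: NetworkVariant) -> int:
    """Truth value of ``agent``'s rule on ``state`` (AND over OR-groups)."""
    groups = rule_groups(agent, variant)
    for group in groups:
        if not any(lit.value(state.__getitem__) for lit in group):
            return 0
    return 1


def step_sync(state: BooleanState, variant: NetworkVariant) -> BooleanState:
    """Synchronous update: every regulated agent re-evaluated on the old state."""
    new = tuple(eval_agent(a, state, variant) for a in REGULATED_AGENTS)
    return BooleanState(
        new,
        x1=state.x1,
        x2=state.x2,
        y1_delayed=state.y1_delayed,
        c3_delayed=state.c3_delayed,
    )


def _iter_states() -> Iterator[tuple[int, ...]]:
    n = len(REGULATED_AGENTS)
    for code in range(1 << n):
        yield tuple((code >> i) & 1 for i in range(n))


def _encode(values: tuple[int, ...]) -> int:
    code = 0
    for i, b in enumerate(values):
        code |= b << i
    return code


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Rotate a cycle so it starts at its smallest state code."""
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def enumerate_attractors(
    variant: NetworkVariant,
    inputs: tuple[int, int] = (0, 0),
    delays: tuple[int, int] = (0, 0),
) -> list[tuple[tuple[int, ...], ...]]:
    """All attractors of the synchronous map over the 2**12 regulated states.

    Inputs and the two delayed literals are held fixed (frozen-delay
    approximation).  Returns a sorted list of cycles; each cycle is a tuple
    of states (each a 12-tuple in ``REGULATED_AGENTS`` order), rotated to
    start at its smallest encoding.  Fixed points are 1-cycles.
    """
    x1, x2 = inputs
    hy1, hc3 = delays
    n = len(REGULATED_AGENTS)
    size = 1 << n

    # Transition table.
    succ = [0] * size
    for values in _iter_states():
        s = BooleanState(values, x1=x1, x2=x2, y1_delayed=hy1, c3_delayed=hc3)
        succ[_encode(values)] = _encode(step_sync(s, variant).values)

    # Locate cycles of the functional graph.
    state_of = [0] * size  # 0 unvisited, 1 in progress, 2 done
    on_cycle = [False] * size
    for start in range(size):
        if state_of[start]:
            continue
        path = []
        node = start
        while state_of[node] == 0:
            state_of[node] = 1
            path.append(node)
            node = succ[node]
        if state_of[node] == 1:  # found a new cycle
            k = path.index(node)
            for c in path[k:]:
                on_cycle[c] = True
        for p in path:
            state_of[p] = 2

    seen: set[int] = set()
    cycles: list[tuple[int, ...]] = []
    for node in range(size):
        if on_cycle[node] and node not in seen:
            cyc = [node]
            cur = succ[node]
            while cur != node:
                cyc.append(cur)
                cur = succ[cur]
            seen.update(cyc)
            cycles.append(_canonical_cycle(cyc))

    cycles.sort()
    decode = lambda code: tuple((code >> i) & 1 for i in range(n))  # noqa: E731
    return [tuple(decode(c) for c in cyc) for cyc in cycles]


def network_json(variant: NetworkVariant = NetworkVariant.CANCER) -> str:
    """Serialize the network (agents, rule strings, variant) as JSON."""
    doc = {
        "variant": NetworkVariant(variant).value,
        "agents": AGENTS,
        "inputs": list(INPUT_AGENTS),
        "delayed_literals": list(DELAYED_LITERALS),
        "rules": {a: rule_string(a, variant) for a in REGULATED_AGENTS},
    }
    return json.dumps(doc, indent=2)
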