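"""Time-reversible substitution-model space: encoding, enumeration, split/merge graph.

A time-reversible nucleotide substitution model is determined, up to its
stationary frequencies, by the six exchangeability rates in the fixed order
(ac, ag, at, cg, ct, gt).  A *model* in the sense of this package is a
grouping (set partition) of those six rates: rates in the same group are
constrained to be equal.  A grouping is written as a six-symbol code in
restricted-growth (lowest-number) canonical form, e.g. ``111111`` ties all
six rates (Jukes-Cantor), ``121121`` ties the four transversions and the two
transitions (HKY), and ``123456`` leaves all rates free (GTR).

Three model sets are supported:

``all_reversible``
    every set partition of the six rates — 203 models (the Bell number B6);
``tstv_split``
    partitions in which no group mixes a transition rate (ag, ct) with a
    transversion rate (ac, at, cg, gt), plus the all-equal model 111111 as
    the sole exception — 31 models;
``named``
    a nested ladder of nine classically named models (JC, HKY, TN93, K81,
    TIM, TVM, GTR and the two intermediates 123345 and 123324).

Models are organised in a directed graph whose edges connect a model to the
models obtained by splitting exactly one rate group into two non-empty
parts.  Split/merge reversible-jump moves walk this graph.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterator, List, Sequence, Tuple

__all__ = [
    "RATE_ORDER",
    "TRANSITION_POSITIONS",
    "ModelId",
    "ModelGraph",
    "ModelSet",
    "canonicalize",
    "enumerate_models",
    "build_model_graph",
    "split_candidates",
    "merge_candidates",
    "model_log_prior",
    "NAMED_MODEL_CODES",
]

#: Fixed ordering of the six exchangeability rates; every length-6 vector in
#: the package uses this order.
RATE_ORDER: Tuple[str, ...] = ("ac", "ag", "at", "cg", "ct", "gt")

#: Positions (into RATE_ORDER) of the two transition rates A<->G and C<->T.
TRANSITION_POSITIONS: Tuple[int, int] = (1, 4)

#: The nine-member named-model ladder: JC, HKY, TN93, K81, TIM, TVM, GTR plus
#: the two intermediates that make the ladder connected by single splits.
NAMED_MODEL_CODES: Tuple[str, ...] = (
    "111111",  # JC
    "121121",  # HKY
    "121131",  # TN93
    "123321",  # K81
    "123341",  # TIM
    "123425",  # TVM
    "123456",  # GTR
    "123345",  # intermediate TIM <-> GTR
    "123324",  # intermediate K81 <-> TVM
)

MODEL_SET_KINDS = ("all_reversible", "tstv_split", "named")
MODEL_PRIOR_KINDS = ("uniform_models", "uniform_dof")


@dataclass(frozen=True)
class ModelId:
    """Canonical identifier of a rate grouping.

    ``code`` is the restricted-growth string as a tuple of small integers:
    the first symbol is 1 and each new symbol is one larger than the maximum
    of all previous symbols.  Equal integers tie the corresponding rates.
    """

    code: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.code) != len(RATE_ORDER):
            raise ValueError(f"model code must have {len(RATE_ORDER)} entries, got {len(self.code)}")
        mx = 0
        for v in self.code:
            if not isinstance(v, int) or v < 1 or v > mx + 1:
                raise ValueError(f"{self.code} is not a canonical (restricted-growth) code")
            mx = max(mx, v)

    @classmethod
    def from_string(cls, s: str) -> "ModelId":
        s = s.replace(",", "").strip()
        if not s.isdigit():
            raise ValueError(f"cannot parse model code {s!r}")
        return cls(tuple(int(c) for c in s))

    @cached_property
    def labels(self) -> Tuple[int, ...]:
        """Zero-based group label per rate position."""
        return tuple(v - 1 for v in self.code)

    @cached_property
    def groups(self) -> Tuple[Tuple[int, ...], ...]:
        """Rate positions per group, in group-label order."""
        out: List[List[int]] = [[] for _ in range(self.n_groups)]
        for pos, lab in enumerate(self.labels):
            out[lab].append(pos)
        return tuple(tuple(g) for g in out)

    @cached_property
    def group_sizes(self) -> Tuple[int, ...]:
        return tuple(len(g) for g in self.groups)

    @property
    def n_groups(self) -> int:
        return max(self.code)

    @property
    def dof(self) -> int:
        """Degrees of freedom of the grouping: number of groups minus one."""
        return self.n_groups - 1

    def __str__(self) -> str:
        return "".join(str(v) for v in self.code)

    def __repr__(self) -> str:
        return f"ModelId({self})"


def canonicalize(raw_code: Sequence[int]) -> ModelId:
    """Relabel an arbitrary grouping code to canonical restricted-growth form.

    Equal entries of ``raw_code`` define the grouping; the canonical form
    relabels groups 1, 2, ... in order of first appearance, so e.g. 646646
    and 212212 both canonicalize to 121121.
    """
    if len(raw_code) != len(RATE_ORDER):
        raise ValueError(f"model code must have {len(RATE_ORDER)} entries, got {len(raw_code)}")
    mapping: Dict[int, int] = {}
    out = []
    for v in raw_code:
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out.append(mapping[v])
    return ModelId(tuple(out))


def _iter_restricted_growth(n: int = 6) -> Iterator[Tuple[int, ...]]:
    """Yield all restricted-growth strings of length n (all set partitions)."""
    code = [1] * n

    def rec(i: int, mx: int) -> Iterator[Tuple[int, ...]]:
        if i == n:
            yield tuple(code)
            return
        for v in range(1, mx + 2):
            code[i] = v
            yield from rec(i + 1, max(mx, v))

    yield from rec(1, 1)


def _mixes_ts_tv(model: ModelId) -> bool:
    """True if some group contains both a transition and a transversion rate."""
    ts = set(TRANSITION_POSITIONS)
    for grp in model.groups:
        has_ts = any(p in ts for p in grp)
        has_tv = any(p not in ts for p in grp)
        if has_ts and has_tv:
            return True
    return False


def enumerate_models(set_kind: str) -> List[ModelId]:
    """Enumerate the canonical models of one of the three supported sets.

    Returns a sorted, duplicate-free list.  ``all_reversible`` yields 203
    models, ``tstv_split`` 31, and ``named`` 9.
    """
    if set_kind not in MODEL_SET_KINDS:
        raise ValueError(f"unknown model set kind {set_kind!r}; expected one of {MODEL_SET_KINDS}")
    if set_kind == "named":
        models = [ModelId.from_string(s) for s in NAMED_MODEL_CODES]
    else:
        models = [ModelId(c) for c in _iter_restricted_growth()]
        if set_kind == "tstv_split":
            jc = ModelId.from_string("111111")
            models = [m for m in models if m == jc or not _mixes_ts_tv(m)]
    return sorted(set(models), key=lambda m: (m.n_groups, m.code))


def _children_of(model: ModelId) -> List[ModelId]:
    """All models obtained by splitting exactly one group into two parts."""
    out = []
    for gi, grp in enumerate(model.groups):
        if len(grp) < 2:
            continue
        rest = grp[1:]
        # Enumerate proper subsets of the group that contain its first member
        # (each unordered split counted once).
        for mask in range(2 ** len(rest) - 1):
            raw = list(model.code)
            new_label = model.n_groups + 1
            for b, pos in enumerate(rest):
                if not (mask >> b) & 1:
                    raw[pos] = new_label
            out.append(canonicalize(raw))
    return out


@dataclass(frozen=True)
class _SplitInfo:
    """Bookkeeping for a single split edge parent -> child.

    ``parent_group``: index of the parent group that was split;
    ``child_i``/``child_j``: indices of the two resulting child groups;
    ``child_to_parent``: parent group index for every child group
    (the two new groups both map to ``parent_group``).
    """

    parent_group: int
    child_i: int
    child_j: int
    child_to_parent: Tuple[int, ...]


@dataclass
class ModelGraph:
    """Directed split graph over a set of models.

    An edge A -> B exists iff B's partition refines A's by splitting exactly
    one group into two non-empty parts and both A and B belong to the set.
    """

    nodes: Tuple[ModelId, ...]
    children: Dict[Tuple[int, ...], Tuple[ModelId, ...]]
    parents: Dict[Tuple[int, ...], Tuple[ModelId, ...]]
    _split_info: Dict[Tuple[Tuple[int, ...], Tuple[int, ...]], _SplitInfo] = field(
        default_factory=dict, repr=False
    )

    def __contains__(self, m: ModelId) -> bool:
        return m.code in self.children

    def split_candidates(self, m: ModelId) -> Tuple[ModelId, ...]:
        if m.code not in self.children:
            raise KeyError(f"model {m} not in graph")
        return self.children[m.code]

    def merge_candidates(self, m: ModelId) -> Tuple[ModelId, ...]:
        if m.code not in self.parents:
            raise KeyError(f"model {m} not in graph")
        return self.parents[m.code]

    def split_info(self, parent: ModelId, child: ModelId) -> _SplitInfo:
        """Identify which parent group splits into which two child groups."""
        key = (parent.code, child.code)
        info = self._split_info.get(key)
        if info is not None:
            return info
        pgroups = [frozenset(g) for g in parent.groups]
        cgroups = [frozenset(g) for g in child.groups]
        child_to_parent = []
        new_children = []
        split_parent = -1
        for ci, cg in enumerate(cgroups):
            pi = next(i for i, pg in enumerate(pgroups) if cg <= pg)
            child_to_parent.append(pi)
            if cg != pgroups[pi]:
                new_children.append(ci)
                split_parent = pi
        if len(new_children) != 2:
            raise ValueError(f"{child} does not refine {parent} by a single split")
        info = _SplitInfo(split_parent, new_children[0], new_children[1], tuple(child_to_parent))
        self._split_info[key] = info
        return info

    def to_dot(self) -> str:
        lines = ["digraph models {"]
        for m in self.nodes:
            lines.append(f'  "{m}";')
        for m in self.nodes:
            for c in self.children[m.code]:
                lines.append(f'  "{m}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [str(m) for m in self.nodes],
                "split_edges": [
                    [str(m), str(c)] for m in self.nodes for c in self.children[m.code]
                ],
            },
            indent=1,
        )


def build_model_graph(models: Sequence[ModelId]) -> ModelGraph:
    """Build the split/merge graph over ``models`` from the refinement rule."""
    codes = {m.code for m in models}
    if len(codes) != len(models):
        raise ValueError("model list contains duplicates")
    children: Dict[Tuple[int, ...], Tuple[ModelId, ...]] = {}
    parents: Dict[Tuple[int, ...], List[ModelId]] = {m.code: [] for m in models}
    for m in models:
        kids = sorted({c for c in _children_of(m) if c.code in codes}, key=lambda x: x.code)
        children[m.code] = tuple(kids)
        for c in kids:
            parents[c.code].append(m)
    return ModelGraph(
        nodes=tuple(sorted(models, key=lambda m: (m.n_groups, m.code))),
        children=children,
        parents={k: tuple(sorted(v, key=lambda x: x.code)) for k, v in parents.items()},
    )


def split_candidates(m: ModelId, g: ModelGraph) -> List[ModelId]:
    """Models reachable from ``m`` by splitting one group (children in the graph)."""
    return list(g.split_candidates(m))


def merge_candidates(m: ModelId, g: ModelGraph) -> List[ModelId]:
    """Models reachable from ``m`` by merging two groups (parents in the graph)."""
    return list(g.merge_candidates(m))


class ModelSet:
    """A model set together with its split graph and degree-of-freedom census."""

    def __init__(self, models: Sequence[ModelId], kind: str = "custom"):
        self.kind = kind
        self.models: Tuple[ModelId, ...] = tuple(sorted(set(models), key=lambda m: (m.n_groups, m.code)))
        self.by_code: Dict[Tuple[int, ...], ModelId] = {m.code: m for m in self.models}
        self.graph: ModelGraph = build_model_graph(self.models)
        self.dof_counts: Dict[int, int] = {}
        for m in self.models:
            self.dof_counts[m.dof] = self.dof_counts.get(m.dof, 0) + 1

    @classmethod
    def create(cls, set_kind: str) -> "ModelSet":
        return cls(enumerate_models(set_kind), kind=set_kind)

    def __len__(self) -> int:
        return len(self.models)

    def __contains__(self, m: ModelId) -> bool:
        return m.code in self.by_code

    def __iter__(self):
        return iter(self.models)


def model_log_prior(m: ModelId, model_set: ModelSet, prior_kind: str) -> float:
    """Log prior probability of a model under the chosen model prior.

    ``uniform_models`` puts equal mass on every member; ``uniform_dof`` puts
    total mass 1/6 on each degrees-of-freedom class 0..5, split evenly within
    the class (so the all-equal and the all-free model each get exactly 1/6
    when they are the sole members of their class).
    """
    if prior_kind not in MODEL_PRIOR_KINDS:
        raise ValueError(f"unknown model prior kind {prior_kind!r}")
    if m.code not in model_set.by_code:
        raise ValueError(f"model {m} not in the {model_set.kind} set")
    if prior_kind == "uniform_models":
        return -math.log(len(model_set))
    n_classes = len(model_set.dof_counts)
    return -math.log(n_classes) - math.log(model_set.dof_counts[m.dof])
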