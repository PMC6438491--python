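"""Minimal discrete causal Bayesian networks over binary nodes.

Just enough machinery for the three-node depression/fear/loathing arguments:
factorized joints, stochastic-intervention graph surgery, and discrimination
among the three candidate causal structures (common cause D -> F, D -> L;
chain F -> D -> L; chain L -> D -> F) from how the manifest marginals move
when the latent node is intervened on.

Networks are dense: one conditional probability table per node, stored as an
array of shape (2,) * n_parents + (2,), last axis over the node's own value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .model_core import LCAParameters

__all__ = [
    "DiscreteBayesNet",
    "StochasticIntervention",
    "JointDistribution",
    "joint_from_network",
    "apply_stochastic_intervention",
    "discriminate_structure",
    "DiscriminationResult",
    "common_cause_net",
    "chain_net",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True, eq=False)
class DiscreteBayesNet:
    """A DAG over binary nodes with one conditional probability table each.

    ``parents`` maps each node to an ordered tuple of parent names; the CPT
    for a node is indexed first by the parent values (in that order), then by
    the node's own value.
    """

    nodes: tuple
    parents: dict
    cpts: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        parents = {n: tuple(self.parents.get(n, ())) for n in self.nodes}
        object.__setattr__(self, "parents", parents)
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        for child, pars in parents.items():
            for p in pars:
                if p not in self.nodes:
                    raise ValueError(f"parent {p!r} of {child!r} is not a node")
                graph.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("the parent structure contains a cycle")
        cpts = {}
        for n in self.nodes:
            if n not in self.cpts:
                raise ValueError(f"missing conditional probability table for {n!r}")
            table = np.asarray(self.cpts[n], dtype=float)
            want = (2,) * len(parents[n]) + (2,)
            if table.shape != want:
                raise ValueError(
                    f"table for {n!r} must have shape {want}, got {table.shape}"
                )
            if np.any(table < 0) or np.any(np.abs(table.sum(axis=-1) - 1.0) > _SUM_TOL):
                raise ValueError(f"rows of the table for {n!r} are not distributions")
            cpts[n] = table
        object.__setattr__(self, "cpts", cpts)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, pars in self.parents.items():
            g.add_edges_from((p, child) for p in pars)
        return g

    def descendants(self, node: str) -> set:
        return nx.descendants(self.graph(), node)


@dataclass(frozen=True)
class StochasticIntervention:
    """Set a new marginal distribution on a target node (graph surgery)."""

    target: str
    marginal: tuple

    def __post_init__(self) -> None:
        m = tuple(float(v) for v in self.marginal)
        if len(m) != 2 or any(v < 0 for v in m) or abs(sum(m) - 1.0) > _SUM_TOL:
            raise ValueError("marginal must be a distribution over {0, 1}")
        object.__setattr__(self, "marginal", m)

    @classmethod
    def set_prevalence(cls, target: str, p1: float) -> "StochasticIntervention":
        return cls(target=target, marginal=(1.0 - p1, p1))


@dataclass(frozen=True, eq=False)
class JointDistribution:
    """A full joint over named binary variables, axes in ``nodes`` order."""

    nodes: tuple
    table: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        table = np.asarray(self.table, dtype=float)
        if table.shape != (2,) * len(self.nodes):
            raise ValueError("table shape must be (2,) * number of nodes")
        if np.any(table < -_SUM_TOL) or abs(table.sum() - 1.0) > _SUM_TOL:
            raise ValueError("joint table must be a distribution")
        object.__setattr__(self, "table", table)

    def marginal(self, node: str) -> np.ndarray:
        """The (2,) marginal distribution of one variable."""
        if node not in self.nodes:
            raise KeyError(node)
        axes = tuple(i for i, n in enumerate(self.nodes) if n != node)
        return self.table.sum(axis=axes)


def joint_from_network(net: DiscreteBayesNet) -> JointDistribution:
    """The joint distribution as the product of the conditional tables.

    P(X_1, ..., X_n) = prod_i P(X_i | parents(X_i)); by the Markov condition
    this is the unique distribution the network represents.
    """
    n = len(net.nodes)
    index = {name: i for i, name in enumerate(net.nodes)}
    table = np.empty((2,) * n)
    for assignment in np.ndindex(*table.shape):
        p = 1.0
        for name in net.nodes:
            idx = tuple(assignment[index[par]] for par in net.parents[name])
            p *= net.cpts[name][idx + (assignment[index[name]],)]
        table[assignment] = p
    return JointDistribution(nodes=net.nodes, table=table)


def apply_stochastic_intervention(
    net: DiscreteBayesNet, intervention: StochasticIntervention
) -> DiscreteBayesNet:
    """Graph surgery for a stochastic intervention.

    Removes every edge into the target, replaces the target's table with the
    new marginal, and leaves all other tables untouched (modularity).  The
    operation is idempotent: applying the same intervention twice equals
    applying it once.
    """
    if intervention.target not in net.nodes:
        raise ValueError(f"target {intervention.target!r} is not a node of the net")
    parents = dict(net.parents)
    cpts = dict(net.cpts)
    parents[intervention.target] = ()
    cpts[intervention.target] = np.asarray(intervention.marginal)
    return DiscreteBayesNet(nodes=net.nodes, parents=parents, cpts=cpts)


@dataclass(frozen=True)
class DiscriminationResult:
    """Which candidate structures are consistent with the marginal changes."""

    supported: tuple
    changed: dict
    indistinguishable: bool


def discriminate_structure(
    candidates: Sequence[DiscreteBayesNet],
    pre_joint: JointDistribution,
    post_joint: JointDistribution,
    *,
    target: str = "D",
    eps: float = 1e-9,
) -> DiscriminationResult:
    """Select candidate structures from marginal changes under intervention.

    For each manifest node, compares its marginal before and after the
    intervention on ``target``; a candidate is supported exactly when the set
    of changed nodes equals the set of the target's descendants in that
    candidate's graph (effects move, non-effects stay put).  If nothing
    changed, the intervention cannot discriminate and every candidate is
    returned with the ``indistinguishable`` flag set.

    ``eps`` is the change threshold: the default suits exact distributions;
    with marginals estimated from finite samples it must be set explicitly to
    a sampling-noise scale (e.g. a multiple of the standard error).
    """
    if not candidates:
        raise ValueError("need at least one candidate structure")
    observable = [n for n in pre_joint.nodes if n != target]
    if set(observable) - set(post_joint.nodes):
        raise ValueError("pre and post joints must share the manifest nodes")
    changed = {}
    for node in observable:
        shift = float(
            np.max(np.abs(pre_joint.marginal(node) - post_joint.marginal(node)))
        )
        changed[node] = shift > eps
    if not any(changed.values()):
        return DiscriminationResult(
            supported=tuple(candidates), changed=changed, indistinguishable=True
        )
    changed_set = {n for n, c in changed.items() if c}
    supported = tuple(
        c
        for c in candidates
        if {n for n in c.descendants(target) if n in changed} == changed_set
    )
    return DiscriminationResult(
        supported=supported, changed=changed, indistinguishable=False
    )


# ---------------------------------------------------------------------------
# The three candidate nets of the running example
# ---------------------------------------------------------------------------


def common_cause_net(params: LCAParameters) -> DiscreteBayesNet:
    """The latent class structure: D is a common cause of F and L."""
    return DiscreteBayesNet(
        nodes=("D", "F", "L"),
        parents={"D": (), "F": ("D",), "L": ("D",)},
        cpts={
            "D": np.array([1 - params.delta, params.delta]),
            "F": np.array(
                [[1 - params.phi0, params.phi0], [1 - params.phi1, params.phi1]]
            ),
            "L": np.array(
                [
                    [1 - params.lambda0, params.lambda0],
                    [1 - params.lambda1, params.lambda1],
                ]
            ),
        },
    )


def chain_net(
    first: str,
    last: str,
    p_first: float,
    p_mid_given_first: Sequence[float],
    p_last_given_mid: Sequence[float],
    mid: str = "D",
) -> DiscreteBayesNet:
    """A chain first -> mid -> last over binary nodes.

    ``p_mid_given_first[j]`` is P(mid = 1 | first = j) and similarly for
    ``p_last_given_mid``; node order in the joint is (mid, manifest nodes in
    alphabetical order) to match the common-cause convention.
    """
    q = list(p_mid_given_first)
    r = list(p_last_given_mid)
    nodes = tuple([mid] + sorted([first, last]))
    return DiscreteBayesNet(
        nodes=nodes,
        parents={first: (), mid: (first,), last: (mid,)},
        cpts={
            first: np.array([1 - p_first, p_first]),
            mid: np.array([[1 - q[0], q[0]], [1 - q[1], q[1]]]),
            last: np.array([[1 - r[0], r[0]], [1 - r[1], r[1]]]),
        },
    )
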