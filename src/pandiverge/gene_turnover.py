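"""Wagner-parsimony gene gain/loss reconstruction on a rooted tree.

Gene-family member counts at the leaves are propagated to ancestral nodes
under linear (Wagner) cost: a bottom-up pass computes each node's optimal
count interval (for two children the Farris intersection-or-gap rule; for m
children, the interval between the m-th and (m+1)-th order statistics of
the 2m child interval endpoints, which is the exact minimizer set of the
convex piecewise-linear subtree cost), and a top-down pass assigns each
node the value in its interval closest to its parent's value. The root
takes its interval's minimum — the most parsimonious ancestor with the
fewest families, matching the convention of counting events from the
minimum number of family members at internal nodes. Total absolute change
along branches is the parsimony minimum.

Per-branch gains/losses are summed over families; dividing by branch length
gives per-branch turnover rates (the free-rates view: every branch has its
own rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import UNDEFINED, PanMatrix, PhyloTree
from .synthetic_data import _label_nodes, node_name

logger = logging.getLogger("pandiverge")


@dataclass
class TurnoverResult:
    """Ancestral totals, per-branch events and rates.

    ``family_counts`` maps each node label to the per-family count vector
    (ordered as ``family_ids``); ``node_counts`` is its sum. Branch entries
    are keyed by the child node's label.
    """

    family_ids: list[str]
    family_counts: dict[str, np.ndarray]
    node_counts: dict[str, int]
    branch_events: dict[str, tuple[int, int]]        # (gains, losses)
    branch_rates: dict[str, tuple[float, float]]
    total_changes: int


def _leaf_count_table(tree: PhyloTree, leaf_counts) -> tuple[list[str], dict[str, np.ndarray]]:
    """Normalize leaf counts to label -> int vector over a family order."""
    if isinstance(leaf_counts, PanMatrix):
        families = list(leaf_counts.family_ids)
        table = {
            g: leaf_counts.counts[:, j].astype(np.int64)
            for j, g in enumerate(leaf_counts.genome_ids)
        }
    else:
        families = sorted({f for counts in leaf_counts.values() for f in counts})
        table = {
            g: np.array([int(counts.get(f, 0)) for f in families], dtype=np.int64)
            for g, counts in leaf_counts.items()
        }
    for g, vec in table.items():
        if np.any(vec < 0):
            raise ValueError(f"negative count for leaf {g!r}")
    return families, table


def wagner_ancestral_counts(tree: PhyloTree, leaf_counts,
                            gain_cost: float = 1.0,
                            loss_cost: float = 1.0) -> TurnoverResult:
    """Minimum-change ancestral gene-family counts and branch events.

    *leaf_counts* is a :class:`PanMatrix` or a mapping
    ``leaf label -> {family -> count}``. The tree must be rooted; every leaf
    must have a count row. With the default equal costs the fast Farris
    interval algorithm is used; asymmetric ``gain_cost``/``loss_cost``
    route through an exact bounded-state dynamic program (minimality is
    then in weighted cost, while reported events stay unweighted counts).
    """
    if not tree.is_rooted:
        raise ValueError("root required: Wagner reconstruction needs a rooted tree")
    if min(gain_cost, loss_cost) <= 0:
        raise ValueError("gain/loss costs must be positive")
    _label_nodes(tree)          # results are keyed by node label
    families, table = _leaf_count_table(tree, leaf_counts)

    if gain_cost == loss_cost == 1.0:
        assigned = _assign_by_intervals(tree, table)
    else:
        assigned = _assign_by_dp(tree, table, gain_cost, loss_cost)

    family_counts: dict[str, np.ndarray] = {}
    node_counts: dict[str, int] = {}
    branch_events: dict[str, tuple[int, int]] = {}
    total = 0
    for node in tree.preorder_node_iter():
        value = assigned[id(node)]
        if node.parent_node is not None:
            delta = value - assigned[id(node.parent_node)]
            gains = int(delta[delta > 0].sum())
            losses = int(-delta[delta < 0].sum())
            branch_events[node_name(node)] = (gains, losses)
            total += gains + losses
        label = node_name(node)
        family_counts[label] = value
        node_counts[label] = int(value.sum())

    branch_rates = branch_turnover_rates(branch_events, tree)
    return TurnoverResult(families, family_counts, node_counts,
                          branch_events, branch_rates, total)


def _assign_by_intervals(tree: PhyloTree,
                         table: dict[str, np.ndarray]) -> dict[int, np.ndarray]:
    """Farris-interval pass for equal gain/loss cost."""
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        key = id(node)
        if node.is_leaf():
            label = node_name(node)
            if label not in table:
                raise ValueError(f"no counts for leaf {label!r}")
            lo[key] = table[label]
            hi[key] = table[label]
        else:
            children = node.child_nodes()
            endpoints = np.stack(
                [lo[id(c)] for c in children] + [hi[id(c)] for c in children])
            endpoints.sort(axis=0)
            m = len(children)
            lo[key] = endpoints[m - 1]
            hi[key] = endpoints[m]

    assigned: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        key = id(node)
        if node.parent_node is None:
            assigned[key] = lo[key]              # root: interval minimum
        else:
            parent_value = assigned[id(node.parent_node)]
            assigned[key] = np.clip(parent_value, lo[key], hi[key])
    return assigned


def _assign_by_dp(tree: PhyloTree, table: dict[str, np.ndarray],
                  gain_cost: float, loss_cost: float) -> dict[int, np.ndarray]:
    """Exact DP over ancestral states 0..max(leaf count) for asymmetric
    linear costs (a gain of one member costs gain_cost on the branch where
    it happens, a loss loss_cost)."""
    smax = int(max((int(v.max()) for v in table.values()), default=0))
    states = np.arange(smax + 1)
    # trans[x, y]: cost of a parent x -> child y change
    delta = states[None, :] - states[:, None]
    trans = np.where(delta > 0, gain_cost * delta, -loss_cost * delta)

    nfam = len(next(iter(table.values()))) if table else 0
    cost: dict[int, np.ndarray] = {}             # node -> (F, S+1)
    for node in tree.postorder_node_iter():
        key = id(node)
        if node.is_leaf():
            label = node_name(node)
            if label not in table:
                raise ValueError(f"no counts for leaf {label!r}")
            c = np.full((nfam, smax + 1), np.inf)
            c[np.arange(nfam), table[label]] = 0.0
            cost[key] = c
        else:
            total = np.zeros((nfam, smax + 1))
            for child in node.child_nodes():
                # min over child state y of C_child(y) + trans(x, y)
                total += (cost[id(child)][:, None, :] + trans[None, :, :]).min(axis=2)
            cost[key] = total

    assigned: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        key = id(node)
        if node.parent_node is None:
            assigned[key] = np.argmin(cost[key], axis=1).astype(np.int64)
        else:
            parent = assigned[id(node.parent_node)]
            c = cost[key] + trans[parent]        # (F, S+1)
            opt = c.min(axis=1, keepdims=True)
            is_opt = np.isclose(c, opt)
            # among minimizers, the state nearest the parent's (then lowest)
            dist = np.abs(states[None, :] - parent[:, None]).astype(float)
            dist[~is_opt] = np.inf
            assigned[key] = np.argmin(dist, axis=1).astype(np.int64)
    return assigned


def branch_gain_loss(tree: PhyloTree,
                     counts: dict[str, np.ndarray]) -> dict[str, tuple[int, int]]:
    """Per-branch (gains, losses) from assigned per-family counts at every
    node: gains = sum of positive child-minus-parent differences, losses the
    negative ones."""
    events: dict[str, tuple[int, int]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = np.asarray(counts[node_name(node)])
        parent = np.asarray(counts[node_name(node.parent_node)])
        delta = child - parent
        events[node_name(node)] = (
            int(delta[delta > 0].sum()), int(-delta[delta < 0].sum()))
    return events


def branch_turnover_rates(branch_events: dict[str, tuple[int, int]],
                          tree: PhyloTree) -> dict[str, tuple[float, float]]:
    """Events per unit branch length; undefined (NaN) on zero-length or
    lengthless branches."""
    lengths = {
        node_name(node): node.edge.length
        for node in tree.preorder_node_iter() if node.parent_node is not None
    }
    rates: dict[str, tuple[float, float]] = {}
    for label, (gains, losses) in branch_events.items():
        length = lengths.get(label)
        if not length:
            if gains or losses:
                logger.warning(
                    "branch %s: events on zero-length branch, rate undefined",
                    label)
            rates[label] = (UNDEFINED, UNDEFINED)
        else:
            rates[label] = (gains / length, losses / length)
    return rates
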