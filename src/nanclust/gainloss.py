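"""Wagner-parsimony gain/loss reconstruction of a binary character on a tree.

Given a rooted species tree and a presence/absence (0/1) profile of the
nan cluster at the leaves, the Sankoff dynamic programme finds a
minimum-cost assignment of ancestral states under per-transition costs
(gain = 0→1, loss = 1→0) and enumerates the per-branch events.  Branches
ending at leaves are the "species-level" (terminal) events.

Tie policy (explicit, since minimum-cost assignments are often not
unique): during traceback a child prefers its parent's state (minimise
change on the incoming branch); at the root, ties resolve to the
configured preferred state, default 0 (cluster ancestrally absent — the
conservative choice for a patchily distributed accessory pathway).  The
number of encountered ties is reported.  Multifurcations are handled
natively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import pandas as pd

INF = float("inf")


@dataclass
class GainLossResult:
    states: dict[str, int]  # node label -> reconstructed state
    events: pd.DataFrame  # one row per branch: child, parent/child state, event
    n_gains: int
    n_losses: int
    terminal_gains: int
    terminal_losses: int
    cost: float
    n_ties: int = 0

    def summary(self) -> dict[str, float]:
        return {
            "n_gains": self.n_gains,
            "n_losses": self.n_losses,
            "terminal_gains": self.terminal_gains,
            "terminal_losses": self.terminal_losses,
            "cost": self.cost,
        }


def _label_nodes(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    """Stable node labels: leaf taxon labels, internal nodes N0..Nk in
    preorder (existing internal labels are kept when unique)."""
    labels: dict[dendropy.Node, str] = {}
    used = set()
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            labels[node] = node.taxon.label
        else:
            lab = node.label if node.label and node.label not in used else f"N{i}"
            i += 1
            labels[node] = lab
        used.add(labels[node])
    return labels


def _transition_cost(s: int, t: int, gain_cost: float, loss_cost: float) -> float:
    if s == t:
        return 0.0
    return gain_cost if t == 1 else loss_cost


def _validate(tree: dendropy.Tree, profile: dict[str, int], gain_cost, loss_cost):
    if gain_cost <= 0 or loss_cost <= 0:
        raise ValueError("gain/loss costs must be positive")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in profile:
            raise ValueError(f"leaf {leaf.taxon.label!r} missing from presence profile")
        if profile[leaf.taxon.label] not in (0, 1):
            raise ValueError(f"leaf {leaf.taxon.label!r}: state must be 0/1")


def wagner_parsimony(
    tree: dendropy.Tree,
    profile: dict[str, int],
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
    root_prefer: int = 0,
) -> GainLossResult:
    """Minimum-cost ancestral reconstruction of a 0/1 character.

    Returns per-node states, per-branch events, total and terminal
    (leaf-branch) gain/loss counts, and the reconstruction cost, which is
    guaranteed minimal: cost = gain_cost*n_gains + loss_cost*n_losses.
    """
    _validate(tree, profile, gain_cost, loss_cost)
    labels = _label_nodes(tree)
    cost: dict[dendropy.Node, list[float]] = {}
    n_ties = 0

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = profile[node.taxon.label]
            cost[node] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            c = [0.0, 0.0]
            for s in (0, 1):
                for child in node.child_nodes():
                    c[s] += min(
                        cost[child][t] + _transition_cost(s, t, gain_cost, loss_cost)
                        for t in (0, 1)
                    )
            cost[node] = c

    root = tree.seed_node
    state: dict[dendropy.Node, int] = {}
    if cost[root][0] == cost[root][1]:
        n_ties += 1
        state[root] = root_prefer
    else:
        state[root] = 0 if cost[root][0] < cost[root][1] else 1

    rows = []
    n_gains = n_losses = terminal_gains = terminal_losses = 0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        s = state[node.parent_node]
        totals = [
            cost[node][t] + _transition_cost(s, t, gain_cost, loss_cost) for t in (0, 1)
        ]
        if totals[0] == totals[1]:
            n_ties += 1
            t_star = s  # prefer no change on the incoming branch
        else:
            t_star = 0 if totals[0] < totals[1] else 1
        state[node] = t_star
        event = "none"
        if s == 0 and t_star == 1:
            event = "gain"
            n_gains += 1
            terminal_gains += node.is_leaf()
        elif s == 1 and t_star == 0:
            event = "loss"
            n_losses += 1
            terminal_losses += node.is_leaf()
        rows.append(
            {
                "child": labels[node],
                "parent_state": s,
                "child_state": t_star,
                "event": event,
                "terminal": bool(node.is_leaf()),
            }
        )

    total_cost = min(cost[root])
    return GainLossResult(
        states={labels[n]: s for n, s in state.items()},
        events=pd.DataFrame(rows, columns=["child", "parent_state", "child_state", "event", "terminal"]),
        n_gains=n_gains,
        n_losses=n_losses,
        terminal_gains=int(terminal_gains),
        terminal_losses=int(terminal_losses),
        cost=float(total_cost),
        n_ties=n_ties,
    )


def event_summary(result: GainLossResult) -> dict[str, float]:
    """Totals plus terminal-branch ("species-level") gain/loss counts."""
    return result.summary()


def brute_force_parsimony(
    tree: dendropy.Tree,
    profile: dict[str, int],
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
    max_internal: int = 20,
) -> tuple[float, list[dict[str, int]]]:
    """Exhaustive minimum over all internal-state assignments (test oracle).

    Refuses trees with more than ``max_internal`` internal nodes.
    Returns the minimal cost and every optimal assignment (internal node
    label -> state).
    """
    _validate(tree, profile, gain_cost, loss_cost)
    labels = _label_nodes(tree)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    if len(internal) > max_internal:
        raise ValueError(f"{len(internal)} internal nodes exceeds limit {max_internal}")
    leaf_state = {
        n: profile[n.taxon.label] for n in tree.leaf_node_iter()
    }
    best_cost = INF
    best: list[dict[str, int]] = []
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        state.update(leaf_state)
        total = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            total += _transition_cost(
                state[node.parent_node], state[node], gain_cost, loss_cost
            )
        if total < best_cost - 1e-12:
            best_cost = total
            best = [{labels[n]: s for n, s in zip(internal, assignment)}]
        elif abs(total - best_cost) <= 1e-12:
            best.append({labels[n]: s for n, s in zip(internal, assignment)})
    return best_cost, best


def write_events(result: GainLossResult, path) -> None:
    result.events.to_csv(path, sep="\t", index=False)
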