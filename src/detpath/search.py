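"""Monte Carlo tree search over backward expansions.

The search grows a tree rooted at the detectable (source) compound by
applying retro rules, guided toward the producible (target) compound by
fingerprint similarity: each new node is scored with the Tanimoto
similarity between its compound and the target, so promising branches
receive more of the iteration budget.

Policy fixed by this module: UCT selection (unvisited children first, ties
on canonical key); expansion materialises all rule applications of the
selected leaf at once; rollout is depth-0 (the new node's similarity to the
target, no random playout).  The search is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence

from .chem import Compound, tanimoto
from .rules import ReactionRule, RuleApplication, expand_once

__all__ = [
    "SearchConfig",
    "SearchNode",
    "SearchTree",
    "mcts_search",
    "uct_select",
    "rollout_score",
]

DEFAULT_EXPLORATION = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class SearchConfig:
    """Search budget and policy knobs."""

    iterations: int = 200
    max_depth: int = 5
    exploration_constant: float = DEFAULT_EXPLORATION
    seed: int = 0
    similarity_threshold: float = 1.0

    def __post_init__(self):
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in [0,1]")


class SearchNode:
    """One node of the search tree (a single compound)."""

    __slots__ = (
        "compound",
        "parent",
        "parent_edge",
        "depth",
        "visits",
        "value_sum",
        "children",
        "terminal",
        "is_hit",
        "exhausted",
    )

    def __init__(
        self,
        compound: Compound,
        parent: Optional["SearchNode"] = None,
        parent_edge: Optional[RuleApplication] = None,
        depth: int = 0,
    ):
        self.compound = compound
        self.parent = parent
        self.parent_edge = parent_edge
        self.depth = depth
        self.visits = 0
        self.value_sum = 0.0
        # None = not yet expanded; [] = expanded, no children (dead end)
        self.children: Optional[List["SearchNode"]] = None
        self.terminal = False
        self.is_hit = False
        # exhausted = this subtree needs no further search budget: the node
        # is terminal, a dead end, or every child subtree is exhausted
        self.exhausted = False

    @property
    def mean_value(self) -> float:
        return self.value_sum / self.visits if self.visits else 0.0

    def ancestor_keys(self) -> set:
        keys = set()
        node = self
        while node is not None:
            keys.add(node.compound.canonical_key)
            node = node.parent
        return keys

    def __repr__(self) -> str:
        return (
            f"SearchNode({self.compound.canonical_key!r}, depth={self.depth}, "
            f"visits={self.visits}, terminal={self.terminal})"
        )


@dataclass
class SearchTree:
    """Result of one MCTS run for a (source, target) pair."""

    root: SearchNode
    source: Compound
    target: Compound
    config: SearchConfig
    hits: List[SearchNode] = field(default_factory=list)
    iterations_run: int = 0
    no_expansion: bool = False
    exhausted: bool = False

    def nodes(self) -> Iterator[SearchNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.children:
                stack.extend(node.children)

    def node_count(self) -> int:
        return sum(1 for _ in self.nodes())

    def compound_keys(self) -> set:
        return {n.compound.canonical_key for n in self.nodes()}

    def to_json(self) -> str:
        nodes = []
        edges = []
        ids: Dict[int, int] = {}
        for i, node in enumerate(self.nodes()):
            ids[id(node)] = i
            nodes.append(
                {
                    "id": i,
                    "compound": node.compound.canonical_key,
                    "depth": node.depth,
                    "visits": node.visits,
                    "value_sum": round(node.value_sum, 10),
                    "terminal": node.terminal,
                    "is_hit": node.is_hit,
                }
            )
            if node.parent is not None:
                edges.append(
                    {
                        "source": ids[id(node.parent)],
                        "target": i,
                        "rule_id": node.parent_edge.rule_id,
                    }
                )
        return json.dumps(
            {
                "source": self.source.canonical_key,
                "target": self.target.canonical_key,
                "iterations_run": self.iterations_run,
                "no_expansion": self.no_expansion,
                "nodes": nodes,
                "edges": edges,
            },
            indent=1,
        )


def rollout_score(node: SearchNode, target: Compound) -> float:
    """Depth-0 rollout: similarity of the node's compound to the target."""
    if node.is_hit:
        return 1.0
    return tanimoto(node.compound, target)


def uct_select(node: SearchNode, c: float) -> SearchNode:
    """UCT child selection.

    Unvisited children are selected before any visited child; among the
    remaining non-exhausted children the argmax of mean value +
    c·sqrt(ln(parent visits)/visits) wins.  Exhausted subtrees (solved or
    dead) receive no further budget.  All ties break on smaller canonical
    key (children are stored in key order, so the first optimum encountered
    wins).
    """
    if not node.children:
        raise ValueError("uct_select requires a node with at least one child")
    for child in node.children:
        if child.visits == 0:
            return child
    log_parent = math.log(max(node.visits, 1))
    candidates = [c for c in node.children if not c.exhausted] or node.children
    best, best_score = None, -math.inf
    for child in candidates:
        score = child.mean_value + c * math.sqrt(log_parent / child.visits)
        if score > best_score:
            best, best_score = child, score
    return best


def _is_hit(compound: Compound, target: Compound, threshold: float) -> bool:
    if compound.canonical_key == target.canonical_key:
        return True
    if threshold < 1.0:
        return tanimoto(compound, target) >= threshold
    return False


def _expand(
    node: SearchNode,
    rules: Sequence[ReactionRule],
    target: Compound,
    config: SearchConfig,
) -> None:
    """Materialise all children of ``node`` from one backward step.

    For multi-reactant applications the child compound is the reactant most
    similar to the target; the other reactants stay attached to the edge as
    side compounds.  Applications whose chosen child would revisit an
    ancestor compound are dropped (cycle guard).
    """
    ancestors = node.ancestor_keys()
    children: List[SearchNode] = []
    for app in expand_once(node.compound, rules):
        main = max(
            app.reactants,
            key=lambda c: (tanimoto(c, target), c.canonical_key),
        )
        if main.canonical_key in ancestors:
            continue
        child = SearchNode(main, parent=node, parent_edge=app, depth=node.depth + 1)
        if _is_hit(main, target, config.similarity_threshold):
            child.terminal = True
            child.is_hit = True
        elif child.depth >= config.max_depth:
            child.terminal = True
        child.exhausted = child.terminal
        children.append(child)
    children.sort(key=lambda n: (n.compound.canonical_key, n.parent_edge.rule_id))
    node.children = children


def mcts_search(
    source: Compound,
    target: Compound,
    rules: Sequence[ReactionRule],
    config: SearchConfig,
) -> SearchTree:
    """Run MCTS from the detectable ``source`` toward the producible ``target``.

    Executes ``config.iterations`` select→expand→rollout→backpropagate
    cycles; the root's visit count equals the number of completed
    iterations.  Nodes matching the target (exact canonical key, or
    similarity ≥ threshold when threshold < 1.0) are terminal hits.  If the
    source matches no rule the returned single-node tree is flagged
    ``no_expansion``.
    """
    if not rules:
        raise ValueError("mcts_search requires a non-empty ruleset")
    # Seeded RNG kept for policy variants; the default policy is
    # deterministic so the stream is currently unused.
    random.Random(config.seed)

    root = SearchNode(source)
    tree = SearchTree(root=root, source=source, target=target, config=config)
    if _is_hit(source, target, config.similarity_threshold):
        root.terminal = True
        root.is_hit = True
        tree.hits.append(root)
        return tree

    for _ in range(config.iterations):
        if root.exhausted:
            tree.exhausted = True
            break
        node = root
        path = [root]
        while node.children:
            node = uct_select(node, config.exploration_constant)
            path.append(node)
        if node.children is None and not node.terminal:
            _expand(node, rules, target, config)
            tree.hits.extend(ch for ch in node.children if ch.is_hit)
            if node is root and not root.children:
                root.visits += 1
                root.value_sum += rollout_score(root, target)
                tree.iterations_run += 1
                tree.no_expansion = True
                return tree
            if node.children:
                child = node.children[0]  # unvisited, smallest canonical key
                path.append(child)
                node = child
        score = rollout_score(node, target)
        for n in path:
            n.visits += 1
            n.value_sum += score
        for n in reversed(path):
            if n.terminal or (n.children is not None and all(
                c.exhausted for c in n.children
            )):
                n.exhausted = True
        tree.iterations_run += 1
    if root.exhausted:
        tree.exhausted = True
    return tree
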