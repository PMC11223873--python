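"""Scope graphs, pathway enumeration, ranking and compound classification.

The search tree is collapsed into a bipartite compound–reaction "scope"
graph on canonical keys.  Pathways are enumerated from the producible
target toward the detectable effector by keeping, at every compound node,
only the producing branches of minimal step count, and combining the
retained branches.  Ranking is worst-step-penalty first (a pathway is only
as good as its worst rule), then precursor flux, then length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .chem import Compound, canonicalize
from .rules import RuleApplication

logger = logging.getLogger(__name__)

__all__ = [
    "ChassisMetabolome",
    "PairNotConnectedError",
    "Pathway",
    "ScopeGraph",
    "build_scope",
    "classify_compounds",
    "enumerate_pathways",
    "load_flux",
    "load_whitelist",
    "pair_summary",
    "PairSummary",
    "prune_scope",
    "rank_pathways",
]

ROLES = ("target", "effector", "precursor", "intermediate", "supplement")

# Hard cap on pathway enumeration, above max_pathways, so the suppressed
# count in the truncation log stays bounded.
_ENUM_HARD_CAP = 100_000


class PairNotConnectedError(RuntimeError):
    """Search finished without a terminal hit for this pair."""

    def __init__(self, source_key: str, target_key: str, stats: Optional[dict] = None):
        self.source_key = source_key
        self.target_key = target_key
        self.stats = stats or {}
        super().__init__(
            f"pair not connected: no route from {target_key!r} to {source_key!r} "
            f"(search stats: {self.stats})"
        )


@dataclass
class ChassisMetabolome:
    """The set of canonical metabolite keys native to a chassis organism.

    Membership is stereo-insensitive by default because chassis metabolite
    lists annotate stereochemistry inconsistently.
    """

    chassis_id: str
    metabolite_keys: frozenset
    display_name: str = ""
    match_stereo: bool = False
    _nostereo: frozenset = field(init=False, repr=False)

    def __post_init__(self):
        if not self.metabolite_keys:
            raise ValueError(f"chassis {self.chassis_id}: empty metabolome")
        if not self.display_name:
            self.display_name = self.chassis_id
        self._nostereo = frozenset(
            canonicalize(k, ignore_stereo=True) for k in self.metabolite_keys
        )

    def contains(self, compound: Compound) -> bool:
        if compound.canonical_key in self.metabolite_keys:
            return True
        if not self.match_stereo:
            return compound.key_nostereo in self._nostereo
        return False


@dataclass
class ScopeGraph:
    """Bipartite compound–reaction network linking target to effector.

    ``graph`` holds two node kinds: ``("c", canonical_key)`` and
    ``("r", reaction_key)``; edges run compound→reaction for forward
    substrates and reaction→compound for the forward product.  Reaction
    node attributes carry the :class:`RuleApplication` and the main-chain
    reactant chosen by the search.
    """

    graph: nx.DiGraph
    compounds: Dict[str, Compound]
    reactions: Dict[tuple, RuleApplication]
    source: Compound  # detectable effector
    target: Compound  # producible target
    target_keys: frozenset  # hit compound keys (== {target key} for exact matching)

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def main_chain_edges(self) -> Iterable[Tuple[str, str, tuple]]:
        """Yield (main_reactant_key, product_key, reaction_key) triples."""
        for rkey, app in self.reactions.items():
            main_key = self.graph.nodes[("r", rkey)]["main_key"]
            yield main_key, app.product.canonical_key, rkey


@dataclass
class Pathway:
    """An ordered forward pathway: producible target first, effector last."""

    steps: List[RuleApplication]
    target_key: str
    effector_key: str
    roles: Dict[str, str] = field(default_factory=dict)
    global_score: float = field(init=False)

    def __post_init__(self):
        if not self.steps:
            raise ValueError("a pathway needs at least one step")
        self.global_score = max(s.penalty_score for s in self.steps)
        self.roles.setdefault(self.target_key, "target")
        self.roles.setdefault(self.effector_key, "effector")

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def rule_ids(self) -> Tuple[str, ...]:
        return tuple(s.rule_id for s in self.steps)

    def compounds(self) -> Dict[str, Compound]:
        out: Dict[str, Compound] = {}
        for step in self.steps:
            for c in step.reactants:
                out.setdefault(c.canonical_key, c)
            out.setdefault(step.product.canonical_key, step.product)
        return out

    @property
    def is_classified(self) -> bool:
        keys = set(self.compounds())
        return keys <= set(self.roles)

    def precursor_flux_sum(self, flux: Optional[Mapping[str, float]] = None) -> float:
        flux = flux or {}
        return sum(
            flux.get(key, 1.0)
            for key, role in self.roles.items()
            if role == "precursor"
        )


def build_scope(tree) -> ScopeGraph:
    """Collapse a search tree into a scope graph on canonical keys.

    Only compounds and reactions lying on some root→hit path survive; tree
    duplicates merge into single graph nodes.  Side reactants of every
    retained edge enter as compound nodes.  Raises
    :class:`PairNotConnectedError` when the tree holds no terminal hit.
    """
    if not tree.hits:
        raise PairNotConnectedError(
            tree.source.canonical_key,
            tree.target.canonical_key,
            stats={
                "iterations_run": tree.iterations_run,
                "nodes": tree.node_count(),
                "no_expansion": tree.no_expansion,
            },
        )
    g = nx.DiGraph()
    compounds: Dict[str, Compound] = {}
    reactions: Dict[tuple, RuleApplication] = {}

    def add_compound(c: Compound) -> str:
        key = c.canonical_key
        if key not in compounds:
            compounds[key] = c
            g.add_node(("c", key), kind="compound")
        return key

    target_keys = set()
    for hit in tree.hits:
        target_keys.add(add_compound(hit.compound))
        node = hit
        while node.parent is not None:
            app = node.parent_edge
            rkey = (app.reactant_keys, app.product.canonical_key)
            main_key = node.compound.canonical_key
            prev = reactions.get(rkey)
            if prev is None or (app.penalty_score, app.rule_id) < (
                prev.penalty_score,
                prev.rule_id,
            ):
                reactions[rkey] = app
            if ("r", rkey) not in g:
                g.add_node(("r", rkey), kind="reaction", main_key=main_key)
                for c in app.reactants:
                    g.add_edge(("c", add_compound(c)), ("r", rkey))
                g.add_edge(("r", rkey), ("c", add_compound(app.product)))
            node = node.parent

    add_compound(tree.source)
    add_compound(tree.target)
    return ScopeGraph(
        graph=g,
        compounds=compounds,
        reactions=reactions,
        source=tree.source,
        target=tree.target,
        target_keys=frozenset(target_keys),
    )


def _retained_reactions(scope: ScopeGraph) -> Dict[tuple, Tuple[str, str]]:
    """Reactions surviving the shortest-branch rule.

    Distances are BFS step counts from the target over main-chain edges; a
    reaction producing compound ``p`` from main reactant ``m`` is retained
    iff ``d(m) + 1`` equals the minimum over all of ``p``'s producing
    branches — i.e. it lies on a per-node-shortest branch.
    """
    chain = nx.DiGraph()
    for main_key, product_key, rkey in scope.main_chain_edges():
        chain.add_edge(main_key, product_key, rkey=rkey)
    dist: Dict[str, int] = {}
    for tk in scope.target_keys:
        if tk in chain or tk in scope.compounds:
            dist[tk] = 0
    frontier = list(dist)
    while frontier:
        nxt = []
        for u in frontier:
            if u not in chain:
                continue
            for v in chain.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    retained: Dict[tuple, Tuple[str, str]] = {}
    for main_key, product_key, rkey in scope.main_chain_edges():
        if main_key not in dist:
            continue
        if dist[main_key] + 1 == dist.get(product_key, -1):
            retained[rkey] = (main_key, product_key)
    return retained


def enumerate_pathways(scope: ScopeGraph, max_pathways: int = 1000) -> List[Pathway]:
    """Enumerate distinct pathways under the shortest-branch rule.

    At every branched compound node only the producing branches of minimal
    step count are kept; the result is every combination of retained
    branches from the target to the effector, de-duplicated on ordered rule
    id lists, rank-sorted, and truncated at ``max_pathways``.
    """
    retained = _retained_reactions(scope)
    # forward adjacency restricted to retained reactions
    succ: Dict[str, List[Tuple[str, tuple]]] = {}
    for rkey, (main_key, product_key) in retained.items():
        succ.setdefault(main_key, []).append((product_key, rkey))
    for lst in succ.values():
        lst.sort()

    effector_key = scope.source.canonical_key
    paths: List[List[tuple]] = []
    suppressed = 0

    def dfs(key: str, rpath: List[tuple], seen: Set[str]):
        nonlocal suppressed
        if key == effector_key and rpath:
            if len(paths) + suppressed >= _ENUM_HARD_CAP:
                suppressed += 1
                return
            paths.append(list(rpath))
            return
        for nxt_key, rkey in succ.get(key, ()):
            if nxt_key in seen:
                continue
            seen.add(nxt_key)
            rpath.append(rkey)
            dfs(nxt_key, rpath, seen)
            rpath.pop()
            seen.remove(nxt_key)

    for tk in sorted(scope.target_keys):
        dfs(tk, [], {tk})

    pathways: List[Pathway] = []
    seen_rule_lists = set()
    for rpath in paths:
        steps = [scope.reactions[rkey] for rkey in rpath]
        ids = tuple(s.rule_id for s in steps)
        if ids in seen_rule_lists:
            continue
        seen_rule_lists.add(ids)
        first_main = retained[rpath[0]][0]
        pathways.append(
            Pathway(steps=steps, target_key=first_main, effector_key=effector_key)
        )

    pathways = rank_pathways(pathways)
    if len(pathways) > max_pathways:
        logger.warning(
            "pathway enumeration truncated: %d of %d pathways kept (%d suppressed)",
            max_pathways,
            len(pathways),
            len(pathways) - max_pathways + suppressed,
        )
        pathways = pathways[:max_pathways]
    elif suppressed:
        logger.warning("pathway enumeration hit hard cap; %d paths suppressed", suppressed)
    return pathways


def prune_scope(scope: ScopeGraph) -> ScopeGraph:
    """Scope restricted to reactions retained by the shortest-branch rule.

    A reaction survives iff it lies on a complete target→effector route
    through retained branches: its main reactant must be reachable from the
    target and its product must still reach the effector.
    """
    retained = _retained_reactions(scope)
    fwd = nx.DiGraph()
    fwd.add_node(scope.source.canonical_key)
    for tk in scope.target_keys:
        fwd.add_node(tk)
    for main_key, product_key in retained.values():
        fwd.add_edge(main_key, product_key)
    from_target = set()
    for tk in scope.target_keys:
        from_target |= {tk} | nx.descendants(fwd, tk)
    to_effector = {scope.source.canonical_key} | nx.ancestors(
        fwd, scope.source.canonical_key
    )
    retained = {
        rkey: (m, p)
        for rkey, (m, p) in retained.items()
        if m in from_target and p in to_effector
    }
    g = nx.DiGraph()
    compounds: Dict[str, Compound] = {}
    reactions: Dict[tuple, RuleApplication] = {}
    for rkey, (main_key, _product_key) in retained.items():
        app = scope.reactions[rkey]
        reactions[rkey] = app
        g.add_node(("r", rkey), kind="reaction", main_key=main_key)
        for c in list(app.reactants) + [app.product]:
            key = c.canonical_key
            if key not in compounds:
                compounds[key] = c
                g.add_node(("c", key), kind="compound")
        for c in app.reactants:
            g.add_edge(("c", c.canonical_key), ("r", rkey))
        g.add_edge(("r", rkey), ("c", app.product.canonical_key))
    for c in (scope.source, scope.target):
        if c.canonical_key not in compounds:
            compounds[c.canonical_key] = c
            g.add_node(("c", c.canonical_key), kind="compound")
    return ScopeGraph(
        graph=g,
        compounds=compounds,
        reactions=reactions,
        source=scope.source,
        target=scope.target,
        target_keys=scope.target_keys,
    )


def rank_pathways(
    pathways: Sequence[Pathway], flux: Optional[Mapping[str, float]] = None
) -> List[Pathway]:
    """Total-order ranking of pathways.

    Ascending worst-step penalty (the global score), then descending sum of
    flux over precursor compounds (default 1.0 per unknown key), then
    ascending length, then the concatenated rule id tuple.
    """
    return sorted(
        pathways,
        key=lambda p: (
            p.global_score,
            -p.precursor_flux_sum(flux),
            p.length,
            p.rule_ids,
        ),
    )


def classify_compounds(
    pathway: Pathway,
    chassis: ChassisMetabolome,
    whitelist: Optional[Set[str]] = None,
) -> Dict[str, str]:
    """Assign a role to every compound of a pathway.

    Target and effector keep their roles.  Any other compound found in the
    chassis metabolome (or the optional producible-precursor whitelist) is a
    precursor; a compound consumed by some step but produced by none (and
    not a precursor) must be supplemented in the medium; everything else —
    produced by one step, consumed by another — is an intermediate.
    """
    whitelist = whitelist or set()
    consumed = set()
    produced = set()
    for step in pathway.steps:
        consumed.update(step.reactant_keys)
        produced.add(step.product.canonical_key)
    roles: Dict[str, str] = {}
    for key, compound in pathway.compounds().items():
        if key == pathway.target_key:
            roles[key] = "target"
        elif key == pathway.effector_key:
            roles[key] = "effector"
        elif chassis.contains(compound) or key in whitelist:
            roles[key] = "precursor"
        elif key in consumed and key not in produced:
            roles[key] = "supplement"
        else:
            roles[key] = "intermediate"
    pathway.roles = roles
    return roles


@dataclass
class PairSummary:
    """Aggregate counts over a set of (producible, effector) results."""

    pairs: int
    pathways: int
    intermediates: int
    precursors: int
    supplements: int
    n_producibles: int
    avg_pathways_per_producible: float
    avg_pairs_per_producible: float
    n_detectables: int
    avg_pathways_per_detectable: float
    avg_pairs_per_detectable: float

    def overall_row(self) -> Dict[str, float]:
        return {
            "Pairs": self.pairs,
            "Pathways": self.pathways,
            "Intermediates": self.intermediates,
            "Precursors": self.precursors,
            "Supplements": self.supplements,
        }

    def by_compound_rows(self) -> List[Dict[str, float]]:
        return [
            {
                "Set": "Producible",
                "Number of compounds": self.n_producibles,
                "Average no. of pathways": self.avg_pathways_per_producible,
                "Average no. of pairs": self.avg_pairs_per_producible,
            },
            {
                "Set": "Detectable",
                "Number of compounds": self.n_detectables,
                "Average no. of pathways": self.avg_pathways_per_detectable,
                "Average no. of pairs": self.avg_pairs_per_detectable,
            },
        ]

    def to_tsv(self) -> str:
        lines = ["\t".join(self.overall_row())]
        lines.append("\t".join(str(v) for v in self.overall_row().values()))
        rows = self.by_compound_rows()
        lines.append("\t".join(rows[0]))
        for row in rows:
            lines.append("\t".join(str(v) for v in row.values()))
        return "\n".join(lines) + "\n"


def pair_summary(
    results: Mapping[Tuple[str, str], Sequence[Pathway]]
) -> PairSummary:
    """Summary table over per-pair pathway lists.

    Keys are (producible id, effector id).  Pairs with an empty pathway
    list are excluded from every count.  Distinct intermediate/precursor/
    supplement compounds are counted on canonical keys, unioned across all
    pathways of all connected pairs.
    """
    if not results:
        raise ValueError("pair_summary requires a non-empty results mapping")
    connected = {k: v for k, v in results.items() if v}
    role_sets = {"intermediate": set(), "precursor": set(), "supplement": set()}
    n_pathways = 0
    per_producible_pathways: Dict[str, int] = {}
    per_producible_pairs: Dict[str, int] = {}
    per_detectable_pathways: Dict[str, int] = {}
    per_detectable_pairs: Dict[str, int] = {}
    for (prod_id, eff_id), pathway_list in connected.items():
        n_pathways += len(pathway_list)
        per_producible_pathways[prod_id] = per_producible_pathways.get(prod_id, 0) + len(
            pathway_list
        )
        per_producible_pairs[prod_id] = per_producible_pairs.get(prod_id, 0) + 1
        per_detectable_pathways[eff_id] = per_detectable_pathways.get(eff_id, 0) + len(
            pathway_list
        )
        per_detectable_pairs[eff_id] = per_detectable_pairs.get(eff_id, 0) + 1
        for pw in pathway_list:
            for key, role in pw.roles.items():
                if role in role_sets:
                    role_sets[role].add(key)

    def avg(d: Dict[str, int]) -> float:
        return sum(d.values()) / len(d) if d else 0.0

    return PairSummary(
        pairs=len(connected),
        pathways=n_pathways,
        intermediates=len(role_sets["intermediate"]),
        precursors=len(role_sets["precursor"]),
        supplements=len(role_sets["supplement"]),
        n_producibles=len(per_producible_pairs),
        avg_pathways_per_producible=avg(per_producible_pathways),
        avg_pairs_per_producible=avg(per_producible_pairs),
        n_detectables=len(per_detectable_pairs),
        avg_pathways_per_detectable=avg(per_detectable_pathways),
        avg_pairs_per_detectable=avg(per_detectable_pairs),
    )


def load_flux(path) -> Dict[str, float]:
    """Two-column delimited file (canonical key, flux value) → mapping."""
    flux: Dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t")
        if len(parts) < 2:
            continue
        flux[canonicalize(parts[0].strip())] = float(parts[1])
    return flux


def load_whitelist(path) -> Set[str]:
    """One-column file of structures/keys → set of canonical keys."""
    keys = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            keys.add(canonicalize(line))
    return keys
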