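"""Shared fixtures: deterministic toy chemistries and helper builders."""

from __future__ import annotations

import pytest

from detpath.chem import Compound
from detpath.datasets import ToyChemistry, _exact_smarts, generate_toy_chemistry
from detpath.pathways import build_scope, classify_compounds, enumerate_pathways
from detpath.rules import ReactionRule
from detpath.search import SearchConfig, mcts_search


@pytest.fixture(scope="session")
def toy_linear() -> ToyChemistry:
    """Seed-1 linear chain of 6 compounds (one ground-truth path per pair)."""
    return generate_toy_chemistry(1, n_compounds=6, branching=1.0)


@pytest.fixture(scope="session")
def toy_branched() -> ToyChemistry:
    """Seed-2 branched universe with at least one multi-path pair."""
    return generate_toy_chemistry(2, n_compounds=8, branching=2.0)


def make_rule(
    parent_smiles: str,
    child_smiles: str,
    rule_id: str,
    penalty: float = 0.5,
    diameter: int = 4,
    extra_reactant: str | None = None,
) -> ReactionRule:
    """Exact-match retro rule rewriting one toy molecule into another.

    ``extra_reactant`` adds a second forward substrate (a side compound),
    producing a multi-reactant retro step.
    """
    rhs = Compound(child_smiles).canonical_key
    if extra_reactant is not None:
        rhs = f"{rhs}.{Compound(extra_reactant).canonical_key}"
    return ReactionRule(
        rule_id=rule_id,
        smarts=f"{_exact_smarts(Compound(parent_smiles).mol)}>>{rhs}",
        diameter=diameter,
        penalty_score=penalty,
    )


def run_engine(source, target, rules, iterations=400, max_depth=5, seed=0,
               max_pathways=1000):
    """search → scope → enumeration, returning the ranked pathway list."""
    cfg = SearchConfig(iterations=iterations, max_depth=max_depth, seed=seed)
    tree = mcts_search(source, target, rules, cfg)
    scope = build_scope(tree)
    return enumerate_pathways(scope, max_pathways)


def engine_rule_id_lists(toy: ToyChemistry, target_id: str, iterations=400, seed=0):
    """Sorted forward rule-id tuples the full engine finds for one pair."""
    target = toy.compound_by_id(target_id)
    pathways = run_engine(
        toy.source, target, toy.retro_rules,
        iterations=iterations, max_depth=toy.max_depth, seed=seed,
    )
    return sorted(p.rule_ids for p in pathways)


__all__ = ["make_rule", "run_engine", "engine_rule_id_lists"]
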