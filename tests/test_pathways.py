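"""Scope construction, enumeration, ranking, classification, summaries."""

import pytest

from detpath.chem import Compound
from detpath.datasets import brute_force_detectable_paths, generate_toy_chemistry
from detpath.pathways import (
    ChassisMetabolome,
    PairNotConnectedError,
    Pathway,
    build_scope,
    classify_compounds,
    enumerate_pathways,
    pair_summary,
    prune_scope,
    rank_pathways,
)
from detpath.search import SearchConfig, mcts_search

from conftest import make_rule, run_engine

# Toy molecule aliases for handcrafted networks
E, X, Y, T = "CO", "CCO", "CN", "CCCO"
Y1, Y2 = "CCN", "CS"


def search_tree(source_smiles, target_smiles, rules, iterations=300, max_depth=5):
    return mcts_search(
        Compound(source_smiles),
        Compound(target_smiles),
        rules,
        SearchConfig(iterations=iterations, max_depth=max_depth, seed=0),
    )


@pytest.fixture
def linear_rules():
    # retro: E -> X -> T; forward production T -> X -> E
    return [make_rule(E, X, "r1", 0.2), make_rule(X, T, "r2", 0.5)]


@pytest.fixture
def diamond_rules():
    # two equal-length branches E<-X<-T and E<-Y<-T
    return [
        make_rule(E, X, "r1", 0.2),
        make_rule(E, Y, "r2", 0.3),
        make_rule(X, T, "r3", 0.4),
        make_rule(Y, T, "r4", 0.6),
    ]


@pytest.fixture
def unequal_diamond_rules():
    # branch via X has 2 steps, branch via Y1,Y2 has 3
    return [
        make_rule(E, X, "r1", 0.2),
        make_rule(X, T, "r2", 0.4),
        make_rule(E, Y1, "r3", 0.3),
        make_rule(Y1, Y2, "r4", 0.3),
        make_rule(Y2, T, "r5", 0.3),
    ]


class TestBuildScope:
    def test_linear_tree_three_compounds_two_reactions(self, linear_rules):
        scope = build_scope(search_tree(E, T, linear_rules))
        assert scope.n_compounds == 3
        assert scope.n_reactions == 2

    def test_branches_merge_on_canonical_keys(self, diamond_rules):
        scope = build_scope(search_tree(E, T, diamond_rules))
        # T reached through X and through Y; T and E appear once each
        assert scope.n_compounds == 4
        assert scope.n_reactions == 4

    def test_dead_branches_pruned(self, diamond_rules):
        # an extra rule into a dead end must not enter the scope
        rules = diamond_rules + [make_rule(Y, "CCS", "dead", 0.1)]
        scope = build_scope(search_tree(E, T, rules))
        assert Compound("CCS").canonical_key not in scope.compounds

    def test_no_hit_raises_with_stats(self, linear_rules):
        tree = search_tree(E, "CCCCCCCC", linear_rules, iterations=40, max_depth=3)
        with pytest.raises(PairNotConnectedError) as exc:
            build_scope(tree)
        assert "iterations_run" in exc.value.stats

    def test_side_compounds_enter_scope(self):
        rules = [
            make_rule(E, X, "r1", 0.2, extra_reactant="O"),
            make_rule(X, T, "r2", 0.5),
        ]
        scope = build_scope(search_tree(E, T, rules))
        assert Compound("O").canonical_key in scope.compounds


class TestEnumeratePathways:
    def test_linear_scope_single_pathway(self, linear_rules):
        pathways = enumerate_pathways(build_scope(search_tree(E, T, linear_rules)))
        assert len(pathways) == 1
        assert pathways[0].rule_ids == ("r2", "r1")  # forward: target first
        assert pathways[0].target_key == Compound(T).canonical_key
        assert pathways[0].effector_key == Compound(E).canonical_key

    def test_equal_diamond_two_pathways(self, diamond_rules):
        pathways = enumerate_pathways(build_scope(search_tree(E, T, diamond_rules)))
        assert sorted(p.rule_ids for p in pathways) == [("r3", "r1"), ("r4", "r2")]

    def test_unequal_diamond_keeps_shorter_branch_only(self, unequal_diamond_rules):
        scope = build_scope(search_tree(E, T, unequal_diamond_rules))
        pathways = enumerate_pathways(scope)
        assert [p.rule_ids for p in pathways] == [("r2", "r1")]

    def test_chaining_invariant(self, diamond_rules):
        for pw in enumerate_pathways(build_scope(search_tree(E, T, diamond_rules))):
            for a, b in zip(pw.steps, pw.steps[1:]):
                assert a.product.canonical_key in b.reactant_keys

    def test_no_duplicate_rule_id_lists(self, diamond_rules):
        pathways = enumerate_pathways(build_scope(search_tree(E, T, diamond_rules)))
        ids = [p.rule_ids for p in pathways]
        assert len(ids) == len(set(ids))

    def test_truncation(self, diamond_rules):
        pathways = enumerate_pathways(
            build_scope(search_tree(E, T, diamond_rules)), max_pathways=1
        )
        assert len(pathways) == 1

    def test_scope_soundness(self, diamond_rules):
        scope = build_scope(search_tree(E, T, diamond_rules))
        for pw in enumerate_pathways(scope):
            assert set(pw.compounds()) <= set(scope.compounds)

    def test_matches_brute_force_oracle_on_random_scopes(self):
        """Enumeration equals the all-simple-paths + shortest-branch oracle."""
        checked = 0
        for seed in range(14):
            toy = generate_toy_chemistry(
                seed + 60, n_compounds=6 + seed % 5, branching=1.0 + seed % 3
            )
            if len(toy.compounds) > 12:
                continue
            for target in toy.compounds[1:]:
                oracle = brute_force_detectable_paths(
                    toy.source, target, toy.retro_rules, toy.max_depth
                )
                pathways = run_engine(
                    toy.source, target, toy.retro_rules,
                    iterations=1500, max_depth=toy.max_depth,
                )
                assert sorted(p.rule_ids for p in pathways) == oracle
                checked += 1
        assert checked >= 10


class TestPruneScope:
    def test_pruned_scope_drops_longer_branch_reactions(self, unequal_diamond_rules):
        scope = build_scope(search_tree(E, T, unequal_diamond_rules))
        pruned = prune_scope(scope)
        assert pruned.n_reactions == 2
        assert pruned.n_reactions < scope.n_reactions


class TestRankPathways:
    def _pathway(self, rules_spec, target=T, effector=E):
        steps = []
        chain = [target, X, effector]
        apps = []
        for i, (rid, penalty) in enumerate(rules_spec):
            rule = make_rule(chain[i + 1], chain[i], rid, penalty)
            from detpath.rules import apply_rule

            found = apply_rule(rule, Compound(chain[i + 1]))
            apps.append(found[0])
        apps.reverse()
        return Pathway(
            steps=apps,
            target_key=Compound(target).canonical_key,
            effector_key=Compound(effector).canonical_key,
        )

    def test_global_score_is_worst_step_penalty(self):
        pw = self._pathway([("a", 0.5), ("b", 0.2)])
        assert pw.global_score == 0.5

    def test_flux_tiebreak(self):
        pw1 = self._pathway([("a", 0.5), ("b", 0.5)])
        pw2 = self._pathway([("c", 0.5), ("d", 0.5)])
        k1 = Compound(X).canonical_key
        pw1.roles[k1] = "precursor"
        k2 = Compound(X).canonical_key
        pw2.roles[k2] = "precursor"
        ranked = rank_pathways([pw1, pw2], flux={k1: 8.0})
        assert ranked[0].precursor_flux_sum({k1: 8.0}) == 8.0

    def test_ordering_matches_brute_force_sort(self, toy_branched):
        target = toy_branched.compounds[-1]
        pathways = run_engine(
            toy_branched.source, target, toy_branched.retro_rules,
            iterations=800, max_depth=toy_branched.max_depth,
        )
        ranked = rank_pathways(pathways)
        oracle = sorted(
            pathways,
            key=lambda p: (p.global_score, -p.precursor_flux_sum(None), p.length,
                           p.rule_ids),
        )
        assert [p.rule_ids for p in ranked] == [p.rule_ids for p in oracle]

    def test_total_order_and_stability(self, diamond_rules):
        pathways = enumerate_pathways(build_scope(search_tree(E, T, diamond_rules)))
        once = rank_pathways(pathways)
        twice = rank_pathways(once)
        assert [p.rule_ids for p in once] == [p.rule_ids for p in twice]
        keys = [
            (p.global_score, -p.precursor_flux_sum(None), p.length, p.rule_ids)
            for p in once
        ]
        assert len(set(keys)) == len(keys)


def two_step_pathway_with_side_compound(side="O"):
    rules = [
        make_rule(E, X, "r1", 0.2, extra_reactant=side),
        make_rule(X, T, "r2", 0.5),
    ]
    scope = build_scope(search_tree(E, T, rules))
    (pw,) = enumerate_pathways(scope)
    return pw


def chassis_with(*smiles, chassis_id="toy"):
    return ChassisMetabolome(
        chassis_id=chassis_id,
        metabolite_keys=frozenset(Compound(s).canonical_key for s in smiles),
    )


class TestClassifyCompounds:
    def test_side_reactant_in_chassis_is_precursor(self):
        pw = two_step_pathway_with_side_compound("O")
        roles = classify_compounds(pw, chassis_with("O", "CCCCC"))
        assert roles[Compound("O").canonical_key] == "precursor"

    def test_side_reactant_absent_is_supplement(self):
        pw = two_step_pathway_with_side_compound("O")
        roles = classify_compounds(pw, chassis_with("CCCCC"))
        assert roles[Compound("O").canonical_key] == "supplement"

    def test_mid_chain_compound_is_intermediate(self):
        pw = two_step_pathway_with_side_compound("O")
        roles = classify_compounds(pw, chassis_with("CCCCC"))
        assert roles[Compound(X).canonical_key] == "intermediate"

    def test_target_and_effector_keep_roles(self):
        pw = two_step_pathway_with_side_compound("O")
        roles = classify_compounds(pw, chassis_with(T, E))
        assert roles[Compound(T).canonical_key] == "target"
        assert roles[Compound(E).canonical_key] == "effector"

    def test_whitelist_makes_precursor(self):
        pw = two_step_pathway_with_side_compound("O")
        roles = classify_compounds(
            pw, chassis_with("CCCCC"), whitelist={Compound("O").canonical_key}
        )
        assert roles[Compound("O").canonical_key] == "precursor"

    def test_partition_is_total_and_exclusive(self):
        pw = two_step_pathway_with_side_compound("O")
        roles = classify_compounds(pw, chassis_with("O"))
        assert set(roles) == set(pw.compounds())
        assert set(roles.values()) <= {
            "target", "effector", "precursor", "intermediate", "supplement"
        }

    def test_membership_flip_flips_role(self):
        pw = two_step_pathway_with_side_compound("O")
        in_roles = classify_compounds(pw, chassis_with("O"))
        out_roles = classify_compounds(pw, chassis_with("CCCCC"))
        key = Compound("O").canonical_key
        assert in_roles[key] == "precursor"
        assert out_roles[key] == "supplement"
        xkey = Compound(X).canonical_key
        assert classify_compounds(pw, chassis_with(X))[xkey] == "precursor"
        assert classify_compounds(pw, chassis_with("CCCCC"))[xkey] == "intermediate"

    def test_stereo_insensitive_membership(self):
        chassis = chassis_with("C[C@H](O)CC")
        assert chassis.contains(Compound("CC(O)CC"))
        strict = ChassisMetabolome(
            chassis_id="strict",
            metabolite_keys=frozenset([Compound("C[C@H](O)CC").canonical_key]),
            match_stereo=True,
        )
        assert not strict.contains(Compound("CC(O)CC"))


class TestPairSummary:
    def _classified(self, chassis_smiles=("CCCCC",)):
        pw = two_step_pathway_with_side_compound("O")
        classify_compounds(pw, chassis_with(*chassis_smiles))
        return pw

    def test_basic_arithmetic(self):
        pw = self._classified()
        results = {
            (f"p{i}", f"e{j}"): [pw] for i in range(2) for j in range(3)
        }
        s = pair_summary(results)
        assert s.pairs == 6
        assert s.pathways == 6
        assert s.avg_pairs_per_producible == 3.0
        assert s.avg_pathways_per_producible == 3.0
        assert s.avg_pairs_per_detectable == 2.0

    def test_distinct_compound_semantics(self):
        pw = self._classified()
        s = pair_summary({("p", "e"): [pw] * 5})
        assert s.pathways == 5
        assert s.intermediates == 1  # X counted once despite 5 pathways
        assert s.supplements == 1    # water

    def test_empty_pair_excluded(self):
        pw = self._classified()
        s = pair_summary({("p1", "e1"): [pw], ("p2", "e2"): []})
        assert s.pairs == 1

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            pair_summary({})

    def test_tsv_has_table_columns(self):
        pw = self._classified()
        text = pair_summary({("p", "e"): [pw]}).to_tsv()
        header = text.splitlines()[0].split("\t")
        assert header == [
            "Pairs", "Pathways", "Intermediates", "Precursors", "Supplements"
        ]
        assert "Average no. of pathways" in text
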