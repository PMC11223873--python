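"""Retro reaction rules and single-step backward expansion.

A rule is a reaction SMARTS written in the retro direction: its single
left-hand template matches the (forward-direction) product and its
right-hand templates generate the forward substrates.  ``apply_rule``
performs one backward expansion step; ``expand_once`` applies a whole
ruleset and de-duplicates identical predicted reactant sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Compound, StructureParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionRule",
    "RuleApplication",
    "RuleTableError",
    "EmptyRulesetError",
    "load_rules",
    "apply_rule",
    "expand_once",
]

VALID_DIAMETERS = frozenset(range(0, 17, 2))


class RuleTableError(ValueError):
    """Rule table missing mandatory columns or otherwise unusable."""


class EmptyRulesetError(ValueError):
    """No usable rule survived loading/filtering."""


@dataclass(frozen=True)
class ReactionRule:
    """A retro transformation with diameter and penalty score.

    ``diameter`` is the atom-vicinity radius around the reaction centre
    (even, 0–16); ``penalty_score`` in [0,1] is the rule-quality penalty
    inherited by pathways (lower is better).
    """

    rule_id: str
    smarts: str
    diameter: int
    penalty_score: float
    source_reaction_id: Optional[str] = None

    def __post_init__(self):
        if self.diameter not in VALID_DIAMETERS:
            raise ValueError(
                f"rule {self.rule_id}: diameter {self.diameter} not in {{0,2,...,16}}"
            )
        if not 0.0 <= self.penalty_score <= 1.0:
            raise ValueError(
                f"rule {self.rule_id}: penalty_score {self.penalty_score} not in [0,1]"
            )
        rxn = _reaction_from_smarts(self.smarts)
        if rxn is None:
            raise ValueError(f"rule {self.rule_id}: invalid reaction SMARTS {self.smarts!r}")
        if rxn.GetNumReactantTemplates() != 1:
            raise ValueError(
                f"rule {self.rule_id}: retro rules must have exactly one "
                f"left-hand template, got {rxn.GetNumReactantTemplates()}"
            )

    @property
    def reaction(self) -> AllChem.ChemicalReaction:
        return _reaction_from_smarts(self.smarts)


@lru_cache(maxsize=4096)
def _reaction_from_smarts(smarts: str):
    try:
        rxn = AllChem.ReactionFromSmarts(smarts)
    except Exception:
        return None
    return rxn


@dataclass(frozen=True)
class RuleApplication:
    """One backward step: forward product plus predicted forward substrates."""

    rule: ReactionRule
    product: Compound
    reactants: Tuple[Compound, ...] = field()  # sorted by canonical key

    def __post_init__(self):
        if not self.reactants:
            raise ValueError("RuleApplication requires at least one reactant")

    @property
    def rule_id(self) -> str:
        return self.rule.rule_id

    @property
    def penalty_score(self) -> float:
        return self.rule.penalty_score

    @property
    def reactant_keys(self) -> frozenset:
        return frozenset(c.canonical_key for c in self.reactants)

    def forward_reaction_smiles(self) -> str:
        lhs = ".".join(c.canonical_key for c in self.reactants)
        return f"{lhs}>>{self.product.canonical_key}"


_COLUMN_ALIASES = {
    "rule_id": ("rule_id", "# rule_id", "rule id", "ruleid", "id"),
    "smarts": ("smarts", "rule_smarts", "rule smarts", "rule", "reaction_smarts"),
    "diameter": ("diameter",),
    "penalty_score": ("penalty_score", "score", "rule_score", "rule usage score"),
    "source_reaction_id": ("source_reaction_id", "reaction_id", "reaction id", "legacy_id"),
}


def _resolve_columns(columns: Sequence[str]) -> dict:
    lower = {c.lower().strip(): c for c in columns}
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    return resolved


def load_rules(
    path, min_diameter: int = 0, max_diameter: int = 16
) -> List[ReactionRule]:
    """Read a rule table (RetroRules-style CSV/TSV) filtered by diameter.

    Mandatory columns (aliases accepted): rule id, reaction SMARTS,
    diameter, score.  Malformed rows are skipped with a warning; an empty
    surviving ruleset raises :class:`EmptyRulesetError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment=None)
    except Exception as exc:
        raise RuleTableError(f"cannot read rule table {path}: {exc}") from exc

    cols = _resolve_columns(list(df.columns))
    missing = [k for k in ("rule_id", "smarts", "diameter", "penalty_score") if k not in cols]
    if missing:
        raise RuleTableError(
            f"rule table {path} lacks mandatory column(s): {', '.join(missing)} "
            f"(found: {list(df.columns)})"
        )

    rules: List[ReactionRule] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            diameter = int(row[cols["diameter"]])
            rule = ReactionRule(
                rule_id=str(row[cols["rule_id"]]),
                smarts=str(row[cols["smarts"]]),
                diameter=diameter,
                penalty_score=float(row[cols["penalty_score"]]),
                source_reaction_id=(
                    str(row[cols["source_reaction_id"]])
                    if "source_reaction_id" in cols and pd.notna(row[cols["source_reaction_id"]])
                    else None
                ),
            )
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping malformed rule row: %s", exc)
            continue
        if min_diameter <= rule.diameter <= max_diameter:
            rules.append(rule)
    if skipped:
        logger.warning("skipped %d malformed rule row(s) in %s", skipped, path)
    if not rules:
        raise EmptyRulesetError(
            f"no usable rules in {path} with diameter in [{min_diameter}, {max_diameter}]"
        )
    return rules


def apply_rule(rule: ReactionRule, compound: Compound) -> List[RuleApplication]:
    """Apply one retro rule to a compound.

    Returns one application per distinct predicted reactant set (set
    semantics on canonical keys collapse symmetric matches), ordered by the
    sorted reactant key tuple.  Chemically unparsable outcomes are dropped
    with a log entry, never raised.
    """
    rxn = rule.reaction
    try:
        outcome_sets = rxn.RunReactants((compound.mol,))
    except Exception as exc:  # pattern/kekulization pathologies
        logger.debug("rule %s failed on %s: %s", rule.rule_id, compound.canonical_key, exc)
        return []

    seen = set()
    apps: List[RuleApplication] = []
    for outcome in outcome_sets:
        reactants: List[Compound] = []
        ok = True
        for mol in outcome:
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                ok = False
                break
            for frag in Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False):
                try:
                    Chem.SanitizeMol(frag)
                    reactants.append(Compound(Chem.MolToSmiles(frag)))
                except (StructureParseError, Exception):
                    ok = False
                    break
            if not ok:
                break
        if not ok or not reactants:
            if not ok:
                logger.debug(
                    "rule %s on %s yielded an unparsable fragment; outcome dropped",
                    rule.rule_id,
                    compound.canonical_key,
                )
            continue
        reactants.sort(key=lambda c: c.canonical_key)
        key = tuple(c.canonical_key for c in reactants)
        if key in seen:
            continue
        seen.add(key)
        apps.append(RuleApplication(rule=rule, product=compound, reactants=tuple(reactants)))
    apps.sort(key=lambda a: tuple(c.canonical_key for c in a.reactants))
    return apps


def expand_once(
    compound: Compound, rules: Iterable[ReactionRule]
) -> List[RuleApplication]:
    """One full backward expansion step over a ruleset.

    Distinct reactant sets are kept once; when several rules predict the
    same reactant set the application with the lowest penalty score (then
    lexicographically smallest rule id) is retained.  Output ordering is
    deterministic: sorted by reactant key tuple, then rule id.
    """
    rules = list(rules)
    if not rules:
        raise EmptyRulesetError("expand_once requires a non-empty ruleset")
    best: dict = {}
    for rule in rules:
        for app in apply_rule(rule, compound):
            key = tuple(c.canonical_key for c in app.reactants)
            cur = best.get(key)
            if cur is None or (app.penalty_score, app.rule_id) < (
                cur.penalty_score,
                cur.rule_id,
            ):
                best[key] = app
    return [best[k] for k in sorted(best)]
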