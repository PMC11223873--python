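"""Input-table readers and the synthetic fixture generator.

Readers cover the three biological tables (detectable effectors,
producible targets, chassis metabolomes — delimited text or SBML).  The
toy-chemistry generator emits a small closed universe of real molecules
plus retro/forward rule pairs whose ground-truth pathway sets are computed
at generation time by an exhaustive expansion + all-simple-paths oracle,
so the whole engine is testable without downloading any database.
"""

from __future__ import annotations

import json
import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from rdkit import Chem

from .chem import Compound, StructureParseError, tanimoto
from .pathways import ChassisMetabolome
from .rules import ReactionRule, expand_once

logger = logging.getLogger(__name__)

__all__ = [
    "EffectorRecord",
    "ProducibleRecord",
    "ToyChemistry",
    "brute_force_detectable_paths",
    "generate_toy_chemistry",
    "load_chassis",
    "load_effectors",
    "load_producibles",
    "write_fixture_bundle",
]


@dataclass
class EffectorRecord:
    """A detectable compound with its allosteric transcription factor(s)."""

    compound: Compound
    transcription_factors: List[Tuple[str, str]]  # (tf_name, organism)
    evidence: Optional[str] = None

    def __post_init__(self):
        if not self.transcription_factors:
            raise ValueError(
                f"effector {self.compound.id}: at least one transcription factor required"
            )


@dataclass
class ProducibleRecord:
    """A bio-based target compound from the producible map."""

    compound: Compound
    display_name: str = ""
    map_category: Optional[str] = None

    def __post_init__(self):
        if not self.display_name:
            self.display_name = self.compound.id


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def _find_column(df: pd.DataFrame, aliases: Sequence[str]) -> Optional[str]:
    lower = {c.lower().strip(): c for c in df.columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    return None


def load_effectors(path) -> List[EffectorRecord]:
    """Read the detectable-compound table.

    Rows sharing one compound (by canonical key) merge into a single record
    carrying every transcription factor.  Unparsable structures are skipped
    with a warning; an empty result is an error.
    """
    df = _read_table(path)
    c_structure = _find_column(df, ("structure", "smiles", "inchi", "effector"))
    c_tf = _find_column(df, ("tf", "tf_name", "transcription_factor"))
    c_org = _find_column(df, ("organism", "source_organism", "species"))
    c_id = _find_column(df, ("id", "name", "compound_id"))
    c_ev = _find_column(df, ("evidence", "reference"))
    if c_structure is None or c_tf is None:
        raise ValueError(
            f"effector table {path} needs structure and transcription-factor columns"
        )
    records: Dict[str, EffectorRecord] = {}
    skipped = 0
    for _, row in df.iterrows():
        try:
            compound = Compound(
                str(row[c_structure]),
                id=str(row[c_id]) if c_id and pd.notna(row[c_id]) else None,
            )
        except StructureParseError as exc:
            skipped += 1
            logger.warning("skipping effector row: %s", exc)
            continue
        tf = (
            str(row[c_tf]),
            str(row[c_org]) if c_org and pd.notna(row[c_org]) else "",
        )
        key = compound.canonical_key
        if key in records:
            if tf not in records[key].transcription_factors:
                records[key].transcription_factors.append(tf)
        else:
            records[key] = EffectorRecord(
                compound=compound,
                transcription_factors=[tf],
                evidence=str(row[c_ev]) if c_ev and pd.notna(row[c_ev]) else None,
            )
    if skipped:
        logger.warning("skipped %d unparsable effector row(s) in %s", skipped, path)
    if not records:
        raise ValueError(f"effector table {path} yielded zero usable records")
    return list(records.values())


def load_producibles(path) -> List[ProducibleRecord]:
    """Read the producible-compound table (id, structure, optional name)."""
    df = _read_table(path)
    c_structure = _find_column(df, ("structure", "smiles", "inchi"))
    c_id = _find_column(df, ("id", "compound_id"))
    c_name = _find_column(df, ("name", "display_name"))
    c_cat = _find_column(df, ("category", "map_category"))
    if c_structure is None:
        raise ValueError(f"producible table {path} needs a structure column")
    records: Dict[str, ProducibleRecord] = {}
    skipped = 0
    for _, row in df.iterrows():
        try:
            compound = Compound(
                str(row[c_structure]),
                id=str(row[c_id]) if c_id and pd.notna(row[c_id]) else None,
            )
        except StructureParseError as exc:
            skipped += 1
            logger.warning("skipping producible row: %s", exc)
            continue
        records.setdefault(
            compound.canonical_key,
            ProducibleRecord(
                compound=compound,
                display_name=str(row[c_name]) if c_name and pd.notna(row[c_name]) else "",
                map_category=str(row[c_cat]) if c_cat and pd.notna(row[c_cat]) else None,
            ),
        )
    if skipped:
        logger.warning("skipped %d unparsable producible row(s) in %s", skipped, path)
    if not records:
        raise ValueError(f"producible table {path} yielded zero usable records")
    return list(records.values())


_INCHI_RE = re.compile(r"InChI=[^\s<\"']+")


def _chassis_from_sbml(path, chassis_id: str) -> ChassisMetabolome:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise ValueError(f"cannot read SBML model from {path}")
    model = doc.getModel()
    keys: Set[str] = set()
    dropped = 0
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        text = ""
        if sp.isSetAnnotation():
            text += sp.getAnnotationString()
        if sp.isSetNotes():
            text += sp.getNotesString()
        match = _INCHI_RE.search(text)
        if not match:
            dropped += 1
            continue
        try:
            keys.add(Compound(match.group(0)).canonical_key)
        except StructureParseError:
            dropped += 1
    if dropped:
        logger.warning("%s: %d species without resolvable structure dropped", path, dropped)
    if not keys:
        raise ValueError(f"SBML model {path} contains no resolvable metabolite structures")
    return ChassisMetabolome(
        chassis_id=chassis_id,
        metabolite_keys=frozenset(keys),
        display_name=model.getName() or chassis_id,
    )


def load_chassis(path, chassis_id: str) -> ChassisMetabolome:
    """Load a chassis metabolome from SBML or a two-column delimited file.

    Delimited format: id, structure (SMILES or InChI).  Metabolites whose
    structure cannot be resolved are dropped with a logged count; zero
    resolvable metabolites is an error.
    """
    path = Path(path)
    head = path.read_text(errors="replace")[:512].lstrip()
    if head.startswith("<?xml") or head.startswith("<sbml"):
        return _chassis_from_sbml(path, chassis_id)
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"chassis table {path} needs (id, structure) columns")
    keys: Set[str] = set()
    dropped = 0
    for _, row in df.iterrows():
        try:
            keys.add(Compound(str(row.iloc[1])).canonical_key)
        except StructureParseError:
            dropped += 1
    if dropped:
        logger.warning("%s: %d metabolite rows without resolvable structure", path, dropped)
    if not keys:
        raise ValueError(f"chassis table {path} yielded zero resolvable metabolites")
    return ChassisMetabolome(
        chassis_id=chassis_id, metabolite_keys=frozenset(keys), display_name=chassis_id
    )


# ---------------------------------------------------------------------------
# Synthetic toy chemistry
# ---------------------------------------------------------------------------

def _exact_smarts(mol: Chem.Mol) -> str:
    """Full-molecule SMARTS with element, H-count and degree constraints.

    Works for the acyclic molecules of the toy universe; the constraints
    prevent the pattern from embedding in any strictly larger universe
    member, so each retro rule fires only on its intended compound.
    """
    bond_symbol = {
        Chem.BondType.SINGLE: "-",
        Chem.BondType.DOUBLE: "=",
        Chem.BondType.TRIPLE: "#",
    }

    def atom_q(atom: Chem.Atom) -> str:
        return f"[#{atom.GetAtomicNum()};H{atom.GetTotalNumHs()};D{atom.GetDegree()}]"

    def rec(atom: Chem.Atom, parent_idx: int) -> str:
        parts = [atom_q(atom)]
        branches = []
        for bond in atom.GetBonds():
            nbr = bond.GetOtherAtom(atom)
            if nbr.GetIdx() == parent_idx:
                continue
            branches.append(bond_symbol[bond.GetBondType()] + rec(nbr, atom.GetIdx()))
        for b in branches[:-1]:
            parts.append(f"({b})")
        if branches:
            parts.append(branches[-1])
        return "".join(parts)

    return rec(mol.GetAtomWithIdx(0), -1)


# (suffix builder, minimum chain length) — each entry defines a family of
# linear molecules distinguishable by exact SMARTS patterns.
_FAMILIES = [
    (lambda n: "C" * n + "O", 1),      # primary alcohol
    (lambda n: "C" * n + "N", 1),      # primary amine
    (lambda n: "C" * n + "Cl", 1),     # alkyl chloride
    (lambda n: "C" * n + "=O", 1),     # aldehyde
    (lambda n: "C" * (n - 1) + "C(=O)O", 1),  # carboxylic acid
    (lambda n: "C" * n + "S", 1),      # thiol
]


def _molecule_pool(limit: int) -> List[str]:
    smiles: List[str] = []
    seen: Set[str] = set()
    length = 1
    while len(smiles) < limit and length <= 12:
        for make, min_len in _FAMILIES:
            if length < min_len:
                continue
            s = make(length)
            key = Compound(s).canonical_key
            if key not in seen:
                seen.add(key)
                smiles.append(key)
            if len(smiles) >= limit:
                break
        length += 1
    return smiles


@dataclass
class ToyChemistry:
    """A closed synthetic universe with verified ground-truth pathways.

    ``ground_truth_paths`` maps (source id, target id) to the list of
    forward-ordered rule-id tuples an exhaustive oracle finds under the
    shortest-branch rule.  Forward rules exist solely for round-trip tests.
    """

    seed: int
    compounds: List[Compound]
    retro_rules: List[ReactionRule]
    forward_rules: List[ReactionRule]
    source: Compound
    max_depth: int
    ground_truth_paths: Dict[Tuple[str, str], List[Tuple[str, ...]]] = field(
        default_factory=dict
    )

    @property
    def rules(self) -> List[ReactionRule]:
        return self.retro_rules + self.forward_rules

    def compound_by_id(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)


def brute_force_detectable_paths(
    source: Compound,
    target: Compound,
    rules: Sequence[ReactionRule],
    max_depth: int,
) -> List[Tuple[str, ...]]:
    """Independent oracle: exhaustive expansion + all-simple-paths.

    Expands backward from ``source`` breadth-first to ``max_depth`` (the
    target is terminal and never expanded; multi-reactant steps follow the
    most-target-similar reactant, as the search does), enumerates every
    simple retro path source→target of length ≤ max_depth, restricts
    distances to the union of those paths, and keeps a path iff each of its
    edges lies on a minimal-step producing branch of its head compound.
    Returns forward-ordered (target-first) rule-id tuples, sorted.
    """
    g = nx.MultiDiGraph()
    compounds: Dict[str, Compound] = {source.canonical_key: source}
    g.add_node(source.canonical_key)
    frontier = [source]
    for _ in range(max_depth):
        nxt: List[Compound] = []
        for compound in frontier:
            if compound.canonical_key == target.canonical_key:
                continue
            for app in expand_once(compound, rules):
                main = max(
                    app.reactants,
                    key=lambda c: (tanimoto(c, target), c.canonical_key),
                )
                mkey = main.canonical_key
                if mkey not in compounds:
                    compounds[mkey] = main
                    nxt.append(main)
                if not g.has_edge(compound.canonical_key, mkey, key=app.rule_id):
                    g.add_edge(compound.canonical_key, mkey, key=app.rule_id)
        frontier = nxt

    skey, tkey = source.canonical_key, target.canonical_key
    if tkey not in g:
        return []
    edge_paths = [
        [(u, v, k) for u, v, k in path]
        for path in nx.all_simple_edge_paths(g, skey, tkey, cutoff=max_depth)
    ]
    if not edge_paths:
        return []
    # union of path edges, forward orientation (retro edge u→v is forward v→u)
    fwd = nx.DiGraph()
    for path in edge_paths:
        for u, v, _k in path:
            fwd.add_edge(v, u)
    dist = nx.single_source_shortest_path_length(fwd, tkey)
    results: Set[Tuple[str, ...]] = set()
    for path in edge_paths:
        ok = all(dist.get(v, -2) + 1 == dist.get(u, -9) for u, v, _k in path)
        if ok:
            results.add(tuple(k for _u, _v, k in reversed(path)))
    return sorted(results)


def generate_toy_chemistry(
    seed: int, n_compounds: int = 12, branching: float = 1.0
) -> ToyChemistry:
    """Deterministically generate a toy universe of molecules and rules.

    Molecules are arranged in levels below a single source (the toy
    "effector"); each retro rule rewrites one molecule into the next-level
    one via an exact-match SMARTS, and every rule ships with its paired
    forward rule for round-trip checks.  ``branching`` sets the level width
    (1.0 → a linear chain) and the chance of extra parents, which creates
    branched nodes with multiple equal-length ground-truth paths.
    """
    if n_compounds > 50:
        raise ValueError("toy universes are capped at 50 compounds")
    if n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    for attempt in range(5):
        toy = _generate_once(seed + 100_000 * attempt, seed, n_compounds, branching)
        if toy is not None:
            return toy
    raise RuntimeError(
        f"could not generate a connected toy chemistry for seed={seed}, "
        f"n_compounds={n_compounds}, branching={branching}"
    )


def _generate_once(
    rng_seed: int, seed: int, n_compounds: int, branching: float
) -> Optional[ToyChemistry]:
    rng = random.Random(rng_seed)
    pool = _molecule_pool(n_compounds)
    rng.shuffle(pool)
    compounds = [Compound(s, id=f"C{i:02d}") for i, s in enumerate(pool[:n_compounds])]

    width = max(1, int(round(branching)))
    levels: List[List[Compound]] = [[compounds[0]]]
    idx = 1
    while idx < len(compounds):
        levels.append(compounds[idx : idx + width])
        idx += width

    edges: List[Tuple[Compound, Compound]] = []
    extra_p = min(0.6, max(0.0, branching - 1.0) / 2.0)
    for li in range(1, len(levels)):
        parents = levels[li - 1]
        for child in levels[li]:
            chosen = {rng.randrange(len(parents))}
            if len(parents) > 1 and rng.random() < extra_p:
                chosen.add(rng.randrange(len(parents)))
            for pi in sorted(chosen):
                edges.append((parents[pi], child))
    # guarantee a diamond when branching allows one
    if width > 1 and len(levels) > 2 and len(levels[1]) > 1 and levels[2]:
        child = levels[2][0]
        for parent in levels[1][:2]:
            if (parent, child) not in edges:
                edges.append((parent, child))

    retro_rules: List[ReactionRule] = []
    forward_rules: List[ReactionRule] = []
    for k, (parent, child) in enumerate(edges):
        diameter = rng.choice((2, 4, 6, 8, 10, 12, 14, 16))
        penalty = round(rng.uniform(0.05, 0.95), 4)
        retro_rules.append(
            ReactionRule(
                rule_id=f"rr{k:04d}",
                smarts=f"{_exact_smarts(parent.mol)}>>{child.canonical_key}",
                diameter=diameter,
                penalty_score=penalty,
            )
        )
        forward_rules.append(
            ReactionRule(
                rule_id=f"fr{k:04d}",
                smarts=f"{_exact_smarts(child.mol)}>>{parent.canonical_key}",
                diameter=diameter,
                penalty_score=penalty,
            )
        )

    source = compounds[0]
    max_depth = len(levels) - 1
    toy = ToyChemistry(
        seed=seed,
        compounds=compounds,
        retro_rules=retro_rules,
        forward_rules=forward_rules,
        source=source,
        max_depth=max_depth,
    )
    for compound in compounds[1:]:
        paths = brute_force_detectable_paths(source, compound, retro_rules, max_depth)
        if not paths:
            return None  # disconnected — caller retries with a new sub-seed
        toy.ground_truth_paths[(source.id, compound.id)] = paths
    return toy


def write_fixture_bundle(toy: ToyChemistry, outdir) -> Dict[str, Path]:
    """Write a toy chemistry as a directory of the standard input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(toy.seed)

    paths: Dict[str, Path] = {}
    rules_rows = [
        {
            "rule_id": r.rule_id,
            "smarts": r.smarts,
            "diameter": r.diameter,
            "penalty_score": r.penalty_score,
        }
        for r in toy.retro_rules
    ]
    paths["rules"] = outdir / "rules.csv"
    pd.DataFrame(rules_rows).to_csv(paths["rules"], index=False)
    paths["forward_rules"] = outdir / "rules_forward.csv"
    pd.DataFrame(
        [
            {
                "rule_id": r.rule_id,
                "smarts": r.smarts,
                "diameter": r.diameter,
                "penalty_score": r.penalty_score,
            }
            for r in toy.forward_rules
        ]
    ).to_csv(paths["forward_rules"], index=False)

    paths["compounds"] = outdir / "compounds.tsv"
    pd.DataFrame(
        [{"id": c.id, "structure": c.canonical_key} for c in toy.compounds]
    ).to_csv(paths["compounds"], sep="\t", index=False)

    paths["effectors"] = outdir / "effectors.tsv"
    pd.DataFrame(
        [
            {
                "id": toy.source.id,
                "structure": toy.source.canonical_key,
                "tf": "ToyR",
                "organism": "Escherichia coli",
            }
        ]
    ).to_csv(paths["effectors"], sep="\t", index=False)

    producibles = [c for c in toy.compounds[1:]]
    paths["producibles"] = outdir / "producibles.tsv"
    pd.DataFrame(
        [{"id": c.id, "structure": c.canonical_key, "name": c.id} for c in producibles]
    ).to_csv(paths["producibles"], sep="\t", index=False)

    # chassis: a random half of the universe plus water/ammonia
    members = sorted(
        rng.sample(range(len(toy.compounds)), max(1, len(toy.compounds) // 2))
    )
    rows = [
        {"id": toy.compounds[i].id, "structure": toy.compounds[i].canonical_key}
        for i in members
    ]
    rows += [{"id": "water", "structure": "O"}, {"id": "ammonia", "structure": "N"}]
    paths["chassis"] = outdir / "chassis.tsv"
    pd.DataFrame(rows).to_csv(paths["chassis"], sep="\t", index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(
        json.dumps(
            {
                f"{s}->{t}": [list(p) for p in plist]
                for (s, t), plist in sorted(toy.ground_truth_paths.items())
            },
            indent=1,
        )
    )
    return paths
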