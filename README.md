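# detpath

Design of **detectable enzymatic pathways**: given a bio-based target
compound, a chassis organism's metabolome, and a table of effector
molecules recognised by allosteric transcription factors, `detpath` finds
short retro-biosynthetic routes that convert the target into a detectable
effector — so a biosensor circuit can indirectly report the target's
concentration.

The engine works in four stages per (target, effector) pair:

1. **Metabolic expansion** — retro reaction rules (RetroRules-style SMARTS
   with diameter and penalty score) are applied backward starting from the
   detectable effector.
2. **Monte Carlo tree search** — a UCT tree search bounds the combinatorial
   expansion, guided by Tanimoto fingerprint similarity of each new
   compound to the target; solved/dead subtrees are pruned so small
   instances are searched exhaustively.
3. **Pathway enumeration** — the tree collapses into a bipartite
   compound–reaction scope graph; at every branched compound node only the
   producing branches of minimal step count are kept, and the retained
   branches are combined into distinct pathways.
4. **Ranking & classification** — each pathway's global score is its worst
   step penalty (lower is better), with precursor steady-state flux and
   length as tie-breaks; every pathway compound is classified against the
   chassis metabolome as precursor, intermediate, or supplement.

Results export to SBML L3V1 (with role/structure annotations), Cytoscape-
style elements JSON, and enzyme-selection query links.

## Command line

```bash
# generate a self-contained synthetic fixture bundle (no downloads needed)
detpath fixtures --seed 2 --n-compounds 8 --branching 2.0 --out fx/

# find detectable pathways from a target to every effector in the table
detpath find --target "$(tail -1 fx/producibles.tsv | cut -f2)" \
    --effectors fx/effectors.tsv --rules fx/rules.csv \
    --chassis fx/chassis.tsv --seed 7 --out results/run1

# aggregate summary tables (Pairs / Pathways / Intermediates / ...)
detpath summary results/run1

# re-export a pair's pathways as network JSON or SBML
detpath export results/run1/pair_001_* --format json --out network.json
```

`find` exit codes: `0` success, `1` input error, `2` usage error,
`3` no (target, effector) pair could be connected.

A YAML config file (`--config`) accepts: `min_diameter`, `max_diameter`,
`iterations`, `max_depth`, `exploration_constant`, `similarity_threshold`,
`max_pathways`, `seed`. Per-pair RNG streams are derived from the master
seed and the pair's canonical keys, so runs are reproducible regardless of
pair order.

## Input formats

- **Rules** — delimited table with rule id, retro reaction SMARTS (single
  left-hand template), even diameter in 0–16, penalty score in [0,1];
  RetroRules CSV column names are accepted.
- **Effectors** — delimited table with structure (SMILES/InChI),
  transcription-factor name, organism; rows merge per compound.
- **Chassis** — SBML model whose species carry InChI annotations, or a
  two-column (id, structure) table.
- **Flux / whitelist** — optional two-column (key, flux) and one-column
  key files used by ranking and precursor classification.

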