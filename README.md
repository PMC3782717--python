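# psimi-coop

Cooperative-interaction annotation for PSI-MI XML 2.5.

Molecular binding events are often interdependent: binding of Cyclin A to
Cdk2 realigns the kinase's active site and exposes T160 for phosphorylation
by Cdk7, and the phosphorylated complex in turn recruits and phosphorylates
the substrate Cdc6. Standard molecular-interaction records capture each
binding event in isolation; the *cooperative* couplings between them —
whether one interaction augments or diminishes another, and whether the
mechanism is **allostery** (reciprocal energetic coupling between two sites
on one molecule; a *k-type* response alters affinity, a *v-type* response
alters catalysis) or **pre-assembly** (prior complex formation creating a
composite binding site, altering physicochemical compatibility, hiding a
site, or pre-organizing a multivalent ligand) — are expressed with a
dedicated block of controlled-vocabulary terms (MI:1149–MI:1175) used as
attribute names inside ordinary PSI-MI 2.5 interaction records, with no
schema change.

This package is for curators and bioinformaticians who produce or consume
such files. It provides:

- **`psimi_coop.cv`** — the embedded cooperative-interaction vocabulary
  (27 terms plus external stubs), with name/accession lookup, transitive
  `is_a`/`part_of` closure, value contracts (what each attribute must carry:
  an interaction id, participant id, feature id, a fold change, or nothing),
  and OBO 1.2 import/export.
- **`psimi_coop.model`** — dataclasses for the PSI-MI 2.5 entry subset
  (experiments, interactors, interactions, participants, features,
  attributes), with per-class id spaces, reference resolution and id-based
  navigation. A participant may reference a *prior interaction* instead of
  an interactor — that is how ordered complex assembly is written down.
- **`psimi_coop.xml_io`** — canonical reader/writer for the compact MIF254
  form, plus validation against a bundled subset XSD.
- **`psimi_coop.cooperativity`** — effect extraction and the semantic rule
  catalogue COOP01–COOP11 (exactly one mechanism per record, a resolvable
  affected interaction distinct from the source, value contracts respected,
  allostery/pre-assembly slot exclusivity, participant-ref resolution,
  inferred-evidence conventions, name/accession consistency).
- **`psimi_coop.coopgraph`** — the directed graph of binding events linked
  by cooperative effects and assembly (participant-of) edges, with
  deterministic topological assembly order and DOT/JSON export.
- **`psimi_coop.fixtures`** — deterministic generators for the
  Cdc6/CyclinA–Cdk2 worked example, three mechanism vignettes
  (CheY–FliM allosteric PTM, Skp2–Cks1–p27 composite binding site,
  PLCγ1–LAT cooperative cycle) and seeded single-rule violations.
- **`psimi-coop`** — a CLI over the above: `validate`, `graph`, `fixture`,
  `cv export|show`, `render`.

## Worked example

```python
import psimi_coop as pc

registry = pc.builtin_registry()
entry = pc.cdc6_full().entries[0]

effects = pc.extract_effects(entry, registry)
print(len(effects))                      # 7
effect = next(e for e in effects if e.source_interaction_id == 10)
print(effect.mechanism.name,             # ALLOSTERY
      effect.affected_interaction_id,    # 12
      effect.outcome.name)               # POSITIVE

graph = pc.build_graph(entry, registry)
print(len(graph.coop_edges))             # 7
print(pc.assembly_order(graph))          # [5, 6, 12]
```

Seven cooperative effects are annotated across eight interaction records
(a record holds at most one effect, so a binding event with several effects
is repeated; the graph merges repeats back onto one node). The assembly
order `[5, 6, 12]` is the hierarchical build-up: CyclinA–Cdk2 complex
formation (interaction 5), its phosphorylation by Cdk7 (6), then Cdc6
recruitment and phosphorylation (12). The effect shown is the positive
v-type allosteric effect of phospho-T160 on Cdc6 phosphorylation, annotated
on the Cdk7-phosphorylation record and pointing at affected interaction 12.

From the shell:

```sh
psimi-coop fixture cdc6 -o cdc6.xml
psimi-coop validate cdc6.xml        # exit 0, no findings
psimi-coop graph cdc6.xml --format dot
psimi-coop cv show MI:1152          # value contract: FOLD_CHANGE
```

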