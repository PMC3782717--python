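# Methods

## The annotation convention

PSI-MI XML 2.5 describes molecular interactions as self-contained `entry`
units with six child element kinds: `source`, `availabilityList`,
`experimentList`, `interactorList`, `interactionList` and `attributeList`.
The format itself has no notion of one interaction influencing another.
Cooperativity is therefore layered on top of the unchanged schema through
controlled-vocabulary terms used as attribute names:

- An interaction that *exerts* a cooperative effect carries, in its
  `attributeList`, a mechanism attribute (`allostery`, MI:1157, or
  `pre-assembly`, MI:1158), an `affected interaction` attribute (MI:1150)
  whose value is the id of the influenced interaction, an outcome attribute
  (`positive`/`negative cooperative effect`, MI:1154/MI:1155), optionally a
  `cooperative effect value` (MI:1152, a dimensionless fold change of an
  affinity or catalytic parameter), and mechanism-specific slots:
  for allostery the `allosteric molecule` (MI:1159, a participant id),
  exactly one of `allosteric effector` (MI:1160, participant id) or
  `allosteric ptm` (MI:1175, feature id), and optional response
  (k-type/v-type), mediating mechanism (structure/dynamics) and allostery
  type (homo/heterotropic) qualifiers; for pre-assembly one response class
  (composite binding site formation, altered physicochemical compatibility,
  binding site hiding, configurational pre-organization).
- Ordered assembly is expressed by a participant referencing a *prior
  interaction* (`interactionRef`) instead of an interactor: the participant
  stands for the pre-formed complex. When a feature (e.g. a PTM) sits on
  one subunit of such a complex, the `participant-ref` feature attribute
  (MI:1151) names that subunit by its participant id *in the referenced
  interaction*.
- Because an attribute list holds exactly one effect, a binding event with
  several effects is curated as repeated interaction records.
- Evidence for cooperativity is inference across experiments/publications,
  so effect-bearing records point at experiments whose detection method is
  `inferred by author` (MI:0363) or `inferred by curator` (MI:0364), while
  the primary evidence for the binding event itself lives in an external
  record referenced by `xref` (the worked example cross-references DIP
  record DIP57013E).

## Vocabulary representation

The 27-term block MI:1149–MI:1175 is embedded as data, together with stub
terms for the seven pre-existing accessions the relations point at
(MI:0000, MI:0252, MI:0363, MI:0364, MI:0500, MI:0664, MI:0668), so closure
queries terminate without loading the full PSI-MI CV. Term names are stored
in lower case, the form used in attribute names in curated XML; published
tables render them in Title Case, so name lookup is exact-case in strict
mode and case-insensitive in lenient mode (the default for validation).
Terms with dual parentage (e.g. `allosteric molecule` is both a biological
role and an interaction attribute name) carry multiple parents rather than
duplicate entries. `value_contract` and `attribute_scope` — which column of
the annotation convention the term belongs to and what its attribute value
must contain — are modelled as explicit enum fields and serialized as OBO
`property_value` lines so the OBO export re-imports with identity. The OBO
parser is a small stanza reader because the package needs line-numbered
parse errors and duplicate-accession detection; an independent OBO library
is used in the tests as a cross-check oracle, not as the implementation.

## Data model and id discipline

Ids are bare positive integers, unique *per element class* within an entry
(experiments, interactors, interactions, participants, features are five
separate id spaces). This matches curated practice — the worked example
uses interactor 3, interactions 5 and 12 and participant 13 concurrently —
and keeps `participant-ref` resolution well defined, since that value is
interpreted inside its referenced interaction. Cross-class collisions are
legal. Uniqueness is enforced at construction time, so a malformed entry
fails deterministically rather than at some later query.

Participant-as-interaction references must form a partial order: a
participant referencing its own enclosing interaction, directly or through
a chain, is reported by `resolve_references` as a cycle finding. Coop
edges, by contrast, may form cycles — mutually stabilizing binding events
are real (the PLCγ1 vignette is a two-cycle) — so only assembly edges are
required to be acyclic.

## XML serialization

Only the compact (id-referenced) form is written; the reader additionally
tolerates expanded inline interactor definitions by lifting them into the
interactor list and rewriting the participant to a reference. Output is
canonical: entry children in schema sequence order, empty optional lists
omitted, attributes ordered `name` then `nameAc`, two-space indent, UTF-8
with declaration, and `level="2" version="5" minorVersion="4"` on the
root. Canonical output makes the round-trip tests exact: `read(write(E)) ==
E` structurally, and `write(read(text)) == text` byte-for-byte on our own
output.

Entry-level elements outside the modeled subset (`availabilityList`
content, foreign elements) are preserved verbatim in an `extras` store and
re-emitted in schema position. Extras are normalized to a
whitespace-independent serialization at read time so they compare equal
across cycles regardless of the surrounding document's indentation;
whitespace-only text inside extras is treated as insignificant.

The bundled XSD (`data/mif254_subset_synthetic.xsd`) is a purpose-written
subset schema covering exactly the modeled element set — it is not the
official MIF254 schema, and documents valid against it use only constructs
that are also valid MIF254. Validation uses lxml's XSD engine and reports
line-numbered findings.

## Validation rule catalogue

`validate` applies eleven rules (stable codes COOP01–COOP11, listed in its
docstring) and returns findings instead of raising; zero ERROR findings
guarantees that `extract_effects` succeeds and every extracted effect
satisfies the structural invariants of `CooperativeEffect`. Design points
that were genuinely open:

- *Scope of allosteric references.* The convention never states whether the
  allosteric molecule/effector/PTM must belong to the effect-bearing record
  or may resolve anywhere in the entry. Here resolution within the source
  record is clean, resolution elsewhere in the entry is a WARNING, and
  failure to resolve at all is an ERROR.
- *Missing outcome* is a WARNING, not an ERROR: the outcome is annotatable
  but nowhere mandated.
- *Fold-change direction.* The effect value is stored as the printed
  magnitude; direction is carried by the positive/negative outcome, since
  the absence-versus-presence phrasing of the value definition is
  direction-ambiguous. Values must be positive finite reals; `1.0` means
  no change.
- *One affected interaction per record* is enforced as an ERROR; several
  effects of one binding event are expressed by record repetition, and a
  record naming two targets is taken as a curation error rather than a
  shorthand.
- Mechanism-conditional rules (COOP06/COOP07) are skipped when COOP01 has
  already fired, so one seeded defect yields one finding rather than a
  cascade.
- The allosteric qualifiers (k/v-type, structure/dynamics,
  homo/heterotropic) are treated as optional annotations, never required.

## Graph construction

Repeated records are merged when they share an identical participant
reference multiset (interaction references canonicalized through the
merge mapping, iterated to a fixpoint) and the same interaction type; the
representative is the lowest record id, matching the curation habit of
annotating the primary record first. Merging never changes the coop-edge
multiset — one edge per extracted effect, endpoints mapped through the
representative. Assembly edges are deduplicated after merging.
`assembly_order` is a lexicographic topological sort (ties broken by
ascending interaction id), so the order is deterministic and is a linear
extension of the assembly partial order by construction.

## Fixtures: what they emulate and what they do not

The fixtures reproduce the published worked examples as data: the
Cdc6/CyclinA–Cdk2 entry (four interactors, eight records, seven positive
effects — five allosteric, two pre-assembly — with the printed identifiers
3/5/12/13 and the DIP cross-reference) and three single-mechanism
vignettes. They are deterministic, generated in code, and schema-valid on
write. Mechanism-category assignments for the seven effects follow the
narrative description of the system: access/exposure phrasing maps to
k-type, catalysis-rate phrasing to v-type, and the bipartite-site and
phosphate-hydrogen-bond effects to the composite-binding-site and
altered-physicochemical-compatibility pre-assembly classes. Which
experiments back each effect is not published record-by-record; fixtures
attach one inferred-by-author or inferred-by-curator experiment per record.
Experiment bibliographic ids are synthetic placeholders; UniProt/ChEBI
accessions are decorative metadata, never fetched.

Passing tests on these fixtures demonstrates that the conventions are
implemented self-consistently at desk scale (a handful of records,
sub-second runtimes); they do not exercise large curated corpora, files
from other producers with unusual namespace or whitespace habits beyond
what the reader tolerates, or the full PSI-MI 2.5 feature set (negative
interactions, confidence lists, inferred-interaction lists and host
organisms are out of scope).

`mutate` produces minimally altered copies that trigger exactly one rule
code each; the COOP10 variant retargets a single record to a fresh
experiment with a concrete detection method so that exactly one finding
results even though the baseline experiments are shared across records.

## Known limitations

- Cross-entry interdependencies cannot be expressed (references are
  entry-local in PSI-MI 2.5); the validator treats an unresolvable affected
  interaction as an error rather than a cross-file link.
- Extras passthrough is entry-level; unknown elements *inside* modeled
  elements (e.g. a confidence list inside an interaction) are dropped on
  read rather than preserved.
- The bundled XSD validates the modeled subset, not full MIF254; a
  document using out-of-subset MIF254 features will be flagged even though
  the official schema would accept it.
- The HTML renderer is a minimal fresh design for human inspection, not a
  reproduction of the historical PSI-MI style sheets.
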