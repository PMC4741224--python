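# Methods

## The problem being modelled

Biological nomenclature requires (or strongly encourages) that nomenclatural
acts — descriptions of new taxa, new combinations, replacement names, type
designations — be registered with a name index before the work publishing
them appears: MycoBank / Index Fungorum / Fungal Names for fungi (mandatory
since 2013), ZooBank for animals (mandatory for e-only works since 2012),
IPNI for vascular plants (pre-publication indexing piloted rather than
mandated). Doing this by hand is impractical for "turbo-taxonomy" papers
that describe hundreds of species at once. `nomenreg` models the automated,
publisher-initiated, machine-to-machine workflow that replaces the manual
step:

1. **Submit on acceptance.** The accepted manuscript (TaxPub-flavoured JATS
   XML) is parsed; article metadata, the author byline and every
   nomenclatural act are upserted into the registry store in the
   `embargoed` state.
2. **Report.** The registry answers with one outcome per act: a minted
   `urn:uuid` identifier, an error message (e.g. act outside the registry's
   recording scope), or a pending marker when the author name collides with
   two or more registered homonyms and an operator must choose.
3. **Inject.** The identifiers are spliced back into the manuscript XML,
   one `registration-id` element per nomenclature block, so the published
   protologue carries its registry identifier.
4. **Release.** On publication day every record of the article flips to
   `public` with a link to the article, and the final published metadata is
   diffed against what was stored at acceptance (discrepancies are
   reported, never auto-corrected).

A changed manuscript may be uploaded again while still embargoed: records
are matched by a deduplication key, so identifiers are stable; acts that
disappeared are marked `superseded`.

## Act classification and the scope matrix

Classification is driven by the status phrase printed in the nomenclature
block (`sp. nov.`, `gen. nov.`, `comb. nov.`, `nom. nov.`, `lectotype
designated`, ...). The phrase vocabulary is a config file
(`data/status_phrases.yaml`), because journals vary; the shipped vocabulary
deliberately carries exactly one phrase per classification so the
phrase-to-act map is injective (synonyms such as `var. nov.` or `trib.
nov.` are user additions). An unrecognized phrase is a classification
error, never a guess. A new species whose epithet repeats its genus name is
reclassified as a tautonym.

Registrability is a constant registry × act-descriptor matrix
(`data/scope_matrix.yaml`, human-auditable) with three code rules layered
on top:

- **Hybrids** are a flag on a new-taxon rank, not a separate act kind; the
  flag is only meaningful under the botanical code (ICNafp), and
  hybrid-flagged acts are `not_applicable` to ZooBank.
- **Tautonyms** are not validly published under ICNafp; the botanical and
  fungal registries record them *with a warning* to be resolved at indexing
  stage. Under the zoological code tautonymy is unremarkable, so the
  matrix row is `not_applicable` for ZooBank (a zoological tautonym is
  simply a new species).
- **IPNI typification scope** is holotypification of new taxa only;
  lecto-, neo- and epitypifications are `not_recorded` there (epitypes do
  not exist under the zoological code at all).

Four cells of the source table were blank in print for the ZooBank column
(suprafamilial new taxa, replacement names, new combinations and the
holo-/lecto-/neotype rows). They are transcribed as `recorded` — the
zoological registry does register those acts — but each carries a
`table_blank: true` annotation and is excluded from the transcription-diff
audit rather than silently asserted.

## Deduplication and author matching

- **Act key**: normalized concatenation of code, act kind, canonical name,
  status phrase and type kind. Normalization is Unicode NFKD decomposition,
  diacritic stripping, casefolding, punctuation removal and whitespace
  collapse — mechanical, no fuzzy scoring.
- **Author key**: normalized surname plus the *initials* of the given-name
  tokens. Reducing given names to initials is what makes "J." and "John"
  compare as the same prefix class, while keeping the key a pure function
  of the name; homonym candidates therefore share the key exactly.
- `match_authors` returns no-match / unique-match / homonyms(≥2). Homonyms
  enter a pending queue; the operator's choice (an existing record or "new
  person") is applied via `resolve_disambiguation`. A pending author blocks
  identifier injection but not the registration of unaffected acts.

Registering two homonymous people requires them to already exist in the
store, so the fixture generator plants homonyms as a `preload_authors`
manifest list (two raw spellings normalizing to one key) that the test or
pipeline registers before submitting the manuscript.

## Registry store semantics

- Identifiers are `urn:uuid` values drawn from a seeded RNG; the store
  guarantees it never reissues one. Clock and RNG are injected, so a whole
  pipeline run is a pure function of (inputs, seed, clock) — the replay
  determinism tests rely on this.
- State machine: `embargoed → public`, `any → superseded`, plus revival
  `superseded → embargoed` when a superseded act reappears in a corrected
  upload before release. `article_link` is set exactly on release.
- A `public` record refuses conflicting payload updates (corrections after
  publication go through explicit supersession); release is idempotent and
  refuses to run before the stated publication date.
- Persistence is an append-only JSON-lines log (one full record snapshot
  per mutation, schema-versioned header line); a store is rebuilt by
  replay, last snapshot per identifier wins. This keeps the manual
  error-correction trail auditable.
- Fungal propagation: registration against one fungal registry can be
  synchronized to the siblings (`propagate`), carrying the source
  identifier as a cross-reference. Fungal Names has no column in the
  printed registrability table and resolves through the Index Fungorum
  column. Targets out of scope for an act report a per-target rejection and
  are left untouched; repeat propagation updates in place.

## XML dialects

- **Manuscript**: minimal JATS article plus `tp:taxon-treatment` /
  `tp:nomenclature` blocks (schema in `data/taxpub_subset.xsd` +
  `data/taxpub_tp.xsd`); prefix-free treatment elements are accepted on
  input. Dates are ISO-8601 calendar dates only; anything else is a
  structural error, as is a publication date preceding the acceptance date
  or a missing title/byline.
- **Injection** is anchor-based text splicing, not re-serialization: the
  output differs from the input by exactly one inserted element per act, so
  byte-stability outside injection points is testable. The splice point is
  the first-child position of each nomenclature block.
- **Report**: `registration-report` dialect (`data/report.xsd`);
  `serialize_report`/`parse_report` are exact inverses.
- **TCS channel**: the botanical route emits a conservative subset of the
  Taxon Concept Transfer Schema (`data/tcs_subset.xsd`) — one `TaxonName`
  per act with rank, status, canonical name/authorship, basionym pointer
  for combinations and the publication citation. Transport is modelled as a
  function call against a registry store; every emitted document is
  schema-validated. A response record without an identifier maps to an
  explicit missing-marker; a batch-size mismatch is a protocol error.

## Synthetic manuscripts

The generator emulates the shape of real turbo-taxonomy submissions:
default composition 70 % new species, 10 % new genera, 10 % new
combinations, 5 % replacement names, 5 % holotypifications; names are
assembled from a closed syllable alphabet so epithets are pronounceable and
collide only when planted. Plantable features: exact duplicate acts (same
dedup key), tautonyms, author homonyms (as preload spellings differing in
diacritics/initials), and acts invalid for a chosen registry. Generation is
byte-deterministic per spec, and the manifest records per-act ground truth.

It does **not** emulate: realistic descriptive prose, specimen citations,
page/figure structure, non-ISO dates, or malformed publisher XML beyond
what the structural-error tests construct by hand. Passing tests therefore
demonstrate the workflow semantics, not robustness to arbitrary real-world
JATS.

## Problem sizes and numerical choices

The bulk-registration checks run the full pipeline at 277, 178 and 101
new-species acts — the published turbo-taxonomy scales — and complete in
well under a second each. The embargo property suite runs 1,000 randomized
register/query/release schedules; round-trip suites cover 100 generator
seeds with 1–6 acts each. There is no floating-point numerics in the
package; determinism questions reduce to seeded RNG and injected clocks.
Ties in homonym candidate ordering are broken by identifier value.

## Known limitations

- Scope validation covers registrability and the three footnote rules
  only — no Latin-diagnosis, gender-agreement or priority checking.
- The dedup key of an act can change across a reupload if its name or
  status phrase was edited; such an act is treated as new + superseded
  rather than renamed (identifier continuity holds only for key-stable
  edits, and only before release).
- `InsertUserProfile`/`UpdateUserProfile`-style registry author profiles
  are modelled minimally as author records.
- The article identity key is the publisher's article-id (falling back to
  normalized title), so retitling an article *between uploads* without a
  publisher-id creates a new article; retitling at publication is reported
  as a metadata diff.
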