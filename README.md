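# nomenreg

Automated, pre-publication registration of nomenclatural acts.

Biological nomenclature increasingly requires new names to be registered in
an online registry *before* the work describing them is published: MycoBank
/ Index Fungorum / Fungal Names for fungi, ZooBank for animals (mandatory
for electronic-only works), IPNI for vascular plants. For
"turbo-taxonomy" papers describing hundreds of new species in one
manuscript, manual registration is hopeless — the workflow has to be
machine-to-machine. `nomenreg` is a library and CLI for publishers,
journal platforms and registry developers that implements that workflow
end to end, with an embedded registry engine so everything is testable
offline:

1. **Submit on acceptance** — parse the TaxPub/JATS manuscript, classify
   every nomenclatural act (`sp. nov.`, `gen. nov.`, `comb. nov.`,
   `nom. nov.`, typifications, tautonyms, hybrid-flagged names), validate
   it against the per-registry registrability matrix, and upsert article +
   authors + acts into the registry store under embargo.
2. **Report** — one outcome per act: a minted `urn:uuid` identifier, an
   error, or a pending marker when the author name collides with
   registered homonyms.
3. **Inject** — splice the identifiers back into the manuscript XML (one
   `registration-id` element per treatment nomenclature block; everything
   else stays byte-identical).
4. **Release** — on publication day, flip the article's records from
   `embargoed` to `public` with a link to the article, and diff the final
   published metadata against what was registered.

Re-uploading a changed manuscript before release replaces the stored data
under the same identifiers (upsert keyed on a normalized deduplication
key); acts that disappeared are marked superseded. The botanical/fungal
route can additionally exchange batches of name records in a Taxon Concept
Transfer Schema (TCS) subset instead of the whole manuscript, and fungal
records propagate between the three fungal registries.

## Worked example

```python
from datetime import date, datetime, timezone
from nomenreg import *
from nomenreg.fixtures import FixtureSpec, generate_manuscript

xml, manifest = generate_manuscript(FixtureSpec(n_acts=3, seed=1))
ms = parse_manuscript(xml)
for act in ms.acts:
    print(f"{act.descriptor:22s} {act.name.canonical()}  ({act.status_phrase})")

store = RegistryStore(Registry.ZOOBANK,
                      clock=Clock(datetime(2016, 1, 7, tzinfo=timezone.utc)), seed=1)
report = register_manuscript(ms, store)
for o in report.act_outcomes:
    print(o.index, o.status.value, o.identifier.value)

pub = PublicationMetadata(publication_date=date(2016, 1, 7),
                          article_link="https://journals.example.org/article/1",
                          final_meta=ms.article_meta)
final_xml, summary = finalize_publication(xml, ms, report, pub, store)
print(f"released={summary.released} injected={summary.injected} diff={summary.metadata_diff}")
```

prints

```
new_taxon/specific     Batimu rolisu  (sp. nov.)
new_taxon/generic      Tevolu  (gen. nov.)
new_taxon/specific     Ludopa nibiso  (sp. nov.)
0 registered urn:uuid:1e2feb89-414c-443c-9027-c4d1c386bbc4
1 registered urn:uuid:78e51061-7311-48a3-82ce-6f447ed4d57b
2 registered urn:uuid:35bf992d-c9e9-4616-a12e-7696a6cecc1b
released=8 injected=3 diff=[]
```

Three synthetic acts were classified, registered under embargo and given
stable UUID identifiers; on publication day all eight records of the
article (3 acts + 4 authors + the article itself) went public, the three
identifiers were injected into the XML, and the published metadata matched
what was registered (`diff=[]`). The same flow is available from the shell:

```bash
nomenreg fixture --n-acts 4 --seed 3 -o ms.xml --manifest ms.json
nomenreg register ms.xml --registry zoobank --store zoobank.jsonl \
    --clock 2016-01-07T00:00:00 --report-out report.xml
nomenreg finalize ms.xml --report report.xml --registry zoobank \
    --store zoobank.jsonl --date 2016-01-07 --clock 2016-01-07T00:00:00 \
    --link https://journals.example.org/article/1 -o published.xml
nomenreg validate ms.xml --registry ipni     # per-act registrability
nomenreg export-tcs ms.xml --registry ipni   # TCS name-record batch
```

The registry store is an append-only JSON-lines log, so the registration
and correction trail stays auditable; clock and identifier seed are
explicit parameters, making every run reproducible.

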