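"""End-to-end registration pipeline between publisher and registry.

The pipeline mirrors the stepwise publisher-initiated model:

1. on acceptance, the manuscript's article metadata, authors and acts are
   submitted to the registry and stored under embargo;
2. the registry answers with a per-act report — identifier, error message,
   or a pending author-homonym marker;
3. the issued identifiers are injected back into the manuscript XML at the
   treatment level;
4. on publication day all records are released publicly with a link to the
   article, and the final published metadata is validated against what the
   registry stored (discrepancies are reported, not auto-corrected).

A changed manuscript can be uploaded again before release: the new data
replaces the previous data under the same identifiers, new acts are
inserted, and acts that disappeared are marked superseded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

from .acts import Registry, validate_act
from .identifiers import Identifier
from .normalize import normalize_text
from .registry import (
    MatchKind,
    PayloadType,
    PendingDisambiguation,
    RecordState,
    RegistryStore,
)
from .taxpub import (
    ActOutcome,
    ArticleMeta,
    AuthorOutcome,
    Manuscript,
    OutcomeStatus,
    RegistrationReport,
    StructuralError,
    inject_identifiers,
)

__all__ = [
    "PublicationMetadata",
    "ReleaseSummary",
    "WorkflowError",
    "register_manuscript",
    "reupload",
    "finalize_publication",
    "resolve_report_pending",
    "article_dedup_key",
]


class WorkflowError(RuntimeError):
    pass


def article_dedup_key(meta: ArticleMeta) -> str:
    """Stable manuscript identity: the publisher's article id when present,
    otherwise the normalized title (so a title correction at publication
    time is a metadata diff, not a new article)."""
    if meta.publisher_id:
        return f"article:id:{normalize_text(meta.publisher_id)}"
    return f"article:title:{normalize_text(meta.title)}"


@dataclass(frozen=True)
class PublicationMetadata:
    """What the publisher knows on publication day."""

    publication_date: date
    article_link: str
    final_meta: ArticleMeta
    archive_name: Optional[str] = None
    issn_or_isbn: Optional[str] = None


@dataclass
class ReleaseSummary:
    released: int
    injected: int
    metadata_diff: list[str] = field(default_factory=list)


def _check_acceptance_metadata(manuscript: Manuscript) -> None:
    missing = []
    if not manuscript.article_meta.title.strip():
        missing.append("missing article title")
    if not manuscript.contributors:
        missing.append("missing contributors")
    if missing:
        raise StructuralError(missing)


def _register_authors(
    manuscript: Manuscript, store: RegistryStore, article_id: Identifier
) -> tuple[AuthorOutcome, ...]:
    outcomes = []
    seen_keys: dict[str, Identifier] = {}
    for idx, author in enumerate(manuscript.contributors):
        key = author.normalized_key
        if key in seen_keys:
            # same person listed twice in one byline resolves to one record
            outcomes.append(
                AuthorOutcome(idx, OutcomeStatus.REGISTERED, identifier=seen_keys[key])
            )
            continue
        match = store.match_authors(author)
        if match.kind is MatchKind.NO_MATCH:
            record = store.insert_author(author, article_id=article_id)
            outcomes.append(
                AuthorOutcome(idx, OutcomeStatus.REGISTERED, identifier=record.id)
            )
            seen_keys[key] = record.id
        elif match.kind is MatchKind.UNIQUE_MATCH:
            outcomes.append(
                AuthorOutcome(idx, OutcomeStatus.REGISTERED, identifier=match.record.id)
            )
            seen_keys[key] = match.record.id
        else:
            outcomes.append(
                AuthorOutcome(
                    idx,
                    OutcomeStatus.PENDING,
                    message=f"homonymous author name: {author.display()}",
                    pending_ref=key,
                )
            )
    return tuple(outcomes)


def _register_acts(
    manuscript: Manuscript, store: RegistryStore, article_id: Identifier
) -> tuple[ActOutcome, ...]:
    outcomes = []
    for idx, act in enumerate(manuscript.acts):
        verdict = validate_act(act, store.registry)
        if not verdict.accepted:
            outcomes.append(ActOutcome(idx, OutcomeStatus.ERROR, message=verdict.reason))
            continue
        record, action = store.upsert_record(act, act.dedup_key, article_id=article_id)
        outcomes.append(
            ActOutcome(
                idx,
                OutcomeStatus.REGISTERED,
                identifier=record.id,
                message=verdict.reason,  # warning text, if any
                action=action,
            )
        )
    return tuple(outcomes)


def register_manuscript(manuscript: Manuscript, store: RegistryStore) -> RegistrationReport:
    """Step 1 + 2a: submit a manuscript on acceptance, get the report back.

    The article, its authors and every act that passes scope validation are
    upserted under embargo. An act outside the registry's scope yields an
    error outcome (never a silent drop); an author name colliding with two
    or more registered homonyms yields a pending outcome that blocks
    identifier injection until an operator resolves it. A manuscript with
    no acceptance-stage metadata is rejected whole — nothing is stored.
    """
    _check_acceptance_metadata(manuscript)
    article_record, _ = store.upsert_record(
        manuscript.article_meta, article_dedup_key(manuscript.article_meta)
    )
    return RegistrationReport(
        article_id=article_record.id,
        act_outcomes=_register_acts(manuscript, store, article_record.id),
        author_outcomes=_register_authors(manuscript, store, article_record.id),
    )


def reupload(manuscript: Manuscript, store: RegistryStore) -> RegistrationReport:
    """Re-submit a changed manuscript before publication.

    Acts keep their identifiers through the dedup key; new acts are
    inserted; acts no longer present in the upload are marked superseded.
    Reupload after release is a conflict — published records are not
    rewritten.
    """
    _check_acceptance_metadata(manuscript)
    key = article_dedup_key(manuscript.article_meta)
    existing = store.search_records({"payload_type": PayloadType.ARTICLE.value, "dedup_key": key})
    if not existing:
        raise WorkflowError("reupload of an article that was never registered")
    article_record = existing[0]
    if article_record.state is RecordState.PUBLIC:
        raise WorkflowError("article already released; records cannot be replaced")

    previous = {
        r.dedup_key: r
        for r in store.records_of_article(article_record.id)
        if r.payload_type is PayloadType.ACT and r.state is not RecordState.SUPERSEDED
    }
    report = RegistrationReport(
        article_id=article_record.id,
        act_outcomes=_register_acts(manuscript, store, article_record.id),
        author_outcomes=_register_authors(manuscript, store, article_record.id),
    )
    current_keys = {a.dedup_key for a in manuscript.acts}
    for dedup_key, record in previous.items():
        if dedup_key not in current_keys:
            store.supersede(record.id)
    # article metadata itself may have changed too
    store.upsert_record(manuscript.article_meta, key)
    return report


def finalize_publication(
    xml_document: str,
    manuscript: Manuscript,
    report: RegistrationReport,
    publication: PublicationMetadata,
    store: RegistryStore,
) -> tuple[str, ReleaseSummary]:
    """Steps 3 + 4: inject identifiers, release the records, validate the
    final metadata.

    Requires a clean report (no pending, no error outcomes). On the
    zoological e-only route the registration must state the preserving
    electronic archive and the ISSN/ISBN of the work; finalization refuses
    to proceed without them. The final published metadata is diffed against
    what the registry stored at acceptance; discrepancies are reported
    field-by-field, never auto-corrected.
    """
    if report.has_pending:
        raise WorkflowError(
            "report has pending author disambiguations; resolve them before injection"
        )
    if report.has_errors:
        raise WorkflowError("report has error outcomes; correct the manuscript first")
    if report.article_id is None:
        raise WorkflowError("report carries no article identifier")

    final = publication.final_meta
    if store.registry is Registry.ZOOBANK:
        archive = publication.archive_name or final.archive_name
        issn = publication.issn_or_isbn or final.issn_or_isbn
        lacking = []
        if not archive:
            lacking.append("name of the preserving electronic archive")
        if not issn:
            lacking.append("ISSN or ISBN associated with the work")
        if lacking:
            raise WorkflowError(
                "electronic publication requires the registration to state the "
                + " and the ".join(lacking)
            )

    assignments = report.identifier_assignments()
    injected_xml = inject_identifiers(manuscript, assignments, xml_document)

    released = store.release_records(
        report.article_id, publication.publication_date, publication.article_link
    )

    stored_meta = store.get(report.article_id).payload
    diff = [
        fieldname
        for fieldname in ("title", "journal", "issn_or_isbn", "archive_name", "doi")
        if getattr(stored_meta, fieldname) != getattr(final, fieldname)
    ]
    return injected_xml, ReleaseSummary(
        released=released, injected=len(assignments), metadata_diff=diff
    )


def resolve_report_pending(
    report: RegistrationReport,
    manuscript: Manuscript,
    store: RegistryStore,
    choices: dict[int, object],
) -> RegistrationReport:
    """Apply operator choices to pending author outcomes.

    ``choices`` maps author index to a candidate :class:`Identifier` or the
    :data:`nomenreg.registry.NEW_AUTHOR` sentinel. Returns a report with
    those outcomes turned into registered ones.
    """
    new_outcomes = []
    for outcome in report.author_outcomes:
        if outcome.status is not OutcomeStatus.PENDING:
            new_outcomes.append(outcome)
            continue
        if outcome.index not in choices:
            new_outcomes.append(outcome)
            continue
        submitted = manuscript.contributors[outcome.index]
        hits = store.search_records(
            {"payload_type": PayloadType.AUTHOR.value, "normalized_key": submitted.normalized_key}
        )
        hits.sort(key=lambda r: r.id.value)
        pending = PendingDisambiguation(submitted=submitted, candidates=tuple(hits))
        record = store.resolve_disambiguation(pending, choices[outcome.index])
        new_outcomes.append(
            AuthorOutcome(outcome.index, OutcomeStatus.REGISTERED, identifier=record.id)
        )
    return RegistrationReport(
        article_id=report.article_id,
        act_outcomes=report.act_outcomes,
        author_outcomes=tuple(new_outcomes),
    )
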