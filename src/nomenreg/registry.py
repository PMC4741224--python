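"""The embedded registry engine.

Models what a nomenclatural registry does between manuscript acceptance and
publication: mint stable identifiers, deduplicate incoming acts and authors
(upsert semantics: update if exists, insert otherwise), queue author
homonyms for operator disambiguation, keep records embargoed until the
publication day, then release them with a link to the article, and
propagate fungal records across the sibling fungal registries.

Determinism is a design constraint, not an afterthought: the store's clock
and its UUID source are both injectable, so an entire registration run is a
pure function of (inputs, seed, clock).
"""

from __future__ import annotations

import enum
import json
import random
import uuid
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Optional, Union

from .acts import NomenclaturalAct, Registry, validate_act
from .identifiers import Identifier
from .taxpub import ArticleMeta, AuthorName

__all__ = [
    "RecordState",
    "PayloadType",
    "RegistryRecord",
    "PendingDisambiguation",
    "MatchKind",
    "AuthorMatch",
    "Clock",
    "RegistryStore",
    "NEW_AUTHOR",
    "QueryError",
    "ConflictError",
    "EmbargoViolationError",
    "NotFoundError",
    "InvalidChoiceError",
    "propagate",
]

STORE_SCHEMA_VERSION = 1


class RecordState(str, enum.Enum):
    EMBARGOED = "embargoed"
    PUBLIC = "public"
    SUPERSEDED = "superseded"


class PayloadType(str, enum.Enum):
    ACT = "act"
    AUTHOR = "author"
    ARTICLE = "article"


Payload = Union[NomenclaturalAct, AuthorName, ArticleMeta]


class QueryError(ValueError):
    pass


class ConflictError(RuntimeError):
    """A public record cannot be silently updated; supersede it instead."""


class EmbargoViolationError(RuntimeError):
    pass


class NotFoundError(KeyError):
    pass


class InvalidChoiceError(ValueError):
    pass


#: Sentinel choice for :meth:`RegistryStore.resolve_disambiguation`: mint a
#: fresh author record instead of linking an existing candidate.
NEW_AUTHOR = object()


@dataclass
class RegistryRecord:
    id: Identifier
    payload: Payload
    payload_type: PayloadType
    dedup_key: str
    state: RecordState
    created_at: datetime
    updated_at: datetime
    article_id: Optional[Identifier] = None
    article_link: Optional[str] = None
    xrefs: dict[str, str] = field(default_factory=dict)  # source registry -> identifier


@dataclass(frozen=True)
class PendingDisambiguation:
    """An author name that matched two or more registered authors; an
    operator must pick the right one (or declare a new person)."""

    submitted: AuthorName
    candidates: tuple[RegistryRecord, ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("a pending disambiguation needs at least one candidate")


class MatchKind(str, enum.Enum):
    NO_MATCH = "no_match"
    UNIQUE_MATCH = "unique_match"
    HOMONYMS = "homonyms"


@dataclass(frozen=True)
class AuthorMatch:
    kind: MatchKind
    record: Optional[RegistryRecord] = None
    pending: Optional[PendingDisambiguation] = None


class Clock:
    """Injectable registry clock so embargo behaviour is deterministic."""

    def __init__(self, start: datetime | None = None):
        self._now = start or datetime(2016, 1, 1, tzinfo=timezone.utc)

    def now(self) -> datetime:
        return self._now

    def today(self) -> date:
        return self._now.date()

    def set(self, when: datetime) -> None:
        self._now = when

    def advance(self, **kwargs) -> None:
        self._now += timedelta(**kwargs)


def _payload_type(payload: Payload) -> PayloadType:
    if isinstance(payload, NomenclaturalAct):
        return PayloadType.ACT
    if isinstance(payload, AuthorName):
        return PayloadType.AUTHOR
    if isinstance(payload, ArticleMeta):
        return PayloadType.ARTICLE
    raise TypeError(f"unsupported payload type: {type(payload).__name__}")


_FILTER_FIELDS = frozenset(
    {"payload_type", "state", "dedup_key", "article_id", "name", "normalized_key", "kind"}
)


def _field_value(record: RegistryRecord, fieldname: str) -> object:
    if fieldname == "payload_type":
        return record.payload_type.value
    if fieldname == "state":
        return record.state.value
    if fieldname == "dedup_key":
        return record.dedup_key
    if fieldname == "article_id":
        return record.article_id.value if record.article_id else None
    if fieldname == "name":
        p = record.payload
        if isinstance(p, NomenclaturalAct):
            return p.name.canonical()
        if isinstance(p, AuthorName):
            return p.display()
        return p.title
    if fieldname == "normalized_key":
        p = record.payload
        return p.normalized_key if isinstance(p, AuthorName) else None
    if fieldname == "kind":
        p = record.payload
        return p.kind.value if isinstance(p, NomenclaturalAct) else None
    raise QueryError(f"unknown filter field: {fieldname}")


class RegistryStore:
    """One registry's record store.

    ``path``, when given, points at an append-only JSON-lines log: every
    mutation appends a full record snapshot, and a store can be rebuilt by
    replaying the log (last snapshot per identifier wins). This keeps the
    manual-correction trail auditable.
    """

    def __init__(
        self,
        registry: Registry,
        clock: Clock | None = None,
        seed: int = 0,
        path: str | Path | None = None,
    ):
        self.registry = registry
        self.clock = clock or Clock()
        self._rng = random.Random(seed)
        self._records: dict[str, RegistryRecord] = {}  # by identifier value
        self._by_dedup: dict[str, str] = {}  # dedup_key -> identifier value
        self._issued: set[str] = set()
        self.path = Path(path) if path else None
        if self.path and self.path.exists():
            self._replay_log()

    # -- identifier minting -------------------------------------------------

    def mint_identifier(self) -> Identifier:
        """A fresh urn:uuid identifier, never previously issued here."""
        while True:
            value = uuid.UUID(int=self._rng.getrandbits(128), version=4).urn
            if value not in self._issued:
                self._issued.add(value)
                return Identifier(value)

    # -- persistence --------------------------------------------------------

    def _append_log(self, record: RegistryRecord) -> None:
        if not self.path:
            return
        new_file = not self.path.exists()
        with self.path.open("a", encoding="utf-8") as fh:
            if new_file:
                fh.write(
                    json.dumps(
                        {"schema": STORE_SCHEMA_VERSION, "registry": self.registry.value}
                    )
                    + "\n"
                )
            fh.write(json.dumps(_record_to_json(record), sort_keys=True) + "\n")

    def _replay_log(self) -> None:
        with self.path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                if i == 0 and "schema" in obj:
                    continue
                record = _record_from_json(obj)
                self._records[record.id.value] = record
                self._by_dedup[record.dedup_key] = record.id.value
                self._issued.add(record.id.value)

    # -- queries ------------------------------------------------------------

    def search_records(
        self, filters: dict[str, object], context: str = "publisher"
    ) -> list[RegistryRecord]:
        """All and only records matching every filter.

        ``context="public"`` sees only released (public) records — embargoed
        and superseded ones are invisible to the outside world. The owning
        publisher context sees everything.
        """
        unknown = set(filters) - _FILTER_FIELDS
        if unknown:
            raise QueryError(f"unknown filter fields: {sorted(unknown)}")
        out = []
        for record in self._records.values():
            if context == "public" and record.state is not RecordState.PUBLIC:
                continue
            if all(_field_value(record, k) == v for k, v in filters.items()):
                out.append(record)
        return out

    def get(self, identifier: Identifier) -> RegistryRecord:
        try:
            return self._records[identifier.value]
        except KeyError:
            raise NotFoundError(identifier.value) from None

    def __len__(self) -> int:
        return len(self._records)

    # -- upsert -------------------------------------------------------------

    def upsert_record(
        self,
        payload: Payload,
        dedup_key: str,
        article_id: Optional[Identifier] = None,
        xrefs: Optional[dict[str, str]] = None,
    ) -> tuple[RegistryRecord, str]:
        """Update-if-exists, insert-otherwise, keyed on ``dedup_key``.

        The identifier never changes across updates of the same record. A
        superseded record hit by a fresh upsert is revived to embargoed
        (the act reappeared in a corrected upload). A public record with a
        conflicting payload raises :class:`ConflictError` — published
        records are corrected by supersession, never silently rewritten.
        """
        now = self.clock.now()
        existing_id = self._by_dedup.get(dedup_key)
        if existing_id is not None:
            record = self._records[existing_id]
            if record.state is RecordState.PUBLIC and record.payload != payload:
                raise ConflictError(
                    f"record {record.id} is public; conflicting update refused"
                )
            record.payload = payload
            if record.state is RecordState.SUPERSEDED:
                record.state = RecordState.EMBARGOED
            if article_id is not None:
                record.article_id = article_id
            if xrefs:
                record.xrefs.update(xrefs)
            record.updated_at = now
            self._append_log(record)
            return record, "updated"

        record = RegistryRecord(
            id=self.mint_identifier(),
            payload=payload,
            payload_type=_payload_type(payload),
            dedup_key=dedup_key,
            state=RecordState.EMBARGOED,
            created_at=now,
            updated_at=now,
            article_id=article_id,
            xrefs=dict(xrefs or {}),
        )
        self._records[record.id.value] = record
        self._by_dedup[dedup_key] = record.id.value
        self._append_log(record)
        return record, "inserted"

    def supersede(self, identifier: Identifier) -> RegistryRecord:
        record = self.get(identifier)
        record.state = RecordState.SUPERSEDED
        record.updated_at = self.clock.now()
        self._append_log(record)
        return record

    # -- author matching ----------------------------------------------------

    def match_authors(self, author: AuthorName) -> AuthorMatch:
        """Match an incoming author against registered authors by
        normalized key: none, exactly one, or a homonym queue entry."""
        if not author.surname.strip():
            raise ValueError("author surname must be non-empty")
        key = author.normalized_key
        hits = self.search_records(
            {"payload_type": PayloadType.AUTHOR.value, "normalized_key": key}
        )
        hits = [h for h in hits if h.state is not RecordState.SUPERSEDED]
        if not hits:
            return AuthorMatch(MatchKind.NO_MATCH)
        if len(hits) == 1:
            return AuthorMatch(MatchKind.UNIQUE_MATCH, record=hits[0])
        hits.sort(key=lambda r: r.id.value)
        return AuthorMatch(
            MatchKind.HOMONYMS,
            pending=PendingDisambiguation(submitted=author, candidates=tuple(hits)),
        )

    def insert_author(
        self, author: AuthorName, article_id: Optional[Identifier] = None
    ) -> RegistryRecord:
        """Register a new author record. The dedup key is made unique per
        person: homonymous people are distinct records sharing a
        normalized key, so the store key carries the identifier."""
        now = self.clock.now()
        record = RegistryRecord(
            id=self.mint_identifier(),
            payload=author,
            payload_type=PayloadType.AUTHOR,
            dedup_key="",
            state=RecordState.EMBARGOED,
            created_at=now,
            updated_at=now,
            article_id=article_id,
        )
        record.dedup_key = f"author:{author.normalized_key}:{record.id.value}"
        self._records[record.id.value] = record
        self._by_dedup[record.dedup_key] = record.id.value
        self._append_log(record)
        return record

    def resolve_disambiguation(
        self, pending: PendingDisambiguation, choice
    ) -> RegistryRecord:
        """Apply the operator's choice: an existing candidate's identifier,
        or :data:`NEW_AUTHOR` to mint a fresh record with the same
        normalized key."""
        if choice is NEW_AUTHOR:
            return self.insert_author(pending.submitted)
        if not isinstance(choice, Identifier):
            raise InvalidChoiceError(f"choice must be an Identifier or NEW_AUTHOR")
        for candidate in pending.candidates:
            if candidate.id == choice:
                return candidate
        raise InvalidChoiceError(f"{choice} is not among the homonym candidates")

    # -- release ------------------------------------------------------------

    def records_of_article(self, article_id: Identifier) -> list[RegistryRecord]:
        out = []
        for record in self._records.values():
            if record.id == article_id or (
                record.article_id is not None and record.article_id == article_id
            ):
                out.append(record)
        return out

    def release_records(
        self, article_id: Identifier, publication_date: date, article_link: str
    ) -> int:
        """Make every embargoed record of an article public with the
        article link set; returns how many records changed state.
        Idempotent: a second call releases nothing more. Release before the
        publication date is an embargo violation and changes nothing."""
        records = self.records_of_article(article_id)
        if not records:
            raise NotFoundError(f"no records for article {article_id}")
        if self.clock.today() < publication_date:
            raise EmbargoViolationError(
                f"publication date {publication_date} is after registry date "
                f"{self.clock.today()}; release refused"
            )
        released = 0
        for record in records:
            if record.state is RecordState.EMBARGOED:
                record.state = RecordState.PUBLIC
                record.article_link = article_link
                record.updated_at = self.clock.now()
                self._append_log(record)
                released += 1
        return released


# ---------------------------------------------------------------------------
# cross-registry propagation (fungal registries)

def propagate(
    record: RegistryRecord,
    source: RegistryStore,
    targets: Iterable[RegistryStore],
) -> dict[Registry, tuple[str, str]]:
    """Propagate a fungal act record to sibling registries.

    Registration can be performed against a single fungal registry, with
    synchronization carrying the record to the others. Each target ends up
    with exactly one equivalent record under the same dedup key, holding
    the source identifier as a cross-reference; a target whose scope does
    not cover the act reports a rejection and is left untouched. Repeat
    propagation updates rather than duplicates.

    Returns per-target ``(action, detail)``: ``("inserted"|"updated", id)``
    or ``("rejected", reason)``.
    """
    if source.get(record.id) is not record:
        raise NotFoundError(f"record {record.id} is not held by the source store")
    if not isinstance(record.payload, NomenclaturalAct):
        raise TypeError("only act records propagate between registries")

    results: dict[Registry, tuple[str, str]] = {}
    for target in targets:
        verdict = validate_act(record.payload, target.registry)
        if not verdict.accepted:
            results[target.registry] = ("rejected", verdict.reason)
            continue
        twin, action = target.upsert_record(
            record.payload,
            record.dedup_key,
            article_id=None,
            xrefs={source.registry.value: record.id.value},
        )
        results[target.registry] = (action, twin.id.value)
    return results


# ---------------------------------------------------------------------------
# JSON-lines (de)serialization

def _payload_to_json(payload: Payload) -> dict:
    if isinstance(payload, NomenclaturalAct):
        return {
            "type": "act",
            "kind": payload.kind.value,
            "rank": payload.rank.value if payload.rank else None,
            "type_kind": payload.type_kind.value if payload.type_kind else None,
            "code": payload.code.value,
            "is_hybrid": payload.is_hybrid,
            "status_phrase": payload.status_phrase,
            "name": {
                "uninomial": payload.name.uninomial,
                "genus": payload.name.genus,
                "species": payload.name.species,
                "infraspecific": payload.name.infraspecific,
                "authorship": payload.name.authorship,
                "basionym_authorship": payload.name.basionym_authorship,
            },
        }
    if isinstance(payload, AuthorName):
        return {
            "type": "author",
            "surname": payload.surname,
            "given_names": payload.given_names,
            "registry_id": payload.registry_id.value if payload.registry_id else None,
        }
    return {
        "type": "article",
        "title": payload.title,
        "journal": payload.journal,
        "issn_or_isbn": payload.issn_or_isbn,
        "archive_name": payload.archive_name,
        "doi": payload.doi,
        "publisher_id": payload.publisher_id,
        "publication_date": payload.publication_date.isoformat()
        if payload.publication_date
        else None,
        "acceptance_date": payload.acceptance_date.isoformat()
        if payload.acceptance_date
        else None,
    }


def _payload_from_json(obj: dict) -> Payload:
    from .acts import ActKind, Code, Rank, ScientificName, TypeKind

    t = obj["type"]
    if t == "act":
        return NomenclaturalAct(
            kind=ActKind(obj["kind"]),
            rank=Rank(obj["rank"]) if obj["rank"] else None,
            type_kind=TypeKind(obj["type_kind"]) if obj["type_kind"] else None,
            code=Code(obj["code"]),
            is_hybrid=obj["is_hybrid"],
            status_phrase=obj["status_phrase"],
            name=ScientificName(**obj["name"]),
        )
    if t == "author":
        return AuthorName(
            surname=obj["surname"],
            given_names=obj["given_names"],
            registry_id=Identifier(obj["registry_id"]) if obj["registry_id"] else None,
        )
    return ArticleMeta(
        title=obj["title"],
        journal=obj["journal"],
        issn_or_isbn=obj["issn_or_isbn"],
        archive_name=obj["archive_name"],
        doi=obj["doi"],
        publisher_id=obj["publisher_id"],
        publication_date=date.fromisoformat(obj["publication_date"])
        if obj["publication_date"]
        else None,
        acceptance_date=date.fromisoformat(obj["acceptance_date"])
        if obj["acceptance_date"]
        else None,
    )


def _record_to_json(record: RegistryRecord) -> dict:
    return {
        "id": record.id.value,
        "payload": _payload_to_json(record.payload),
        "payload_type": record.payload_type.value,
        "dedup_key": record.dedup_key,
        "state": record.state.value,
        "created_at": record.created_at.isoformat(),
        "updated_at": record.updated_at.isoformat(),
        "article_id": record.article_id.value if record.article_id else None,
        "article_link": record.article_link,
        "xrefs": record.xrefs,
    }


def _record_from_json(obj: dict) -> RegistryRecord:
    return RegistryRecord(
        id=Identifier(obj["id"]),
        payload=_payload_from_json(obj["payload"]),
        payload_type=PayloadType(obj["payload_type"]),
        dedup_key=obj["dedup_key"],
        state=RecordState(obj["state"]),
        created_at=datetime.fromisoformat(obj["created_at"]),
        updated_at=datetime.fromisoformat(obj["updated_at"]),
        article_id=Identifier(obj["article_id"]) if obj["article_id"] else None,
        article_link=obj["article_link"],
        xrefs=dict(obj["xrefs"]),
    )
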