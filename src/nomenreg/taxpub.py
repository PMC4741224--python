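"""Reading and writing the TaxPub/JATS manuscript dialect.

The manuscript format is a minimal JATS article carrying taxonomic
treatments as ``tp:taxon-treatment`` elements, each holding one or more
``tp:nomenclature`` blocks (one block per nomenclatural act). Both the
namespaced (``tp:``-prefixed) and prefix-free spellings of the treatment
elements are accepted on input.

Identifier injection is anchor-based: the returned XML is the input text
with one ``registration-id`` element spliced in as the first child of each
nomenclature block, and is byte-identical to the input everywhere else.
Whitespace and attribute order are never touched, which makes the
byte-stability of everything outside the injection points a testable
invariant rather than a hope.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional, Sequence

from lxml import etree

from .acts import Code, NomenclaturalAct, classify_act
from .identifiers import Identifier
from .normalize import author_key

__all__ = [
    "TP_NS",
    "ArticleMeta",
    "AuthorName",
    "Treatment",
    "Manuscript",
    "OutcomeStatus",
    "ActOutcome",
    "AuthorOutcome",
    "RegistrationReport",
    "ParseError",
    "StructuralError",
    "IncompleteAssignmentError",
    "parse_manuscript",
    "inject_identifiers",
    "serialize_report",
    "parse_report",
]

TP_NS = "http://www.plazi.org/taxpub"


class ParseError(ValueError):
    """Malformed XML; message carries lxml's line/column diagnostics."""


class StructuralError(ValueError):
    """Well-formed XML missing required structure (title, contributors, dates)."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__("structural validation failed: " + "; ".join(self.missing))


class IncompleteAssignmentError(ValueError):
    def __init__(self, uncovered: Sequence[int]):
        self.uncovered = list(uncovered)
        super().__init__(
            f"no identifier assigned for act indices {sorted(self.uncovered)}"
        )


@dataclass(frozen=True)
class ArticleMeta:
    title: str = ""
    journal: str = ""
    issn_or_isbn: Optional[str] = None
    archive_name: Optional[str] = None
    doi: Optional[str] = None
    publisher_id: Optional[str] = None
    publication_date: Optional[date] = None
    acceptance_date: Optional[date] = None


@dataclass(frozen=True)
class AuthorName:
    surname: str
    given_names: str = ""
    registry_id: Optional[Identifier] = None

    @property
    def normalized_key(self) -> str:
        return author_key(self.surname, self.given_names)

    def display(self) -> str:
        return f"{self.surname}, {self.given_names}".rstrip(", ")


@dataclass
class Treatment:
    acts: list[NomenclaturalAct] = field(default_factory=list)
    injected_ids: list[Identifier] = field(default_factory=list)


@dataclass
class Manuscript:
    article_meta: ArticleMeta
    contributors: list[AuthorName]
    treatments: list[Treatment]
    code: Code = Code.ICZN
    #: (start, end) spans of each nomenclature open tag in the source text,
    #: in document order — one anchor per act.
    source_anchors: list[tuple[int, int]] = field(default_factory=list)

    @property
    def acts(self) -> list[NomenclaturalAct]:
        return [a for t in self.treatments for a in t.acts]

    @property
    def injected_identifiers(self) -> list[Identifier]:
        return [i for t in self.treatments for i in t.injected_ids]


# ---------------------------------------------------------------------------
# parsing

def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _children(el: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in el if isinstance(c.tag, str) and _localname(c) == name]

def _descendants(el: etree._Element, name: str) -> list[etree._Element]:
    return [d for d in el.iter() if isinstance(d.tag, str) and _localname(d) == name]


def _first_text(el: etree._Element, name: str) -> str:
    found = _descendants(el, name)
    return (found[0].text or "").strip() if found else ""


def _parse_iso_date(raw: str, what: str) -> date:
    try:
        return date.fromisoformat(raw)
    except ValueError:
        raise StructuralError([f"{what} is not an ISO-8601 calendar date: {raw!r}"]) from None


# one anchor per nomenclature block open tag; self-closing blocks excluded
_NOMENCLATURE_TAG = re.compile(r"<(tp:)?nomenclature(?=[\s>])[^>]*[^/>]>|<(tp:)?nomenclature>")


def _nomenclature_anchors(xml_document: str) -> list[tuple[int, int, str]]:
    anchors = []
    for m in _NOMENCLATURE_TAG.finditer(xml_document):
        prefix = "tp:" if m.group(0).startswith("<tp:") else ""
        anchors.append((m.start(), m.end(), prefix))
    return anchors


def _extract_meta(root: etree._Element) -> tuple[ArticleMeta, Code, list[str]]:
    missing: list[str] = []
    title = _first_text(root, "article-title")
    if not title:
        missing.append("missing article-title")
    journal = _first_text(root, "journal-title")
    issn = _first_text(root, "issn") or None

    doi = publisher_id = None
    for aid in _descendants(root, "article-id"):
        kind = aid.get("pub-id-type", "")
        if kind == "doi":
            doi = (aid.text or "").strip() or None
        elif kind == "publisher-id":
            publisher_id = (aid.text or "").strip() or None

    pub_date = acc_date = None
    for pd in _descendants(root, "pub-date"):
        raw = pd.get("iso-8601-date", "").strip()
        if not raw:
            continue
        parsed = _parse_iso_date(raw, f"pub-date[{pd.get('date-type')}]")
        if pd.get("date-type") == "accepted":
            acc_date = parsed
        elif pd.get("date-type") in ("pub", "epub", None):
            pub_date = parsed

    archive = None
    code = Code.ICZN
    for cm in _descendants(root, "custom-meta"):
        name = _first_text(cm, "meta-name")
        value = _first_text(cm, "meta-value")
        if name == "archive-name":
            archive = value or None
        elif name == "nomenclatural-code":
            try:
                code = Code(value)
            except ValueError:
                missing.append(f"unknown nomenclatural-code: {value!r}")

    if pub_date and acc_date and pub_date < acc_date:
        missing.append(
            f"publication date {pub_date} precedes acceptance date {acc_date}"
        )

    meta = ArticleMeta(
        title=title,
        journal=journal,
        issn_or_isbn=issn,
        archive_name=archive,
        doi=doi,
        publisher_id=publisher_id,
        publication_date=pub_date,
        acceptance_date=acc_date,
    )
    return meta, code, missing


_BASIONYM_AUTH = re.compile(r"^\((?P<basionym>[^)]+)\)\s*(?P<rest>.*)$")


def _fragment_from_block(block: etree._Element, code: Code) -> dict[str, object]:
    frag: dict[str, object] = {"code": code}
    names = _children(block, "taxon-name")
    if names:
        name_el = names[0]
        frag["hybrid"] = name_el.get("hybrid", "") in ("yes", "true")
        for part in _descendants(name_el, "taxon-name-part"):
            part_type = part.get("taxon-name-part-type", "")
            if part_type in ("uninomial", "genus", "species", "infraspecific"):
                frag[part_type] = (part.text or "").strip()
    authority = _first_text(block, "taxon-authority")
    m = _BASIONYM_AUTH.match(authority)
    if m:
        frag["basionym_authorship"] = m.group("basionym").strip()
        frag["authorship"] = m.group("rest").strip()
    else:
        frag["authorship"] = authority
    frag["status"] = _first_text(block, "taxon-status")
    return frag


def parse_manuscript(xml_document: str) -> Manuscript:
    """Parse a TaxPub manuscript into a :class:`Manuscript`.

    Treatments and their acts come out in document order. Raises
    :class:`ParseError` on malformed XML (naming line/column) and
    :class:`StructuralError` listing every missing required element.
    """
    try:
        root = etree.fromstring(xml_document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc

    meta, code, missing = _extract_meta(root)
    contributors = []
    for contrib in _descendants(root, "contrib"):
        surname = _first_text(contrib, "surname")
        given = _first_text(contrib, "given-names")
        if surname:
            contributors.append(AuthorName(surname=surname, given_names=given))
    if not contributors:
        missing.append("missing contributors (at least one contrib with a surname)")
    if missing:
        raise StructuralError(missing)

    treatments: list[Treatment] = []
    for t_el in _descendants(root, "taxon-treatment"):
        treatment = Treatment()
        for block in _descendants(t_el, "nomenclature"):
            frag = _fragment_from_block(block, code)
            treatment.acts.append(classify_act(frag))
            for rid in _children(block, "registration-id"):
                treatment.injected_ids.append(Identifier((rid.text or "").strip()))
        treatments.append(treatment)

    anchors = [(s, e) for s, e, _ in _nomenclature_anchors(xml_document)]
    return Manuscript(
        article_meta=meta,
        contributors=contributors,
        treatments=treatments,
        code=code,
        source_anchors=anchors,
    )


# ---------------------------------------------------------------------------
# injection

def inject_identifiers(
    manuscript: Manuscript,
    assignments: Mapping[int, Identifier],
    xml_document: str,
) -> str:
    """Splice one ``registration-id`` element into each nomenclature block.

    ``assignments`` maps global act index (document order) to identifier and
    must cover every act. The output differs from the input only by the
    inserted elements; everything else is byte-identical.
    """
    n_acts = len(manuscript.acts)
    uncovered = [i for i in range(n_acts) if i not in assignments]
    if uncovered:
        raise IncompleteAssignmentError(uncovered)
    if n_acts == 0:
        return xml_document

    anchors = _nomenclature_anchors(xml_document)
    if len(anchors) != n_acts:
        raise ParseError(
            f"found {len(anchors)} nomenclature blocks in source but "
            f"manuscript has {n_acts} acts"
        )

    out = xml_document
    for idx in range(n_acts - 1, -1, -1):  # splice back-to-front, offsets stay valid
        _, end, prefix = anchors[idx]
        element = (
            f"<{prefix}registration-id>{assignments[idx].value}</{prefix}registration-id>"
        )
        out = out[:end] + element + out[end:]
    return out


# ---------------------------------------------------------------------------
# registration report (the Step 2a response document)

class OutcomeStatus(str, enum.Enum):
    REGISTERED = "registered"
    ERROR = "error"
    PENDING = "pending"


@dataclass(frozen=True)
class ActOutcome:
    index: int
    status: OutcomeStatus
    identifier: Optional[Identifier] = None
    message: str = ""
    pending_ref: Optional[str] = None
    action: Optional[str] = None  # inserted | updated, when registered


@dataclass(frozen=True)
class AuthorOutcome:
    index: int
    status: OutcomeStatus
    identifier: Optional[Identifier] = None
    message: str = ""
    pending_ref: Optional[str] = None


@dataclass(frozen=True)
class RegistrationReport:
    """Per-act / per-author outcomes for one submitted manuscript: each act
    gets exactly one outcome — an identifier, an error message, or a
    pending-disambiguation marker — in act order."""

    article_id: Optional[Identifier]
    act_outcomes: tuple[ActOutcome, ...] = ()
    author_outcomes: tuple[AuthorOutcome, ...] = ()

    @property
    def has_pending(self) -> bool:
        return any(
            o.status is OutcomeStatus.PENDING
            for o in (*self.act_outcomes, *self.author_outcomes)
        )

    @property
    def has_errors(self) -> bool:
        return any(
            o.status is OutcomeStatus.ERROR
            for o in (*self.act_outcomes, *self.author_outcomes)
        )

    def identifier_assignments(self) -> dict[int, Identifier]:
        """Map of act index -> identifier for registered acts."""
        return {
            o.index: o.identifier
            for o in self.act_outcomes
            if o.status is OutcomeStatus.REGISTERED and o.identifier is not None
        }


def _outcome_to_xml(parent: etree._Element, tag: str, outcome) -> None:
    el = etree.SubElement(parent, tag, index=str(outcome.index), status=outcome.status.value)
    if getattr(outcome, "action", None):
        el.set("action", outcome.action)
    if outcome.identifier is not None:
        etree.SubElement(el, "identifier").text = outcome.identifier.value
    if outcome.message:
        etree.SubElement(el, "message").text = outcome.message
    if outcome.pending_ref:
        etree.SubElement(el, "pending-ref").text = outcome.pending_ref


def serialize_report(report: RegistrationReport) -> str:
    """Serialize a report to the response XML; :func:`parse_report` is its
    exact inverse."""
    root = etree.Element("registration-report")
    if report.article_id is not None:
        root.set("article-id", report.article_id.value)
    acts = etree.SubElement(root, "acts")
    for o in report.act_outcomes:
        _outcome_to_xml(acts, "act", o)
    authors = etree.SubElement(root, "authors")
    for o in report.author_outcomes:
        _outcome_to_xml(authors, "author", o)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _outcome_from_xml(el: etree._Element, cls):
    ident = _first_text(el, "identifier")
    kwargs = dict(
        index=int(el.get("index")),
        status=OutcomeStatus(el.get("status")),
        identifier=Identifier(ident) if ident else None,
        message=_first_text(el, "message"),
        pending_ref=_first_text(el, "pending-ref") or None,
    )
    if cls is ActOutcome:
        kwargs["action"] = el.get("action")
    return cls(**kwargs)


def parse_report(xml_document: str) -> RegistrationReport:
    try:
        root = etree.fromstring(xml_document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    if _localname(root) != "registration-report":
        raise ParseError(f"not a registration report: root is <{root.tag}>")
    article_raw = root.get("article-id")
    acts = []
    authors = []
    for section in root:
        if _localname(section) == "acts":
            acts = [_outcome_from_xml(el, ActOutcome) for el in _children(section, "act")]
        elif _localname(section) == "authors":
            authors = [
                _outcome_from_xml(el, AuthorOutcome) for el in _children(section, "author")
            ]
    return RegistrationReport(
        article_id=Identifier(article_raw) if article_raw else None,
        act_outcomes=tuple(acts),
        author_outcomes=tuple(authors),
    )
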