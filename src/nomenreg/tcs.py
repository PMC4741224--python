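"""TCS name-record channel for the botanical/fungal registries.

Zoological registration travels as the whole manuscript (TaxPub); the
botanical route instead submits a batch of name records encoded in a
conservative subset of the Taxon Concept Transfer Schema (TCS) and gets the
same document back with registry identifiers inserted. Transport is
modelled as a function call against a :class:`~nomenreg.registry.RegistryStore`
(the POST request is out of scope); request/response documents are plain
UTF-8 XML that validates against the in-repo schema.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence, Union

from lxml import etree

from .acts import (
    ActKind,
    Code,
    NomenclaturalAct,
    Registry,
    classify_act,
    validate_act,
)
from .identifiers import Identifier
from .registry import RegistryStore
from .taxpub import ArticleMeta

__all__ = [
    "TCS_NS",
    "MISSING_IDENTIFIER",
    "TcsExportError",
    "ProtocolError",
    "to_tcs",
    "parse_tcs_request",
    "parse_tcs_response",
    "submit_tcs",
    "tcs_schema",
]

TCS_NS = "http://www.tdwg.org/schemas/tcs/1.01"
_T = "{%s}" % TCS_NS

#: Marker for a record whose identifier the registry failed to return.
MISSING_IDENTIFIER = object()

_CODE_TO_TCS = {Code.ICNAFP: "Botanical", Code.ICZN: "Zoological"}
_TCS_TO_CODE = {v: k for k, v in _CODE_TO_TCS.items()}


class TcsExportError(ValueError):
    pass


class ProtocolError(RuntimeError):
    pass


@lru_cache(maxsize=None)
def tcs_schema() -> etree.XMLSchema:
    text = resources.files("nomenreg.data").joinpath("tcs_subset.xsd").read_bytes()
    return etree.XMLSchema(etree.fromstring(text))


def _rank_label(act: NomenclaturalAct) -> Optional[str]:
    return act.rank.value if act.rank else None


def to_tcs(
    acts: Sequence[NomenclaturalAct],
    meta: ArticleMeta,
    registry: Registry = Registry.IPNI,
) -> str:
    """Emit one TaxonName record per act, in act order.

    Every act must pass scope validation for the target registry; a
    rejected act refuses the whole export with the validation reason (the
    publisher must correct or drop it, never submit it silently). The
    emitted document validates against the in-repo TCS-subset schema.
    """
    for i, act in enumerate(acts):
        verdict = validate_act(act, registry)
        if not verdict.accepted:
            raise TcsExportError(f"act {i} not exportable to {registry.value}: {verdict.reason}")

    root = etree.Element(_T + "DataSet", nsmap={None: TCS_NS})
    md = etree.SubElement(root, _T + "MetaData")
    cit = etree.SubElement(md, _T + "PublicationCitation")
    etree.SubElement(cit, _T + "Title").text = meta.title
    if meta.journal:
        etree.SubElement(cit, _T + "Journal").text = meta.journal
    if meta.issn_or_isbn:
        etree.SubElement(cit, _T + "ISSN").text = meta.issn_or_isbn
    if meta.doi:
        etree.SubElement(cit, _T + "DOI").text = meta.doi

    names = etree.SubElement(root, _T + "TaxonNames")
    for i, act in enumerate(acts):
        el = etree.SubElement(
            names,
            _T + "TaxonName",
            id=f"tn{i + 1}",
            nomenclaturalCode=_CODE_TO_TCS[act.code],
        )
        if act.is_hybrid:
            el.set("isHybrid", "true")
        etree.SubElement(el, _T + "Simple").text = act.name.full()
        rank = _rank_label(act)
        if rank:
            etree.SubElement(el, _T + "Rank").text = rank
        etree.SubElement(el, _T + "CanonicalName").text = act.name.canonical()
        if act.name.authorship or act.name.basionym_authorship:
            auth = act.name.authorship
            if act.name.basionym_authorship:
                auth = f"({act.name.basionym_authorship}) {act.name.authorship}".strip()
            etree.SubElement(el, _T + "CanonicalAuthorship").text = auth
        etree.SubElement(el, _T + "NomenclaturalStatus").text = act.status_phrase
        if act.kind is ActKind.NEW_COMBINATION and act.name.basionym_authorship:
            etree.SubElement(el, _T + "Basionym").text = act.name.basionym_authorship
        if act.type_kind is not None:
            etree.SubElement(el, _T + "TypificationKind").text = act.type_kind.value

    doc = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    tree = etree.fromstring(doc)
    tcs_schema().assertValid(tree)
    return doc.decode("utf-8")


def _text(el: etree._Element, tag: str) -> str:
    found = el.find(_T + tag)
    return (found.text or "").strip() if found is not None else ""


def _name_from_canonical(canonical: str) -> dict[str, str]:
    tokens = canonical.split()
    frag: dict[str, str] = {}
    if len(tokens) == 1:
        frag["uninomial"] = tokens[0]
    elif len(tokens) == 2:
        frag["genus"], frag["species"] = tokens
    elif len(tokens) >= 3:
        frag["genus"], frag["species"], frag["infraspecific"] = tokens[0], tokens[1], tokens[2]
    return frag


def parse_tcs_request(xml_document: str) -> list[NomenclaturalAct]:
    """Reconstruct acts from a TCS request batch (the registry side)."""
    tree = etree.fromstring(xml_document.encode("utf-8"))
    tcs_schema().assertValid(tree)
    acts = []
    for el in tree.iter(_T + "TaxonName"):
        status = _text(el, "NomenclaturalStatus")
        code = _TCS_TO_CODE[el.get("nomenclaturalCode")]
        frag: dict[str, object] = {"status": status, "code": code}
        frag.update(_name_from_canonical(_text(el, "CanonicalName")))
        auth = _text(el, "CanonicalAuthorship")
        basionym = _text(el, "Basionym")
        if basionym and auth.startswith("("):
            frag["authorship"] = auth.split(")", 1)[1].strip()
            frag["basionym_authorship"] = basionym
        else:
            frag["authorship"] = auth
        if el.get("isHybrid") == "true":
            frag["hybrid"] = True
        acts.append(classify_act(frag))
    return acts


def parse_tcs_response(
    xml_document: str, expected_count: Optional[int] = None
) -> dict[int, Union[Identifier, object]]:
    """Map each submitted record index to its returned identifier.

    The map is total over the batch: a record the registry answered without
    an identifier maps to :data:`MISSING_IDENTIFIER`. A response whose
    record count differs from the submitted batch size is a protocol
    error.
    """
    tree = etree.fromstring(xml_document.encode("utf-8"))
    tcs_schema().assertValid(tree)
    records = list(tree.iter(_T + "TaxonName"))
    if expected_count is not None and len(records) != expected_count:
        raise ProtocolError(
            f"submitted batch of {expected_count} records but response has {len(records)}"
        )
    out: dict[int, Union[Identifier, object]] = {}
    for i, el in enumerate(records):
        raw = _text(el, "RegistryIdentifier")
        out[i] = Identifier(raw) if raw else MISSING_IDENTIFIER
    return out


def submit_tcs(xml_document: str, store: RegistryStore) -> str:
    """Loopback registry endpoint: upsert each record, insert identifiers.

    Plays the role of the registry API for the TCS channel; the response is
    the request document with a ``RegistryIdentifier`` appended to every
    TaxonName record.
    """
    acts = parse_tcs_request(xml_document)
    tree = etree.fromstring(xml_document.encode("utf-8"))
    elements = list(tree.iter(_T + "TaxonName"))
    for act, el in zip(acts, elements):
        record, _ = store.upsert_record(act, act.dedup_key)
        etree.SubElement(el, _T + "RegistryIdentifier").text = record.id.value
    doc = etree.tostring(tree, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    tcs_schema().assertValid(etree.fromstring(doc))
    return doc.decode("utf-8")
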