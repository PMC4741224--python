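"""Nomenclatural-act classification and per-registry scope validation.

A nomenclatural act is a code-governed event that fixes a name's status:
describing a new taxon, proposing a new combination or replacement name,
or designating a type specimen. Not every registry records every kind of
act — e.g. IPNI does not record new lectotypifications, and concepts such
as tautonyms or epitypes do not exist under the zoological code. The scope
matrix encodes that registrability grid; :func:`validate_act` applies it
together with three code-specific rules:

* hybrids are not a separate act category but a flag on a new-taxon rank,
  and have no meaning under the zoological code;
* tautonyms (epithet repeating the genus name) are not validly published
  under the botanical code, so botanical/fungal registries record them only
  with a warning to be resolved at indexing stage;
* typifications other than holotypification of a new taxon are out of
  IPNI's recording scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

import yaml

from .normalize import normalize_text

__all__ = [
    "ActKind",
    "Rank",
    "TypeKind",
    "Code",
    "Registry",
    "Validity",
    "ScientificName",
    "NomenclaturalAct",
    "ScopeCell",
    "ScopeMatrix",
    "ValidationResult",
    "ClassificationError",
    "classify_act",
    "validate_act",
    "scope_matrix",
    "status_phrases",
]


class ActKind(str, enum.Enum):
    NEW_TAXON = "new_taxon"
    NEW_REPLACEMENT_NAME = "new_replacement_name"
    NEW_COMBINATION = "new_combination"
    TAUTONYM = "tautonym"
    TYPIFICATION = "typification"


class Rank(str, enum.Enum):
    SUPRAFAMILIAL = "suprafamilial"
    FAMILIAL = "familial"
    INFRAFAMILIAL = "infrafamilial"
    GENERIC = "generic"
    INFRAGENERIC = "infrageneric"
    SPECIFIC = "specific"
    INFRASPECIFIC = "infraspecific"


class TypeKind(str, enum.Enum):
    HOLOTYPE = "holotype"
    LECTOTYPE = "lectotype"
    NEOTYPE = "neotype"
    EPITYPE = "epitype"


class Code(str, enum.Enum):
    """Nomenclatural code governing an act."""

    ICNAFP = "ICNafp"  # algae, fungi and plants
    ICZN = "ICZN"  # animals


class Registry(str, enum.Enum):
    IPNI = "ipni"
    INDEX_FUNGORUM = "index_fungorum"
    MYCOBANK = "mycobank"
    ZOOBANK = "zoobank"
    # Approved fungal registry with no dedicated column in the printed
    # registrability table; treated as equivalent to Index Fungorum.
    FUNGAL_NAMES = "fungal_names"


#: Fungal registries participating in cross-registry propagation.
FUNGAL_REGISTRIES = (Registry.INDEX_FUNGORUM, Registry.MYCOBANK, Registry.FUNGAL_NAMES)


class Validity(str, enum.Enum):
    RECORDED = "recorded"
    NOT_RECORDED = "not_recorded"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ScientificName:
    """Name parts plus authorship; a new combination carries the basionym
    authorship in parentheses form (e.g. ``(Oliv.) H. Rob.``)."""

    uninomial: str = ""
    genus: str = ""
    species: str = ""
    infraspecific: str = ""
    authorship: str = ""
    basionym_authorship: str = ""

    def canonical(self) -> str:
        if self.uninomial:
            return self.uninomial
        parts = [p for p in (self.genus, self.species, self.infraspecific) if p]
        return " ".join(parts)

    def full(self) -> str:
        auth = self.authorship
        if self.basionym_authorship and not auth.startswith("("):
            auth = f"({self.basionym_authorship}) {self.authorship}".strip()
        return f"{self.canonical()} {auth}".strip()


class ClassificationError(ValueError):
    """Raised when a nomenclature block cannot be classified. Carries the
    offending status phrase; classification never guesses silently."""

    def __init__(self, phrase: str):
        self.phrase = phrase
        super().__init__(f"unrecognized nomenclatural status phrase: {phrase!r}")


@dataclass
class NomenclaturalAct:
    kind: ActKind
    name: ScientificName
    code: Code
    rank: Optional[Rank] = None  # required iff kind == NEW_TAXON
    type_kind: Optional[TypeKind] = None  # required iff kind == TYPIFICATION
    is_hybrid: bool = False
    status_phrase: str = ""

    def __post_init__(self) -> None:
        if (self.rank is not None) != (self.kind is ActKind.NEW_TAXON):
            raise ValueError("rank must be present exactly when kind is new_taxon")
        if (self.type_kind is not None) != (self.kind is ActKind.TYPIFICATION):
            raise ValueError("type_kind must be present exactly when kind is typification")
        if self.is_hybrid and self.code is not Code.ICNAFP:
            raise ValueError("hybrid flag is only meaningful under ICNafp")

    @property
    def descriptor(self) -> str:
        """Row key of this act in the scope matrix."""
        if self.kind is ActKind.NEW_TAXON:
            return f"new_taxon/{self.rank.value}"
        if self.kind is ActKind.TYPIFICATION:
            return f"typification/{self.type_kind.value}"
        return self.kind.value

    @property
    def dedup_key(self) -> str:
        """Registry deduplication key: code, kind, canonical name with its
        status marker, and type kind, all under the author-name
        normalization so spelling noise does not split records."""
        parts = [
            self.code.value,
            self.kind.value,
            self.name.canonical(),
            self.status_phrase,
            self.type_kind.value if self.type_kind else "",
        ]
        return normalize_text(" ".join(p for p in parts if p))


@dataclass(frozen=True)
class ScopeCell:
    value: Validity
    table_blank: bool = False  # blank in the printed source table


@dataclass(frozen=True)
class ScopeMatrix:
    """Registry × act-descriptor registrability grid; total over the four
    indexing services and every act descriptor."""

    cells: Mapping[tuple[Registry, str], ScopeCell]

    #: Table columns; Fungal Names resolves through Index Fungorum.
    COLUMNS = (Registry.IPNI, Registry.INDEX_FUNGORUM, Registry.MYCOBANK, Registry.ZOOBANK)

    def cell(self, registry: Registry, descriptor: str) -> ScopeCell:
        if registry is Registry.FUNGAL_NAMES:
            registry = Registry.INDEX_FUNGORUM
        try:
            return self.cells[(registry, descriptor)]
        except KeyError:
            raise KeyError(f"no scope-matrix cell for ({registry.value}, {descriptor})") from None

    def descriptors(self) -> list[str]:
        seen: dict[str, None] = {}
        for (_, d) in self.cells:
            seen.setdefault(d)
        return list(seen)

    def to_rows(self) -> list[dict[str, object]]:
        """Serialize for audit/diff: one dict per descriptor with the four
        column values and blank annotations."""
        rows = []
        for d in self.descriptors():
            row: dict[str, object] = {"act": d}
            for reg in self.COLUMNS:
                c = self.cell(reg, d)
                row[reg.value] = c.value.value
                if c.table_blank:
                    row[f"{reg.value}_table_blank"] = True
            rows.append(row)
        return rows


@lru_cache(maxsize=None)
def scope_matrix() -> ScopeMatrix:
    """Load the constant registrability matrix from the in-package config."""
    raw = yaml.safe_load(resources.files("nomenreg.data").joinpath("scope_matrix.yaml").read_text())
    cells: dict[tuple[Registry, str], ScopeCell] = {}
    for row in raw:
        descriptor = row["act"]
        for reg in ScopeMatrix.COLUMNS:
            entry = row[reg.value]
            if isinstance(entry, dict):
                cell = ScopeCell(Validity(entry["value"]), bool(entry.get("table_blank", False)))
            else:
                cell = ScopeCell(Validity(entry))
            cells[(reg, descriptor)] = cell
    return ScopeMatrix(cells)


@lru_cache(maxsize=None)
def status_phrases() -> Mapping[str, Mapping[str, str]]:
    """The configured status-phrase vocabulary (phrase -> classification)."""
    raw = yaml.safe_load(
        resources.files("nomenreg.data").joinpath("status_phrases.yaml").read_text()
    )
    return {k: dict(v) for k, v in raw.items()}


def classify_act(fragment: Mapping[str, object]) -> NomenclaturalAct:
    """Classify a parsed nomenclature block into a :class:`NomenclaturalAct`.

    ``fragment`` carries the status phrase, name parts, authorship and the
    hybrid flag as extracted from the treatment XML. An unknown status
    phrase raises :class:`ClassificationError` — never a silent guess. A
    new species whose epithet repeats the genus name is classified as a
    tautonym.
    """
    phrase = str(fragment.get("status", "")).strip()
    vocab = status_phrases()
    if phrase not in vocab:
        raise ClassificationError(phrase)
    entry = vocab[phrase]
    kind = ActKind(entry["kind"])
    rank = Rank(entry["rank"]) if "rank" in entry else None
    type_kind = TypeKind(entry["type_kind"]) if "type_kind" in entry else None

    name = ScientificName(
        uninomial=str(fragment.get("uninomial", "") or ""),
        genus=str(fragment.get("genus", "") or ""),
        species=str(fragment.get("species", "") or ""),
        infraspecific=str(fragment.get("infraspecific", "") or ""),
        authorship=str(fragment.get("authorship", "") or ""),
        basionym_authorship=str(fragment.get("basionym_authorship", "") or ""),
    )
    code = Code(fragment.get("code", Code.ICZN))
    is_hybrid = bool(fragment.get("hybrid", False))

    if (
        kind is ActKind.NEW_TAXON
        and rank is Rank.SPECIFIC
        and name.genus
        and name.genus.casefold() == name.species.casefold()
    ):
        kind, rank = ActKind.TAUTONYM, None

    return NomenclaturalAct(
        kind=kind,
        rank=rank,
        type_kind=type_kind,
        name=name,
        code=code,
        is_hybrid=is_hybrid,
        status_phrase=phrase,
    )


class Outcome(str, enum.Enum):
    ACCEPT = "accept"
    REJECT = "reject"
    WARN = "warn"


@dataclass(frozen=True)
class ValidationResult:
    outcome: Outcome
    reason: str = ""

    @property
    def accepted(self) -> bool:
        """Registrable (accept or accept-with-warning)."""
        return self.outcome is not Outcome.REJECT


def validate_act(act: NomenclaturalAct, registry: Registry) -> ValidationResult:
    """Validate an act's registrability for one registry.

    Accept iff the scope-matrix cell is ``recorded`` and no code rule fires.
    A cell of ``not_recorded`` or ``not_applicable`` always rejects. The
    tautonym-under-ICNafp case is recorded with a warning rather than
    accepted cleanly, since such names are not validly published under that
    code and must be flagged at indexing stage.
    """
    matrix = scope_matrix()
    cell = matrix.cell(registry, act.descriptor)

    if cell.value is Validity.NOT_APPLICABLE:
        return ValidationResult(
            Outcome.REJECT,
            f"not_applicable: {act.descriptor} has no meaning for {registry.value}",
        )
    if cell.value is Validity.NOT_RECORDED:
        return ValidationResult(
            Outcome.REJECT, f"{registry.value} does not record {act.descriptor}"
        )

    if act.is_hybrid:
        hybrid_cell = matrix.cell(registry, "new_taxon/hybrid")
        if hybrid_cell.value is Validity.NOT_APPLICABLE:
            return ValidationResult(
                Outcome.REJECT,
                f"not_applicable: hybrid-flagged acts have no meaning for {registry.value}",
            )
        if hybrid_cell.value is Validity.NOT_RECORDED:
            return ValidationResult(
                Outcome.REJECT, f"{registry.value} does not record hybrid-flagged acts"
            )

    if act.kind is ActKind.TAUTONYM and act.code is Code.ICNAFP:
        return ValidationResult(
            Outcome.WARN,
            "tautonym is not validly published under ICNafp; recorded if "
            "published but must be flagged at indexing stage",
        )

    return ValidationResult(Outcome.ACCEPT)
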