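"""Seeded synthetic-manuscript generator.

Every other module is exercised against manuscripts produced here: a valid
TaxPub document plus a manifest that enumerates what was planted (expected
act classifications, duplicate acts, author homonyms, acts invalid for a
given registry), so tests can diff pipeline output against ground truth
without any external data.

Generation is a pure function of the :class:`FixtureSpec`: the same spec
yields byte-identical XML. Names are assembled from a closed syllable
alphabet so epithets are pronounceable and collide only when a collision is
planted. Homonym planting produces author spellings that differ in raw form
(diacritics, initials vs. full given names) but normalize to the same key,
exercising the matching rules; because homonyms are a property of the
registry's existing content, the manifest lists them as ``preload_authors``
to be registered before the manuscript is submitted.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from typing import Mapping, Optional

from lxml import etree

from .acts import ActKind, Code, Registry
from .taxpub import TP_NS

__all__ = ["FixtureSpec", "SpecError", "generate_manuscript", "DEFAULT_KIND_MIX"]

_T = "{%s}" % TP_NS

#: Realistic turbo-taxonomy composition: overwhelmingly new species, a few
#: new genera, plus occasional combinations, replacement names and
#: typifications.
DEFAULT_KIND_MIX: Mapping[str, float] = {
    "new_taxon/specific": 0.70,
    "new_taxon/generic": 0.10,
    "new_combination": 0.10,
    "new_replacement_name": 0.05,
    "typification/holotype": 0.05,
}

_SYLLABLES = (
    "ba be bi bo bu ca ce ci co cu da de di do du fa fe fi fo fu "
    "ga ge gi go gu la le li lo lu ma me mi mo mu na ne ni no nu "
    "pa pe pi po pu ra re ri ro ru sa se si so su ta te ti to tu "
    "va ve vi vo vu za ze zi zo zu"
).split()

_SURNAME_SYLLABLES = _SYLLABLES
_GIVEN_NAMES = (
    "Maria", "John", "Elena", "Pavel", "Anna", "Teodor", "Lucia", "Viktor",
    "Nina", "Carlos", "Greta", "Ivan",
)
_DIACRITIC_MAP = str.maketrans({"a": "á", "e": "é", "o": "ö", "u": "ü", "i": "í"})

_STATUS_BY_DESCRIPTOR = {
    "new_taxon/suprafamilial": "ord. nov.",
    "new_taxon/familial": "fam. nov.",
    "new_taxon/infrafamilial": "subfam. nov.",
    "new_taxon/generic": "gen. nov.",
    "new_taxon/infrageneric": "subgen. nov.",
    "new_taxon/specific": "sp. nov.",
    "new_taxon/infraspecific": "subsp. nov.",
    "new_combination": "comb. nov.",
    "new_replacement_name": "nom. nov.",
    "tautonym": "sp. nov.",
    "typification/holotype": "holotype designated",
    "typification/lectotype": "lectotype designated",
    "typification/neotype": "neotype designated",
    "typification/epitype": "epitype designated",
}

_UNINOMIAL_DESCRIPTORS = {
    "new_taxon/suprafamilial",
    "new_taxon/familial",
    "new_taxon/infrafamilial",
    "new_taxon/generic",
    "new_taxon/infrageneric",
}


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic manuscript.

    ``n_acts`` is the total act count; planted tautonyms, duplicates and
    registry-invalid acts are part of it, not on top of it.
    ``planted_invalid`` pairs an act descriptor (a scope-matrix row such as
    ``typification/epitype`` or the pseudo-descriptor ``new_taxon/hybrid``)
    with the registry it should be rejected by.
    """

    n_acts: int = 5
    kind_mix: Optional[Mapping[str, float]] = None
    code: Code = Code.ICZN
    n_authors: int = 4
    n_author_homonyms: int = 0
    n_duplicate_acts: int = 0
    n_tautonyms: int = 0
    planted_invalid: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        problems = []
        n_planted = self.n_duplicate_acts + self.n_tautonyms + len(self.planted_invalid)
        n_base = self.n_acts - n_planted
        if self.n_acts < 0:
            problems.append("n_acts must be non-negative")
        if n_base < 0:
            problems.append(
                f"planted acts ({n_planted}) exceed n_acts ({self.n_acts})"
            )
        if self.n_duplicate_acts > 0 and n_base < 1:
            problems.append("duplicate acts need at least one base act to copy")
        if self.n_authors < 1:
            problems.append("a manuscript needs at least one author")
        if self.n_author_homonyms > self.n_authors:
            problems.append("cannot plant more homonyms than authors")
        if self.code is not Code.ICNAFP and any(
            descriptor == "new_taxon/hybrid" for descriptor, _ in self.planted_invalid
        ):
            problems.append("hybrid-flagged acts require an ICNafp fixture")
        mix = self.kind_mix or DEFAULT_KIND_MIX
        unknown = set(mix) - set(_STATUS_BY_DESCRIPTOR)
        if unknown:
            problems.append(f"unknown act descriptors in kind_mix: {sorted(unknown)}")
        known_planted = set(_STATUS_BY_DESCRIPTOR) | {"new_taxon/hybrid"}
        bad_planted = {d for d, _ in self.planted_invalid} - known_planted
        if bad_planted:
            problems.append(f"unknown planted_invalid descriptors: {sorted(bad_planted)}")
        if problems:
            raise SpecError("; ".join(problems))


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _unique(rng: random.Random, used: set[str], make) -> str:
    while True:
        candidate = make()
        if candidate not in used:
            used.add(candidate)
            return candidate


def _authorship(rng: random.Random) -> str:
    return _word(rng, 2).capitalize()


def _make_contributors(rng: random.Random, spec: FixtureSpec):
    used: set[str] = set()
    contributors = []
    for _ in range(spec.n_authors):
        surname = _unique(rng, used, lambda: _word(rng, 3).capitalize())
        given = rng.choice(_GIVEN_NAMES)
        contributors.append({"surname": surname, "given_names": given})

    preload = []
    homonym_keys = []
    for i in range(spec.n_author_homonyms):
        target = contributors[i]
        # two pre-registered people whose spellings normalize onto the
        # contributor's key: one with accented surname + initial, one with
        # plain surname + full given name
        accented = target["surname"].translate(_DIACRITIC_MAP)
        preload.append({"surname": accented, "given_names": target["given_names"][0] + "."})
        preload.append({"surname": target["surname"], "given_names": target["given_names"]})
        homonym_keys.append(i)
    return contributors, preload, homonym_keys


def _plan_acts(rng: random.Random, spec: FixtureSpec) -> list[dict]:
    mix = dict(spec.kind_mix or DEFAULT_KIND_MIX)
    descriptors = sorted(mix)
    weights = [mix[d] for d in descriptors]
    n_planted = spec.n_duplicate_acts + spec.n_tautonyms + len(spec.planted_invalid)
    n_base = spec.n_acts - n_planted

    used_names: set[str] = set()
    n_genera = max(3, n_base // 25)
    genera = [
        _unique(rng, used_names, lambda: _word(rng, 3).capitalize())
        for _ in range(n_genera)
    ]

    plan: list[dict] = []

    def new_act(descriptor: str, hybrid: bool = False) -> dict:
        status = _STATUS_BY_DESCRIPTOR[descriptor]
        entry: dict = {
            "descriptor": descriptor,
            "status": status,
            "hybrid": hybrid,
            "duplicate_of": None,
            "invalid_for": [],
            "tautonym": False,
        }
        if descriptor in _UNINOMIAL_DESCRIPTORS:
            entry["uninomial"] = _unique(rng, used_names, lambda: _word(rng, 3).capitalize())
            entry["authorship"] = _authorship(rng)
        elif descriptor == "tautonym":
            genus = _unique(rng, used_names, lambda: _word(rng, 3).capitalize())
            entry["genus"], entry["species"] = genus, genus.lower()
            used_names.add(f"{genus} {genus.lower()}")
            entry["authorship"] = _authorship(rng)
            entry["tautonym"] = True
        else:
            genus = rng.choice(genera)
            species = _unique(rng, used_names, lambda: f"{genus} {_word(rng, 3)}").split()[1]
            entry["genus"], entry["species"] = genus, species
            if descriptor == "new_taxon/infraspecific":
                entry["infraspecific"] = _word(rng, 3)
            if descriptor == "new_combination":
                entry["authorship"] = f"({_authorship(rng)}) {_authorship(rng)}"
            else:
                entry["authorship"] = _authorship(rng)
        return entry

    for _ in range(n_base):
        plan.append(new_act(rng.choices(descriptors, weights=weights, k=1)[0]))

    for _ in range(spec.n_tautonyms):
        plan.append(new_act("tautonym"))

    for descriptor, registry in spec.planted_invalid:
        Registry(registry)  # validate early
        if descriptor == "new_taxon/hybrid":
            entry = new_act("new_taxon/specific", hybrid=True)
        else:
            entry = new_act(descriptor)
        entry["invalid_for"].append(registry)
        plan.append(entry)

    for _ in range(spec.n_duplicate_acts):
        source_idx = rng.randrange(n_base) if n_base else 0
        duplicate = dict(plan[source_idx])
        duplicate["invalid_for"] = list(plan[source_idx]["invalid_for"])
        duplicate["duplicate_of"] = source_idx
        plan.append(duplicate)

    for i, entry in enumerate(plan):
        entry["index"] = i
    return plan


def _canonical(entry: dict) -> str:
    if "uninomial" in entry:
        return entry["uninomial"]
    parts = [entry.get("genus", ""), entry.get("species", ""), entry.get("infraspecific", "")]
    return " ".join(p for p in parts if p)


def _expected_kind(entry: dict) -> str:
    d = entry["descriptor"]
    if entry["tautonym"]:
        return ActKind.TAUTONYM.value
    if d.startswith("new_taxon/"):
        return ActKind.NEW_TAXON.value
    if d.startswith("typification/"):
        return ActKind.TYPIFICATION.value
    return d


def _build_xml(spec: FixtureSpec, contributors, plan) -> str:
    root = etree.Element("article", nsmap={"tp": TP_NS})
    root.set("dtd-version", "1.0")
    front = etree.SubElement(root, "front")
    jm = etree.SubElement(front, "journal-meta")
    jtg = etree.SubElement(jm, "journal-title-group")
    journal = (
        "Synthetic Journal of Zootaxonomy"
        if spec.code is Code.ICZN
        else "Synthetic Journal of Phytotaxonomy"
    )
    etree.SubElement(jtg, "journal-title").text = journal
    etree.SubElement(jm, "issn").text = "2000-0001"

    am = etree.SubElement(front, "article-meta")
    pub_id = etree.SubElement(am, "article-id", **{"pub-id-type": "publisher-id"})
    pub_id.text = f"MS-{spec.seed}-{spec.n_acts}"
    doi = etree.SubElement(am, "article-id", **{"pub-id-type": "doi"})
    doi.text = f"10.9999/synthetic.{spec.seed}.{spec.n_acts}"
    tg = etree.SubElement(am, "title-group")
    etree.SubElement(tg, "article-title").text = (
        f"Synthetic turbo-taxonomy manuscript with {spec.n_acts} nomenclatural "
        f"acts (seed {spec.seed})"
    )
    cg = etree.SubElement(am, "contrib-group")
    for c in contributors:
        contrib = etree.SubElement(cg, "contrib", **{"contrib-type": "author"})
        name = etree.SubElement(contrib, "name")
        etree.SubElement(name, "surname").text = c["surname"]
        etree.SubElement(name, "given-names").text = c["given_names"]
    etree.SubElement(
        am, "pub-date", **{"date-type": "accepted", "iso-8601-date": "2015-11-15"}
    )
    cmg = etree.SubElement(am, "custom-meta-group")
    for meta_name, meta_value in (
        ("nomenclatural-code", spec.code.value),
        ("archive-name", "Synthetic Digital Archive"),
    ):
        cm = etree.SubElement(cmg, "custom-meta")
        etree.SubElement(cm, "meta-name").text = meta_name
        etree.SubElement(cm, "meta-value").text = meta_value

    body = etree.SubElement(root, "body")
    for entry in plan:
        treatment = etree.SubElement(body, _T + "taxon-treatment")
        nomenclature = etree.SubElement(treatment, _T + "nomenclature")
        name_el = etree.SubElement(nomenclature, _T + "taxon-name")
        if entry["hybrid"]:
            name_el.set("hybrid", "yes")
        if "uninomial" in entry:
            part = etree.SubElement(
                name_el, _T + "taxon-name-part", **{"taxon-name-part-type": "uninomial"}
            )
            part.text = entry["uninomial"]
        else:
            for part_type in ("genus", "species", "infraspecific"):
                if entry.get(part_type):
                    part = etree.SubElement(
                        name_el,
                        _T + "taxon-name-part",
                        **{"taxon-name-part-type": part_type},
                    )
                    part.text = entry[part_type]
        etree.SubElement(nomenclature, _T + "taxon-authority").text = entry["authorship"]
        etree.SubElement(nomenclature, _T + "taxon-status").text = entry["status"]
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def generate_manuscript(spec: FixtureSpec) -> tuple[str, dict]:
    """Generate (TaxPub XML text, manifest) from a fixture spec.

    The manifest records the article metadata, contributors, authors to
    preload for homonym scenarios, and per-act ground truth (expected kind,
    canonical name, duplicate/invalid annotations).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    contributors, preload, homonym_targets = _make_contributors(rng, spec)
    plan = _plan_acts(rng, spec)
    xml_text = _build_xml(spec, contributors, plan)

    manifest = {
        "spec": {
            "n_acts": spec.n_acts,
            "code": spec.code.value,
            "n_authors": spec.n_authors,
            "n_author_homonyms": spec.n_author_homonyms,
            "n_duplicate_acts": spec.n_duplicate_acts,
            "n_tautonyms": spec.n_tautonyms,
            "planted_invalid": [list(p) for p in spec.planted_invalid],
            "seed": spec.seed,
            "kind_mix": dict(spec.kind_mix) if spec.kind_mix else None,
        },
        "article": {
            "publisher_id": f"MS-{spec.seed}-{spec.n_acts}",
            "code": spec.code.value,
        },
        "contributors": contributors,
        "preload_authors": preload,
        "homonym_contributor_indices": homonym_targets,
        "acts": [
            {
                "index": e["index"],
                "descriptor": e["descriptor"],
                "expected_kind": _expected_kind(e),
                "status": e["status"],
                "canonical": _canonical(e),
                "hybrid": e["hybrid"],
                "duplicate_of": e["duplicate_of"],
                "invalid_for": e["invalid_for"],
                "tautonym": e["tautonym"],
            }
            for e in plan
        ],
    }
    return xml_text, manifest


def manifest_to_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=2, sort_keys=True)
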