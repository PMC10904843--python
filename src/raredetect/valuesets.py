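"""Value sets: named groups of clinical codes and description synonyms.

A value set unifies spelling and naming variants of one clinical concept
(e.g. "familial hypercholesterolemia" vs "familial hypercholesterolaemia")
into a single filterable unit, so that every screen rule references one
name instead of enumerating variants.

Matching is exact on normalised description strings (lowercased, collapsed
whitespace) or on (code_system, code) pairs; fuzzy matching is deliberately
out of scope.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .ehr_model import CodeSystem, ProblemEntry
from .errors import ConfigurationError, DataError

_WHITESPACE = re.compile(r"\s+")


def normalise(text: str) -> str:
    """Canonical form of a description: lowercase, single spaces, stripped."""
    return _WHITESPACE.sub(" ", text.strip().lower())


@dataclass(frozen=True)
class ValueSet:
    name: str
    codes: frozenset[tuple[CodeSystem, str]] = frozenset()
    synonyms: frozenset[str] = frozenset()


def build_value_set(
    name: str,
    codes: set[tuple[CodeSystem | str, str]] | None = None,
    synonyms: set[str] | None = None,
) -> ValueSet:
    """Construct a value set, normalising synonyms and deduplicating.

    At least one code or synonym is required.
    """
    if not name:
        raise ConfigurationError("value set name must be non-empty")
    codes = codes or set()
    synonyms = synonyms or set()
    if not codes and not synonyms:
        raise ConfigurationError(f"value set {name!r}: empty definition")
    norm_codes = frozenset((CodeSystem(system), str(code)) for system, code in codes)
    norm_syn = frozenset(normalise(s) for s in synonyms if normalise(s))
    return ValueSet(name=name, codes=norm_codes, synonyms=norm_syn)


def matches(vs: ValueSet, entry: ProblemEntry) -> bool:
    """True iff the entry's code is in the set, or its normalised
    description equals one of the set's synonyms (code match first)."""
    if (entry.code_system, entry.code) in vs.codes:
        return True
    return normalise(entry.description) in vs.synonyms


@dataclass
class ValueSetCatalog:
    """Named collection of value sets."""

    sets: dict[str, ValueSet] = field(default_factory=dict)
    version: str = "0"

    def __getitem__(self, name: str) -> ValueSet:
        try:
            return self.sets[name]
        except KeyError:
            raise ConfigurationError(f"unknown value set {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def add(self, vs: ValueSet) -> None:
        if vs.name in self.sets:
            raise ConfigurationError(f"duplicate value set name {vs.name!r}")
        self.sets[vs.name] = vs


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

_CATALOG_KEYS = {"version", "sets"}
_SET_KEYS = {"name", "codes", "synonyms"}
_CODE_KEYS = {"system", "code"}


def _check_keys(obj: dict, allowed: set[str], where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise DataError(f"unknown field {sorted(unknown)[0]!r} at {where}")


def load_catalog(path: str | Path) -> ValueSetCatalog:
    """Load a catalog from JSON; schema violations raise :class:`DataError`
    naming the offending field with a JSON-pointer-style location."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing catalog file: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DataError(f"catalog is not valid JSON: {exc}") from None
    if not isinstance(raw, dict):
        raise DataError("catalog root must be a JSON object at /")
    _check_keys(raw, _CATALOG_KEYS, "/")

    catalog = ValueSetCatalog(version=str(raw.get("version", "0")))
    for i, entry in enumerate(raw.get("sets", [])):
        where = f"/sets/{i}"
        if not isinstance(entry, dict):
            raise DataError(f"value set must be an object at {where}")
        _check_keys(entry, _SET_KEYS, where)
        codes = set()
        for j, code in enumerate(entry.get("codes", [])):
            cwhere = f"{where}/codes/{j}"
            if not isinstance(code, dict):
                raise DataError(f"code must be an object at {cwhere}")
            _check_keys(code, _CODE_KEYS, cwhere)
            try:
                codes.add((CodeSystem(code["system"]), str(code["code"])))
            except (KeyError, ValueError) as exc:
                raise DataError(f"bad code at {cwhere}: {exc}") from None
        try:
            vs = build_value_set(
                entry.get("name", ""), codes, set(entry.get("synonyms", []))
            )
        except ConfigurationError as exc:
            raise DataError(f"bad value set at {where}: {exc}") from None
        catalog.add(vs)
    return catalog


def save_catalog(catalog: ValueSetCatalog, path: str | Path) -> None:
    payload = {
        "version": catalog.version,
        "sets": [
            {
                "name": vs.name,
                "codes": [
                    {"system": system.value, "code": code}
                    for system, code in sorted(vs.codes, key=lambda c: (c[0].value, c[1]))
                ],
                "synonyms": sorted(vs.synonyms),
            }
            for vs in catalog.sets.values()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Default catalog
# ---------------------------------------------------------------------------

#: Names of the two disease-diagnosis value sets in the default catalog.
FABRY_DX_SET = "fabry disease"
FH_DX_SET = "familial hypercholesterolaemia"
ASCVD_SET = "ascvd"

_DEFAULT_PHENOTYPES: dict[str, list[str]] = {
    "chronic kidney disease": ["chronic kidney disease", "chronic renal disease"],
    "proteinuria": ["proteinuria"],
    "microalbuminuria": ["microalbuminuria"],
    "cardiomyopathy": ["cardiomyopathy", "hypertrophic cardiomyopathy"],
    "valvular heart disease": ["valvular heart disease", "heart valve disorder"],
    "arrhythmia": ["arrhythmia", "cardiac arrhythmia"],
    "stroke ischemic": ["stroke ischemic", "ischemic stroke", "ischaemic stroke"],
    "transient ischemic attack": ["transient ischemic attack", "transient ischaemic attack"],
    "acroparaesthesia": ["acroparaesthesia", "acroparesthesia"],
    "angiokeratomas": ["angiokeratomas", "angiokeratoma"],
    "impaired sweating/hypohidrosis": ["impaired sweating", "hypohidrosis"],
    "heat and cold tolerance": ["heat and cold tolerance", "heat intolerance", "cold intolerance"],
    "corneal whirling": ["corneal whirling"],
    "cornea verticillata": ["cornea verticillata", "cornea verticillate"],
    "corneal and lenticular opacities": ["corneal and lenticular opacities",
                                         "corneal opacity", "lenticular opacity"],
    "vasculopathy (retina, conjunctiva)": ["vasculopathy (retina, conjunctiva)",
                                           "retinal vasculopathy", "conjunctival vasculopathy"],
}

_ASCVD_SYNONYMS = [
    "myocardial infarction",
    "angina",
    "angina pectoris",
    "coronary revascularisation",
    "coronary revascularization",
    "ischaemic stroke",
    "ischemic stroke",
    "peripheral arterial disease",
]


def default_catalog() -> ValueSetCatalog:
    """The shipped catalog: phenotype sets for the five-organ-system screen,
    an ASCVD set, and the two disease-diagnosis sets.

    Codes are placeholder local codes (no terminology licence required);
    real deployments override the catalog via JSON.
    """
    catalog = ValueSetCatalog(version="default-1")
    for i, (name, synonyms) in enumerate(sorted(_DEFAULT_PHENOTYPES.items()), start=1):
        catalog.add(build_value_set(
            name, {(CodeSystem.LOCAL, f"VS{i:03d}")}, set(synonyms)
        ))
    catalog.add(build_value_set(
        ASCVD_SET, {(CodeSystem.LOCAL, "VS100")}, set(_ASCVD_SYNONYMS)
    ))
    catalog.add(build_value_set(
        FABRY_DX_SET,
        {(CodeSystem.SNOMED, "16652001"), (CodeSystem.LOCAL, "DX-FABRY")},
        {"fabry disease", "fabry's disease", "anderson-fabry disease"},
    ))
    catalog.add(build_value_set(
        FH_DX_SET,
        {(CodeSystem.SNOMED, "398036000"), (CodeSystem.LOCAL, "DX-FH")},
        {"familial hypercholesterolemia", "familial hypercholesterolaemia"},
    ))
    return catalog
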