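"""Diagnosis code sets and medication classes referenced by the phenotype rules.

The phenotype distinguishes four diagnosis-code groups — type 1 diabetes
(ICD-10 chapter E10, ICD-9 250.xx with fifth digit 1/3), type 2 diabetes
(E11, 250.xx with fifth digit 0/2), other diabetes forms (secondary,
other-specified/MODY, neonatal), and everything else — plus two medication
classes (insulin, metformin) matched by keyword against free-text drug names.

Code matching is dot-insensitive and case-insensitive: ``E10.9`` and ``e109``
are the same code.  A pattern is either an exact code or, with a trailing
``*``, a prefix that matches the code and any subclassification characters.

The neonatal-diabetes code differs between algorithm revisions: version 1
used P61.0 and version 2 onward corrected this to P70.2, so the catalog
carries both other-DM sets and the engine selects by version.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "CodeSystem",
    "DxCategory",
    "AlgorithmVersion",
    "CodeSet",
    "CodeCatalog",
    "code_matches",
    "classify_dx_code",
    "load_catalog",
    "default_catalog",
]


class CodeSystem(str, enum.Enum):
    """Origin of a pattern list: ICD diagnosis codes or medication keywords."""

    ICD = "ICD"
    MED_CLASS = "MED_CLASS"


class DxCategory(str, enum.Enum):
    """Diagnosis-code group a single ICD code falls into."""

    T1DM = "T1DM"
    T2DM = "T2DM"
    OTHER_DM = "OTHER_DM"
    NOT_DM = "NOT_DM"


class AlgorithmVersion(str, enum.Enum):
    """Published revisions of the phenotype algorithm.

    v1: original rules (neonatal DM coded P61.0 in the other-DM set).
    v2: other-DM set uses P70.2 instead of P61.0.
    v3: additionally requires a metformin prescription for T2DM.
    """

    V1 = "v1"
    V2 = "v2"
    V3 = "v3"


def _normalize_code(code: str) -> str:
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeSet:
    """A named collection of code patterns with a membership test."""

    name: str
    system: CodeSystem
    patterns: tuple[str, ...]
    # normalized (pattern, is_prefix) pairs, derived once
    _compiled: tuple[tuple[str, bool], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"code set {self.name!r} has no patterns")
        compiled = []
        for raw in self.patterns:
            if not raw or raw != raw.strip() or " " in raw:
                raise ValueError(f"code set {self.name!r}: bad pattern {raw!r}")
            if raw != raw.upper():
                raise ValueError(f"code set {self.name!r}: pattern {raw!r} not uppercase")
            is_prefix = raw.endswith("*")
            pat = _normalize_code(raw[:-1] if is_prefix else raw)
            if not pat:
                raise ValueError(f"code set {self.name!r}: empty pattern after '*' strip")
            compiled.append((pat, is_prefix))
        object.__setattr__(self, "_compiled", tuple(compiled))

    def contains(self, code: str) -> bool:
        """Dot- and case-insensitive membership test for a single code."""
        if not code or not code.strip():
            raise ValueError("empty diagnosis code")
        norm = _normalize_code(code)
        for pat, is_prefix in self._compiled:
            if norm == pat or (is_prefix and norm.startswith(pat)):
                return True
        return False

    def matches_keyword(self, text: str) -> bool:
        """Substring keyword match for medication names (MED_CLASS sets)."""
        if not text or not text.strip():
            return False
        up = text.upper()
        return any(pat in up for pat, _ in self._compiled)


def code_matches(code: str, codeset: CodeSet) -> bool:
    """True iff ``code`` matches an exact pattern or a prefix pattern of the set."""
    return codeset.contains(code)


@dataclass(frozen=True)
class CodeCatalog:
    """The six code sets the phenotype rules reference.

    The three diagnosis sets active under any one version must be pairwise
    disjoint so that :func:`classify_dx_code` is a function; this is checked
    at construction over the pattern lists.
    """

    t1dm_dx: CodeSet
    t2dm_dx: CodeSet
    other_dm_dx_v1: CodeSet
    other_dm_dx_v2: CodeSet
    insulin_meds: CodeSet
    metformin_meds: CodeSet

    def __post_init__(self) -> None:
        if self.other_dm_dx_v1.contains("P61.0") is False:
            raise ValueError("other_dm_dx_v1 must contain P61.0")
        if self.other_dm_dx_v1.contains("P70.2"):
            raise ValueError("other_dm_dx_v1 must not contain P70.2")
        if not self.other_dm_dx_v2.contains("P70.2"):
            raise ValueError("other_dm_dx_v2 must contain P70.2")
        if self.other_dm_dx_v2.contains("P61.0"):
            raise ValueError("other_dm_dx_v2 must not contain P61.0")
        for other in (self.other_dm_dx_v1, self.other_dm_dx_v2):
            _check_disjoint(self.t1dm_dx, self.t2dm_dx)
            _check_disjoint(self.t1dm_dx, other)
            _check_disjoint(self.t2dm_dx, other)

    def other_dm_dx(self, version: AlgorithmVersion) -> CodeSet:
        """Version-appropriate other-DM diagnosis set."""
        if version is AlgorithmVersion.V1:
            return self.other_dm_dx_v1
        return self.other_dm_dx_v2


def _pattern_overlap(a: tuple[str, bool], b: tuple[str, bool]) -> bool:
    pa, prefa = a
    pb, prefb = b
    if pa == pb:
        return True
    if prefa and pb.startswith(pa):
        return True
    if prefb and pa.startswith(pb):
        return True
    return False


def _check_disjoint(s1: CodeSet, s2: CodeSet) -> None:
    for a in s1._compiled:
        for b in s2._compiled:
            if _pattern_overlap(a, b):
                raise ValueError(
                    f"code sets {s1.name!r} and {s2.name!r} overlap on "
                    f"patterns {a[0]!r} / {b[0]!r}"
                )


def classify_dx_code(
    code: str, catalog: CodeCatalog, version: AlgorithmVersion
) -> DxCategory:
    """Classify one diagnosis code into exactly one category.

    Returns NOT_DM when no set matches.  The catalog's disjointness invariant
    guarantees at most one set can match.
    """
    hits = []
    if catalog.t1dm_dx.contains(code):
        hits.append(DxCategory.T1DM)
    if catalog.t2dm_dx.contains(code):
        hits.append(DxCategory.T2DM)
    if catalog.other_dm_dx(version).contains(code):
        hits.append(DxCategory.OTHER_DM)
    if len(hits) > 1:
        raise ValueError(f"code {code!r} matches multiple sets: {hits} (catalog misconfigured)")
    return hits[0] if hits else DxCategory.NOT_DM


def _codeset_from_config(name: str, section: dict) -> CodeSet:
    try:
        system = CodeSystem(section["system"])
        patterns = tuple(str(p) for p in section["patterns"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"catalog section {name!r} malformed: {exc}") from exc
    return CodeSet(name=name, system=system, patterns=patterns)


_REQUIRED_SECTIONS = (
    "t1dm_dx",
    "t2dm_dx",
    "other_dm_dx_v1",
    "other_dm_dx_v2",
    "insulin_meds",
    "metformin_meds",
)


def load_catalog(path: str | Path) -> CodeCatalog:
    """Load a code catalog from a YAML file (one section per code set)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _catalog_from_mapping(raw)


def _catalog_from_mapping(raw: dict) -> CodeCatalog:
    if not isinstance(raw, dict):
        raise ValueError("catalog file must map section names to code sets")
    missing = [s for s in _REQUIRED_SECTIONS if s not in raw]
    if missing:
        raise ValueError(f"catalog missing sections: {missing}")
    sets = {name: _codeset_from_config(name, raw[name]) for name in _REQUIRED_SECTIONS}
    return CodeCatalog(**sets)


def default_catalog() -> CodeCatalog:
    """The bundled default catalog (user-overridable via ``load_catalog``)."""
    ref = resources.files("pediphen.data").joinpath("default_catalog.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _catalog_from_mapping(raw)


def drug_class_of(name: str, catalog: CodeCatalog) -> str:
    """Deterministic drug class (INSULIN / METFORMIN / OTHER) from a drug name."""
    if catalog.insulin_meds.matches_keyword(name):
        return "INSULIN"
    if catalog.metformin_meds.matches_keyword(name):
        return "METFORMIN"
    return "OTHER"
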