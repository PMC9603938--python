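"""Rearrangement registry and chromosomal-barcode species diagnosis.

Each taxon carries a set of named chromosomal rearrangements relative to the
group-standard banding sequence: fixed inversions and transpositions
(present in every homologue, sample frequency 1.00), segregating autosomal
polymorphisms, and sex-linked markers such as an anucleolate Y (suppressed
nucleolar-organizer expression on the Y homologue).  Names follow the
group's cytological convention; aliases arise when the same inversion was
named independently in different species (e.g. an inversion fixed in one
taxon may be a named polymorphism in another), so all comparisons are by
canonical name after alias resolution.

Counting rules:

* a "fixed difference" total sums component counts over fixed records, so a
  complex of overlapping fixed inversions contributes each hypothesized
  component;
* shared-rearrangement sets intersect canonical names regardless of status
  or sample frequency (frequency is sample metadata, not identity), and
  include sex-linked markers present in both taxa;
* diagnosis ranks registry taxa by matching fixed records, penalized by
  conflicts (fixed records present in exactly one of query and candidate);
  ties are reported explicitly, never silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

VALID_STATUS = ("fixed", "polymorphic", "sex_linked_marker")
VALID_KIND = ("inversion", "transposition", "nucleolar_expression")


class RegistryError(ValueError):
    """Invalid registry content or unresolvable name."""


@dataclass(frozen=True)
class RearrangementRecord:
    """One named rearrangement carried by a taxon.

    ``component_count`` expands complexes of overlapping inversions that are
    registered under one name; ``frequency`` is the fraction of homologues
    carrying the rearrangement in the focal sample (None when the sample
    frequency is not recorded, e.g. for comparison taxa or sex-linked
    expression markers).
    """

    name: str
    arm_id: str
    status: str
    kind: str = "inversion"
    component_count: int = 1
    frequency: Optional[float] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise RegistryError(f"{self.name}: invalid status {self.status!r}")
        if self.kind not in VALID_KIND:
            raise RegistryError(f"{self.name}: invalid kind {self.kind!r}")
        if self.component_count < 1:
            raise RegistryError(f"{self.name}: component_count must be >= 1")
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise RegistryError(f"{self.name}: frequency outside [0, 1]")
        if self.status == "fixed" and self.frequency not in (None, 1.0):
            raise RegistryError(f"{self.name}: fixed records must have frequency 1.0")


@dataclass
class TaxonProfile:
    """A taxon's rearrangement records, optionally with per-arm banding sequences."""

    taxon: str
    records: list[RearrangementRecord] = field(default_factory=list)
    arm_sequences: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegistryError(f"{self.taxon}: duplicate record names {dupes}")

    @property
    def fixed_records(self) -> list[RearrangementRecord]:
        return [r for r in self.records if r.status == "fixed"]

    def record(self, name: str) -> RearrangementRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise RegistryError(f"{self.taxon}: no record named {name!r}")


class AliasTable:
    """Maps alternative rearrangement names onto canonical ones.

    Canonical spellings follow the focal sample's frequency table; aliases
    record historical or per-species names for the same rearrangement.
    """

    def __init__(self, aliases: Optional[dict[str, str]] = None) -> None:
        self._map = dict(aliases or {})

    def canonical(self, name: str) -> str:
        seen = set()
        while name in self._map:
            if name in seen:
                raise RegistryError(f"alias cycle at {name!r}")
            seen.add(name)
            name = self._map[name]
        return name

    def add(self, alias: str, canonical: str) -> None:
        self._map[alias] = canonical

    def items(self):
        return self._map.items()


def fixed_difference_count(profile: TaxonProfile) -> int:
    """Total fixed rearrangements separating a taxon from the group standard.

    Inversions and transpositions count alike; complexes contribute their
    component count.
    """
    return sum(r.component_count for r in profile.fixed_records)


def shared_rearrangements(
    a: TaxonProfile,
    b: TaxonProfile,
    aliases: Optional[AliasTable] = None,
) -> set[str]:
    """Canonical names of rearrangements present in both taxa."""
    aliases = aliases or AliasTable()
    names_a = {aliases.canonical(r.name) for r in a.records}
    names_b = {aliases.canonical(r.name) for r in b.records}
    return names_a & names_b


@dataclass
class DiagnosisMatch:
    taxon: str
    score: int
    matched: int
    conflicts: int
    tied: bool = False


def diagnose_taxon(
    query: TaxonProfile,
    registry: Iterable[TaxonProfile],
    aliases: Optional[AliasTable] = None,
) -> list[DiagnosisMatch]:
    """Rank registry taxa against the query's fixed rearrangements.

    Score = matched fixed records - conflicting fixed records, where a
    conflict is a fixed record present in exactly one of query and
    candidate.  A query holding all and only a taxon's fixed records ranks
    that taxon first with a conflict-free full score.  Equal top scores are
    flagged ``tied`` on every member of the tie.
    """
    registry = list(registry)
    if not registry:
        raise RegistryError("empty registry")
    aliases = aliases or AliasTable()
    q = {aliases.canonical(r.name) for r in query.fixed_records}
    matches = []
    for t in registry:
        tset = {aliases.canonical(r.name) for r in t.fixed_records}
        matched = len(q & tset)
        conflicts = len(q ^ tset)
        matches.append(DiagnosisMatch(taxon=t.taxon, score=matched - conflicts,
                                      matched=matched, conflicts=conflicts))
    matches.sort(key=lambda m: (-m.score, -m.matched, m.taxon))
    for m in matches:
        m.tied = sum(1 for x in matches if (x.score, x.matched) == (m.score, m.matched)) > 1
    return matches
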