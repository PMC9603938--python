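"""Population cytogenetics on per-larva inversion genotypes.

Each larva is scored, per polymorphic inversion, as ``ss`` (standard
homozygote), ``si`` (heterozygote), or ``ii`` (inverted homozygote), plus a
sex and a nucleolar-organizer expression state.  The module estimates
inverted-homologue frequencies, tests Hardy-Weinberg equilibrium by Pearson
chi-square (df = 1, allele frequency estimated from the sample, no
continuity correction), summarizes autosomal heterozygosity per larva, and
classifies nucleolar expression as Y-linked or autosomal.

The HWE eligibility rule — "adequate representation" — is implemented as a
named, overridable policy on the total number of scored larvae (n > 5 by
default): with three genotype classes and one estimated allele frequency,
smaller samples leave the chi-square approximation meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import chi2 as _chi2

SEXES = ("female", "male")
NUCLEOLAR_STATES = ("nucleolate_homozygous", "heterozygous", "anucleolate_homozygous")
GENOTYPES = ("ss", "si", "ii")

#: Minimum number of scored larvae (exclusive) for a HWE test to be reported.
DEFAULT_MIN_CELLS = 5


class PopgenError(ValueError):
    """Invalid genotype data."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one inversion: standard/het/inverted homozygotes."""

    ss: int
    si: int
    ii: int

    def __post_init__(self) -> None:
        if min(self.ss, self.si, self.ii) < 0:
            raise PopgenError("genotype counts must be non-negative")
        if self.n < 1:
            raise PopgenError("at least one scored larva required")

    @property
    def n(self) -> int:
        return self.ss + self.si + self.ii


@dataclass(frozen=True)
class LarvaRecord:
    """One larva: sex, nucleolar-organizer state, and inversion genotypes."""

    larva_id: str
    sex: str
    nucleolar_state: str
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PopgenError(f"{self.larva_id}: invalid sex {self.sex!r}")
        if self.nucleolar_state not in NUCLEOLAR_STATES:
            raise PopgenError(f"{self.larva_id}: invalid nucleolar state {self.nucleolar_state!r}")
        for name, g in self.genotypes.items():
            if g is not None and g not in GENOTYPES:
                raise PopgenError(f"{self.larva_id}: invalid genotype {g!r} for {name}")


@dataclass
class HWEResult:
    chi2: Optional[float]
    df: int
    p: Optional[float]
    expected: Optional[tuple[float, float, float]]
    eligible: bool


def allele_frequency(c: GenotypeCounts) -> float:
    """Fraction of inverted homologues, (2 ii + si) / 2n."""
    return (2 * c.ii + c.si) / (2 * c.n)


def eligibility(c: GenotypeCounts, min_cells: int = DEFAULT_MIN_CELLS) -> bool:
    """Adequate representation for a HWE test: more than ``min_cells`` scored larvae."""
    return c.n > min_cells


def hwe_test(c: GenotypeCounts, min_cells: int = DEFAULT_MIN_CELLS) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    Expected counts are (n q^2, 2 n p q, n p^2) at the sample allele
    frequency; the statistic uses no continuity correction and has one
    degree of freedom (three classes, one estimated frequency).  The exact
    upper-tail probability of chi-square(1) is reported.  Monomorphic
    samples carry no information about mating structure and yield an
    ineligible, statistic-free result.
    """
    q = allele_frequency(c)
    eligible = eligibility(c, min_cells)
    if q in (0.0, 1.0):
        return HWEResult(chi2=None, df=1, p=None, expected=None, eligible=False)
    p = 1.0 - q
    n = c.n
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    stat = sum((o - e) ** 2 / e for o, e in zip((c.ss, c.si, c.ii), expected))
    return HWEResult(chi2=stat, df=1, p=float(_chi2.sf(stat, 1)), expected=expected, eligible=eligible)


def counts_for(table: Iterable[LarvaRecord], inversion: str) -> GenotypeCounts:
    """Tally ss/si/ii for one inversion over a larva table, skipping missing calls."""
    tally = {g: 0 for g in GENOTYPES}
    for rec in table:
        g = rec.genotypes.get(inversion)
        if g is not None:
            tally[g] += 1
    return GenotypeCounts(**tally)


def mean_heterozygosity(table: list[LarvaRecord], autosomal_only: bool = True) -> float:
    """Mean number of heterozygous inversions per larva.

    Counts ``si`` calls over the genotype map (autosomal polymorphisms);
    with ``autosomal_only=False`` a heterozygous nucleolar state adds one.
    """
    if not table:
        raise PopgenError("empty larva table")
    total = 0
    for rec in table:
        total += sum(1 for g in rec.genotypes.values() if g == "si")
        if not autosomal_only and rec.nucleolar_state == "heterozygous":
            total += 1
    return total / len(table)


@dataclass
class SexLinkageResult:
    classification: str  # sex_linked_Y_anucleolate | autosomal | inconsistent
    exceptions: list[str]


def sex_linkage_classify(table: list[LarvaRecord]) -> SexLinkageResult:
    """Classify nucleolar-organizer expression against sex.

    Y-linked suppression predicts every female homozygously nucleolate
    (X0 X0) and every male heterozygous (X0 Y1).  Larvae violating that
    prediction are listed as exceptions; if nucleolar state shows no sex
    association at all (all larvae homozygous nucleolate) the marker is
    classified autosomal.
    """
    if not table:
        raise PopgenError("empty larva table")
    exceptions = []
    for rec in table:
        want = "nucleolate_homozygous" if rec.sex == "female" else "heterozygous"
        if rec.nucleolar_state != want:
            exceptions.append(rec.larva_id)
    if not exceptions:
        return SexLinkageResult("sex_linked_Y_anucleolate", [])
    if all(rec.nucleolar_state == "nucleolate_homozygous" for rec in table):
        return SexLinkageResult("autosomal", exceptions)
    return SexLinkageResult("inconsistent", exceptions)


def frequency_table(
    table: list[LarvaRecord],
    profile,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Per-rearrangement frequency report in the layout of a cytological frequency table.

    One row per registry record: fixed records at frequency 1.00,
    polymorphic records at the sample inverted-homologue frequency with a
    HWE annotation when eligible, sex-linked expression markers flagged
    with ``*``.  ``profile`` is a :class:`cytobarcode.registry.TaxonProfile`.
    """
    rows = []
    known = {r.name for r in profile.records}
    for rec in table:
        for name in rec.genotypes:
            if name not in known:
                raise PopgenError(f"unknown rearrangement {name!r} in genotype table")
    for r in profile.records:
        if r.status == "fixed":
            rows.append({"name": r.name, "status": r.status, "frequency": 1.0,
                         "n": None, "chi2": None, "df": None, "p": None, "hwe_eligible": None})
        elif r.status == "sex_linked_marker":
            rows.append({"name": r.name, "status": r.status, "frequency": None,
                         "n": None, "chi2": None, "df": None, "p": None, "hwe_eligible": None})
        else:
            scored = [rec for rec in table if rec.genotypes.get(r.name) is not None]
            if not scored:
                rows.append({"name": r.name, "status": r.status,
                             "frequency": r.frequency, "n": 0,
                             "chi2": None, "df": None, "p": None, "hwe_eligible": None})
                continue
            c = counts_for(scored, r.name)
            h = hwe_test(c, min_cells)
            rows.append({
                "name": r.name, "status": r.status,
                "frequency": allele_frequency(c), "n": c.n,
                "chi2": h.chi2 if h.eligible else None,
                "df": h.df if h.eligible and h.chi2 is not None else None,
                "p": h.p if h.eligible else None,
                "hwe_eligible": h.eligible,
            })
    return pd.DataFrame(rows)
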