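"""File formats and packaged fixtures.

Formats
-------
Banding file
    TSV, one arm record per line: ``taxon <TAB> arm_id <TAB> fragments``,
    where fragments are a concatenation of single-character labels or a
    comma-separated list of multi-character labels.
Scenario file
    Either multi-line bracket/slash notation (one bracketed inversion per
    line, optional trailing state line) or TSV of ``step, start, end, name``.
Genotype table
    TSV with columns ``larva_id, sex, nucleolar_state`` followed by one
    column per rearrangement holding ``ss``/``si``/``ii``/``NA``.
Distance matrix
    Square PHYLIP-style TSV: first line the taxon count, then one row per
    taxon (name, then distances).

Fixtures
--------
The packaged fixtures encode the focal study's printed data: the IIL
derivation block, the rearrangement-frequency registry with its alias
table, per-arm banding sequences, and the genotype counts behind the HWE
worked example.  Fragment labels for arms other than IIL are schematic
(the group standard defines the identity order by construction); the IIL
labels are the printed a..r fragments.  Fixtures load offline and the
derivation fixture re-verifies on load.
"""

from __future__ import annotations

import csv
from importlib import resources
from io import StringIO
from typing import IO, Iterable, Optional, Union

import numpy as np

from .banding import (
    BandingError,
    BandingSequence,
    InversionStep,
    Scenario,
    apply_inversion,
    parse_banding,
    parse_scenario_notation,
)
from .phylo import DistanceMatrix
from .popgen import GenotypeCounts, LarvaRecord
from .registry import AliasTable, RearrangementRecord, RegistryError, TaxonProfile

STANDARD_TAXON = "annulus-group standard"
FIXTURE_NAMES = (
    "ustulatum_IIL_derivation",
    "table1_registry",
    "aliases",
    "arms",
    "il_us1_counts",
)


def _data_text(filename: str) -> str:
    return (resources.files("cytobarcode") / "data" / filename).read_text()


# ---------------------------------------------------------------------------
# Banding files


def read_banding_file(source: Union[str, IO]) -> dict[tuple[str, str], BandingSequence]:
    """Read a banding TSV into {(taxon, arm_id): BandingSequence}.

    Each arm's label set is taken from the standard taxon's row for that arm
    when present, otherwise from the row itself.
    """
    text = source.read() if hasattr(source, "read") else open(source).read()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[:2] == ["taxon", "arm_id"]:
            continue
        if len(parts) != 3:
            raise BandingError(f"banding file line {lineno}: expected 3 tab-separated fields")
        rows.append((lineno, *[p.strip() for p in parts]))
    out: dict[tuple[str, str], BandingSequence] = {}
    reference: dict[str, frozenset] = {}
    for lineno, taxon, arm, frag in rows:
        if taxon == STANDARD_TAXON:
            seq = BandingSequence(arm_id=arm, fragments=tuple(_split_frags(frag)),
                                  reference_name=STANDARD_TAXON)
            reference[arm] = seq.labels
            out[(taxon, arm)] = seq
    for lineno, taxon, arm, frag in rows:
        if taxon == STANDARD_TAXON:
            continue
        labels = reference.get(arm) or frozenset(_split_frags(frag))
        try:
            out[(taxon, arm)] = parse_banding(frag, labels, arm_id=arm)
        except BandingError as e:
            raise BandingError(f"banding file line {lineno}: {e}") from e
    return out


def _split_frags(frag: str) -> list[str]:
    if "," in frag:
        return [t.strip() for t in frag.split(",") if t.strip()]
    return list(frag.replace("/", "").replace(" ", ""))


def write_banding_file(seqs: dict[tuple[str, str], BandingSequence], handle: IO) -> None:
    handle.write("taxon\tarm_id\tfragments\n")
    for (taxon, arm), seq in seqs.items():
        handle.write(f"{taxon}\t{arm}\t{seq}\n")


# ---------------------------------------------------------------------------
# Scenario files


def read_scenario_file(source: Union[str, IO], arm_id: str = "IIL") -> Scenario:
    """Read a scenario in bracket notation or step TSV (auto-detected)."""
    text = source.read() if hasattr(source, "read") else open(source).read()
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise BandingError("empty scenario file")
    if any("[" in l for l in lines):
        return parse_scenario_notation(lines, arm_id=arm_id)
    raise BandingError(
        "scenario TSV requires a start sequence; use read_scenario_steps for bare steps"
    )


def read_scenario_steps(source: Union[str, IO]) -> list[InversionStep]:
    """Read bare inversion steps from TSV columns step, start, end[, name]."""
    text = source.read() if hasattr(source, "read") else open(source).read()
    steps = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if parts[0] in ("step", "step#"):
            continue
        if len(parts) < 3:
            raise BandingError(f"scenario TSV line {lineno}: expected step, start, end[, name]")
        name = parts[3] if len(parts) > 3 and parts[3] else None
        steps.append(InversionStep(start=int(parts[1]), end=int(parts[2]), name=name))
    return steps


def write_scenario(scenario: Scenario, handle: IO) -> None:
    for line in scenario.render():
        handle.write(line + "\n")


# ---------------------------------------------------------------------------
# Genotype tables


def read_genotype_table(source: Union[str, IO]) -> list[LarvaRecord]:
    text = source.read() if hasattr(source, "read") else open(source).read()
    reader = csv.DictReader(StringIO(text), delimiter="\t")
    fixed_cols = ("larva_id", "sex", "nucleolar_state")
    if reader.fieldnames is None or list(reader.fieldnames[:3]) != list(fixed_cols):
        raise ValueError(f"genotype TSV must start with columns {fixed_cols}")
    inversions = reader.fieldnames[3:]
    out = []
    for row in reader:
        genotypes = {}
        for name in inversions:
            v = (row[name] or "").strip()
            genotypes[name] = None if v in ("", "NA") else v
        out.append(LarvaRecord(larva_id=row["larva_id"], sex=row["sex"],
                               nucleolar_state=row["nucleolar_state"], genotypes=genotypes))
    return out


def write_genotype_table(table: Iterable[LarvaRecord], handle: IO) -> None:
    table = list(table)
    inversions = sorted({name for rec in table for name in rec.genotypes})
    handle.write("\t".join(["larva_id", "sex", "nucleolar_state", *inversions]) + "\n")
    for rec in table:
        vals = [rec.genotypes.get(n) or "NA" for n in inversions]
        handle.write("\t".join([rec.larva_id, rec.sex, rec.nucleolar_state, *vals]) + "\n")


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_matrix(D: DistanceMatrix, handle: IO, decimals: int = 6) -> None:
    handle.write(f"{len(D.ids)}\n")
    for i, t in enumerate(D.ids):
        row = "\t".join(f"{x:.{decimals}f}" for x in D.matrix[i])
        handle.write(f"{t}\t{row}\n")


def read_distance_matrix(source: Union[str, IO]) -> DistanceMatrix:
    text = source.read() if hasattr(source, "read") else open(source).read()
    lines = [l for l in text.splitlines() if l.strip()]
    n = int(lines[0].strip())
    ids, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split("\t")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(ids=ids, matrix=np.array(rows))


# ---------------------------------------------------------------------------
# Registry TSV and fixtures


def _parse_registry_rows(text: str) -> dict[str, TaxonProfile]:
    profiles: dict[str, list[RearrangementRecord]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if parts[0] == "taxon":
            continue
        # pad optional trailing columns (frequency, notes)
        parts += [""] * (8 - len(parts))
        taxon, name, arm, status, kind, comp, freq, notes = parts[:8]
        try:
            rec = RearrangementRecord(
                name=name, arm_id=arm, status=status, kind=kind,
                component_count=int(comp),
                frequency=float(freq) if freq else None,
                notes=notes,
            )
        except (ValueError, RegistryError) as e:
            raise RegistryError(f"registry line {lineno}: {e}") from e
        profiles.setdefault(taxon, []).append(rec)
    return {t: TaxonProfile(taxon=t, records=recs) for t, recs in profiles.items()}


def read_registry(source: Union[str, IO]) -> dict[str, TaxonProfile]:
    text = source.read() if hasattr(source, "read") else open(source).read()
    return _parse_registry_rows(text)


def read_alias_table(source: Union[str, IO]) -> AliasTable:
    text = source.read() if hasattr(source, "read") else open(source).read()
    table = AliasTable()
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "alias\t")):
            continue
        parts = [p.strip() for p in line.split("\t")]
        table.add(parts[0], parts[1])
    return table


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Known names: ``ustulatum_IIL_derivation`` (the 7-step Scenario, verified
    on load), ``table1_registry`` (dict taxon -> TaxonProfile, including the
    record-free group standard), ``aliases`` (AliasTable),
    ``arms`` (dict (taxon, arm_id) -> BandingSequence), and
    ``il_us1_counts`` (GenotypeCounts for the HWE worked example).
    """
    if name == "ustulatum_IIL_derivation":
        scenario = parse_scenario_notation(_data_text("derivation_IIL.txt").splitlines())
        state = scenario.start_seq
        for step in scenario.steps:
            state = apply_inversion(state, step)
        if "".join(state.fragments) != "abcdefghijklmnopqr":
            raise BandingError("packaged derivation fixture does not reach the standard")
        return scenario
    if name == "table1_registry":
        profiles = _parse_registry_rows(_data_text("registry.tsv"))
        profiles[STANDARD_TAXON] = TaxonProfile(taxon=STANDARD_TAXON, records=[])
        return profiles
    if name == "aliases":
        return read_alias_table(StringIO(_data_text("aliases.tsv")))
    if name == "arms":
        return read_banding_file(StringIO(_data_text("arms.tsv")))
    if name == "il_us1_counts":
        lines = [l for l in _data_text("genotype_counts.tsv").splitlines() if l.strip()]
        parts = lines[1].split("\t")
        return GenotypeCounts(ss=int(parts[1]), si=int(parts[2]), ii=int(parts[3]))
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
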