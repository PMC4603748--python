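"""Genotype, phenotype and marker-list file handling.

A microbial genome is represented by its *genotype profile*: the set of
clusters of orthologous groups (COGs/NOGs) that its protein-coding genes map
to.  Phenotypic traits are binary organism-level properties (motile,
thermophilic, obligate intracellular, ...) labelled YES/NO/NA per genome.

File formats (UTF-8; Unix or Windows newlines accepted on read):

* genotype TSV -- one genome per line: ``genome_id TAB cog TAB cog ...``;
  lines starting with ``#`` are comments, blank lines are ignored.
* phenotype TSV -- a header row naming the traits, then one row per genome:
  ``genome_id TAB YES|NO|NA ...`` (one column per trait, case-insensitive).
* marker list -- one COG id per line; nominally the 40 near-universal
  single-copy prokaryotic marker families used to score genome completeness.

COG identifiers are case-sensitive opaque strings (eggNOG mixes ``COG...``
and ``NOG...`` prefixes); no normalization beyond whitespace trimming is
applied, so distinct groups are never silently merged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Label",
    "GenotypeProfile",
    "PhenotypeTable",
    "MarkerSet",
    "GenotypeFormatError",
    "PhenotypeFormatError",
    "MarkerFormatError",
    "load_genotypes",
    "write_genotypes",
    "load_phenotypes",
    "write_phenotypes",
    "load_marker_set",
    "completeness_filter",
]


class GenotypeFormatError(ValueError):
    """Malformed genotype file (missing ids, duplicate genomes, ...)."""


class PhenotypeFormatError(ValueError):
    """Malformed phenotype file (unknown trait, invalid label token, ...)."""


class MarkerFormatError(ValueError):
    """Malformed marker-COG list."""


class Label(enum.Enum):
    """Trait state of one genome. UNKNOWN (``NA``) genomes are retained on
    load but excluded from training and evaluation."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNKNOWN = "UNKNOWN"


_TOKEN_TO_LABEL = {"YES": Label.POSITIVE, "NO": Label.NEGATIVE, "NA": Label.UNKNOWN}
_LABEL_TO_TOKEN = {Label.POSITIVE: "YES", Label.NEGATIVE: "NO", Label.UNKNOWN: "NA"}


@dataclass(frozen=True)
class GenotypeProfile:
    """One genome: its identifier and the set of COGs it contains."""

    genome_id: str
    cogs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genome_id or self.genome_id != self.genome_id.strip():
            raise ValueError(f"invalid genome id {self.genome_id!r}")
        object.__setattr__(self, "cogs", frozenset(self.cogs))
        for cog in self.cogs:
            if not cog or any(ch.isspace() for ch in cog):
                raise ValueError(
                    f"invalid COG id {cog!r} in genome {self.genome_id!r}"
                )


@dataclass
class PhenotypeTable:
    """genome_id -> :class:`Label` map for one named trait."""

    trait_name: str
    labels: dict[str, Label] = field(default_factory=dict)

    def classified(self) -> dict[str, Label]:
        """Labels with UNKNOWN entries dropped."""
        return {g: l for g, l in self.labels.items() if l is not Label.UNKNOWN}

    def count(self, label: Label) -> int:
        return sum(1 for l in self.labels.values() if l is label)


@dataclass(frozen=True)
class MarkerSet:
    """Marker-COG panel with the completeness threshold.

    A genome is deemed complete if at least ``min_present`` of the
    ``marker_cogs`` are present; the field defaults mirror the 39-of-40
    universal prokaryotic marker rule.
    """

    marker_cogs: tuple[str, ...]
    min_present: int = 39

    def __post_init__(self) -> None:
        if len(set(self.marker_cogs)) != len(self.marker_cogs):
            raise ValueError("marker list contains duplicate COG ids")
        if not 0 <= self.min_present <= len(self.marker_cogs):
            raise ValueError(
                f"min_present={self.min_present} outside "
                f"[0, {len(self.marker_cogs)}]"
            )


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping blanks/comments."""
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_genotypes(path: str | Path) -> list[GenotypeProfile]:
    """Read a genotype TSV into a list of profiles, preserving genome order.

    Duplicate COG tokens within one line collapse (set semantics); a
    duplicate genome id across lines is a hard error.
    """
    profiles: list[GenotypeProfile] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        genome_id = fields[0]
        if not genome_id:
            raise GenotypeFormatError(f"line {lineno}: missing genome id")
        if genome_id in seen:
            raise GenotypeFormatError(
                f"line {lineno}: duplicate genome {genome_id!r}"
            )
        seen.add(genome_id)
        cogs = frozenset(f for f in fields[1:] if f)
        profiles.append(GenotypeProfile(genome_id, cogs))
    return profiles


def write_genotypes(profiles: Sequence[GenotypeProfile], path: str | Path) -> None:
    """Write profiles as genotype TSV; COGs in lexicographic order so output
    is bit-reproducible and ``load_genotypes`` round-trips exactly."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p in profiles:
            fh.write("\t".join([p.genome_id, *sorted(p.cogs)]) + "\n")


def load_phenotypes(path: str | Path, trait_name: str) -> PhenotypeTable:
    """Read one trait column from a phenotype TSV.

    The header row names the traits (first column is the genome-id column);
    body tokens YES/NO/NA are matched case-insensitively and map to
    POSITIVE/NEGATIVE/UNKNOWN.
    """
    lines = iter(_data_lines(path))
    try:
        _, header = next(lines)
    except StopIteration:
        raise PhenotypeFormatError(f"{path}: empty phenotype file") from None
    columns = [c.strip() for c in header.split("\t")]
    traits = columns[1:]
    if trait_name not in traits:
        raise PhenotypeFormatError(
            f"trait {trait_name!r} not in file; available traits: "
            + ", ".join(repr(t) for t in traits)
        )
    col = 1 + traits.index(trait_name)
    labels: dict[str, Label] = {}
    for lineno, line in lines:
        fields = [f.strip() for f in line.split("\t")]
        genome_id = fields[0]
        if not genome_id:
            raise PhenotypeFormatError(f"line {lineno}: missing genome id")
        if genome_id in labels:
            raise PhenotypeFormatError(
                f"line {lineno}: duplicate genome {genome_id!r}"
            )
        if len(fields) <= col:
            raise PhenotypeFormatError(
                f"line {lineno}: missing label for trait {trait_name!r}"
            )
        token = fields[col].upper()
        if token not in _TOKEN_TO_LABEL:
            raise PhenotypeFormatError(
                f"invalid label {fields[col]!r} at row {lineno} "
                "(expected YES, NO or NA)"
            )
        labels[genome_id] = _TOKEN_TO_LABEL[token]
    return PhenotypeTable(trait_name=trait_name, labels=labels)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    """Write a single-trait phenotype TSV (genome order = insertion order)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"genome_id\t{table.trait_name}\n")
        for genome_id, label in table.labels.items():
            fh.write(f"{genome_id}\t{_LABEL_TO_TOKEN[label]}\n")


def load_marker_set(path: str | Path, min_present: int | None = None) -> MarkerSet:
    """Read a marker-COG list (one id per line).

    ``min_present`` defaults to ``len(markers) - 1``, i.e. the at-least-39-
    of-40 completeness rule for the canonical 40-marker panel.
    """
    markers: list[str] = []
    for lineno, line in _data_lines(path):
        cog = line.strip()
        if any(ch.isspace() for ch in cog):
            raise MarkerFormatError(f"line {lineno}: invalid marker id {cog!r}")
        if cog in markers:
            raise MarkerFormatError(f"line {lineno}: duplicate marker {cog!r}")
        markers.append(cog)
    if not markers:
        raise MarkerFormatError(f"{path}: empty marker list")
    if min_present is None:
        min_present = len(markers) - 1
    return MarkerSet(marker_cogs=tuple(markers), min_present=min_present)


def completeness_filter(
    profiles: Sequence[GenotypeProfile], markers: MarkerSet
) -> tuple[list[GenotypeProfile], list[str]]:
    """Partition genomes into (kept, rejected ids) by marker completeness.

    A genome is kept iff it carries at least ``markers.min_present`` of the
    marker COGs; input order is preserved on both sides.
    """
    if not markers.marker_cogs:
        raise ValueError("marker set is empty")
    marker_set = frozenset(markers.marker_cogs)
    kept: list[GenotypeProfile] = []
    rejected: list[str] = []
    for p in profiles:
        if len(p.cogs & marker_set) >= markers.min_present:
            kept.append(p)
        else:
            rejected.append(p.genome_id)
    return kept, rejected
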