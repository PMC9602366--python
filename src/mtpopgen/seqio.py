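"""Aligned-sequence input/output and haplotype collapsing.

This module owns the basic data model for the whole package: an
:class:`Alignment` of equal-length DNA sequences, a :class:`PopulationMap`
assigning each sample to a population (with optional pooled groupings such
as ``ES = E + S``), and a :class:`HaplotypeTable` of distinct sequences with
per-population counts.

Coordinates are 0-based internally; every user-facing report and site map
uses 1-based alignment columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SequenceRecord",
    "Alignment",
    "PopulationMap",
    "HaplotypeTable",
    "AlignmentError",
    "FormatError",
    "read_fasta",
    "parse_fasta",
    "write_fasta",
    "read_popmap",
    "mask_sites",
    "collapse_haplotypes",
]

VALID_CHARS = frozenset("ACGTN-")


class FormatError(ValueError):
    """Malformed input file (empty, bad characters, duplicate ids...)."""


class AlignmentError(ValueError):
    """Sequences that do not form a valid alignment."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named DNA sequence over the alphabet ``{A,C,G,T,N,-}``."""

    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FormatError("sample_id must be non-empty")
        if not self.sequence:
            raise FormatError(f"sequence for {self.sample_id!r} is empty")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise FormatError(
                f"record {self.sample_id!r} contains illegal characters: "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length sequence records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample ids: {dupes}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(r.sequence for r in self.records)

    def column(self, j: int) -> str:
        """States of 0-based column *j*, in record order."""
        return "".join(r.sequence[j] for r in self.records)

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        """Alignment restricted to *sample_ids*, keeping record order."""
        wanted = set(sample_ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise KeyError(f"samples not in alignment: {sorted(missing)}")
        return Alignment(
            tuple(r for r in self.records if r.sample_id in wanted)
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(
            tuple(SequenceRecord(i, normalize_sequence(s)) for i, s in pairs)
        )


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class PopulationMap:
    """sample_id -> population label, plus named pooled groupings.

    A grouping pools base labels under a new name, e.g. ``{"ES": ("E", "S")}``.
    Groupings must be disjoint unions of existing base labels.
    """

    assignment: Mapping[str, str]
    groupings: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        base = set(self.assignment.values())
        for name, members in self.groupings.items():
            unknown = set(members) - base
            if unknown:
                raise ValueError(
                    f"grouping {name!r} references unknown labels "
                    f"{sorted(unknown)}"
                )
            if len(set(members)) != len(members):
                raise ValueError(f"grouping {name!r} repeats a label")
        seen: set[str] = set()
        for members in self.groupings.values():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(
                    f"groupings overlap on labels {sorted(overlap)}"
                )
            seen |= set(members)

    @property
    def populations(self) -> tuple[str, ...]:
        """Base population labels in order of first appearance."""
        out: list[str] = []
        for p in self.assignment.values():
            if p not in out:
                out.append(p)
        return tuple(out)

    def members(self, label: str) -> tuple[str, ...]:
        """Sample ids belonging to base label or grouping *label*."""
        labels = set(self.groupings.get(label, (label,)))
        return tuple(s for s, p in self.assignment.items() if p in labels)

    def label_of(self, sample_id: str, *, grouped: bool = False) -> str:
        p = self.assignment[sample_id]
        if grouped:
            for name, members in self.groupings.items():
                if p in members:
                    return name
        return p

    def with_grouping(self, name: str, members: Sequence[str]) -> "PopulationMap":
        g = dict(self.groupings)
        g[name] = tuple(members)
        return PopulationMap(dict(self.assignment), g)

    def pooled(self) -> "PopulationMap":
        """Map with every grouped base label replaced by its group name."""
        assignment = {
            s: self.label_of(s, grouped=True) for s in self.assignment
        }
        return PopulationMap(assignment)

    def validate_against(self, aln: Alignment) -> None:
        missing = set(aln.sample_ids) - set(self.assignment)
        if missing:
            raise ValueError(
                f"samples missing from population map: {sorted(missing)}"
            )


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with per-population counts.

    ``haplotypes`` maps haplotype id (``H1``..``Hk``, numbered by first
    appearance) to its sequence; ``counts`` maps ``(haplotype_id, population)``
    to a positive occurrence count.
    """

    haplotypes: Mapping[str, str]
    counts: Mapping[tuple[str, str], int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_samples(self) -> int:
        return sum(self.counts.values())

    @property
    def populations(self) -> tuple[str, ...]:
        out: list[str] = []
        for _, p in self.counts:
            if p not in out:
                out.append(p)
        return tuple(out)

    def total_count(self, hap_id: str) -> int:
        return sum(c for (h, _), c in self.counts.items() if h == hap_id)

    def frequency_vector(self, population: str | None = None) -> list[int]:
        """Haplotype counts (order H1..Hk) overall or for one population."""
        out = []
        for h in self.haplotypes:
            if population is None:
                out.append(self.total_count(h))
            else:
                out.append(self.counts.get((h, population), 0))
        return [c for c in out if c > 0]


# ---------------------------------------------------------------------------
# Readers / writers


def parse_fasta(text: str) -> Alignment:
    """Parse FASTA text into an :class:`Alignment`."""
    pairs: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                pairs.append((name, "".join(chunks)))
            name = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        else:
            if name is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line)
    if name is not None:
        pairs.append((name, "".join(chunks)))
    if not pairs:
        raise FormatError("empty FASTA input")
    return Alignment.from_pairs(pairs)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are uppercased and U is mapped to T. Raises
    :class:`AlignmentError` on unequal lengths and :class:`FormatError` on
    empty input or illegal characters.
    """
    with open(path) as fh:
        return parse_fasta(fh.read())


def write_fasta(aln: Alignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in aln.records:
            fh.write(f">{r.sample_id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def read_popmap(path) -> PopulationMap:
    """Read a two-column TSV ``sample_id<TAB>population`` map.

    A first line reading ``sample<TAB>population`` (any case, also
    ``sample_id``) is treated as a header. Duplicate sample ids are rejected.
    """
    with open(path) as fh:
        return parse_popmap(fh.read())


def parse_popmap(text: str) -> PopulationMap:
    assignment: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"popmap line {ln}: expected 2 columns")
        sid, pop = parts
        if ln == 1 and sid.lower() in {"sample", "sample_id"}:
            continue
        if sid in assignment:
            raise FormatError(f"duplicate sample id {sid!r} in popmap")
        assignment[sid] = pop
    if not assignment:
        raise FormatError("empty population map")
    return PopulationMap(assignment)


# ---------------------------------------------------------------------------
# Site masking and haplotype collapsing


def mask_sites(
    aln: Alignment, policy: str = "complete_deletion"
) -> tuple[Alignment, list[int]]:
    """Remove alignment columns containing gaps or Ns.

    With ``complete_deletion`` (the default, and currently the only policy
    that modifies the alignment) every column containing ``-`` or ``N`` in
    any sequence is dropped.  Returns the masked alignment and the 1-based
    original coordinates of the retained columns.

    ``pairwise`` leaves the alignment untouched (downstream statistics may
    then skip ambiguous positions pair by pair); the site map is the
    identity.
    """
    if policy == "pairwise":
        return aln, list(range(1, aln.length + 1))
    if policy != "complete_deletion":
        raise ValueError(f"unknown masking policy {policy!r}")
    keep = [
        j
        for j in range(aln.length)
        if not (set(aln.column(j)) & {"-", "N"})
    ]
    if not keep:
        raise AlignmentError("all columns removed by masking")
    if len(keep) == aln.length:
        return aln, [j + 1 for j in keep]
    records = tuple(
        SequenceRecord(r.sample_id, "".join(r.sequence[j] for j in keep))
        for r in aln.records
    )
    return Alignment(records), [j + 1 for j in keep]


def collapse_haplotypes(aln: Alignment, pm: PopulationMap) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes H1..Hk.

    Identity is exact string equality on the analyzed sites.  Haplotypes are
    numbered by order of first appearance in the alignment; counts are
    partitioned by (base) population label.
    """
    pm.validate_against(aln)
    hap_of_seq: dict[str, str] = {}
    haplotypes: dict[str, str] = {}
    counts: dict[tuple[str, str], int] = {}
    for r in aln.records:
        hid = hap_of_seq.get(r.sequence)
        if hid is None:
            hid = f"H{len(haplotypes) + 1}"
            hap_of_seq[r.sequence] = hid
            haplotypes[hid] = r.sequence
        pop = pm.assignment[r.sample_id]
        counts[(hid, pop)] = counts.get((hid, pop), 0) + 1
    return HaplotypeTable(haplotypes, counts)
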