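"""Core domain types shared across the pipeline.

The package analyses uniparental (maternally or paternally inherited) marker
data: mitochondrial control-region sequences and Y-chromosomal STR profiles,
each carried by one individual sampled from a named subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

SEQ_ALPHABET = frozenset("ACGTN-")

#: Sentinel haplogroup label for records whose haplogroup could not be called.
UNKNOWN = "UNKNOWN"


class Marker(str, Enum):
    """Marker class of a sample: mitochondrial DNA or Y chromosome."""

    MT = "MT"
    Y = "Y"


@dataclass(frozen=True)
class AlignedSeq:
    """A control-region haplotype on a fixed-length alignment.

    Bases are over {A, C, G, T, N, -}; 'N' and '-' are treated as missing in
    pairwise comparisons (pairwise deletion).  ``coordinate_note`` records the
    rCRS segments the alignment covers (metadata only; all arithmetic is done
    on alignment columns).
    """

    bases: str
    coordinate_note: str = "rCRS 16024-16385 + 73-340"

    def __post_init__(self) -> None:
        seq = self.bases.upper()
        bad = set(seq) - SEQ_ALPHABET
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        if not seq:
            raise ValueError("empty sequence")
        object.__setattr__(self, "bases", seq)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class StrProfile:
    """An ordered Y-STR repeat-count profile over a declared locus panel."""

    repeats: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        reps = tuple((str(l), int(c)) for l, c in self.repeats)
        if not reps:
            raise ValueError("empty STR profile")
        for locus, count in reps:
            if count < 1:
                raise ValueError(f"non-positive repeat count at {locus}: {count}")
        if len({l for l, _ in reps}) != len(reps):
            raise ValueError("duplicate locus in STR profile")
        object.__setattr__(self, "repeats", reps)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.repeats)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(c for _, c in self.repeats)


#: 16-locus Yfiler panel (the 17-locus kit barring DYS635, the subset shared
#: by both data sources the study design emulates).
YFILER_16 = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS635",
    "GATA_H4", "DYS385",
)[:16]


@dataclass(frozen=True)
class SampleRecord:
    """One individual's marker class, subpopulation, haplogroup and haplotype.

    ``haplotype`` may be ``None`` for frequency-only tables (haplogroup counts
    with no sequence/profile payload).
    """

    sample_id: str
    marker: Marker
    subpop: str
    haplogroup: str = UNKNOWN
    haplotype: AlignedSeq | StrProfile | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.haplotype is not None:
            if self.marker is Marker.MT and not isinstance(self.haplotype, AlignedSeq):
                raise TypeError("MT records carry AlignedSeq haplotypes")
            if self.marker is Marker.Y and not isinstance(self.haplotype, StrProfile):
                raise TypeError("Y records carry StrProfile haplotypes")


@dataclass(frozen=True)
class RegionPartition:
    """Mapping from subpopulation code to region label (e.g. SW / NE)."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty partition")
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.assignment.values():
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    def region_of(self, subpop: str) -> str:
        try:
            return self.assignment[subpop]
        except KeyError:
            raise KeyError(f"subpopulation {subpop!r} not mapped to a region") from None

    def codes(self, region: str) -> tuple[str, ...]:
        return tuple(c for c, r in self.assignment.items() if r == region)

    @classmethod
    def from_sides(cls, side_a: Sequence[str], side_b: Sequence[str],
                   labels: tuple[str, str] = ("SW", "NE")) -> "RegionPartition":
        mapping = {c: labels[0] for c in side_a}
        mapping.update({c: labels[1] for c in side_b})
        return cls(mapping)


def validate_collection(records: Sequence[SampleRecord]) -> None:
    """Check cross-record invariants: unique ids, one marker, equal lengths.

    Raises ``ValueError`` naming the offending sample on violation.
    """
    seen: set[str] = set()
    length: int | None = None
    panel: tuple[str, ...] | None = None
    for rec in records:
        if rec.sample_id in seen:
            raise ValueError(f"duplicate sample_id: {rec.sample_id}")
        seen.add(rec.sample_id)
        if isinstance(rec.haplotype, AlignedSeq):
            if length is None:
                length = len(rec.haplotype)
            elif len(rec.haplotype) != length:
                raise ValueError(
                    f"sequence length mismatch for {rec.sample_id}: "
                    f"{len(rec.haplotype)} != {length}")
        elif isinstance(rec.haplotype, StrProfile):
            if panel is None:
                panel = rec.haplotype.loci
            elif rec.haplotype.loci != panel:
                raise ValueError(f"locus panel mismatch for {rec.sample_id}")
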