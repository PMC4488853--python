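"""Haplogroup label handling and HUNT/FARM cluster assignment.

Mitochondrial haplogroup nomenclature alternates letter and digit runs
("U5b1" -> U, 5, b, 1).  Cluster assignment matches the longest explicit
scheme token that is a whole-token prefix of the label, so an explicit "HV"
token captures "HV1" before the one-letter "H" token can.

The default scheme encodes the Neolithic-transition grouping: haplogroups U
and V are associated with Mesolithic hunter-gatherers (HUNT), H, J, T and K
with Neolithic farmers (FARM); everything else — including the explicitly
listed HV, D, I, N, R, W, X, Z — is OTHER.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .records import UNKNOWN, AlignedSeq, RegionPartition, SampleRecord

_TOKEN_RE = re.compile(r"[A-Za-z]+|[0-9]+|'+")


class Cluster(str, Enum):
    HUNT = "HUNT"
    FARM = "FARM"
    OTHER = "OTHER"


def tokenize(label: str) -> tuple[str, ...]:
    """Split a haplogroup label into letter/digit runs: 'U5b1' -> (U, 5, b, 1)."""
    return tuple(_TOKEN_RE.findall(label))


@dataclass(frozen=True)
class ClusterScheme:
    """Ordered mapping from haplogroup tokens to clusters.

    Matching is longest-explicit-token first and respects token boundaries,
    so row order in a scheme file never affects assignment.
    """

    entries: tuple[tuple[str, Cluster], ...]

    def __post_init__(self) -> None:
        ents = tuple((str(t), Cluster(c)) for t, c in self.entries)
        tokens = [t for t, _ in ents]
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in cluster scheme")
        object.__setattr__(self, "entries", ents)

    def assign(self, label: str) -> Cluster:
        """Cluster of ``label``; UNKNOWN and unmatched labels are OTHER."""
        if not label or label == UNKNOWN:
            return Cluster.OTHER
        label_tokens = tokenize(label)
        best: Cluster | None = None
        best_len = -1
        for token, cluster in self.entries:
            tt = tokenize(token)
            if len(tt) <= len(label_tokens) and label_tokens[: len(tt)] == tt:
                if len(token) > best_len:
                    best_len = len(token)
                    best = cluster
        return best if best is not None else Cluster.OTHER

    def members(self, cluster: Cluster) -> tuple[str, ...]:
        return tuple(t for t, c in self.entries if c == cluster)


def default_scheme() -> ClusterScheme:
    """The packaged HUNT = {U, V} / FARM = {H, J, T, K} scheme."""
    hunt = ["U", "V"]
    farm = ["H", "J", "T", "K"]
    other = ["HV", "D", "I", "N", "R", "W", "X", "Z"]
    return ClusterScheme(
        tuple((t, Cluster.HUNT) for t in hunt)
        + tuple((t, Cluster.FARM) for t in farm)
        + tuple((t, Cluster.OTHER) for t in other)
    )


def assign_cluster(label: str, scheme: ClusterScheme | None = None) -> Cluster:
    """Cluster of a haplogroup label under ``scheme`` (default packaged scheme)."""
    return (scheme or default_scheme()).assign(label)


# ---------------------------------------------------------------------------
# Motif-based classification

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class MotifTable:
    """Haplogroup-defining variants as (alignment position, derived base).

    Positions are 1-based alignment columns.  This is a deliberately light
    classifier: a haplogroup matches when every one of its defining variants
    is present in the sequence.
    """

    motifs: Mapping[str, frozenset[tuple[int, str]]]

    def __post_init__(self) -> None:
        clean = {
            str(h): frozenset((int(p), str(b).upper()) for p, b in var)
            for h, var in dict(self.motifs).items()
        }
        object.__setattr__(self, "motifs", clean)


def classify_by_motif(seq: AlignedSeq, motifs: MotifTable) -> str:
    """Classify a sequence conservatively from a motif table.

    Returns the unique full-matching haplogroup that strictly dominates all
    other full matches by motif-set inclusion.  Zero full matches, or two or
    more incomparable full matches, yield UNASSIGNED — ambiguous sequences
    are excluded rather than guessed.
    """
    L = len(seq)
    matches: dict[str, frozenset[tuple[int, str]]] = {}
    for hap, variants in motifs.motifs.items():
        ok = True
        for pos, base in variants:
            if not (1 <= pos <= L):
                raise ValueError(
                    f"motif position {pos} of {hap} outside alignment of length {L}")
            if seq.bases[pos - 1] != base:
                ok = False
        if ok:
            matches[hap] = variants
    if not matches:
        return UNASSIGNED
    # the winner's motif set must be a strict-or-equal superset of every other
    for hap, var in matches.items():
        if all(other <= var for other in matches.values()):
            return hap
    return UNASSIGNED


# ---------------------------------------------------------------------------
# Cluster counts per region

def cluster_counts(
    records: Sequence[SampleRecord],
    scheme: ClusterScheme,
    partition: RegionPartition,
) -> dict[tuple[str, Cluster], int]:
    """Count records per (region, cluster) cell.

    Every record's subpopulation must be mapped by ``partition``; totals per
    region always satisfy HUNT + FARM + OTHER = region N.
    """
    counts: dict[tuple[str, Cluster], int] = {
        (region, cluster): 0
        for region in partition.regions
        for cluster in Cluster
    }
    for rec in records:
        region = partition.region_of(rec.subpop)
        counts[(region, scheme.assign(rec.haplogroup))] += 1
    return counts


def cluster_totals(counts: Mapping[tuple[str, Cluster], int]) -> dict[Cluster, int]:
    """Marginal cluster totals over all regions."""
    out: dict[Cluster, int] = {c: 0 for c in Cluster}
    for (_, cluster), n in counts.items():
        out[cluster] += n
    return out
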