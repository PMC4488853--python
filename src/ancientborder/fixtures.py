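"""Programmatic label fixtures reproducing the published marginal counts.

These fixtures carry haplogroup labels and regional assignments only (no
sequence payload): they exist so that frequency and cluster arithmetic can be
checked against the published per-haplogroup sample counts without any
external data.
"""

from __future__ import annotations

from itertools import cycle

from .io import FINLAND_NE, FINLAND_SW
from .records import Marker, RegionPartition, SampleRecord

#: Per-region mtDNA haplogroup sample counts (SW, NE).  The residual
#: non-HUNT/non-FARM mass is spread over the explicitly reported OTHER
#: haplogroup labels.
MT_COUNTS = {
    "U": (70, 132),
    "V": (12, 18),
    "H": (133, 143),
    "J": (33, 13),
    "T": (28, 23),
    "K": (24, 22),
}
MT_OTHER = (89, 92)   # SW, NE residuals: 389 and 443 region totals
MT_OTHER_LABELS = ("HV", "D", "I", "N", "R", "W", "X", "Z")

#: Y haplogroup counts as (SW, NE, unknown-location) triples.
Y_COUNTS = {
    "N1c": (115, 162, 12),
    "I1": (170, 58, 14),
    "I2": (2, 6, 2),
    "R1a": (11, 9, 2),
    "Q": (1, 0, 0),
    "R1b": (6, 8, 2),
    "E1b1": (1, 0, 2),
    "J": (0, 0, 1),
}


def table1_samples() -> list[SampleRecord]:
    """832 mtDNA label records with the published SW/NE haplogroup counts.

    Subpopulations cycle deterministically through each region's codes, so
    regional totals (389 SW, 443 NE) are preserved exactly.
    """
    records: list[SampleRecord] = []

    def emit(label: str, n: int, codes: tuple[str, ...], tag: str) -> None:
        pool = cycle(codes)
        for i in range(n):
            records.append(SampleRecord(
                sample_id=f"mt_{tag}_{label}_{i:03d}", marker=Marker.MT,
                subpop=next(pool), haplogroup=label, source="fixture"))

    for label, (n_sw, n_ne) in MT_COUNTS.items():
        emit(label, n_sw, FINLAND_SW, "SW")
        emit(label, n_ne, FINLAND_NE, "NE")
    for region, codes, n_other in (("SW", FINLAND_SW, MT_OTHER[0]),
                                   ("NE", FINLAND_NE, MT_OTHER[1])):
        labels = cycle(MT_OTHER_LABELS)
        pool = cycle(codes)
        for i in range(n_other):
            records.append(SampleRecord(
                sample_id=f"mt_{region}_other_{i:03d}", marker=Marker.MT,
                subpop=next(pool), haplogroup=next(labels), source="fixture"))
    return records


def table2_samples() -> list[SampleRecord]:
    """584 Y label records with the published regional haplogroup counts.

    Region is carried directly as the subpopulation code (SW / NE / UNK for
    the 35 samples of unknown sampling location, which count towards the
    whole-country denominator only).
    """
    records: list[SampleRecord] = []
    for label, (n_sw, n_ne, n_unk) in Y_COUNTS.items():
        for region, n in (("SW", n_sw), ("NE", n_ne), ("UNK", n_unk)):
            for i in range(n):
                records.append(SampleRecord(
                    sample_id=f"y_{region}_{label}_{i:03d}", marker=Marker.Y,
                    subpop=region, haplogroup=label, source="fixture"))
    return records


def table1_partition() -> RegionPartition:
    return RegionPartition.from_sides(FINLAND_SW, FINLAND_NE, labels=("SW", "NE"))


def table2_partition() -> RegionPartition:
    return RegionPartition({"SW": "SW", "NE": "NE", "UNK": "UNK"})
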