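import networkx as nx
import numpy as np
import pytest

from ancientborder import AlignedSeq, Marker, SampleRecord, StrProfile, finland_graph


@pytest.fixture(scope="session")
def graph13() -> nx.Graph:
    return finland_graph()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210621)


@pytest.fixture()
def mt_records() -> list[SampleRecord]:
    seqs = ["ACGTACGTAC", "ACGTACGTAC", "ACGTTCGTAC", "ACGTTCGAAC", "GCGTACGTAC"]
    return [
        SampleRecord(sample_id=f"s{i}", marker=Marker.MT, subpop=sub,
                     haplogroup=hap, haplotype=AlignedSeq(seq), source="unit")
        for i, (sub, hap, seq) in enumerate(
            zip(["TU", "TU", "NC", "NC", "OU"],
                ["U5b1", "H1", "U5a", "J1c2", "HV1"], seqs))
    ]


@pytest.fixture()
def y_records() -> list[SampleRecord]:
    panel = ("DYS19", "DYS390", "DYS391")
    profiles = [(14, 23, 10), (14, 23, 10), (15, 22, 10), (13, 24, 11)]
    return [
        SampleRecord(sample_id=f"y{i}", marker=Marker.Y, subpop=sub,
                     haplogroup=hap,
                     haplotype=StrProfile(tuple(zip(panel, counts))))
        for i, (sub, hap, counts) in enumerate(
            zip(["TU", "NC", "NC", "OU"], ["N1c", "N1c", "I1", "I1"], profiles))
    ]
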