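"""On-disk formats: sample tables, FASTA sequences, adjacency graphs, schemes, reports.

Sample tables are UTF-8 CSV or TSV (dialect auto-detected from the header
line, first row is the header).  MT haplotypes travel either inline in a
``haplotype`` column or in a companion FASTA keyed by sample id; Y-STR
profiles are encoded ``LOCUS=count,LOCUS=count,...``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import yaml
from Bio import SeqIO

from .biasage import AgeContrast
from .borderscan import Bipartition, BorderScanResult, GlmFit
from .diversity import DiversitySummary
from .haplogroups import Cluster, ClusterScheme, MotifTable
from .records import (
    UNKNOWN, AlignedSeq, Marker, RegionPartition, SampleRecord, StrProfile,
    validate_collection,
)

__all__ = [
    "read_samples", "write_samples", "read_adjacency", "write_adjacency",
    "read_scheme", "write_report", "read_motifs", "read_ages",
    "finland_graph", "finland_partition", "packaged_scheme",
]

_REQUIRED_COLUMNS = ("sample_id", "marker", "subpop", "haplogroup")

#: SW/NE assignment of the 13 Finnish subpopulation codes.
FINLAND_SW = ("AL", "TU", "HA", "VA", "UU", "LMO")
FINLAND_NE = ("MI", "CF", "KU", "KY", "NC", "OU", "LA")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_str_profile(text: str) -> StrProfile:
    pairs = []
    for chunk in text.split(","):
        locus, _, count = chunk.partition("=")
        if not count:
            raise ValueError(f"malformed STR haplotype field: {chunk!r}")
        pairs.append((locus.strip(), int(count)))
    return StrProfile(tuple(pairs))


def _format_haplotype(h: AlignedSeq | StrProfile | None) -> str:
    if h is None:
        return ""
    if isinstance(h, AlignedSeq):
        return h.bases
    return ",".join(f"{l}={c}" for l, c in h.repeats)


def read_samples(
    path: str | Path,
    marker: Marker | str,
    fasta: str | Path | None = None,
    known_subpops: Iterable[str] | None = None,
) -> list[SampleRecord]:
    """Read a sample table; returns records in row order.

    Rows with an empty haplogroup are retained with haplogroup UNKNOWN.
    Errors name the offending row or sample: malformed rows, duplicate
    sample ids, sequence-length mismatches and (when ``known_subpops`` is
    given) undeclared subpopulation codes all raise ``ValueError``.
    """
    marker = Marker(marker)
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = [h.strip() for h in (reader.fieldnames or [])]
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        seqs: dict[str, str] = {}
        if fasta is not None:
            seqs = {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(fasta), "fasta")}
        known = set(known_subpops) if known_subpops is not None else None
        records: list[SampleRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = (row["sample_id"] or "").strip()
                if not sid:
                    raise ValueError("empty sample_id")
                subpop = (row["subpop"] or "").strip()
                if known is not None and subpop not in known:
                    raise ValueError(f"undeclared subpopulation code {subpop!r}")
                hap_label = (row["haplogroup"] or "").strip() or UNKNOWN
                row_marker = Marker((row["marker"] or "").strip())
                if row_marker is not marker:
                    raise ValueError(
                        f"marker {row_marker.value} does not match requested "
                        f"{marker.value}")
                payload = (row.get("haplotype") or "").strip()
                haplotype: AlignedSeq | StrProfile | None = None
                if marker is Marker.MT:
                    seq = payload or seqs.get(sid, "")
                    if seq:
                        haplotype = AlignedSeq(seq)
                elif payload:
                    haplotype = _parse_str_profile(payload)
                records.append(SampleRecord(
                    sample_id=sid, marker=marker, subpop=subpop,
                    haplogroup=hap_label, haplotype=haplotype,
                    source=(row.get("source") or "").strip()))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    validate_collection(records)
    return records


def write_samples(
    records: Sequence[SampleRecord],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write a sample table readable back by :func:`read_samples`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["sample_id", "marker", "subpop", "haplogroup",
                         "haplotype", "source"])
        for rec in records:
            writer.writerow([rec.sample_id, rec.marker.value, rec.subpop,
                             rec.haplogroup, _format_haplotype(rec.haplotype),
                             rec.source])


# ---------------------------------------------------------------------------
# Adjacency graphs

def read_adjacency(path: str | Path) -> nx.Graph:
    """Read a subpopulation adjacency graph from a YAML node/edge list.

    The graph must be simple, undirected and connected; self-loops and edges
    naming undeclared codes are rejected.
    """
    with Path(path).open(encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    return graph_from_spec(spec)


def graph_from_spec(spec: Mapping[str, Any]) -> nx.Graph:
    nodes = [str(n) for n in spec.get("nodes", [])]
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate subpopulation codes")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for edge in spec.get("edges", []):
        a, b = (str(x) for x in edge)
        if a == b:
            raise ValueError(f"self-loop on {a}")
        for x in (a, b):
            if x not in g:
                raise ValueError(f"edge references unknown code {x!r}")
        g.add_edge(a, b)
    if len(g) == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        raise ValueError("adjacency graph is disconnected")
    return g


def write_adjacency(graph: nx.Graph, path: str | Path) -> None:
    spec = {"nodes": sorted(graph.nodes),
            "edges": [sorted(e) for e in sorted(map(tuple, map(sorted, graph.edges)))]}
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)


def finland_graph() -> nx.Graph:
    """The packaged 13-subpopulation Finland adjacency graph."""
    ref = resources.files("ancientborder.data") / "finland_adjacency.yaml"
    return graph_from_spec(yaml.safe_load(ref.read_text(encoding="utf-8")))


def finland_partition() -> RegionPartition:
    """The published SW/NE regional assignment of the 13 subpopulations."""
    return RegionPartition.from_sides(FINLAND_SW, FINLAND_NE, labels=("SW", "NE"))


# ---------------------------------------------------------------------------
# Cluster schemes, motifs, ages

def read_scheme(path: str | Path) -> ClusterScheme:
    """Read a TSV cluster scheme: columns token, cluster."""
    entries = []
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.append((row["token"].strip(), Cluster(row["cluster"].strip())))
    return ClusterScheme(tuple(entries))


def packaged_scheme() -> ClusterScheme:
    ref = resources.files("ancientborder.data") / "cluster_scheme.tsv"
    entries = []
    for line in ref.read_text(encoding="utf-8").splitlines()[1:]:
        if line.strip():
            token, cluster = line.split("\t")
            entries.append((token.strip(), Cluster(cluster.strip())))
    return ClusterScheme(tuple(entries))


def read_motifs(path: str | Path) -> MotifTable:
    """Read a TSV motif table: columns haplogroup, variants ('pos:base,pos:base')."""
    motifs: dict[str, set[tuple[int, str]]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            hap = row["haplogroup"].strip()
            if hap in motifs:
                raise ValueError(f"duplicate haplogroup {hap!r} in motif table")
            variants = set()
            for chunk in row["variants"].split(","):
                pos, _, base = chunk.strip().partition(":")
                variants.add((int(pos), base.strip().upper()))
            motifs[hap] = variants
    return MotifTable({h: frozenset(v) for h, v in motifs.items()})


def read_ages(path: str | Path) -> list[AgeContrast]:
    """Read a TSV age-contrast table: columns haplogroup, delta_age (years)."""
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(AgeContrast(haplogroup=row["haplogroup"].strip(),
                                   delta_age=float(row["delta_age"])))
    return out


# ---------------------------------------------------------------------------
# Reports

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Bipartition):  # pragma: no cover - caught by dataclass branch
        return {"side_a": sorted(obj.side_a), "side_b": sorted(obj.side_b)}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if hasattr(obj, "item"):
        return _jsonable(obj.item())
    if isinstance(obj, (Cluster, Marker)):
        return obj.value
    return obj


_TSV_COLUMNS = ("group", "region", "n", "f", "a", "h", "h_sd", "pi", "pi_sd")


def write_report(result: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a summary object to TSV or JSON.

    Numeric fields are written at 12 significant digits, so a write/parse
    round trip is lossless at that precision.  DiversitySummary lists get a
    Table-1/2-shaped TSV; everything else serializes structurally.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(_jsonable(result), fh, indent=1)
            fh.write("\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unknown report format: {format!r}")
    rows: Sequence[Any] = result if isinstance(result, (list, tuple)) else [result]
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        if all(isinstance(r, DiversitySummary) for r in rows):
            writer.writerow(_TSV_COLUMNS)
            for r in rows:
                writer.writerow([
                    r.group, r.region, r.n,
                    *(("" if v is None else f"{v:.12g}")
                      for v in (r.f, r.a, r.h, r.h_sd, r.pi, r.pi_sd))])
        else:
            for r in rows:
                d = _jsonable(r)
                if not isinstance(d, dict):
                    raise ValueError("TSV format needs dataclass-like rows")
                writer.writerow(d.keys())
                writer.writerow([json.dumps(v) if isinstance(v, (dict, list))
                                 else v for v in d.values()])
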