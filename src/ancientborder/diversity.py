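"""Within-group diversity statistics: A, haplotype diversity, nucleotide diversity.

Haplotype diversity uses Nei's (1987) unbiased estimator with the n/(n-1)
small-sample correction and its analytic sampling variance; a sample of n
all-distinct haplotypes therefore has H exactly 1.  Nucleotide diversity is
per comparable site (pairwise deletion of 'N' and '-') with Tajima's (1983)
total variance for its SD.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .haplogroups import Cluster, ClusterScheme
from .records import AlignedSeq, RegionPartition, SampleRecord, StrProfile

__all__ = [
    "DiversitySummary",
    "haplogroup_frequency",
    "haplotype_spectrum",
    "haplotype_diversity",
    "nucleotide_diversity",
    "summarize",
]


@dataclass(frozen=True)
class DiversitySummary:
    """One haplogroup-by-region cell of a diversity table."""

    group: str
    region: str
    n: int
    f: float
    a: int | None = None
    h: float | None = None
    h_sd: float | None = None
    pi: float | None = None
    pi_sd: float | None = None


def haplogroup_frequency(n_group: int, n_total: int) -> float:
    """Haplogroup frequency f = n_group / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_group <= n_total:
        raise ValueError("require 0 <= n_group <= n_total")
    return n_group / n_total


def haplotype_spectrum(
    haplotypes: Iterable[AlignedSeq | StrProfile],
) -> dict[AlignedSeq | StrProfile, int]:
    """Counts per unique haplotype (exact equality; sequences are upper-cased)."""
    counts: Counter = Counter()
    for h in haplotypes:
        counts[h] += 1
    return dict(counts)


def haplotype_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its analytic SD.

    H = n/(n-1) * (1 - sum p_i^2);
    Var(H) = 2/(n(n-1)) * [2(n-2)(sum p_i^3 - (sum p_i^2)^2)
                           + sum p_i^2 - (sum p_i^2)^2].

    Requires n >= 2: the estimator is undefined for a single observation.
    """
    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = np.asarray(counts, dtype=float) / n
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    h = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return h, math.sqrt(max(var, 0.0))


def _pairwise_diff(a: str, b: str) -> tuple[int, int]:
    """(number of differing sites, number of comparable sites), pairwise deletion."""
    diffs = 0
    comparable = 0
    for x, y in zip(a, b):
        if x in "N-" or y in "N-":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    return diffs, comparable


def nucleotide_diversity(
    spectrum: Mapping[AlignedSeq, int],
) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its SD over a haplotype spectrum.

    pi = n/(n-1) * sum_{i<j over classes} 2 p_i p_j (d_ij / L_ij) with d_ij
    the pairwise difference count under pairwise deletion and L_ij the number
    of sites comparable in that pair.  This is exactly the mean of the
    per-pair per-site differences over all n(n-1)/2 individual pairs (within-
    class pairs contribute zero).  SD from Tajima's total variance
    V = (n+1)/(3(n-1)L)pi + 2(n^2+n+3)/(9n(n-1))pi^2, with L the mean
    comparable length over cross-class pairs.
    """
    classes = [(s, c) for s, c in spectrum.items() if c > 0]
    n = sum(c for _, c in classes)
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2")
    lengths = {len(s) for s, _ in classes}
    if len(lengths) != 1:
        raise ValueError(f"sequence length mismatch: {sorted(lengths)}")
    weighted_ratio = 0.0
    weighted_l = 0.0
    weight_sum = 0.0
    for i in range(len(classes)):
        si, ci = classes[i]
        for j in range(i + 1, len(classes)):
            sj, cj = classes[j]
            d, comp = _pairwise_diff(si.bases, sj.bases)
            if comp == 0:
                raise ValueError("a sequence pair shares no comparable sites")
            w = ci * cj
            weighted_ratio += w * (d / comp)
            weighted_l += w * comp
            weight_sum += w
    if weight_sum == 0.0:  # single haplotype class
        l_eff = float(next(iter(lengths)))
        pi = 0.0
    else:
        l_eff = weighted_l / weight_sum
        # mean of d/L over all n(n-1)/2 pairs; within-class pairs add zero
        pi = 2.0 * weighted_ratio / (n * (n - 1))
    var = ((n + 1) / (3.0 * (n - 1) * l_eff) * pi
           + 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1)) * pi ** 2)
    return pi, math.sqrt(max(var, 0.0))


def _group_summary(group: str, region: str, members: list[SampleRecord],
                   n_region_total: int) -> DiversitySummary:
    n = len(members)
    f = haplogroup_frequency(n, n_region_total)
    haps = [r.haplotype for r in members if r.haplotype is not None]
    a = h = h_sd = pi = pi_sd = None
    if haps and len(haps) == n:
        spectrum = haplotype_spectrum(haps)
        a = len(spectrum)
        if n >= 2:
            h, h_sd = haplotype_diversity(list(spectrum.values()))
        if all(isinstance(x, AlignedSeq) for x in haps) and n >= 2:
            pi, pi_sd = nucleotide_diversity(spectrum)  # type: ignore[arg-type]
    return DiversitySummary(group=group, region=region, n=n, f=f,
                            a=a, h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd)


def summarize(
    records: Sequence[SampleRecord],
    scheme: ClusterScheme,
    partition: RegionPartition | None = None,
) -> list[DiversitySummary]:
    """Per-haplogroup and per-cluster diversity table across regions.

    One row per (group, region) with group ranging over observed haplogroup
    labels, the HUNT/FARM cluster aggregates, and ALL; region over ALL plus
    the partition's regions.  Empty (group, region) cells are omitted.
    """
    regions: list[str] = ["ALL"]
    if partition is not None:
        regions += list(partition.regions)

    def in_region(rec: SampleRecord, region: str) -> bool:
        if region == "ALL":
            return True
        assert partition is not None
        return partition.region_of(rec.subpop) == region

    labels: list[str] = []
    for rec in records:
        if rec.haplogroup not in labels:
            labels.append(rec.haplogroup)

    rows: list[DiversitySummary] = []
    for region in regions:
        pool = [r for r in records if in_region(r, region)]
        if not pool:
            continue
        n_total = len(pool)
        for label in labels:
            members = [r for r in pool if r.haplogroup == label]
            if members:
                rows.append(_group_summary(label, region, members, n_total))
        for cluster in (Cluster.HUNT, Cluster.FARM):
            members = [r for r in pool if scheme.assign(r.haplogroup) == cluster]
            if members:
                rows.append(_group_summary(cluster.value, region, members, n_total))
        rows.append(_group_summary("ALL", region, pool, n_total))
    return rows
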