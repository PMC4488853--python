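"""Two-level AMOVA: F_ST / Phi_ST between populations with permutation p-values.

The decomposition follows Excoffier, Smouse & Quattro (1992): squared
molecular distances between haplotypes are partitioned into among- and
within-population variance components.  With 0/1 identity distances the
statistic is the conventional haplotype-frequency F_ST; with sequence
mismatch counts or squared STR repeat differences it is Phi_ST.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .records import AlignedSeq, StrProfile

__all__ = [
    "DistanceModel",
    "AmovaResult",
    "distance_matrix",
    "amova_two_level",
    "permutation_p",
]


class DistanceModel(str, Enum):
    #: d^2 = 0/1 haplotype mismatch -> conventional F_ST
    IDENTITY = "identity"
    #: d^2 = number of differing sites (pairwise deletion) -> sequence Phi_ST
    SEQ_DIFF = "seqdiff"
    #: d^2 = sum over loci of squared repeat difference -> R_ST-style Phi_ST
    STR_SQUARED = "strsq"


@dataclass(frozen=True)
class AmovaResult:
    sigma2_a: float          # among-population variance component
    sigma2_b: float          # within-population variance component
    phi_st: float
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def distance_matrix(
    haplotypes: Sequence[AlignedSeq | StrProfile],
    model: DistanceModel,
) -> np.ndarray:
    """Symmetric matrix of squared molecular distances between haplotypes."""
    n = len(haplotypes)
    kinds = {type(h) for h in haplotypes}
    if len(kinds) > 1:
        raise ValueError("mixed haplotype kinds in one distance matrix")
    d2 = np.zeros((n, n), dtype=float)
    if model is DistanceModel.IDENTITY:
        for i in range(n):
            for j in range(i + 1, n):
                d2[i, j] = d2[j, i] = 0.0 if haplotypes[i] == haplotypes[j] else 1.0
        return d2
    if model is DistanceModel.SEQ_DIFF:
        if kinds and kinds != {AlignedSeq}:
            raise ValueError("SEQ_DIFF requires aligned sequences")
        seqs = [np.frombuffer(h.bases.encode(), dtype="S1") for h in haplotypes]  # type: ignore[union-attr]
        valid = [(s != b"N") & (s != b"-") for s in seqs]
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                d = int(np.sum((seqs[i] != seqs[j]) & both))
                d2[i, j] = d2[j, i] = d
        return d2
    if model is DistanceModel.STR_SQUARED:
        if kinds and kinds != {StrProfile}:
            raise ValueError("STR_SQUARED requires STR profiles")
        mat = np.array([h.counts for h in haplotypes], dtype=float)  # type: ignore[union-attr]
        diff = mat[:, None, :] - mat[None, :, :]
        return np.sum(diff ** 2, axis=-1)
    raise ValueError(f"unknown model: {model}")


def _phi_from_labels(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Variance components (sigma2_a, sigma2_b) and Phi_ST for one labelling."""
    n = d2.shape[0]
    pops, counts = np.unique(labels, return_counts=True)
    p = len(pops)
    if p < 2:
        raise ValueError("need at least two populations")
    if n < 3:
        raise ValueError("need at least three individuals")
    ss_total = float(np.sum(d2)) / 2.0 / n
    ss_within = 0.0
    for pop, n_p in zip(pops, counts):
        idx = np.flatnonzero(labels == pop)
        ss_within += float(np.sum(d2[np.ix_(idx, idx)])) / 2.0 / n_p
    ss_among = ss_total - ss_within
    sigma2_b = ss_within / (n - p)
    n_prime = (n - float(np.sum(counts.astype(float) ** 2)) / n) / (p - 1)
    sigma2_a = (ss_among / (p - 1) - sigma2_b) / n_prime
    denom = sigma2_a + sigma2_b
    phi = sigma2_a / denom if denom != 0.0 else 0.0
    return sigma2_a, sigma2_b, phi


def amova_two_level(d2: np.ndarray, pop_labels: Sequence) -> AmovaResult:
    """Variance components and Phi_ST for a fixed population labelling.

    Negative components are reported as-is (standard unbiased-estimator
    behaviour); Phi_ST may then be slightly negative.
    """
    labels = np.asarray(pop_labels)
    if labels.shape[0] != d2.shape[0]:
        raise ValueError("labels and distance matrix disagree in size")
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 1):
        raise ValueError("empty population")
    sigma2_a, sigma2_b, phi = _phi_from_labels(np.asarray(d2, dtype=float), labels)
    return AmovaResult(sigma2_a=sigma2_a, sigma2_b=sigma2_b, phi_st=phi)


def permutation_p(
    d2: np.ndarray,
    pop_labels: Sequence,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """Permutation p-value for Phi_ST.

    Individuals are shuffled among populations preserving sample sizes;
    p = (1 + #{permuted Phi_ST >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = np.asarray(d2, dtype=float)
    labels = np.asarray(pop_labels)
    obs = amova_two_level(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        _, _, phi = _phi_from_labels(d2, perm)
        if phi >= obs.phi_st:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return AmovaResult(sigma2_a=obs.sigma2_a, sigma2_b=obs.sigma2_b,
                       phi_st=obs.phi_st, p_value=p,
                       n_permutations=n_perm, seed=seed)
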