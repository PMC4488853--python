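"""Correlation of per-haplogroup regional bias with haplogroup age contrasts.

A haplogroup that coalesced earlier in Europe than in the Near East is a
candidate hunter-gatherer-associated lineage; the analysis asks whether such
haplogroups show a stronger north-eastern bias.  Age contrasts are external,
user-supplied estimates — the package ships only a synthetic example table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .borderscan import GlmFit

__all__ = ["AgeContrast", "CorrelationReport", "correlate_bias_age"]


@dataclass(frozen=True)
class AgeContrast:
    """Haplogroup age difference: age(Europe) - age(Near East), in years."""

    haplogroup: str
    delta_age: float


@dataclass(frozen=True)
class CorrelationReport:
    n: int
    r2: float
    rho: float
    p_rho: float
    n_permutations: int
    seed: int | None
    labels: tuple[str, ...]


def _norm_label(label: str) -> str:
    return label.strip().upper()


def correlate_bias_age(
    bias: Sequence[GlmFit],
    ages: Sequence[AgeContrast],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> CorrelationReport:
    """Pearson r^2 and Spearman rho between side bias and age contrast.

    Haplogroups are joined by normalized label (at least three in common).
    rho uses average ranks for ties; its p-value is a two-sided permutation
    test (``n_perm`` shuffles of the age column, +1 correction).
    """
    bias_by_label = {_norm_label(f.label): f.beta for f in bias if f.label}
    age_by_label = {_norm_label(a.haplogroup): a.delta_age for a in ages}
    common = sorted(set(bias_by_label) & set(age_by_label))
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 haplogroups common to both tables, got {len(common)}")
    x = np.array([bias_by_label[l] for l in common])
    y = np.array([age_by_label[l] for l in common])
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_rho = float(stats.spearmanr(x, rng.permutation(y)).statistic)
        if abs(perm_rho) >= abs(rho) - 1e-12:
            count += 1
    p_rho = (1 + count) / (n_perm + 1)
    return CorrelationReport(n=len(common), r2=r * r, rho=rho, p_rho=p_rho,
                             n_permutations=n_perm, seed=seed,
                             labels=tuple(common))
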