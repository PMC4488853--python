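"""Border detection by exhaustive scan over contiguous bipartitions.

The method: split the subpopulation adjacency graph into every two-sided
partition in which both sides induce connected subgraphs, fit a binomial
logistic regression (intercept + side) to the per-subpopulation counts of the
hunter-gatherer (HUNT) and farmer (FARM) haplogroup clusters, and score each
bipartition with the product of the two two-sided Wald p-values,
S = p_HUNT * p_FARM.  The bipartition minimizing S is the inferred border.
As a validity control, S at the optimum is compared against the scores of
random NON-contiguous bipartitions: a genuine geographic cline produces a
contiguous optimum orders of magnitude below that null range.

Convention: side_A is the SW-like side; a negative coefficient means lower
odds of cluster membership in side_A than in side_B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import norm

__all__ = [
    "Bipartition",
    "GlmFit",
    "BorderScanResult",
    "contiguous_bipartitions",
    "is_contiguous",
    "fit_side_glm",
    "scan_border",
    "random_bipartition_null",
    "haplogroup_bias",
]

MAX_EXHAUSTIVE_NODES = 24


@dataclass(frozen=True)
class Bipartition:
    """Unordered two-sided split of subpopulation codes.

    Canonical form: the side containing the lexicographically smallest code
    is ``side_a``.  ``contiguous`` records whether both induced subgraphs are
    connected on the adjacency graph the split was built against.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]
    contiguous: bool | None = None

    def __post_init__(self) -> None:
        a, b = frozenset(self.side_a), frozenset(self.side_b)
        if not a or not b:
            raise ValueError("both sides must be nonempty")
        if a & b:
            raise ValueError("sides overlap")
        if min(b) < min(a):
            a, b = b, a
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @property
    def nodes(self) -> frozenset[str]:
        return self.side_a | self.side_b

    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))

    def oriented(self, side_a: Iterable[str]) -> tuple[frozenset[str], frozenset[str]]:
        """Return (requested side, complement); requested side must equal one side."""
        want = frozenset(side_a)
        if want == self.side_a:
            return self.side_a, self.side_b
        if want == self.side_b:
            return self.side_b, self.side_a
        raise ValueError("requested side is not a side of this bipartition")


@dataclass(frozen=True)
class GlmFit:
    """Logistic-regression side effect: log-odds difference, SE, Wald p."""

    beta: float
    se: float
    p: float
    converged: bool
    label: str = ""

    @property
    def tier(self) -> str:
        """Significance tier: '***' p<0.001, '**' p<0.01, '*' p<0.05, ''. """
        if not self.converged:
            return ""
        for thresh, stars in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < thresh:
                return stars
        return ""


@dataclass(frozen=True)
class BorderScanResult:
    best: Bipartition
    p_hunt: float
    p_farm: float
    product: float
    all_scores: tuple[tuple[Bipartition, float], ...]
    null_products: tuple[float, ...] = ()
    null_bipartitions: tuple[Bipartition, ...] = ()
    seed: int | None = None


# ---------------------------------------------------------------------------
# Bipartition enumeration

def is_contiguous(graph: nx.Graph, split: Bipartition) -> bool:
    """Both sides induce connected subgraphs of ``graph``."""
    return (nx.is_connected(graph.subgraph(split.side_a))
            and nx.is_connected(graph.subgraph(split.side_b)))


def contiguous_bipartitions(graph: nx.Graph, min_side: int = 1) -> list[Bipartition]:
    """All unordered bipartitions with both sides connected and >= min_side nodes.

    Exhaustive over the 2^(n-1) - 1 unordered splits; refuses graphs above
    24 nodes (use a sampling strategy for larger systems).
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n > MAX_EXHAUSTIVE_NODES:
        raise ValueError(
            f"{n} nodes exceeds the exhaustive-scan bound of "
            f"{MAX_EXHAUSTIVE_NODES}; sample bipartitions instead")
    if n < 2:
        raise ValueError("need at least two nodes")
    if not nx.is_connected(graph):
        raise ValueError("adjacency graph must be connected")
    anchor, rest = nodes[0], nodes[1:]
    out: list[Bipartition] = []
    for mask in range(2 ** (n - 1)):
        side_a = {anchor} | {rest[i] for i in range(n - 1) if mask >> i & 1}
        if len(side_a) == n:
            continue
        side_b = set(nodes) - side_a
        if len(side_a) < min_side or len(side_b) < min_side:
            continue
        if (nx.is_connected(graph.subgraph(side_a))
                and nx.is_connected(graph.subgraph(side_b))):
            out.append(Bipartition(frozenset(side_a), frozenset(side_b),
                                   contiguous=True))
    return out


# ---------------------------------------------------------------------------
# Binomial GLM with a single side indicator

def _pooled_2x2(successes: np.ndarray, totals: np.ndarray,
                side: np.ndarray) -> tuple[float, float, float, float]:
    a = float(successes[side].sum())          # successes, side A
    b = float(totals[side].sum() - a)         # failures, side A
    c = float(successes[~side].sum())         # successes, side B
    d = float(totals[~side].sum() - c)        # failures, side B
    return a, b, c, d


def fit_side_glm(
    successes: Sequence[int],
    totals: Sequence[int],
    side_a: Sequence[bool],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GlmFit:
    """Binomial logit GLM of per-subpopulation counts on a side indicator.

    Fits intercept + side by iteratively reweighted least squares; ``beta`` is
    the coefficient of side_A membership (log-odds in side_A minus side_B) and
    ``p`` the two-sided Wald p-value.  Complete separation — zero or full
    successes pooled on either side — is flagged ``converged=False`` with the
    penalized score p = 1.0, so a separated bipartition can never win a scan.
    """
    y = np.asarray(successes, dtype=float)
    m = np.asarray(totals, dtype=float)
    s = np.asarray(side_a, dtype=bool)
    if y.shape != m.shape or y.shape != s.shape:
        raise ValueError("successes, totals and side indicator disagree in length")
    if np.any(y < 0) or np.any(y > m):
        raise ValueError("require 0 <= successes <= totals")
    if s.all() or not s.any():
        raise ValueError("both sides must be represented")

    a, b, c, d = _pooled_2x2(y, m, s)
    if min(a, b, c, d) <= 0.0:
        return GlmFit(beta=math.nan, se=math.nan, p=1.0, converged=False)

    # IRLS on the 2-parameter model, started at the pooled (saturated) MLE.
    X = np.column_stack([np.ones_like(y), s.astype(float)])
    beta = np.array([math.log(c / d), math.log((a / b) / (c / d))])
    cov = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = m * mu * (1.0 - mu)
        xtwx = X.T @ (X * w[:, None])
        score = X.T @ (y - m * mu)
        cov = np.linalg.inv(xtwx)
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        return GlmFit(beta=float(beta[1]), se=math.nan, p=1.0, converged=False)
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se
    p = 2.0 * float(norm.sf(abs(z)))
    return GlmFit(beta=float(beta[1]), se=se, p=max(p, 1e-300), converged=True)


def _score_bipartition(
    split: Bipartition,
    hunt: Mapping[str, int],
    farm: Mapping[str, int],
    totals: Mapping[str, int],
    nodes: Sequence[str],
) -> tuple[float, float]:
    side = np.array([n in split.side_a for n in nodes])
    tot = np.array([totals[n] for n in nodes])
    p_hunt = fit_side_glm(np.array([hunt[n] for n in nodes]), tot, side).p
    p_farm = fit_side_glm(np.array([farm[n] for n in nodes]), tot, side).p
    return p_hunt, p_farm


def score_bipartition(
    split: Bipartition,
    hunt_counts: Mapping[str, int],
    farm_counts: Mapping[str, int],
    totals: Mapping[str, int],
) -> tuple[float, float]:
    """(p_HUNT, p_FARM) for one fixed bipartition."""
    nodes = sorted(totals)
    return _score_bipartition(split, hunt_counts, farm_counts, totals, nodes)


def scan_border(
    hunt_counts: Mapping[str, int],
    farm_counts: Mapping[str, int],
    totals: Mapping[str, int],
    graph: nx.Graph,
    min_side: int = 1,
    null_draws: int = 0,
    seed: int | None = None,
) -> BorderScanResult:
    """Exhaustive contiguous-bipartition scan minimizing S = p_HUNT * p_FARM.

    Ties are broken in favour of the more balanced split (larger smaller
    side), then canonical lexicographic order.  The full score list is kept
    for audit.  With ``null_draws`` > 0, that many random non-contiguous
    bipartitions are scored as the validity null.
    """
    nodes = sorted(graph.nodes)
    for name, table in (("hunt", hunt_counts), ("farm", farm_counts),
                        ("totals", totals)):
        missing = set(nodes) - set(table)
        if missing:
            raise ValueError(f"{name} counts missing for nodes {sorted(missing)}")
    candidates = contiguous_bipartitions(graph, min_side=min_side)
    scored: list[tuple[Bipartition, float, float, float]] = []
    for split in candidates:
        p_h, p_f = _score_bipartition(split, hunt_counts, farm_counts, totals, nodes)
        scored.append((split, p_h, p_f, p_h * p_f))
    best = min(scored, key=lambda t: (t[3], -min(len(t[0].side_a), len(t[0].side_b)),
                                      t[0].key()))
    null_products: tuple[float, ...] = ()
    null_splits: tuple[Bipartition, ...] = ()
    if null_draws > 0:
        null_splits = tuple(_draw_noncontiguous(graph, null_draws, seed))
        null_products = tuple(
            math.prod(_score_bipartition(s, hunt_counts, farm_counts, totals, nodes))
            for s in null_splits)
    return BorderScanResult(
        best=best[0], p_hunt=best[1], p_farm=best[2], product=best[3],
        all_scores=tuple((s, prod) for s, _, _, prod in scored),
        null_products=null_products, null_bipartitions=null_splits, seed=seed)


def _draw_noncontiguous(graph: nx.Graph, k: int,
                        seed: int | None) -> list[Bipartition]:
    nodes = sorted(graph.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    out: list[Bipartition] = []
    attempts = 0
    # a complete (or otherwise all-contiguous) graph makes rejection hopeless
    limit = max(10_000, 1000 * k)
    while len(out) < k:
        attempts += 1
        if attempts > limit:
            raise ValueError(
                "could not draw a non-contiguous bipartition: every split of "
                "this graph appears to be contiguous")
        mask = rng.integers(1, 2 ** n - 1)
        side_a = frozenset(nodes[i] for i in range(n) if mask >> i & 1)
        split = Bipartition(side_a, frozenset(nodes) - side_a, contiguous=None)
        if not is_contiguous(graph, split):
            out.append(Bipartition(split.side_a, split.side_b, contiguous=False))
    return out


def random_bipartition_null(
    graph: nx.Graph,
    hunt_counts: Mapping[str, int],
    farm_counts: Mapping[str, int],
    totals: Mapping[str, int],
    k: int = 10,
    seed: int | None = None,
) -> tuple[tuple[Bipartition, ...], tuple[float, ...]]:
    """Score ``k`` uniform random NON-contiguous bipartitions (validity null)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = sorted(graph.nodes)
    splits = _draw_noncontiguous(graph, k, seed)
    products = tuple(
        math.prod(_score_bipartition(s, hunt_counts, farm_counts, totals, nodes))
        for s in splits)
    return tuple(splits), products


# ---------------------------------------------------------------------------
# Per-haplogroup SW/NE bias

def haplogroup_bias(
    counts: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
    side_a_nodes: Iterable[str],
    min_count: int = 10,
) -> list[GlmFit]:
    """Per-haplogroup side bias on a fixed bipartition.

    ``counts`` maps haplogroup -> {subpop: members}; ``totals`` gives samples
    per subpop.  For each haplogroup with at least ``min_count`` carriers a
    membership-vs-side logit GLM is fitted; beta > 0 means excess in side_A
    (the SW-like side).  Haplogroups below ``min_count`` are skipped.
    """
    side_set = frozenset(side_a_nodes)
    nodes = sorted(totals)
    side = np.array([n in side_set for n in nodes])
    tot = np.array([totals[n] for n in nodes])
    fits: list[GlmFit] = []
    for hap in counts:
        y = np.array([counts[hap].get(n, 0) for n in nodes])
        if y.sum() < min_count:
            continue
        fit = fit_side_glm(y, tot, side)
        fits.append(GlmFit(beta=fit.beta, se=fit.se, p=fit.p,
                           converged=fit.converged, label=hap))
    return fits
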