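import itertools
import math

import numpy as np
import pytest

from ancientborder import (
    AlignedSeq, AmovaResult, DistanceModel, StrProfile, amova_two_level,
    distance_matrix, permutation_p,
)


def _brute_components(d2, labels):
    """Independent sums-of-squares evaluation, straight from the definitions."""
    n = len(labels)
    pops = sorted(set(labels))
    ss_total = sum(d2[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for p in pops:
        idx = [i for i, l in enumerate(labels) if l == p]
        ss_within += sum(d2[i][j] for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    sizes = [labels.count(p) for p in pops]
    P = len(pops)
    s2b = ss_within / (n - P)
    n_prime = (n - sum(k * k for k in sizes) / n) / (P - 1)
    s2a = (ss_among / (P - 1) - s2b) / n_prime
    return s2a, s2b


def test_distance_models():
    a, b = AlignedSeq("ACGTACGT"), AlignedSeq("ACGTTCGA")
    d_id = distance_matrix([a, a, b], DistanceModel.IDENTITY)
    assert d_id[0, 1] == 0 and d_id[0, 2] == 1
    d_seq = distance_matrix([a, b], DistanceModel.SEQ_DIFF)
    assert d_seq[0, 1] == 2
    p1 = StrProfile((("DYS19", 13), ("DYS390", 14)))
    p2 = StrProfile((("DYS19", 15), ("DYS390", 14)))
    d_str = distance_matrix([p1, p2], DistanceModel.STR_SQUARED)
    assert d_str[0, 1] == 4.0
    for d in (d_id, d_seq, d_str):
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


def test_seq_diff_pairwise_deletion():
    a, b = AlignedSeq("ACGTN"), AlignedSeq("ACTT-")
    assert distance_matrix([a, b], DistanceModel.SEQ_DIFF)[0, 1] == 1


def test_mixed_kinds_rejected():
    with pytest.raises(ValueError):
        distance_matrix([AlignedSeq("ACGT"),
                         StrProfile((("DYS19", 13),))], DistanceModel.IDENTITY)


def test_monomorphic_distinct_pops_phi_one():
    haps = [AlignedSeq("AAAA")] * 3 + [AlignedSeq("TTTT")] * 3
    d2 = distance_matrix(haps, DistanceModel.IDENTITY)
    res = amova_two_level(d2, ["A"] * 3 + ["B"] * 3)
    assert res.phi_st == pytest.approx(1.0)


def test_mirrored_composition_phi_slightly_negative():
    # two pops with exactly mirrored composition have SS_among = 0, so the
    # unbiased among-component is -sigma2_b/n' and phi = -1/(n_p - 1) exactly,
    # approaching zero from below as samples grow
    for n_half in (2, 5, 20):
        haps = [AlignedSeq("AAAA"), AlignedSeq("TTTT")] * n_half
        labels = (["A"] * n_half + ["B"] * n_half) * 1
        # interleave so each pop holds n_half/1 of each haplotype
        haps = ([AlignedSeq("AAAA")] * n_half + [AlignedSeq("TTTT")] * n_half) * 2
        labels = ["A"] * 2 * n_half + ["B"] * 2 * n_half
        d2 = distance_matrix(haps, DistanceModel.IDENTITY)
        res = amova_two_level(d2, labels)
        assert res.phi_st == pytest.approx(-1 / (2 * n_half - 1), abs=1e-12)
    assert abs(amova_two_level(d2, labels).phi_st) < 0.03  # large-sample limit


def test_components_match_brute_force(rng):
    for _ in range(10):
        n = int(rng.integers(6, 12))
        d2 = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.integers(0, 9, size=len(iu[0])).astype(float)
        d2[iu] = vals
        d2 += d2.T
        labels = list("AAABBBCCCCCC"[:n])
        res = amova_two_level(d2, labels)
        s2a, s2b = _brute_components(d2.tolist(), labels)
        assert res.sigma2_a == pytest.approx(s2a, abs=1e-10)
        assert res.sigma2_b == pytest.approx(s2b, abs=1e-10)


def test_identity_model_equals_frequency_fst(rng):
    # with 0/1 distances the sums of squares reduce to haplotype-frequency
    # sums: SS_total = (N - sum_k c_k^2 / N)/2 etc.; check that identity
    haps = [AlignedSeq(s) for s in
            rng.choice(["AAAA", "CCCC", "GGGG", "TTTT"], size=14)]
    labels = ["A"] * 7 + ["B"] * 7
    d2 = distance_matrix(haps, DistanceModel.IDENTITY)
    res = amova_two_level(d2, labels)

    def freq_ss(sub):
        counts = {}
        for h in sub:
            counts[h.bases] = counts.get(h.bases, 0) + 1
        m = len(sub)
        return (m - sum(c * c for c in counts.values()) / m) / 2.0

    n = len(haps)
    ss_total = freq_ss(haps)
    ss_within = freq_ss(haps[:7]) + freq_ss(haps[7:])
    s2b = ss_within / (n - 2)
    n_prime = (n - (49 + 49) / n) / 1
    s2a = ((ss_total - ss_within) / 1 - s2b) / n_prime
    assert res.sigma2_a == pytest.approx(s2a, abs=1e-10)
    assert res.phi_st == pytest.approx(s2a / (s2a + s2b), abs=1e-10)


def test_phi_invariant_under_scaling_and_relabeling(rng):
    haps = [AlignedSeq(s) for s in rng.choice(["AAAA", "CCCC", "GGGG"], size=10)]
    labels = ["A"] * 5 + ["B"] * 5
    d2 = distance_matrix(haps, DistanceModel.IDENTITY)
    base = amova_two_level(d2, labels).phi_st
    assert amova_two_level(3.7 * d2, labels).phi_st == pytest.approx(base, abs=1e-12)
    flipped = ["B" if l == "A" else "A" for l in labels]
    assert amova_two_level(d2, flipped).phi_st == pytest.approx(base, abs=1e-12)


def test_permutation_p_deterministic_and_bounded():
    haps = [AlignedSeq("AAAA")] * 4 + [AlignedSeq("TTTT")] * 4
    d2 = distance_matrix(haps, DistanceModel.IDENTITY)
    labels = ["A"] * 4 + ["B"] * 4
    r1 = permutation_p(d2, labels, n_perm=200, seed=11)
    r2 = permutation_p(d2, labels, n_perm=200, seed=11)
    assert r1.p_value == r2.p_value
    # maximal differentiation: only degenerate permutations can tie
    assert r1.p_value <= (1 + 200 * (2 / math.comb(8, 4))) / 201 + 0.05


def test_permutation_p_matches_exhaustive_enumeration():
    haps = [AlignedSeq("AAAA"), AlignedSeq("AAAA"), AlignedSeq("TTTT"),
            AlignedSeq("TTTT"), AlignedSeq("TTTT"), AlignedSeq("CCCC")]
    d2 = distance_matrix(haps, DistanceModel.IDENTITY)
    labels = ["A", "A", "A", "B", "B", "B"]
    obs = amova_two_level(d2, labels).phi_st
    hits = total = 0
    for perm in itertools.permutations(range(6)):
        perm_labels = [labels[i] for i in perm]
        total += 1
        if amova_two_level(d2, perm_labels).phi_st >= obs:
            hits += 1
    exact = hits / total
    mc = permutation_p(d2, labels, n_perm=4000, seed=5).p_value
    se = math.sqrt(exact * (1 - exact) / 4000)
    assert abs(mc - exact) < 4 * se + 1 / 4001


def test_null_permutation_p_approximately_uniform(rng):
    # random labels => p roughly Uniform(0,1): never anti-conservative at any
    # level, and not degenerate.  Ties in the permuted statistic make the
    # test conservative (super-uniform), so the bound is one-sided.
    haps = [AlignedSeq(s) for s in rng.choice(["AAAA", "CCCC", "GGGG", "TTTT",
                                               "AATT"], size=16)]
    d2 = distance_matrix(haps, DistanceModel.IDENTITY)
    pvals = np.sort([
        permutation_p(d2, rng.permutation(["A"] * 8 + ["B"] * 8), n_perm=99,
                      seed=int(rng.integers(2 ** 31))).p_value
        for _ in range(300)])
    grid = np.linspace(0.01, 1, 100)
    ecdf = np.searchsorted(pvals, grid, side="right") / len(pvals)
    assert np.max(ecdf - grid) < 0.06       # no inflated rejection rate
    assert 0.4 < pvals.mean() < 0.75        # not degenerate / over-conservative
    assert ecdf[4] <= 0.05 + 0.04           # type-I control at alpha = 0.05


def test_empty_population_rejected():
    d2 = np.zeros((3, 3))
    with pytest.raises(ValueError):
        amova_two_level(d2, ["A", "A", "A"])
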