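import itertools

import numpy as np
import pandas as pd
import pytest

from evopharm.enrichment import (
    preranked_gsea,
    sample_set_score,
    score_delta,
)
from evopharm.io import ExpressionMatrix, GeneSetCollection, ValidationError


def brute_force_es(genes, stats, member_set, p=1.0):
    """Independent O(N) running-sum oracle: explicit loop, no vectorization."""
    order = sorted(range(len(genes)), key=lambda i: (-stats[i], genes[i]))
    hits = [genes[i] in member_set for i in order]
    n, nh = len(genes), sum(hits)
    norm = sum(abs(stats[i]) ** p for i in order if genes[i] in member_set)
    running, best = 0.0, 0.0
    for i, idx in enumerate(order):
        if hits[i]:
            running += (abs(stats[idx]) ** p / norm) if norm > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def test_singleton_top_gene_gives_unit_es():
    ranked = pd.Series({f"g{i}": 10.0 - i for i in range(10)})
    res = preranked_gsea(ranked, ["g0"], n_perm=50, seed=0)
    assert res.es == 1.0
    assert res.leading_edge == ["g0"]


def test_full_set_is_rejected():
    ranked = pd.Series({"a": 2.0, "b": 1.0})
    with pytest.raises(ValidationError, match="no misses"):
        preranked_gsea(ranked, ["a", "b"], n_perm=10)


def test_empty_intersection_is_rejected():
    ranked = pd.Series({"a": 2.0, "b": 1.0, "c": 0.5})
    with pytest.raises(ValidationError, match="intersect"):
        preranked_gsea(ranked, ["zzz"], n_perm=10)


def test_es_matches_brute_force_oracle(rng):
    for _ in range(1000):
        n = int(rng.integers(5, 51))
        genes = [f"g{i}" for i in range(n)]
        stats = rng.normal(0, 2, size=n)
        k = int(rng.integers(1, n))
        members = set(rng.choice(genes, size=k, replace=False))
        ranked = pd.Series(stats, index=genes)
        res = preranked_gsea(ranked, members, n_perm=5, seed=0)
        assert res.es == pytest.approx(
            brute_force_es(genes, stats, members), abs=1e-12)


def test_equal_stats_exhaustive_subsets_match_oracle():
    genes = [f"g{i}" for i in range(8)]
    stats = [1.0] * 8
    ranked = pd.Series(stats, index=genes)
    for subset in itertools.combinations(genes, 3):
        res = preranked_gsea(ranked, set(subset), n_perm=5, seed=1)
        assert res.es == pytest.approx(
            brute_force_es(genes, list(stats), set(subset)), abs=1e-12)


def test_es_antisymmetry(rng):
    genes = [f"g{i}" for i in range(20)]
    stats = np.sort(rng.normal(size=20))[::-1]
    members = {"g2", "g5", "g11"}
    es_pos = preranked_gsea(pd.Series(stats, index=genes), members, n_perm=5).es
    es_neg = preranked_gsea(pd.Series(-stats[::-1], index=genes[::-1]),
                            members, n_perm=5).es
    assert es_neg == pytest.approx(-es_pos, abs=1e-12)


def test_permutation_p_add_one_smoothing(rng):
    ranked = pd.Series(np.linspace(10, 1, 500),
                       index=[f"g{i}" for i in range(500)])
    res = preranked_gsea(ranked, ["g0"], n_perm=20, seed=0)
    assert res.p_perm >= 1 / 21
    # with this null draw no permuted singleton lands on the top rank
    assert res.p_perm == pytest.approx(1 / 21)
    assert res.nes > 1.0


# ------------------------------------------------------- per-sample scores

def toy_expression(rng, n_genes=100, n_samples=6):
    values = rng.lognormal(1.0, 1.0, size=(n_genes, n_samples))
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    ))


def test_identical_samples_get_identical_scores(rng):
    expr = toy_expression(rng)
    expr.df["S1"] = expr.df["S0"]
    sets = GeneSetCollection({"set1": [f"G{i}" for i in range(10)]})
    scores = sample_set_score(expr, sets)
    assert scores.at["set1", "S0"] == scores.at["set1", "S1"]


def test_monotone_transform_invariance(rng):
    expr = toy_expression(rng)
    sets = GeneSetCollection({"set1": [f"G{i}" for i in range(0, 30, 3)]})
    base = sample_set_score(expr, sets)
    transformed = ExpressionMatrix(np.exp(expr.df / expr.df.max().max() * 3))
    again = sample_set_score(transformed, sets)
    pd.testing.assert_frame_equal(base, again)


def test_boosting_set_genes_increases_score(rng):
    expr = toy_expression(rng)
    members = [f"G{i}" for i in range(10)]
    sets = GeneSetCollection({"set1": members})
    base = sample_set_score(expr, sets).at["set1", "S0"]
    boosted = expr.df.copy()
    boosted.loc[members, "S0"] = boosted["S0"].max() * np.arange(2, 12)
    higher = sample_set_score(ExpressionMatrix(boosted), sets).at["set1", "S0"]
    assert higher > base


def test_fifteen_pathways_scored_without_missing(rng):
    expr = toy_expression(rng, n_genes=100, n_samples=5)
    sets = GeneSetCollection({
        f"pathway{k}": [f"G{(k * 7 + i) % 100}" for i in range(8)]
        for k in range(15)
    })
    scores = sample_set_score(expr, sets)
    assert scores.shape == (15, 5)
    assert scores.notna().all().all()


def test_unexpressed_set_flagged_missing(rng):
    expr = toy_expression(rng, n_genes=20)
    sets = GeneSetCollection({"ghost": ["NOPE1", "NOPE2"]})
    scores = sample_set_score(expr, sets)
    assert scores.isna().all().all()


# ------------------------------------------------------------ score deltas

def paired_scores(shift, sigma, n_pairs, rng):
    cols, vals = [], []
    for i in range(n_pairs):
        cols += [f"P{i}_T1", f"P{i}_T2"]
        base = rng.normal(0.0, 1.0)
        vals += [base + rng.normal(0, sigma),
                 base + shift + rng.normal(0, sigma)]
    scores = pd.DataFrame([vals], index=["set1"], columns=cols)
    pairing = {f"P{i}": (f"P{i}_T1", f"P{i}_T2") for i in range(n_pairs)}
    return scores, pairing


def test_delta_zero_for_equal_scores(rng):
    scores, pairing = paired_scores(0.0, 0.0, 5, rng)
    out = score_delta(scores, pairing)[0]
    assert out.delta == pytest.approx(0.0)


def test_delta_exact_for_noise_free_shift(rng):
    scores, pairing = paired_scores(0.3, 0.0, 6, rng)
    out = score_delta(scores, pairing)[0]
    assert out.delta == pytest.approx(0.3, abs=1e-12)


def test_delta_antisymmetric_under_swap(rng):
    scores, pairing = paired_scores(0.4, 0.2, 8, rng)
    swapped = {p: (b, a) for p, (a, b) in pairing.items()}
    fwd = score_delta(scores, pairing)[0]
    rev = score_delta(scores, swapped)[0]
    assert rev.delta == pytest.approx(-fwd.delta, abs=1e-12)
    assert rev.p == pytest.approx(fwd.p, rel=1e-9)


def test_paired_power_for_planted_shift(rng):
    """Planted +0.3 shift, sigma=0.1, 10 pairs: paired t detects at p<0.01
    in >=95% of 200 simulations."""
    hits = 0
    for _ in range(200):
        scores, pairing = paired_scores(0.3, 0.1, 10, rng)
        if score_delta(scores, pairing)[0].p < 0.01:
            hits += 1
    assert hits >= 190


def test_unmatched_pairing_is_error(rng):
    scores, pairing = paired_scores(0.1, 0.1, 4, rng)
    pairing["P0"] = ("P0_T1", "MISSING")
    with pytest.raises(ValidationError, match="unmatched"):
        score_delta(scores, pairing)
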