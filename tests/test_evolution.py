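import numpy as np
import pytest
from scipy.stats import chi2_contingency

from evopharm.evolution import (
    GENETIC_CODE,
    PresenceRule,
    classify_evolution,
    classify_fusions,
    cds_site_counts,
    codon_site_counts,
    dnds_ratio,
    math_score,
    metastasis_association,
    partition_variants,
)
from evopharm.io import ValidationError

from conftest import make_variant_table


# ------------------------------------------------------------ partitioning

def test_partition_truncal_and_private():
    table = make_variant_table([
        ("P1", "P1_T1", 1, "EGFR", "L858R", 60, 40),
        ("P1", "P1_T2", 2, "EGFR", "L858R", 60, 40),
        ("P1", "P1_T1", 1, "TP53", "R273H", 90, 10),
        ("P1", "P1_T2", 2, "TP53", "R273H", 98, 2),  # alt below min_alt
    ])
    parts = partition_variants(table, PresenceRule(min_alt=3, min_vaf=0.02))
    assert parts["P1"].truncal == {("EGFR", "L858R")}
    assert parts["P1"].private == {(1,): {("TP53", "R273H")}}


def test_partition_skips_single_timepoint_patient():
    table = make_variant_table([("P1", "P1_T1", 1, "EGFR", "L858R", 60, 40)])
    assert partition_variants(table) == {}


# ------------------------------------------------------- evolution classes

CASES = [
    # (rows at T1, rows at T2, pattern, label)
    ([("EGFR", "L858R")], [("EGFR", "L858R")], "1>1", "persistence"),
    ([("EGFR", "L858R")], [("EGFR", "L858R"), ("EGFR", "I744M")], "1>2", "expansion"),
    ([("EGFR", "L858R")], [], "1>0", "extinction"),
    ([], [("EGFR", "L858R")], "0>1", "expansion"),
    ([("EGFR", "L858R")], [("EGFR", "T790M")], "1>1", "complex"),
    ([], [], "0>0", "absent"),
]


@pytest.mark.parametrize("at_t1,at_t2,pattern,label", CASES)
def test_classify_evolution_patterns(at_t1, at_t2, pattern, label):
    rows = [("P1", "P1_T1", 1, "KRAS", "G12D", 60, 40),
            ("P1", "P1_T2", 2, "KRAS", "G12D", 60, 40)]
    rows += [("P1", "P1_T1", 1, g, c, 60, 40) for g, c in at_t1]
    rows += [("P1", "P1_T2", 2, g, c, 60, 40) for g, c in at_t2]
    call = classify_evolution(make_variant_table(rows), "P1", "EGFR")
    assert (call.pattern, call.label) == (pattern, label)


def test_classify_missing_timepoint_names_patient():
    table = make_variant_table([
        ("P1", "P1_T1", 1, "EGFR", "L858R", 60, 40),
        ("P1", "P1_T2", 2, "EGFR", "L858R", 60, 40),
    ])
    with pytest.raises(ValidationError, match="P1"):
        classify_evolution(table, "P1", "EGFR", t_from=1, t_to=3)


def test_presence_rule_applies_to_classification():
    table = make_variant_table([
        ("P1", "P1_T1", 1, "EGFR", "L858R", 60, 40),
        ("P1", "P1_T2", 2, "EGFR", "L858R", 98, 2),  # below min_alt at T2
    ])
    call = classify_evolution(table, "P1", "EGFR")
    assert (call.pattern, call.label) == ("1>0", "extinction")


# -------------------------------------------------------------- MATH score

def test_math_zero_dispersion():
    assert math_score([0.5, 0.5, 0.5]).value == 0.0


def test_math_hand_computed_example():
    # MAD = 1.4826 * 0.2 = 0.29652; / 0.4 * 100 = 74.13
    assert math_score([0.2, 0.4, 0.6]).value == pytest.approx(74.13, abs=1e-9)


def test_math_scale_invariance(rng):
    for _ in range(1000):
        vafs = rng.uniform(0.05, 1.0, size=rng.integers(2, 20))
        scale = rng.uniform(0.1, 1.0)
        a = math_score(vafs).value
        b = math_score(vafs * scale).value
        assert a == pytest.approx(b, rel=1e-9)


def test_math_too_few_variants_flagged():
    score = math_score([0.5])
    assert not score.computable and np.isnan(score.value)


def test_math_rejects_out_of_range_vaf():
    with pytest.raises(ValidationError):
        math_score([0.5, 1.5])


# ------------------------------------------------------------------- dN/dS

def test_codon_ttt_site_split():
    # Phe codon: 8 of 9 single-nt changes are nonsynonymous, 1 synonymous
    n, s = codon_site_counts("TTT")
    assert n == pytest.approx(8 / 3)
    assert s == pytest.approx(1 / 3)


def test_site_counts_sum_to_three_per_codon(rng):
    seq = _random_cds(rng, 100)
    n, s = cds_site_counts(seq)
    assert n + s == pytest.approx(3 * 100, abs=1e-9)


def test_all_synonymous_gives_omega_zero():
    cds = {"c": "CTTCTC"}  # Leu-Leu
    muts = [("c", 2, "T", "G")]  # CTT->CTG, synonymous
    est = dnds_ratio(muts, cds)
    assert est.n_obs == 0 and est.s_obs == 1 and est.omega == 0.0


def test_omega_undefined_without_synonymous_observations():
    cds = {"c": "CTTCTC"}
    est = dnds_ratio([("c", 1, "T", "A")], cds)  # CTT->CAT nonsynonymous
    assert est.omega is None


def test_ref_mismatch_is_reported():
    with pytest.raises(ValidationError, match="ref mismatch"):
        dnds_ratio([("c", 0, "A", "G")], {"c": "CTT"})


def test_stop_codon_cds_rejected():
    with pytest.raises(ValidationError, match="stop"):
        dnds_ratio([], {"c": "TAA"})


def _random_cds(rng, n_codons):
    codons = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
    return "".join(rng.choice(codons, size=n_codons))


def _all_changes(seq):
    for pos in range(len(seq)):
        for base in "ACGT":
            if base != seq[pos]:
                yield pos, seq[pos], base


def test_dnds_neutral_and_selected(rng):
    """Uniform mutations give omega ~ 1; 2:1 nonsynonymous excess gives ~ 2."""
    seq = _random_cds(rng, 300)
    changes = list(_all_changes(seq))
    idx = rng.integers(0, len(changes), size=10000)
    muts = [("c", *changes[i]) for i in idx]
    est = dnds_ratio(muts, {"c": seq})
    assert 0.9 <= est.omega <= 1.1

    # weight nonsynonymous changes 2x
    def is_nonsyn(pos, ref, alt):
        start = (pos // 3) * 3
        codon = seq[start:start + 3]
        mutant = codon[:pos - start] + alt + codon[pos - start + 1:]
        return GENETIC_CODE[mutant] != GENETIC_CODE[codon]

    weights = np.array([2.0 if is_nonsyn(*c) else 1.0 for c in changes])
    weights /= weights.sum()
    idx = rng.choice(len(changes), size=10000, p=weights)
    est2 = dnds_ratio([("c", *changes[i]) for i in idx], {"c": seq})
    assert est2.omega == pytest.approx(2.0, rel=0.1)


# ----------------------------------------------------------------- fusions

@pytest.mark.parametrize("f1,f2,expected", [
    ({"A", "B"}, {"B", "C"}, (1, 1, 1)),
    ({"A"}, {"A"}, (1, 0, 0)),
    (set(), {"A"}, (0, 0, 1)),
])
def test_fusion_examples(f1, f2, expected):
    dyn = classify_fusions({1: f1, 2: f2}, 1, 2)
    assert (dyn.maintained, dyn.vanished, dyn.acquired) == expected


def test_fusion_conservation_identities(rng):
    pool = [f"F{i}" for i in range(20)]
    for _ in range(1000):
        f1 = set(rng.choice(pool, size=rng.integers(0, 10), replace=False))
        f2 = set(rng.choice(pool, size=rng.integers(0, 10), replace=False))
        dyn = classify_fusions({1: f1, 2: f2}, 1, 2)
        assert dyn.maintained + dyn.vanished == len(f1)
        assert dyn.maintained + dyn.acquired == len(f2)


def test_fusion_missing_timepoint():
    with pytest.raises(ValidationError):
        classify_fusions({1: {"A"}}, 1, 2)


# ------------------------------------------------------------- contingency

def test_contingency_closed_form_example():
    res = metastasis_association(10, 20, 20, 10)
    assert res.odds_ratio == pytest.approx(0.25)
    assert res.chi2 == pytest.approx(20 / 3, abs=1e-9)


def test_contingency_independence():
    res = metastasis_association(5, 5, 5, 5)
    assert res.odds_ratio == 1.0 and res.chi2 == 0.0


def test_contingency_infinite_or_flag():
    res = metastasis_association(5, 0, 3, 2)
    assert np.isinf(res.odds_ratio)


def test_contingency_zero_margin_not_computable():
    res = metastasis_association(0, 0, 5, 5)
    assert not res.computable


def test_contingency_matches_scipy(rng):
    for _ in range(100):
        a, b, c, d = rng.integers(1, 50, size=4)
        res = metastasis_association(a, b, c, d)
        chi2, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        assert res.chi2 == pytest.approx(chi2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-12)
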