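import numpy as np
import pandas as pd
import pytest

from evopharm.io import ExpressionMatrix, ValidationError
from evopharm.profiling import (
    QcParams,
    cluster_signature,
    deconvolve,
    qc_filter,
    roc_auc,
    stage_patient,
    stage_patients,
)
from evopharm.simulate import generate_cell_counts, make_reference_profiles, simulate_mixtures


# ------------------------------------------------------------------- QC

def qc_toy_matrix():
    """4 cells engineered to exact mito fractions and feature counts."""
    n_genes = 7500
    genes = [f"MT-{i}" for i in range(10)] + [f"G{i}" for i in range(n_genes - 10)]
    rows = {}

    def make_cell(mito_frac, n_feat):
        # one mito gene plus (n_feat - 1) non-mito genes at one count each;
        # the mito count sets the requested fraction
        counts = np.zeros(n_genes, dtype=int)
        nonmito = n_feat - 1
        counts[10:10 + nonmito] = 1
        counts[0] = max(1, round(mito_frac / (1 - mito_frac) * nonmito))
        return counts

    rows["highmito"] = make_cell(0.40, 3000)
    rows["lowfeat"] = make_cell(0.10, 150)
    rows["highfeat"] = make_cell(0.10, 7000)
    rows["good"] = make_cell(0.10, 3000)
    return pd.DataFrame(rows, index=genes).T, [f"MT-{i}" for i in range(10)]


def test_qc_toy_example_one_survivor():
    counts, mito = qc_toy_matrix()
    kept, report = qc_filter(counts, mito)
    assert list(kept.index) == ["good"]
    assert report.loc["highmito", "rule"] == "mito_fraction"
    assert report.loc["lowfeat", "rule"] == "low_features"
    assert report.loc["highfeat", "rule"] == "high_features"
    assert not report.loc["good", "dropped"]


def test_qc_boundary_cells_kept():
    genes = [f"MT-{i}" for i in range(10)] + [f"G{i}" for i in range(500)]
    counts = np.zeros(510, dtype=int)
    counts[0] = 300           # exactly 30% of 1000 total
    counts[10:209] = 1        # 199 non-mito features -> 200 total features
    counts[10] += 501         # remaining mass
    frame = pd.DataFrame([counts], index=["edge"], columns=genes)
    kept, report = qc_filter(frame, [f"MT-{i}" for i in range(10)])
    assert report.loc["edge", "mito_fraction"] == pytest.approx(0.30)
    assert report.loc["edge", "n_features"] == 200
    assert list(kept.index) == ["edge"]


def test_qc_empty_matrix():
    empty = pd.DataFrame(columns=["MT-1", "G1"]).astype(int)
    kept, report = qc_filter(empty, ["MT-1"])
    assert kept.empty and report.empty


def test_qc_idempotent():
    counts, mito = qc_toy_matrix()
    once, _ = qc_filter(counts, mito)
    twice, _ = qc_filter(once, mito)
    pd.testing.assert_frame_equal(once, twice)


# ------------------------------------------------------ cluster signatures

def test_exclusive_gene_tops_signature(rng):
    counts, labels, mito, _ = generate_cell_counts(
        n_cells=60, n_genes=50, n_clusters=2, markers_per_cluster=5, seed=0)
    counts["EXCL"] = 0
    counts.loc[labels == "cluster1", "EXCL"] = 50
    sig = cluster_signature(counts, labels, "cluster1", top_n=5)
    assert "EXCL" in sig.genes
    row = sig.table[sig.table["gene"] == "EXCL"].iloc[0]
    assert row["log2fc"] > 0


def test_identical_distributions_not_ranked(rng):
    cells = [f"c{i}" for i in range(40)]
    counts = pd.DataFrame(
        rng.poisson(5, size=(40, 30)),
        index=cells, columns=[f"G{i}" for i in range(30)],
    )
    labels = pd.Series(["a"] * 20 + ["b"] * 20, index=cells)
    sig = cluster_signature(counts, labels, "a", top_n=30)
    assert sig.table["p"].min() > 0.001  # nothing spuriously extreme


def test_small_cluster_rejected(rng):
    counts, labels, _, _ = generate_cell_counts(n_cells=10, n_genes=30,
                                                n_clusters=2, seed=1)
    labels.iloc[:] = "big"
    labels.iloc[0] = "tiny"
    with pytest.raises(ValidationError):
        cluster_signature(counts, labels, "tiny")


def test_marker_recovery_over_seeds():
    """>=90% of 30 planted markers appear in the top-50 DEGs (20 seeds)."""
    rates = []
    for seed in range(20):
        counts, labels, _, truth = generate_cell_counts(
            n_cells=240, n_genes=200, n_clusters=3,
            markers_per_cluster=30, seed=seed)
        sig = cluster_signature(counts, labels, "cluster1", top_n=50)
        markers = set(truth["markers"]["cluster1"])
        rates.append(len(markers & set(sig.genes)) / 30)
    assert np.median(rates) >= 0.9


# ----------------------------------------------------------- deconvolution

def test_exact_mixture_recovered():
    ref = make_reference_profiles(2, 30, seed=2)
    bulk_vals = (0.7 * ref.iloc[0] + 0.3 * ref.iloc[1]).to_frame("S1")
    bulk = ExpressionMatrix(bulk_vals)
    est = deconvolve(bulk, ref)
    assert est.loc["S1"].to_numpy() == pytest.approx([0.7, 0.3], abs=1e-9)


def test_pure_sample():
    ref = make_reference_profiles(3, 40, seed=3)
    bulk = ExpressionMatrix(ref.iloc[0].to_frame("S1"))
    est = deconvolve(bulk, ref)
    assert est.loc["S1"].to_numpy() == pytest.approx([1.0, 0.0, 0.0], abs=1e-9)


def test_noisy_mixture_recovery_and_simplex():
    ref = make_reference_profiles(7, 200, seed=4)
    bulk, fractions = simulate_mixtures(ref, 100, seed=5, noise_frac=0.05)
    est = deconvolve(bulk, ref)
    assert np.abs(est.to_numpy() - fractions.to_numpy()).mean() < 0.05
    assert est.sum(axis=1).to_numpy() == pytest.approx(np.ones(100), abs=1e-9)


def test_celltype_permutation_equivariance():
    ref = make_reference_profiles(4, 60, seed=6)
    bulk, _ = simulate_mixtures(ref, 5, seed=7, noise_frac=0.02)
    est = deconvolve(bulk, ref)
    perm = [2, 0, 3, 1]
    est_perm = deconvolve(bulk, ref.iloc[perm])
    pd.testing.assert_frame_equal(est_perm, est[ref.index[perm]])


def test_rank_deficient_reference_rejected():
    ref = make_reference_profiles(2, 30, seed=8)
    ref.iloc[1] = 2 * ref.iloc[0]
    bulk = ExpressionMatrix(ref.iloc[0].to_frame("S1"))
    with pytest.raises(ValidationError, match="rank"):
        deconvolve(bulk, ref)


# ----------------------------------------------------------------- staging

@pytest.mark.parametrize("gen,t790m,osi,stage", [
    (0, False, False, "BASELINE"),
    (1, False, False, "POST1"),
    (2, False, False, "POST1"),
    (1, True, False, "POST2"),
    (1, True, True, "POST3"),   # precedence
    (3, False, False, "POST3"),
])
def test_stage_rules(gen, t790m, osi, stage):
    assert stage_patient(gen, t790m, osi) == stage


def test_contradictory_records_rejected():
    with pytest.raises(ValidationError):
        stage_patient(0, False, True)   # naive + osimertinib
    with pytest.raises(ValidationError):
        stage_patient(0, True, False)   # T790M without TKI


def test_stage_patients_table():
    history = pd.DataFrame({
        "patient_id": ["a", "b"],
        "tki_generation": [0, 1],
        "t790m_status": [False, True],
        "osimertinib_flag": [False, False],
    })
    stages = stage_patients(history)
    assert stages.to_dict() == {"a": "BASELINE", "b": "POST2"}


# -------------------------------------------------------------------- ROC

def test_roc_enumeration_examples():
    idx = list("abcd")
    scores = pd.Series([1, 2, 3, 4], index=idx, dtype=float)
    assert roc_auc(scores, pd.Series([0, 0, 1, 1], index=idx)) == 1.0
    assert roc_auc(scores, pd.Series([1, 0, 1, 0], index=idx)) == 0.25
    assert roc_auc(pd.Series([2, 2, 2, 2], index=idx, dtype=float),
                   pd.Series([0, 1, 0, 1], index=idx)) == 0.5


def test_roc_single_class_rejected():
    idx = list("ab")
    with pytest.raises(ValidationError):
        roc_auc(pd.Series([1.0, 2.0], index=idx), pd.Series([1, 1], index=idx))


def test_roc_complement_identity(rng):
    for _ in range(1000):
        n = int(rng.integers(4, 30))
        scores = rng.permutation(n).astype(float)  # tie-free
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        idx = [f"s{i}" for i in range(n)]
        s = pd.Series(scores, index=idx)
        lab = pd.Series(labels, index=idx)
        assert roc_auc(s, lab) + roc_auc(-s, lab) == pytest.approx(1.0, abs=1e-12)
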